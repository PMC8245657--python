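"""Neoantigen records, per-patient load, and vaccine-candidate selection.

A called nsSNV becomes a neoantigen when (a) at least one of its 8-11mer
mutant peptides is predicted to bind at least one of the patient's HLA
class I alleles with IC50 strictly below threshold (default 500 nM), and
(b) RNA-seq reads cover the mutated position (default: read count >= 1).
"Neoantigen load" is the per-patient count of neoantigens under a
configurable counting unit; the default counts distinct mutant peptide
sequences, with peptide-allele pairs and variants as alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass

from .binding import BindingPrediction, predict_binding
from .caller import SomaticVariant
from .errors import InputError
from .peptides import (DEFAULT_PEPTIDE_LENGTHS, MutantPeptide,
                       enumerate_mutant_peptides, mutant_protein)
from .reference import TranscriptModel

COUNTING_UNITS = ("distinct_peptides", "peptide_allele_pairs", "variants")


@dataclass(frozen=True)
class NeoantigenParams:
    ic50_threshold_nm: float = 500.0
    min_rna_read_count: int = 1
    peptide_lengths: tuple[int, ...] = DEFAULT_PEPTIDE_LENGTHS
    load_counting_unit: str = "distinct_peptides"
    read_count_mode: str = "covering"

    def __post_init__(self):
        if self.ic50_threshold_nm <= 0:
            raise InputError("ic50_threshold_nm must be > 0")
        if self.min_rna_read_count < 0:
            raise InputError("min_rna_read_count must be >= 0")
        if self.load_counting_unit not in COUNTING_UNITS:
            raise InputError(f"unknown counting unit {self.load_counting_unit}")
        if self.read_count_mode not in ("covering", "mutant_supporting"):
            raise InputError(f"unknown read-count mode {self.read_count_mode}")


@dataclass(frozen=True)
class NeoantigenRecord:
    """An expressed nsSNV with its binding peptides passing the IC50 filter."""

    variant: SomaticVariant
    passing_predictions: tuple[BindingPrediction, ...]
    rna_read_count: int

    def __post_init__(self):
        if not self.passing_predictions:
            raise InputError("a NeoantigenRecord requires >= 1 passing prediction")
        if self.rna_read_count < 0:
            raise InputError("rna_read_count must be >= 0")


@dataclass
class PatientProfile:
    """Per-patient summary row consumed by the cohort statistics."""

    patient_id: str
    subtype: str
    tnbc_flag: bool
    n_exonic: int
    n_nssnv: int
    n_predicted_binders: int
    neoantigen_load: int
    immune_expression: dict[str, float]

    def __post_init__(self):
        if self.n_nssnv > self.n_exonic:
            raise InputError(f"{self.patient_id}: n_nssnv > n_exonic")
        if self.neoantigen_load < 0:
            raise InputError(f"{self.patient_id}: negative load")


def filter_binders(predictions: list[BindingPrediction],
                   params: NeoantigenParams) -> list[BindingPrediction]:
    """Keep exactly the predictions with IC50 strictly below the threshold."""
    return [p for p in predictions if p.ic50_nm < params.ic50_threshold_nm]


def mutation_read_count(counts: dict, variant: SomaticVariant,
                        mode: str = "covering") -> int:
    """RNA reads at the mutated position; absent variants count 0.

    Table values are either a bare covering count or a (covering,
    mutant_supporting) pair; ``mode`` selects which is returned.
    """
    key = (variant.transcript_id, variant.cds_position)
    value = counts.get(key, 0)
    if isinstance(value, tuple):
        covering, mutant = value
    else:
        covering = mutant = value
    chosen = covering if mode == "covering" else mutant
    if chosen < 0:
        raise InputError(f"negative RNA read count for {key}")
    return int(chosen)


def build_neoantigen_records(nssnvs: list[SomaticVariant],
                             models: dict[str, TranscriptModel],
                             hla_alleles: list[str],
                             predictor,
                             rna_counts: dict,
                             params: NeoantigenParams = NeoantigenParams()
                             ) -> tuple[list[NeoantigenRecord], int]:
    """Per-variant neoantigen records plus the IC50-only binder count.

    Returns ``(records, n_predicted_binders)`` where the second value is
    the number of distinct mutant peptide sequences passing the IC50
    filter for >= 1 allele regardless of expression (the "predicted
    neoantigens" quantity, before the RNA criterion defines the load).
    """
    records: list[NeoantigenRecord] = []
    binder_sequences: set[str] = set()
    unique_alleles = list(dict.fromkeys(hla_alleles))
    fast = hasattr(predictor, "ic50_many")
    pid = getattr(predictor, "predictor_id", "custom")
    for variant in nssnvs:
        if variant.mutation_class != "nsSNV":
            raise InputError("build_neoantigen_records expects nsSNVs only")
        model = models[variant.transcript_id]
        protein, pos = mutant_protein(model, variant)
        peptides = enumerate_mutant_peptides(
            protein, pos, params.peptide_lengths,
            wildtype_protein=model.protein, source_variant=variant)
        if fast:
            # vectorized scoring: filter on IC50 arrays, build prediction
            # objects only for the passing few
            passing = []
            by_len: dict[int, list[MutantPeptide]] = {}
            for p in peptides:
                by_len.setdefault(p.length, []).append(p)
            for allele in unique_alleles:
                for group in by_len.values():
                    ic50s = predictor.ic50_many(
                        [p.sequence for p in group], allele)
                    for i in (ic50s < params.ic50_threshold_nm).nonzero()[0]:
                        passing.append(BindingPrediction(
                            group[i], allele, float(ic50s[i]), pid))
        else:
            predictions, _missing = predict_binding(peptides, unique_alleles,
                                                    predictor)
            passing = filter_binders(predictions, params)
        if not passing:
            continue
        binder_sequences.update(p.peptide.sequence for p in passing)
        count = mutation_read_count(rna_counts, variant,
                                    params.read_count_mode)
        if count >= params.min_rna_read_count:
            records.append(NeoantigenRecord(variant, tuple(passing), count))
    return records, len(binder_sequences)


def neoantigen_load(records: list[NeoantigenRecord],
                    params: NeoantigenParams = NeoantigenParams()) -> int:
    """Count neoantigens under the configured unit.

    distinct_peptides (default): distinct mutant peptide sequences passing
    IC50 for >= 1 patient allele whose source variant is expressed;
    peptide_allele_pairs: distinct (sequence, allele) pairs; variants:
    number of qualifying nsSNVs.
    """
    if params.load_counting_unit == "variants":
        return len(records)
    if params.load_counting_unit == "peptide_allele_pairs":
        pairs = {(p.peptide.sequence, p.hla_allele)
                 for r in records for p in r.passing_predictions}
        return len(pairs)
    seqs = {p.peptide.sequence
            for r in records for p in r.passing_predictions}
    return len(seqs)


@dataclass(frozen=True)
class VaccineCandidate:
    sequence: str
    wildtype_sequence: str
    ic50_nm: float
    hla_allele: str
    rna_read_count: int
    variant: SomaticVariant


def select_vaccine_candidates(records: list[NeoantigenRecord],
                              allele: str,
                              min_read_count: int = 2,
                              top_k: int = 10,
                              patient_alleles: list[str] | None = None
                              ) -> list[VaccineCandidate]:
    """Rank peptide candidates for one allele, as for vaccine synthesis.

    Candidates are peptides from records meeting the (stricter) read-count
    threshold whose prediction targets the given allele, ranked by
    ascending IC50 with lexicographic peptide order breaking ties; at most
    ``top_k`` are returned with wildtype counterparts attached.
    """
    known = set(patient_alleles) if patient_alleles is not None else {
        p.hla_allele for r in records for p in r.passing_predictions}
    if allele not in known:
        raise InputError(f"allele {allele} not among patient alleles")
    best: dict[str, VaccineCandidate] = {}
    for rec in records:
        if rec.rna_read_count < min_read_count:
            continue
        for pred in rec.passing_predictions:
            if pred.hla_allele != allele:
                continue
            seq = pred.peptide.sequence
            cand = VaccineCandidate(
                sequence=seq,
                wildtype_sequence=pred.peptide.wildtype_sequence,
                ic50_nm=pred.ic50_nm,
                hla_allele=allele,
                rna_read_count=rec.rna_read_count,
                variant=rec.variant,
            )
            if seq not in best or pred.ic50_nm < best[seq].ic50_nm:
                best[seq] = cand
    ranked = sorted(best.values(), key=lambda c: (c.ic50_nm, c.sequence))
    return ranked[:top_k]
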