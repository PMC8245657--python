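"""Synthetic tumor/normal cohort generation with known ground truth.

The study's sequencing data are not public, so every downstream stage is
exercised on simulated cohorts that mirror the study's structure: 31
patients, 13 triple-negative (TNBC), per-patient exonic mutation burdens
dominated by nsSNVs (~62%), higher burden in TNBC, tumor/normal read
depths around 100x with sequencing error, and zero-inflated RNA coverage
of mutated positions so the expression filter has real attrition.

Ground truth is explicit: each patient records its true somatic events,
its allele-count table (including germline-heterozygous and pure-noise
decoy sites for specificity testing) and its RNA read counts, so caller
sensitivity/specificity and load computations can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .caller import AlleleCountSite, DELETION_TOKEN, INSERTION_TOKEN
from .errors import InputError, ParameterError
from .reference import BASES, TranscriptModel
from Bio.Seq import Seq

DEFAULT_CLASS_MIX = {
    "nsSNV": 0.624,
    "sSNV": 0.250,
    "stopgain": 0.040,
    "stoploss": 0.003,
    "splicing": 0.033,
    "INDEL": 0.050,
}

#: HLA pools the genotype sampler draws from (asset alleles).
HLA_POOLS = {
    "A": ("HLA-A*01:01", "HLA-A*02:01", "HLA-A*02:06", "HLA-A*24:02"),
    "B": ("HLA-B*07:02", "HLA-B*35:01", "HLA-B*40:02"),
    "C": ("HLA-C*04:01", "HLA-C*07:02", "HLA-C*12:02"),
}


@dataclass(frozen=True)
class GroundTruthVariant:
    """A spiked somatic event with its designed class and allele fraction."""

    transcript_id: str
    cds_position: int
    ref_base: str
    alt_base: str
    mutation_class: str
    vaf: float

    @property
    def key(self) -> tuple[str, int]:
        return (self.transcript_id, self.cds_position)


@dataclass
class SyntheticPatient:
    patient_id: str
    subtype: str                                  # "TNBC" or "non-TNBC"
    true_variants: list[GroundTruthVariant]
    allele_counts: list[AlleleCountSite]
    rna_read_counts: dict[tuple[str, int], int]
    hla_alleles: list[str]
    #: ground-truth labels for non-somatic sites: key -> "germline" | "noise"
    decoy_kinds: dict[tuple[str, int], str] = field(default_factory=dict)

    def __post_init__(self):
        keys = {v.key for v in self.true_variants}
        if not set(self.rna_read_counts) <= keys:
            raise InputError(f"{self.patient_id}: RNA counts for unknown variants")
        site_keys = [(s.transcript_id, s.cds_position) for s in self.allele_counts]
        if not keys <= set(site_keys):
            raise InputError(f"{self.patient_id}: true variant without a site")


@dataclass(frozen=True)
class SimulationParams:
    """Cohort-generator knobs; defaults echo the study's scale."""

    n_patients: int = 31
    tnbc_fraction: float = 13 / 31
    mean_burden: float = 70.0          # expected exonic mutations, non-TNBC
    tnbc_burden_multiplier: float = 2.0
    burden_dispersion: float = 5.0     # negative-binomial size parameter
    tumor_depth: float = 100.0
    normal_depth: float = 100.0
    vaf_alpha: float = 2.0             # Beta(alpha, beta) truncated to
    vaf_beta: float = 5.0              # [vaf_min, 1] per-variant tumor VAF
    vaf_min: float = 0.05
    sequencing_error_rate: float = 1e-3
    rna_zero_inflation: float = 0.5    # P(structural zero) per variant
    rna_mean_count: float = 5.0        # Poisson mean for expressed variants
    class_mix: tuple[tuple[str, float], ...] = tuple(DEFAULT_CLASS_MIX.items())
    n_germline_decoys: int = 30
    n_noise_decoys: int = 30
    seed: int = 0

    def __post_init__(self):
        for name in ("tnbc_fraction", "sequencing_error_rate",
                     "rna_zero_inflation", "vaf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0,1]")
        if self.tumor_depth < 1 or self.normal_depth < 1:
            raise ParameterError("depths must be >= 1")
        if self.n_patients < 1:
            raise ParameterError("n_patients must be >= 1")
        if self.mean_burden < 0:
            raise ParameterError("mean_burden must be >= 0")
        if self.tnbc_burden_multiplier < 1:
            raise ParameterError("tnbc_burden_multiplier must be >= 1")
        total = sum(f for _, f in self.class_mix)
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"class mix sums to {total}, expected 1")
        mix = dict(self.class_mix)
        if set(mix) - set(DEFAULT_CLASS_MIX):
            raise ParameterError(f"unknown mutation classes in mix: "
                                 f"{sorted(set(mix) - set(DEFAULT_CLASS_MIX))}")
        # canonical class order so equal mixes compare equal however given
        object.__setattr__(self, "class_mix",
                           tuple((c, mix[c]) for c in DEFAULT_CLASS_MIX
                                 if c in mix))


def _truncated_beta(rng: np.random.Generator, a: float, b: float,
                    lo: float) -> float:
    while True:
        v = rng.beta(a, b)
        if v >= lo:
            return float(v)


def _negative_binomial(rng: np.random.Generator, mean: float,
                       size_param: float) -> int:
    if mean <= 0:
        return 0
    p = size_param / (size_param + mean)
    return int(rng.negative_binomial(size_param, p))


def _snv_class(model: TranscriptModel, pos: int, alt: str) -> str:
    """Codon-level class of an SNV outside the splice window."""
    ci, off = (pos - 1) // 3, (pos - 1) % 3
    codon = model.cds_sequence[ci * 3: ci * 3 + 3]
    mut = codon[:off] + alt + codon[off + 1:]
    ref_aa, alt_aa = str(Seq(codon).translate()), str(Seq(mut).translate())
    if ref_aa != "*" and alt_aa == "*":
        return "stopgain"
    if ref_aa == "*" and alt_aa != "*":
        return "stoploss"
    return "sSNV" if ref_aa == alt_aa else "nsSNV"


def _draw_variant(rng: np.random.Generator, reference: list[TranscriptModel],
                  spliceable: list[int], wanted: str,
                  used: set[tuple[str, int]]
                  ) -> tuple[str, int, str, str, str]:
    """Rejection-sample (transcript, position, ref, alt, class) of the wanted
    class; splicing falls back to nsSNV if no transcript has junctions."""
    if wanted == "splicing" and not spliceable:
        wanted = "nsSNV"
    for _ in range(10000):
        if wanted == "splicing":
            model = reference[spliceable[rng.integers(len(spliceable))]]
            window = sorted(model.splice_window_positions())
            pos = int(window[rng.integers(len(window))])
        else:
            model = reference[rng.integers(len(reference))]
            if wanted == "stoploss":
                pos = len(model.cds_sequence) - 2 + int(rng.integers(3))
            else:
                pos = int(rng.integers(1, len(model.cds_sequence) - 2))
            if pos in model.splice_window_positions():
                continue
        if (model.gene_symbol, pos) in used:
            continue
        ref = model.cds_sequence[pos - 1]
        if wanted == "INDEL":
            alt = INSERTION_TOKEN if rng.random() < 0.5 else DELETION_TOKEN
            return model.gene_symbol, pos, ref, alt, wanted
        alt = BASES[rng.integers(4)]
        if alt == ref:
            continue
        if wanted == "splicing":
            return model.gene_symbol, pos, ref, alt, wanted
        if _snv_class(model, pos, alt) == wanted:
            return model.gene_symbol, pos, ref, alt, wanted
    raise ParameterError(f"could not place a {wanted} variant "
                         "(reference too small?)")


def _read_counts(rng: np.random.Generator, mean_depth: float,
                 alt_prob: float) -> tuple[int, int]:
    depth = max(1, int(rng.poisson(mean_depth)))
    alt = int(rng.binomial(depth, min(1.0, alt_prob)))
    return depth - alt, alt


def simulate_patient(rng: np.random.Generator,
                     reference: list[TranscriptModel],
                     params: SimulationParams,
                     patient_id: str, subtype: str) -> SyntheticPatient:
    spliceable = [i for i, m in enumerate(reference) if m.exon_boundaries]
    mult = params.tnbc_burden_multiplier if subtype == "TNBC" else 1.0
    burden = _negative_binomial(rng, params.mean_burden * mult,
                                params.burden_dispersion)
    classes = [c for c, _ in params.class_mix]
    probs = np.array([f for _, f in params.class_mix])
    err = params.sequencing_error_rate

    used: set[tuple[str, int]] = set()
    variants: list[GroundTruthVariant] = []
    sites: list[AlleleCountSite] = []
    for _ in range(burden):
        wanted = classes[rng.choice(len(classes), p=probs)]
        tid, pos, ref, alt, klass = _draw_variant(rng, reference, spliceable,
                                                  wanted, used)
        used.add((tid, pos))
        vaf = _truncated_beta(rng, params.vaf_alpha, params.vaf_beta,
                              params.vaf_min)
        variants.append(GroundTruthVariant(tid, pos, ref, alt, klass, vaf))
        t_ref, t_alt = _read_counts(rng, params.tumor_depth, vaf + err)
        n_ref, n_alt = _read_counts(rng, params.normal_depth, err)
        sites.append(AlleleCountSite(tid, pos, ref, alt,
                                     t_ref, t_alt, n_ref, n_alt))

    # decoys: germline heterozygous (VAF ~ 0.5 in both samples) and pure noise
    decoy_kinds: dict[tuple[str, int], str] = {}
    for kind, n_decoys, alt_prob_t, alt_prob_n in (
            ("germline", params.n_germline_decoys, 0.5, 0.5),
            ("noise", params.n_noise_decoys, err, err)):
        for _ in range(n_decoys):
            for _ in range(1000):
                model = reference[rng.integers(len(reference))]
                pos = int(rng.integers(1, len(model.cds_sequence) + 1))
                if (model.gene_symbol, pos) not in used:
                    break
            used.add((model.gene_symbol, pos))
            ref = model.cds_sequence[pos - 1]
            alt = BASES[(BASES.index(ref) + 1 + int(rng.integers(3))) % 4]
            t_ref, t_alt = _read_counts(rng, params.tumor_depth, alt_prob_t)
            n_ref, n_alt = _read_counts(rng, params.normal_depth, alt_prob_n)
            sites.append(AlleleCountSite(model.gene_symbol, pos, ref, alt,
                                         t_ref, t_alt, n_ref, n_alt))
            decoy_kinds[(model.gene_symbol, pos)] = kind

    rna = {}
    for v in variants:
        expressed = rng.random() >= params.rna_zero_inflation
        rna[v.key] = int(rng.poisson(params.rna_mean_count)) if expressed else 0

    hla = []
    for locus in ("A", "B", "C"):
        pool = HLA_POOLS[locus]
        hla += [pool[rng.integers(len(pool))] for _ in range(2)]

    sites.sort(key=lambda s: (s.transcript_id, s.cds_position))
    return SyntheticPatient(patient_id, subtype, variants, sites, rna, hla,
                            decoy_kinds)


def simulate_cohort(reference: list[TranscriptModel],
                    params: SimulationParams) -> list[SyntheticPatient]:
    """Generate a seeded cohort; identical params give identical cohorts."""
    if not reference:
        raise InputError("reference panel is empty")
    rng = np.random.default_rng(params.seed)
    n_tnbc = round(params.n_patients * params.tnbc_fraction)
    patients = []
    for i in range(params.n_patients):
        subtype = "TNBC" if i < n_tnbc else "non-TNBC"
        patients.append(simulate_patient(
            rng, reference, params, f"BC{i + 1:02d}", subtype))
    return patients
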