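"""End-to-end orchestration: simulate -> call -> classify -> neoantigens
-> cohort statistics, with a run manifest for reproducibility.

The in-memory entry points (:func:`profile_patient`,
:func:`profile_cohort`) are what analyses and tests drive;``run_pipeline``
wraps them with file outputs under an output directory.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .binding import ToyBindingModel
from .caller import (CallerParams, SomaticVariant, call_somatic_variants,
                     classify_variant, summarize_mutations)
from .errors import StageError
from .io import (config_to_dict, write_allele_counts, write_hla_genotype,
                 write_json, write_peptides_fasta, write_profiles,
                 write_reference, write_results_table, write_rna_counts,
                 write_variants_vcf)
from .neoantigen import (NeoantigenParams, PatientProfile,
                         build_neoantigen_records, neoantigen_load)
from .reference import TranscriptModel, generate_reference
from .simulate import SimulationParams, SyntheticPatient, simulate_cohort
from .stats import IMMUNE_GENE_PANEL, cohort_report


@dataclass
class RunManifest:
    tool_version: str
    config_hash: str
    seed: int
    input_checksums: dict[str, str] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def to_dict(self) -> dict:
        return {
            "tool_version": self.tool_version,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "input_checksums": self.input_checksums,
            "started": self.started,
            "finished": self.finished,
        }


def simulate_immune_expression(seed: int, patient_ids: list[str],
                               genes: tuple[str, ...] = IMMUNE_GENE_PANEL
                               ) -> dict[str, dict[str, float]]:
    """Log-normal immune-gene FPKM drawn independently of everything else.

    The generator deliberately carries no dependence on mutation burden or
    load, mirroring the observed absence of association between load and
    T-cell marker expression; correlation tests against these values are
    therefore null-calibration checks.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(7,)))
    return {pid: {g: float(rng.lognormal(mean=2.0, sigma=1.0))
                  for g in genes}
            for pid in patient_ids}


def profile_patient(patient: SyntheticPatient,
                    models: dict[str, TranscriptModel],
                    caller_params: CallerParams,
                    neo_params: NeoantigenParams,
                    predictor,
                    immune_expression: dict[str, float] | None = None
                    ) -> tuple[PatientProfile, list[SomaticVariant], list]:
    """Call, classify and filter one patient into its profile.

    Returns (profile, classified variants, neoantigen records).
    """
    calls = call_somatic_variants(patient.allele_counts, caller_params)
    classified = [classify_variant(v, models[v.transcript_id]) for v in calls]
    summary = summarize_mutations(classified)
    nssnvs = [v for v in classified if v.mutation_class == "nsSNV"]
    records, n_binders = build_neoantigen_records(
        nssnvs, models, patient.hla_alleles, predictor,
        patient.rna_read_counts, neo_params)
    load = neoantigen_load(records, neo_params)
    profile = PatientProfile(
        patient_id=patient.patient_id,
        subtype=patient.subtype,
        tnbc_flag=patient.subtype == "TNBC",
        n_exonic=summary["total"],
        n_nssnv=len(nssnvs),
        n_predicted_binders=n_binders,
        neoantigen_load=load,
        immune_expression=dict(immune_expression or {}),
    )
    return profile, classified, records


def profile_cohort(reference: list[TranscriptModel],
                   patients: list[SyntheticPatient],
                   caller_params: CallerParams = CallerParams(),
                   neo_params: NeoantigenParams = NeoantigenParams(),
                   predictor=None,
                   immune_seed: int | None = None
                   ) -> tuple[list[PatientProfile], dict]:
    """Run the full analysis over a cohort in memory.

    Returns (profiles, extras) where extras maps patient_id to its
    classified variants and neoantigen records.
    """
    predictor = predictor or ToyBindingModel()
    models = {m.gene_symbol: m for m in reference}
    immune = (simulate_immune_expression(immune_seed,
                                         [p.patient_id for p in patients])
              if immune_seed is not None else {})
    profiles, extras = [], {}
    for patient in patients:
        profile, classified, records = profile_patient(
            patient, models, caller_params, neo_params, predictor,
            immune.get(patient.patient_id))
        profiles.append(profile)
        extras[patient.patient_id] = {
            "variants": classified, "records": records}
    return profiles, extras


def run_pipeline(out_dir,
                 caller_params: CallerParams = CallerParams(),
                 neo_params: NeoantigenParams = NeoantigenParams(),
                 sim_params: SimulationParams = SimulationParams(),
                 n_genes: int = 60,
                 cds_length_range: tuple[int, int] = (300, 1500)
                 ) -> RunManifest:
    """Simulate a cohort, run every stage, and write all outputs.

    The single simulation seed determines every stage; rerunning with the
    same configuration reproduces byte-identical tables (the manifest's
    timestamps are the only run-specific output).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config_to_dict(caller_params, neo_params, sim_params)
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()
    manifest = RunManifest(
        tool_version=__version__, config_hash=config_hash,
        seed=sim_params.seed,
        started=datetime.datetime.now(datetime.timezone.utc).isoformat())

    try:
        reference = generate_reference(n_genes, cds_length_range,
                                       seed=sim_params.seed)
        write_reference(reference, out / "reference_cds.fasta",
                        out / "reference_annotation.tsv")
    except Exception as exc:
        raise StageError("reference", str(exc)) from exc

    try:
        patients = simulate_cohort(reference, sim_params)
        for p in patients:
            write_allele_counts(p.allele_counts,
                                out / f"{p.patient_id}.allele_counts.tsv")
            write_rna_counts(p.rna_read_counts,
                             out / f"{p.patient_id}.rna_counts.tsv")
            write_hla_genotype(p.hla_alleles, out / f"{p.patient_id}.hla.txt")
    except Exception as exc:
        raise StageError("simulate", str(exc)) from exc

    try:
        profiles, extras = profile_cohort(
            reference, patients, caller_params, neo_params,
            immune_seed=sim_params.seed)
        for p in patients:
            data = extras[p.patient_id]
            write_variants_vcf(data["variants"],
                               out / f"{p.patient_id}.variants.vcf")
            write_peptides_fasta(data["records"],
                                 out / f"{p.patient_id}.neoantigens.fasta")
            summary = summarize_mutations(data["variants"])
            write_json({"patient_id": p.patient_id,
                        "counts": summary["counts"],
                        "total": summary["total"],
                        "nssnv_fraction": summary["nssnv_fraction"]},
                       out / f"{p.patient_id}.summary.json")
        write_profiles(profiles, out / "cohort_profiles.tsv")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("profile", str(exc)) from exc

    try:
        report = cohort_report(profiles)
        write_results_table(report, out / "cohort_results.tsv")
    except Exception as exc:
        raise StageError("statistics", str(exc)) from exc

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest.input_checksums[f.name] = hashlib.sha256(
                f.read_bytes()).hexdigest()
    manifest.finished = datetime.datetime.now(
        datetime.timezone.utc).isoformat()
    write_json(manifest.to_dict(), out / "manifest.json")
    return manifest
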