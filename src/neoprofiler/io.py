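"""Readers and writers for every format the pipeline touches.

All tabular outputs are UTF-8, tab-separated, single header row, floats
fixed to 6 significant digits so outputs are bit-exact across platforms.
Readers validate invariants and reject malformed rows with line numbers;
they never silently coerce.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .binding import AffinityTable
from .caller import (AlleleCountSite, CallerParams, DELETION_TOKEN,
                     INSERTION_TOKEN, MUTATION_CLASSES, SomaticVariant)
from .errors import InputError, ParseError
from .neoantigen import NeoantigenParams, PatientProfile
from .reference import TranscriptModel
from .simulate import SimulationParams

FLOAT_FMT = "%.6g"

_ALLELE_COUNT_COLUMNS = ("transcript_id", "cds_position", "ref", "alt",
                         "tumor_ref", "tumor_alt", "normal_ref", "normal_alt")


def _fmt(value) -> str:
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return FLOAT_FMT % value
    return str(value)


# ---------------------------------------------------------------- allele counts

def write_allele_counts(sites: list[AlleleCountSite], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ALLELE_COUNT_COLUMNS) + "\n")
        for s in sites:
            fh.write("\t".join(map(str, (
                s.transcript_id, s.cds_position, s.ref_base, s.alt_base,
                s.tumor_ref, s.tumor_alt, s.normal_ref, s.normal_alt))) + "\n")


def read_allele_counts(path) -> list[AlleleCountSite]:
    path = str(path)
    sites = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _ALLELE_COUNT_COLUMNS:
            raise ParseError(f"bad header {header}", path, 1)
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_ALLELE_COUNT_COLUMNS):
                raise ParseError(f"expected {len(_ALLELE_COUNT_COLUMNS)} "
                                 f"columns, got {len(fields)}", path, lineno)
            try:
                sites.append(AlleleCountSite(
                    transcript_id=fields[0], cds_position=int(fields[1]),
                    ref_base=fields[2], alt_base=fields[3],
                    tumor_ref=int(fields[4]), tumor_alt=int(fields[5]),
                    normal_ref=int(fields[6]), normal_alt=int(fields[7])))
            except (ValueError, InputError) as exc:
                raise ParseError(str(exc), path, lineno) from exc
    return sites


# ------------------------------------------------------------------- RNA counts

def write_rna_counts(counts: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tcds_position\tread_count\n")
        for (tid, pos), count in sorted(counts.items()):
            fh.write(f"{tid}\t{pos}\t{count}\n")


def read_rna_counts(path) -> dict:
    path = str(path)
    counts = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["transcript_id", "cds_position", "read_count"]:
            raise ParseError(f"bad header {header}", path, 1)
        for lineno, line in enumerate(fh, start=2):
            tid, pos, count = line.rstrip("\n").split("\t")
            value = int(count)
            if value < 0:
                raise ParseError("negative read count", path, lineno)
            counts[(tid, int(pos))] = value
    return counts


# ---------------------------------------------------------------- HLA genotypes

def write_hla_genotype(alleles: list[str], path) -> None:
    Path(path).write_text("".join(a + "\n" for a in alleles))


def read_hla_genotype(path) -> list[str]:
    alleles = [line.strip() for line in Path(path).read_text().splitlines()
               if line.strip() and not line.startswith("#")]
    if len(alleles) > 6:
        raise ParseError("HLA genotype has more than 6 alleles", str(path))
    return alleles


# ------------------------------------------------------------- reference panels

def write_reference(panel: list[TranscriptModel], fasta_path,
                    annotation_path) -> None:
    records = [SeqRecord(Seq(m.cds_sequence), id=m.gene_symbol, description="")
               for m in panel]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(annotation_path, "w") as fh:
        fh.write("gene_symbol\texon_boundaries\tstrand\n")
        for m in panel:
            bounds = ",".join(map(str, m.exon_boundaries)) or "."
            fh.write(f"{m.gene_symbol}\t{bounds}\t{m.strand}\n")


def read_reference(fasta_path, annotation_path) -> list[TranscriptModel]:
    seqs = {rec.id: str(rec.seq)
            for rec in SeqIO.parse(str(fasta_path), "fasta")}
    panel = []
    with open(annotation_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene_symbol", "exon_boundaries", "strand"]:
            raise ParseError(f"bad header {header}", str(annotation_path), 1)
        for lineno, line in enumerate(fh, start=2):
            gene, bounds, strand = line.rstrip("\n").split("\t")
            if gene not in seqs:
                raise ParseError(f"{gene} missing from FASTA",
                                 str(annotation_path), lineno)
            boundaries = (tuple(int(b) for b in bounds.split(","))
                          if bounds != "." else ())
            panel.append(TranscriptModel(gene, seqs[gene], boundaries, strand))
    return panel


# --------------------------------------------------------------- affinity table

def read_affinity_table(path, strict: bool = False) -> AffinityTable:
    """NetMHC-like dialect: tab-separated allele, peptide, ic50_nm columns.

    Lenient mode resolves duplicate (peptide, allele) rows by keeping the
    minimum IC50 and recording the conflict; strict mode raises.
    """
    path = str(path)
    table = AffinityTable(strict=strict)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["allele", "peptide", "ic50_nm"]:
            raise ParseError(f"bad header {header}", path, 1)
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ParseError("expected 3 columns", path, lineno)
            allele, peptide, raw = fields
            try:
                ic50 = float(raw)
            except ValueError:
                raise ParseError(f"non-numeric IC50 {raw!r}", path,
                                 lineno) from None
            try:
                table.add(peptide, allele, ic50)
            except InputError as exc:
                raise ParseError(str(exc), path, lineno) from exc
    return table


def write_affinity_table(table: AffinityTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("allele\tpeptide\tic50_nm\n")
        for (peptide, allele), ic50 in sorted(table._table.items(),
                                              key=lambda kv: (kv[0][1],
                                                              kv[0][0])):
            fh.write(f"{allele}\t{peptide}\t{FLOAT_FMT % ic50}\n")


# ------------------------------------------------------------------ VCF dialect

_VCF_ALT = {INSERTION_TOKEN: "<INS>", DELETION_TOKEN: "<DEL>"}
_VCF_ALT_BACK = {v: k for k, v in _VCF_ALT.items()}

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=neoprofiler
##INFO=<ID=CLASS,Number=1,Type=String,Description="Mutation class">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=FP,Number=1,Type=Float,Description="Fisher exact p-value">
##INFO=<ID=TVAF,Number=1,Type=Float,Description="Tumor variant allele frequency">
##INFO=<ID=NVAF,Number=1,Type=Float,Description="Normal variant allele frequency">
##INFO=<ID=TDP,Number=2,Type=Integer,Description="Tumor ref,alt depth">
##INFO=<ID=NDP,Number=2,Type=Integer,Description="Normal ref,alt depth">
##INFO=<ID=AAC,Number=1,Type=String,Description="Amino acid change ref/pos/alt">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_variants_vcf(variants: list[SomaticVariant], path) -> None:
    """Minimal VCF 4.2 with transcript ids as contig surrogates.

    Input is sorted by (transcript, position) before writing (a VCF must
    be position-sorted); classification fields travel in INFO.
    """
    ordered = sorted(variants,
                     key=lambda v: (v.transcript_id, v.cds_position))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for v in ordered:
            s = v.site
            info = [f"CLASS={v.mutation_class or '.'}",
                    f"GENE={v.gene_symbol or '.'}",
                    f"FP={FLOAT_FMT % v.fisher_p}",
                    f"TVAF={FLOAT_FMT % v.tumor_vaf}",
                    f"NVAF={FLOAT_FMT % v.normal_vaf}",
                    f"TDP={s.tumor_ref},{s.tumor_alt}",
                    f"NDP={s.normal_ref},{s.normal_alt}"]
            if v.ref_aa:
                info.append(f"AAC={v.ref_aa}{v.protein_position}{v.alt_aa}")
            alt = _VCF_ALT.get(s.alt_base, s.alt_base)
            fh.write(f"{s.transcript_id}\t{s.cds_position}\t.\t{s.ref_base}"
                     f"\t{alt}\t.\tPASS\t{';'.join(info)}\n")


def read_variants_vcf(path) -> list[SomaticVariant]:
    path = str(path)
    variants = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 8:
                raise ParseError("expected 8 VCF columns", path, lineno)
            chrom, pos, _id, ref, alt, _q, _f, info_raw = fields
            info = dict(kv.split("=", 1) for kv in info_raw.split(";"))
            klass = info.get("CLASS", ".")
            if klass != "." and klass not in MUTATION_CLASSES:
                raise ParseError(f"unknown mutation class {klass!r}",
                                 path, lineno)
            t_ref, t_alt = map(int, info["TDP"].split(","))
            n_ref, n_alt = map(int, info["NDP"].split(","))
            site = AlleleCountSite(chrom, int(pos), ref,
                                   _VCF_ALT_BACK.get(alt, alt),
                                   t_ref, t_alt, n_ref, n_alt)
            ref_aa = alt_aa = ""
            ppos = 0
            if "AAC" in info:
                aac = info["AAC"]
                ref_aa, alt_aa = aac[0], aac[-1]
                ppos = int(aac[1:-1])
            variants.append(SomaticVariant(
                site=site, fisher_p=float(info["FP"]),
                tumor_vaf=float(info["TVAF"]),
                normal_vaf=float(info["NVAF"]),
                mutation_class=None if klass == "." else klass,
                gene_symbol="" if info.get("GENE", ".") == "." else info["GENE"],
                ref_aa=ref_aa, alt_aa=alt_aa, protein_position=ppos))
    return variants


# ------------------------------------------------------------ peptides / tables

def write_peptides_fasta(records, path) -> None:
    """Mutant+wildtype peptide FASTA; headers encode variant and window."""
    seqs = []
    for rec in records:
        for pred in rec.passing_predictions:
            p = pred.peptide
            v = rec.variant
            base = (f"{v.transcript_id}_{v.cds_position}_"
                    f"L{p.length}_off{p.mutated_offset}")
            seqs.append(SeqRecord(Seq(p.sequence), id=f"{base}_MT",
                                  description=""))
            seqs.append(SeqRecord(Seq(p.wildtype_sequence), id=f"{base}_WT",
                                  description=""))
    SeqIO.write(seqs, str(path), "fasta")


def write_profiles(profiles: list[PatientProfile], path) -> None:
    genes = sorted({g for p in profiles for g in p.immune_expression})
    with open(path, "w") as fh:
        fh.write("patient_id\tsubtype\ttnbc_flag\tn_exonic\tn_nssnv"
                 "\tn_predicted_binders\tneoantigen_load")
        for g in genes:
            fh.write(f"\t{g}_fpkm")
        fh.write("\n")
        for p in profiles:
            fh.write(f"{p.patient_id}\t{p.subtype}\t{p.tnbc_flag}"
                     f"\t{p.n_exonic}\t{p.n_nssnv}\t{p.n_predicted_binders}"
                     f"\t{p.neoantigen_load}")
            for g in genes:
                fh.write("\t" + FLOAT_FMT % p.immune_expression.get(g, 0.0))
            fh.write("\n")


def read_profiles(path) -> list[PatientProfile]:
    path = str(path)
    profiles = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        fixed = header[:7]
        if fixed != ["patient_id", "subtype", "tnbc_flag", "n_exonic",
                     "n_nssnv", "n_predicted_binders", "neoantigen_load"]:
            raise ParseError(f"bad header {fixed}", path, 1)
        genes = [c[:-5] for c in header[7:]]
        for lineno, line in enumerate(fh, start=2):
            f = line.rstrip("\n").split("\t")
            if len(f) != len(header):
                raise ParseError("column count mismatch", path, lineno)
            try:
                profiles.append(PatientProfile(
                    patient_id=f[0], subtype=f[1],
                    tnbc_flag=f[2] == "True",
                    n_exonic=int(f[3]), n_nssnv=int(f[4]),
                    n_predicted_binders=int(f[5]), neoantigen_load=int(f[6]),
                    immune_expression={g: float(v)
                                       for g, v in zip(genes, f[7:])}))
            except (ValueError, InputError) as exc:
                raise ParseError(str(exc), path, lineno) from exc
    return profiles


def write_results_table(df, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# --------------------------------------------------------------- config / files

def config_to_dict(caller: CallerParams, neo: NeoantigenParams,
                   sim: SimulationParams) -> dict:
    return {
        "caller": {k: getattr(caller, k) for k in
                   ("min_depth", "min_variant_depth", "min_tumor_vaf",
                    "max_normal_vaf", "max_fisher_p")},
        "neoantigen": {
            "ic50_threshold_nm": neo.ic50_threshold_nm,
            "min_rna_read_count": neo.min_rna_read_count,
            "peptide_lengths": list(neo.peptide_lengths),
            "load_counting_unit": neo.load_counting_unit,
            "read_count_mode": neo.read_count_mode,
        },
        "simulation": {
            **{k: getattr(sim, k) for k in (
                "n_patients", "tnbc_fraction", "mean_burden",
                "tnbc_burden_multiplier", "burden_dispersion", "tumor_depth",
                "normal_depth", "vaf_alpha", "vaf_beta", "vaf_min",
                "sequencing_error_rate", "rna_zero_inflation",
                "rna_mean_count", "n_germline_decoys", "n_noise_decoys",
                "seed")},
            "class_mix": {c: f for c, f in sim.class_mix},
        },
    }


def load_config(path) -> dict:
    """Load a YAML config; unknown sections or keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    defaults = config_to_dict(CallerParams(), NeoantigenParams(),
                              SimulationParams())
    known_sections = set(defaults) | {"paths", "log_level"}
    unknown = set(raw) - known_sections
    if unknown:
        raise ParseError(f"unknown config sections: {sorted(unknown)}",
                         str(path))
    for section in ("caller", "neoantigen", "simulation"):
        extra = set(raw.get(section, {})) - set(defaults[section])
        if extra:
            raise ParseError(f"unknown keys in [{section}]: {sorted(extra)}",
                             str(path))
    return raw


def parse_config(raw: dict) -> tuple[CallerParams, NeoantigenParams,
                                     SimulationParams]:
    caller = CallerParams(**raw.get("caller", {}))
    neo_kwargs = dict(raw.get("neoantigen", {}))
    if "peptide_lengths" in neo_kwargs:
        neo_kwargs["peptide_lengths"] = tuple(neo_kwargs["peptide_lengths"])
    neo = NeoantigenParams(**neo_kwargs)
    sim_kwargs = dict(raw.get("simulation", {}))
    if "class_mix" in sim_kwargs:
        sim_kwargs["class_mix"] = tuple(sim_kwargs["class_mix"].items())
    sim = SimulationParams(**sim_kwargs)
    return caller, neo, sim


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
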