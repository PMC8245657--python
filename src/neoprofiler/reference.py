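"""Synthetic transcript reference panels.

Real neoantigen pipelines annotate variants against genome-wide transcript
models (RefSeq/Ensembl on GRCh37-style coordinates). For a self-contained,
fully testable pipeline we work directly in CDS space: each transcript is a
coding sequence starting at ATG and ending in a stop codon, with exon
junction offsets recorded so splice-site variants can be classified. All
coordinates downstream (allele counts, variants) are 1-based positions in
this CDS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .errors import InputError, ParameterError

STOP_CODONS = ("TAA", "TAG", "TGA")
BASES = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def translate_cds(cds: str) -> str:
    """Translate a CDS (standard code) into its protein, excluding the stop."""
    if len(cds) % 3 != 0:
        raise InputError(f"CDS length {len(cds)} not divisible by 3")
    aa = str(Seq(cds).translate())
    return aa[:-1] if aa.endswith("*") else aa


@dataclass(frozen=True)
class TranscriptModel:
    """A coding transcript: CDS sequence plus exon-junction offsets.

    ``exon_boundaries`` lists 1-based CDS offsets j meaning "an exon junction
    falls immediately after CDS base j"; offsets are strictly increasing and
    interior (0 < j < len(cds)). ``protein`` is the translation of the CDS
    without the terminal stop.
    """

    gene_symbol: str
    cds_sequence: str
    exon_boundaries: tuple[int, ...]
    strand: str = "+"
    protein: str = field(default="", compare=False)

    def __post_init__(self):
        cds = self.cds_sequence
        if len(cds) < 6 or len(cds) % 3 != 0:
            raise InputError(
                f"{self.gene_symbol}: CDS length {len(cds)} invalid")
        if not cds.startswith("ATG"):
            raise InputError(f"{self.gene_symbol}: CDS must start with ATG")
        if cds[-3:] not in STOP_CODONS:
            raise InputError(f"{self.gene_symbol}: CDS must end in a stop codon")
        if self.strand not in "+-":
            raise InputError(f"{self.gene_symbol}: strand must be + or -")
        bounds = self.exon_boundaries
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise InputError(f"{self.gene_symbol}: exon boundaries not increasing")
        if bounds and (bounds[0] < 1 or bounds[-1] >= len(cds)):
            raise InputError(f"{self.gene_symbol}: exon boundary outside CDS interior")
        derived = translate_cds(cds)
        if "*" in derived:
            raise InputError(f"{self.gene_symbol}: internal stop codon")
        if self.protein and self.protein != derived:
            raise InputError(f"{self.gene_symbol}: protein does not match CDS")
        if not self.protein:
            object.__setattr__(self, "protein", derived)

    def __len__(self) -> int:
        return len(self.cds_sequence)

    def splice_window_positions(self, halfwidth: int = 2) -> frozenset[int]:
        """1-based CDS positions within ``halfwidth`` bases of a junction.

        Junction after base j covers positions j-halfwidth+1 .. j+halfwidth.
        """
        pos: set[int] = set()
        for j in self.exon_boundaries:
            for p in range(j - halfwidth + 1, j + halfwidth + 1):
                if 1 <= p <= len(self.cds_sequence):
                    pos.add(p)
        return frozenset(pos)


def _random_coding_codons(rng: np.random.Generator, n_codons: int) -> str:
    """Draw sense codons uniformly from the 61 non-stop codons."""
    codons = [a + b + c for a in BASES for b in BASES for c in BASES
              if a + b + c not in STOP_CODONS]
    idx = rng.integers(0, len(codons), size=n_codons)
    return "".join(codons[i] for i in idx)


def generate_reference(n_genes: int,
                       cds_length_range: tuple[int, int],
                       seed: int,
                       mean_exons: float = 4.0) -> list[TranscriptModel]:
    """Generate a deterministic panel of synthetic transcript models.

    Parameters
    ----------
    n_genes : number of transcripts (>= 1).
    cds_length_range : inclusive (lo, hi) bounds on CDS length in bases;
        drawn lengths are rounded down to a multiple of 3, minimum 27
        (ATG + >= 7 sense codons + stop).
    seed : fully determines the panel.
    mean_exons : average exon count per transcript (junctions are placed
        uniformly in the CDS interior).
    """
    if n_genes < 1:
        raise ParameterError("n_genes must be >= 1")
    lo, hi = cds_length_range
    if lo < 27 or hi < lo:
        raise ParameterError(
            f"invalid cds_length_range {cds_length_range}: need 27 <= lo <= hi")
    rng = np.random.default_rng(seed)
    panel = []
    for g in range(n_genes):
        length = int(rng.integers(lo, hi + 1)) // 3 * 3
        length = max(length, 27)
        n_codons = length // 3 - 2          # minus ATG and stop
        body = _random_coding_codons(rng, n_codons)
        stop = STOP_CODONS[rng.integers(0, 3)]
        cds = "ATG" + body + stop
        n_junctions = max(0, int(rng.poisson(mean_exons - 1)))
        interior = np.arange(5, length - 5)
        n_junctions = min(n_junctions, interior.size)
        bounds = tuple(sorted(int(b) for b in
                              rng.choice(interior, size=n_junctions,
                                         replace=False)))
        strand = "+" if rng.random() < 0.5 else "-"
        panel.append(TranscriptModel(
            gene_symbol=f"GENE{g + 1:04d}",
            cds_sequence=cds,
            exon_boundaries=bounds,
            strand=strand,
        ))
    return panel
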