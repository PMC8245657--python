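"""Mutant protein construction and exhaustive 8-11mer epitope enumeration.

For each nsSNV the mutant protein is the wildtype protein with a single
residue substituted. Every peptide window of length 8-11 that lies fully
inside the protein and contains the substituted residue is a candidate
epitope; its wildtype counterpart is the same window in the wildtype
protein.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import CoordinateError, InputError
from .caller import SomaticVariant
from .reference import TranscriptModel

DEFAULT_PEPTIDE_LENGTHS = (8, 9, 10, 11)


@dataclass(frozen=True)
class MutantPeptide:
    """An 8-11mer containing the substituted residue, with its wildtype twin."""

    sequence: str
    mutated_offset: int          # 0-based index of the substitution
    wildtype_sequence: str
    source_variant: SomaticVariant | None = None

    def __post_init__(self):
        n = len(self.sequence)
        if not 8 <= n <= 11:
            raise InputError(f"peptide length {n} outside 8-11")
        if len(self.wildtype_sequence) != n:
            raise InputError("wildtype/mutant length mismatch")
        if not 0 <= self.mutated_offset < n:
            raise InputError("mutated_offset outside peptide")
        diffs = [i for i in range(n)
                 if self.sequence[i] != self.wildtype_sequence[i]]
        if diffs != [self.mutated_offset]:
            raise InputError(
                "mutant and wildtype must differ exactly at mutated_offset")

    @property
    def length(self) -> int:
        return len(self.sequence)


def mutant_protein(model: TranscriptModel,
                   variant: SomaticVariant) -> tuple[str, int]:
    """Mutant protein and 1-based substituted position for an nsSNV.

    Only nsSNVs generate candidate epitopes; any other class is rejected.
    """
    if variant.mutation_class != "nsSNV":
        raise InputError(
            f"mutant_protein requires an nsSNV, got {variant.mutation_class}")
    pos = variant.protein_position
    wt = model.protein
    if not 1 <= pos <= len(wt):
        raise CoordinateError(
            f"protein position {pos} outside protein of length {len(wt)}")
    if wt[pos - 1] != variant.ref_aa:
        raise InputError(
            f"wildtype residue {wt[pos - 1]} != variant ref_aa {variant.ref_aa}")
    mutant = wt[:pos - 1] + variant.alt_aa + wt[pos:]
    return mutant, pos


def window_count(protein_length: int, position: int, length: int) -> int:
    """Closed-form number of length-L windows inside the protein containing
    the 1-based position: min(i, n-L+1) - max(1, i-L+1) + 1, floored at 0."""
    hi = min(position, protein_length - length + 1)
    lo = max(1, position - length + 1)
    return max(0, hi - lo + 1)


def enumerate_mutant_peptides(protein: str,
                              position: int,
                              lengths: tuple[int, ...] = DEFAULT_PEPTIDE_LENGTHS,
                              wildtype_protein: str | None = None,
                              source_variant: SomaticVariant | None = None
                              ) -> list[MutantPeptide]:
    """All windows of the given lengths containing the substituted position.

    Parameters
    ----------
    protein : the mutant protein sequence.
    position : 1-based substituted position within ``protein``.
    lengths : peptide lengths to enumerate (each emitted once, ordered by
        length then start).
    wildtype_protein : same-length protein differing only at ``position``;
        if omitted, a placeholder wildtype is synthesized by swapping the
        substituted residue for an arbitrary different one (window counting
        and sequence content are unaffected).
    """
    n = len(protein)
    if not 1 <= position <= n:
        raise CoordinateError(f"position {position} outside protein length {n}")
    if wildtype_protein is None:
        other = "A" if protein[position - 1] != "A" else "G"
        wildtype_protein = protein[:position - 1] + other + protein[position:]
    if len(wildtype_protein) != n:
        raise InputError("wildtype protein length mismatch")
    out = []
    for L in sorted(set(lengths)):
        lo = max(1, position - L + 1)
        hi = min(position, n - L + 1)
        for start in range(lo, hi + 1):       # 1-based window start
            out.append(MutantPeptide(
                sequence=protein[start - 1: start - 1 + L],
                mutated_offset=position - start,
                wildtype_sequence=wildtype_protein[start - 1: start - 1 + L],
                source_variant=source_variant,
            ))
    return out
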