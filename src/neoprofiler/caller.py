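"""Fisher's-exact-test somatic variant calling and mutation classification.

The caller takes per-site tumor/normal allele counts (base-quality and
mapping filters are assumed applied upstream, i.e. counts reflect reads
with base quality >= 15) and emits somatic variants passing six filters:

1. base quality >= 15            -- upstream, encoded in the counts
2. sequence depth >= 10          -- applied to both tumor and normal
3. variant depth >= 4            -- tumor alt reads
4. tumor variant frequency >= 10%
5. normal variant frequency < 2%
6. two-sided Fisher exact p < 0.05 on [[tumor_ref, tumor_alt],
                                       [normal_ref, normal_alt]]

Called variants are then classified against a transcript model into six
classes: nsSNV, sSNV, stopgain, stoploss, splicing, INDEL.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.special import gammaln
from Bio.Seq import Seq

from .errors import ConsistencyError, CoordinateError, InputError, StateError
from .reference import TranscriptModel

MUTATION_CLASSES = ("nsSNV", "sSNV", "stopgain", "stoploss", "splicing", "INDEL")

#: alt-allele tokens that denote an insertion / deletion rather than an SNV
INSERTION_TOKEN = "+"
DELETION_TOKEN = "-"
INDEL_TOKENS = (INSERTION_TOKEN, DELETION_TOKEN)


@dataclass(frozen=True)
class AlleleCountSite:
    """Tumor/normal ref/alt read counts at one CDS site (1-based)."""

    transcript_id: str
    cds_position: int
    ref_base: str
    alt_base: str
    tumor_ref: int
    tumor_alt: int
    normal_ref: int
    normal_alt: int

    def __post_init__(self):
        if min(self.tumor_ref, self.tumor_alt,
               self.normal_ref, self.normal_alt) < 0:
            raise InputError(f"{self.transcript_id}:{self.cds_position}: "
                             "negative read count")
        if self.cds_position < 1:
            raise InputError(f"{self.transcript_id}: cds_position must be >= 1")
        if self.ref_base not in "ACGT":
            raise InputError(f"{self.transcript_id}:{self.cds_position}: "
                             f"bad ref base {self.ref_base!r}")
        if self.alt_base not in "ACGT" and self.alt_base not in INDEL_TOKENS:
            raise InputError(f"{self.transcript_id}:{self.cds_position}: "
                             f"bad alt base {self.alt_base!r}")

    @property
    def tumor_depth(self) -> int:
        return self.tumor_ref + self.tumor_alt

    @property
    def normal_depth(self) -> int:
        return self.normal_ref + self.normal_alt

    @property
    def tumor_vaf(self) -> float:
        d = self.tumor_depth
        return self.tumor_alt / d if d else 0.0

    @property
    def normal_vaf(self) -> float:
        d = self.normal_depth
        return self.normal_alt / d if d else 0.0

    @property
    def is_indel(self) -> bool:
        return self.alt_base in INDEL_TOKENS


@dataclass(frozen=True)
class CallerParams:
    """The caller's filter thresholds; defaults are the standard six."""

    min_depth: int = 10
    min_variant_depth: int = 4
    min_tumor_vaf: float = 0.10
    max_normal_vaf: float = 0.02
    max_fisher_p: float = 0.05

    def __post_init__(self):
        if self.min_depth < 0 or self.min_variant_depth < 0:
            raise InputError("depth thresholds must be >= 0")
        for v in (self.min_tumor_vaf, self.max_normal_vaf, self.max_fisher_p):
            if not 0.0 <= v <= 1.0:
                raise InputError(f"proportion threshold {v} outside [0,1]")


@dataclass(frozen=True)
class SomaticVariant:
    """A called somatic variant; classification fields filled by classify_variant."""

    site: AlleleCountSite
    fisher_p: float
    tumor_vaf: float
    normal_vaf: float
    mutation_class: str | None = None
    gene_symbol: str = ""
    ref_aa: str = ""
    alt_aa: str = ""
    protein_position: int = 0

    @property
    def transcript_id(self) -> str:
        return self.site.transcript_id

    @property
    def cds_position(self) -> int:
        return self.site.cds_position


#: relative tolerance treating numerically tied table probabilities as tied;
#: must exceed the ~1e-13 relative noise of gammaln-based pmfs so genuine
#: hypergeometric ties (mirror tables) are never dropped
_TIE_GUARD = 1 + 1e-11


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


@lru_cache(maxsize=65536)
def _fisher_p_cached(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p over the hypergeometric support, vectorized.

    Conditioning on all margins of [[a, b], [c, d]], every admissible table
    is indexed by its top-left cell x; the p-value sums the probabilities
    of tables no more likely than the observed one (minimum-likelihood
    convention, with a 1e-14 relative guard for floating-point ties).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n_total = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    x = np.arange(lo, hi + 1)
    logpmf = (_log_binom(r1, x) + _log_binom(r2, c1 - x)
              - _log_binom(n_total, c1))
    pmf = np.exp(logpmf)
    p_obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * _TIE_GUARD].sum()))


def fisher_somatic_p(site: AlleleCountSite) -> float:
    """Two-sided Fisher exact p for [[tumor_ref, tumor_alt], [normal_ref, normal_alt]].

    The two-sided p sums the probabilities of all tables with the same
    margins whose hypergeometric probability does not exceed the observed
    table's (standard minimum-likelihood convention). Invariant under
    swapping rows with columns.
    """
    if site.tumor_depth == 0 and site.normal_depth == 0:
        raise InputError(f"{site.transcript_id}:{site.cds_position}: "
                         "no reads in either sample")
    return _fisher_p_cached(site.tumor_ref, site.tumor_alt,
                            site.normal_ref, site.normal_alt)


def passes_filters(site: AlleleCountSite, params: CallerParams) -> bool:
    """Apply the six somatic filters (Fisher test evaluated last, lazily)."""
    if site.tumor_depth < params.min_depth or site.normal_depth < params.min_depth:
        return False
    if site.tumor_alt < params.min_variant_depth:
        return False
    if site.tumor_vaf < params.min_tumor_vaf:
        return False
    if site.normal_vaf >= params.max_normal_vaf:
        return False
    return fisher_somatic_p(site) < params.max_fisher_p


def call_somatic_variants(sites: list[AlleleCountSite],
                          params: CallerParams = CallerParams()
                          ) -> list[SomaticVariant]:
    """Emit (unclassified) SomaticVariants for sites passing all filters.

    Output preserves input order. Cheap count filters are applied before
    the Fisher test so the exact test only runs on surviving sites.
    """
    calls = []
    for site in sites:
        if passes_filters(site, params):
            calls.append(SomaticVariant(
                site=site,
                fisher_p=fisher_somatic_p(site),
                tumor_vaf=site.tumor_vaf,
                normal_vaf=site.normal_vaf,
            ))
    return calls


def classify_variant(variant: SomaticVariant,
                     model: TranscriptModel,
                     splice_halfwidth: int = 2) -> SomaticVariant:
    """Assign one of the six mutation classes and the amino-acid change.

    Precedence: INDEL token -> INDEL; SNV inside the splice window flanking
    an exon junction -> splicing; otherwise the mutated codon is translated
    (new stop -> stopgain, lost terminal stop -> stoploss, same residue ->
    sSNV, different residue -> nsSNV).
    """
    site = variant.site
    pos = site.cds_position
    if not 1 <= pos <= len(model.cds_sequence):
        raise CoordinateError(
            f"{site.transcript_id}: position {pos} outside CDS of length "
            f"{len(model.cds_sequence)}")
    if model.cds_sequence[pos - 1] != site.ref_base:
        raise ConsistencyError(
            f"{site.transcript_id}:{pos}: ref {site.ref_base} does not match "
            f"transcript base {model.cds_sequence[pos - 1]}")

    common = dict(gene_symbol=model.gene_symbol)
    if site.is_indel:
        return replace(variant, mutation_class="INDEL", **common)
    if pos in model.splice_window_positions(splice_halfwidth):
        return replace(variant, mutation_class="splicing", **common)

    codon_index = (pos - 1) // 3            # 0-based codon number
    offset = (pos - 1) % 3
    codon = model.cds_sequence[codon_index * 3: codon_index * 3 + 3]
    mut_codon = codon[:offset] + site.alt_base + codon[offset + 1:]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(mut_codon).translate())
    common.update(ref_aa=ref_aa, alt_aa=alt_aa,
                  protein_position=codon_index + 1)

    if ref_aa != "*" and alt_aa == "*":
        klass = "stopgain"
    elif ref_aa == "*" and alt_aa != "*":
        klass = "stoploss"
    elif ref_aa == alt_aa:
        klass = "sSNV"
    else:
        klass = "nsSNV"
    return replace(variant, mutation_class=klass, **common)


def summarize_mutations(variants: list[SomaticVariant]) -> dict:
    """Per-class counts, the total, and the nsSNV fraction (None if empty)."""
    counts = {c: 0 for c in MUTATION_CLASSES}
    for v in variants:
        if v.mutation_class is None:
            raise StateError(
                f"{v.transcript_id}:{v.cds_position}: variant not classified")
        counts[v.mutation_class] += 1
    total = len(variants)
    return {
        "counts": counts,
        "total": total,
        "nssnv_fraction": counts["nsSNV"] / total if total else None,
    }
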