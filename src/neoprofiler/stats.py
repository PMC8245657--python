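"""Cohort-level and assay-level statistics.

Covers the expression unit (FPKM), Pearson correlation, two-group
comparison of neoantigen loads, IFN-gamma ELISpot response positivity and
the calcein-release cytotoxicity percentage, plus the cohort report that
ties them together (mutation-burden correlations, immune-gene panel,
TNBC vs non-TNBC comparison).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError, ParameterError

#: immune genes examined against neoantigen load (T cell and cytolytic markers)
IMMUNE_GENE_PANEL = ("CD8A", "CD4", "TCRB", "GZMA", "GZMB", "PRF1")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise InputError(f"|r| > 1: {self.r}")
        if self.n < 3:
            raise InputError("Pearson p-value needs n >= 3")


@dataclass(frozen=True)
class GroupComparison:
    t: float
    p: float
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    range_a: tuple[float, float]
    range_b: tuple[float, float]
    paired: bool
    note: str = ""


def fpkm(gene_reads: int, gene_length_bp: int, total_mapped_reads: int) -> float:
    """Fragments per kilobase of transcript per million mapped reads.

    FPKM = reads * 1e9 / (total_mapped_reads * gene_length_bp).
    """
    if gene_length_bp < 1 or total_mapped_reads < 1:
        raise ParameterError("gene length and total mapped reads must be >= 1")
    if gene_reads < 0:
        raise InputError("gene_reads must be >= 0")
    return gene_reads * 1e9 / (total_mapped_reads * gene_length_bp)


def pearson(x, y) -> CorrelationResult:
    """Pearson r with the two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise InputError("Pearson correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("zero variance in input vector")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), int(x.size))


def group_compare(a, b, paired: bool = False) -> GroupComparison:
    """Student's t-test between two groups with medians and ranges.

    The unpaired test is the equal-variance two-sample t; ``paired=True``
    switches to the paired test (lengths must then match). Identical
    constant groups are degenerate (t undefined) and flagged via note.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs n >= 2")
    note = ""
    if paired:
        if a.size != b.size:
            raise InputError("paired comparison requires equal lengths")
        diffs = a - b
        if np.ptp(diffs) == 0 and diffs[0] == 0:
            t, p, note = 0.0, 1.0, "degenerate: identical paired samples"
        elif np.ptp(diffs) == 0:
            raise InputError("zero-variance paired differences")
        else:
            t, p = sps.ttest_rel(a, b)
    else:
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            t, p, note = 0.0, 1.0, "degenerate: both groups constant and equal"
        elif np.ptp(a) == 0 and np.ptp(b) == 0:
            raise InputError("zero variance in both groups")
        else:
            t, p = sps.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        t=float(t), p=float(p), n_a=int(a.size), n_b=int(b.size),
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        range_a=(float(a.min()), float(a.max())),
        range_b=(float(b.min()), float(b.max())),
        paired=paired, note=note)


def elispot_response(sample_spots: int, control_spots: int,
                     positivity_margin: float = 0.5) -> dict:
    """Fold increase over control and positivity under the strict rule.

    Positive iff sample > control * (1 + margin); a zero control with a
    positive sample is positive with an unbounded fold increase.
    """
    if sample_spots < 0 or control_spots < 0:
        raise InputError("spot counts must be >= 0")
    if control_spots == 0:
        positive = sample_spots > 0
        return {"fold_increase": float("inf") if positive else 0.0,
                "positive": positive, "unbounded": positive}
    fold = sample_spots / control_spots
    return {"fold_increase": fold,
            "positive": sample_spots > control_spots * (1 + positivity_margin),
            "unbounded": False}


def cytotoxicity_percent(control_fluorescence: float,
                         sample_fluorescence: float) -> float:
    """(control - sample) / control * 100; negative values are reported."""
    if control_fluorescence <= 0:
        raise ParameterError("control fluorescence must be > 0")
    if sample_fluorescence < 0:
        raise InputError("sample fluorescence must be >= 0")
    return (control_fluorescence - sample_fluorescence) \
        / control_fluorescence * 100.0


def cohort_report(profiles: list) -> pd.DataFrame:
    """Flat table of the cohort's correlations and the subtype comparison.

    Correlates exonic burden vs nsSNV count, nsSNV count vs predicted
    binders, nsSNV count vs load, and load vs each immune-gene FPKM; then
    compares TNBC vs non-TNBC loads with the unpaired t-test (the paired
    test is impossible for unequal group sizes, which is noted in the
    output row rather than silently resolved).
    """
    if len(profiles) < 3:
        raise InputError("cohort report needs >= 3 profiles")
    rows = []

    def corr(name, x, y):
        try:
            res = pearson(x, y)
            rows.append({"comparison": name, "statistic": res.r,
                         "p": res.p, "n": res.n, "kind": "pearson_r",
                         "note": ""})
        except InputError as exc:
            rows.append({"comparison": name, "statistic": float("nan"),
                         "p": float("nan"), "n": len(x), "kind": "pearson_r",
                         "note": str(exc)})

    n_exonic = [p.n_exonic for p in profiles]
    n_nssnv = [p.n_nssnv for p in profiles]
    binders = [p.n_predicted_binders for p in profiles]
    load = [p.neoantigen_load for p in profiles]
    corr("n_exonic_vs_n_nssnv", n_exonic, n_nssnv)
    corr("n_nssnv_vs_predicted_binders", n_nssnv, binders)
    corr("n_nssnv_vs_neoantigen_load", n_nssnv, load)
    for gene in IMMUNE_GENE_PANEL:
        expr = [p.immune_expression.get(gene, float("nan")) for p in profiles]
        if any(np.isnan(expr)):
            rows.append({"comparison": f"load_vs_{gene}_fpkm",
                         "statistic": float("nan"), "p": float("nan"),
                         "n": len(profiles), "kind": "pearson_r",
                         "note": f"missing {gene} expression"})
        else:
            corr(f"load_vs_{gene}_fpkm", load, expr)

    tnbc = [p.neoantigen_load for p in profiles if p.tnbc_flag]
    non = [p.neoantigen_load for p in profiles if not p.tnbc_flag]
    if len(tnbc) >= 2 and len(non) >= 2:
        cmp_ = group_compare(tnbc, non, paired=False)
        rows.append({
            "comparison": "tnbc_vs_non_tnbc_load", "statistic": cmp_.t,
            "p": cmp_.p, "n": cmp_.n_a + cmp_.n_b, "kind": "student_t",
            "note": ("unpaired two-sample test; a paired test is undefined "
                     "for unequal group sizes"
                     + (f"; {cmp_.note}" if cmp_.note else ""))})
    else:
        rows.append({"comparison": "tnbc_vs_non_tnbc_load",
                     "statistic": float("nan"), "p": float("nan"),
                     "n": len(profiles), "kind": "student_t",
                     "note": "needs >= 2 patients per subtype group"})
    return pd.DataFrame(rows)
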