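"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the implementation's code paths: the Fisher
oracle enumerates hypergeometric tables with exact integer numerators, the
window oracle scans every substring.
"""

from math import comb


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive table enumeration.

    Fixing all margins of [[a, b], [c, d]], every admissible table is
    [[x, r1-x], [c1-x, r2-c1+x]]; its probability has numerator
    comb(r1, x) * comb(r2, c1-x) over the common denominator comb(N, c1),
    so "probability <= observed" is an exact integer comparison (ties are
    exact, no floating-point guard needed).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n_total = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    numerators = [comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)]
    n_obs = numerators[a - lo]
    total = sum(n for n in numerators if n <= n_obs)
    return total / comb(n_total, c1)


def windows_containing(protein: str, position: int, length: int) -> list[str]:
    """Every length-L substring of the protein containing the 1-based position."""
    out = []
    for start in range(1, len(protein) - length + 2):
        if start <= position <= start + length - 1:
            out.append(protein[start - 1: start - 1 + length])
    return out
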