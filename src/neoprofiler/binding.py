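"""HLA class I binding-affinity prediction interfaces.

Real pipelines score peptides with external predictors (NetMHC-family
neural networks) and consume their output tables. Here two predictors
implement a common interface:

* :class:`ToyBindingModel` — a deterministic position-weight-matrix model
  shipped as a versioned text asset. It is NOT a re-implementation of any
  neural predictor; it exists so every downstream stage has a reproducible,
  platform-independent affinity source with a realistic binder rate
  (roughly 2% of random 8-11mers under 500 nM per allele).
* :class:`AffinityTable` — a lookup over a NetMHC-like tab-separated
  table (allele, peptide, IC50 nM), for plugging in externally computed
  affinities.

Scoring maps peptide positions onto 9 PWM slots (first four positions to
slots 0-3, last five to slots 4-8; middle positions of 10/11mers fold onto
slot 4 with damped weight) and converts the summed score s monotonically
onto (0, 50000] nM via ic50 = 50000 * logistic(-(s - midpoint)/scale).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.special import expit, ndtri

from .errors import CoverageError, InputError, ParseError
from .peptides import MutantPeptide
from .reference import AMINO_ACIDS

IC50_CEILING_NM = 50000.0
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_ANCHOR_SLOTS = (1, 8)
_ANCHOR_SCALE = 2.5
_MIDDLE_DAMP = 0.3
N_SLOTS = 9


@dataclass(frozen=True)
class BindingPrediction:
    """Predicted affinity of one mutant peptide for one HLA allele."""

    peptide: MutantPeptide
    hla_allele: str
    ic50_nm: float
    predictor_id: str = "toy-pwm"

    def __post_init__(self):
        if not self.ic50_nm > 0:
            raise InputError(f"ic50_nm must be > 0, got {self.ic50_nm}")


def slot_map(length: int) -> tuple[np.ndarray, np.ndarray]:
    """(slots, weights) for each position of a length-8..11 peptide."""
    if not 8 <= length <= 11:
        raise InputError(f"peptide length {length} outside 8-11")
    slots, weights = [], []
    for i in range(length):
        if i < 4:
            slots.append(i)
            weights.append(1.0)
        elif i >= length - 5:
            slots.append(9 - (length - i))
            weights.append(1.0)
        else:                       # middle bulge of 10/11mers
            slots.append(4)
            weights.append(_MIDDLE_DAMP)
    return np.array(slots), np.array(weights)


def _encode(peptides: list[str]) -> np.ndarray:
    """Encode same-length peptides as an (n, L) int array of residue indices."""
    try:
        return np.array([[_AA_INDEX[aa] for aa in p] for p in peptides])
    except KeyError as exc:
        raise InputError(f"non-standard residue {exc.args[0]!r}") from None


def _hash_pwm(allele: str) -> np.ndarray:
    """Deterministic PWM for an allele outside the shipped asset.

    Weights come from SHA-256 of (allele, residue, slot) mapped through the
    normal quantile function, so any allele name yields the same matrix on
    any platform; anchors and column centering match the asset convention.
    """
    w = np.empty((20, N_SLOTS))
    for i, aa in enumerate(AMINO_ACIDS):
        for j in range(N_SLOTS):
            digest = hashlib.sha256(f"{allele}|{aa}|{j}".encode()).digest()
            u = (int.from_bytes(digest[:8], "big") + 0.5) / 2 ** 64
            w[i, j] = ndtri(u)
    w[:, list(_ANCHOR_SLOTS)] *= _ANCHOR_SCALE
    w -= w.mean(axis=0, keepdims=True)
    return w


def _load_asset() -> tuple[dict[str, np.ndarray], float, float]:
    pwms: dict[str, np.ndarray] = {}
    midpoint = scale = None
    text = (resources.files("neoprofiler") / "data" / "pwm_alleles.tsv"
            ).read_text()
    for line in text.splitlines():
        if line.startswith("#midpoint="):
            midpoint = float(line.split("=")[1])
        elif line.startswith("#scale="):
            scale = float(line.split("=")[1])
        elif line.startswith("#") or line.startswith("allele\t") or not line:
            continue
        else:
            allele, aa, *vals = line.split("\t")
            row = pwms.setdefault(allele, np.zeros((20, N_SLOTS)))
            row[_AA_INDEX[aa]] = [float(v) for v in vals]
    if midpoint is None or scale is None:
        raise ParseError("PWM asset missing midpoint/scale header")
    return pwms, midpoint, scale


class ToyBindingModel:
    """Deterministic PWM-based IC50 predictor (asset alleles + hash fallback)."""

    predictor_id = "toy-pwm"

    def __init__(self):
        self._pwms, self._midpoint, self._scale = _load_asset()

    def pwm(self, allele: str) -> np.ndarray:
        if not allele:
            raise InputError("allele name must be non-empty")
        if allele not in self._pwms:
            self._pwms[allele] = _hash_pwm(allele)
        return self._pwms[allele]

    def score_many(self, peptides: list[str], allele: str) -> np.ndarray:
        """PWM scores for same-length peptides against one allele."""
        if not peptides:
            return np.zeros(0)
        L = len(peptides[0])
        if any(len(p) != L for p in peptides):
            raise InputError("score_many requires same-length peptides")
        slots, weights = slot_map(L)
        idx = _encode(peptides)
        return (self.pwm(allele)[idx, slots] * weights).sum(axis=1)

    def ic50_many(self, peptides: list[str], allele: str) -> np.ndarray:
        s = self.score_many(peptides, allele)
        return IC50_CEILING_NM * expit(-(s - self._midpoint) / self._scale)

    def ic50(self, peptide: str, allele: str) -> float:
        return float(self.ic50_many([peptide], allele)[0])


_DEFAULT_MODEL: ToyBindingModel | None = None


def toy_binding_model(peptide: str, allele: str) -> float:
    """IC50 (nM) of a peptide for an allele under the shipped toy model."""
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = ToyBindingModel()
    return _DEFAULT_MODEL.ic50(peptide, allele)


class AffinityTable:
    """(peptide, allele) -> IC50 lookup backed by a NetMHC-like TSV table.

    Duplicate rows for a pair keep the minimum IC50 (conservative toward
    calling a binder) unless ``strict``, in which case conflicting
    duplicates are an error. Missing pairs return ``None`` from ``get``.
    """

    predictor_id = "affinity-table"

    def __init__(self, entries: dict[tuple[str, str], float] | None = None,
                 strict: bool = False):
        self._table = dict(entries or {})
        self.strict = strict
        self.duplicate_conflicts: list[tuple[str, str]] = []

    def add(self, peptide: str, allele: str, ic50: float) -> None:
        if ic50 <= 0:
            raise InputError(f"IC50 must be positive, got {ic50}")
        key = (peptide, allele)
        if key in self._table and self._table[key] != ic50:
            if self.strict:
                raise InputError(
                    f"conflicting duplicate affinity rows for {key}")
            self.duplicate_conflicts.append(key)
            self._table[key] = min(self._table[key], ic50)
        else:
            self._table[key] = ic50

    def get(self, peptide: str, allele: str) -> float | None:
        return self._table.get((peptide, allele))

    def ic50(self, peptide: str, allele: str) -> float:
        val = self.get(peptide, allele)
        if val is None:
            raise CoverageError(f"no affinity for ({peptide}, {allele})")
        return val

    def __len__(self) -> int:
        return len(self._table)


def predict_binding(peptides: list[MutantPeptide],
                    alleles: list[str],
                    predictor) -> tuple[list[BindingPrediction],
                                        list[tuple[str, str]]]:
    """One prediction per (peptide, deduplicated allele) pair.

    Homozygous alleles are deduplicated (first occurrence order kept).
    Returns (predictions, missing_pairs); a table predictor in strict mode
    raises :class:`CoverageError` on the first missing pair instead.
    """
    unique_alleles = list(dict.fromkeys(alleles))
    predictions: list[BindingPrediction] = []
    missing: list[tuple[str, str]] = []
    pid = getattr(predictor, "predictor_id", "custom")
    for allele in unique_alleles:
        if hasattr(predictor, "ic50_many") and peptides:
            by_len: dict[int, list[int]] = {}
            for i, p in enumerate(peptides):
                by_len.setdefault(p.length, []).append(i)
            vals = np.empty(len(peptides))
            for L, idxs in by_len.items():
                vals[idxs] = predictor.ic50_many(
                    [peptides[i].sequence for i in idxs], allele)
            for p, v in zip(peptides, vals):
                predictions.append(BindingPrediction(p, allele, float(v), pid))
        else:
            for p in peptides:
                if isinstance(predictor, AffinityTable):
                    val = predictor.get(p.sequence, allele)
                    if val is None:
                        if predictor.strict:
                            raise CoverageError(
                                f"no affinity for ({p.sequence}, {allele})")
                        missing.append((p.sequence, allele))
                        continue
                else:
                    val = predictor.ic50(p.sequence, allele)
                predictions.append(BindingPrediction(p, allele, float(val), pid))
    return predictions, missing
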