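"""HLA class I binding via additive position-weight matrices.

The built-in scorer follows the classic additive-matrix paradigm: a peptide's
score against an allele is the sum of per-position, per-residue weights, and
its relative score is that sum divided by the maximum attainable sum. A
peptide is called a binder when the relative score reaches a threshold
(default 0.5, the half-max heuristic). External affinity predictors can be
plugged in through :class:`PredictorAdapter`; the core pipeline never
requires them.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class BindingMatrix:
    """Additive scoring matrix for one (allele, peptide length) pair."""

    allele: str
    length: int
    weights: np.ndarray  # shape (length, 20), residue order = AMINO_ACIDS

    def __post_init__(self) -> None:
        if self.weights.shape != (self.length, 20):
            raise ValueError(f"weights must be ({self.length}, 20)")

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())


@dataclass(frozen=True)
class BindingRecord:
    peptide: str
    allele: str
    score: float
    relative_score: float
    is_binder: bool


def score_peptide(matrix: BindingMatrix, peptide: str, threshold: float = 0.5) -> BindingRecord:
    """Sum per-position weights; normalize by the matrix's maximum score."""
    peptide = peptide.upper()
    if len(peptide) != matrix.length:
        raise ValueError(f"peptide length {len(peptide)} != matrix length {matrix.length}")
    try:
        idx = [_AA_INDEX[aa] for aa in peptide]
    except KeyError as e:
        raise ValueError(f"unknown residue {e.args[0]!r} in {peptide}") from None
    score = float(matrix.weights[np.arange(matrix.length), idx].sum())
    mx = matrix.max_score
    rel = score / mx if mx > 0 else 0.0
    return BindingRecord(peptide, matrix.allele, score, rel, rel >= threshold)


class MatrixSet:
    """Matrices keyed by (allele, length); one allele may cover several lengths."""

    def __init__(self, matrices: Iterable[BindingMatrix]):
        self._by_key: dict[tuple[str, int], BindingMatrix] = {}
        for m in matrices:
            self._by_key[(m.allele, m.length)] = m

    def get(self, allele: str, length: int) -> Optional[BindingMatrix]:
        return self._by_key.get((allele, length))

    def alleles(self) -> list[str]:
        return sorted({a for a, _ in self._by_key})

    def __len__(self) -> int:
        return len(self._by_key)


def predict_binders(
    candidates: Sequence,
    allele_set: Sequence[str],
    matrices: MatrixSet,
    threshold: float = 0.5,
    strict: bool = False,
) -> list:
    """Filter a peptide search space to predicted neoepitopes (PNE).

    A candidate is a PNE when it is a binder for at least one of the
    patient's alleles (homozygous duplicates are deduplicated; at most six
    alleles). Binding records for all scoreable alleles are attached to every
    candidate. Alleles lacking a matrix for a candidate's length are skipped
    with a warning (or raise when ``strict``).
    """
    alleles = list(dict.fromkeys(allele_set))  # dedupe, keep order
    if len(alleles) > 6:
        raise ValueError("at most six HLA class I alleles per patient")
    missing_warned = set()
    pne = []
    for cand in candidates:
        cand.binding_records = []
        for allele in alleles:
            m = matrices.get(allele, len(cand.sequence))
            if m is None:
                if strict:
                    raise ValueError(f"no matrix for allele {allele}, length {len(cand.sequence)}")
                if (allele, len(cand.sequence)) not in missing_warned:
                    log.warning("no matrix for allele %s length %d; skipped",
                                allele, len(cand.sequence))
                    missing_warned.add((allele, len(cand.sequence)))
                continue
            cand.binding_records.append(score_peptide(m, cand.sequence, threshold))
        if any(r.is_binder for r in cand.binding_records):
            cand.tier_flags.add("PNE")
            pne.append(cand)
    return pne


def peptide_is_binder(
    peptide: str, alleles: Sequence[str], matrices: MatrixSet, threshold: float = 0.5
) -> bool:
    for allele in dict.fromkeys(alleles):
        m = matrices.get(allele, len(peptide))
        if m is not None and score_peptide(m, peptide, threshold).is_binder:
            return True
    return False


def binder_fraction(
    peptides: Sequence[str],
    alleles: Sequence[str],
    matrices: MatrixSet,
    threshold: float = 0.5,
) -> Optional[float]:
    """Fraction of an eluted-ligand list predicted to bind any patient allele.

    Returns ``None`` (absent, not zero) for an empty list.
    """
    if not peptides:
        return None
    n_pass = sum(peptide_is_binder(p, alleles, matrices, threshold) for p in peptides)
    return n_pass / len(peptides)


def random_matrix_set(
    alleles: Sequence[str],
    lengths: Iterable[int],
    rng: np.random.Generator,
) -> MatrixSet:
    """Generate a seeded fixture matrix set (sparse anchor-style weights).

    Each matrix places strong weights on a few anchor positions for a small
    residue subset, echoing the anchor-residue structure of real HLA motifs;
    these are synthetic fixtures, not published matrices.
    """
    mats = []
    for allele in alleles:
        for L in lengths:
            w = rng.uniform(0.0, 1.0, size=(L, 20))
            anchors = rng.choice(L, size=2, replace=False)
            for pos in anchors:
                favored = rng.choice(20, size=3, replace=False)
                w[pos, :] *= 0.2
                w[pos, favored] = rng.uniform(6.0, 10.0, size=3)
            mats.append(BindingMatrix(allele=allele, length=L, weights=w))
    return MatrixSet(mats)


def matrix_to_frame(m: BindingMatrix) -> pd.DataFrame:
    rows = [
        {"position": i + 1, "residue": aa, "weight": float(m.weights[i, j])}
        for i in range(m.length)
        for j, aa in enumerate(AMINO_ACIDS)
    ]
    return pd.DataFrame(rows)


def matrix_from_frame(df: pd.DataFrame, allele: str, length: int) -> BindingMatrix:
    w = np.zeros((length, 20))
    for _, r in df.iterrows():
        w[int(r["position"]) - 1, _AA_INDEX[str(r["residue"])]] = float(r["weight"])
    return BindingMatrix(allele=allele, length=length, weights=w)


class PredictorAdapter:
    """Contract for external affinity predictors (rank-based).

    An adapter maps (peptides, allele) to a percentile rank per peptide;
    binder iff rank <= ``rank_threshold`` (default 2.0). Optional — nothing in
    the core pipeline depends on one being available.
    """

    def __init__(self, predict: Callable[[Sequence[str], str], Mapping[str, float]],
                 rank_threshold: float = 2.0):
        self._predict = predict
        self.rank_threshold = rank_threshold

    def is_binder(self, peptides: Sequence[str], allele: str) -> dict[str, bool]:
        ranks = self._predict(peptides, allele)
        return {p: ranks[p] <= self.rank_threshold for p in peptides}
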