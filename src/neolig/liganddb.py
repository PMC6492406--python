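"""Wild-type ligand background database: exact-match counting and
knowledge-based prioritization of predicted neoepitopes.

The prioritization heuristic: the more often a candidate's wild-type
counterpart (WT^lig) has already been observed as a natural HLA ligand across
samples, the more plausible it is that the mutated counterpart can be
presented — so candidates are ranked by WT^lig match count, each containing
sample counted as a separate match.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd


class LigandDatabase:
    """Index mapping peptide -> set of sample identifiers observing it.

    Query results are independent of insertion/storage order.
    """

    def __init__(self, entries: Iterable[tuple[str, str]] = ()):
        self._index: dict[str, set[str]] = {}
        for peptide, sample_id in entries:
            self.add(peptide, sample_id)

    def add(self, peptide: str, sample_id: str) -> None:
        if not peptide or not sample_id:
            raise ValueError("peptide and sample_id must be nonempty")
        self._index.setdefault(peptide.upper(), set()).add(sample_id)

    def __len__(self) -> int:
        return len(self._index)

    def samples_for(self, peptide: str) -> frozenset[str]:
        return frozenset(self._index.get(peptide.upper(), set()))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LigandDatabase":
        required = {"peptide", "sample_id"}
        if not required <= set(df.columns):
            raise ValueError(f"database table must have columns {sorted(required)}")
        return cls(zip(df["peptide"].astype(str), df["sample_id"].astype(str)))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"peptide": p, "sample_id": s}
            for p in sorted(self._index)
            for s in sorted(self._index[p])
        ]
        return pd.DataFrame(rows, columns=["peptide", "sample_id"])


def db_match(peptide: str, database: LigandDatabase) -> int:
    """Number of distinct database samples containing the exact peptide string;
    0 when absent. Monotone under database growth."""
    return len(database.samples_for(peptide))


def prioritize_pne(
    candidates: Sequence,
    database: LigandDatabase,
    tie_break: str = "stable",
) -> pd.DataFrame:
    """Rank candidates by WT^lig match count, descending.

    The sort is stable: by default ties keep input order. ``tie_break="score"``
    instead orders ties by (binding relative score descending, peptide
    lexicographic), which is invariant to input order. Candidates without a
    wild-type counterpart rank last with an absent count. The output is a
    permutation of the input — nothing is gained or lost.
    """
    rows = []
    for i, cand in enumerate(candidates):
        wt = getattr(cand, "wt_counterpart", None)
        count = db_match(wt, database) if wt else None
        best_rel = max((r.relative_score for r in getattr(cand, "binding_records", [])),
                       default=0.0)
        rows.append({
            "peptide": cand.sequence,
            "wt_counterpart": wt if wt else "",
            "wt_matches": count,
            "best_relative_score": best_rel,
            "source_protein": cand.source_protein,
            "_input_order": i,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        df["rank"] = pd.Series(dtype=int)
        return df.drop(columns=["_input_order"], errors="ignore")
    df["_has_wt"] = df["wt_matches"].notna()
    df["_count"] = df["wt_matches"].fillna(-1)
    if tie_break == "stable":
        keys, order = ["_has_wt", "_count"], [False, False]
    elif tie_break == "score":
        keys = ["_has_wt", "_count", "best_relative_score", "peptide"]
        order = [False, False, False, True]
    else:
        raise ValueError(f"unknown tie_break: {tie_break!r}")
    df = df.sort_values(by=keys, ascending=order, kind="mergesort").reset_index(drop=True)
    df["rank"] = df.index + 1
    return df.drop(columns=["_has_wt", "_count", "_input_order"])


def top_k_report(prioritized: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    return prioritized.head(k).copy()
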