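"""Cohort-level descriptive statistics: tier means +/- SD, Var-vs-PNE
correlations, TMB category fractions, and cross-cohort benchmarking."""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .evidence import TierSummary, summaries_to_frame

_TIER_COLS = ("Var", "Var_ns", "Var_exp", "PSS", "PNE", "PNE_exp", "PNE_prot", "NE_lig")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Pearson product-moment correlation; None (with a warning) when either
    series has zero variance or fewer than 3 pairs are supplied."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return None
    return float(sps.pearsonr(x, y).statistic)


def tmb_categories(
    varns_counts: Sequence[int],
    thresholds: Sequence[float] = (100, 400),
) -> tuple[float, ...]:
    """Fraction of tumors strictly exceeding each Var^ns threshold."""
    counts = np.asarray(varns_counts)
    if counts.size == 0:
        raise ValueError("empty cohort")
    if (counts < 0).any():
        raise ValueError("counts must be >= 0")
    return tuple(float((counts > t).mean()) for t in thresholds)


@dataclass
class CohortReport:
    """Tier summaries plus the cohort-level descriptive layer.

    SD is the sample standard deviation (n-1 denominator), matching the
    conventional "mean ± SD" reporting.
    """

    summaries: list[TierSummary]
    callable_region_mb: float = 35.0
    settings: dict = field(default_factory=dict)
    tmb_thresholds: tuple[float, ...] = (100, 400)

    @property
    def frame(self) -> pd.DataFrame:
        return summaries_to_frame(self.summaries)

    def tier_stats(self) -> pd.DataFrame:
        df = self.frame
        rows = []
        for col in _TIER_COLS:
            vals = df[col].to_numpy(dtype=float)
            rows.append({
                "tier": col,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            })
        tmb = df["Var_ns"].to_numpy(dtype=float) / self.callable_region_mb
        rows.append({
            "tier": "TMB",
            "mean": float(tmb.mean()),
            "sd": float(tmb.std(ddof=1)) if len(tmb) > 1 else 0.0,
        })
        return pd.DataFrame(rows)

    def correlations(self) -> dict[str, Optional[float]]:
        df = self.frame
        return {
            "varns_vs_pne": pearson_r(df["Var_ns"], df["PNE"]),
            "varexp_vs_pneexp": pearson_r(df["Var_exp"], df["PNE_exp"]),
        }

    def category_fractions(self) -> dict[float, float]:
        fracs = tmb_categories(self.frame["Var_ns"].tolist(), self.tmb_thresholds)
        return dict(zip(self.tmb_thresholds, fracs))


def benchmark_cohorts(report_a: CohortReport, report_b: CohortReport) -> pd.DataFrame:
    """Fold-differences of tier means between two cohorts processed with
    identical pipeline settings, plus side-by-side TMB category fractions."""
    if report_a.settings != report_b.settings:
        raise ValueError("cohorts were processed with different pipeline settings")
    sa = report_a.tier_stats().set_index("tier")["mean"]
    sb = report_b.tier_stats().set_index("tier")["mean"]
    rows = []
    for tier in ("Var_ns", "PSS", "PNE", "TMB"):
        a, b = float(sa[tier]), float(sb[tier])
        rows.append({
            "quantity": tier, "mean_a": a, "mean_b": b,
            "ratio_b_over_a": b / a if a != 0 else float("nan"),
        })
    fa, fb = report_a.category_fractions(), report_b.category_fractions()
    for t in report_a.tmb_thresholds:
        rows.append({
            "quantity": f"frac_varns_gt_{int(t)}",
            "mean_a": fa[t], "mean_b": fb.get(t, float("nan")),
            "ratio_b_over_a": fb.get(t, float("nan")) / fa[t] if fa[t] else float("nan"),
        })
    return pd.DataFrame(rows)
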