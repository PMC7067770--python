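"""Independent-sample t-tests with tiered significance flagging.

The default variant is the pooled-variance Student's t-test (df = n1+n2-2),
with Welch's unequal-variance test available.  P-values are two-sided.
Significance tiers follow strict inequalities:
``‡`` p < 0.01, ``†`` p < 0.05, ``*`` p < 0.1, otherwise ``ns``.

A small Monte-Carlo harness (:func:`calibration_sim`) checks the empirical
type-I error of the test at the study's group size under a normal null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "independent_t_test",
    "significance_flag",
    "calibration_sim",
    "compare_sides",
    "FLAG_THRESHOLDS",
]

#: significance tiers, strict inequalities, strongest first
FLAG_THRESHOLDS = (("‡", 0.01), ("†", 0.05), ("*", 0.1))


def significance_flag(p: float) -> str:
    """Map a p-value to its significance tier (strict inequalities)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value out of range: {p}")
    for flag, thr in FLAG_THRESHOLDS:
        if p < thr:
            return flag
    return "ns"


@dataclass(frozen=True)
class TestResult:
    t_stat: float
    df: float
    p_value: float
    variant: str
    n1: int
    n2: int

    @property
    def flag(self) -> str:
        return significance_flag(self.p_value)


def independent_t_test(a, b, variant: str = "pooled") -> TestResult:
    """Two-sided independent-sample t-test between two groups.

    ``variant="pooled"`` uses the pooled-variance Student statistic with
    ``df = n1 + n2 - 2``; ``variant="welch"`` uses Welch's statistic with
    Welch-Satterthwaite degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("samples contain non-finite values")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            # identical constant samples: no evidence of any difference
            df = a.size + b.size - 2
            return TestResult(0.0, float(df), 1.0, variant, a.size, b.size)
        raise ValueError("both samples have zero variance; t statistic undefined")
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    df = float(a.size + b.size - 2) if variant == "pooled" else float(res.df)
    return TestResult(float(res.statistic), df, float(res.pvalue), variant, a.size, b.size)


def calibration_sim(
    n_per_group: int = 6,
    n_reps: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    variant: str = "pooled",
) -> float:
    """Empirical type-I error of the t-test under a standard-normal null.

    Draws ``n_reps`` pairs of null samples of size ``n_per_group`` and returns
    the fraction with p < alpha.  Deterministic given ``seed``.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0,1]")
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_reps, n_per_group))
    b = rng.standard_normal((n_reps, n_per_group))
    res = sps.ttest_ind(a, b, axis=1, equal_var=(variant == "pooled"))
    return float(np.mean(res.pvalue < alpha))


def compare_sides(
    report: pd.DataFrame,
    metric: str,
    variant: str = "pooled",
    side_a: str = "INJURY",
    side_b: str = "NON_INJURY",
) -> pd.DataFrame:
    """t-test ``side_a`` vs ``side_b`` per (group, day) cell of a tidy report.

    Expects the long-format report produced by
    :func:`myotomo.quantify.build_report`; returns one row per (group, day)
    with columns ``metric, group, day, n1, n2, t, df, p, flag``.
    """
    sub = report[report["metric"] == metric]
    rows = []
    for (group, day), cell in sub.groupby(["group", "day"], sort=True):
        va = cell.loc[cell["side"] == side_a, "value"].to_numpy()
        vb = cell.loc[cell["side"] == side_b, "value"].to_numpy()
        if len(va) < 2 or len(vb) < 2:
            continue
        r = independent_t_test(va, vb, variant)
        rows.append(
            {
                "metric": metric,
                "group": group,
                "day": day,
                "n1": r.n1,
                "n2": r.n2,
                "t": r.t_stat,
                "df": r.df,
                "p": r.p_value,
                "flag": r.flag,
            }
        )
    return pd.DataFrame(rows, columns=["metric", "group", "day", "n1", "n2", "t", "df", "p", "flag"])
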