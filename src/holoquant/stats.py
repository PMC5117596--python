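"""Condition comparison by Student's t-test.

Compares symbiont protein content between two conditions (e.g. freshly
collected vs starved animals) with the classic pooled-variance two-sample
t-test, either from replicate values or directly from published summary
statistics (mean, sample sd, n). Welch's unequal-variance form is
available behind a flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SummaryStats:
    """Mean, sample standard deviation (n-1 denominator) and replicate count."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")
        if self.n < 2:
            raise ValidationError("n must be >= 2")

    @classmethod
    def from_values(cls, values) -> "SummaryStats":
        arr = np.asarray(list(values), dtype=float)
        return cls(mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=len(arr))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_two_tailed: float
    mean_difference: float


def pooled_ttest_summary(a: SummaryStats, b: SummaryStats, *, welch: bool = False) -> TTestResult:
    """Two-sample t-test from summary statistics.

    Pooled-variance (Student) by default:
    s_p^2 = ((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2),
    t = (m1-m2) / (s_p sqrt(1/n1 + 1/n2)), df = n1+n2-2, two-tailed p.
    With ``welch=True`` uses the unequal-variance form with
    Welch-Satterthwaite degrees of freedom.
    """
    diff = a.mean - b.mean
    if welch:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        se = math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1)) if se > 0 else a.n + b.n - 2
    else:
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
        se = math.sqrt(sp2) * math.sqrt(1 / a.n + 1 / b.n)
    if se == 0:
        if diff == 0:
            return TTestResult(t=0.0, df=df, p_two_tailed=1.0, mean_difference=0.0)
        logger.warning("zero pooled variance with unequal means: degenerate t-test, p = 0")
        return TTestResult(t=math.copysign(math.inf, diff), df=df, p_two_tailed=0.0, mean_difference=diff)
    t = diff / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(t=t, df=df, p_two_tailed=p, mean_difference=diff)


def compare_conditions(
    values: pd.DataFrame,
    design: pd.DataFrame,
    *,
    metric: str = "symbiont_fraction",
    welch: bool = False,
) -> tuple[TTestResult, pd.DataFrame]:
    """t-test of a per-sample quantity between the design's two conditions.

    *values* is indexed by sample_id and must contain the *metric* column
    (e.g. the per-sample symbiont fraction from
    :func:`holoquant.quant.taxon_fractions`, or a total-nSpC column).
    Returns the test result and a summary table with one row per condition
    (mean, sd, n) plus the p-value — the shape of a published
    condition-comparison table.
    """
    if metric not in values.columns:
        raise ValidationError(f"metric column {metric!r} not in the values table")
    merged = values.reset_index().merge(design, on="sample_id", how="inner")
    conditions = list(dict.fromkeys(design["condition"]))
    if len(conditions) != 2:
        raise ValidationError(f"exactly 2 conditions required, found {conditions}")
    per_cond = {}
    for cond in conditions:
        vals = merged.loc[merged["condition"] == cond, metric].dropna()
        if len(vals) < 2:
            raise ValidationError(f"condition {cond!r} has fewer than 2 replicates")
        per_cond[cond] = SummaryStats.from_values(vals)
    a, b = (per_cond[c] for c in conditions)
    result = pooled_ttest_summary(a, b, welch=welch)
    summary = pd.DataFrame(
        {
            "condition": conditions,
            "mean": [a.mean, b.mean],
            "sd": [a.sd, b.sd],
            "n": [a.n, b.n],
        }
    )
    summary["p_two_tailed"] = result.p_two_tailed
    return result, summary
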