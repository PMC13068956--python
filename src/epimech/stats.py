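"""Replicate aggregation and the paired statistics used for monolayer data.

Technical replicates (or matrix measurements within one monolayer) are
averaged into a single representative value per biological replicate before
testing. Paired designs are tested with a two-sided paired t-test or, for
multiplicative (fold-change) readouts, a ratio paired t-test — a paired t on
log-transformed values. Multi-group comparisons use one-way ANOVA. No
multiple-testing correction is applied; p-values are reported per test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DegenerateVarianceError",
    "PairedTestResult",
    "AnovaResult",
    "aggregate_technical",
    "paired_t",
    "ratio_paired_t",
    "one_way_anova",
    "significance_stars",
]


class DegenerateVarianceError(ValueError):
    """The paired differences (or log-ratios) have zero variance."""


@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float
    n: int
    log_transformed: bool = False

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


def significance_stars(p: float) -> str:
    """Caption-style star annotation: * p<0.05 ... **** p<0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p < cut:
            return stars
    return "ns"


def aggregate_technical(raw: pd.DataFrame,
                        value_col: str = "value",
                        group_cols: tuple[str, ...] = ("replicate", "condition",
                                                       "measurement"),
                        ) -> pd.DataFrame:
    """Average technical replicates into per-biological-replicate values.

    Groups rows by (replicate, condition, measurement), takes the arithmetic
    mean of ``value_col`` and records how many technical values entered each
    mean. Row order within groups is irrelevant.
    """
    grouped = raw.groupby(list(group_cols), sort=True)[value_col]
    out = grouped.agg(value="mean", n_technical="count").reset_index()
    return out


def _check_pairs(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D arrays of equal length")
    if a.size < 2:
        raise ValueError("paired tests need at least 2 replicate pairs")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("values must be finite")
    return a, b


def paired_t(values_a, values_b) -> PairedTestResult:
    """Two-sided paired t-test on the differences b − a.

    The sign convention makes t positive when condition b exceeds a;
    swapping the arguments negates t and leaves p unchanged.
    """
    a, b = _check_pairs(values_a, values_b)
    d = b - a
    if np.isclose(np.std(d, ddof=1), 0.0):
        raise DegenerateVarianceError("paired differences have zero variance")
    res = sps.ttest_rel(b, a)
    return PairedTestResult(t=float(res.statistic), df=a.size - 1,
                            p=float(res.pvalue), n=a.size)


def ratio_paired_t(values_a, values_b) -> PairedTestResult:
    """Two-sided ratio paired t-test: paired t on log-transformed values.

    Tests the null of unit mean ratio b/a, so it is invariant to rescaling
    either condition by a constant. All values must be positive. (Natural
    logs are used; the statistic and p-value are base-independent.)
    """
    a, b = _check_pairs(values_a, values_b)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("ratio paired t-test requires strictly positive values")
    log_d = np.log(b) - np.log(a)
    if np.isclose(np.std(log_d, ddof=1), 0.0):
        raise DegenerateVarianceError("log-ratios have zero variance")
    res = sps.ttest_rel(np.log(b), np.log(a))
    return PairedTestResult(t=float(res.statistic), df=a.size - 1,
                            p=float(res.pvalue), n=a.size,
                            log_transformed=True)


def one_way_anova(groups) -> AnovaResult:
    """One-way ANOVA over ≥2 groups, each with ≥2 values."""
    arrays = [np.asarray(g, float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(g.size < 2 for g in arrays):
        raise ValueError("every group needs at least 2 values")
    res = sps.f_oneway(*arrays)
    n_total = sum(g.size for g in arrays)
    return AnovaResult(F=float(res.statistic),
                       df_between=len(arrays) - 1,
                       df_within=n_total - len(arrays),
                       p=float(res.pvalue))
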