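"""Calibration/prediction diagnostics for spectroscopic regression.

Core statistics: R-squared against the evaluated set's own mean, RMSE, and
the residual predictive deviation RPD = 1/sqrt(1 - R^2), plus bias, SEP
(standard error of prediction, bias-corrected, n-1 denominator), t-based
95 % intervals, qualitative interpretation bands, residual shape summaries,
and one-way ANOVA with Tukey HSD for comparing model families on replicate
RMSEP values.

Interpretation bands (closed on the left):
    R^2:  [0, 0.6) poor, [0.6, 0.8) good, [0.8, 1] excellent
    RPD:  [0, 1.5) insufficient, [1.5, 2.0) acceptable, [2.0, inf) outstanding
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "PredictionSet", "MetricsReport", "ComparisonReport", "ResidualSummary",
    "r_squared", "rmse", "rpd_from_r2", "bias_and_sep", "confidence_intervals",
    "interpret", "anova_tukey", "residual_summary", "evaluate",
]


@dataclass(frozen=True)
class PredictionSet:
    """Reference values and predictions (%) for one data partition."""

    y_true: np.ndarray
    y_pred: np.ndarray
    label: str = "prediction"  # calibration | cv | prediction

    def __post_init__(self) -> None:
        yt = np.asarray(self.y_true, float)
        yp = np.asarray(self.y_pred, float)
        if yt.shape != yp.shape or yt.ndim != 1:
            raise ValueError("y_true and y_pred must be equal-length 1-D vectors")
        if yt.size < 2:
            raise ValueError("need at least 2 samples")
        object.__setattr__(self, "y_true", yt)
        object.__setattr__(self, "y_pred", yp)

    @property
    def n(self) -> int:
        return self.y_true.size

    @property
    def residuals(self) -> np.ndarray:
        """Predicted minus reference (negative bias = underestimation)."""
        return self.y_pred - self.y_true


@dataclass(frozen=True)
class MetricsReport:
    r2: float
    rmse: float
    rpd: float
    bias: float
    sep: float
    ci_mean: tuple[float, float]
    ci_single: tuple[float, float]
    label: str
    interpretation: str


@dataclass(frozen=True)
class ComparisonReport:
    groups: tuple[str, ...]
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, reject


@dataclass(frozen=True)
class ResidualSummary:
    mean: float
    sd: float
    skewness: float
    excess_kurtosis: float
    normality_p: float
    degenerate: bool = False


def r_squared(ps: PredictionSet) -> float:
    """1 - SS_res/SS_tot, with SS_tot about the evaluated set's own mean."""
    y, yp = ps.y_true, ps.y_pred
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("reference values have zero variance")
    return 1.0 - float(((yp - y) ** 2).sum()) / ss_tot


def rmse(ps: PredictionSet) -> float:
    return float(np.sqrt(np.mean(ps.residuals**2)))


def rpd_from_r2(r2: float) -> float:
    """Residual predictive deviation, RPD = 1/sqrt(1 - R^2)."""
    if r2 >= 1:
        raise ValueError("RPD is unbounded for R^2 >= 1")
    return 1.0 / np.sqrt(1.0 - r2)


def bias_and_sep(ps: PredictionSet) -> tuple[float, float]:
    """Bias = mean(predicted - reference); SEP = SD of bias-corrected
    residuals with n-1 denominator."""
    r = ps.residuals
    bias = float(r.mean())
    sep = float(np.sqrt(((r - bias) ** 2).sum() / (ps.n - 1)))
    return bias, sep


def confidence_intervals(ps: PredictionSet) -> tuple[tuple[float, float], tuple[float, float]]:
    """95 % t intervals around the mean prediction: mean-level
    (+- t * SEP/sqrt(n)) and single-new-prediction (+- t * SEP)."""
    if ps.n < 3:
        raise ValueError("need at least 3 samples for intervals")
    _, sep = bias_and_sep(ps)
    t = float(stats.t.ppf(0.975, ps.n - 1))
    center = float(ps.y_pred.mean())
    return (
        (center - t * sep / np.sqrt(ps.n), center + t * sep / np.sqrt(ps.n)),
        (center - t * sep, center + t * sep),
    )


def interpret(r2: float, rpd: float) -> str:
    if r2 < 0.6:
        r2_band = "poor"
    elif r2 < 0.8:
        r2_band = "good"
    else:
        r2_band = "excellent"
    if rpd < 1.5:
        rpd_band = "insufficient"
    elif rpd < 2.0:
        rpd_band = "acceptable"
    else:
        rpd_band = "outstanding"
    return f"{r2_band} / {rpd_band}"


def evaluate(ps: PredictionSet) -> MetricsReport:
    """Full MetricsReport for one partition."""
    r2 = r_squared(ps)
    err = rmse(ps)
    rpd = rpd_from_r2(r2) if r2 < 1 else float("inf")
    bias, sep = bias_and_sep(ps)
    ci_mean, ci_single = confidence_intervals(ps)
    return MetricsReport(r2, err, rpd, bias, sep, ci_mean, ci_single,
                         ps.label, interpret(r2, rpd))


def anova_tukey(groups: dict[str, np.ndarray], alpha: float = 0.05) -> ComparisonReport:
    """One-way ANOVA F test plus Tukey HSD pairwise comparisons on the
    per-group replicate values (e.g. RMSEP over repeated splits)."""
    names = tuple(groups)
    arrays = [np.asarray(groups[g], float) for g in names]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 replicates each")
    if all(a.std() == 0 for a in arrays):
        raise ValueError("zero within-group variance in every group")
    f_stat, p = stats.f_oneway(*arrays)
    values = np.concatenate(arrays)
    labels = np.concatenate([[g] * a.size for g, a in zip(names, arrays)])
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    tukey_df = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    df1 = len(arrays) - 1
    df2 = values.size - len(arrays)
    return ComparisonReport(names, float(f_stat), (df1, df2), float(p), tukey_df)


def residual_summary(ps: PredictionSet) -> ResidualSummary:
    """Residual shape diagnostics; Shapiro-Wilk for normality."""
    if ps.n < 8:
        raise ValueError("need at least 8 residuals")
    r = ps.residuals
    sd = float(r.std(ddof=1))
    if sd == 0:
        return ResidualSummary(float(r.mean()), 0.0, 0.0, 0.0, 1.0, degenerate=True)
    return ResidualSummary(
        mean=float(r.mean()),
        sd=sd,
        skewness=float(stats.skew(r)),
        excess_kurtosis=float(stats.kurtosis(r)),
        normality_p=float(stats.shapiro(r).pvalue),
    )
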