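"""Statistical comparison of quantification metrics.

Per-parameter linear regressions of each metric against the serially
varied phantom parameters; cross-model slope comparison with Holm-Sidak
correction; the two-covariate ideal-metric model

    CEST effect [%M0] = alpha * pH + beta * [BSA] + epsilon

whose fit quality over *all* phantoms (including the relaxation arms,
where pH and protein are at baseline) measures how specific a metric is to
the exchange-relevant parameters; and the pairwise Delta-pH machinery that
inverts the ideal model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spinsystem import InvalidInputError

__all__ = [
    "RegressionResult", "IdealModelFit", "DeltaPHResult", "SlopeComparison",
    "regress_metric", "compare_slopes", "holm_sidak", "sidak_thresholds",
    "fit_ideal_model", "delta_cest_significance", "delta_ph", "sign_accuracy",
]


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of metric value against one varied parameter."""

    metric: str
    varied_parameter: str
    model: str
    slope: float
    slope_se: float
    intercept: float
    p_value: float
    n: int
    r_squared: float


def regress_metric(parameter_values, metric_values, *, metric: str = "",
                   varied_parameter: str = "", model: str = "") -> RegressionResult:
    """Ordinary least-squares regression with a two-sided slope test."""
    x = np.asarray(parameter_values, dtype=float)
    y = np.asarray(metric_values, dtype=float)
    if x.size < 3:
        raise InvalidInputError("need at least 3 phantoms for a regression")
    if np.ptp(x) == 0:
        raise InvalidInputError("degenerate regression: parameter is constant")
    res = stats.linregress(x, y)
    # linregress returns nan p for exactly collinear data; the slope test
    # is then decided by whether the slope is nonzero
    p = res.pvalue
    if math.isnan(p):
        p = 0.0 if res.slope != 0 else 1.0
    return RegressionResult(
        metric=metric, varied_parameter=varied_parameter, model=model,
        slope=float(res.slope), slope_se=float(res.stderr),
        intercept=float(res.intercept), p_value=float(p), n=int(x.size),
        r_squared=float(res.rvalue ** 2))


@dataclass(frozen=True)
class SlopeComparison:
    """Welch t comparison of two regression slopes."""

    t_statistic: float
    df: float
    p_value: float
    p_adjusted_rank1: float   # Sidak-adjusted assuming smallest rank in family
    family_size: int
    significant_rank1: bool


def compare_slopes(a: RegressionResult, b: RegressionResult,
                   family_size: int = 24, alpha: float = 0.05) -> SlopeComparison:
    """Compare the absolute slopes of two regressions (Welch t on the
    regression standard errors, Welch-Satterthwaite df).

    The returned adjusted quantities treat this test as the smallest-rank
    member of a Holm-Sidak family of ``family_size`` tests, i.e. the most
    conservative step; use :func:`holm_sidak` for full-family step-down
    decisions.
    """
    if family_size < 1:
        raise InvalidInputError("family_size must be >= 1")
    se2 = a.slope_se ** 2 + b.slope_se ** 2
    if se2 == 0:
        t = 0.0 if abs(a.slope) == abs(b.slope) else math.inf
        df = a.n + b.n - 4
    else:
        t = (abs(a.slope) - abs(b.slope)) / math.sqrt(se2)
        df1, df2 = a.n - 2, b.n - 2
        df = se2 ** 2 / (a.slope_se ** 4 / df1 + b.slope_se ** 4 / df2)
    p = 2.0 * stats.t.sf(abs(t), df) if math.isfinite(t) else 0.0
    p_adj = 1.0 - (1.0 - p) ** family_size
    threshold = 1.0 - (1.0 - alpha) ** (1.0 / family_size)
    return SlopeComparison(
        t_statistic=float(t), df=float(df), p_value=float(p),
        p_adjusted_rank1=float(min(p_adj, 1.0)), family_size=family_size,
        significant_rank1=bool(p < threshold))


def sidak_thresholds(m: int, alpha: float = 0.05) -> np.ndarray:
    """Holm-Sidak per-rank thresholds: 1 - (1-alpha)^(1/(m-i)) for
    ascending rank i = 0..m-1."""
    if m < 1:
        raise InvalidInputError("family size must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / (m - np.arange(m)))


def holm_sidak(p_values, alpha: float = 0.05):
    """Holm-Sidak step-down decisions and adjusted p values.

    Tests are ordered by raw p; rank i (0-based) is tested at
    1-(1-alpha)^(1/(m-i)) and testing stops at the first non-rejection.
    Adjusted p values are the running maxima of 1-(1-p_(i))^(m-i).
    Returns (reject, p_adjusted) in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidInputError("p_values must be a nonempty 1-D array")
    if np.any((p < 0) | (p > 1)):
        raise InvalidInputError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = sidak_thresholds(m, alpha)
    reject_sorted = np.zeros(m, dtype=bool)
    for i in range(m):
        if p[order[i]] < thresholds[i]:
            reject_sorted[i] = True
        else:
            break
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    reject = np.zeros(m, dtype=bool)
    p_adj = np.zeros(m)
    reject[order] = reject_sorted
    p_adj[order] = np.minimum(adj_sorted, 1.0)
    return reject, p_adj


@dataclass(frozen=True)
class IdealModelFit:
    """Coefficients of the ideal-metric model and its specificity."""

    metric: str
    alpha: float      # %M0 per pH unit
    beta: float       # %M0 per %w/v protein
    epsilon: float    # %M0
    r_squared: float  # squared Pearson corr. of predicted vs measured
    clipped: bool = False


def fit_ideal_model(ph, bsa, values, *, metric: str = "") -> IdealModelFit:
    """Least-squares (alpha, beta, epsilon) over pooled phantoms, plus the
    specificity r^2.

    The theoretical effect alpha*pH + beta*[BSA] + epsilon is evaluated for
    every phantom — including the relaxation arms, where it is constant —
    and correlated against the measured values; metrics contaminated by
    T1/T2 variation decorrelate and score low.
    """
    ph = np.asarray(ph, dtype=float)
    bsa = np.asarray(bsa, dtype=float)
    y = np.asarray(values, dtype=float)
    if not (ph.size == bsa.size == y.size):
        raise InvalidInputError("ph, bsa and values must have equal length")
    X = np.column_stack([ph, bsa, np.ones_like(ph)])
    if np.linalg.matrix_rank(X) < 3:
        raise InvalidInputError(
            "rank-deficient design: need variation in both pH and [BSA]")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    predicted = X @ coef
    clipped = False
    if np.ptp(predicted) == 0 or np.ptp(y) == 0:
        r2, clipped = 0.0, True
    else:
        r = np.corrcoef(predicted, y)[0, 1]
        r2 = float(r ** 2)
        if not np.isfinite(r2):
            r2, clipped = 0.0, True
    return IdealModelFit(metric=metric, alpha=float(coef[0]),
                         beta=float(coef[1]), epsilon=float(coef[2]),
                         r_squared=r2, clipped=clipped)


@dataclass(frozen=True)
class DeltaPHResult:
    """Pairwise CEST-effect difference and its pH interpretation."""

    id_a: str
    id_b: str
    delta_cest: float
    sigma_delta: float
    significant: bool
    calculated_delta_ph: float
    experimental_delta_ph: float

    @property
    def sign_correct(self) -> bool:
        return (np.sign(self.calculated_delta_ph)
                == np.sign(self.experimental_delta_ph))


def delta_cest_significance(value_a: float, sd_a: float,
                            value_b: float, sd_b: float):
    """Quadrature significance rule for a pairwise difference.

    Returns (delta, sigma, significant): the difference is significant
    when it exceeds the two measurement sds added in quadrature.
    """
    delta = value_a - value_b
    sigma = math.sqrt(sd_a ** 2 + sd_b ** 2)
    return delta, sigma, bool(abs(delta) > sigma)


def delta_ph(delta_cest: float, delta_bsa: float, model: IdealModelFit) -> float:
    """Invert the ideal-metric model for a pH difference.

    delta_pH = (delta_CEST - beta * delta_[BSA]) / alpha; with matched
    protein content this reduces to delta_CEST / alpha.
    """
    if model.alpha == 0:
        raise InvalidInputError("alpha = 0: model carries no pH sensitivity")
    return (delta_cest - model.beta * delta_bsa) / model.alpha


def sign_accuracy(results, threshold: float = 0.6) -> dict:
    """Sign-prediction accuracy of significant pairs, grouped by the
    magnitude of the experimental pH difference.

    Groups: experimental delta-pH below -threshold, within +/-threshold,
    above +threshold.  Per group the fraction of *significant* pairs whose
    calculated delta-pH has the correct sign; empty groups report None.
    """
    groups = {"below": [], "within": [], "above": []}
    for r in results:
        if not r.significant:
            continue
        if r.experimental_delta_ph < -threshold:
            groups["below"].append(r)
        elif r.experimental_delta_ph > threshold:
            groups["above"].append(r)
        else:
            groups["within"].append(r)
    out = {}
    for name, members in groups.items():
        if not members:
            out[name] = {"n": 0, "accuracy": None}
        else:
            correct = sum(1 for r in members if r.sign_correct)
            out[name] = {"n": len(members),
                         "accuracy": correct / len(members)}
    return out
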