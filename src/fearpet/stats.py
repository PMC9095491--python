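"""Subject-level inference for directed hypotheses.

Implements the statistics used at the cohort level: a directed paired t-test
of baseline versus post-challenge binding potential (reported with the mean
per-subject percent change and its two-sided 95% CI), directed Pearson
correlations with one-sided p-values and one-sided 95% intervals of the form
[L, 1], a bivariate Mahalanobis outlier screen against chi-square with 2
degrees of freedom at P < 0.001, and Steiger's (1980) Z for comparing two
dependent correlations that share one variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "RegionSummary",
    "CorrelationResult",
    "paired_directed_test",
    "pearson_directed",
    "mahalanobis_screen",
    "dependent_corr_compare",
    "MAHALANOBIS_P",
]

#: Outlier criterion for the Mahalanobis screen.
MAHALANOBIS_P = 0.001


@dataclass(frozen=True)
class RegionSummary:
    """Directed paired comparison of baseline vs post binding potential."""

    n: int
    df: int
    t: float
    p_one_sided: float
    mean_pct_change: float          # mean of per-subject 100*(1 - post/base)
    ci_low: float                   # two-sided 95% CI of the mean change
    ci_high: float
    pct_change: np.ndarray          # per-subject values


@dataclass(frozen=True)
class CorrelationResult:
    """Directed Pearson correlation with a one-sided 95% interval."""

    r: float
    n: int
    p_one_sided: float
    ci_low: float                   # interval is (ci_low, 1] for direction="positive"
    ci_high: float = 1.0
    direction: str = "positive"


def paired_directed_test(baseline: np.ndarray, post: np.ndarray,
                         direction: str = "decrease",
                         pct_change_of_means: bool = False) -> RegionSummary:
    """Directed paired t-test of post-challenge vs baseline values.

    ``direction="decrease"`` tests the one-sided hypothesis post < baseline
    (release); ``"increase"`` the opposite.  The percent change is summarised
    per subject as 100*(1 - post/base) and averaged (set
    ``pct_change_of_means`` to report the percent change of the means
    instead); its 95% CI is two-sided, matching the usual reporting style.
    """
    base = np.asarray(baseline, dtype=float)
    post = np.asarray(post, dtype=float)
    if base.shape != post.shape or base.ndim != 1:
        raise ValueError("baseline and post must be 1-D arrays of equal length")
    n = base.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if direction not in ("decrease", "increase"):
        raise ValueError("direction must be 'decrease' or 'increase'")
    diff = base - post
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("paired differences have zero variance")
    t = diff.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = sps.t.sf(t, df) if direction == "decrease" else sps.t.cdf(t, df)

    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(base > 0, 100.0 * (1.0 - post / base), np.nan)
    ok = np.isfinite(pct)
    n_ok = int(ok.sum())   # subjects with base <= 0 have no defined % change
    if pct_change_of_means:
        mean_pct = 100.0 * (1.0 - post.mean() / base.mean())
    else:
        mean_pct = float(pct[ok].mean()) if n_ok else np.nan
    se = (pct[ok].std(ddof=1) / np.sqrt(n_ok)) if n_ok > 1 else np.nan
    tcrit = sps.t.ppf(0.975, df)
    return RegionSummary(n=n, df=df, t=float(t), p_one_sided=float(p),
                         mean_pct_change=float(mean_pct),
                         ci_low=float(mean_pct - tcrit * se),
                         ci_high=float(mean_pct + tcrit * se),
                         pct_change=pct)


def pearson_directed(x: np.ndarray, y: np.ndarray,
                     direction: str = "positive") -> CorrelationResult:
    """Pearson correlation with a one-sided p-value and directed interval.

    The one-sided p comes from t = r sqrt((n-2)/(1-r^2)); the directed 95%
    interval is [L, 1] (or [-1, U]) with the bound from the one-sided
    Fisher-z confidence limit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in input")
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        t = np.inf * np.sign(r)
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    df = n - 2
    p = sps.t.sf(t, df) if direction == "positive" else sps.t.cdf(t, df)
    z = np.arctanh(r)
    zcrit = sps.norm.ppf(0.95)
    half = zcrit / np.sqrt(n - 3)
    if direction == "positive":
        lo, hi = float(np.tanh(z - half)), 1.0
    else:
        lo, hi = -1.0, float(np.tanh(z + half))
    return CorrelationResult(r=r, n=n, p_one_sided=float(p),
                             ci_low=lo, ci_high=hi, direction=direction)


def mahalanobis_screen(points: np.ndarray, p_crit: float = MAHALANOBIS_P):
    """Bivariate outlier screen: MD^2 against the chi-square(2) quantile.

    Squared Mahalanobis distances from the sample mean and covariance are
    compared with the chi-square (df = 2) quantile at 1 - ``p_crit``
    (13.8155 at the standard P < 0.001 criterion).  Returns
    ``(md2, flags, threshold)``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = pts.shape[0]
    if n < 4:
        raise ValueError("need at least 4 points")
    mu = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    if abs(np.linalg.det(cov)) < 1e-300:
        raise np.linalg.LinAlgError("singular sample covariance")
    vi = np.linalg.inv(cov)
    d = pts - mu
    md2 = np.einsum("ij,jk,ik->i", d, vi, d)
    threshold = float(sps.chi2.ppf(1.0 - p_crit, df=2))
    return md2, md2 > threshold, threshold


def dependent_corr_compare(r12: float, r13: float, r23: float, n: int):
    """Steiger's (1980) Z for two dependent correlations sharing variable 1.

    Tests r12 against r13 when both involve variable 1 and variables 2 and 3
    are themselves correlated at r23, using the pooled-correlation
    modification of the Dunn-Clark statistic:

        Z = (z12 - z13) sqrt((n - 3) / (2 (1 - s))),

    with z the Fisher transforms, rbar = (r12 + r13)/2 and
    s = [r23 (1 - 2 rbar^2) - rbar^2 (1 - 2 rbar^2 - r23^2) / 2]
        / (1 - rbar^2)^2.

    Returns ``(Z, p_one_sided)`` for the hypothesis r12 > r13.
    """
    for r in (r12, r13, r23):
        if abs(r) > 1:
            raise ValueError("correlations must lie in [-1, 1]")
    if n < 10:
        raise ValueError("need n >= 10")
    R = np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])
    if np.linalg.eigvalsh(R).min() < -1e-10:
        raise ValueError("inconsistent correlation triple (non-PSD matrix)")
    z12, z13 = np.arctanh(r12), np.arctanh(r13)
    rbar = 0.5 * (r12 + r13)
    psi = r23 * (1.0 - 2.0 * rbar ** 2) - \
        0.5 * rbar ** 2 * (1.0 - 2.0 * rbar ** 2 - r23 ** 2)
    s = psi / (1.0 - rbar ** 2) ** 2
    Z = (z12 - z13) * np.sqrt((n - 3) / (2.0 * (1.0 - s)))
    return float(Z), float(sps.norm.sf(Z))
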