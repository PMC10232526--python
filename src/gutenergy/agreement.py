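"""Agreement between measured and modeled quantities.

Lin's concordance correlation coefficient rho_c decomposes agreement into a
precision component (Pearson's r) and an accuracy component (the bias
correction factor Cb), rho_c = r * Cb, using population (n-denominator)
moments per Lin's original definition.  Bland-Altman analysis quantifies
systematic bias (mean difference with t-based CI and 1.96-SD limits of
agreement) and proportional bias (OLS slope of the differences on the pair
means).  Differences are oriented measured - modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ConcordanceResult",
    "BlandAltmanResult",
    "PairedTResult",
    "lin_ccc",
    "bland_altman",
    "paired_two_tailed_t",
    "plot_concordance",
    "plot_bland_altman",
]


class DegenerateInputError(ValueError):
    """Raised for inputs without the variance the statistic requires."""


@dataclass(frozen=True)
class ConcordanceResult:
    rho_c: float   # concordance correlation coefficient
    r: float       # Pearson correlation (precision)
    cb: float      # bias correction factor (accuracy); rho_c = r * cb
    n: int


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    ci95_mean_diff: tuple[float, float]
    loa_low: float
    loa_high: float
    prop_slope: float
    prop_p: float
    sd_diff: float
    n: int


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float


def _clean_pair(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {x.size}")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("inputs must be finite")
    return x, y


def lin_ccc(x, y) -> ConcordanceResult:
    """Lin's concordance correlation coefficient with its r/Cb decomposition.

    ``rho_c = 2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)`` with
    population (n-denominator) moments.  ``cb = rho_c / r`` is NaN when
    r = 0 (rho_c is still returned).
    """
    x, y = _clean_pair(x, y, 3)
    n = x.size
    mx, my = x.mean(), y.mean()
    sx2 = np.mean((x - mx) ** 2)
    sy2 = np.mean((y - my) ** 2)
    if sx2 == 0.0 or sy2 == 0.0:
        raise DegenerateInputError("lin_ccc requires non-zero variance in both vectors")
    sxy = np.mean((x - mx) * (y - my))
    rho_c = 2.0 * sxy / (sx2 + sy2 + (mx - my) ** 2)
    r = sxy / np.sqrt(sx2 * sy2)
    cb = rho_c / r if r != 0.0 else float("nan")
    return ConcordanceResult(float(rho_c), float(r), float(cb), n)


def bland_altman(x, y, loa_sd: float = 1.96) -> BlandAltmanResult:
    """Bland-Altman agreement of x (measured) vs y (modeled).

    Differences ``d = x - y``; limits of agreement are mean +/- 1.96 SD (of
    d, sample SD); proportional bias is the OLS slope of d on (x+y)/2.
    """
    x, y = _clean_pair(x, y, 3)
    d = x - y
    n = d.size
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    ci = (mean_diff - tcrit * se, mean_diff + tcrit * se)
    means = (x + y) / 2.0
    if np.ptp(means) == 0.0 or sd == 0.0:
        slope, pval = 0.0, 1.0
    else:
        fit = stats.linregress(means, d)
        slope, pval = float(fit.slope), float(fit.pvalue)
    return BlandAltmanResult(
        mean_diff=mean_diff,
        ci95_mean_diff=ci,
        loa_low=mean_diff - loa_sd * sd,
        loa_high=mean_diff + loa_sd * sd,
        prop_slope=slope,
        prop_p=pval,
        sd_diff=sd,
        n=n,
    )


def paired_two_tailed_t(x, y) -> PairedTResult:
    """Classical paired t-test on x - y (df = n - 1, two-sided P).

    Zero-variance differences are degenerate: P = 1 if the common
    difference is zero, else P = 0 (reported, not raised).
    """
    x, y = _clean_pair(x, y, 2)
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return PairedTResult(0.0, n - 1, 1.0)
        return PairedTResult(float("inf") if d.mean() > 0 else float("-inf"), n - 1, 0.0)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return PairedTResult(float(t), n - 1, float(p))


def plot_concordance(x, y, ax=None, xlabel="measured", ylabel="modeled"):
    """Scatter of pairs with the identity line and the OLS fit annotated with rho_c."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x, y = _clean_pair(x, y, 3)
    res = lin_ccc(x, y)
    lim = [min(x.min(), y.min()), max(x.max(), y.max())]
    ax.plot(lim, lim, "k-", lw=1, label="identity")
    fit = stats.linregress(x, y)
    ax.plot(lim, [fit.intercept + fit.slope * v for v in lim], "k--", lw=1, label="OLS")
    ax.scatter(x, y)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title(f"rho_c={res.rho_c:.3f}  r={res.r:.3f}  Cb={res.cb:.3f}")
    ax.legend()
    return ax


def plot_bland_altman(x, y, ax=None):
    """Difference-vs-mean plot with bias line and limits of agreement."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x, y = _clean_pair(x, y, 3)
    res = bland_altman(x, y)
    means = (x + y) / 2.0
    ax.scatter(means, x - y)
    for level, style in ((res.mean_diff, "-"), (res.loa_low, "--"), (res.loa_high, "--")):
        ax.axhline(level, color="k", ls=style, lw=1)
    ax.set_xlabel("pair mean")
    ax.set_ylabel("measured - modeled")
    ax.set_title(f"bias={res.mean_diff:.3f}  slope={res.prop_slope:.3f} (P={res.prop_p:.3f})")
    return ax
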