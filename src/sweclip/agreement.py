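"""Method-comparison statistics: Spearman, Bland-Altman, and Shieh's exact test.

Validation of a new analysis method against a reference runs three
complementary analyses on paired per-clip values:

* Spearman's rank correlation (convergent validity);
* the Bland-Altman workflow: bias (mean difference) with a t-based 95% CI,
  limits of agreement at ``bias +- 1.96 * SD`` of the differences, and a
  proportional-bias check by regressing differences on averages — repeated
  on log-transformed data to separate true proportional bias from
  non-normality;
* Shieh's exact agreement test, which rejects non-agreement when the exact
  one-sided noncentral-t confidence bounds for the population central
  coverage range ``mu -+ gamma * sigma`` fall inside pre-specified margins.

The difference convention is ``d = a - b`` (method A minus reference B).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedSeries",
    "BlandAltmanResult",
    "RegressionResult",
    "ShiehResult",
    "MethodComparison",
    "spearman_correlation",
    "bland_altman",
    "proportional_bias_regression",
    "shieh_agreement_test",
    "compare_methods",
    "bland_altman_plot",
    "correlation_plot",
]

LOA_MULTIPLIER = 1.96  # fixed, not t-based, by convention


@dataclass
class PairedSeries:
    """Per-clip values from two analysis methods, index-matched."""

    a: np.ndarray
    b: np.ndarray
    unit: str = ""

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("paired series must be 1-d arrays of equal length")
        if self.n < 3:
            raise ValueError("paired comparison needs at least 3 pairs")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.b))):
            raise ValueError("paired series must be finite")

    @property
    def n(self) -> int:
        return len(self.a)

    def log(self) -> "PairedSeries":
        if np.any(self.a <= 0) or np.any(self.b <= 0):
            raise ValueError("log transform requires strictly positive values")
        return PairedSeries(np.log(self.a), np.log(self.b), unit=f"log({self.unit})")


@dataclass
class RegressionResult:
    """OLS of differences on averages (proportional-bias check)."""

    slope: float
    intercept: float
    F: float
    p: float
    exact_fit: bool = False


@dataclass
class BlandAltmanResult:
    n: int
    bias: float
    bias_ci: tuple
    sd_diff: float
    loa: tuple
    loa_width: float
    pct_within: float
    reg_slope: float | None
    reg_intercept: float | None
    reg_F: float | None
    reg_p: float | None
    log_transformed: bool = False


@dataclass
class ShiehResult:
    n: int
    mean_diff: float
    sd_diff: float
    gamma: float
    alpha: float
    coverage: float
    bound_low: float
    bound_high: float
    delta: tuple
    reject_h0: bool  # True = methods interchangeable within delta


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _exact_spearman_p(ra: np.ndarray, rb: np.ndarray, rho_obs: float,
                      chunk: int = 200_000) -> float:
    """Two-sided permutation p-value by full enumeration of pairings."""
    ac = ra - ra.mean()
    bc = rb - rb.mean()
    denom = np.sqrt((ac ** 2).sum() * (bc ** 2).sum())
    target = abs(rho_obs) - 1e-12
    it = itertools.permutations(bc)
    count = total = 0
    while True:
        block = list(itertools.islice(it, chunk))
        if not block:
            break
        rhos = np.asarray(block) @ ac / denom
        count += int(np.sum(np.abs(rhos) >= target))
        total += len(block)
    return count / total


def spearman_correlation(s: PairedSeries, exact_max_n: int = 10):
    """Spearman's rho with a two-sided p-value.

    rho is the Pearson correlation of average ranks. The p-value is exact
    (full permutation enumeration) for n <= ``exact_max_n`` and otherwise
    uses the t approximation with n - 2 degrees of freedom.
    """
    ra, rb = _rank(s.a), _rank(s.b)
    if np.ptp(ra) == 0 or np.ptp(rb) == 0:
        raise ValueError("Spearman correlation undefined: a series has zero rank variance")
    rho = float(np.corrcoef(ra, rb)[0, 1])
    if s.n <= exact_max_n:
        p = _exact_spearman_p(ra, rb, rho)
    elif abs(rho) >= 1.0 - 1e-15:
        p = 0.0
    else:
        t = rho * np.sqrt((s.n - 2) / (1.0 - rho ** 2))
        p = float(2.0 * sps.t.sf(abs(t), s.n - 2))
    return rho, p


def proportional_bias_regression(means, diffs) -> RegressionResult:
    """OLS of differences on averages, with the slope F-test on (1, n-2) df.

    A slope different from zero signals proportional bias (or non-normal
    differences). Degenerate cases: constant differences give slope 0, F 0,
    p 1; a perfect non-constant linear fit gives p 0 with ``exact_fit`` set.
    """
    means = np.asarray(means, dtype=float)
    diffs = np.asarray(diffs, dtype=float)
    n = len(means)
    if n < 3 or len(diffs) != n:
        raise ValueError("regression needs >= 3 matched pairs")
    mc = means - means.mean()
    sxx = float((mc ** 2).sum())
    if sxx == 0:
        raise ValueError("averages are constant; proportional-bias regression undefined")
    slope = float((mc * (diffs - diffs.mean())).sum() / sxx)
    intercept = float(diffs.mean() - slope * means.mean())
    fitted = intercept + slope * means
    sse = float(((diffs - fitted) ** 2).sum())
    ssr = float(((fitted - diffs.mean()) ** 2).sum())
    scale = max(float((diffs ** 2).sum()), 1.0)
    if sse <= 1e-12 * scale:
        if ssr <= 1e-12 * scale:
            return RegressionResult(0.0, intercept, 0.0, 1.0)
        return RegressionResult(slope, intercept, float("inf"), 0.0, exact_fit=True)
    F = ssr / (sse / (n - 2))
    p = float(sps.f.sf(F, 1, n - 2))
    return RegressionResult(slope, intercept, float(F), p)


def bland_altman(s: PairedSeries, log_transform: bool = False) -> BlandAltmanResult:
    """The full Bland-Altman computation on raw or log-transformed pairs.

    Differences are ``a - b``; the bias CI uses the t distribution with
    n - 1 df; the limits of agreement are ``bias +- 1.96 * SD`` (SD with
    the n - 1 denominator). When the differences are constant the
    regression fields are undefined (None) and everything else is computed.
    """
    if log_transform:
        s = s.log()
    d = s.a - s.b
    m = (s.a + s.b) / 2.0
    n = s.n
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa = (bias - LOA_MULTIPLIER * sd, bias + LOA_MULTIPLIER * sd)
    half = float(sps.t.ppf(0.975, n - 1)) * sd / np.sqrt(n)
    bias_ci = (float(bias - half), float(bias + half))
    pct_within = float(100.0 * np.mean((d >= loa[0]) & (d <= loa[1])))
    if sd == 0 or np.ptp(m) == 0:
        reg = None
    else:
        reg = proportional_bias_regression(m, d)
    return BlandAltmanResult(
        n=n, bias=bias, bias_ci=bias_ci, sd_diff=sd, loa=loa,
        loa_width=loa[1] - loa[0], pct_within=pct_within,
        reg_slope=None if reg is None else reg.slope,
        reg_intercept=None if reg is None else reg.intercept,
        reg_F=None if reg is None else reg.F,
        reg_p=None if reg is None else reg.p,
        log_transformed=log_transform,
    )


def shieh_agreement_test(diffs, delta, alpha: float = 0.05,
                         coverage: float = 0.95) -> ShiehResult:
    """Shieh's exact agreement test for paired differences.

    Tests whether the population central ``coverage`` range of the
    differences, ``(mu - gamma * sigma, mu + gamma * sigma)`` with
    ``gamma`` the standard-normal quantile at ``(1 + coverage) / 2``, lies
    inside the agreement margins ``delta``. Exact one-sided ``1 - alpha``
    confidence bounds come from the noncentral t distribution:

        bound = mean -+ q * sd / sqrt(n),
        q = nct.ppf(1 - alpha, df=n - 1, nc=sqrt(n) * gamma)

    The two bounds form a ``1 - 2 * alpha`` confidence interval (90% at the
    default alpha = 0.05). H0 (non-agreement) is rejected — the methods are
    declared interchangeable — iff both bounds fall strictly inside delta.
    """
    d = np.asarray(diffs, dtype=float)
    n = len(d)
    if n < 3:
        raise ValueError("Shieh's test needs at least 3 differences")
    lo, hi = (float(delta[0]), float(delta[1]))
    if not lo < hi:
        raise ValueError(f"invalid agreement margins {delta}")
    if not (0.0 < alpha < 0.5):
        raise ValueError("alpha must be in (0, 0.5)")
    if not (0.0 < coverage < 1.0):
        raise ValueError("coverage must be in (0, 1)")
    gamma = float(sps.norm.ppf((1.0 + coverage) / 2.0))
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        bound_low = bound_high = mean
    else:
        q = float(sps.nct.ppf(1.0 - alpha, df=n - 1, nc=np.sqrt(n) * gamma))
        bound_low = mean - q * sd / np.sqrt(n)
        bound_high = mean + q * sd / np.sqrt(n)
    reject = bool(lo < bound_low and bound_high < hi)
    return ShiehResult(n=n, mean_diff=mean, sd_diff=sd, gamma=gamma, alpha=alpha,
                       coverage=coverage, bound_low=bound_low, bound_high=bound_high,
                       delta=(lo, hi), reject_h0=reject)


@dataclass
class MethodComparison:
    """Serialised report of the full method-comparison workflow."""

    unit: str
    n: int
    ids: list
    unmatched_a: list
    unmatched_b: list
    spearman_rho: float
    spearman_p: float
    bland_altman_raw: BlandAltmanResult
    bland_altman_log: BlandAltmanResult | None
    shieh_raw: ShiehResult | None
    shieh_log: ShiehResult | None

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, float) and np.isinf(obj):
                return "inf"
            return obj

        return clean(asdict(self))


def compare_methods(a, b, unit: str = "kPa", delta=None, delta_log=None,
                    alpha: float = 0.05, coverage: float = 0.95) -> MethodComparison:
    """Run Spearman + Bland-Altman (raw and log) + Shieh on matched clips.

    ``a`` and ``b`` are pandas Series (or mappings) of per-clip summary
    values indexed by a shared clip identifier, with the convention
    ``difference = a - b``. Unmatched identifiers are excluded with a
    warning. Shieh's test runs only when agreement margins are supplied
    (``delta`` for the raw branch, ``delta_log`` for the log branch) —
    margins are a substantive choice with no defensible default. The log
    branch is skipped when any value is non-positive.
    """
    sa, sb = pd.Series(dict(a) if isinstance(a, dict) else a), \
        pd.Series(dict(b) if isinstance(b, dict) else b)
    if not isinstance(a, (pd.Series, dict)) or not isinstance(b, (pd.Series, dict)):
        if len(sa) != len(sb):
            raise ValueError(f"paired series of different lengths: {len(sa)} vs {len(sb)}")
    common = sa.index.intersection(sb.index)
    unmatched_a = sorted(map(str, sa.index.difference(sb.index)))
    unmatched_b = sorted(map(str, sb.index.difference(sa.index)))
    if unmatched_a or unmatched_b:
        warnings.warn(
            f"excluding unmatched clip identifiers: only in A {unmatched_a}, "
            f"only in B {unmatched_b}", stacklevel=2)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} matched clips; need at least 3")
    series = PairedSeries(sa.loc[common].to_numpy(), sb.loc[common].to_numpy(), unit=unit)

    rho, p = spearman_correlation(series)
    ba_raw = bland_altman(series, log_transform=False)
    positive = np.all(series.a > 0) and np.all(series.b > 0)
    ba_log = bland_altman(series, log_transform=True) if positive else None
    d = series.a - series.b
    shieh_raw = (shieh_agreement_test(d, delta, alpha, coverage)
                 if delta is not None else None)
    shieh_log = (shieh_agreement_test(np.log(series.a) - np.log(series.b),
                                      delta_log, alpha, coverage)
                 if (delta_log is not None and positive) else None)
    return MethodComparison(
        unit=unit, n=len(common), ids=[str(i) for i in common],
        unmatched_a=unmatched_a, unmatched_b=unmatched_b,
        spearman_rho=rho, spearman_p=p,
        bland_altman_raw=ba_raw, bland_altman_log=ba_log,
        shieh_raw=shieh_raw, shieh_log=shieh_log,
    )


def bland_altman_plot(s: PairedSeries, result: BlandAltmanResult | None = None,
                      log_transform: bool = False, ax=None):
    """Scattergram of differences on averages with bias, LoA, and trend line."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if result is None:
        result = bland_altman(s, log_transform=log_transform)
    if log_transform:
        s = s.log()
    d = s.a - s.b
    m = (s.a + s.b) / 2.0
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(m, d, s=14, alpha=0.7, edgecolor="none")
    ax.axhline(result.bias, color="black", lw=1.2, label=f"bias {result.bias:.3g}")
    for y in result.loa:
        ax.axhline(y, color="black", lw=1.0, ls="--")
    if result.reg_slope is not None:
        xs = np.linspace(m.min(), m.max(), 50)
        ax.plot(xs, result.reg_intercept + result.reg_slope * xs,
                color="goldenrod", lw=1.5, label="trend")
    ax.set_xlabel(f"mean of methods [{s.unit}]")
    ax.set_ylabel(f"difference A - B [{s.unit}]")
    ax.legend(loc="best", fontsize=8)
    return ax


def correlation_plot(s: PairedSeries, ax=None):
    """Scatter of method A against method B with the line of equality."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(s.b, s.a, s=14, alpha=0.7, edgecolor="none")
    lims = [min(s.a.min(), s.b.min()), max(s.a.max(), s.b.max())]
    ax.plot(lims, lims, "k--", lw=1.0, label="equality")
    slope, intercept = np.polyfit(s.b, s.a, 1)
    xs = np.linspace(lims[0], lims[1], 50)
    ax.plot(xs, intercept + slope * xs, color="goldenrod", lw=1.5, label="best fit")
    ax.set_xlabel(f"method B [{s.unit}]")
    ax.set_ylabel(f"method A [{s.unit}]")
    ax.legend(loc="best", fontsize=8)
    return ax
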