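"""Method-agreement statistics for paired device measurements.

The validation design is a paired one: every specimen is measured on a
reference device (micro-CT-like) and a test device (HR-pQCT-like), and per
parameter the two series are compared by

* Pearson correlation with a 95% Fisher-z confidence interval, R^2 and a
  t-based p-value for r = 0,
* Bland-Altman agreement: mean difference (bias), 95% limits of agreement
  (bias +/- 1.96 SD of the differences), and an ordinary least-squares
  trend of differences on pair means to expose proportional bias,
* a two-sided paired t-test with the confidence interval of the mean
  difference.

All dispersions are sample standard deviations (ddof = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedMeasurements",
    "CorrelationResult",
    "BlandAltmanResult",
    "TTestResult",
    "describe",
    "fisher_ci",
    "pearson_ci",
    "bland_altman",
    "paired_ttest",
]


@dataclass
class PairedMeasurements:
    """Per-specimen pairs of one parameter from two devices."""

    parameter_name: str
    reference: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        self.test = np.asarray(self.test, dtype=float)
        if self.reference.ndim != 1 or self.test.ndim != 1:
            raise ValueError("reference and test must be 1D")
        if self.reference.size != self.test.size:
            raise ValueError("reference and test lengths differ")
        if self.reference.size < 3:
            raise ValueError("need n >= 3 pairs")
        if not (np.all(np.isfinite(self.reference)) and np.all(np.isfinite(self.test))):
            raise ValueError("missing or non-finite values are not allowed")

    @property
    def n(self) -> int:
        return self.reference.size

    @property
    def differences(self) -> np.ndarray:
        """Per-pair differences, test minus reference."""
        return self.test - self.reference

    @property
    def means(self) -> np.ndarray:
        return (self.test + self.reference) / 2.0


@dataclass
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    r2: float
    p: float


@dataclass
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    trend_slope: float
    trend_intercept: float
    trend_slope_ci: tuple[float, float] = field(default=(np.nan, np.nan))
    trend_intercept_ci: tuple[float, float] = field(default=(np.nan, np.nan))


@dataclass
class TTestResult:
    p: float
    diff_ci_low: float
    diff_ci_high: float
    mean_diff: float


def describe(values) -> tuple[float, float]:
    """Arithmetic mean and sample SD of a series (n >= 2)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    return float(v.mean()), float(v.std(ddof=1))


def fisher_ci(r: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Fisher z-transform confidence interval for a Pearson correlation.

    ``atanh(r) +/- z_{1-alpha/2} / sqrt(n - 3)``, back-transformed.  Needs
    only the coefficient and the sample size, so printed correlations can
    be checked without the raw data.
    """
    if not -1.0 < r < 1.0:
        raise ValueError("r must lie strictly inside (-1, 1) for a Fisher CI")
    if n < 4:
        raise ValueError("Fisher CI needs n >= 4")
    z = np.arctanh(r)
    half = sps.norm.ppf(1.0 - alpha / 2.0) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def pearson_ci(pairs: PairedMeasurements, alpha: float = 0.05) -> CorrelationResult:
    """Pearson r with Fisher-z CI, R^2 and the p-value for r = 0."""
    x, y = pairs.reference, pairs.test
    if pairs.n < 4:
        raise ValueError("correlation CI needs n >= 4 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the series")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) < 1.0:
        ci_low, ci_high = fisher_ci(r, pairs.n, alpha)
        t = r * np.sqrt((pairs.n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), pairs.n - 2))
    else:
        ci_low = ci_high = r
        p = 0.0
    return CorrelationResult(r=r, ci_low=ci_low, ci_high=ci_high, r2=r * r, p=p)


def bland_altman(pairs: PairedMeasurements) -> BlandAltmanResult:
    """Bland-Altman agreement of test against reference.

    Bias is the mean difference (test - reference); the limits of agreement
    are bias +/- 1.96 sample SD of the differences.  The proportional-bias
    trend is the OLS regression of differences on pair means, with 95%
    t-based CIs on slope and intercept (NaN when the means are constant).
    """
    d = pairs.differences
    m = pairs.means
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    if m.std() == 0:
        return BlandAltmanResult(bias=bias, loa_low=loa_low, loa_high=loa_high,
                                 sd_diff=sd, trend_slope=0.0, trend_intercept=bias)
    fit = sps.linregress(m, d)
    n = pairs.n
    tq = sps.t.ppf(0.975, n - 2)
    slope_ci = (fit.slope - tq * fit.stderr, fit.slope + tq * fit.stderr)
    icept_ci = (fit.intercept - tq * fit.intercept_stderr,
                fit.intercept + tq * fit.intercept_stderr)
    return BlandAltmanResult(
        bias=bias, loa_low=loa_low, loa_high=loa_high, sd_diff=sd,
        trend_slope=float(fit.slope), trend_intercept=float(fit.intercept),
        trend_slope_ci=(float(slope_ci[0]), float(slope_ci[1])),
        trend_intercept_ci=(float(icept_ci[0]), float(icept_ci[1])),
    )


def paired_ttest(pairs: PairedMeasurements, alpha: float = 0.05) -> TTestResult:
    """Two-sided paired t-test with CI of the mean difference.

    Degenerate inputs (all differences identical, zero SD) return a
    zero-width CI at the common difference, with p = 1 when that difference
    is zero and p = NaN otherwise.
    """
    d = pairs.differences
    n = pairs.n
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        return TTestResult(p=1.0 if mean_d == 0 else np.nan,
                           diff_ci_low=mean_d, diff_ci_high=mean_d,
                           mean_diff=mean_d)
    tq = sps.t.ppf(1.0 - alpha / 2.0, n - 1)
    half = tq * sd / np.sqrt(n)
    t_stat = mean_d / (sd / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t_stat), n - 1))
    return TTestResult(p=p, diff_ci_low=mean_d - half, diff_ci_high=mean_d + half,
                       mean_diff=mean_d)
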