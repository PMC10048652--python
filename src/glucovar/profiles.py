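"""Descriptive statistics and time-series character of glucose profiles.

Each profile is summarised by count, mean, SD, quartiles, CV and skewness,
given a skewness class, and labelled for stationarity (ADF + KPSS, combined
as: stationary if both tests agree the series is stationary, difference
stationary if only ADF, trend stationary if only KPSS, else non-stationary)
and for seasonality (autocorrelation above 0.9 at some candidate period
between 1 hour and 7 days).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.tsa.stattools import acf, adfuller, kpss

from .series import GlucoseSeries

SYMMETRICAL = "Symmetrical"
MODERATELY_SKEWED = "Moderately Skewed"
HIGHLY_SKEWED = "Highly Skewed"


@dataclass
class ProfileStats:
    """One profile's descriptive row: counts, moments, quartiles, labels."""

    count: int
    mean: float
    sd: float
    q1: float
    q2: float
    q3: float
    cv: float
    skewness: float
    distribution_label: str
    days: int
    stationarity_label: str | None = None
    seasonal: bool | None = None
    period: int | None = None
    id: str | None = None


@dataclass
class CohortSummary:
    """(min, avg, max) triplets per statistic over a cohort of profiles."""

    fields: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def __getitem__(self, key: str) -> tuple[float, float, float]:
        return self.fields[key]


def classify_skewness(skew: float) -> str:
    """|skew| <= 0.5 is symmetrical, (0.5, 1] moderately skewed, > 1 highly
    skewed.  Boundary values go to the milder class."""
    if not np.isfinite(skew):
        raise ValueError("skewness must be finite")
    a = abs(skew)
    if a > 1.0:
        return HIGHLY_SKEWED
    if a > 0.5:
        return MODERATELY_SKEWED
    return SYMMETRICAL


def count_to_days(count: int, interval: float = 5.0) -> int:
    """Whole days of data represented by ``count`` samples at the given
    sampling interval (288 samples/day at 5 minutes)."""
    if count < 0:
        raise ValueError("count must be non-negative")
    return int(count // (1440.0 / interval))


def stationarity_label(adf_says_stationary: bool, kpss_says_stationary: bool) -> str:
    if adf_says_stationary and kpss_says_stationary:
        return "stationary"
    if adf_says_stationary:
        return "difference stationary"
    if kpss_says_stationary:
        return "trend stationary"
    return "non-stationary"


def _decimate_for_tests(
    x: np.ndarray, target_corr: float = 0.8, min_n: int = 300
) -> np.ndarray:
    """Thin a strongly autocorrelated sequence before unit-root testing.

    Stationarity is invariant to subsampling, but KPSS has severe size
    distortion when consecutive samples are nearly perfectly correlated
    (CGM traces at 5 minutes have lag-1 correlation ~0.98).  Doubling the
    stride until the lag-1 correlation of the tested sequence drops to
    ``target_corr`` — while keeping at least ``min_n`` points — restores
    the tests' nominal behaviour without altering their verdict class.
    """
    k = 1
    while len(x[:: 2 * k]) >= min_n:
        xs = x[::k]
        r = np.corrcoef(xs[1:], xs[:-1])[0, 1]
        if not np.isfinite(r) or abs(r) <= target_corr:
            break
        k *= 2
    return x[::k]


def run_stationarity_tests(
    s: GlucoseSeries | np.ndarray, alpha: float = 0.05
) -> tuple[bool, bool]:
    """ADF and KPSS verdicts on a series.

    ADF's null is a unit root, so "stationary" means rejection at ``alpha``;
    KPSS's null is (level) stationarity, so "stationary" means NOT rejecting.
    Missing slots are dropped and strongly autocorrelated series are thinned
    (see :func:`_decimate_for_tests`) before testing.
    """
    x = s.present_values() if isinstance(s, GlucoseSeries) else np.asarray(s, float)
    x = x[np.isfinite(x)]
    if len(x) < 50:
        raise ValueError(f"stationarity tests need >= 50 values, got {len(x)}")
    x = _decimate_for_tests(x)
    adf_p = adfuller(x, autolag="AIC")[1]
    with warnings.catch_warnings():
        # KPSS p-values are table-interpolated and warn outside [0.01, 0.1];
        # the verdict at alpha=0.05 is unaffected
        warnings.simplefilter("ignore")
        kpss_p = kpss(x, regression="c", nlags="auto")[1]
    return bool(adf_p < alpha), bool(kpss_p >= alpha)


def detect_seasonality(
    s: GlucoseSeries, threshold: float = 0.9, max_period_days: float = 7.0
) -> tuple[bool, int | None]:
    """Seasonal iff the autocorrelation exceeds ``threshold`` at some
    candidate period between 1 hour and ``max_period_days``.

    Candidate lags are whole multiples of 1 hour on the sampling grid; lags
    under 1 hour are excluded because consecutive CGM samples are trivially
    correlated.  Returns (seasonal, period-in-slots).
    """
    if s.span() < pd.Timedelta(days=2):
        raise ValueError("seasonality detection needs >= 2 days of data")
    x = pd.Series(s.values).interpolate(limit_direction="both").to_numpy()
    slots_per_hour = int(round(60.0 / s.interval))
    max_lag = min(int(max_period_days * 24) * slots_per_hour, len(x) // 2)
    # adjusted (unbiased) estimator: the default divisor damps long lags,
    # which would hide genuine daily periodicity in short windows
    r = acf(x, nlags=max_lag, fft=True, adjusted=True)
    candidates = np.arange(slots_per_hour, max_lag + 1, slots_per_hour)
    if len(candidates) == 0:
        return False, None
    # a period must be a local maximum of the ACF on the hourly candidate
    # grid (merely-high short lags reflect smoothness, not seasonality);
    # the smallest qualifying lag is the fundamental period
    for i, lag in enumerate(candidates):
        left = r[candidates[i - 1]] if i > 0 else r[0]
        right = r[candidates[i + 1]] if i + 1 < len(candidates) else -np.inf
        if r[lag] > threshold and r[lag] >= left and r[lag] >= right:
            return True, int(lag)
    return False, None


def describe(
    s: GlucoseSeries,
    run_tests: bool = True,
    alpha: float = 0.05,
    id: str | None = None,
) -> ProfileStats:
    """Full descriptive row for one profile.

    Sample SD (n-1 denominator), quartiles by linear interpolation between
    order statistics, adjusted Fisher-Pearson skewness, CV = 100*SD/mean.
    Stationarity/seasonality labelling is skipped when ``run_tests`` is
    False or the series is too short for the tests.
    """
    x = s.present_values()
    if len(x) < 2:
        raise ValueError("describe needs >= 2 present values")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    q1, q2, q3 = (float(q) for q in np.quantile(x, [0.25, 0.5, 0.75]))
    cv = 100.0 * sd / mean
    skew = float(sps.skew(x, bias=False)) if sd > 0 else 0.0
    st = ProfileStats(
        count=len(x),
        mean=mean,
        sd=sd,
        q1=q1,
        q2=q2,
        q3=q3,
        cv=cv,
        skewness=skew,
        distribution_label=classify_skewness(skew),
        days=count_to_days(len(x), s.interval),
        id=id,
    )
    if run_tests and len(x) >= 50:
        st.stationarity_label = stationarity_label(*run_stationarity_tests(s, alpha))
    if run_tests and s.span() >= pd.Timedelta(days=2):
        st.seasonal, st.period = detect_seasonality(s)
    return st


_NON_NUMERIC = ("distribution_label", "stationarity_label", "id", "seasonal", "period", "window", "absent")


def summarize_cohort(stats_list: list, ndigits: int = 2) -> CohortSummary:
    """Unweighted (min, arithmetic mean, max) per numeric field over a
    cohort, rounded for reporting (full precision is one call away from the
    per-profile objects)."""
    if not stats_list:
        raise ValueError("summarize_cohort needs a non-empty list")
    summary = CohortSummary()
    first = stats_list[0]
    for name in vars(first):
        if name in _NON_NUMERIC:
            continue
        vals = [getattr(obj, name) for obj in stats_list]
        vals = [v for v in vals if v is not None and np.isfinite(v)]
        if not vals:
            continue
        summary.fields[name] = (
            round(float(np.min(vals)), ndigits),
            round(float(np.mean(vals)), ndigits),
            round(float(np.max(vals)), ndigits),
        )
    return summary
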