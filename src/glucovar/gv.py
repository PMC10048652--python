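"""Glycemic-variability metrics.

Nineteen clinically used metrics computed from one glucose window: mean, SD,
CV, time below/in/above range, SD of the rate of change, low/high blood
glucose risk indices, glucose management indicator, J-index, CONGA, lability
index, GRADE, MODD, MAGE, ADRR, M-value and MAG.  All metrics use
complete-pair analysis over present readings — missing grid slots are never
imputed, so interpolation cannot bias difference-based metrics.

Input convention is mg/dL throughout; GRADE and the lability index convert
to mmol/L internally (factor 18.016) as their standard definitions require.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .series import MMOL_TO_MGDL, GlucoseSeries


@dataclass(frozen=True)
class RangeThresholds:
    """Target sensor glucose range, mg/dL (consensus default 70-180)."""

    low: float = 70.0
    high: float = 180.0

    def __post_init__(self) -> None:
        if self.low >= self.high:
            raise ValueError("low threshold must be below high")


@dataclass
class GVReport:
    """The 19 metric values for one glucose window.

    Metrics whose preconditions fail (e.g. MODD on a window of 24 h or
    less) are None, with the reason recorded in ``absent``.
    """

    mean: float | None = None
    sd: float | None = None
    cv: float | None = None
    tbr: float | None = None
    tir: float | None = None
    tar: float | None = None
    sd_roc: float | None = None
    lbgi: float | None = None
    hbgi: float | None = None
    gmi: float | None = None
    j_index: float | None = None
    conga: float | None = None
    li: float | None = None
    grade: float | None = None
    modd: float | None = None
    mage: float | None = None
    adrr: float | None = None
    m_value: float | None = None
    mag: float | None = None
    window: tuple | None = None
    id: str | None = None
    absent: dict = field(default_factory=dict)

    def metric_names(self) -> list[str]:
        skip = {"window", "absent", "id"}
        return [f.name for f in fields(self) if f.name not in skip]


def _present(s: GlucoseSeries) -> np.ndarray:
    x = s.present_values()
    if len(x) == 0:
        raise ValueError("empty glucose window")
    return x


def time_in_ranges(
    s: GlucoseSeries, thr: RangeThresholds = RangeThresholds()
) -> tuple[float, float, float]:
    """Percent of present readings below, inside and above the target range.

    Readings exactly at a threshold count as in range (the below/above
    inequalities are strict).  The three percentages sum to 100.
    """
    x = _present(s)
    n = len(x)
    nb = int((x < thr.low).sum())
    na = int((x > thr.high).sum())
    ni = n - nb - na
    return 100.0 * nb / n, 100.0 * ni / n, 100.0 * na / n


def glucose_risk(g: float) -> tuple[float, float]:
    """Symmetrised blood-glucose risk of a single reading (mg/dL).

    f(g) = 1.509*((ln g)^1.084 - 5.381) maps the clinical range onto a
    scale symmetric about ~112.5 mg/dL; risk is 10*f^2 split into its low
    (f<0) and high (f>0) branches.
    """
    if g <= 0:
        raise ValueError("glucose must be positive")
    f = 1.509 * (math.log(g) ** 1.084 - 5.381)
    r = 10.0 * f * f
    return (r, 0.0) if f < 0 else (0.0, r) if f > 0 else (0.0, 0.0)


def _risk_arrays(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    f = 1.509 * (np.log(x) ** 1.084 - 5.381)
    r = 10.0 * f * f
    return np.where(f < 0, r, 0.0), np.where(f > 0, r, 0.0)


def lbgi_hbgi(s: GlucoseSeries) -> tuple[float, float]:
    """Low/high blood-glucose risk indices: mean per-reading low and high
    risk over the window."""
    x = _present(s)
    if (x <= 0).any():
        raise ValueError("glucose readings must be positive")
    rl, rh = _risk_arrays(x)
    return float(rl.mean()), float(rh.mean())


def gmi(mean_mgdl: float) -> float:
    """Glucose management indicator (%): 3.31 + 0.02392 * mean CGM glucose
    (mg/dL) — an HbA1c-like mapping of the window mean."""
    if mean_mgdl <= 0:
        raise ValueError("mean glucose must be positive")
    return 3.31 + 0.02392 * mean_mgdl


def j_index(mean: float, sd: float) -> float:
    """Combined level-and-variability score 0.001*(mean+SD)^2, mg/dL inputs."""
    if mean < 0 or sd < 0:
        raise ValueError("mean and sd must be non-negative")
    return 0.001 * (mean + sd) ** 2


def conga(s: GlucoseSeries, n_hours: float = 1.0) -> float:
    """Continuous overall net glycemic action: sample SD of differences
    between readings exactly ``n_hours`` apart on the grid."""
    if s.span() <= pd.Timedelta(hours=n_hours):
        raise ValueError(f"window span must exceed {n_hours} h for CONGA")
    lag = int(round(n_hours * 60.0 / s.interval))
    v = s.values
    d = v[lag:] - v[:-lag]
    d = d[np.isfinite(d)]
    if len(d) < 2:
        raise ValueError("no valid reading pairs for CONGA")
    return float(np.std(d, ddof=1))


def li(s: GlucoseSeries) -> float:
    """Lability index: sum of squared consecutive hourly glucose changes
    (mmol/L) per elapsed hour, normalised per week of data."""
    if s.span() < pd.Timedelta(hours=2):
        raise ValueError("lability index needs >= 2 h of data")
    hourly = s.to_pandas().resample("1h").mean() / MMOL_TO_MGDL
    vals = hourly.to_numpy()
    hours = np.arange(len(vals), dtype=float)
    ok = np.isfinite(vals)
    vals, hours = vals[ok], hours[ok]
    if len(vals) < 2:
        raise ValueError("lability index needs >= 2 hourly values")
    dh = np.diff(hours)
    # only consecutive present hourly values contribute; pairs across gaps drop
    contrib = (np.diff(vals) ** 2 / dh)[dh == 1.0]
    weeks = len(hourly) / 168.0
    return float(contrib.sum() / weeks)


def grade(s: GlucoseSeries, cap: float = 50.0) -> float:
    """GRADE score: mean over readings of
    425*(log10(log10(g_mmol)) + 0.16)^2, each reading's contribution capped.

    Readings at or below 37 mg/dL (~2 mmol/L) are outside the log-log
    domain and raise an error naming the offending sample.
    """
    x = _present(s)
    bad = np.nonzero(x <= 37.0)[0]
    if len(bad):
        raise ValueError(
            f"GRADE undefined for glucose <= 37 mg/dL "
            f"(first offending reading {x[bad[0]]:.1f} mg/dL at index {bad[0]})"
        )
    h = 425.0 * (np.log10(np.log10(x / MMOL_TO_MGDL)) + 0.16) ** 2
    return float(np.minimum(h, cap).mean())


def modd(s: GlucoseSeries) -> float:
    """Mean of daily differences: mean |g(t) - g(t - 24 h)| over all grid
    slots where both readings are present."""
    if s.span() <= pd.Timedelta(hours=24):
        raise ValueError("MODD needs a window span > 24 h")
    lag = s.slots_per_day()
    d = s.values[lag:] - s.values[:-lag]
    d = d[np.isfinite(d)]
    if len(d) == 0:
        raise ValueError("no 24-h-apart reading pairs for MODD")
    return float(np.abs(d).mean())


def _turning_points(x: np.ndarray) -> np.ndarray:
    """Indices (into x) of alternating interior local extrema.

    Plateaus are collapsed before detection so monotone runs merge into
    single excursion legs; window endpoints are not extrema, so partial
    first/last legs never contribute excursions.
    """
    keep = np.concatenate(([True], np.diff(x) != 0))
    idx = np.nonzero(keep)[0]
    y = x[idx]
    if len(y) < 3:
        return idx[:0]
    interior = np.sign(np.diff(y[:-1])) != np.sign(np.diff(y[1:]))
    mask = np.concatenate(([False], interior, [False]))
    return idx[mask]


def mage(s: GlucoseSeries, direction: str = "both") -> float:
    """Mean amplitude of glycemic excursions.

    Turning points are found after merging monotone runs; an excursion
    (consecutive nadir-to-peak or peak-to-nadir leg) qualifies if its
    amplitude exceeds one SD of the whole window.  ``direction`` selects
    ascending legs, descending legs, or both (default).  0 if no excursion
    qualifies.
    """
    if direction not in ("both", "asc", "desc"):
        raise ValueError(f"unknown mage direction {direction!r}")
    if s.span() < pd.Timedelta(days=1):
        raise ValueError("MAGE needs >= 1 day of data")
    x = _present(s)
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        return 0.0
    tp = _turning_points(x)
    if len(tp) < 2:
        return 0.0
    legs = np.diff(x[tp])
    if direction == "asc":
        legs = legs[legs > 0]
    elif direction == "desc":
        legs = legs[legs < 0]
    amp = np.abs(legs)
    qual = amp[amp > sd]
    return float(qual.mean()) if len(qual) else 0.0


def _complete_days(s: GlucoseSeries, min_completeness: float = 0.8):
    """Yield (day, present-values) for UTC calendar days with at least
    ``min_completeness`` of their grid slots present."""
    ser = s.to_pandas()
    slots = s.slots_per_day()
    for day, grp in ser.groupby(ser.index.floor("1D")):
        vals = grp.dropna().to_numpy()
        if len(vals) >= min_completeness * slots:
            yield day, vals


def adrr(s: GlucoseSeries, min_completeness: float = 0.8) -> float:
    """Average daily risk range: per complete UTC day, the maximum low risk
    plus the maximum high risk; averaged over days."""
    if s.span() < pd.Timedelta(days=1):
        raise ValueError("ADRR needs >= 1 complete day")
    totals = []
    for _, vals in _complete_days(s, min_completeness):
        rl, rh = _risk_arrays(vals)
        totals.append(rl.max() + rh.max())
    if not totals:
        raise ValueError("no complete day (>= 80% of slots) for ADRR")
    return float(np.mean(totals))


def m_value(s: GlucoseSeries, reference: float = 120.0) -> float:
    """Schlichtkrull-style M-value: mean |10*log10(g/reference)|^3 over
    readings; reference 120 mg/dL."""
    x = _present(s)
    if (x <= 0).any():
        raise ValueError("glucose readings must be positive")
    return float((np.abs(10.0 * np.log10(x / reference)) ** 3).mean())


def mag(s: GlucoseSeries) -> float:
    """Mean absolute glucose change: sum of |consecutive differences| of
    present readings divided by the elapsed hours between the first and
    last present reading."""
    ts = s.timestamps[s.present]
    x = s.present_values()
    if len(x) < 2:
        raise ValueError("MAG needs >= 2 present values")
    hours = (ts[-1] - ts[0]).total_seconds() / 3600.0
    if hours == 0:
        raise ValueError("zero elapsed time")
    return float(np.abs(np.diff(x)).sum() / hours)


def sd_roc(s: GlucoseSeries, max_gap_min: float = 15.0) -> float:
    """SD of the glucose rate of change (mg/dL per minute) over consecutive
    present reading pairs at most ``max_gap_min`` apart."""
    ts = s.timestamps[s.present]
    x = s.present_values()
    if len(x) < 3:
        raise ValueError("SD-ROC needs >= 3 present values")
    dt = np.diff(ts.asi8) / 60e9  # minutes
    rates = np.diff(x) / dt
    rates = rates[dt <= max_gap_min]
    if len(rates) < 2:
        raise ValueError("fewer than 2 valid rate pairs for SD-ROC")
    return float(np.std(rates, ddof=1))


def gv_report(
    s: GlucoseSeries,
    thr: RangeThresholds = RangeThresholds(),
    conga_hours: float = 1.0,
    mage_direction: str = "both",
    id: str | None = None,
) -> GVReport:
    """All 19 metrics for one window; metrics whose preconditions fail are
    reported absent with the reason."""
    rep = GVReport(id=id)
    if len(s):
        rep.window = (s.timestamps[0], s.timestamps[-1])

    def attempt(name, fn):
        try:
            return fn()
        except ValueError as exc:
            rep.absent[name] = str(exc)
            return None

    x = s.present_values()
    if len(x) == 0:
        rep.absent["all"] = "empty window"
        return rep
    rep.mean = float(np.mean(x))
    rep.sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    rep.cv = 100.0 * rep.sd / rep.mean if rep.mean else None
    rep.tbr, rep.tir, rep.tar = time_in_ranges(s, thr)
    rep.gmi = gmi(rep.mean)
    rep.j_index = j_index(rep.mean, rep.sd)
    rep.sd_roc = attempt("sd_roc", lambda: sd_roc(s))
    lh = attempt("lbgi", lambda: lbgi_hbgi(s))
    if lh is not None:
        rep.lbgi, rep.hbgi = lh
    else:
        rep.absent["hbgi"] = rep.absent["lbgi"]
    rep.conga = attempt("conga", lambda: conga(s, conga_hours))
    rep.li = attempt("li", lambda: li(s))
    rep.grade = attempt("grade", lambda: grade(s))
    rep.modd = attempt("modd", lambda: modd(s))
    rep.mage = attempt("mage", lambda: mage(s, mage_direction))
    rep.adrr = attempt("adrr", lambda: adrr(s))
    rep.m_value = attempt("m_value", lambda: m_value(s))
    rep.mag = attempt("mag", lambda: mag(s))
    return rep
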