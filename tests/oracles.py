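"""Independent brute-force reference implementations of the GV metrics.

Deliberately naive (explicit Python loops, no shared code with the package)
so they serve as cross-checks for the vectorised implementations.
"""

import math

import numpy as np
import pandas as pd

MMOL = 18.016


def _present_pairs(series):
    ts = list(series.timestamps)
    vals = list(series.values)
    return ts, vals


def _sample_sd(xs):
    n = len(xs)
    m = sum(xs) / n
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (n - 1))


def conga_oracle(series, n_hours=1.0):
    ts, vals = _present_pairs(series)
    delta = pd.Timedelta(hours=n_hours)
    lookup = {t: v for t, v in zip(ts, vals) if not math.isnan(v)}
    diffs = []
    for t, v in lookup.items():
        prev = t - delta
        if prev in lookup:
            diffs.append(v - lookup[prev])
    return _sample_sd(diffs)


def modd_oracle(series):
    ts, vals = _present_pairs(series)
    delta = pd.Timedelta(hours=24)
    lookup = {t: v for t, v in zip(ts, vals) if not math.isnan(v)}
    diffs = [abs(v - lookup[t - delta]) for t, v in lookup.items() if t - delta in lookup]
    return sum(diffs) / len(diffs)


def risk_oracle(g):
    f = 1.509 * (math.log(g) ** 1.084 - 5.381)
    return (10 * f * f if f < 0 else 0.0, 10 * f * f if f > 0 else 0.0)


def lbgi_hbgi_oracle(series):
    vals = [v for v in series.values if not math.isnan(v)]
    lows = [risk_oracle(v)[0] for v in vals]
    highs = [risk_oracle(v)[1] for v in vals]
    return sum(lows) / len(lows), sum(highs) / len(highs)


def m_value_oracle(series, reference=120.0):
    vals = [v for v in series.values if not math.isnan(v)]
    return sum(abs(10 * math.log10(v / reference)) ** 3 for v in vals) / len(vals)


def mag_oracle(series):
    pairs = [
        (t, v) for t, v in zip(series.timestamps, series.values) if not math.isnan(v)
    ]
    total = sum(abs(b[1] - a[1]) for a, b in zip(pairs, pairs[1:]))
    hours = (pairs[-1][0] - pairs[0][0]).total_seconds() / 3600
    return total / hours


def li_oracle(series):
    ser = series.to_pandas()
    hourly = ser.resample("1h").mean() / MMOL
    vals = list(hourly)
    total = 0.0
    for i in range(len(vals) - 1):
        a, b = vals[i], vals[i + 1]
        if not (math.isnan(a) or math.isnan(b)):
            total += (b - a) ** 2
    return total / (len(vals) / 168.0)


def grade_oracle(series, cap=50.0):
    vals = [v for v in series.values if not math.isnan(v)]
    hs = []
    for v in vals:
        h = 425 * (math.log10(math.log10(v / MMOL)) + 0.16) ** 2
        hs.append(min(h, cap))
    return sum(hs) / len(hs)


def adrr_oracle(series, min_completeness=0.8):
    by_day = {}
    for t, v in zip(series.timestamps, series.values):
        if not math.isnan(v):
            by_day.setdefault(t.floor("1D"), []).append(v)
    slots = int(round(1440 / series.interval))
    totals = []
    for day in sorted(by_day):
        vals = by_day[day]
        if len(vals) >= min_completeness * slots:
            lr = max(risk_oracle(v)[0] for v in vals)
            hr = max(risk_oracle(v)[1] for v in vals)
            totals.append(lr + hr)
    return sum(totals) / len(totals)


def mage_oracle(series, direction="both"):
    vals = [v for v in series.values if not math.isnan(v)]
    sd = _sample_sd(vals)
    if sd == 0:
        return 0.0
    # collapse plateaus
    seq = [vals[0]]
    for v in vals[1:]:
        if v != seq[-1]:
            seq.append(v)
    # interior extrema scan (endpoints are not turning points)
    extrema = []
    for i in range(1, len(seq) - 1):
        if (seq[i] - seq[i - 1]) * (seq[i + 1] - seq[i]) < 0:
            extrema.append(seq[i])
    amps = []
    for a, b in zip(extrema, extrema[1:]):
        leg = b - a
        if direction == "asc" and leg <= 0:
            continue
        if direction == "desc" and leg >= 0:
            continue
        if abs(leg) > sd:
            amps.append(abs(leg))
    return sum(amps) / len(amps) if amps else 0.0


def sd_roc_oracle(series, max_gap_min=15.0):
    pairs = [
        (t, v) for t, v in zip(series.timestamps, series.values) if not math.isnan(v)
    ]
    rates = []
    for a, b in zip(pairs, pairs[1:]):
        dt = (b[0] - a[0]).total_seconds() / 60
        if dt <= max_gap_min:
            rates.append((b[1] - a[1]) / dt)
    return _sample_sd(rates)
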