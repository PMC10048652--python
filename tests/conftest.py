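import numpy as np
import pandas as pd
import pytest

from glucovar.series import GlucoseSeries

START = pd.Timestamp("2021-03-01T00:00:00Z")


def make_series(values, interval=5.0, start=START) -> GlucoseSeries:
    """Gridded series from a value list (NaN marks missing slots)."""
    values = np.asarray(values, dtype=float)
    ts = start + pd.to_timedelta(np.arange(len(values)) * interval, unit="m")
    return GlucoseSeries(pd.DatetimeIndex(ts), values, interval)


def random_walk_series(rng, n_slots, nan_frac=0.0, interval=5.0) -> GlucoseSeries:
    """Clipped random-walk glucose trace for oracle cross-checks."""
    steps = rng.normal(0.0, 4.0, size=n_slots)
    vals = np.clip(120.0 + np.cumsum(steps), 45.0, 390.0)
    if nan_frac > 0:
        mask = rng.random(n_slots) < nan_frac
        # keep first/last present so span is stable
        mask[0] = mask[-1] = False
        vals = vals.copy()
        vals[mask] = np.nan
    return make_series(vals, interval)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def two_day_series(rng):
    return random_walk_series(rng, 2 * 288)
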