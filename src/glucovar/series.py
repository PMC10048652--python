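"""Core container for timestamped glucose data.

A :class:`GlucoseSeries` holds glucose concentrations (mg/dL) at strictly
increasing UTC instants on a nominal sampling grid (5 minutes for typical CGM
sensors).  Missing grid slots are represented as NaN so that downstream
metrics can do complete-pair analysis without imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Physiologic reporting limits of common CGM sensors, mg/dL.
GLUCOSE_MIN = 39.0
GLUCOSE_MAX = 400.0

#: Conversion factor between mmol/L and mg/dL for glucose.
MMOL_TO_MGDL = 18.016


@dataclass(frozen=True)
class GlucoseSeries:
    """Glucose values (mg/dL) at strictly increasing UTC timestamps.

    Parameters
    ----------
    timestamps:
        tz-aware (UTC) DatetimeIndex, strictly increasing.
    values:
        Glucose in mg/dL; NaN marks a missing grid slot.
    interval:
        Nominal grid spacing in minutes (default 5).
    """

    timestamps: pd.DatetimeIndex
    values: np.ndarray
    interval: float = 5.0

    def __post_init__(self) -> None:
        ts = pd.DatetimeIndex(self.timestamps)
        if ts.tz is None:
            ts = ts.tz_localize("UTC")
        else:
            ts = ts.tz_convert("UTC")
        vals = np.asarray(self.values, dtype=float)
        if len(ts) != len(vals):
            raise ValueError("timestamps and values must have equal length")
        if len(ts) > 1 and not (np.diff(ts.asi8) > 0).all():
            raise ValueError("timestamps must be strictly increasing")
        if self.interval <= 0:
            raise ValueError("interval must be positive")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def present(self) -> np.ndarray:
        """Boolean mask of non-missing slots."""
        return ~np.isnan(self.values)

    @property
    def n_present(self) -> int:
        return int(self.present.sum())

    def present_values(self) -> np.ndarray:
        return self.values[self.present]

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.values, index=self.timestamps, name="glucose_mgdl")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"timestamp": self.timestamps, "glucose_mgdl": self.values}
        )

    @classmethod
    def from_pandas(cls, s: pd.Series, interval: float = 5.0) -> "GlucoseSeries":
        return cls(pd.DatetimeIndex(s.index), s.to_numpy(dtype=float), interval)

    def slots_per_day(self) -> int:
        return int(round(1440 / self.interval))

    def span(self) -> pd.Timedelta:
        """Duration from first to last timestamp."""
        if len(self) == 0:
            return pd.Timedelta(0)
        return self.timestamps[-1] - self.timestamps[0]

    def slice_time(self, start: pd.Timestamp, end: pd.Timestamp) -> "GlucoseSeries":
        """Sub-series with start <= t < end."""
        mask = (self.timestamps >= start) & (self.timestamps < end)
        return GlucoseSeries(self.timestamps[mask], self.values[mask], self.interval)

    def tail_slots(self, n: int) -> "GlucoseSeries":
        return GlucoseSeries(self.timestamps[-n:], self.values[-n:], self.interval)

    def head_slots(self, n: int) -> "GlucoseSeries":
        return GlucoseSeries(self.timestamps[:n], self.values[:n], self.interval)

    def is_on_grid(self) -> bool:
        """True if consecutive timestamps are exactly ``interval`` apart."""
        if len(self) < 2:
            return True
        step = pd.Timedelta(minutes=self.interval).value
        return bool((np.diff(self.timestamps.asi8) == step).all())

    def write_csv(self, path) -> None:
        df = self.to_frame()
        df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
        df.to_csv(path, index=False)
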