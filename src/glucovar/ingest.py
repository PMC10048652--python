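"""Raw-record ingestion, cleaning, gridding and train/test splitting.

Raw CGM exports arrive as loosely ordered (timestamp, value) records with
duplicates, dropouts and unparsable entries.  The cleaning stage sorts,
de-duplicates (first occurrence wins), parses, and drops values outside the
physiologic reporting range [39, 400] mg/dL, accounting for every input
record in a :class:`CleaningLog`.  A separate resampling step places the
cleaned series on a regular grid (nominally 5 minutes), linearly
interpolating gaps of at most 30 minutes and leaving longer gaps missing so
that difference-based variability metrics are not biased by long
interpolated stretches.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .series import GLUCOSE_MAX, GLUCOSE_MIN, MMOL_TO_MGDL, GlucoseSeries
from .simulate import RawRecordSet


@dataclass
class CleaningLog:
    """Per-record accounting of one cleaning pass; every input record is
    either kept or counted in exactly one drop bucket."""

    n_input: int = 0
    n_duplicates_dropped: int = 0
    n_unparsable_dropped: int = 0
    n_out_of_range_dropped: int = 0
    n_gap_slots: int = 0
    n_interpolated: int = 0

    @property
    def n_kept(self) -> int:
        return (
            self.n_input
            - self.n_duplicates_dropped
            - self.n_unparsable_dropped
            - self.n_out_of_range_dropped
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class SplitSpec:
    """Training window length (days) and forecast horizon (hours)."""

    train_days: int = 30
    horizon_hours: int = 48

    def __post_init__(self) -> None:
        if self.train_days < 1:
            raise ValueError("train_days must be >= 1")
        if self.horizon_hours < 1:
            raise ValueError("horizon_hours must be >= 1")


def read_records(path, format: str = "csv", unit: str = "mgdl") -> RawRecordSet:
    """Read raw (timestamp, value) records from a CSV or Nightscout-style
    JSON export.

    Values are kept as raw strings (the cleaning stage decides their fate);
    parsable values in an mmol/L source are converted to mg/dL here
    (factor 18.016) so cleaning always sees mg/dL.
    """
    if unit not in ("mgdl", "mmoll"):
        raise ValueError(f"unknown unit {unit!r}")
    records: list[tuple[str, str]] = []
    if format == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected at least 2 CSV columns")
        for ts, val in zip(df.iloc[:, 0], df.iloc[:, 1]):
            records.append((str(ts), str(val)))
    elif format == "nightscout-json":
        with open(path) as fh:
            entries = json.load(fh)
        for e in entries:
            if "dateString" in e and "sgv" in e:
                records.append((str(e["dateString"]), str(e["sgv"])))
    else:
        raise ValueError(f"unknown format {format!r}")
    if not records:
        raise ValueError(f"{path}: no records found")
    if unit == "mmoll":
        converted = []
        for ts, val in records:
            try:
                converted.append((ts, repr(float(val) * MMOL_TO_MGDL)))
            except ValueError:
                converted.append((ts, val))
        records = converted
    return RawRecordSet(records)


def clean(
    raw: RawRecordSet,
    interval: float = 5.0,
    valid_range: tuple[float, float] = (GLUCOSE_MIN, GLUCOSE_MAX),
) -> tuple[GlucoseSeries, CleaningLog]:
    """Sort, de-duplicate, parse and range-filter raw records.

    Duplicate timestamps keep the first occurrence in input order
    (deterministic and order-stable).  Returns the cleaned irregular series
    and a log that accounts for every input record.
    """
    log = CleaningLog(n_input=len(raw.records))
    parsed: list[tuple[pd.Timestamp, float]] = []
    seen: set[pd.Timestamp] = set()
    lo, hi = valid_range
    for ts_str, val_str in raw.records:
        try:
            ts = pd.Timestamp(ts_str)
        except (ValueError, TypeError):
            log.n_unparsable_dropped += 1
            continue
        if ts.tz is None:
            ts = ts.tz_localize("UTC")
        else:
            ts = ts.tz_convert("UTC")
        if ts in seen:
            log.n_duplicates_dropped += 1
            continue
        try:
            val = float(val_str)
        except (ValueError, TypeError):
            seen.add(ts)
            log.n_unparsable_dropped += 1
            continue
        if not np.isfinite(val) or not (lo <= val <= hi):
            seen.add(ts)
            log.n_out_of_range_dropped += 1
            continue
        seen.add(ts)
        parsed.append((ts, val))
    if len(parsed) < 2:
        raise ValueError(f"cleaning left {len(parsed)} valid records; need >= 2")
    parsed.sort(key=lambda tv: tv[0])
    ts_idx = pd.DatetimeIndex([t for t, _ in parsed])
    vals = np.array([v for _, v in parsed])
    return GlucoseSeries(ts_idx, vals, interval), log


def resample_to_grid(
    s: GlucoseSeries,
    interval: float = 5.0,
    max_interp_gap: float = 30.0,
    log: CleaningLog | None = None,
) -> GlucoseSeries:
    """Place a cleaned series on a regular grid.

    The grid is anchored at the first timestamp floored to the interval;
    each slot takes the nearest observation within interval/2, else is
    missing.  Runs of missing slots spanning at most ``max_interp_gap``
    minutes are linearly interpolated (counted in ``log.n_interpolated``);
    longer gaps stay missing (counted in ``log.n_gap_slots``).
    """
    if len(s) == 0:
        raise ValueError("cannot resample an empty series")
    step = pd.Timedelta(minutes=interval)
    start = s.timestamps[0].floor(step)
    n_slots = int((s.timestamps[-1] - start) // step) + 1
    grid = pd.DatetimeIndex(start + step * np.arange(n_slots))

    # nearest observation within half an interval of each slot
    obs = s.to_pandas().dropna()
    slot_of_obs = ((obs.index - start) / step).round().astype(int)
    dist = np.abs((obs.index - (start + step * slot_of_obs)).total_seconds())
    values = np.full(n_slots, np.nan)
    best = np.full(n_slots, np.inf)
    for slot, d, v in zip(slot_of_obs, dist, obs.to_numpy()):
        if 0 <= slot < n_slots and d <= interval * 30.0 and d < best[slot]:
            best[slot] = d
            values[slot] = v

    # interpolate short interior gaps only
    gridded = pd.Series(values, index=grid)
    max_slots = int(max_interp_gap / interval)
    filled = gridded.interpolate(method="linear", limit=max_slots, limit_area="inside")
    isna = gridded.isna().to_numpy()
    # a run of missing slots is interpolated only if the whole run fits the cap
    run_start = None
    n_interp = 0
    n_gap = 0
    out = filled.to_numpy().copy()
    for i in range(n_slots + 1):
        missing = i < n_slots and isna[i]
        if missing and run_start is None:
            run_start = i
        elif not missing and run_start is not None:
            run_len = i - run_start
            interior = run_start > 0 and i < n_slots
            if interior and run_len <= max_slots:
                n_interp += run_len
            else:
                out[run_start:i] = np.nan
                n_gap += run_len
            run_start = None
    if log is not None:
        log.n_interpolated += n_interp
        log.n_gap_slots += n_gap
    return GlucoseSeries(grid, out, interval)


def split_train_test(s: GlucoseSeries, spec: SplitSpec) -> tuple[GlucoseSeries, GlucoseSeries]:
    """Final ``horizon_hours`` become the test window; the ``train_days``
    immediately preceding become the training window.  Both are contiguous
    on the grid with no overlap."""
    if not s.is_on_grid():
        raise ValueError("split requires a regular gridded series")
    slots_per_day = s.slots_per_day()
    n_test = int(round(spec.horizon_hours * 60.0 / s.interval))
    n_train = spec.train_days * slots_per_day
    required = n_train + n_test
    if len(s) < required:
        req_days = required / slots_per_day
        have_days = len(s) / slots_per_day
        raise ValueError(
            f"series spans {have_days:.2f} days; "
            f"{req_days:.2f} days required for a {spec.train_days}-day train "
            f"window plus a {spec.horizon_hours}-h test window"
        )
    test = s.tail_slots(n_test)
    train = GlucoseSeries(
        s.timestamps[-required:-n_test], s.values[-required:-n_test], s.interval
    )
    return train, test
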