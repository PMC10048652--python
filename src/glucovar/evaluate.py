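"""Forecast scoring and predicted-vs-expected GV comparison.

Point forecasts are scored with MAE and RMSE.  Variability outcomes of a
predicted 48-h profile are compared with the observed profile metric by
metric, using two complementary error measures:

* relative error, ``100 * |pred - exp| / |exp|`` — interpretable but
  unstable when the expected metric approaches 0 (a TBR of 0% is common and
  desirable, and any nonzero prediction then blows the relative error up);
* proportional error, ``max(|pred|,|exp|) / min(|pred|,|exp|)`` — a
  symmetric ratio that is 1 exactly when the magnitudes agree.

Metrics where a measure is undefined (zero or opposite-sign values) are
flagged and excluded from cohort aggregation, with the exclusion counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gv import GVReport, RangeThresholds, gv_report
from .series import GlucoseSeries


@dataclass
class ScoreReport:
    mae: float
    rmse: float
    n: int


@dataclass
class MetricError:
    expected: float | None
    predicted: float | None
    relative: float | None  # %
    proportional: float | None  # ratio >= 1
    undefined_reason: str | None = None


@dataclass
class GVErrorReport:
    """Per-metric errors between a predicted and an expected window."""

    metrics: dict[str, MetricError] = field(default_factory=dict)
    id: str | None = None


@dataclass
class CohortErrorSummary:
    """(min, avg, max) of each error kind per metric over profiles."""

    relative: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    proportional: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    n_excluded: dict[str, int] = field(default_factory=dict)


def score(pred: np.ndarray, actual: np.ndarray) -> ScoreReport:
    """MAE and RMSE of aligned prediction/actual sequences (mg/dL)."""
    pred = np.asarray(pred, float)
    actual = np.asarray(actual, float)
    if pred.shape != actual.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {actual.shape}")
    if pred.size == 0:
        raise ValueError("empty sequences")
    err = pred - actual
    return ScoreReport(
        mae=float(np.abs(err).mean()),
        rmse=float(np.sqrt((err**2).mean())),
        n=int(pred.size),
    )


def relative_error(predicted: float, expected: float) -> float | None:
    """100 * |predicted - expected| / |expected|; None (undefined) when the
    expected value is 0 and the prediction is not; 0 when both are 0."""
    if expected == 0:
        return 0.0 if predicted == 0 else None
    return 100.0 * abs(predicted - expected) / abs(expected)


def proportional_error(predicted: float, expected: float) -> float | None:
    """Symmetric magnitude ratio max/min >= 1; None (undefined) for zero or
    opposite-sign inputs."""
    if predicted == 0 or expected == 0 or (predicted > 0) != (expected > 0):
        return None
    a, b = abs(predicted), abs(expected)
    return max(a, b) / min(a, b)


def compare_gv(
    pred_window: GlucoseSeries,
    actual_window: GlucoseSeries,
    thr: RangeThresholds = RangeThresholds(),
    id: str | None = None,
    **gv_kwargs,
) -> GVErrorReport:
    """GV metrics on both windows plus per-metric relative and
    proportional errors."""
    rep_p = gv_report(pred_window, thr, id=id, **gv_kwargs)
    rep_a = gv_report(actual_window, thr, id=id, **gv_kwargs)
    return compare_reports(rep_p, rep_a, id=id)


def compare_reports(rep_p: GVReport, rep_a: GVReport, id: str | None = None) -> GVErrorReport:
    out = GVErrorReport(id=id)
    for name in rep_a.metric_names():
        e, p = getattr(rep_a, name), getattr(rep_p, name)
        if e is None or p is None:
            out.metrics[name] = MetricError(e, p, None, None, "metric absent")
            continue
        rel = relative_error(p, e)
        prop = proportional_error(p, e)
        reason = None
        if rel is None or prop is None:
            reason = "zero or opposite-sign metric value"
        out.metrics[name] = MetricError(e, p, rel, prop, reason)
    return out


def aggregate_errors(reports: list[GVErrorReport]) -> CohortErrorSummary:
    """Min/avg/max of each error kind per metric across profiles; undefined
    entries are excluded and counted."""
    if not reports:
        raise ValueError("aggregate_errors needs >= 1 report")
    summary = CohortErrorSummary()
    names: list[str] = []
    for rep in reports:
        for name in rep.metrics:
            if name not in names:
                names.append(name)
    for name in names:
        rels, props, excl = [], [], 0
        for rep in reports:
            me = rep.metrics.get(name)
            if me is None:
                continue
            if me.relative is None and me.proportional is None:
                excl += 1
                continue
            if me.relative is not None:
                rels.append(me.relative)
            if me.proportional is not None:
                props.append(me.proportional)
        summary.n_excluded[name] = excl
        if rels:
            summary.relative[name] = (
                float(np.min(rels)),
                float(np.mean(rels)),
                float(np.max(rels)),
            )
        if props:
            summary.proportional[name] = (
                float(np.min(props)),
                float(np.mean(props)),
                float(np.max(props)),
            )
    return summary
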