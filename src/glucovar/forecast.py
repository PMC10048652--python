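"""Univariate glucose forecasting up to 48 h.

Four model families are supported on equal footing: an ARIMA(7,1,0) fit by
maximum likelihood, gradient-boosted trees and random forests on 7 lagged
glucose features, and an LSTM (lags=1, 15 epochs, batch size 1, 50 neurons)
behind an optional deep-learning backend — the other three families run
without one.  An SVR family is recognised but deliberately unsupported (its
training cost scales worse than quadratically with samples).

Two evaluation modes are provided and always labelled: ``rolling`` one-step
prediction, where the model state advances with observed values (no refit),
and ``recursive`` multi-step forecasting, where the model feeds on its own
predictions.  Forecasts are clamped to physiologic bounds before any GV
analysis.
"""

from __future__ import annotations

import time
import tracemalloc
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .series import GLUCOSE_MAX, GLUCOSE_MIN, GlucoseSeries

FAMILIES = ("arima", "gbtree", "rforest", "lstm", "persistence")


class BackendUnavailable(RuntimeError):
    """Raised when a model family's optional backend is not installed."""


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters for one model family.

    Defaults are the fine-tuned values of the emulated study: ARIMA order
    (7,1,0); gradient boosting with learning rate 0.1, 100 estimators,
    subsample 1, max depth 3; random forest with unlimited depth, 100
    estimators, min samples split 2; LSTM with 1 lag, 15 epochs, batch
    size 1, 50 neurons.  Tree models see ``feature_lags`` lagged glucose
    values (default 7, mirroring the ARIMA order).
    """

    family: str = "arima"
    # arima
    p: int = 7
    d: int = 1
    q: int = 0
    # gbtree
    learning_rate: float = 0.1
    n_estimators: int = 100
    subsample: float = 1.0
    max_depth: int = 3
    # rforest
    rf_max_depth: int | None = None
    min_samples_split: int = 2
    # lstm
    lstm_lags: int = 1
    epochs: int = 15
    batch_size: int = 1
    neurons: int = 50
    # shared
    feature_lags: int = 7
    seed: int = 0
    clamp: tuple[float, float] = (GLUCOSE_MIN, GLUCOSE_MAX)
    backend: str = "sklearn"  # for gbtree: sklearn | xgboost

    def __post_init__(self) -> None:
        if self.family not in FAMILIES + ("svr",):
            raise ValueError(f"unknown model family {self.family!r}")
        if min(self.p, self.d, self.q) < 0:
            raise ValueError("ARIMA orders must be non-negative")
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.feature_lags < 1 or self.lstm_lags < 1:
            raise ValueError("lags must be >= 1")


@dataclass
class ResourceUsage:
    wall_seconds: float
    peak_memory_mb: float


@dataclass
class ForecastResult:
    """Aligned predictions for a test window or open horizon."""

    model_id: str
    mode: str  # rolling | recursive
    timestamps: pd.DatetimeIndex
    predictions: np.ndarray
    horizon_hours: float
    resource: ResourceUsage | None = None

    def to_frame(self, actual: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"timestamp": self.timestamps, "predicted": self.predictions})
        if actual is not None:
            df.insert(1, "actual", actual)
        return df


@dataclass
class FittedModel:
    config: ModelConfig
    train: GlucoseSeries
    _impl: object
    residual_mean: float
    residual_sd: float

    @property
    def model_id(self) -> str:
        return self.config.family


def measure_resources(task: Callable[[], object]) -> tuple[object, ResourceUsage]:
    """Run ``task`` recording wall time and peak traced memory.  Logged for
    cost reporting only; never part of any correctness check."""
    tracemalloc.start()
    t0 = time.perf_counter()
    try:
        result = task()
    finally:
        _, peak = tracemalloc.get_traced_memory()
        tracemalloc.stop()
    wall = time.perf_counter() - t0
    return result, ResourceUsage(wall, peak / 2**20)


def _check_train(cfg: ModelConfig, train: GlucoseSeries) -> np.ndarray:
    if not train.is_on_grid():
        raise ValueError("training series must be on a regular grid")
    if not train.present.all():
        raise ValueError("training series must have no missing slots")
    min_len = 10 * max(cfg.feature_lags, cfg.p, cfg.lstm_lags)
    if len(train) < min_len:
        raise ValueError(f"training series too short: {len(train)} < {min_len}")
    return train.values.astype(float)


def _lag_matrix(y: np.ndarray, lags: int) -> tuple[np.ndarray, np.ndarray]:
    """Supervised pairs: features are the ``lags`` previous values
    (most recent first), target the current value."""
    X = np.column_stack([y[lags - k - 1 : len(y) - k - 1] for k in range(lags)])
    return X, y[lags:]


def _fit_arima(cfg: ModelConfig, y: np.ndarray):
    from statsmodels.tsa.arima.model import ARIMA

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = ARIMA(y, order=(cfg.p, cfg.d, cfg.q)).fit()
    return res


def _fit_tree(cfg: ModelConfig, y: np.ndarray):
    X, t = _lag_matrix(y, cfg.feature_lags)
    if cfg.family == "gbtree":
        if cfg.backend == "xgboost":
            from xgboost import XGBRegressor

            est = XGBRegressor(
                learning_rate=cfg.learning_rate,
                n_estimators=cfg.n_estimators,
                subsample=cfg.subsample,
                max_depth=cfg.max_depth,
                random_state=cfg.seed,
                n_jobs=1,
            )
        else:
            from sklearn.ensemble import GradientBoostingRegressor

            est = GradientBoostingRegressor(
                learning_rate=cfg.learning_rate,
                n_estimators=cfg.n_estimators,
                subsample=cfg.subsample,
                max_depth=cfg.max_depth,
                random_state=cfg.seed,
            )
    else:
        from sklearn.ensemble import RandomForestRegressor

        est = RandomForestRegressor(
            n_estimators=cfg.n_estimators,
            max_depth=cfg.rf_max_depth,
            min_samples_split=cfg.min_samples_split,
            random_state=cfg.seed,
            n_jobs=1,
        )
    est.fit(X, t)
    return est


class _LSTMImpl:
    """Minimal torch LSTM regressor on standardized lagged inputs."""

    def __init__(self, cfg: ModelConfig, y: np.ndarray):
        try:
            import torch
            from torch import nn
        except ImportError as exc:  # pragma: no cover - backend optional
            raise BackendUnavailable(
                "the lstm family needs a deep-learning backend (torch); "
                "none is installed — use arima, gbtree or rforest"
            ) from exc
        self.torch = torch
        self.mu, self.sigma = float(y.mean()), float(y.std()) or 1.0
        z = (y - self.mu) / self.sigma
        X, t = _lag_matrix(z, cfg.lstm_lags)
        torch.manual_seed(cfg.seed)
        torch.set_num_threads(1)
        self.lstm = nn.LSTM(1, cfg.neurons, batch_first=True)
        self.head = nn.Linear(cfg.neurons, 1)
        params = list(self.lstm.parameters()) + list(self.head.parameters())
        opt = torch.optim.Adam(params)
        loss_fn = nn.MSELoss()
        Xt = torch.tensor(X, dtype=torch.float32).unsqueeze(-1)
        tt = torch.tensor(t, dtype=torch.float32)
        for _ in range(cfg.epochs):
            for i in range(0, len(Xt), cfg.batch_size):
                xb, yb = Xt[i : i + cfg.batch_size], tt[i : i + cfg.batch_size]
                opt.zero_grad()
                out, _ = self.lstm(xb)
                pred = self.head(out[:, -1, :]).squeeze(-1)
                loss = loss_fn(pred, yb)
                loss.backward()
                opt.step()
        self.cfg = cfg

    def predict(self, X: np.ndarray) -> np.ndarray:
        torch = self.torch
        with torch.no_grad():
            z = (X - self.mu) / self.sigma
            xt = torch.tensor(z, dtype=torch.float32).unsqueeze(-1)
            out, _ = self.lstm(xt)
            pred = self.head(out[:, -1, :]).squeeze(-1).numpy()
        return pred * self.sigma + self.mu


def fit(cfg: ModelConfig, train: GlucoseSeries) -> FittedModel:
    """Fit one model family on a gapless training window.

    Deterministic given (config, seed); in-sample residual mean/SD are
    recorded as the adequacy diagnostic of the fit.
    """
    if cfg.family == "svr":
        raise NotImplementedError(
            "svr is not supported: training cost grows worse than "
            "quadratically with samples and the family was dropped"
        )
    y = _check_train(cfg, train)
    if cfg.family == "arima":
        impl = _fit_arima(cfg, y)
        resid = np.asarray(impl.resid)[cfg.d + cfg.p :]
    elif cfg.family in ("gbtree", "rforest"):
        impl = _fit_tree(cfg, y)
        X, t = _lag_matrix(y, cfg.feature_lags)
        resid = t - impl.predict(X)
    elif cfg.family == "lstm":
        impl = _LSTMImpl(cfg, y)
        X, t = _lag_matrix(y, cfg.lstm_lags)
        resid = t - impl.predict(X)
    elif cfg.family == "persistence":
        impl = None
        resid = np.diff(y)
    return FittedModel(
        config=cfg,
        train=train,
        _impl=impl,
        residual_mean=float(np.mean(resid)),
        residual_sd=float(np.std(resid, ddof=1)),
    )


def _clamp(cfg: ModelConfig, pred: np.ndarray) -> np.ndarray:
    lo, hi = cfg.clamp
    return np.clip(pred, lo, hi)


def predict_rolling(m: FittedModel, test: GlucoseSeries) -> ForecastResult:
    """One-step-ahead predictions over the test window, advancing the model
    state with the observed values (no refitting)."""
    cfg = m.config
    step = pd.Timedelta(minutes=m.train.interval)
    if test.timestamps[0] - m.train.timestamps[-1] != step:
        raise ValueError("test window must immediately follow the training window")
    if not test.present.all():
        raise ValueError("rolling evaluation needs a gapless test window")
    y_train = m.train.values
    y_test = test.values.astype(float)
    lags = cfg.feature_lags if cfg.family in ("gbtree", "rforest") else cfg.lstm_lags

    if cfg.family == "arima":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            extended = m._impl.append(y_test, refit=False)
            pred = np.asarray(
                extended.predict(start=len(y_train), end=len(y_train) + len(y_test) - 1)
            )
    elif cfg.family in ("gbtree", "rforest", "lstm"):
        full = np.concatenate([y_train, y_test])
        n = len(y_test)
        X = np.column_stack(
            [full[len(y_train) - 1 - k : len(full) - 1 - k] for k in range(lags)]
        )
        pred = np.asarray(m._impl.predict(X[:n]))
    elif cfg.family == "persistence":
        full = np.concatenate([y_train[-1:], y_test[:-1]])
        pred = full
    horizon = len(y_test) * m.train.interval / 60.0
    return ForecastResult(
        model_id=m.model_id,
        mode="rolling",
        timestamps=test.timestamps,
        predictions=_clamp(cfg, pred),
        horizon_hours=horizon,
    )


def predict_recursive(m: FittedModel, horizon_hours: float) -> ForecastResult:
    """Multi-step forecast from the end of training, each step feeding on
    the model's own predictions."""
    cfg = m.config
    interval = m.train.interval
    n = int(round(horizon_hours * 60.0 / interval))
    y_train = m.train.values
    if cfg.family == "arima":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = np.asarray(m._impl.forecast(steps=n))
    elif cfg.family == "persistence":
        pred = np.full(n, y_train[-1])
    else:
        lags = cfg.feature_lags if cfg.family in ("gbtree", "rforest") else cfg.lstm_lags
        history = list(y_train[-lags:])
        pred = np.empty(n)
        for i in range(n):
            X = np.array(history[::-1][:lags])[None, :]
            p = float(np.asarray(m._impl.predict(X))[0])
            pred[i] = p
            history.append(p)
            history = history[-lags:]
    step = pd.Timedelta(minutes=interval)
    ts = pd.DatetimeIndex(m.train.timestamps[-1] + step * np.arange(1, n + 1))
    return ForecastResult(
        model_id=m.model_id,
        mode="recursive",
        timestamps=ts,
        predictions=_clamp(cfg, pred),
        horizon_hours=horizon_hours,
    )


def persistence_mae(test: GlucoseSeries) -> float:
    """MAE of the naive last-value forecaster over a gapless test window
    given its true predecessor values — equals mean |consecutive change|."""
    y = test.values
    return float(np.abs(np.diff(y)).mean())
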