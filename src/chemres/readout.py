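"""Linear dynamic readouts: ridge regression and the absolute scaled error.

For the dynamic tasks the reservoir trace x(t) (binned to 10 s) is mapped
onto a target series by a single linear layer, y_hat(t) = W x(t) + b,
fitted by ridge regression (alpha = 5e-5) over a training window
(default the first 30 min of the record).  For forecasting the target is
the reactor's own input shifted dt = 120 s into the future.

Prediction quality is reported as the absolute scaled error

    ASE(t) = |y_hat(t) - y(t)| / mean_train |y(t) - y_bar_train|,

the pointwise error scaled by the training-window mean absolute error of
a naive mean forecast; ASE < 1 beats that naive forecast, and the measure
is invariant under rescaling of the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .input_profiles import InputProfile
from .metabolic import TargetSeries
from .reservoir import ReservoirTrace

__all__ = [
    "RidgeReadout",
    "PredictionResult",
    "train_ridge",
    "predict",
    "make_forecast_targets",
    "ase",
    "evaluate_prediction",
]


class ReadoutError(ValueError):
    pass


@dataclass
class RidgeReadout:
    """Trained ridge readout: W is (n_targets, n_channels)."""

    weights: np.ndarray
    intercepts: np.ndarray
    alpha: float
    train_window_s: tuple[float, float]
    channels: list[str]
    target_names: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ReadoutError("alpha must be > 0")
        if self.weights.shape != (len(self.target_names), len(self.channels)):
            raise ReadoutError("weight matrix shape inconsistent with names")


def _as_matrix(obj) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(obj, ReservoirTrace):
        return obj.time_s, obj.values, list(obj.channels)
    if isinstance(obj, TargetSeries):
        return obj.time_s, obj.values, list(obj.substrates)
    raise ReadoutError(f"expected a trace or target series, got {type(obj).__name__}")


def train_ridge(
    trace: ReservoirTrace,
    targets: TargetSeries | np.ndarray,
    alpha: float = 5e-5,
    train_window_min: float = 30.0,
    train_start_s: float = 0.0,
) -> RidgeReadout:
    """Fit W minimising ||Y - XW - b||^2 + alpha ||W||^2 on the window.

    Features are centred through the (unpenalised) intercept only — no
    variance scaling — so the fit equals the closed-form normal equations
    on centred data.  Trace and target must share the time grid inside
    the training window.
    """
    t_x, X, channels = _as_matrix(trace)
    if isinstance(targets, np.ndarray):
        t_y, Y, names = t_x, np.atleast_2d(targets.T).T, [
            f"target_{i}" for i in range(np.atleast_2d(targets.T).T.shape[1])
        ]
    else:
        t_y, Y, names = _as_matrix(targets)
    lo, hi = train_start_s, train_start_s + train_window_min * 60.0
    mask_x = (t_x >= lo - 1e-9) & (t_x < hi - 1e-9)
    mask_y = (t_y >= lo - 1e-9) & (t_y < hi - 1e-9)
    if not mask_x.any():
        raise ReadoutError("empty training window")
    if mask_x.sum() != mask_y.sum() or not np.allclose(
        t_x[mask_x], t_y[mask_y], atol=1e-6
    ):
        raise ReadoutError("trace and target time grids differ inside the window")
    model = Ridge(alpha=alpha, fit_intercept=True)
    model.fit(X[mask_x], Y[mask_y])
    W = np.atleast_2d(model.coef_)
    b = np.atleast_1d(model.intercept_)
    return RidgeReadout(
        weights=W,
        intercepts=b,
        alpha=alpha,
        train_window_s=(lo, hi),
        channels=channels,
        target_names=names,
        provenance={"n_train_samples": int(mask_x.sum())},
    )


def predict(readout: RidgeReadout, trace: ReservoirTrace) -> np.ndarray:
    """Apply the readout: y_hat(t) = W x(t) + b for every trace time."""
    if list(trace.channels) != readout.channels:
        raise ReadoutError("trace channels do not match the trained readout")
    return trace.values @ readout.weights.T + readout.intercepts


def make_forecast_targets(
    profile: InputProfile,
    trace_time_s: np.ndarray,
    dt_s: float = 120.0,
    channels: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Targets for input forecasting: u(t + dt) aligned with x(t).

    Returns ``(times_kept, target_matrix, channels)`` where the final
    ``dt_s`` of the record is dropped (its future is unobserved).  ``dt_s``
    must be a multiple of the trace's time step.
    """
    t = np.asarray(trace_time_s, dtype=float)
    step = float(np.median(np.diff(t)))
    shift_f = dt_s / step
    shift = int(round(shift_f))
    if abs(shift_f - shift) > 1e-6:
        raise ReadoutError(
            f"dt ({dt_s} s) is not a multiple of the trace step ({step} s)"
        )
    if shift >= t.size:
        raise ReadoutError("dt exceeds the trace duration")
    if t[t.size - 1 - shift] + dt_s > profile.duration_s + step:
        raise ReadoutError("profile does not cover t + dt for the kept record")
    channels = channels or [c for c in profile.channels]
    u = profile.sample(t + dt_s, channels)
    if shift == 0:
        return t, u, channels
    return t[:-shift], u[: t.size - shift], channels


def ase(
    predicted: np.ndarray,
    truth: np.ndarray,
    train_truth: np.ndarray,
) -> np.ndarray:
    """Absolute scaled error per time point (columns = targets).

    The denominator is the training-window mean absolute deviation of the
    truth about its training mean — the error a naive constant (mean)
    forecast makes on the training data.
    """
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float).T).T
    truth = np.atleast_2d(np.asarray(truth, dtype=float).T).T
    train_truth = np.atleast_2d(np.asarray(train_truth, dtype=float).T).T
    if predicted.shape != truth.shape:
        raise ReadoutError("prediction and truth shapes differ")
    denom = np.mean(
        np.abs(train_truth - train_truth.mean(axis=0)), axis=0
    )
    bad = denom <= 0
    if np.any(bad):
        raise ReadoutError(
            f"constant training truth for target column(s) {np.flatnonzero(bad).tolist()}; "
            "ASE denominator is zero"
        )
    return np.abs(predicted - truth) / denom


@dataclass
class PredictionResult:
    """Prediction, truth and ASE traces, split into train/test windows."""

    time_s: np.ndarray
    predicted: np.ndarray
    truth: np.ndarray
    ase_t: np.ndarray
    target_names: list[str]
    train_boundary_s: float
    train_mean: np.ndarray
    n_train: int

    @property
    def test_mask(self) -> np.ndarray:
        return self.time_s >= self.train_boundary_s - 1e-9

    def mean_test_ase(self) -> pd.Series:
        return pd.Series(
            self.ase_t[self.test_mask].mean(axis=0), index=self.target_names
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.time_s}
        for j, name in enumerate(self.target_names):
            data[f"{name}_true"] = self.truth[:, j]
            data[f"{name}_pred"] = self.predicted[:, j]
            data[f"{name}_ase"] = self.ase_t[:, j]
        return pd.DataFrame(data)


def evaluate_prediction(
    readout: RidgeReadout,
    trace: ReservoirTrace,
    truth: np.ndarray,
    target_names: list[str] | None = None,
) -> PredictionResult:
    """Predict over the full trace and score ASE against the truth.

    The ASE denominator uses only the readout's training window, so test
    values are comparable across targets of different scales.
    """
    y_hat = predict(readout, trace)
    truth = np.atleast_2d(np.asarray(truth, dtype=float).T).T
    if truth.shape != y_hat.shape:
        raise ReadoutError("truth shape does not match predictions")
    lo, hi = readout.train_window_s
    train_mask = (trace.time_s >= lo - 1e-9) & (trace.time_s < hi - 1e-9)
    err = ase(y_hat, truth, truth[train_mask])
    return PredictionResult(
        time_s=trace.time_s.copy(),
        predicted=y_hat,
        truth=truth,
        ase_t=err,
        target_names=target_names or readout.target_names,
        train_boundary_s=hi,
        train_mean=truth[train_mask].mean(axis=0),
        n_train=int(train_mask.sum()),
    )
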