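"""Lagged mutual information between inputs and reservoir channels.

The reservoir's memory is quantified as I(u(t); x(t + dt)) across a grid
of lags: negative dt measures how much a channel remembers about *past*
input, positive dt how much it anticipates *future* input.  Two
estimators are provided — a k-nearest-neighbour estimator (default,
k = 3; the standard continuous-data choice) and a plug-in histogram
estimator used as a cross-check.  All values are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import mutual_info_regression

__all__ = ["MISettings", "MIProfile", "mi_estimate", "lagged_mi"]


class InfoError(ValueError):
    pass


MIN_SAMPLES = 50


@dataclass(frozen=True)
class MISettings:
    """Estimator configuration: ``method`` is 'knn' or 'histogram'."""

    method: str = "knn"
    n_neighbors: int = 3
    bins: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("knn", "histogram"):
            raise InfoError(f"unknown MI method {self.method!r}")


def _histogram_mi(u: np.ndarray, x: np.ndarray, bins: int) -> float:
    """Plug-in estimate from a 2-D histogram (nats)."""
    joint, _, _ = np.histogram2d(u, x, bins=bins)
    p_uv = joint / joint.sum()
    p_u = p_uv.sum(axis=1, keepdims=True)
    p_v = p_uv.sum(axis=0, keepdims=True)
    mask = p_uv > 0
    return float(np.sum(p_uv[mask] * np.log(p_uv[mask] / (p_u @ p_v)[mask])))


def mi_estimate(u, x, settings: MISettings | None = None) -> float:
    """Nonnegative estimate of I(U; X) in nats from paired samples.

    The kNN estimator handles continuous data without binning bias; the
    histogram estimator is the direct plug-in evaluation of the defining
    sum.  Estimates below zero (possible for kNN) are clipped to 0.
    """
    settings = settings or MISettings()
    u = np.asarray(u, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    if u.size != x.size:
        raise InfoError(f"length mismatch: {u.size} vs {x.size}")
    if u.size < MIN_SAMPLES:
        raise InfoError(f"need at least {MIN_SAMPLES} paired samples, got {u.size}")
    if settings.method == "histogram":
        return max(_histogram_mi(u, x, settings.bins), 0.0)
    est = mutual_info_regression(
        u.reshape(-1, 1),
        x,
        n_neighbors=settings.n_neighbors,
        random_state=settings.seed,
    )
    return float(max(est[0], 0.0))


@dataclass
class MIProfile:
    """MI as a function of lag for every (input, channel) pair.

    ``mi`` has shape (n_inputs, n_channels, n_lags); lags are in seconds,
    negative = reservoir state vs past input.
    """

    lags_s: np.ndarray
    mi: np.ndarray
    input_names: list[str]
    channel_names: list[str]
    n_samples: np.ndarray
    settings: MISettings = field(default_factory=MISettings)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, u_name in enumerate(self.input_names):
            for j, c_name in enumerate(self.channel_names):
                for k, lag in enumerate(self.lags_s):
                    rows.append(
                        {
                            "input": u_name,
                            "channel": c_name,
                            "lag_s": float(lag),
                            "mi_nats": float(self.mi[i, j, k]),
                            "n_samples": int(self.n_samples[k]),
                        }
                    )
        return pd.DataFrame(rows)


def lagged_mi(
    u_values: np.ndarray,
    x_values: np.ndarray,
    time_s: np.ndarray,
    lags_s: np.ndarray,
    input_names: list[str] | None = None,
    channel_names: list[str] | None = None,
    settings: MISettings | None = None,
) -> MIProfile:
    """I(x(t); u(t + dt)) over a lag grid, on a shared time grid.

    Negative dt pairs the reservoir state with *past* input (memory),
    positive dt with *future* input (anticipation): a channel that copies
    its input with a pure delay d peaks at dt = -d.  For each lag the two
    series are truncated to their overlap (no wrap-around).  Lags must be
    multiples of the grid step and smaller than half the record.
    """
    settings = settings or MISettings()
    u_values = np.atleast_2d(np.asarray(u_values, dtype=float).T).T
    x_values = np.atleast_2d(np.asarray(x_values, dtype=float).T).T
    time_s = np.asarray(time_s, dtype=float)
    n = time_s.size
    if u_values.shape[0] != n or x_values.shape[0] != n:
        raise InfoError("inputs, channels and time grid must share a length")
    step = float(np.median(np.diff(time_s)))
    lags_s = np.asarray(lags_s, dtype=float)
    shifts = lags_s / step
    if np.any(np.abs(shifts - np.round(shifts)) > 1e-6):
        raise InfoError("every lag must be a multiple of the time-grid step")
    if np.any(np.abs(lags_s) >= n * step / 2):
        raise InfoError("lags must stay below half the record length")
    shifts = np.round(shifts).astype(int)
    n_in, n_ch = u_values.shape[1], x_values.shape[1]
    mi = np.zeros((n_in, n_ch, lags_s.size))
    n_samples = np.zeros(lags_s.size, dtype=int)
    for k, shift in enumerate(shifts):
        # pair x(t) with u(t + shift); truncate to the overlap
        if shift >= 0:
            u_seg = u_values[shift:]
            x_seg = x_values[: n - shift]
        else:
            u_seg = u_values[: n + shift]
            x_seg = x_values[-shift:]
        n_samples[k] = u_seg.shape[0]
        for i in range(n_in):
            for j in range(n_ch):
                mi[i, j, k] = mi_estimate(u_seg[:, i], x_seg[:, j], settings)
    return MIProfile(
        lags_s=lags_s,
        mi=mi,
        input_names=input_names or [f"u{i}" for i in range(n_in)],
        channel_names=channel_names or [f"x{j}" for j in range(n_ch)],
        n_samples=n_samples,
        settings=settings,
    )
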