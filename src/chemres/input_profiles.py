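"""Input schedules for a CSTR-hosted chemical reservoir.

All experiments drive the reactor with piecewise-constant, multi-channel
input schedules: reagent concentrations are converted to syringe flow
rates, a water channel balances the total flow, and the residence time
``tau = V / F_tot`` sets the reservoir's intrinsic memory timescale.

Three families of schedule are provided:

* random 2-D concentration grids for static classification tasks,
* Gaussian step profiles (flow rates redrawn every hold period) for
  dynamic-emulation experiments,
* three-channel profiles derived from the Lorenz attractor for
  forecasting experiments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

logger = logging.getLogger(__name__)

#: Total flow rate used in all experiments (ul / min).
DEFAULT_TOTAL_FLOW = 217.5
#: Reactor volume (ul); together with the total flow this gives a 2 min
#: residence time.
DEFAULT_REACTOR_VOLUME = 435.0
#: Syringe stock concentrations (mM).  The DHA stock of 300 mM makes the
#: mean flow of 36.25 ul/min correspond to a mean input of 50 mM at the
#: default total flow; the other stocks are plausible working values and
#: are configurable.
DEFAULT_SYRINGE_CONCENTRATIONS: Mapping[str, float] = {
    "dha": 300.0,
    "form": 600.0,
    "naoh": 200.0,
    "cacl2": 100.0,
}

WATER_CHANNEL = "water"


class ProfileError(ValueError):
    """Raised when an input schedule violates a physical constraint."""


@dataclass(frozen=True)
class FlowSettings:
    """Hydraulic configuration of the flow reactor.

    Parameters
    ----------
    total_flow : float
        Total volumetric flow rate ``F_tot`` (ul / min), held constant.
    reactor_volume : float
        Reactor volume ``V`` (ul).
    syringe_concentrations : mapping
        Stock concentration ``C_syr`` (mM) per reagent channel.
    """

    total_flow: float = DEFAULT_TOTAL_FLOW
    reactor_volume: float = DEFAULT_REACTOR_VOLUME
    syringe_concentrations: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SYRINGE_CONCENTRATIONS)
    )

    def __post_init__(self) -> None:
        if not self.total_flow > 0:
            raise ProfileError(f"total_flow must be > 0, got {self.total_flow}")
        if not self.reactor_volume > 0:
            raise ProfileError(
                f"reactor_volume must be > 0, got {self.reactor_volume}"
            )
        for name, c in self.syringe_concentrations.items():
            if not c > 0:
                raise ProfileError(
                    f"syringe concentration for channel {name!r} must be > 0, got {c}"
                )


def residence_time(settings: FlowSettings) -> float:
    """Hydraulic residence time ``tau = V / F_tot`` in minutes."""
    return settings.reactor_volume / settings.total_flow


def concentration_to_flow(c_in: float, settings: FlowSettings, channel: str) -> float:
    """Flow rate (ul/min) delivering concentration ``c_in`` on ``channel``.

    ``F = F_tot * C_in / C_syr``: diluting the syringe stock into the total
    flow.  Concentrations above the stock are unreachable.
    """
    c_syr = settings.syringe_concentrations[channel]
    c_in = np.asarray(c_in, dtype=float)
    if np.any(c_in < 0):
        raise ProfileError(f"negative concentration requested on channel {channel!r}")
    if np.any(c_in > c_syr):
        raise ProfileError(
            f"channel {channel!r}: requested concentration exceeds the "
            f"syringe stock ({float(np.max(c_in)):g} > {c_syr:g} mM); unreachable"
        )
    return settings.total_flow * c_in / c_syr


def concentration_from_flow(flow: float, settings: FlowSettings, channel: str) -> float:
    """Inverse of :func:`concentration_to_flow`: ``C_in = F * C_syr / F_tot``."""
    flow = np.asarray(flow, dtype=float)
    if np.any(flow < 0):
        raise ProfileError(f"negative flow on channel {channel!r}")
    return flow * settings.syringe_concentrations[channel] / settings.total_flow


@dataclass
class InputProfile:
    """Piecewise-constant multi-channel input schedule.

    ``segment_starts`` holds the start time (s) of each hold segment;
    ``concentrations`` the reagent concentration (mM) per channel per
    segment; ``flows`` the corresponding syringe flow rates (ul/min),
    including the balancing water channel once added.
    """

    segment_starts: np.ndarray
    hold_s: np.ndarray
    concentrations: dict[str, np.ndarray]
    flows: dict[str, np.ndarray]
    settings: FlowSettings

    def __post_init__(self) -> None:
        self.segment_starts = np.asarray(self.segment_starts, dtype=float)
        self.hold_s = np.asarray(self.hold_s, dtype=float)
        n = self.segment_starts.size
        for name, arr in list(self.concentrations.items()):
            arr = np.asarray(arr, dtype=float)
            if arr.size != n:
                raise ProfileError(f"channel {name!r}: {arr.size} segments, expected {n}")
            if np.any(arr < 0):
                raise ProfileError(f"channel {name!r}: negative concentration")
            self.concentrations[name] = arr
        for name, arr in list(self.flows.items()):
            arr = np.asarray(arr, dtype=float)
            if np.any(arr < 0):
                raise ProfileError(f"channel {name!r}: negative flow")
            self.flows[name] = arr

    @property
    def channels(self) -> list[str]:
        return list(self.concentrations)

    @property
    def n_segments(self) -> int:
        return int(self.segment_starts.size)

    @property
    def duration_s(self) -> float:
        return float(self.segment_starts[-1] + self.hold_s[-1])

    def segment_index(self, t_s) -> np.ndarray:
        """Index of the hold segment containing each time (clipped to ends)."""
        t = np.atleast_1d(np.asarray(t_s, dtype=float))
        idx = np.searchsorted(self.segment_starts, t, side="right") - 1
        return np.clip(idx, 0, self.n_segments - 1)

    def concentration_at(self, t_s, channel: str) -> np.ndarray:
        return self.concentrations[channel][self.segment_index(t_s)]

    def sample(self, t_s, channels: Sequence[str] | None = None) -> np.ndarray:
        """Sample concentrations on an arbitrary grid -> (n_times, n_channels)."""
        channels = list(channels) if channels is not None else self.channels
        idx = self.segment_index(t_s)
        return np.column_stack([self.concentrations[c][idx] for c in channels])

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: ``time_s`` + one ``<channel>_mM`` column per reagent,
        plus ``water_ul_min`` if the water make-up flow has been computed."""
        data = {"time_s": self.segment_starts}
        for name in self.channels:
            data[f"{name}_mM"] = self.concentrations[name]
        if WATER_CHANNEL in self.flows:
            data["water_ul_min"] = self.flows[WATER_CHANNEL]
        return pd.DataFrame(data)


def make_constant_profile(
    concentrations_mM: Mapping[str, float],
    duration_s: float,
    settings: FlowSettings | None = None,
    hold_s: float | None = None,
) -> InputProfile:
    """A single- (or multi-) segment profile with constant concentrations."""
    settings = settings or FlowSettings()
    hold = float(hold_s) if hold_s is not None else float(duration_s)
    starts, holds = _segment_grid(duration_s, hold)
    conc = {
        name: np.full(starts.size, float(c)) for name, c in concentrations_mM.items()
    }
    flows = {
        name: concentration_to_flow(arr, settings, name) for name, arr in conc.items()
    }
    return balance_with_water(
        InputProfile(starts, holds, conc, flows, settings), settings
    )


def _segment_grid(duration_s: float, hold_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Segment start times and hold durations; a final partial segment is
    truncated rather than extended past the requested duration."""
    if duration_s <= 0 or hold_s <= 0:
        raise ProfileError("duration and hold must be positive")
    n_full = int(np.floor(duration_s / hold_s + 1e-9))
    starts = np.arange(n_full, dtype=float) * hold_s
    holds = np.full(n_full, float(hold_s))
    remainder = duration_s - n_full * hold_s
    if remainder > 1e-9:
        starts = np.append(starts, n_full * hold_s)
        holds = np.append(holds, remainder)
    return starts, holds


@dataclass(frozen=True)
class InputGrid:
    """Random 2-D concentration grid for static classification tasks."""

    raw: np.ndarray          # (n, 2) concentrations in mM
    normalized: np.ndarray   # (n, 2) affinely mapped onto [0, 1]^2
    ranges: tuple[tuple[float, float], tuple[float, float]]
    channels: tuple[str, str] = ("form", "naoh")

    @property
    def n_points(self) -> int:
        return int(self.raw.shape[0])


def sample_classification_grid(
    n: int = 132,
    range_1: tuple[float, float] = (10.0, 150.0),
    range_2: tuple[float, float] = (10.0, 50.0),
    seed: int = 0,
    channels: tuple[str, str] = ("form", "naoh"),
) -> InputGrid:
    """Uniformly sample ``n`` (formaldehyde, NaOH) concentration pairs.

    Defaults reproduce the classification input space: 132 points over
    10-150 mM x 10-50 mM, normalised onto the unit square.
    """
    if n < 1:
        raise ProfileError("n must be >= 1")
    for lo, hi in (range_1, range_2):
        if not hi > lo:
            raise ProfileError(f"degenerate range ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    raw = np.column_stack(
        [
            rng.uniform(range_1[0], range_1[1], size=n),
            rng.uniform(range_2[0], range_2[1], size=n),
        ]
    )
    lo = np.array([range_1[0], range_2[0]])
    hi = np.array([range_1[1], range_2[1]])
    normalized = (raw - lo) / (hi - lo)
    return InputGrid(raw=raw, normalized=normalized, ranges=(range_1, range_2),
                     channels=channels)


def gaussian_step_profile(
    mean_flow: float = 36.25,
    sd_flow: float = 10.36,
    hold_s: float = 60.0,
    duration_s: float = 3600.0,
    seed: int = 0,
    settings: FlowSettings | None = None,
    channel: str = "dha",
    constant_mM: Mapping[str, float] | None = None,
) -> InputProfile:
    """Fluctuating flow profile: one channel redrawn from N(mean, sd) every
    hold period, held constant in between, other reagents constant.

    Defaults follow the dynamic-emulation protocol: DHA flow with mean
    36.25 ul/min and s.d. 10.36 ul/min, 60 s holds, formaldehyde / NaOH /
    CaCl2 constant at 50 / 30 / 15 mM.  Negative draws are clipped at zero.
    """
    settings = settings or FlowSettings()
    if sd_flow < 0:
        raise ProfileError("sd_flow must be >= 0")
    if mean_flow > settings.total_flow:
        raise ProfileError(
            f"mean flow {mean_flow} exceeds total flow {settings.total_flow}"
        )
    if constant_mM is None:
        constant_mM = {"form": 50.0, "naoh": 30.0, "cacl2": 15.0}
    starts, holds = _segment_grid(duration_s, hold_s)
    rng = np.random.default_rng(seed)
    draws = rng.normal(mean_flow, sd_flow, size=starts.size)
    n_neg = int(np.sum(draws < 0))
    if n_neg:
        logger.warning("clipped %d negative flow draws to 0", n_neg)
    flows_ch = np.clip(draws, 0.0, None)
    conc = {channel: concentration_from_flow(flows_ch, settings, channel)}
    flows = {channel: flows_ch}
    for name, c in constant_mM.items():
        conc[name] = np.full(starts.size, float(c))
        flows[name] = concentration_to_flow(conc[name], settings, name)
    profile = InputProfile(starts, holds, conc, flows, settings)
    return balance_with_water(profile, settings)


@dataclass(frozen=True)
class LorenzParams:
    """Lorenz system parameters and their mapping onto input channels.

    The raw axes are mean-centred, multiplied by ``scales`` and added to
    ``baselines_mM``; ``time_compression`` converts profile seconds to
    Lorenz model time units.
    """

    rho: float = 28.0
    sigma: float = 10.0
    beta: float = 8.0 / 3.0
    scales: Mapping[str, float] = field(
        default_factory=lambda: {"x": 1.4, "y": 1.0, "z": 1.3}
    )
    axis_channels: Mapping[str, str] = field(
        default_factory=lambda: {"x": "naoh", "y": "dha", "z": "form"}
    )
    baselines_mM: Mapping[str, float] = field(
        default_factory=lambda: {"naoh": 30.0, "dha": 50.0, "form": 50.0}
    )
    time_compression: float = 1.0 / 600.0   # model time units per second
    initial_state: tuple[float, float, float] = (1.0, 1.0, 1.0)
    transient: float = 30.0                  # model time units discarded

    def __post_init__(self) -> None:
        for name, v in (("rho", self.rho), ("sigma", self.sigma), ("beta", self.beta)):
            if not v > 0:
                raise ProfileError(f"{name} must be > 0, got {v}")
        for axis, s in self.scales.items():
            if not s > 0:
                raise ProfileError(f"scale for axis {axis!r} must be > 0, got {s}")


def lorenz_rhs(t: float, state: np.ndarray, sigma: float, rho: float, beta: float):
    x, y, z = state
    return [sigma * (y - x), x * (rho - z) - y, x * y - beta * z]


def integrate_lorenz(
    params: LorenzParams,
    duration: float,
    n_points: int,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the Lorenz system past its transient.

    Returns (model time grid, (n_points, 3) trajectory) covering
    ``duration`` model time units after discarding the initial transient.
    """
    t_end = params.transient + duration
    sol = solve_ivp(
        lorenz_rhs,
        (0.0, t_end),
        np.asarray(params.initial_state, dtype=float),
        args=(params.sigma, params.rho, params.beta),
        dense_output=True,
        rtol=rtol,
        atol=atol,
        method="RK45",
    )
    if not sol.success:
        raise ProfileError(f"Lorenz integration failed: {sol.message}")
    t = np.linspace(params.transient, t_end, n_points)
    return t - params.transient, sol.sol(t).T


def lorenz_profile(
    params: LorenzParams | None = None,
    duration_s: float = 8 * 3600.0,
    settings: FlowSettings | None = None,
    hold_s: float = 20.0,
    constant_mM: Mapping[str, float] | None = None,
) -> InputProfile:
    """Three-channel input profile tracing a Lorenz attractor.

    Each axis is mean-centred over the sampled trajectory, scaled
    (defaults 1.4 / 1.0 / 1.3 for x->NaOH, y->DHA, z->formaldehyde) and
    added to its channel baseline, then discretised onto the hold grid.
    """
    params = params or LorenzParams()
    settings = settings or FlowSettings()
    if duration_s <= 0:
        raise ProfileError("duration must be positive")
    if constant_mM is None:
        constant_mM = {"cacl2": 15.0}
    starts, holds = _segment_grid(duration_s, hold_s)
    model_duration = duration_s * params.time_compression
    # sample the dense solution at segment centres
    centres_model = (starts + holds / 2.0) * params.time_compression
    _, traj = integrate_lorenz(params, model_duration, n_points=4096)
    t_model = np.linspace(0.0, model_duration, 4096)
    conc: dict[str, np.ndarray] = {}
    for i, axis in enumerate(("x", "y", "z")):
        channel = params.axis_channels[axis]
        series = np.interp(centres_model, t_model, traj[:, i])
        centred = series - traj[:, i].mean()
        values = params.baselines_mM[channel] + params.scales[axis] * centred
        if np.any(values < 0):
            t_bad = starts[int(np.argmax(values < 0))]
            raise ProfileError(
                f"channel {channel!r} goes negative at t={t_bad:.0f} s; "
                "increase its baseline or decrease its scale factor"
            )
        conc[channel] = values
    for name, c in constant_mM.items():
        conc[name] = np.full(starts.size, float(c))
    flows = {
        name: concentration_to_flow(arr, settings, name) for name, arr in conc.items()
    }
    profile = InputProfile(starts, holds, conc, flows, settings)
    return balance_with_water(profile, settings)


def balance_with_water(profile: InputProfile, settings: FlowSettings) -> InputProfile:
    """Add the water make-up channel so channel flows sum to ``F_tot``.

    The reagent flows must never exceed the total flow; the first
    offending time is reported otherwise.
    """
    reagent_total = np.zeros(profile.n_segments)
    for name, arr in profile.flows.items():
        if name != WATER_CHANNEL:
            reagent_total = reagent_total + arr
    excess = reagent_total - settings.total_flow
    if np.any(excess > 1e-9):
        i = int(np.argmax(excess > 1e-9))
        raise ProfileError(
            f"reagent flows ({reagent_total[i]:g} ul/min) exceed the total flow "
            f"({settings.total_flow:g}) at t={profile.segment_starts[i]:.0f} s"
        )
    water = np.clip(settings.total_flow - reagent_total, 0.0, None)
    flows = dict(profile.flows)
    flows[WATER_CHANNEL] = water
    return InputProfile(
        profile.segment_starts.copy(),
        profile.hold_s.copy(),
        {k: v.copy() for k, v in profile.concentrations.items()},
        flows,
        settings,
    )
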