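"""Simulated chemical reservoir: a mass-action network in a CSTR.

The physical reservoir (an autocatalytic sugar-forming network observed by
ion-mobility mass spectrometry) is replaced by a seeded random mass-action
reaction network simulated in a continuous stirred tank reactor.  Every
species obeys

    dX/dt = k_f * (X_in(t) - X) + S @ v(X)

with ``k_f`` the inverse residence time, ``X_in`` the (piecewise-constant)
inflow concentrations and ``S @ v`` the stoichiometry-weighted mass-action
rates.  A detection layer maps species concentrations to many noisy,
saturating "ion trace" channels sampled at 500 ms, emulating electrospray
detection without modelling the instrument.

The surrogate is built to exhibit the qualitative properties that make a
chemical network usable as a reservoir: nonlinear response to inputs,
fading memory at the residence-time scale, and high-dimensional readout.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .input_profiles import InputProfile

__all__ = [
    "Reaction",
    "CRNSpec",
    "ReservoirConfig",
    "ReservoirTrace",
    "generate_random_crn",
    "simulate_cstr",
    "observe",
    "steady_state_features",
    "bin_average",
]


class ReservoirError(ValueError):
    pass


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction: reactant/product stoichiometries and k.

    Rate constant units: min^-1 for unimolecular, mM^-1 min^-1 for
    bimolecular steps (concentrations in mM, time in minutes).
    """

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_constant: float

    def __post_init__(self) -> None:
        if self.rate_constant <= 0:
            raise ReservoirError(f"rate constant must be > 0, got {self.rate_constant}")
        for name, coeff in self.reactants + self.products:
            if coeff < 0 or int(coeff) != coeff:
                raise ReservoirError(
                    f"stoichiometric coefficient for {name!r} must be a "
                    f"nonnegative integer, got {coeff}"
                )

    def format(self) -> str:
        def side(pairs):
            return " + ".join(
                (f"{c} {s}" if c != 1 else s) for s, c in pairs
            ) or "0"
        return f"{side(self.reactants)} -> {side(self.products)} ; k={self.rate_constant:g}"


@dataclass
class CRNSpec:
    """Declarative description of a reaction network.

    ``sizes`` gives the monomer-equivalent mass of each species (carbon
    count in the sugar-network analogy); with mass-conserving generation
    every reaction conserves the size-weighted total.
    ``input_map`` assigns each input channel to the species it feeds.
    """

    species: list[str]
    reactions: list[Reaction]
    input_map: dict[str, str]
    sizes: dict[str, int] = field(default_factory=dict)
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.species)
        for rxn in self.reactions:
            for name, _ in rxn.reactants + rxn.products:
                if name not in known:
                    raise ReservoirError(f"reaction references unknown species {name!r}")
        for channel, target in self.input_map.items():
            if target not in known:
                raise ReservoirError(
                    f"input channel {channel!r} maps to unknown species {target!r}"
                )

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def stoichiometry(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(reactant matrix R, net matrix S, rate constants k).

        R and S are (n_reactions, n_species); the ODE right-hand side is
        ``S.T @ (k * prod(X**R))``.
        """
        index = {s: i for i, s in enumerate(self.species)}
        n_r, n_s = self.n_reactions, self.n_species
        R = np.zeros((n_r, n_s))
        P = np.zeros((n_r, n_s))
        k = np.empty(n_r)
        for j, rxn in enumerate(self.reactions):
            k[j] = rxn.rate_constant
            for name, coeff in rxn.reactants:
                R[j, index[name]] += coeff
            for name, coeff in rxn.products:
                P[j, index[name]] += coeff
        return R, P - R, k

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(",".join(self.species).encode())
        for rxn in self.reactions:
            h.update(rxn.format().encode())
        h.update(repr(sorted(self.input_map.items())).encode())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class ReservoirConfig:
    """Observation and flow configuration of the simulated reservoir."""

    flow_constant: float = 0.5        # k_f = 1/tau, min^-1
    sampling_period_s: float = 0.5    # detector time resolution
    n_channels: int = 106             # observed ion-trace channels
    noise_cv: float = 0.05            # multiplicative lognormal CV
    noise_floor: float = 0.01         # additive Gaussian sd (a.u.)
    bin_s: float = 10.0               # averaging window for readouts
    identity_observation: bool = False  # 1:1 noiseless channel per species
    observation_seed: int = 0         # fixes the channel map (the "instrument")

    def __post_init__(self) -> None:
        if self.flow_constant <= 0:
            raise ReservoirError("flow_constant must be > 0")
        if self.sampling_period_s <= 0:
            raise ReservoirError("sampling period must be > 0")
        if self.n_channels < 1:
            raise ReservoirError("need at least one observation channel")


@dataclass
class ReservoirTrace:
    """Time-resolved record of reservoir channels.

    ``values`` is (n_times, n_channels); intensities are nonnegative.
    ``provenance`` records the network hash and seeds that produced it.
    """

    time_s: np.ndarray
    values: np.ndarray
    channels: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.time_s.size:
            raise ReservoirError("values must be (n_times, n_channels)")
        if self.values.shape[1] != len(self.channels):
            raise ReservoirError("column count must equal channel count")
        if np.any(np.diff(self.time_s) <= 0):
            raise ReservoirError("time grid must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.channels)
        df.insert(0, "time_s", self.time_s)
        return df


# ---------------------------------------------------------------------------
# random network generation

def generate_random_crn(
    n_species: int = 40,
    n_reactions: int = 120,
    seed: int = 0,
    frac_bimolecular: float = 0.45,
    frac_autocatalytic: float = 0.15,
    input_channels: Sequence[str] = ("dha", "form", "naoh", "cacl2"),
    max_size: int = 6,
    mass_conserving: bool = True,
    n_catalysts: int = 2,
    frac_catalysed: float = 0.5,
) -> CRNSpec:
    """Generate a seeded random mass-action network.

    Carbon species are organised by monomer count 1..``max_size``
    (condensation chemistry: small units combine into larger ones, larger
    ones fragment or isomerise, and a fraction of steps are autocatalytic,
    ``A + B -> 2 B``).  Condensations draw their reactants preferentially
    from the small feedstock units, as in sugar-forming chemistry.  With
    ``mass_conserving`` every reaction conserves the size-weighted carbon
    total, so the closed system (k_f = 0) has a linear conserved quantity.

    ``n_catalysts`` species act purely catalytically (appearing unchanged
    on both sides of a fraction ``frac_catalysed`` of reactions),
    emulating base/salt inputs that modulate rates network-wide rather
    than feeding mass in.  Input channels feed, in order, a trimer, a
    monomer, then the catalyst species; every input species takes part in
    at least one reaction.
    """
    if n_species < 2 or n_reactions < 1:
        raise ReservoirError("need n_species >= 2 and n_reactions >= 1")
    if frac_bimolecular < 0 or frac_autocatalytic < 0:
        raise ReservoirError("reaction-type fractions must be >= 0")
    n_auto = int(round(frac_autocatalytic * n_reactions))
    n_bi = int(round(frac_bimolecular * n_reactions))
    if n_auto + n_bi > n_reactions:
        raise ReservoirError(
            f"infeasible fractions: {n_bi} bimolecular + {n_auto} autocatalytic "
            f"> {n_reactions} reactions"
        )
    n_catalysts = min(n_catalysts, max(n_species - 2, 0))
    rng = np.random.default_rng(seed)

    # carbon species named C<size>_<index>; every size 1..max_size
    # represented; catalysts carry no carbon (size 0)
    n_carbon = n_species - n_catalysts
    sizes_list = [1 + i % max_size for i in range(n_carbon)]
    species = [f"C{sz}_{i}" for i, sz in enumerate(sizes_list)]
    catalysts = [f"cat_{j}" for j in range(n_catalysts)]
    species = species + catalysts
    sizes = dict(zip(species, sizes_list + [0] * n_catalysts))
    by_size: dict[int, list[str]] = {}
    for name, sz in sizes.items():
        if sz > 0:
            by_size.setdefault(sz, []).append(name)
    carbon = [s for s in species if sizes[s] > 0]
    # weight small units heavily when drawing condensation partners
    cond_w = np.array([1.0 / sizes[s] ** 2 for s in carbon])
    cond_w /= cond_w.sum()

    def k_uni() -> float:
        return float(np.exp(rng.uniform(np.log(0.05), np.log(2.0))))

    def k_bi() -> float:
        return float(np.exp(rng.uniform(np.log(0.002), np.log(0.08))))

    def pick(names: list[str]) -> str:
        return names[rng.integers(len(names))]

    def catalyse(rxn: Reaction) -> Reaction:
        """Attach a catalyst to both sides and rescale k to keep the flux
        comparable at working catalyst concentrations (~30 mM)."""
        if not catalysts or rng.random() >= frac_catalysed:
            return rxn
        cat = pick(catalysts)
        return Reaction(
            rxn.reactants + ((cat, 1),),
            rxn.products + ((cat, 1),),
            rxn.rate_constant / 30.0,
        )

    def condensation() -> Reaction:
        while True:
            a, b = (carbon[i] for i in rng.choice(len(carbon), size=2, p=cond_w))
            tot = sizes[a] + sizes[b]
            if tot in by_size:
                c = pick(by_size[tot])
                if a == b:
                    return catalyse(Reaction(((a, 2),), ((c, 1),), k_bi()))
                return catalyse(Reaction(((a, 1), (b, 1)), ((c, 1),), k_bi()))

    def k_auto() -> float:
        # weak enough that k * [partner] stays below the outflow rate at
        # working concentrations, preserving the echo-state property
        return float(np.exp(rng.uniform(np.log(0.001), np.log(0.008))))

    def autocatalytic() -> Reaction:
        # A + B -> 2B with size(A) == size(B): catalysed conversion where
        # the template copies itself (formose-style autocatalysis)
        while True:
            sz = int(rng.integers(1, max_size + 1))
            pool = by_size.get(sz, [])
            if len(pool) >= 2:
                a, b = rng.choice(len(pool), size=2, replace=False)
                return Reaction(
                    ((pool[a], 1), (pool[b], 1)), ((pool[b], 2),), k_auto()
                )

    def unimolecular() -> Reaction:
        c = pick(carbon)
        sz = sizes[c]
        if sz > 1 and rng.random() < 0.5:
            # fragmentation into two smaller units
            s1 = int(rng.integers(1, sz))
            s2 = sz - s1
            if s1 in by_size and s2 in by_size:
                a, b = pick(by_size[s1]), pick(by_size[s2])
                if a == b:
                    return catalyse(Reaction(((c, 1),), ((a, 2),), k_uni()))
                return catalyse(Reaction(((c, 1),), ((a, 1), (b, 1)), k_uni()))
        pool = [s for s in by_size[sz] if s != c]
        if not pool:
            return unimolecular()
        return catalyse(Reaction(((c, 1),), ((pick(pool), 1),), k_uni()))

    reactions: list[Reaction] = []
    for _ in range(n_bi):
        reactions.append(condensation())
    for _ in range(n_auto):
        reactions.append(autocatalytic())
    while len(reactions) < n_reactions:
        reactions.append(unimolecular())

    # input channels feed: a trimer (DHA analogue), a monomer
    # (formaldehyde analogue), then the catalyst species, then remaining
    # small carbon units
    preferred: list[str] = []
    for sz in (3, 1):
        pool = by_size.get(sz) or carbon
        preferred.append(pool[0])
    preferred.extend(catalysts)
    preferred.extend(s for s in sorted(carbon, key=lambda s: (sizes[s], s))
                     if s not in preferred)
    input_map = {ch: preferred[i % len(preferred)]
                 for i, ch in enumerate(input_channels)}

    # guarantee every input species is consumed and every species touched
    consumed = {name for rxn in reactions for name, _ in rxn.reactants}
    touched = consumed | {
        name for rxn in reactions for name, _ in rxn.products
    }
    extras: list[Reaction] = []
    for target in input_map.values():
        if target not in consumed:
            extras.append(
                _consuming_reaction(target, sizes, by_size, pick, k_uni, k_bi, rng)
            )
            consumed.add(target)
    for name in species:
        if name not in touched:
            extras.append(
                _consuming_reaction(name, sizes, by_size, pick, k_uni, k_bi, rng)
            )
            touched.add(name)
    if extras:
        # replace the tail of the unimolecular fill to keep the count exact
        reactions = reactions[: n_reactions - len(extras)] + extras

    return CRNSpec(
        species=species,
        reactions=reactions,
        input_map=dict(input_map),
        sizes=sizes,
        seed=seed,
        params={
            "n_species": n_species,
            "n_reactions": n_reactions,
            "frac_bimolecular": frac_bimolecular,
            "frac_autocatalytic": frac_autocatalytic,
            "mass_conserving": mass_conserving,
        },
    )


def _consuming_reaction(target, sizes, by_size, pick, k_uni, k_bi, rng) -> Reaction:
    """A mass-conserving reaction consuming (or, for a catalyst, using)
    ``target``."""
    sz = sizes[target]
    if sz == 0:
        # unused catalyst: attach it to an isomerisation of any monomer
        a = pick(by_size[min(by_size)])
        pool = [s for s in by_size[sizes[a]] if s != a]
        b = pick(pool) if pool else a
        return Reaction(((a, 1), (target, 1)), ((b, 1), (target, 1)), k_uni() / 30.0)
    pool = [s for s in by_size[sz] if s != target]
    if pool:
        return Reaction(((target, 1),), ((pick(pool), 1),), k_uni())
    # no same-size partner: condense with a monomer if possible
    if sz + 1 in by_size and 1 in by_size:
        a = pick(by_size[1])
        c = pick(by_size[sz + 1])
        return Reaction(((target, 1), (a, 1)), ((c, 1),), k_bi())
    raise ReservoirError(f"cannot build a consuming reaction for {target!r}")


# ---------------------------------------------------------------------------
# CSTR simulation

def _make_rhs(crn: CRNSpec, k_f: float):
    R, S, k = crn.stoichiometry()
    ST = S.T.copy()

    def rhs(t, x, x_in):
        xp = np.maximum(x, 0.0)
        v = k * np.prod(xp[None, :] ** R, axis=1)
        return k_f * (x_in - x) + ST @ v

    return rhs


def simulate_cstr(
    crn: CRNSpec,
    profile: InputProfile,
    config: ReservoirConfig | None = None,
    x0: np.ndarray | Mapping[str, float] | None = None,
    equilibration_min: float = 0.0,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> ReservoirTrace:
    """Simulate the reservoir network in the CSTR under a driving profile.

    The inflow concentration of each mapped species follows its input
    channel segment by segment; the state is carried across segment
    boundaries.  With ``equilibration_min`` the reactor is first run to
    (near) steady state under the profile's initial inputs, mirroring the
    experimental 30-minute equilibration, and recording starts afterwards
    with time zero at the profile start.

    Returns the species-concentration trace sampled every
    ``config.sampling_period_s``.
    """
    config = config or ReservoirConfig()
    for channel in profile.channels:
        if channel not in crn.input_map and channel != "water":
            raise ReservoirError(
                f"profile channel {channel!r} has no input mapping in the network"
            )
    index = {s: i for i, s in enumerate(crn.species)}
    k_f = config.flow_constant
    rhs = _make_rhs(crn, k_f)

    def inflow_for_segment(seg: int) -> np.ndarray:
        x_in = np.zeros(crn.n_species)
        for channel, target in crn.input_map.items():
            if channel in profile.concentrations:
                x_in[index[target]] += profile.concentrations[channel][seg]
        return x_in

    if x0 is None:
        state = np.zeros(crn.n_species)
    elif isinstance(x0, Mapping):
        state = np.zeros(crn.n_species)
        for name, c in x0.items():
            state[index[name]] = c
    else:
        state = np.asarray(x0, dtype=float).copy()
    if np.any(state < 0):
        raise ReservoirError("initial concentrations must be nonnegative")

    def integrate(x, x_in, t0_min, t1_min, t_eval_min=None):
        sol = solve_ivp(
            rhs,
            (t0_min, t1_min),
            x,
            args=(x_in,),
            method="LSODA",
            t_eval=t_eval_min,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise ReservoirError(
                f"integrator failed near t={sol.t[-1] * 60:.1f} s: {sol.message}"
            )
        return sol

    if equilibration_min > 0:
        sol = integrate(state, inflow_for_segment(0), 0.0, equilibration_min)
        state = sol.y[:, -1]

    dt_min = config.sampling_period_s / 60.0
    n_samples = int(np.floor(profile.duration_s / config.sampling_period_s + 1e-9)) + 1
    sample_t_s = np.arange(n_samples) * config.sampling_period_s
    out = np.empty((n_samples, crn.n_species))
    cursor = 0
    for seg in range(profile.n_segments):
        t0 = profile.segment_starts[seg]
        t1 = t0 + profile.hold_s[seg]
        # samples in [t0, t1), plus the final endpoint on the last segment
        hi = n_samples if seg == profile.n_segments - 1 else int(
            np.searchsorted(sample_t_s, t1 - 1e-9)
        )
        t_eval = sample_t_s[cursor:hi] / 60.0
        x_in = inflow_for_segment(seg)
        t_eval_full = t_eval
        if t_eval.size == 0 or t_eval[-1] < t1 / 60.0 - 1e-12:
            t_eval_full = np.append(t_eval, t1 / 60.0)
        sol = integrate(state, x_in, t0 / 60.0, t1 / 60.0, t_eval_full)
        ys = sol.y.T
        out[cursor:hi] = ys[: hi - cursor]
        state = ys[-1]
        cursor = hi
    out = np.clip(out, 0.0, None)
    return ReservoirTrace(
        time_s=sample_t_s,
        values=out,
        channels=list(crn.species),
        provenance={
            "crn_hash": crn.content_hash(),
            "crn_seed": crn.seed,
            "k_f_per_min": k_f,
            "sampling_period_s": config.sampling_period_s,
            "equilibration_min": equilibration_min,
        },
    )


# ---------------------------------------------------------------------------
# observation layer

def _observation_matrix(
    n_species: int,
    n_channels: int,
    rng: np.random.Generator,
    abundance: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sparse nonnegative mixing weights plus per-channel gain/saturation.

    Each channel reads 1-3 species (emulating adducts of the same
    compound), with a saturating response ``g * s / (1 + s / K)``.  With
    ``abundance`` given, source species are drawn proportionally to their
    abundance: the recorded ion channels correspond to compounds actually
    present in the reactor, not to arbitrary species.
    """
    if abundance is not None:
        p = np.asarray(abundance, dtype=float).clip(min=0.0)
        p = p + 0.01 * max(p.max(), 1e-12)   # smoothing keeps rare species reachable
        p = p / p.sum()
    else:
        p = None
    W = np.zeros((n_channels, n_species))
    for ch in range(n_channels):
        n_src = int(rng.integers(1, 4))
        src = rng.choice(n_species, size=min(n_src, n_species), replace=False, p=p)
        W[ch, src] = rng.uniform(0.3, 1.0, size=src.size)
    gains = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=n_channels))
    sat_K = np.exp(rng.uniform(np.log(5.0), np.log(100.0), size=n_channels))
    return W, gains, sat_K


def observation_weights(
    crn: CRNSpec,
    config: ReservoirConfig | None = None,
    reference_mM: Mapping[str, float] | None = None,
    equilibration_min: float = 30.0,
) -> np.ndarray:
    """Species abundances at a reference operating point.

    Simulates the network to steady state under nominal constant inputs
    (mid-range concentrations by default) and returns the time-mean
    species concentrations, used to weight which species the observation
    channels read.  Deterministic given the network and configuration.
    """
    from .input_profiles import make_constant_profile

    config = config or ReservoirConfig()
    if reference_mM is None:
        reference_mM = {"form": 80.0, "naoh": 30.0, "dha": 50.0, "cacl2": 15.0}
    reference_mM = {k: v for k, v in reference_mM.items() if k in crn.input_map}
    profile = make_constant_profile(reference_mM, duration_s=120.0)
    ref_cfg = ReservoirConfig(
        flow_constant=config.flow_constant, sampling_period_s=10.0,
        n_channels=config.n_channels, noise_cv=0.0, noise_floor=0.0,
    )
    trace = simulate_cstr(crn, profile, ref_cfg, equilibration_min=equilibration_min)
    return trace.values.mean(axis=0)


def observe(
    trace: ReservoirTrace,
    config: ReservoirConfig | None = None,
    seed: int = 0,
    abundance: np.ndarray | None = None,
) -> ReservoirTrace:
    """Map species concentrations to noisy ion-trace channels.

    Each observed channel is a saturating monotone transform of a sparse
    nonnegative combination of species, with multiplicative lognormal
    noise (CV ``config.noise_cv``) and an additive noise floor, clipped at
    zero.  With ``config.identity_observation`` the channels are the
    species themselves (still subject to noise if configured).

    The channel map itself (which species each channel reads, gains,
    saturation) is the instrument: it is drawn once from
    ``config.observation_seed`` and stays fixed across runs, while
    ``seed`` drives only the detection noise.
    """
    config = config or ReservoirConfig()
    rng = np.random.default_rng(seed)
    n_times, n_species = trace.values.shape
    if config.identity_observation:
        signal = trace.values.copy()
        channels = list(trace.channels)
    else:
        if config.n_channels > n_species * 3:
            raise ReservoirError(
                f"{config.n_channels} channels exceeds 3 adducts per species "
                f"for {n_species} species"
            )
        map_rng = np.random.default_rng(config.observation_seed)
        W, gains, sat_K = _observation_matrix(
            n_species, config.n_channels, map_rng, abundance=abundance
        )
        s = trace.values @ W.T
        signal = gains * s / (1.0 + s / sat_K)
        channels = [f"ion_{i:03d}" for i in range(config.n_channels)]
    if config.noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.noise_cv**2))
        signal = signal * rng.lognormal(-0.5 * sigma**2, sigma, size=signal.shape)
    if config.noise_floor > 0:
        signal = signal + rng.normal(0.0, config.noise_floor, size=signal.shape)
    signal = np.clip(signal, 0.0, None)
    prov = dict(trace.provenance)
    prov.update({"observation_seed": seed, "noise_cv": config.noise_cv,
                 "noise_floor": config.noise_floor})
    return ReservoirTrace(trace.time_s.copy(), signal, channels, prov)


# ---------------------------------------------------------------------------
# feature extraction

def steady_state_features(trace: ReservoirTrace, window_min: float = 10.0) -> np.ndarray:
    """Per-channel mean over the final ``window_min`` minutes.

    This is the steady-state readout used for static classification: with
    500 ms sampling, a 10-minute window averages 1,200 samples per channel.
    """
    window_s = window_min * 60.0
    if trace.duration_s + 1e-9 < window_s:
        raise ReservoirError(
            f"trace ({trace.duration_s:.0f} s) shorter than window ({window_s:.0f} s)"
        )
    t_end = trace.time_s[-1]
    mask = trace.time_s > t_end - window_s + 1e-9
    return trace.values[mask].mean(axis=0)


def bin_average(trace: ReservoirTrace, bin_s: float = 10.0) -> ReservoirTrace:
    """Average the trace over non-overlapping bins to reduce noise.

    Output times are bin centres; a trailing partial bin is dropped.
    """
    step = float(np.median(np.diff(trace.time_s)))
    if bin_s < step - 1e-12:
        raise ReservoirError(
            f"bin ({bin_s} s) smaller than the sampling period ({step} s)"
        )
    per_bin = int(round(bin_s / step))
    n_bins = trace.time_s.size // per_bin
    if n_bins == 0:
        raise ReservoirError("trace shorter than one bin")
    n_used = n_bins * per_bin
    values = trace.values[:n_used].reshape(n_bins, per_bin, -1).mean(axis=1)
    t0 = trace.time_s[0]
    times = t0 + (np.arange(n_bins) + 0.5) * per_bin * step - step / 2.0
    prov = dict(trace.provenance)
    prov["bin_s"] = bin_s
    return ReservoirTrace(times, values, list(trace.channels), prov)
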