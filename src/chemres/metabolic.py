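"""Dynamic target generation: a flow-modified metabolic ODE network.

The dynamic-emulation task asks the reservoir to reproduce the response
of a metabolic-style kinetic model placed in the same flow regime as the
reactor: every substrate gains an inflow term ``0 -> X (k_f * X_in)`` and
an outflow term ``X -> 0 (k_f * X)``, with ``k_f = 0.5 min^-1`` and the
inflow concentrations set to the model's initial concentrations.  One
designated substrate (the DHA-fed entry point) has its inflow
concentration follow the fluctuating input profile.

The shipped model is a deliberately small (~13 substrate) caricature of
central carbon metabolism with four features that matter for the task:

* a substrate fed directly by the driven input (fast, linear response),
* a downstream branch with saturating Michaelis-Menten kinetics
  (nonlinear response),
* an ATP/ADP cofactor pair whose total is conserved in the closed system,
* a glyoxylate-shunt-like autocatalytic C4 cycle whose near-neutral mode
  relaxes much more slowly than the flow timescale (the "slow species"
  that linear readouts of a fast reservoir predict poorly).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .input_profiles import InputProfile

__all__ = [
    "MetReaction",
    "MetabolicModel",
    "TargetSeries",
    "add_cstr_terms",
    "toy_metabolism",
    "simulate_driven",
]


class MetabolicError(ValueError):
    pass


@dataclass(frozen=True)
class MetReaction:
    """A reaction with either mass-action or saturating kinetics.

    ``law`` is ``"mass_action"`` (v = k * prod[S_i^n_i]) or
    ``"michaelis_menten"`` (v = vmax * prod_i S_i / (km_i + S_i), one
    saturating factor per reactant).
    """

    name: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    law: str = "mass_action"
    k: float | None = None
    vmax: float | None = None
    km: float | None = None

    def rate(self, conc: Mapping[str, float]) -> float:
        if self.law == "mass_action":
            v = self.k
            for name, coeff in self.reactants:
                v *= conc[name] ** coeff
            return v
        if self.law == "michaelis_menten":
            v = self.vmax
            for name, _ in self.reactants:
                s = conc[name]
                v *= s / (self.km + s)
            return v
        raise MetabolicError(f"unknown rate law {self.law!r}")


@dataclass
class MetabolicModel:
    """Kinetic model, optionally augmented with CSTR flow terms."""

    substrates: list[str]
    reactions: list[MetReaction]
    initial_concentrations: dict[str, float]
    flow_constant: float | None = None        # k_f (min^-1); None = closed
    inflow_concentrations: dict[str, float] | None = None
    driven: str | None = None                 # substrate following u(t)

    def __post_init__(self) -> None:
        known = set(self.substrates)
        for rxn in self.reactions:
            for name, _ in rxn.reactants + rxn.products:
                if name not in known:
                    raise MetabolicError(
                        f"reaction {rxn.name!r} references unknown substrate {name!r}"
                    )
        if self.driven is not None and self.driven not in known:
            raise MetabolicError(f"driven substrate {self.driven!r} unknown")

    def rhs(self) -> "callable":
        """Vectorised ODE right-hand side (time in minutes)."""
        index = {s: i for i, s in enumerate(self.substrates)}
        n = len(self.substrates)
        k_f = self.flow_constant or 0.0
        x_in = np.zeros(n)
        if self.inflow_concentrations:
            for name, c in self.inflow_concentrations.items():
                x_in[index[name]] = c
        # precompute stoichiometry rows
        stoich = []
        for rxn in self.reactions:
            row = np.zeros(n)
            for name, coeff in rxn.reactants:
                row[index[name]] -= coeff
            for name, coeff in rxn.products:
                row[index[name]] += coeff
            stoich.append(row)
        stoich = np.array(stoich)
        reactions = self.reactions
        substrates = self.substrates

        def fn(t, x, x_in_override=None):
            xi = x_in if x_in_override is None else x_in_override
            conc = {s: max(x[i], 0.0) for s, i in index.items()}
            v = np.array([rxn.rate(conc) for rxn in reactions])
            return k_f * (xi - x) + stoich.T @ v

        fn.index = index
        fn.x_in = x_in
        return fn


@dataclass
class TargetSeries:
    """Substrate trajectories y(t) plus the driving input record u(t)."""

    time_s: np.ndarray
    values: np.ndarray               # (n_times, n_substrates)
    substrates: list[str]
    driven_input: np.ndarray | None = None
    train_boundary_s: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.time_s.size, len(self.substrates)):
            raise MetabolicError("values must be (n_times, n_substrates)")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.substrates)
        df.insert(0, "time_s", self.time_s)
        if self.driven_input is not None:
            df["u_driven"] = self.driven_input
        return df


def add_cstr_terms(
    model: MetabolicModel,
    k_f: float = 0.5,
    inflow_concentrations: Mapping[str, float] | None = None,
) -> MetabolicModel:
    """Augment every substrate with inflow/outflow terms at rate ``k_f``.

    Inflow concentrations default to the substrate's initial
    concentration, so the unforced flow system relaxes toward the model's
    reference state.
    """
    if k_f <= 0:
        raise MetabolicError("k_f must be > 0")
    x_in = dict(inflow_concentrations or {})
    for s in model.substrates:
        if s not in x_in:
            if s not in model.initial_concentrations:
                raise MetabolicError(f"substrate {s!r} has no initial concentration")
            x_in[s] = model.initial_concentrations[s]
    return replace(model, flow_constant=k_f, inflow_concentrations=x_in)


def toy_metabolism() -> MetabolicModel:
    """The built-in ~13-substrate central-carbon caricature (closed form;
    apply :func:`add_cstr_terms` before driving it).

    Topology: DHA -> triose phosphate -> PEP -> pyruvate -> acetyl-CoA
    feeding a TCA/glyoxylate loop (OAA + AcCoA -> citrate -> isocitrate;
    the glyoxylate shunt ICIT + GLX -> 2 GLX + SUC is autocatalytic in
    glyoxylate; GLX + AcCoA -> malate; succinate -> malate; malate ->
    OAA), with PEP -> pyruvate coupled to ADP -> ATP and a first-order
    ATP drain closing the cofactor pair.  The autocatalytic shunt,
    balanced against the outflow, produces a near-neutral collective mode
    that relaxes several-fold more slowly than the flow timescale.
    """
    mm = MetReaction
    reactions = [
        mm("dha_uptake", (("dha", 1),), (("g3p", 1),), k=2.0),
        mm("glycolysis", (("g3p", 1),), (("pep", 1),),
           law="michaelis_menten", vmax=60.0, km=5.0),
        mm("pyk", (("pep", 1), ("adp", 1)), (("pyr", 1), ("atp", 1)), k=0.4),
        mm("atp_use", (("atp", 1),), (("adp", 1),), k=1.5),
        mm("pdh", (("pyr", 1),), (("accoa", 1),),
           law="michaelis_menten", vmax=25.0, km=6.0),
        mm("cs", (("accoa", 1), ("oaa", 1)), (("cit", 1),), k=0.55),
        mm("acn", (("cit", 1),), (("icit", 1),), k=0.9),
        mm("icl", (("icit", 1), ("glx", 1)), (("glx", 2), ("suc", 1)), k=0.45),
        mm("ms", (("glx", 1), ("accoa", 1)), (("mal", 1),), k=0.05),
        mm("sdh", (("suc", 1),), (("mal", 1),), k=0.5),
        mm("mdh", (("mal", 1),), (("oaa", 1),), k=0.8),
        mm("overflow", (("pyr", 1),), (("lac", 1),), k=0.25),
    ]
    initial = {
        "dha": 50.0, "g3p": 8.0, "pep": 4.0, "pyr": 6.0, "accoa": 4.0,
        "oaa": 1.0, "cit": 2.0, "icit": 1.0, "glx": 0.05, "suc": 1.0,
        "mal": 1.5, "lac": 2.0, "atp": 2.0, "adp": 2.0,
    }
    return MetabolicModel(
        substrates=list(initial),
        reactions=reactions,
        initial_concentrations=initial,
        driven="dha",
    )


def find_steady_state(
    model: MetabolicModel,
    t_max_min: float = 1000.0,
    tol: float = 1e-9,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Integrate from the initial concentrations until ``t_max_min`` and
    verify a steady state: max |dX/dt| < tol * max(X, 1)."""
    if model.flow_constant is None:
        raise MetabolicError("add CSTR terms before equilibrating")
    fn = model.rhs()
    x0 = np.array([model.initial_concentrations[s] for s in model.substrates])
    sol = solve_ivp(fn, (0.0, t_max_min), x0, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise MetabolicError(f"equilibration failed: {sol.message}")
    x_ss = sol.y[:, -1]
    resid = np.abs(fn(t_max_min, x_ss))
    bound = tol * np.maximum(np.abs(x_ss), 1.0)
    if np.any(resid > bound):
        worst = int(np.argmax(resid / bound))
        raise MetabolicError(
            f"no steady state by t={t_max_min:g} min: |d{model.substrates[worst]}/dt| "
            f"= {resid[worst]:.3e}"
        )
    return x_ss


def simulate_driven(
    model: MetabolicModel,
    profile: InputProfile,
    equilibration_min: float = 1000.0,
    bin_s: float = 10.0,
    time_grid_s: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> TargetSeries:
    """Drive the flow-augmented model with an input profile.

    The model is first equilibrated under its default inflow for
    ``equilibration_min`` (steady state verified).  Then, segment by
    segment, the driven substrate's inflow concentration is set to the
    profile value and the ODE integrated from the previous final state.
    The trajectory is returned on a uniform ``bin_s`` grid (bin centres)
    aligned with the binned reservoir trace.
    """
    if model.flow_constant is None:
        raise MetabolicError("model has no flow terms; call add_cstr_terms first")
    if model.driven is None:
        raise MetabolicError("model has no designated driven substrate")
    driven_channel = None
    for ch in profile.channels:
        if ch in ("dha", model.driven):
            driven_channel = ch
            break
    if driven_channel is None:
        driven_channel = profile.channels[0]
    fn = model.rhs()
    idx_driven = fn.index[model.driven]

    state = find_steady_state(model, t_max_min=equilibration_min)

    if time_grid_s is not None:
        sample_t_s = np.asarray(time_grid_s, dtype=float)
        if sample_t_s[-1] > profile.duration_s + 1e-9:
            raise MetabolicError("requested time grid extends past the profile")
        n_bins = sample_t_s.size
    else:
        n_bins = int(np.floor(profile.duration_s / bin_s + 1e-9))
        sample_t_s = (np.arange(n_bins) + 0.5) * bin_s

    values = np.empty((n_bins, len(model.substrates)))
    u_record = np.empty(n_bins)
    cursor = 0
    for seg in range(profile.n_segments):
        t0 = profile.segment_starts[seg]
        t1 = t0 + profile.hold_s[seg]
        x_in = fn.x_in.copy()
        x_in[idx_driven] = profile.concentrations[driven_channel][seg]
        hi = n_bins if seg == profile.n_segments - 1 else int(
            np.searchsorted(sample_t_s, t1 - 1e-9)
        )
        t_eval = sample_t_s[cursor:hi] / 60.0
        t_eval_full = t_eval
        if t_eval.size == 0 or t_eval[-1] < t1 / 60.0 - 1e-12:
            t_eval_full = np.append(t_eval, t1 / 60.0)
        sol = solve_ivp(
            fn, (t0 / 60.0, t1 / 60.0), state, args=(x_in,),
            method="LSODA", t_eval=t_eval_full, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise MetabolicError(f"integration failed in segment {seg}: {sol.message}")
        ys = sol.y.T
        values[cursor:hi] = ys[: hi - cursor]
        u_record[cursor:hi] = profile.concentrations[driven_channel][seg]
        state = ys[-1]
        cursor = hi
    values = np.clip(values, 0.0, None)
    return TargetSeries(
        time_s=sample_t_s,
        values=values,
        substrates=list(model.substrates),
        driven_input=u_record,
        provenance={
            "k_f_per_min": model.flow_constant,
            "driven": model.driven,
            "equilibration_min": equilibration_min,
            "bin_s": bin_s,
        },
    )
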