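# chemres

Reservoir computing with a simulated chemical reaction network.

In physical reservoir computing, a fixed nonlinear dynamical system — here a
chemical reaction network running in a continuous stirred tank reactor
(CSTR) — transforms time-varying inputs into a high-dimensional state
`x(t)`, and only a single linear readout layer `W` is trained. The
experimental version of this idea drives an autocatalytic sugar-forming
network with reagent flows and reads the state as ~106 ion-intensity traces
from a mass spectrometer. `chemres` replaces the wet reactor with a seeded
random mass-action network in the same flow regime,

```
dX/dt = k_f (X_in(t) − X) + S · v(X),      k_f = 1/τ,  τ = V / F_tot = 2 min
```

and implements the full computational pipeline around it as tested,
reusable stages:

* **Input schedules** — flow/concentration algebra (`F = F_tot·C_in/C_syr`),
  random 2-D classification grids, Gaussian step profiles, Lorenz-attractor
  drives (ρ = 28, σ = 10, β = 8/3), with a water channel balancing total flow.
* **Synthetic reservoir** — CSTR simulation of a random condensation
  network with catalyst species and weak autocatalysis, observed as noisy,
  saturating "ion trace" channels at 500 ms resolution.
* **Static classification** — ten binary tasks on the unit square, a linear
  support-vector readout on steady-state features, stratified leave-five-out
  cross-validation (20 repeats × 26 splits = 520 evaluations), scored by the
  Φ (Matthews) correlation mapped to [0, 1] as (Φ + 1)/2.
* **Dynamic emulation** — a flow-modified metabolic ODE network as the
  target `y(t)`; ridge regression (α = 5·10⁻⁵) maps the reservoir trace onto
  the substrate trajectories.
* **Forecasting** — the same readout trained on the reactor's own inputs
  shifted δt = 120 s into the future.
* **Evaluation** — absolute scaled error
  `ASE(t) = |ŷ(t) − y(t)| / mean_train|y − ȳ_train|` (ASE < 1 beats a naive
  mean forecast) and lagged mutual information `I(x(t); u(t+δt))` in nats
  (negative δt = memory of past input).

The intended users are people studying unconventional / physical computing
who want a desk-scale, fully reproducible stand-in for a chemical reservoir
experiment: every pipeline is deterministic given a seed bundle.

## Worked example

Emulate the metabolic target from the simulated reservoir (90-min record,
30-min training window, 10-s evaluation bins):

```bash
chemres dynamics --seed 1
```

```json
{
  "mean_test_ase": {
    "dha": 0.281, "g3p": 0.257, "pep": 0.422, "pyr": 0.304,
    "accoa": 1.222, "oaa": 1.597, "cit": 1.288, "icit": 1.961,
    "glx": 1.854, "suc": 1.941, "mal": 1.655, "lac": 1.113,
    "atp": 0.334, "adp": 0.334
  }
}
```

Each number is the time-mean absolute scaled error of that substrate over
the 60-min test window. Substrates fed directly by the fluctuating DHA
input (`dha`, `g3p`, `pep`, `pyr`, the ATP/ADP pair) are emulated several
times better than the naive mean forecast (ASE ≪ 1), while the slow
glyoxylate-shunt cycle (`glx`, `suc`, `mal`, `oaa`) scores ASE > 1: its
relaxation time is much longer than the reservoir's 2-min residence-time
memory, so a linear readout of the fast reservoir cannot track it. That
contrast — good emulation of input-driven species, failure on slow internal
cycles — is the qualitative signature this package reproduces.

Static classification with the same reservoir:

```bash
chemres classify --task xor --seed 1
```

```json
{
  "task": "xor",
  "phi_accuracy": 0.9208810005619661,
  "n_evaluations": 520,
  "baseline_lsvc": 0.4308008740258276
}
```

The reservoir's steady-state features make XOR linearly separable
(Φ accuracy 0.92 over 520 leave-five-out splits) while the same linear
classifier on the raw 2-D inputs stays at chance (0.43) — the reservoir is
doing the nonlinear work.

Other entry points: `chemres forecast`, `chemres mi`, `chemres demo`, and
`chemres simulate --config configs/<kind>.yaml` for config-driven runs that
write tidy TSV tables, a JSON summary and a provenance manifest. The same
pipelines are importable from Python
(`chemres.experiment.classification_pipeline`, `dynamics_pipeline`,
`forecast_pipeline`, `mi_pipeline`).

## Layout

```
src/chemres/
  input_profiles.py   flow algebra, grids, Gaussian step and Lorenz drives
  reservoir.py        random CRN generation, CSTR simulation, observation
  classification.py   tasks, Φ scoring, leave-five-out CV, baselines (incl. ELM)
  metabolic.py        flow-modified kinetic target, toy metabolism
  readout.py          ridge readout, forecast targets, absolute scaled error
  infotheory.py       kNN / histogram MI, lagged profiles
  io.py               tidy TSV tables, declarative reaction-network format
  experiment.py       end-to-end pipelines, config, manifests
  cli.py              `chemres` command-line interface
```

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
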