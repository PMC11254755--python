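# Methods

This note documents the models behind `chemres`, the parameters that
matter, and what the synthetic data can and cannot show.

## The reservoir model

Every species in the reactor obeys CSTR dynamics

    dX/dt = k_f (X_in(t) − X) + S · v(X)

with `k_f` the flow constant (inverse residence time), `X_in(t)` the
piecewise-constant inflow concentrations set by the input schedule, `S`
the stoichiometric matrix and `v(X)` mass-action rates. Defaults follow
the reference flow regime: total flow 217.5 µl/min through a 435 µl
reactor, so τ = 2 min and `k_f = 0.5 min⁻¹`. Flow input `F = F_tot·C_in/C_syr`
converts a requested concentration into a syringe flow rate; a water
channel is computed so channel flows always sum to `F_tot` exactly.

The reservoir chemistry itself is *not* a mechanistic model of the
sugar-forming (formose) network — that mechanism is treated as a black
box in the original experiment too. Instead `generate_random_crn` builds
a seeded random condensation network designed to have the properties that
make a chemical network usable as a reservoir:

* **Carbon species** carry a monomer count 1–6 (`C3_12` is a trimer).
  Reactions are condensations (`A + B -> C`), fragmentations,
  isomerisations and a small autocatalytic fraction (`A + B -> 2B`), all
  conserving the size-weighted carbon total, so the closed system has an
  exact linear conservation law used as an integrator oracle in tests.
* **Catalyst species** (fed by the NaOH and CaCl₂ channels) appear
  unchanged on both sides of roughly half the reactions. This mirrors how
  base and salt modulate the rate landscape globally rather than feeding
  carbon in, and it is what gives the network strong, seed-robust
  sensitivity to the "catalytic" inputs.
* **Autocatalysis is kept weak** (rate constants 10⁻³–8·10⁻³ mM⁻¹min⁻¹).
  At working concentrations the positive feedback then never overcomes
  the outflow, so trajectories from different initial states converge
  under a common input — the fading-memory (echo-state) property.
  Stronger autocatalysis produces bistable networks that remember their
  initial condition forever, which would break reservoir computing.

Defaults: 40 species, 120 reactions, 45 % bimolecular, 15 % autocatalytic.
Input channels feed a trimer (the DHA analogue), a monomer (formaldehyde
analogue) and the two catalysts.

### Observation layer

The detector model maps species to `n_channels = 106` ion-trace channels
sampled every 500 ms. Each channel reads a sparse nonnegative combination
of 1–3 species (adducts of the same compound) through a saturating gain
`g·s/(1 + s/K)`, then receives multiplicative lognormal noise (CV 5 %) and
a small additive floor (σ = 0.01 a.u.), clipped at zero. Channel *sources
are drawn proportionally to species abundance* at a reference operating
point: real extracted-ion lists contain compounds actually present in the
reactor, and sampling sources uniformly would create dead channels whose
standardised features are pure noise. The channel map is the instrument:
it is fixed by `ReservoirConfig.observation_seed`, while the per-run seed
drives only the noise. The true instrument response and noise statistics
are not published; these defaults are stated, not fitted, and are
configurable.

## Static classification

132 (formaldehyde, NaOH) pairs are drawn uniformly from
10–150 mM × 10–50 mM and normalised onto the unit square; DHA and CaCl₂
are held at 50 and 15 mM. Each input is simulated to steady state
(20 min equilibration by default in the desk-scale pipeline; the wet
protocol used 30 min) and the final 10 min of the noisy observation —
1,200 samples per channel — is averaged into one feature vector.

Ten task boundaries are declared explicitly because the original tasks
are published only as shaded regions: AND/OR/XOR threshold both axes at
0.5; linear is `u₂ > u₁`; triangle is the interior of
{(0,0),(1,0),(0.5,1)}; checkers is a 3×3 alternating grid; circle is the
disc of radius 0.3 at the centre; sine is `u₂ > 0.5 + 0.25·sin 2πu₁`;
rings is the annulus between radii 0.15 and 0.35; dots is the union of
three radius-0.15 discs. All are replaceable `TaskDef` objects.

Features are standardised (mean 0, unit population variance; parameters
estimated from the training fold only) and a linear SVC (squared-hinge,
C = 1.0 — the published protocol does not report the value) is trained.
Cross-validation is stratified leave-five-out: per repeat the inputs are
class-interleaved and partitioned into 26 disjoint test sets of five; the
two leftover inputs (132 − 130) are train-only for that repeat. Φ is
computed per split with the convention Φ = 0 when a margin is degenerate,
mapped to (Φ+1)/2, and averaged over all 520 evaluations. Stratification
across splits of five cannot match class ratios exactly; the interleave
is best-effort. Baselines run the identical protocol on the raw 2-D
inputs: linear SVC, RBF SVC, a small MLP, a Gaussian-process classifier,
and an extreme learning machine (random tanh features + linear SVC,
implemented in-package; with zero hidden units it reduces exactly to the
linear SVC).

## The metabolic target

The dynamic target is a ~13-substrate caricature of central carbon
metabolism, *not* a fidelity model of E. coli (the original 87-substrate
kinetic model is an optional extension point; it is not bundled so the
package builds and tests offline). `add_cstr_terms` augments every
substrate with `+k_f·X_in − k_f·X`, `k_f = 0.5 min⁻¹`, `X_in` equal to the
initial concentrations; the DHA-fed entry substrate's `X_in` follows the
input profile segment by segment, with the state carried across segment
boundaries. The model is equilibrated for 1,000 min and steady state is
verified (`max |dX/dt| < 10⁻⁹·max(X, 1)`).

Design features, each load-bearing for a tested property:

* mass-action DHA uptake → fast, nearly linear response;
* Michaelis–Menten steps (glycolysis vmax 60, Km 5 mM; PDH vmax 25,
  Km 6 mM) → saturating nonlinear response;
* ATP/ADP pair exchanged by two reactions only → exact conservation when
  `k_f = 0`;
* a glyoxylate-shunt loop that is explicitly autocatalytic
  (`icit + glx -> 2 glx + suc`). With outflow on every substrate, a
  passive cycle cannot relax more slowly than 1/k_f; the near-neutral
  autocatalytic mode is the only way to create a genuinely slow species.
  Its slowest Jacobian eigenvalue at steady state is ≈ −0.2 min⁻¹, giving
  the shunt intermediates autocorrelation times ≳ 5× the driven
  substrate's under the fluctuating drive. This is what reproduces the
  characteristic failure mode: species slower than the reservoir's memory
  are predicted poorly.

## Readouts and their training data

Both dynamic readouts are ridge regressions with α = 5·10⁻⁵ and an
unpenalised intercept; features are centred through the intercept only
(no variance scaling). The fit equals the closed-form normal equations
`(XᵀX + αI)⁻¹XᵀY` on centred data, which the tests verify against an
independent implementation.

Readouts are trained on the **full-rate 500 ms record** — ≈ 3,600 samples
per channel for the 30-min window, the sample count the protocol quotes —
and evaluated on the 10-s binned record (binning suppresses detection
noise in the reported traces). Training on the binned record instead
(180 samples vs 106 channels) makes α = 5·10⁻⁵ effectively unregularised
least squares; the fit then memorises the training window and the Lorenz
forecast degrades to worse-than-naive at every input timescale we tried.
The 3,600-sample window is therefore treated as the operative protocol.

Forecast targets are the input channels sampled at `t + δt` (δt = 120 s,
which must be a multiple of the trace step); the final δt of the record is
dropped. ASE is computed per target with the training-window mean
absolute deviation as denominator; a constant training truth is an error
(the naive forecast would be exact and the scale undefined).

## The Lorenz drive

The three-channel forecasting input integrates the Lorenz system
(ρ = 28, σ = 10, β = 8/3; adaptive RK45, rtol 10⁻⁹, initial state
(1,1,1), a 30-unit transient discarded), mean-centres each axis, scales
x/y/z by 1.4/1.0/1.3, adds channel baselines (NaOH 30, DHA 50,
formaldehyde 50 mM) and discretises onto a 20-s hold grid. Negative
concentrations raise an error instructing a larger baseline or smaller
scale.

The mapping of Lorenz model time to reactor time is not published; it is
exposed as `time_compression` with default 1/600 units per second. The
choice matters: δt = 120 s is then 0.2 Lorenz units — within the window
where the chaotic flow is still smoothly predictable — and the
oscillation period (~7 min) sits above the 2-min reservoir memory, so the
state can track the drive. At 1/60–1/300 the 120-s horizon spans ≳ 0.5
Lyapunov times and even noiseless readouts cannot beat the naive
forecast; much slower than 1/600 the 90-min record becomes too
nonstationary for the 30-min training window.

## Mutual information

`mi_estimate` provides a k-nearest-neighbour estimator (k = 3, the
standard continuous-data choice; negative estimates clipped at 0) and a
plug-in histogram estimator (16 bins per axis) as a cross-check; both are
validated against the bivariate-Gaussian closed form −½·ln(1 − r²).
Values are in nats. `lagged_mi` computes I(x(t); u(t+δt)) on the shared
grid, truncating to the overlap (never wrapping): negative δt quantifies
memory of past input, and a channel that copies its input with delay d
peaks at δt = −d. The kNN noise floor for ~10³ samples is ≈ 0.03–0.05
nats; independence fixtures in the tests document it.

## Seeding and provenance

A single master seed expands through `SeedSequence` into independent
stage seeds (network generation, profile sampling, detection noise, CV
shuffling), all below 2³¹ and recorded in trace provenance and run
manifests. Identical configs reproduce bit-identical artifacts;
`run_experiment` writes SHA-256 hashes of every output to
`manifest.json`.

## Desk-scale problem sizes

The shipped pipelines simulate 90-min records (30-min train, 60-min
test) and a 20-min equilibration per classification input rather than the
multi-hour wet-lab runs; these sizes were chosen so a full experiment
family completes in seconds on one CPU while keeping every protocol
count (1,200-sample windows, 3,600-sample training, 520 CV evaluations)
intact.

## What passing tests do and do not show

The synthetic reservoir reproduces the *mechanism-level* claims: a
driven nonlinear network with fading memory supports linear-readout
classification, emulation of a flow-coupled kinetic model, short-horizon
forecasting, and measurable lagged mutual information. It does not
reproduce — and the package deliberately does not claim — the published
per-task Φ accuracies or prediction curves, which depend on the real
formose chemistry and instrument; product distributions, m/z assignment
and ion-mobility physics are out of scope. Detection-noise statistics are
assumptions, and the toy metabolism is a topological caricature whose
rate constants were chosen for its dynamical features, not biological
realism.
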