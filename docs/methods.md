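# Methods

## Model

The biological submodel tracks six culture concentrations in an aerated,
isothermal (30 °C), pH-controlled batch stirred tank: biomass X, glucose G,
fructose R, sucrose S, urea U and ethanol Et, all in g/L, plus the culture
volume V (constant in batch; feed terms exist in the balances for
generality but are identically zero here). Assumptions: constant density
and rheology, homogeneous broth, no evaporation, oxygen never rate-limiting
(dissolved-oxygen dynamics are deliberately out of scope), no cell death.

Kinetics:

- **Sucrose hydrolysis** by extracellular invertase,
  r_S = α_S · S/(S+K_S) · X, feeding the glucose and fructose pools each
  with yield Y_AF/S (g monosaccharide per g sucrose; the stoichiometric
  value per monosaccharide is 180/342 ≈ 0.526).
- **Monod growth with ethanol inhibition** on each monosaccharide,
  μ_G = μ_max,G · G/(K_G+G) · K_i,Et/(K_i,Et+Et), analogously for
  fructose.
- **Catabolite repression**: the fructose parameters (μ_max,R, K_R) blend
  continuously to post-glucose values (μ_max,postG, K_R,postG) through an
  appearance gate in G. This is a pure function of the instantaneous
  glucose concentration — no hidden switching state.
- **Crabtree-effect ethanol formation** proportional to total growth,
  r_Et = Y_Et/X · μ_X · X, gated on fructose presence, and **respiratory
  ethanol consumption** μ_Et = μ_max,Et · Et/(K_Et+Et) ·
  K_inh,AF/(K_inh,AF + G + R): respiration stays off while fermentable
  monosaccharides (AF = G + R; sucrose acts only through its hydrolysis
  products) are present.
- **Sugar consumption** splits into growth-linked, maintenance and
  ethanol-linked demands, e.g.
  r_G = (Y_G/X·μ_G·X + m_G·X + μ_X·X·Y_Et/X / Y_Et/G) · gate(G).
- **Urea uptake** proportional to total growth, r_Ur = μ_X/Y_X/Ur · X.
- μ_X = μ_G + μ_R + μ_Et; an optional temperature factor is fixed at 1
  (isothermal operation).

**Depletion gates.** Each consumption/production rate that must vanish when
its driving species depletes is multiplied by a normalized leaky ReLU,

    gate(z) = max(γz, z) / sqrt(z² + ε),   z = c − threshold,

with defaults γ = 0.01, ε = 1e−6 (g/L)² and threshold = 0.001 g/L. The gate
runs continuously from ≈ 1 (species present) to a small negative leak of
magnitude ≤ γ·threshold/√ε below the threshold. γ and ε are modeling
constants, not fitted: γ = 0.01 is the conventional leaky slope and ε must
satisfy ε ≪ threshold² so the gate saturates away from the threshold. The
leak is a feature: below the threshold it reverses the rate's sign and
pushes the state back toward the threshold, so the continuous dynamics can
never cross zero.

Two printed-form ambiguities are exposed as flags rather than silently
resolved: `fructose_ethanol_yield_denominator` ("G" by default — the
fructose consumption's ethanol-linked term divides by Y_Et/G; "R" uses
Y_Et/R) and `ethanol_production_gate` ("R" by default — ethanol formation
gates on fructose alone; "G+R" gates on total monosaccharides). Note that
under the "G" default Y_Et/R appears nowhere in the equations and is
therefore structurally non-identifiable; the parameter-recovery experiment
uses the "R" variant for exactly that reason.

**Numerics.** The ODE system is integrated with the explicit 8th-order
Dormand–Prince method (scipy `DOP853`), atol = rtol = 1e−6. The gate kinks
degrade the step-error estimator near depletion: the measured true error at
the default tolerance is ~5e−3 g/L (far below the 5% measurement noise) and
convergence to a 1e−11-tolerance reference is monotone; applications needing
tighter output (the finite-difference sensitivity oracle) pass tighter
tolerances explicitly. Dense-output interpolation can overshoot the
depletion kink inside long steps and report spurious negative
concentrations; since the true solution cannot cross zero (see above),
negative output values are clamped to zero, and only a drop below −1 g/L —
genuine divergence — aborts. Inside the right-hand side, Monod and
inhibition terms see the non-negative part of each state so a transient
undershoot can never reach the pole at c = −K; consumption terms are
switched off exactly at c ≤ 0 while the restoring leak is kept. A
numba-compiled right-hand side is used when numba is importable, with a
pure-Python closure as behavioral twin (a unit test asserts exact
agreement).

## Synthetic data

The generator emulates the reference study design: two biological replicate
training batches with initial conditions drawn from Normal(mean, SD)
truncated at zero (sucrose 32.7 ± 3.9, glucose 27.3 ± 3.8, fructose
27.1 ± 4.1, biomass 0.5 ± 0.1, urea 2.6 ± 0.7 g/L; ethanol 0), one test
batch at fixed shifted values (39.6/27.5/25.8/1.2/2.3 g/L), working volume
0.3 L. Sampling times: every 1.5–3 h (uniform draw per interval) up to
30 h, then every 6 h to a 48 h horizon, first sample at inoculation.
Measurement noise is Gaussian with SD = max(5% of the value, 0.02 g/L),
truncated at zero; the initial row is the prepared medium and is left
noise-free. The 5% figure mirrors the replicate scatter of the study's
initial-condition table; the floor represents assay quantification limits.

What the generator does **not** emulate: analytical-method biases
(chromatography calibration drift), replicate-to-replicate invertase
variability, oxygen-transfer differences between runs, and the late-phase
growth-rate drop attributed to cell death. Passing tests on this data
therefore demonstrate correctness of the algorithms under the model's own
assumptions, not predictive validity for real cultures.

**Densification.** Sparse noisy series are fitted per variable with
polynomials of degree 2–6 on standardized time (scikit-learn
LinearRegression on polynomial features); the degree maximizing *adjusted*
R² wins (the adjustment plus a non-negativity clamp guard against
oscillatory overfit); a constant channel gets a degree-0 fit with R² := 1 by
convention. The fitted curves are evaluated on an even grid of
10 × (number of free parameters) points — e.g. 220 points for the full
22-parameter model — which is the dataset calibration and PRA consume.

## Calibration

Objective: J(θ) = Σ_datasets Σ_variables Σ_times
((x_model − x_exp)/N_v)², N_v = max_t x_exp per variable and dataset. A
pointwise normalization mode (dividing each residual by its own
observation, skipping zeros) exists behind a flag but is not the default:
it is singular at depletion and measured to condition the problem worse.
Solver failures return a 1e9 penalty so the population search continues.

Grey wolf optimization in its canonical form: positions move toward the
three best wolves with A = 2a·r₁ − a, C = 2r₂, a decaying linearly 2 → 0
over the planned epochs; population 30 (common default for a ~20-dimensional
problem), positions clipped to bounds, best-so-far retained. The optimizer
object is resumable so the bound-recalibration schedule runs as *one*
continuous 160-epoch search with bound checks every 20 epochs: a parameter
within 1e−6 (relative) of a box edge gets new bounds estimate × (1 ∓ 0.10)
intersected with [literature_lower/10, literature_upper×10]; the search
stops early once a round brings neither improvement nor a recalibration.
When no bound is ever touched this is identical to a single 160-epoch run.

**Known limitation (measured, documented honestly).** Canonical GWO's
exploration coefficient C ~ U(0, 2) never decays, so late-stage steps scale
with a·|x| and the optimizer carries a percent-level relative positional
noise floor at a 160-epoch budget. On this model's objective — whose
curvature spans four orders of magnitude across parameters, with strong
α_S–K_S and μ_max,Et–Y_c,Et/X correlation valleys — a 14-parameter noiseless
recovery experiment leaves several parameters 10–30% from the truth
(final J ≈ 0.02–0.1 where the optimum is exactly 0), reproducibly across
seeds and reproducible on the exact quadratic model built from the true
Fisher matrix. The corresponding acceptance test asserts the 10% recovery
target as specified and currently fails; gradient-based polishing, which
would close the gap, is out of scope by design. Users needing tight
estimates should fix the weakly determined constants first (see PRA) or
increase the epoch budget.

## Identifiability (pre–post-regression analysis)

Forward sensitivities S_vj(t) = ∂x_v(t)/∂θ_j are integrated alongside the
states, dS/dt = (∂f/∂x)S + ∂f/∂θ, S(0) = 0, with Jacobians derived
symbolically (sympy) from the smooth gated right-hand side — the gate's
max(γz, z) is rewritten as ((1+γ)z + (1−γ)|z|)/2 so derivatives stay
explicit — and integrated with LSODA at 1e−8 tolerances (one automatic
retry at 10× tighter on failure). A finite-difference oracle validates the
sensitivities; agreement is measured on the *scaled* matrix (entries
× θ_j/N_v, the same scaling the PRA uses) relative to its largest entry,
because relative error per entry is meaningless for parameters whose
sensitivity is numerically zero (K_R,postG at an estimate of 7e−9 changes
nothing the finite-difference step can resolve).

Metrics: covariance s²(SᵀS)⁻¹ with s² = J(θ̂)/(n_obs − n_free) (the
residual-variance estimator is a package choice), σ_θ = √diag, t = θ̂/σ_θ,
correlation matrix K, and per-variable average absolute scaled
sensitivities G_prom. A parameter whose sensitivity column is exactly zero
gets t := 0 (the data carry no information about it), and a singular SᵀS
falls back to the pseudo-inverse with affected parameters flagged.
Confidence intervals are θ̂ ± 1σ — the convention that reproduces the
reference calibration table (e.g. 29.935 at 19.68% → [24.04, 35.83]) — with
a `ci_multiplier` option for ±1.96σ.

Sequential fixing follows the screening order significance → identifiability
→ sensitivity: first every t ≤ 2 parameter is fixed at its estimate, then
correlated pairs |K| ≥ 0.95 are resolved one at a time by fixing the member
with the smaller t (ties by smaller mean G_prom), then parameters whose
largest G_prom falls below 1e−3 of the global maximum are *flagged but
retained* (they may be phenomenologically necessary). The procedure does
not loop back, so a parameter's t may legitimately fall below 2 after a
correlated partner is fixed. θ is constant throughout the screening, so the
scaled sensitivity matrix is computed once and sliced per stage.

Monte Carlo uncertainty: N = 100 simulations with each parameter drawn
independently from Normal(θ̂_j, 0.05·θ̂_j) (truncated at bounds and at
zero), envelope = pointwise min/max over successful runs; individual
failures are dropped with a warning and at least 80% must succeed. The
envelope deliberately excludes the nominal run, so nominal-containment is a
real (and tested) property, not a tautology.

## Residual hybrid

Residuals r(t_i) = y_exp(t_i) − y_pheno(t_i) per channel at the sample
times; channels are min–max scaled to [0, 1] with the scaler fitted on
training residuals only (a degenerate channel maps to zeros and inverts to
its constant; test-set values may leave [0, 1]). Look-back windows of
p = 5 chronologically ordered rows predict the next residual vector;
windows never straddle run boundaries.

The forecaster is a two-layer LSTM with the standard gate recurrence
(σ gates, configurable candidate/output nonlinearity, tanh default),
h₀ = c₀ = 0, and a linear output head, implemented in numpy with
backpropagation through time (gradients verified against finite differences
for every activation). Training: chronological 80/20 fit/validation split,
MSE loss, Adam/Nadam/RMSprop, inverted dropout on layer inputs and a
per-sequence-constant mask on the recurrent state, early stopping with
patience 15 and best-weight restoration, epoch cap 500 (the cap is a
package choice; only the patience is prescribed). Hyper-parameters — units
per layer ∈ {32, 64, 128, 256} (independent per layer), activation
(ReLU/ELU/tanh/sigmoid/LeakyReLU with α ∈ [0.01, 0.3]), dropout and
recurrent dropout ∈ [0, 0.5], learning rate log-uniform in [1e−5, 1e−2],
batch size ∈ {16, 32, 64, 128}, optimizer ∈ {Adam, RMSprop, Nadam} — are
tuned by a tree-structured Parzen estimator: after a random startup phase
the trials are split at the 25% loss quantile, each dimension is modeled
with a Gaussian KDE (continuous, log-space for the learning rate) or
add-one-smoothed counts (categorical), candidates are drawn from the good
density and the best l(x)/g(x) ratio is evaluated. Dimensions are treated
independently, as in the standard factorized formulation.

Hybrid output: y_ml = y_pheno + predicted residual (inverse-scaled), and
y_hybrid = λ_pheno·y_pheno + λ_ml·y_ml with defaults 0.3/0.7. Defining
y_ml additively makes λ = (1, 0) reduce exactly to the mechanistic model.
For the first p points no window exists and the hybrid falls back to the
mechanistic prediction — the visible jump at the window boundary is an
accepted artifact of the windowing, documented rather than smoothed. Two
roll-out modes: `teacher` rebuilds windows from measured residuals wherever
observations exist (one-step-ahead correction, the default), `recursive`
feeds the model's own predictions forward past the first window (open-loop
forecasting). Outputs are clamped at zero.

## Evaluation

Per-variable RMSE at the observation times; replicates of the same role
pool squared errors before the root. The "Total" of a six-variable row is
their arithmetic mean — the convention that reproduces all four published
row totals (1.955, 1.025, 5.598, 2.865 → printed 1.95, 1.03, 5.60, 2.87;
two of these sit exactly on the half-rounding boundary, so printed-total
comparisons allow half a printed unit) — with a pooled-RMSE alternative
behind a flag. Fold reduction = mechanistic total / hybrid total, one
decimal.

## Problem sizes and budgets

Defaults follow the study conditions (GWO population 30, 160 epochs, 100
TPE trials, N = 100 Monte Carlo iterations, 10 densified observations per
free parameter). The test suite and the acceptance script scale the
expensive stages down where the check does not need the full size: the
hybrid-benefit study uses 10 TPE trials and a 300-epoch training cap, the
pipeline smoke test uses 2 trials and 8 Monte Carlo iterations, and
module-level optimizer tests use small populations. These sizes are stated
in the respective configurations and do not change any default.

## Known limitations

- No oxygen, pH or temperature dynamics; no cell-death term — the
  mechanistic model overestimates late-phase biomass by construction.
- The GWO precision floor discussed under Calibration.
- Teacher-forced hybrid evaluation requires observations at prediction
  times; purely predictive use must accept the recursive roll-out's
  error accumulation.
- The synthetic generator's noise model is uncorrelated across times and
  variables, which real assay errors are not.
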