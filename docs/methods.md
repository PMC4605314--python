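# Methods

## Model

A ligand with two linked intercalating moieties binds each DNA site in two
sequential steps: a reversible bimolecular first intercalation
(k₁ in nM⁻¹s⁻¹, k₋₁ in s⁻¹) and a reversible monomolecular conversion to
the bis-intercalated state (k₂, k₋₂ in s⁻¹). Sites are treated as
independent and identical: no neighbour exclusion, no cooperativity, no
sequence heterogeneity. Free ligand concentration is constant (excess
ligand in a flow cell). Under these assumptions the per-site state
fractions (P₀, P₁, P₂) obey a linear ODE whose relaxation from ligand-free
DNA is exactly bi-exponential; the two eigenrates are

    λ± = (S ± √(S² − 4P))/2,  S = k₁C + k₋₁ + k₂ + k₋₂,
                              P = k₁C·(k₂ + k₋₂) + k₋₁·k₋₂.

The pre-equilibrium closed forms k_f = k₁C + k₋₁ and
k_s = k₂·k₁C/(k₁C + k₋₁) + k₋₂ are the large-ratio
((k₁C + k₋₁)/(k₂ + k₋₂) ≫ 1) limit of these eigenvalues; the relative
error is roughly the inverse of that ratio.

**Extension readout.** A mono-intercalated ligand contributes half of the
per-site saturated elongation, a bis-intercalated ligand the full amount
(`trace_model.MONO_EXTENSION_FRACTION = 0.5`, a module constant so
sensitivity analyses can vary it). This equal-step assumption is also what
produces the f/2 factor in the equilibrium amplitude partition
dx_f = dx_eq·f/2, dx_s = dx_eq·(1 − f/2), with
f = (C/K_d1)/(C/K_d1 + 1) the mono-state probability. As printed sources
of this amplitude model differ typographically, the implementation uses
the algebraically consistent form in which dx_f + dx_s = dx_eq exactly and
dx_f/dx_s = (C/K_d1)/(C/K_d1 + 2).

**Force dependence.** Every elementary rate follows the Bell form
k(F) = k⁰·exp(F·x†/k_BT) with a signed transition distance (positive:
the complex is longer at the transition state than at the departing
state). Equilibrium constants follow K(F) = K⁰·exp(−F·x⁰/k_BT) with
x⁰ = x₊† − x₋† per step. Thermal energy defaults to k_BT = 4.05 pN·nm
(20 °C), configurable everywhere and never baked into a formula.

**Elasticity.** Bare and saturated DNA are described by the high-force
extensible worm-like-chain interpolation
x(F) = x_max(1 − 1/(2√(FA/k_BT)) + F/S). No exact WLC solution is
substituted, because the fits this package mirrors used the interpolated
form. Occupancy is the linear interpolation of a measured extension
between the bare and saturated curves at the same force. Extensions are
stored per base pair; per-molecule lengths require an explicit bp count.

## Estimation pipeline

1. **Trace fit.** Nonlinear least squares of the bi-exponential, with
   initial values from exponential peeling (single-exponential fit of the
   tail for the slow mode, then the early residual for the fast mode).
   Modes are ordered k_f ≥ k_s after the fit. A fit is flagged when the
   modes are closer than 3-fold ("modes_unresolved"), when the trace is
   shorter than 3/k_s ("slow_mode_unresolved"), or when it did not
   converge; flags are never silent failures. Traces whose extension
   decreases overall are rejected as a sign-convention error.
2. **Decomposition.** Per force, the concentration dependence of
   (k_f, k_s) is inverted for the four elementary rates.
   `decompose_rates` offers the sequential route (linear fit of k_f vs C,
   then a linear fit of k_s against g(C) = k₁C/(k₁C + k₋₁) with the
   first-step rates fixed), a bounded joint fit of the two closed forms,
   and `method="exact"`, which fits the exact eigenvalue expressions.
   The pipeline uses the exact method: under the default study grid the
   pre-equilibrium ratio is only 3–8, and fitting the approximate closed
   forms to exact-eigenvalue data leaves a 10–18% systematic bias that the
   exact model removes (the closed forms remain available and are what
   the ratio-based warnings refer to). Inverse-variance weighting is used
   when trace-fit uncertainties are available, unweighted otherwise.
   Negative fitted rates are clipped to zero and flagged. A caveat found
   in simulation: at zero force, where k₁C ≪ k₋₁, the sequential route
   propagates a noisy (occasionally negative) k₁ into the slow-rate
   design and can lose k₂ entirely; the bounded joint fit is the robust
   variant there and is what the noise-recovery tests exercise.
3. **Bell fits.** Per rate, linear regression of ln k on F (the straight
   line of a semi-log rate-force plot): slope·k_BT = x†, intercept = ln k⁰,
   uncertainties from the regression covariance. Bootstrap is deliberately
   not the default.
4. **Global refinement.** The staged Bell estimates seed a weighted joint
   fit of all eight parameters (four k⁰, four x†) to every observed
   (k_f, k_s) across the force × concentration grid, using the exact
   eigenvalue model. The staged per-rate fits see one rate at three
   forces and are noise-limited by that short baseline (per-replicate x†
   scatter for the weakest rate, k₋₂, is ~0.1 nm); pooling all 24
   observations reduces the median transition-distance error to a few
   hundredths of a nm. Staged estimates remain available
   (`PipelineResult.bell_staged`).
5. **Equilibrium route.** Independently of the rates, per-force binding
   constants come from the amplitude data: K_d from the occupancy
   isotherm Θ(C) = (C/K_d)/(C/K_d + 1), K_d1 from the amplitude ratio,
   K₂ = K_d1/K_d; log-linear force-law fits then give zero-force values
   and elongations. A consistency report compares the two routes side by
   side with ratios and overlap-within-uncertainty flags.

Each trace is assumed to start from ligand-free DNA (a fresh molecule per
relaxation); there is no carry-over state. Model selection is not
performed: the two-exponential model is fixed by the scheme.

## Synthetic data

The generator emulates the constant-force protocol: the mean path is the
exact solution of the mean-field ODE (eigen-decomposition, not numerical
integration), scaled by dx_sat(F) = x_sat(F) − x_ds(F) from the two WLC
curves, with i.i.d. Gaussian noise per sample and optional linear drift.
The `gillespie` backend draws an exact stochastic path of the aggregate
site-state counts — statistically identical to simulating n independent
sites — with the same ½/1 extension readout. Identical config and seed
give bit-identical traces.

Default conditions are the study grid: F ∈ {20, 30, 50} pN,
C ∈ {1, 3, 5, 7} nM, 600 s at 1 Hz. The noise level 0.002 nm/bp is an
order-of-magnitude instrument figure chosen so that the two relaxation
modes are resolvable, and drift defaults to zero; both are configurable,
as no measured values are available. The saturated-curve fixture uses
five forces 5/10/20/35/50 pN (a documented choice; only the count is
known). What the generator does **not** emulate: neighbour exclusion and
binding cooperativity, sequence-dependent heterogeneity, force-feedback
controller dynamics, bead/trap Brownian noise (the added noise is white,
instrument noise is not), and ligand depletion. Passing recovery tests
therefore demonstrate estimator correctness under the stated model, not
robustness to every artefact of real tweezers data.

## Free-energy landscape

Five states along the elongation coordinate (non-intercalated at 0, TS1
at x₊₁†, mono at x₁ = x₊₁† − x₋₁†, TS2 at x₁ + x₊₂†, bis at x₁ + x₂).
Energies in k_BT with the bis state as reference: the non minimum at
ln(C/K_d) (zero when C = K_d), barriers from rates via
ΔG† = ln(k₀_attempt/k) with attempt rate 1 s⁻¹ by default — barrier
absolute values are convention-dependent and the attempt rate is always
reported alongside them. Because the published constants are internally
inconsistent at the ~0.3 k_BT level (the independently fitted K_d1/K_d
ratio is 2.33 while the directly fitted K₂ is 1.8), the mono-state energy
supports both conventions (`mono_convention="kd_ratio"` or `"k2"`);
neither is silently preferred, and the exact rate↔barrier duality holds
only when the constants are derived from the rates themselves. With a
bimolecular first step the barrier out of the non-intercalated state
varies as −ln C; the absolute TS energies and all other minima are
concentration-independent.

## Numerical choices

- All nonlinear fits are `scipy.optimize` least squares with closed-form
  linear-regression stages where the model permits; the Bell fit is
  exactly the log-space least-squares solution.
- Fits are bounded to non-negative amplitudes and rates; rate ordering is
  enforced by post-fit swapping, not by constraint.
- The pre-equilibrium warning threshold is ratio = 10, configurable in
  spirit ("much greater" is not a number); warnings are attached to
  results, not only printed.
- `RelaxationParams` tolerates dx_f + dx_s exceeding dx_eq by a noise
  allowance (10% relative + 0.001 nm/bp absolute), since fitted noisy
  traces legitimately start slightly below zero excess extension.
- Concentration is nM throughout; conversions are explicit, never
  implicit.
- Text outputs carry 12 significant digits so write/read round trips are
  lossless to formatting precision.

## Problem sizes

The recovery studies use 20 replicate synthetic experiments of 12 traces
each (the full grid) for the noisy case and a single noiseless
experiment for the exact-inversion checks; the law-of-large-numbers
check of the stochastic backend uses 2×10⁴ sites over 120 s. These sizes
give median estimates with Monte-Carlo error well inside the bands they
are checked against.

## Known limitations

- The equilibrium plateau of a simulated trace equals the stationary
  mean-field occupancy, which the single-K_d isotherm only approximates
  (it folds the mono population into "bound"); the difference is a few
  percent at mid-saturation and is visible in equilibrium-route fits as
  a small systematic offset in K_d.
- Zero-force parameters are extrapolations over a 20–50 pN baseline;
  the weakest rate (k₋₂) dominates the error budget.
- The published parameter values used as generator truth are themselves
  measurements; they are not reproducible from this package without the
  raw instrument data and enter only as fixtures.
- Schemes with more than two sequential steps, cooperative lattices
  (McGhee–von Hippel), and force-tilted landscapes at F > 0 are out of
  scope.
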