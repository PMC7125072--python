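# Methods

## Scope and model family

`acetokin` models a batch monoculture of a hydrogen-consuming reductive
acetogen with three coupled ODEs for hydrogen `H` (mM), acetate `P` (mM)
and cell dry weight `X` (g L⁻¹).  Every structure shares the
Wood–Ljungdahl coupling dP/dt = −(1/4)·dH/dt and the biomass balance
dX/dt = −Y·dH/dt − k_d·X.  Assumptions inherited from the experimental
setting: all co-substrates (including CO₂) are non-limiting; gas–liquid
mass transfer is not modelled (batch serum-bottle data give no dissolved-gas
measurements to constrain it, and threshold estimates are expected to be
insensitive to it under batch conditions); maintenance consumption of
substrate is negligible; death is first-order with constant k_d.

Five base hydrogen-uptake laws are provided: Monod, first-order
(linearised Monod, η ≃ μ_max/K_H), a hard threshold T1
(uptake ∝ max(H−H_t, 0), derivative continuous but not differentiable at
H_t), a sigmoid-gated law T2 (gate F = 1/(1+exp(A(T−H)))), and reversible
Michaelis–Menten T3, whose net flux vanishes on the metabolite ray
P/H = μ_max,H·K_R/(μ_max,R·K_H); for the published best-fit parameters this
is P ≈ 3.43·H, an attracting state when biomass is present.  Non-linearised
threshold variants (full Monod saturation plus threshold) exist as RHS
functions but are excluded from default fitting: μ_max and K_H cannot be
separated using a single batch curve, so only their ratio is estimable.
Fitting them requires an explicit `allow_nonidentifiable=True`.

The original sigmoid-threshold formulation defines two sigmoids (one inside
the saturation term, one multiplicative gate); published typography labels
both `f`.  Only the multiplicative gate `F` enters the linearised T2
equation used here, so only `F` is implemented in T2; the inner sigmoid
appears solely in the non-linearised variant.

A two-substrate extension adds a yeast-extract pool `E` consumed by
first-order kinetics (η_E, yield Y_E) contributing b_EP mol acetate per mol
extract; the hydrogen equation is unchanged.  The extension leaves T1-type
thresholds untouched and is normally combined with T2 or T3.

## Numerical integration

`simulate` uses adaptive LSODA (stiff-capable, via `scipy`) with
rtol = 1e-8, atol = 1e-10 by default; the T1 kink and steep T2 gates can
make the system locally stiff.  Output is evaluated at the requested
(irregular) observation times; the first output row is pinned to the exact
initial condition; negative overshoot is clipped to zero after evaluation
and the largest clip recorded on the trajectory.

The calibration inner loop runs at rtol = 1e-6, atol = 1e-8 (a fit
evaluates the model up to hundreds of thousands of times; the looser
tolerance is still far below the data noise).  For the five base
structures that loop — a Dormand–Prince RK45 integrator, the objective,
and the full Metropolis chain — is compiled with numba
(`acetokin._fastpath`), which is what makes 10⁴–10⁵-iteration chains
practical on one CPU; a step-budget exhaustion (pathologically stiff
parameter proposals) returns an infinite objective and the proposal is
rejected.  Extended (yeast-extract) fits, and environments without numba,
use an interpreted implementation of the identical algorithm via
`scipy.integrate.odeint`.  The conservation identity
P(t) − P(0) = (H(0) − H(t))/4 holds along exact solutions of every
non-extended structure and is used as an integrator error probe
(`conservation_residual`, typically < 1e-9 mM at default tolerances).

## Calibration

The objective is the sum of normalised squared differences between model
and observations.  Each residual is divided by the observation's replicate
standard deviation when one is provided; otherwise by the mean of that
variable over the time course, which makes mM and g L⁻¹ residuals
commensurable.  Zero or missing SDs fall back to the mean scale; missing
observations contribute nothing; a failed integration returns +∞ (the
proposal is rejected rather than aborting the chain).

Sampling: random-walk Metropolis on log-parameters (all parameters are
positive and span orders of magnitude), with Haario-style adaptive
covariance — proposal covariance (2.38²/d)·Ĉ from the running sample
covariance, refreshed during burn-in (default 20%) and frozen afterwards.
Priors are uniform on log-parameters within ±3 decades of the initial
guess by default; explicit bounds per parameter override this.  The
likelihood treats the normalised residuals as Gaussian with one unknown
global scale σ marginalised under a Jeffreys prior, giving
log p ∝ −(N/2)·log(objective/N); this makes inference invariant to the
overall magnitude of the normalisation constants, so posterior width is
set by the actual residual scatter rather than by taking variable means or
small-sample replicate SDs literally as noise SDs.  A floor of 1e-12 on
the mean square keeps the target proper on noise-free data.

Point estimate: the minimum-objective sample by default (the posterior
median is always reported alongside; on ridge-shaped posteriors the two
differ, and the minimum-objective point may sit outside the central
interval).  "95% confidence intervals" are central posterior credible
intervals (2.5–97.5 percentiles) over chains pooled after burn-in.
Convergence is the split-R̂ per parameter (threshold 1.05 by default;
values below 1 are clamped to 1).  Posterior correlations are Pearson
coefficients of the **log**-parameters: on multiplicative parameters
spanning decades, natural-scale correlation is dominated by the largest
samples and understates ridge non-identifiability.  Initial states are
taken from the first observation of each variable (configurable), not
fitted.  Extended-model fits can pin base-model parameters (`fixed_params`)
and sample only η_E, Y_E, b_EP, mirroring the situation where the base
model was calibrated on a minimal medium first.

Defaults: 10⁶ iterations (the full-length production setting), 4 chains
(extra chains start jittered by 0.5 in log-space — on ridge-shaped
posteriors dispersed starts are what make pooled intervals honest about
ridge extent), burn-in 0.2, R̂ threshold 1.05, seed-deterministic
throughout.  Tests and recovery studies use 2×10⁴–2×10⁵ total evaluations
(e.g. 5×10⁴ iterations × 4 chains), which is what these 3–6-parameter
batch-kinetics posteriors — especially the μ_max–K_H ridge — need to mix;
shorter chains (≲10³) give prior-dominated, under-dispersed intervals.

## Synthetic data

The generator emulates the structure of the calibration and validation
experiments (whose raw data exist only as published figures): a handful of
sampling times over tens of hours, hydrogen declining from a few hundred
mM, stoichiometric acetate rise, sigmoid-then-declining biomass, and
multiplicative replicate noise — observation = truth·(1+ε),
ε ~ N(0, cv²), truncated at zero, with per-point replicate means and SDs
(the figures' error bars are SDs of three determinations, and error bars
scale roughly with signal).  Defaults: `bernalier_like_scenario` uses the
published T1 best fit (η = 0.0008 h⁻¹ mM⁻¹, Y = 0.0014 g L⁻¹ mM⁻¹,
k_d = 0.014 h⁻¹, H_t = 86.2 mM) with H(0) = 400 mM, P(0) = 0,
X(0) = 0.01 g L⁻¹, 8 equispaced samples over 0–80 h, cv = 0.1, 3
replicates; `dsmz_like_scenario` uses a T2 or T3 base plus the
illustrative yeast-extract sets (T2: η_E = 0.0018, Y_E = 0.02,
b_EP = 0.43, k_d = 0.112; T3: η_E = 0.002, Y_E = 0.013, b_EP = 0.5,
k_d = 0.08) with E(0) = 100 mM.  Initial states, sampling grids, E(0) and
noise levels are invented defaults — stand-ins, never reproductions of the
original experiments — and each scenario says so in its description.  For
Monod there is no reliable published estimate (the ridge), so a synthetic
reference set (μ_max = 0.24 h⁻¹, K_H = 300 mM, ratio equal to the
published η) is used for data generation and recovery tests.

What passing tests on these data do **not** show: robustness to
gas-phase sampling error, headspace depletion, medium batch effects, or
non-multiplicative noise; and recovery tests say nothing about structural
misspecification (fitting one structure to data generated by another).

## Desk analyses

Unit conversions use CDW = 0.37·OD and molar masses 2.016 (H₂) and 59.044
(acetate) g mol⁻¹.  The headspace hydrogen inventory is ideal-gas
(R = 8.314 J mol⁻¹ K⁻¹); temperature defaults to 310.15 K (37 °C culture),
and the reference 0.4 L, 200 kPa, 66% H₂ headspace rounds to 0.02 mol at
either 298 or 310 K.  The acetate ceiling divides that inventory by 4
(stoichiometry) and the medium volume; observed or predicted terminal
acetate above the ceiling indicates fermentation of other carbon sources
(in practice: yeast-extract-rich media).  The Ribes-style default sigmoid
tuning A = 100/H_t, T = 1.1·H_t is provided as a convenience; fitted
values for a given organism can differ from it by an order of magnitude,
so it is a starting point, not a calibration.  (The literature's printed
percentage comparison of these defaults to fitted T2 values does not follow
from its own printed numbers — 100/86.2 ÷ 0.015 ≈ 7700%, not 773% — so no
such comparison is computed here.)  The literature uptake threshold of
70 ± 12.7 mM (measured as 1100 ± 200 ppm) is stored as a citation constant
only — the ppm→mM conversion basis is not stated in the sources, so the
package does not recompute it.

## Design choices where the design was open

- **Likelihood scale.** The calibration objective is fixed (normalised
  squared differences), but its mapping to a posterior is not; the
  marginalised-σ form above was chosen over exp(−obj/2) because the
  normalisation constants are not noise SDs, and treating them as such
  makes posterior width an artefact of the normalisation choice.
- **Point estimator.** Minimum-objective sample by default because the
  headline published estimates are best-fit values; the posterior median
  is reported alongside and selectable.
- **Correlations on the log scale**, for the reason above.
- **T1 below threshold**: biomass continues to decay at k_d indefinitely
  (the equations as written imply it); no dormancy term is added.
- **Extension validity**: the two-substrate extension is accepted with any
  base structure (it leaves every hydrogen equation unchanged), though the
  motivating use pairs it with T2/T3.

## Known limitations

No gas–liquid transfer, pH or CO₂ dynamics; death-rate constancy over the
whole culture; thresholds are phenomenological (no thermodynamic
derivation); the T3 structure is inappropriate for high-acetate,
low-hydrogen environments (it predicts acetate consumption and biomass
loss there with the same yield, which is unvalidated); MCMC settings below
~10³ iterations produce prior-dominated intervals; and the synthetic-data
scenarios are structural stand-ins for figure-derived experiments, so
quantitative agreement with the original raw data cannot be claimed.
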