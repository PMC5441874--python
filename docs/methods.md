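# Methods

This note documents the models implemented in `odornav`, the parameter
choices, the numerical details, and what the synthetic-data tests do and do
not establish about real recordings.

## The odor field

The evaporating 2-nonanone gradient on a closed 9-cm plate is modeled
phenomenologically, not as a diffusion PDE.  Each of the two odor spots
contributes an exponential saturation toward a position-dependent asymptote:

    C(x, y, t) = Σᵢ a(rᵢ) (1 − exp(−b(rᵢ) t)),
    a(r) = a₀ exp(−a₁ r − a₂ r²),   b(r) = b₀ exp(−b₁ r − b₂ r²),

with `rᵢ` the distance (cm) to source *i*, `a` in μM and `b` per minute.
The defaults are the published fitted constants (a₀ = 20.68 μM,
a₁ = 0.7355 cm⁻¹, a₂ = −0.05408 cm⁻², b₀ = 0.8384 min⁻¹, b₁ = 0.7835 cm⁻¹,
b₂ = −0.05761 cm⁻²).  The additivity of the two sources is a low-
concentration approximation valid on the measurement half-plate (x > 0).

**Units.** Model time is minutes (`b₀` is per minute); trajectory and
stimulus series are in seconds, and every derivative output is μM/s.
Conversion happens at the module boundary (`trajectory_concentration`).

**Source positions.** The spot coordinates are not part of the published
parameter set (the assay figure is schematic).  The default places the two
point sources at (−3.0, ±0.75) cm, on the left half and symmetric about
y = 0; all gradient computations take the sources from the
`GradientParams` config, so a different plate layout is one constructor
argument away.

**Fitting.** `fit_gradient` is an unweighted Levenberg–Marquardt
least-squares fit of all six constants to per-measurement replicate
medians (replicates are not weighted by their quartile spread).
Degenerate all-zero data raises; non-convergence is reported in the result
rather than silently returned.

**Identifiability.** At the default synthetic sampling grid
(x ∈ {11…66} mm × y ∈ {0, 15, 30} mm, t ∈ {1, 3, 6, 9, 12} min) the field
is only partially saturated by 12 min, so the amplitude trio (a₀, a₁, a₂)
trades off against the rate trio (b₀, b₁, b₂) under measurement noise:
with 5% multiplicative replicate noise the fitted constants can deviate by
more than 10% on unlucky seeds while the *predicted field* stays within a
few percent.  Noiseless refits recover all six constants to machine
precision regardless of the starting point perturbation.  Parameter-level
conclusions from noisy GC data should therefore be drawn from the
predicted concentrations, not from individual constants.

**Differentiation.** `central_difference` uses second-order central
differences with first-order one-sided endpoints (endpoint handling is a
package choice; only interior values feed the analyses).  The analytic
∂C/∂t is also available and is used as the convergence oracle in tests.

**GC calibration.** The semiconductor sensor responds in two regimes; the
calibration is two straight lines in log-log space split at a breakpoint
concentration supplied by the caller (no published numeric breakpoint
exists), and inversion exponentiates the inverse linear map of the
matching segment.

## Behavioral segmentation

A second of a 1-Hz track is a **turn** when the migratory vector rotates
by more than 90° from the previous second.  The published rule extends the
turn while the animal stays slow "in the following frames"; the package
makes this concrete as: subsequent seconds with speed < 0.1 mm/s remain
part of the same turn until the speed recovers.  Head-tracked 10-Hz data
are first smoothed with a ±10-frame (±1 s) centered moving average and
decimated to 1 Hz; 1-Hz centroid data are used as-is.

Turn-free migration durations are histogrammed in 1-s bins and fitted by
`N(t) = A₁e^{−λ₁t} + A₂e^{−λ₂t}` (unweighted least squares in linear
space, matching a least-squares fit of histogram counts; log-space fitting
is available as an option).  The pirouette/run threshold is the component
crossing `t_crit = ln(A₁/A₂)/(λ₁ − λ₂)`; the reference value from the
original avoidance data set is 13.1 s and is kept as a documented default.
A second exponential component must reduce the residual sum of squares to
below half of the single-exponential fit, otherwise the fit is flagged
degenerate — this rejects single-population interval data instead of
hallucinating a second time scale.

Migrations longer than `t_crit` are runs; shorter migrations and the turns
themselves are pirouette.  Boundary migrations at the window edges are
classified by the same duration rule.

**Bearings.** The bearing B of a migration step is the signed angle to the
local **down-gradient** direction −∇C evaluated under the field model at
the animal's position (not the straight line to one source, which is
ill-defined with two sources); B = 0° is directly away from the odor,
±180° directly toward it.  For salt-taxis-style data the `toward_zero`
convention flips the reference.  Exact ±90° bearings count as "within
±90°".

**Onset detection.** Turning-rate time courses are per-animal turns/s in
10-s bins with across-animal mean ± SEM.  Deviations from baseline use the
100(1−α)% prediction interval for one future observation,
x̄ ± t_{α/2,n−1}·s·√(1+1/n), with the baseline sample taken from the
odor-zero (or plateau) phase; `first_crossing` returns the earliest bin
beyond the bound.  Default α = 0.01.

**QC.** Records are excluded for: interrupted tracking, weak basal
fluorescence (threshold from config), an abnormal pre-stimulus transient,
or basal speed below 0.02 mm/s (normal animals move ≈0.15 mm/s).  Every
exclusion is logged with its reason.

## Neural-response models

All models are driven by the 1-Hz stimulus series and fitted to the
measured ΔF/F₀ (or estimated calcium) by least squares:

| family | equation | free parameters (M) |
|---|---|---|
| differential | X = k·dC/dt | k (1) |
| leaky | dX/dt = kI − X/τ, I = ±dC/dt | k, τ (2) |
| leaky_delayed | as leaky with I = −(C(t)−C(t−Δt))/Δt | k, τ, Δt (3) |
| leaky_generalized | dX/dt = kI − (X−X_base)/τ | k, τ, f_min, X_base (4) |

Integrators advance by forward Euler with a 1-s step from X(0) = 0
(generalized: X(0) = X_base); at 1 s the Euler error is below 2% of the
plateau for τ ≥ 10 s (verified against the constant-input closed form
kIτ(1−e^{−t/τ})).  τ is profiled on a log grid and refined by bounded
scalar minimization after the linear gain k is solved in closed form; the
upper bound 10⁴ s encodes the pure-integrator limit and is reported as
"τ → ∞".  Δt is a joint integer-second grid search (default 1–120 s).
The fit window convention is stimulus onset −60 s through the end of the
post phase (N = 135/180/270 samples for the 45/90/180-s ramps); traces at
higher rates are bin-averaged to 1 Hz first.

**Preprocessing.** Background subtraction, ±1-frame moving average,
F₀ = mean fluorescence over the 60 s before stimulus onset,
ΔF/F₀ = (F−F₀)/F₀.  Ratiometric mode (ΔR from two channels) is available
for experiments where mutations may shift the baseline; ΔF/F₀ is the
default.

**Hill inversion.** Calcium is estimated from ΔF/F₀ by inverting the
indicator saturation curve,
[Ca²⁺] = K_d·((1+ΔF/F₀−f_min)/(f_max−1−ΔF/F₀))^{1/h}, with K_d = 405 nM
and the GCaMP3 dynamic-range constraint f_max = 12·f_min enforced during
generalized fits.  The Hill coefficient h is not part of the published
parameter set (it comes from the indicator characterization); the package
default h = 2.1 reproduces the published basal calcium (66.1 nM follows
from f_min = 0.81, f_max = 9.7 at h ≈ 2.11, and h = 2.1 gives 65.6 nM).
Estimates of X_base are sensitive to h, which is exposed in `HillParams`.
The calcium-scale gain is stored in nM per (μM/s·s); the corresponding
μM-scale figure is 1000× smaller.

**Model comparison.** BIC = N·ln(RSS/N) + M·ln N, lower is better; it
depends only on (RSS, N, M), so any relabeling of the time axis that keeps
the same fitted samples leaves the ranking unchanged.  RSS = 0 returns a
−∞ sentinel with a warning.  The two-component composition (a measured
fast transient plus a simulated slow leaky component, summed pointwise)
uses the published slow-component parameters (k = 2.96 μM⁻¹, τ = 10.4 s)
as defaults.

## The agent-based simulator

Time is discretized at Δt = 1 s; each run lasts 720 s.  All locomotor
constants are the published ones: speed 0.14 mm/s, per-second heading
noise Gaussian(−0.065°, 5.14°), a 0.1-mm 0.5-Hz sinusoidal head swing, 3-s
turns, 0.2 s⁻¹ turn rate in the high-turning state, and the low-state
pirouette-initiation rate 0.0326/(0.200 + e^{−231·dC/dt}) + 0.0260 s⁻¹.
The odor is sensed at the anterior end; because the 0.5-Hz swing is
sampled at 1 Hz, the discretized head position alternates sides of the
track each second (a quarter-period phase offset avoids the degenerate
sin(πt) = 0 sampling), which is exactly the sensor noise that
distinguishes the two decision rules.

The **integration** rule accumulates X by one Euler step per second with
the rectified drive max(−dC/dt, 0) — evidence accumulates only while the
sensed concentration falls — and transitions high→low when X > θ = 0.18.
X resets on every turn, and during the 3-s turns (centroid stationary) the
integrator receives no input but keeps decaying.  The integrator
parameters default to the wild-type AWB down-90 ΔF/F₀ fit (k = 3.6 μM⁻¹,
τ = 28.1 s) so that θ is commensurate with the ΔF/F₀-scale threshold
associated with turn suppression; both are in `SimConfig`.  The
**differentiation** rule transitions on any single second with dC/dt < 0.

Post-turn directions are drawn uniformly on (−180°, 180°] by default; an
empirical pool of measured deviations can be supplied instead.  The plate
boundary applies specular reflection at the 4.5-cm wall (the original
boundary handling is unpublished; in practice fewer than ~2% of steps
touch the wall).  Runs start at the plate center with a random heading in
the high-turning state at t = 0, and run-initiation bearings are analyzed
over 121–720 s to mirror the real-data window.  Each run consumes an
independent stream spawned from the ensemble seed, so results are
bit-for-bit reproducible.

Under the default field the integration ensemble initiates ~80% of runs
within ±90° of straight-away versus ~65% for differentiation, and the two
bearing distributions separate at p ≪ 0.001 (Mardia–Watson–Wheeler) with
100 runs per rule.

## Circular statistics

The two-sample Mardia–Watson–Wheeler uniform-scores test ranks the pooled
angles (midranks on ties), maps ranks to scores β = 2π·rank/N, and forms
W = 2·Σ_g R_g²/n_g from the per-sample resultants.  For
min(n₁, n₂) ≥ 10, p comes from the asymptotic χ²(2) distribution; below
that, from a seeded label permutation (10⁴ resamples), since the χ²
approximation is unreliable in small samples.  Watson's U² uses the
rotation-invariant Cramér–von Mises form with the finite-sample
modification (U² − 0.1/n + 0.1/n²)(1 + 0.8/n) and the alternating
exponential series for p; a Monte-Carlo fallback is available.  Both
statistics are invariant under common rotation; U² also under reflection.
Null calibration of both tests is verified in the suite against
permutation/Monte-Carlo oracles.

## Synthetic data

The generators emulate the statistical structure the analyses assume:
multiplicative replicate noise on GC samples (medians/quartiles reported),
piecewise-linear 0↔1 μM stimulus ramps over 45/90/180 s with a 60-s
lead-in and 30-s post phase, model-generated fluorescence traces with
additive Gaussian noise on the ΔF/F₀ scale (default SD 0.05; the original
study shows SEM envelopes but no noise model), two-exponential interval
samples with mixing weights proportional to the count densities A_i/λ_i,
and simulator tracks re-emitted in the trajectory table format.  Every
generator is a pure function of (parameters, seed).

What passing on synthetic data shows: the estimators are consistent and
correctly implemented (self-consistency recoveries are exact in the
noiseless limit), the decision-rule contrast is a property of the model
dynamics, and the statistical machinery is calibrated.  What it does not
show: robustness to real-data pathologies — tracking dropouts, collisions
between animals, indicator bleaching and motion artifacts, non-Gaussian
noise, or departures of the real plate gradient from the two-source model.
The published real-animal percentages (78.4% of run initiations within
±90°, 83.5% of run steps, 5.2 turns per pirouette, the fitted
t_crit = 13.1 s) depend on the original recordings and are carried only as
documented reference values.

## Problem sizes

The test suite and the acceptance script use desk-scale problem sizes
chosen to make the statistical assertions sharp: 90 gradient sample points
for refits, 10⁴ intervals for the geometric-interval fraction, 10⁵
Monte-Carlo draws for prediction-interval coverage, 10⁴ permutation
resamples for small-sample p-values, and 100 simulated assays per decision
rule (the published ensemble size).
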