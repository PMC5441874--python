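# odornav

Quantitative analysis and simulation of *C. elegans* 2-nonanone avoidance:
how a worm decides, from a noisy odor signal, when to commit to a long
escape run.

Worms avoid the repulsive odor 2-nonanone by alternating two behavioral
states: **pirouettes** (bursts of sharp turns with short migrations) and
**runs** (long straight migrations, mostly down-gradient).  The package
implements the full desk-side pipeline of such a study for people working on
chemosensory behavior and neural coding of evidence accumulation:

* **`odornav.odor_field`** — the two-source exponential-saturation model of
  the evaporating odor gradient on a 9-cm plate,
  `C(x,y,t) = Σᵢ a(rᵢ)(1 − e^{−b(rᵢ)t})` with
  `a(r) = a₀e^{−a₁r−a₂r²}`, `b(r) = b₀e^{−b₁r−b₂r²}`; Levenberg–Marquardt
  fitting, the experienced concentration `C_worm(t)` and its derivative, and
  the two-segment log-log GC calibration.
* **`odornav.behavior`** — per-second turn detection (>90° heading change
  with a low-speed extension), the two-exponential turn-interval fit whose
  component crossing defines `t_crit`, pirouette/run segmentation, bearings
  relative to the local down-gradient direction, turning-rate time courses,
  Student-t prediction intervals for onset detection, and QC filters.
* **`odornav.neural_models`** — the sensory-response model family:
  time-differential `X = k·dC/dt` (ASH-like), leaky integrator
  `dX/dt = kI − X/τ` (AWB-like), the delayed-input variant
  `I = −(C(t)−C(t−Δt))/Δt`, and the generalized calcium-scale form with
  basal level `X_base`; ΔF/F₀ preprocessing, GCaMP Hill-equation inversion
  `[Ca²⁺] = K_d·((1+ΔF/F₀−f_min)/(f_max−1−ΔF/F₀))^{1/h}`, least-squares
  fitting, and BIC model comparison (`BIC = N·ln(RSS/N) + M·ln N`).
* **`odornav.simulator`** — an agent-based model of the plate assay that
  contrasts two decision rules for the high→low turning transition:
  **integration** (leaky integration of −dC/dt crossing θ = 0.18) versus
  **differentiation** (any single second with dC/dt < 0).
* **`odornav.circstats`** — Mardia–Watson–Wheeler two-sample and Watson U²
  one-sample circular tests for bearing distributions.
* **`odornav.synthetic`** — seeded generators for every input format
  (gradient samples, stimulus ramps, fluorescence traces, turn intervals,
  plate tracks), so the whole pipeline is testable without any recordings.

## Worked example

```python
import numpy as np
from odornav import behavior as bh, circstats as cs, neural_models as nm, \
    odor_field as of, simulator as sim, synthetic as syn

# 1. the published odor field: concentration 1.1 cm right of center, 6 min in
field = of.GradientParams()
of.eval_gradient(field, 1.1, 0.0, 6.0)        # -> 2.008 (uM)

# 2. which response model explains a (synthetic, noisy) odor-down trace?
stim = syn.gen_stimulus_program("down", 90)    # 1 uM -> 0 over 90 s
trace = nm.simulate_response(nm.AWB_LEAKY[90], stim)
trace += 0.05 * np.random.default_rng(0).standard_normal(trace.size)
ranked = nm.compare_models(trace, stim, ("differential", "leaky"), input_sign=-1)
print(nm.ranking_table(ranked)[["family", "k", "tau", "bic", "delta_bic"]]
      .round(2).to_string(index=False))

# 3. integration vs differentiation decision rules, 100 simulated assays each
ri = sim.run_simulation(sim.SimConfig(), field, "integration", seed=1)
rd = sim.run_simulation(sim.SimConfig(), field, "differentiation", seed=2)
res = cs.mardia_watson_wheeler(cs.AngularSample(ri.bearings),
                               cs.AngularSample(rd.bearings))
for r in (ri, rd):
    print("%-15s %d run initiations, %.1f%% within +/-90 deg"
          % (r.rule + ":", r.bearings.size,
             100 * bh.fraction_within_90(r.bearings)))
print("MWW: W = %.1f, p = %.2e" % (res.statistic, res.p_value))
```

Output:

```
      family     k   tau      bic  delta_bic
       leaky  3.63 27.81 -1080.51       0.00
differential 71.43   inf  -372.40     708.11

integration:     1490 run initiations, 82.5% within +/-90 deg
differentiation: 2795 run initiations, 66.3% within +/-90 deg
MWW: W = 72.9, p = 1.52e-16
```

The BIC table shows that the noisy down-ramp trace is far better explained
by the leaky integrator (ΔBIC ≈ 708) and that the generating parameters
(k = 3.6 μM⁻¹, τ = 28.1 s) are recovered.  The simulation shows the
behavioral consequence of the decision rule: an integrating agent commits to
runs mostly after genuine down-gradient evidence (82.5% of run initiations
within ±90° of straight-away), while a differentiating agent is triggered by
single-second fluctuations of the sensed signal (66.3%), and the two bearing
distributions differ strongly (Mardia–Watson–Wheeler p ≈ 10⁻¹⁶).

A command-line front end mirrors these stages; see `odornav --help`
(`fit-gradient`, `eval-gradient`, `segment`, `fit-trace`, `simulate`,
`stats`, `gen`).

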