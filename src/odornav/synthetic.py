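"""Synthetic inputs for every pipeline stage.

No raw tracks or traces from the original experiments are publicly
deposited, so every consumer in this package is exercised on generated data
with the statistical structure the analysis assumes: GC-style gradient
samples with replicate noise, the linear 0↔1 μM odor ramps of the
flow-delivery experiments, fluorescence traces produced by the response
models (optionally passed through the Hill nonlinearity), two-exponential
turn-interval samples, and simulator plate tracks re-emitted in the
trajectory table format.  Every generator is a pure function of its
parameters and an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import simulator
from .odor_field import (
    ConcentrationSeries,
    GradientMeasurement,
    GradientParams,
    central_difference,
    eval_gradient,
)
from .neural_models import (
    FluorescenceTrace,
    HillParams,
    ResponseModel,
    hill_forward,
    simulate_response,
)

#: GC sampling-position pattern over the right half-plate (mm -> cm) and the
#: measurement times (min).  The first grid points follow the published
#: sampling schematic; the grid extends the same pattern far enough to
#: identify all six model constants.
DEFAULT_GC_GRID_CM = tuple(
    (x_mm / 10.0, y_mm / 10.0)
    for x_mm in (11, 22, 33, 44, 55, 66)
    for y_mm in (0, 15, 30)
)
DEFAULT_GC_TIMES_MIN = (1.0, 3.0, 6.0, 9.0, 12.0)

#: Default stimulus-phase plans: 60-s odor-zero (or plateau) lead-in, a
#: linear 0↔1 μM ramp, then 30 s of the final level (sample counts match the
#: published fit windows: 135/180/270 frames for 45/90/180-s ramps).
RAMP_DURATIONS_S = (45, 90, 180)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive/multiplicative Gaussian noise and its seed."""

    additive_sd: float = 0.0
    multiplicative_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.additive_sd < 0 or self.multiplicative_sd < 0:
            raise ValueError("noise SDs must be non-negative")


def gen_gradient_measurements(params: GradientParams,
                              grid=DEFAULT_GC_GRID_CM,
                              times_min=DEFAULT_GC_TIMES_MIN,
                              replicates: int = 9,
                              noise: NoiseSpec = NoiseSpec()) -> list:
    """GC-style gradient samples: the model evaluated on the grid × times,
    with multiplicative replicate noise."""
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(noise.seed)
    out = []
    for (x, y) in grid:
        for t in times_min:
            c = eval_gradient(params, x, y, t)
            reps = c * (1.0 + noise.multiplicative_sd
                        * rng.standard_normal(replicates)) \
                + noise.additive_sd * rng.standard_normal(replicates)
            out.append(GradientMeasurement(x, y, t, tuple(np.maximum(reps, 0.0))))
    return out


def gen_stimulus_program(direction: str, ramp_s: int,
                         lead_s: int = 60, post_s: int = 30,
                         c_max_uM: float = 1.0) -> ConcentrationSeries:
    """Piecewise-linear odor program at 1 Hz.

    ``direction='up'``: odor-zero lead-in, linear 0→``c_max`` ramp over
    ``ramp_s`` seconds, then a plateau; ``'down'``: plateau lead-in, ramp to
    zero, then odor-zero.  Time is relative to ramp onset (t = 0), so the
    default window spans −60 … ramp_s+29 s (N = lead+ramp+post samples).
    """
    if c_max_uM < 0:
        raise ValueError("negative concentration")
    t = np.arange(-lead_s, ramp_s + post_s, 1.0)
    ramp = np.clip(t / ramp_s, 0.0, 1.0)
    if direction == "up":
        c = c_max_uM * ramp
    elif direction == "down":
        c = c_max_uM * (1.0 - ramp)
    elif direction == "plateau":
        c = np.full_like(t, c_max_uM)
    elif direction == "zero":
        c = np.zeros_like(t)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return central_difference(ConcentrationSeries(t, c))


def gen_fluorescence_trace(model: ResponseModel,
                           stimulus: ConcentrationSeries,
                           noise: NoiseSpec = NoiseSpec(),
                           hill: HillParams | None = None,
                           f0: float = 1000.0,
                           background: float = 100.0) -> FluorescenceTrace:
    """Raw-trace generator that round-trips through ``process_fluorescence``.

    The model response (ΔF/F0 scale, or calcium when ``hill`` is given, in
    which case the response is mapped through the indicator saturation
    curve) receives additive Gaussian noise and is re-expressed as raw cell
    and background intensities with baseline ``f0``.
    """
    rng = np.random.default_rng(noise.seed)
    x = simulate_response(model, stimulus)
    dff = hill_forward(x, hill) if hill is not None else x
    dff = dff + noise.additive_sd * rng.standard_normal(dff.size)
    f_cell = f0 * (1.0 + dff) + background
    return FluorescenceTrace(stimulus.time_s.copy(), f_cell,
                             np.full(dff.size, background))


def gen_turn_intervals(A1: float, lam1: float, A2: float, lam2: float,
                       n: int, seed: int = 0) -> np.ndarray:
    """Draw turn intervals from the two-exponential mixture.

    The histogram amplitudes are count densities, so component *i*
    contributes total mass A_i/λ_i; draws mix accordingly.
    """
    if n == 0:
        return np.empty(0)
    if not (lam1 > lam2 > 0):
        raise ValueError("need lam1 > lam2 > 0")
    rng = np.random.default_rng(seed)
    w1 = (A1 / lam1) / (A1 / lam1 + A2 / lam2)
    comp = rng.random(n) < w1
    draws = np.where(comp,
                     rng.exponential(1.0 / lam1, n),
                     rng.exponential(1.0 / lam2, n))
    return draws


def gen_plate_tracks(cfg: simulator.SimConfig, field: GradientParams,
                     rule: str, n: int, seed: int = 0) -> list:
    """Simulator tracks re-emitted as behavior-module trajectories (with
    animal ids), for end-to-end pipeline tests."""
    result = simulator.run_simulation(cfg, field, rule, n_runs=n, seed=seed)
    tracks = []
    for i, tr in enumerate(result.tracks):
        tracks.append(type(tr)(tr.time_s, tr.x, tr.y, tr.rate_hz,
                               animal_id=f"{rule}_{i:03d}",
                               window_s=tr.window_s))
    return tracks
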