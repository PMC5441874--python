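"""Agent-based simulation of 2-nonanone avoidance on the fitted odor field.

A model worm moves on the 9-cm plate in 1-s steps and switches between a
high-turning state (pirouette-like: frequent random turns) and a low-turning
state (run-like: long migrations with a dC/dt-dependent pirouette-initiation
rate).  The scientific question is the rule for the high→low transition —
the decision to commit to a run:

* ``integration`` rule — a leaky integrator accumulates the sensed −dC/dt
  (only while the animal experiences a falling concentration) and the
  transition fires when the integral exceeds the threshold θ = 0.18;
* ``differentiation`` rule — the transition fires on any single second with
  dC/dt < 0.

All locomotor constants are the published ones measured from real animals:
speed 0.14 mm/s, per-second heading noise Gaussian(−0.065°, 5.14°), a
0.1-mm, 0.5-Hz sinusoidal head swing (the odor is sensed at the anterior
end), 3-s turns, a constant 0.2 s⁻¹ turn rate in the high-turning state and
the rate function 0.0326/(0.200 + exp(−231·dC/dt)) + 0.0260 in the
low-turning state.  Each run is 12 simulated minutes; run-initiation
bearings are analyzed over the 121–720 s window as in the plate assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import behavior
from .odor_field import (
    GradientParams,
    PLATE_RADIUS_CM,
    SECONDS_PER_MINUTE,
    eval_gradient,
)

RULES = ("integration", "differentiation")


class SimulationError(ValueError):
    """Raised for invalid simulator configuration."""


def pirouette_initiation_rate(dcdt):
    """Probability per second of initiating a turn in the low-turning state:

        0.0326 / (0.200 + exp(−231·dC/dt)) + 0.0260

    with dC/dt in μM/s; ≈0.026 s⁻¹ for strongly negative dC/dt, rising to
    0.189 s⁻¹ for strongly positive dC/dt.  Clipped to [0, 1].
    """
    d = np.asarray(dcdt, float)
    r = 0.0326 / (0.200 + np.exp(-231.0 * d)) + 0.0260
    r = np.clip(r, 0.0, 1.0)
    return r if r.ndim else float(r)


@dataclass(frozen=True)
class SimConfig:
    """All constants of the agent-based model (printed values as defaults)."""

    speed_mm_s: float = 0.14
    heading_noise_mean_deg: float = -0.065
    heading_noise_sd_deg: float = 5.14
    head_amplitude_mm: float = 0.1
    head_frequency_hz: float = 0.5
    turn_duration_s: int = 3
    high_turn_rate_per_s: float = 0.2
    decision_threshold: float = 0.18
    #: Decision-integrator gain/time constant; defaults to the wild-type AWB
    #: down-90 ΔF/F0 leaky fit so θ = 0.18 sits on the ΔF/F0 scale.
    decision_k: float = 3.6
    decision_tau_s: float = 28.1
    dt_s: float = 1.0
    duration_s: float = 720.0
    plate_radius_cm: float = PLATE_RADIUS_CM
    start_xy_cm: tuple = (0.0, 0.0)
    analysis_window_s: tuple = behavior.DEFAULT_WINDOW_S
    n_runs: int = 100
    #: Optional empirical pool (degrees) of post-turn direction deviations;
    #: None draws uniformly on (−180, 180].
    post_turn_pool: tuple | None = None

    def __post_init__(self):
        if self.decision_threshold <= 0:
            raise SimulationError("decision threshold must be positive")
        if not 0 <= self.high_turn_rate_per_s <= 1:
            raise SimulationError("per-step turn probability must be in [0, 1]")
        if self.dt_s <= 0 or self.duration_s <= 0:
            raise SimulationError("time step and duration must be positive")


def decision_update(x: float, dcdt: float, cfg: SimConfig) -> float:
    """One Euler step of the decision integrator.

    The input is the rectified down-gradient signal max(−dC/dt, 0): evidence
    accumulates only while the sensed concentration is falling, and decays
    with time constant τ otherwise.
    """
    drive = max(-dcdt, 0.0)
    return x + cfg.dt_s * cfg.decision_k * drive \
        - (cfg.dt_s / cfg.decision_tau_s) * x


def decision_first_passage(cfg: SimConfig, dcdt_const: float,
                           max_s: float = 3600.0) -> float | None:
    """Time (s) for the decision variable to cross θ under a constant
    sensed dC/dt, from X = 0; ``None`` if it never crosses within
    ``max_s``.  The continuous-time reference is the crossing of
    k·g·τ·(1 − e^(−t/τ)) with g = −dC/dt."""
    x = 0.0
    t = 0.0
    while t < max_s:
        x = decision_update(x, dcdt_const, cfg)
        t += cfg.dt_s
        if x > cfg.decision_threshold:
            return t
    return None


@dataclass
class SimResult:
    """Outcome of an ensemble of simulated avoidance assays."""

    tracks: list                       # behavior.Trajectory per run
    bearings: np.ndarray               # run-initiation bearings, window only
    state_logs: list                   # per-run per-second state strings
    transition_times: list             # per-run high->low transition times (s)
    seed: int
    rule: str
    config: SimConfig
    field_params: GradientParams


def _reflect(pos: np.ndarray, heading_rad: float, radius: float):
    """Specular reflection at the circular dish wall."""
    d = np.hypot(*pos)
    if d <= radius:
        return pos, heading_rad
    n = pos / d
    pos = pos * (2 * radius - d) / d
    v = np.array([np.cos(heading_rad), np.sin(heading_rad)])
    v = v - 2 * (v @ n) * n
    return pos, float(np.arctan2(v[1], v[0]))


def simulate_run(cfg: SimConfig, field: GradientParams, rule: str,
                 rng: np.random.Generator):
    """One simulated animal; returns (track, state log, transition times).

    Per 1-s step: advance the centroid 0.14 mm along the heading (perturbed
    by the Gaussian heading noise), place the anterior end on the lateral
    sinusoid, sense dC/dt as the 1-s concentration difference along the
    anterior-end path, then apply the state machine.  During the 3-s turns
    the centroid is stationary and the decision integrator receives no input
    but keeps decaying; the integrator resets on every turn.
    """
    if rule not in RULES:
        raise SimulationError(f"unknown rule {rule!r}")
    n_steps = int(round(cfg.duration_s / cfg.dt_s))
    step_cm = cfg.speed_mm_s * cfg.dt_s / 10.0
    amp_cm = cfg.head_amplitude_mm / 10.0
    noise_mean = np.radians(cfg.heading_noise_mean_deg)
    noise_sd = np.radians(cfg.heading_noise_sd_deg)
    decay = cfg.dt_s / cfg.decision_tau_s

    pos = np.array(cfg.start_xy_cm, float)
    heading = rng.uniform(-np.pi, np.pi)
    state = "high_turning"
    x_dec = 0.0
    turn_left = 0

    times = np.arange(n_steps + 1, dtype=float) * cfg.dt_s
    xs = np.empty(n_steps + 1)
    ys = np.empty(n_steps + 1)
    xs[0], ys[0] = pos
    states = []
    transitions = []

    def anterior(p, hdg, t_s):
        # 0.5-Hz sinusoid sampled at 1 Hz with a quarter-period phase offset:
        # the head alternates sides of the track each second
        phase = 2 * np.pi * cfg.head_frequency_hz * t_s + np.pi / 2
        lateral = amp_cm * np.sin(phase)
        normal = np.array([-np.sin(hdg), np.cos(hdg)])
        return p + lateral * normal

    c_prev = float(eval_gradient(field, *anterior(pos, heading, 0.0),
                                 0.0 / SECONDS_PER_MINUTE))

    for i in range(n_steps):
        t_now = times[i + 1]
        if turn_left > 0:
            # reorientation in place
            turn_left -= 1
            x_dec -= decay * x_dec
            if turn_left == 0:
                if cfg.post_turn_pool is not None:
                    heading += np.radians(
                        cfg.post_turn_pool[rng.integers(len(cfg.post_turn_pool))])
                else:
                    heading = rng.uniform(-np.pi, np.pi)
                state = "high_turning"
            xs[i + 1], ys[i + 1] = pos
            states.append("turning")
            c_prev = float(eval_gradient(field, *anterior(pos, heading, t_now),
                                         t_now / SECONDS_PER_MINUTE))
            continue

        heading += rng.normal(noise_mean, noise_sd)
        pos = pos + step_cm * np.array([np.cos(heading), np.sin(heading)])
        pos, heading = _reflect(pos, heading, cfg.plate_radius_cm)
        xs[i + 1], ys[i + 1] = pos

        c_now = float(eval_gradient(field, *anterior(pos, heading, t_now),
                                    t_now / SECONDS_PER_MINUTE))
        dcdt = (c_now - c_prev) / cfg.dt_s
        c_prev = c_now

        if state == "high_turning":
            if rule == "integration":
                x_dec = decision_update(x_dec, dcdt, cfg)
                if x_dec > cfg.decision_threshold:
                    state = "low_turning"
                    transitions.append(t_now)
            else:
                if dcdt < 0.0:
                    state = "low_turning"
                    transitions.append(t_now)

        if state == "high_turning":
            if rng.random() < cfg.high_turn_rate_per_s * cfg.dt_s:
                turn_left = cfg.turn_duration_s
                x_dec = 0.0
        elif state == "low_turning":
            if rng.random() < pirouette_initiation_rate(dcdt) * cfg.dt_s:
                turn_left = cfg.turn_duration_s
                x_dec = 0.0
        states.append(state)

    track = behavior.Trajectory(times, xs, ys, rate_hz=1.0 / cfg.dt_s,
                                window_s=cfg.analysis_window_s)
    return track, states, transitions


def _transition_bearings(track, transitions, field, cfg):
    """Bearing of the first moving step after each high→low transition
    inside the analysis window."""
    w0, w1 = cfg.analysis_window_s
    out = []
    t = track.time_s
    for tt in transitions:
        if not (w0 <= tt <= w1):
            continue
        i = int(np.searchsorted(t, tt))
        while i + 1 < t.size:
            disp = (track.x[i + 1] - track.x[i], track.y[i + 1] - track.y[i])
            if np.hypot(*disp) > 0:
                out.append(behavior.bearing(
                    disp, (track.x[i], track.y[i]), field,
                    t[i] / SECONDS_PER_MINUTE, "away_zero"))
                break
            i += 1
    return out


def run_simulation(cfg: SimConfig, field: GradientParams, rule: str,
                   n_runs: int | None = None, seed: int = 0) -> SimResult:
    """Simulate an ensemble of independent animals.

    Fully reproducible: each run consumes an independent stream spawned from
    ``seed``.
    """
    n = cfg.n_runs if n_runs is None else n_runs
    if n < 1:
        raise SimulationError("need at least one run")
    streams = np.random.SeedSequence(seed).spawn(n)
    tracks, logs, trans, bearings = [], [], [], []
    for s in streams:
        track, states, transitions = simulate_run(
            cfg, field, rule, np.random.default_rng(s))
        tracks.append(track)
        logs.append(states)
        trans.append(transitions)
        bearings.extend(_transition_bearings(track, transitions, field, cfg))
    return SimResult(tracks, np.asarray(bearings, float), logs, trans,
                     seed, rule, cfg, field)


def high_state_intervals(n_intervals: int, seed: int = 0,
                         turn_rate_per_s: float = 0.2) -> np.ndarray:
    """Inter-turn migratory durations (s) generated by the high-turning
    state alone: with a constant per-second turn probability the durations
    are geometric."""
    if n_intervals == 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    return rng.geometric(turn_rate_per_s, n_intervals).astype(float)
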