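"""Behavioral-state analysis of worm trajectories.

*C. elegans* navigates gradients by alternating two locomotor states: the
pirouette (frequent sharp turns separated by short migrations) and the run
(a long, relatively straight migration).  This module turns positional time
series into that description:

* turn detection — a second is a turn when the centroid's migratory vector
  rotates by more than 90° from the previous second, with a sticky low-speed
  extension;
* the pirouette/run boundary ``t_crit`` — the turn-interval histogram is
  fitted by a sum of two exponentials and ``t_crit`` is the interval at which
  the two components contribute equal counts;
* bearings — signed angle between a migration step and the local
  down-gradient (avoidance convention, B = 0° is straight away from the odor)
  or up-gradient direction (taxis convention);
* turning-rate time courses, turn probability vs dC/dt, Student-t prediction
  intervals for onset detection, and the record-level quality filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .odor_field import (
    ConcentrationSeries,
    GradientParams,
    eval_gradient_spatial,
    SECONDS_PER_MINUTE,
)

#: Plate-assay analysis window (s): avoidance is not initiated during the
#: first two minutes, so analysis spans 121–720 s of the 12-min recording.
DEFAULT_WINDOW_S = (121.0, 720.0)

#: Heading-change threshold defining a turn (degrees per second).
TURN_ANGLE_DEG = 90.0

#: Speed below which post-turn frames stay part of the same turn (mm/s).
TURN_LOW_SPEED_MM_S = 0.1

#: Records with basal speed below this are excluded from analysis (mm/s).
MIN_BASAL_SPEED_MM_S = 0.02

#: Pirouette/run interval threshold fitted from real avoidance data (s).
#: Kept as a documented reference default; refit via fit_interval_mixture.
T_CRIT_REFERENCE_S = 13.1


class BehaviorError(ValueError):
    """Raised for invalid behavioral inputs."""


@dataclass(frozen=True)
class Trajectory:
    """Positional time series of one animal.

    Positions are in cm, time in seconds, sampled uniformly at ``rate_hz``.
    """

    time_s: np.ndarray
    x: np.ndarray
    y: np.ndarray
    rate_hz: float = 1.0
    animal_id: str = "worm"
    window_s: tuple = DEFAULT_WINDOW_S

    def __post_init__(self):
        t = np.asarray(self.time_s, float)
        x = np.asarray(self.x, float)
        y = np.asarray(self.y, float)
        if not (t.size == x.size == y.size):
            raise BehaviorError("time, x, y must be equal-length")
        if t.size >= 2:
            steps = np.diff(t)
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise BehaviorError("non-uniform sampling")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def clip_window(self) -> "Trajectory":
        t0, t1 = self.window_s
        m = (self.time_s >= t0) & (self.time_s <= t1)
        return replace(self, time_s=self.time_s[m], x=self.x[m], y=self.y[m])


@dataclass(frozen=True)
class TurnSequence:
    """Detected turns: merged (start, end) events plus per-second flags."""

    events: tuple            # ((start_s, end_s), ...) inclusive seconds
    time_s: np.ndarray       # per-second time base of the flags
    flags: np.ndarray        # bool, True where the second is a turn

    def __post_init__(self):
        starts = [e[0] for e in self.events]
        if sorted(starts) != list(starts):
            raise BehaviorError("turn events must be ordered")
        for (s1, e1), (s2, _) in zip(self.events, self.events[1:]):
            if s2 <= e1:
                raise BehaviorError("turn events must not overlap")

    def intervals(self) -> np.ndarray:
        """Turn-free migratory durations (s) between consecutive turns."""
        if len(self.events) < 2:
            return np.empty(0)
        return np.array([s2 - e1 for (_, e1), (s2, _) in
                         zip(self.events, self.events[1:])], float)


@dataclass(frozen=True)
class IntervalMixtureFit:
    """Two-exponential fit of the turn-interval histogram.

    ``N(t) = A1*exp(-lam1*t) + A2*exp(-lam2*t)`` with ``lam1 > lam2``; the
    crossing of the two components defines ``t_crit``.
    """

    A1: float
    lam1: float
    A2: float
    lam2: float

    def __post_init__(self):
        if not (self.lam1 > self.lam2 > 0):
            raise BehaviorError("need lam1 > lam2 > 0 (short vs long component)")

    @property
    def t_crit(self) -> float:
        return float(np.log(self.A1 / self.A2) / (self.lam1 - self.lam2))


@dataclass(frozen=True)
class StateSegmentation:
    """Partition of the analysis window into pirouette and run intervals."""

    intervals: tuple          # ((start_s, end_s, "pirouette"|"run"), ...)

    def runs(self):
        return [iv for iv in self.intervals if iv[2] == "run"]

    def pirouettes(self):
        return [iv for iv in self.intervals if iv[2] == "pirouette"]

    def state_at(self, t: float) -> str | None:
        for s, e, label in self.intervals:
            if s <= t <= e:
                return label
        return None


@dataclass(frozen=True)
class PredictionInterval:
    """100(1-α)% prediction interval for a single future observation."""

    mean: float
    sd: float
    n: int
    alpha: float
    lower: float
    upper: float


# ---------------------------------------------------------------------------
# Smoothing / resampling
# ---------------------------------------------------------------------------

def smooth_track(track: Trajectory, half_window: int = 10) -> Trajectory:
    """Centered moving average of x and y over ±``half_window`` frames.

    Edges use truncated windows.  The ±10-frame default matches head-tracked
    10-Hz records (±1 s); pass 0 for 1-Hz centroid data.
    """
    if half_window < 0:
        raise BehaviorError("half_window must be >= 0")
    if half_window == 0:
        return track

    def smooth(v):
        n = v.size
        csum = np.concatenate(([0.0], np.cumsum(v)))
        idx = np.arange(n)
        lo = np.maximum(idx - half_window, 0)
        hi = np.minimum(idx + half_window, n - 1)
        return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)

    return replace(track, x=smooth(track.x), y=smooth(track.y))


def resample_1hz(track: Trajectory) -> Trajectory:
    """Decimate a higher-rate (smoothed) track to 1 Hz by taking every
    ``rate_hz``-th sample."""
    step = int(round(track.rate_hz))
    if step <= 1:
        return track
    return replace(track, time_s=track.time_s[::step], x=track.x[::step],
                   y=track.y[::step], rate_hz=1.0)


# ---------------------------------------------------------------------------
# Turn detection
# ---------------------------------------------------------------------------

def detect_turns(track: Trajectory,
                 angle_deg: float = TURN_ANGLE_DEG,
                 low_speed_mm_s: float = TURN_LOW_SPEED_MM_S) -> TurnSequence:
    """Per-second turn classification on a 1-Hz track.

    A second is a turn when the migratory vector rotates by more than 90°
    relative to the previous second; seconds immediately after such a change
    whose speed stays below 0.1 mm/s extend the same turn (the animal is
    still reorienting).  Contiguous turn-seconds merge into one event.
    """
    if abs(track.rate_hz - 1.0) > 1e-9:
        raise BehaviorError("detect_turns expects a 1-Hz track; resample first")
    t = track.time_s
    if t.size < 3:
        raise BehaviorError("track too short for turn detection (< 3 s)")
    dx = np.diff(track.x)
    dy = np.diff(track.y)
    heading = np.degrees(np.arctan2(dy, dx))        # per migratory second
    dhead = np.abs((np.diff(heading) + 180.0) % 360.0 - 180.0)
    speed_mm_s = np.hypot(dx, dy) * 10.0            # cm/s -> mm/s

    # flags[i] refers to the migratory second ending at t[i+1]; the first
    # flagged second is the one *after* the first, where Δheading exists.
    n = heading.size
    flags = np.zeros(n, bool)
    in_extension = False
    for i in range(1, n):
        if dhead[i - 1] > angle_deg:
            flags[i] = True
            in_extension = True
        elif in_extension and speed_mm_s[i] < low_speed_mm_s:
            flags[i] = True
        else:
            in_extension = False

    flag_times = t[1:]  # second i covers (t[i], t[i+1]]
    events = []
    i = 0
    while i < n:
        if flags[i]:
            j = i
            while j + 1 < n and flags[j + 1]:
                j += 1
            events.append((float(flag_times[i] - 1.0), float(flag_times[j])))
            i = j + 1
        else:
            i += 1
    return TurnSequence(tuple(events), flag_times, flags)


# ---------------------------------------------------------------------------
# Interval mixture and t_crit
# ---------------------------------------------------------------------------

def fit_interval_mixture(intervals, bin_s: float = 1.0,
                         log_space: bool = False) -> IntervalMixtureFit:
    """Fit the turn-interval histogram with a sum of two exponentials.

    The intervals are binned at 1 s and the counts fitted by unweighted least
    squares (linear space by default, log-space optionally); ``t_crit``
    follows analytically from the crossing of the two components.  A
    degenerate fit (components indistinguishable, ``lam1 ≈ lam2``) raises
    :class:`BehaviorError`.
    """
    iv = np.asarray(list(intervals), float)
    if iv.size < 30:
        raise BehaviorError("need at least 30 intervals")
    edges = np.arange(0.0, iv.max() + 2 * bin_s, bin_s)
    counts, _ = np.histogram(iv, edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0 if log_space else np.ones_like(counts, bool)

    def model(t, A1, lam1, A2, lam2):
        return A1 * np.exp(-lam1 * t) + A2 * np.exp(-lam2 * t)

    mean_iv = iv.mean()
    p0 = [counts.max(), 2.0 / max(mean_iv / 2, 0.5),
          counts.max() / 10.0, 0.5 / mean_iv]
    target = np.log(counts[keep]) if log_space else counts[keep].astype(float)

    def residuals(p):
        A1, lam1, A2, lam2 = p
        pred = model(centers[keep], A1, lam1, A2, lam2)
        if log_space:
            pred = np.log(np.maximum(pred, 1e-12))
        return pred - target

    sol = optimize.least_squares(
        residuals, p0,
        bounds=([0, 1e-6, 0, 1e-6], [np.inf, np.inf, np.inf, np.inf]),
        xtol=1e-12, ftol=1e-12)
    A1, lam1, A2, lam2 = sol.x
    if lam1 < lam2:
        A1, lam1, A2, lam2 = A2, lam2, A1, lam1
    if not np.isfinite([A1, lam1, A2, lam2]).all() or A1 <= 0 or A2 <= 0:
        raise BehaviorError("two-exponential fit degenerate (component vanished)")
    if (lam1 - lam2) / lam1 < 0.05:
        raise BehaviorError("two-exponential fit degenerate (lam1 ≈ lam2)")

    # a second component must earn its keep: compare against the best
    # single-exponential fit of the same histogram
    def single_residuals(p):
        pred = p[0] * np.exp(-p[1] * centers[keep])
        if log_space:
            pred = np.log(np.maximum(pred, 1e-12))
        return pred - target

    sol1 = optimize.least_squares(
        single_residuals, [counts.max(), 1.0 / max(mean_iv, 0.5)],
        bounds=([0, 1e-6], [np.inf, np.inf]), xtol=1e-12, ftol=1e-12)
    rss2 = float(sol.fun @ sol.fun)
    rss1 = float(sol1.fun @ sol1.fun)
    if rss1 > 0 and rss2 > 0.5 * rss1:
        raise BehaviorError(
            "two-exponential fit degenerate (no better than one component)")
    return IntervalMixtureFit(float(A1), float(lam1), float(A2), float(lam2))


# ---------------------------------------------------------------------------
# Pirouette / run segmentation
# ---------------------------------------------------------------------------

def segment_states(turns: TurnSequence, t_crit: float = T_CRIT_REFERENCE_S,
                   window_s: tuple | None = None) -> StateSegmentation:
    """Label the analysis window: inter-turn migrations longer than ``t_crit``
    are runs; shorter migrations and the turns themselves are pirouette."""
    if t_crit <= 0:
        raise BehaviorError("t_crit must be positive")
    if window_s is None:
        if turns.time_s.size == 0:
            raise BehaviorError("empty turn sequence and no window given")
        window_s = (float(turns.time_s[0] - 1.0), float(turns.time_s[-1]))
    w0, w1 = window_s

    # boundary migrations (before first / after last turn) are classified by
    # the same duration rule
    marks = [(w0, w0)] + [e for e in turns.events if e[1] >= w0 and e[0] <= w1] \
        + [(w1, w1)]
    raw = []
    for (s1, e1), (s2, _) in zip(marks, marks[1:]):
        if e1 > s1 or (s1, e1) not in ((w0, w0), (w1, w1)):
            raw.append((max(s1, w0), min(e1, w1), "pirouette"))     # the turn
        gap = s2 - e1
        if gap > 0:
            label = "run" if gap > t_crit else "pirouette"
            raw.append((e1, min(s2, w1), label))

    # merge adjacent same-label intervals into a partition
    merged = []
    for s, e, lab in raw:
        if e <= s and not (s == e and not merged):
            if e < s:
                continue
        if merged and merged[-1][2] == lab and abs(merged[-1][1] - s) < 1e-9:
            merged[-1] = (merged[-1][0], e, lab)
        elif e > s:
            merged.append((s, e, lab))
    return StateSegmentation(tuple(merged))


# ---------------------------------------------------------------------------
# Bearings
# ---------------------------------------------------------------------------

def gradient_direction(position, params: GradientParams, t_min: float,
                       convention: str = "away_zero") -> np.ndarray:
    """Unit vector of the B = 0° reference direction at ``position``:
    down-gradient (−∇C) for the avoidance convention ``away_zero``,
    up-gradient (+∇C) for the taxis convention ``toward_zero``."""
    gx, gy = eval_gradient_spatial(params, position[0], position[1], t_min)
    g = np.array([gx, gy], float)
    norm = np.hypot(*g)
    if norm == 0:
        raise BehaviorError("gradient vanishes; bearing undefined")
    if convention == "away_zero":
        return -g / norm
    if convention == "toward_zero":
        return g / norm
    raise BehaviorError(f"unknown bearing convention {convention!r}")


def bearing(displacement, position, params: GradientParams,
            t_min: float = 12.0, convention: str = "away_zero") -> float:
    """Signed bearing B in (−180, 180]°: the angle between a migration vector
    and the gradient reference direction.  B = 0° is straight away from the
    odor source under ``away_zero`` (±180° is straight toward it)."""
    d = np.asarray(displacement, float)
    if np.hypot(*d) == 0:
        raise BehaviorError("zero displacement has no bearing")
    ref = gradient_direction(position, params, t_min, convention)
    ang = np.degrees(np.arctan2(d[1], d[0]) - np.arctan2(ref[1], ref[0]))
    ang = (ang + 180.0) % 360.0 - 180.0
    return float(180.0 if np.isclose(ang, -180.0) else ang)


def run_initiation_bearings(seg: StateSegmentation, track: Trajectory,
                            params: GradientParams,
                            convention: str = "away_zero") -> np.ndarray:
    """Bearing of the first 1-s step of each run."""
    if not seg.runs():
        raise BehaviorError("segmentation contains no runs")
    out = []
    t = track.time_s
    for s, _, _ in seg.runs():
        i = int(np.searchsorted(t, s - 1e-9))
        if i + 1 >= t.size:
            continue
        disp = (track.x[i + 1] - track.x[i], track.y[i + 1] - track.y[i])
        if np.hypot(*disp) == 0:
            continue
        out.append(bearing(disp, (track.x[i], track.y[i]), params,
                           t[i] / SECONDS_PER_MINUTE, convention))
    return np.asarray(out)


def fraction_within_90(bearings) -> float:
    """Fraction of bearings within ±90° (boundary values count inward)."""
    b = np.asarray(bearings, float)
    if b.size == 0:
        raise BehaviorError("no bearings")
    return float(np.mean(np.abs(b) <= 90.0))


# ---------------------------------------------------------------------------
# Turning-rate summaries
# ---------------------------------------------------------------------------

def turning_rate_timecourse(flag_sets, time_s, bin_s: float = 10.0
                            ) -> pd.DataFrame:
    """Ensemble turning rate per time bin.

    ``flag_sets`` is a sequence of per-animal boolean turn flags on the
    shared per-second time base ``time_s``.  Returns a DataFrame with the bin
    start, per-bin mean rate across animals (turns/s) and the SEM.
    """
    flags = np.asarray(list(flag_sets), bool)
    if flags.size == 0:
        raise BehaviorError("empty ensemble")
    t = np.asarray(time_s, float)
    edges = np.arange(t[0], t[-1] + bin_s, bin_s)
    idx = np.digitize(t, edges) - 1
    n_bins = edges.size - 1
    rates = np.full((flags.shape[0], n_bins), np.nan)
    for b in range(n_bins):
        m = idx == b
        if m.any():
            rates[:, b] = flags[:, m].mean(axis=1)
    mean = np.nanmean(rates, axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sem = np.nanstd(rates, axis=0, ddof=1) / np.sqrt(flags.shape[0])
    return pd.DataFrame({"bin_start_s": edges[:-1], "rate": mean, "sem": sem})


def turning_rate_vs_dcdt(dcdt, turn_flags, states=None,
                         bin_uM_s: float = 0.005) -> pd.DataFrame:
    """P(turn in the next second | dC/dt in bin), optionally split by state.

    ``dcdt[i]`` is the concentration change during second *i* and
    ``turn_flags[i+1]`` says whether the next second was a turn; bins with no
    observations are omitted.
    """
    d = np.asarray(dcdt, float)
    f = np.asarray(turn_flags, bool)
    if d.size != f.size:
        raise BehaviorError("dC/dt and turn flags must align per second")
    x = d[:-1]
    y = f[1:]
    lab = None if states is None else np.asarray(list(states))[:-1]
    lo = np.floor(x.min() / bin_uM_s) * bin_uM_s
    hi = np.ceil(x.max() / bin_uM_s) * bin_uM_s + bin_uM_s
    edges = np.arange(lo, hi + bin_uM_s / 2, bin_uM_s)
    rows = []
    groups = [(None, np.ones_like(y, bool))] if lab is None else \
        [(s, lab == s) for s in np.unique(lab)]
    for state, m in groups:
        idx = np.digitize(x[m], edges) - 1
        for b in range(edges.size - 1):
            sel = idx == b
            if sel.sum() == 0:
                continue
            rows.append({
                "state": state, "bin_start": edges[b],
                "p_turn": float(y[m][sel].mean()), "n": int(sel.sum()),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Prediction interval and onset detection
# ---------------------------------------------------------------------------

def prediction_interval(baseline, alpha: float = 0.01) -> PredictionInterval:
    """Student-t prediction interval for one future observation:

        x̄ ± t_{α/2, n−1} · s · sqrt(1 + 1/n)
    """
    x = np.asarray(list(baseline), float)
    n = x.size
    if n < 2:
        raise BehaviorError("need at least 2 baseline observations")
    if not 0 < alpha < 1:
        raise BehaviorError("alpha must be in (0, 1)")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    half = float(stats.t.ppf(1 - alpha / 2, n - 1) * sd * np.sqrt(1 + 1 / n))
    return PredictionInterval(mean, sd, n, alpha, mean - half, mean + half)


def first_crossing(bin_times, rates, bound: float,
                   direction: str = "above") -> float | None:
    """Earliest bin time whose rate exceeds (``above``) or falls below
    (``below``) the prediction bound; ``None`` if never crossed."""
    r = np.asarray(rates, float)
    t = np.asarray(bin_times, float)
    hit = r > bound if direction == "above" else r < bound
    i = np.argmax(hit)
    return float(t[i]) if hit.any() else None


# ---------------------------------------------------------------------------
# Quality filters
# ---------------------------------------------------------------------------

def qc_filter(records, min_speed_mm_s: float = MIN_BASAL_SPEED_MM_S,
              min_fluorescence: float | None = None):
    """Apply the four record-exclusion rules.

    Each record is a dict that may carry ``track`` (:class:`Trajectory`),
    ``tracking_interrupted`` (bool), ``basal_fluorescence`` (a.u.) and
    ``abnormal_prestim_transient`` (bool).  Returns ``(retained, log)`` where
    the log lists ``(record index, reason)`` for every exclusion.
    """
    retained, log = [], []
    for i, rec in enumerate(records):
        if rec.get("tracking_interrupted", False):
            log.append((i, "tracking_interrupted"))
            continue
        if min_fluorescence is not None and \
                rec.get("basal_fluorescence", np.inf) < min_fluorescence:
            log.append((i, "weak_fluorescence"))
            continue
        if rec.get("abnormal_prestim_transient", False):
            log.append((i, "abnormal_prestim_transient"))
            continue
        track = rec.get("track")
        if track is not None:
            disp_cm = np.hypot(np.diff(track.x), np.diff(track.y))
            dt = np.diff(track.time_s)
            speed = float(np.mean(disp_cm / dt)) * 10.0      # mm/s
            if speed < min_speed_mm_s:
                log.append((i, "slow"))
                continue
        retained.append(rec)
    return retained, log


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_tracks(path, rate_hz: float = 1.0) -> list:
    """Read trajectories from TSV/CSV with columns animal_id, t_s, x_cm, y_cm."""
    df = pd.read_csv(path, sep=None, engine="python")
    return [
        Trajectory(grp["t_s"].to_numpy(float), grp["x_cm"].to_numpy(float),
                   grp["y_cm"].to_numpy(float), rate_hz, str(aid))
        for aid, grp in df.groupby("animal_id", sort=True)
    ]


def write_tracks(tracks, path) -> None:
    frames = [
        pd.DataFrame({"animal_id": tr.animal_id, "t_s": tr.time_s,
                      "x_cm": tr.x, "y_cm": tr.y})
        for tr in tracks
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_segmentation(seg: StateSegmentation, path) -> None:
    pd.DataFrame(
        [{"start_s": s, "end_s": e, "state": lab} for s, e, lab in seg.intervals]
    ).to_csv(path, sep="\t", index=False)
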