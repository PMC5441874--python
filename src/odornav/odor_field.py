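"""Two-source exponential-saturation model of a volatile odor gradient.

A droplet of 2-nonanone placed on a closed agar plate evaporates and spreads;
at any point the air-phase concentration rises toward a position-dependent
asymptote.  The field is modeled phenomenologically as a sum over the two
sources,

    C(x, y, t) = sum_i a(r_i) * (1 - exp(-b(r_i) * t)),

where ``r_i`` is the Euclidean distance (cm) from ``(x, y)`` to source *i*,
the asymptotic concentration is ``a(r) = a0 * exp(-a1*r - a2*r**2)`` (μM) and
the saturation rate is ``b(r) = b0 * exp(-b1*r - b2*r**2)`` (per minute).
This module evaluates, differentiates and fits that model, converts animal
trajectories into experienced-concentration series (``C_worm``), and handles
the two-segment log-log calibration used to turn gas-chromatograph peak
heights into concentrations.

Units: positions in cm, concentrations in μM, model time in minutes
(``b0`` is per-minute); trajectory/series time and all derivatives are in
seconds and μM/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

SECONDS_PER_MINUTE = 60.0

#: Fitted constants of the published 9-cm-plate 2-nonanone gradient.
DEFAULT_A0 = 20.68      # μM
DEFAULT_A1 = 0.7355     # cm^-1
DEFAULT_A2 = -0.05408   # cm^-2
DEFAULT_B0 = 0.8384     # min^-1
DEFAULT_B1 = 0.7835     # cm^-1
DEFAULT_B2 = -0.05761   # cm^-2

#: Default odor-spot coordinates (cm): two point sources on the left half of
#: the 9-cm plate, symmetric about y = 0.  Not printed in the source study
#: (schematic only); override via config for a different plate layout.
DEFAULT_SOURCES = ((-3.0, 0.75), (-3.0, -0.75))

#: 9-cm dish radius (cm).
PLATE_RADIUS_CM = 4.5


class GradientError(ValueError):
    """Raised for invalid gradient-model inputs (negative time, bad data)."""


class FitDegenerateError(GradientError):
    """Raised when the data cannot identify the model (e.g. all zeros)."""


@dataclass(frozen=True)
class GradientParams:
    """The six fitted constants and source positions of the odor field."""

    a0: float = DEFAULT_A0
    a1: float = DEFAULT_A1
    a2: float = DEFAULT_A2
    b0: float = DEFAULT_B0
    b1: float = DEFAULT_B1
    b2: float = DEFAULT_B2
    sources: tuple = DEFAULT_SOURCES

    def __post_init__(self):
        if self.a0 < 0 or self.b0 < 0:
            raise GradientError("a0 and b0 must be non-negative")
        if len(self.sources) < 1:
            raise GradientError("at least one source position required")

    def as_vector(self) -> np.ndarray:
        return np.array([self.a0, self.a1, self.a2, self.b0, self.b1, self.b2])

    @classmethod
    def from_vector(cls, v, sources=DEFAULT_SOURCES) -> "GradientParams":
        a0, a1, a2, b0, b1, b2 = (float(x) for x in v)
        return cls(a0, a1, a2, b0, b1, b2, tuple(map(tuple, sources)))

    def to_dict(self) -> dict:
        return {
            "a0": self.a0, "a1": self.a1, "a2": self.a2,
            "b0": self.b0, "b1": self.b1, "b2": self.b2,
            "sources": [list(s) for s in self.sources],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GradientParams":
        return cls(
            d["a0"], d["a1"], d["a2"], d["b0"], d["b1"], d["b2"],
            tuple(tuple(s) for s in d.get("sources", DEFAULT_SOURCES)),
        )


@dataclass(frozen=True)
class GradientMeasurement:
    """GC-style concentration sample: replicates at one position and time."""

    x: float                      # cm
    y: float                      # cm
    t_min: float                  # minutes
    replicates: tuple             # μM

    def __post_init__(self):
        if self.t_min <= 0:
            raise GradientError("measurement time must be positive")
        if len(self.replicates) < 1:
            raise GradientError("at least one replicate required")

    @property
    def median(self) -> float:
        return float(np.median(self.replicates))

    @property
    def quartiles(self) -> tuple:
        q1, q3 = np.percentile(self.replicates, [25, 75])
        return float(q1), float(q3)


@dataclass(frozen=True)
class ConcentrationSeries:
    """Concentration vs time at 1 Hz (or declared spacing), with optional
    derivative in μM/s."""

    time_s: np.ndarray
    value_uM: np.ndarray
    derivative: np.ndarray | None = None

    def __post_init__(self):
        t = np.asarray(self.time_s, float)
        v = np.asarray(self.value_uM, float)
        if t.ndim != 1 or t.size != v.size:
            raise GradientError("time and value must be 1-D and equal-length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise GradientError("time must be strictly increasing")
        if self.derivative is not None and np.asarray(self.derivative).size != v.size:
            raise GradientError("derivative must match value length")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "value_uM", v)
        if self.derivative is not None:
            object.__setattr__(self, "derivative", np.asarray(self.derivative, float))

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0]) if self.time_s.size > 1 else np.nan


# ---------------------------------------------------------------------------
# Model evaluation
# ---------------------------------------------------------------------------

def _broadcast_inputs(x, y, t):
    return np.broadcast_arrays(np.asarray(x, float), np.asarray(y, float),
                               np.asarray(t, float))


def _source_distances(params: GradientParams, x, y) -> np.ndarray:
    """Distances from (x, y) to each source; shape (n_sources,) + shape(x)."""
    src = np.asarray(params.sources, float)
    return np.sqrt(
        (x[None, ...] - src[:, 0].reshape((-1,) + (1,) * x.ndim)) ** 2
        + (y[None, ...] - src[:, 1].reshape((-1,) + (1,) * y.ndim)) ** 2
    )


def eval_gradient(params: GradientParams, x, y, t_min):
    """Odor concentration (μM) at plate position (x, y) cm and time t (min).

    Vectorized over broadcastable ``x``, ``y``, ``t_min``.
    """
    x, y, t = _broadcast_inputs(x, y, t_min)
    if np.any(t < 0):
        raise GradientError("time must be non-negative")
    r = _source_distances(params, x, y)
    a = params.a0 * np.exp(-params.a1 * r - params.a2 * r**2)
    b = params.b0 * np.exp(-params.b1 * r - params.b2 * r**2)
    c = np.sum(a * (1.0 - np.exp(-b * t)), axis=0)
    return c if c.ndim else float(c)


def eval_gradient_dt(params: GradientParams, x, y, t_min):
    """Analytic ∂C/∂t in μM/s at time t (minutes)."""
    x, y, t = _broadcast_inputs(x, y, t_min)
    if np.any(t < 0):
        raise GradientError("time must be non-negative")
    r = _source_distances(params, x, y)
    a = params.a0 * np.exp(-params.a1 * r - params.a2 * r**2)
    b = params.b0 * np.exp(-params.b1 * r - params.b2 * r**2)
    d = np.sum(a * b * np.exp(-b * t), axis=0) / SECONDS_PER_MINUTE
    return d if d.ndim else float(d)


def eval_gradient_spatial(params: GradientParams, x, y, t_min, h_cm: float = 1e-5):
    """Spatial gradient (∂C/∂x, ∂C/∂y) in μM/cm by central differences."""
    gx = (eval_gradient(params, np.asarray(x) + h_cm, y, t_min)
          - eval_gradient(params, np.asarray(x) - h_cm, y, t_min)) / (2 * h_cm)
    gy = (eval_gradient(params, x, np.asarray(y) + h_cm, t_min)
          - eval_gradient(params, x, np.asarray(y) - h_cm, t_min)) / (2 * h_cm)
    return gx, gy


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradientFit:
    """Result of a Levenberg–Marquardt gradient fit."""

    params: GradientParams
    residual_norm: float
    converged: bool
    n_points: int


def fit_gradient(
    measurements,
    init: GradientParams | None = None,
    sources=DEFAULT_SOURCES,
) -> GradientFit:
    """Fit all six model constants to median replicate concentrations.

    Uses unweighted Levenberg–Marquardt least squares on the per-measurement
    medians.  Raises :class:`FitDegenerateError` for all-zero data and
    :class:`GradientError` for fewer than six distinct (position, time)
    points; non-convergence is reported via ``converged=False``.
    """
    measurements = list(measurements)
    keys = {(m.x, m.y, m.t_min) for m in measurements}
    if len(keys) < 6:
        raise GradientError("need at least 6 distinct (position, time) points")
    xs = np.array([m.x for m in measurements])
    ys = np.array([m.y for m in measurements])
    ts = np.array([m.t_min for m in measurements])
    cs = np.array([m.median for m in measurements])
    if np.allclose(cs, 0.0):
        raise FitDegenerateError("all concentrations are zero")

    if init is None:
        # crude heuristic: amplitude from the largest median, gentle decays
        init = GradientParams(
            a0=max(cs.max(), 1e-6), a1=0.5, a2=0.0, b0=0.5, b1=0.5, b2=0.0,
            sources=tuple(map(tuple, sources)),
        )
    src = init.sources

    def residuals(v):
        p = GradientParams.from_vector(np.abs(v[:1]).tolist() + list(v[1:]), src) \
            if False else GradientParams(
                a0=abs(v[0]), a1=v[1], a2=v[2], b0=abs(v[3]), b1=v[4], b2=v[5],
                sources=src)
        return eval_gradient(p, xs, ys, ts) - cs

    sol = optimize.least_squares(residuals, init.as_vector(), method="lm",
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    v = sol.x
    fitted = GradientParams(abs(v[0]), v[1], v[2], abs(v[3]), v[4], v[5], src)
    return GradientFit(
        params=fitted,
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.success),
        n_points=len(measurements),
    )


# ---------------------------------------------------------------------------
# Differentiation and trajectory concentrations
# ---------------------------------------------------------------------------

def central_difference(series: ConcentrationSeries) -> ConcentrationSeries:
    """Numerical dC/dt (μM/s): central differences inside, one-sided at the
    ends.  Requires >= 3 uniformly spaced samples."""
    t, v = series.time_s, series.value_uM
    if t.size < 3:
        raise GradientError("need at least 3 samples")
    steps = np.diff(t)
    if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-12):
        raise GradientError("non-uniform time spacing")
    dt = steps[0]
    d = np.empty_like(v)
    d[1:-1] = (v[2:] - v[:-2]) / (2 * dt)
    d[0] = (v[1] - v[0]) / dt
    d[-1] = (v[-1] - v[-2]) / dt
    return replace(series, derivative=d)


def trajectory_concentration(track, params: GradientParams,
                             bounds_radius_cm: float = PLATE_RADIUS_CM
                             ) -> ConcentrationSeries:
    """``C_worm``: the concentration experienced along a trajectory, with its
    per-second derivative.

    ``track`` is any object with 1-D ``time_s``, ``x`` and ``y`` attributes
    (cm); trajectory time is in seconds and converted to the model's minutes
    internally.
    """
    t_s = np.asarray(track.time_s, float)
    x = np.asarray(track.x, float)
    y = np.asarray(track.y, float)
    if t_s.size == 0:
        raise GradientError("empty track")
    if np.any(np.hypot(x, y) > bounds_radius_cm * (1 + 1e-9)):
        raise GradientError("track leaves the plate bounds")
    c = eval_gradient(params, x, y, t_s / SECONDS_PER_MINUTE)
    series = ConcentrationSeries(t_s, np.atleast_1d(c))
    if t_s.size >= 3:
        series = central_difference(series)
    return series


# ---------------------------------------------------------------------------
# GC calibration (two-segment log-log regression)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationCurve:
    """Peak-height -> concentration map: two log-log regression lines split
    at a breakpoint concentration, one for each sensor regime."""

    breakpoint_uM: float
    low_slope: float
    low_intercept: float
    high_slope: float
    high_intercept: float
    r2_low: float = field(default=np.nan)
    r2_high: float = field(default=np.nan)

    def __post_init__(self):
        if self.low_slope <= 0 or self.high_slope <= 0:
            raise GradientError("calibration segments must be increasing in log-log space")


def _loglog_fit(conc, peak):
    logc, logp = np.log(conc), np.log(peak)
    slope, intercept = np.polyfit(logc, logp, 1)
    pred = slope * logc + intercept
    ss_res = float(np.sum((logp - pred) ** 2))
    ss_tot = float(np.sum((logp - logp.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


def fit_calibration(peak_heights, concentrations, breakpoint_uM: float
                    ) -> CalibrationCurve:
    """Fit log(peak) = slope*log(conc) + intercept separately below and above
    the breakpoint concentration.  Needs >= 2 positive points per segment."""
    peak = np.asarray(peak_heights, float)
    conc = np.asarray(concentrations, float)
    if np.any(peak <= 0) or np.any(conc <= 0):
        raise GradientError("calibration requires positive peaks and concentrations")
    low = conc <= breakpoint_uM
    high = ~low
    if low.sum() < 2 or high.sum() < 2:
        raise GradientError("need at least 2 points per calibration segment")
    ls, li, r2l = _loglog_fit(conc[low], peak[low])
    hs, hi, r2h = _loglog_fit(conc[high], peak[high])
    return CalibrationCurve(breakpoint_uM, ls, li, hs, hi, r2l, r2h)


def invert_calibration(curve: CalibrationCurve, peak_height) -> np.ndarray | float:
    """Concentration (μM) for a measured peak height, choosing the segment by
    the peak height at the breakpoint."""
    p = np.asarray(peak_height, float)
    if np.any(p <= 0):
        raise GradientError("peak height must be positive")
    logp_break = curve.low_slope * np.log(curve.breakpoint_uM) + curve.low_intercept
    low = np.log(p) <= logp_break
    c = np.where(
        low,
        np.exp((np.log(p) - curve.low_intercept) / curve.low_slope),
        np.exp((np.log(p) - curve.high_intercept) / curve.high_slope),
    )
    return c if c.ndim else float(c)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_measurements(path) -> list:
    """Read GC samples from TSV/CSV with columns x_cm, y_cm, t_min, conc_uM,
    replicate_id; replicates are grouped by (x_cm, y_cm, t_min)."""
    df = pd.read_csv(path, sep=None, engine="python")
    out = []
    for (x, y, t), grp in df.groupby(["x_cm", "y_cm", "t_min"], sort=True):
        out.append(GradientMeasurement(float(x), float(y), float(t),
                                       tuple(grp["conc_uM"].astype(float))))
    return out


def write_measurements(measurements, path) -> None:
    rows = [
        {"x_cm": m.x, "y_cm": m.y, "t_min": m.t_min, "conc_uM": c, "replicate_id": i}
        for m in measurements for i, c in enumerate(m.replicates)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
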