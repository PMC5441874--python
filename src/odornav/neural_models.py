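"""Models of sensory-neuron responses to temporal odor stimuli.

The fluorescence of a genetically encoded calcium indicator (GCaMP) in a
sensory neuron is recorded while the odor concentration C(t) is ramped up or
down.  Four response models are compared:

* ``differential``  — X(t) = k·dC/dt: a phasic response proportional to the
  instantaneous concentration change (ASH-like).
* ``leaky``         — dX/dt = k·I − X/τ with I = ±dC/dt: a leaky integrator
  that accumulates the recent concentration change with exponential
  forgetting over the time constant τ (AWB-like evidence accumulation).
* ``leaky_delayed`` — the same integrator driven by the concentration
  difference over a long interval Δt, I = −(C(t) − C(t−Δt))/Δt; Δt is fitted
  on an integer-second grid (*odr-3*-mutant-like responses).
* ``leaky_generalized`` — dX/dt = k·I − (X − X_base)/τ on the calcium
  concentration scale, where X_base is the basal calcium level; used
  together with the Hill-equation inversion of ΔF/F0.

The integrators are advanced by the forward Euler method with a 1-s step.
Model fits minimize the residual sum of squares against the measured ΔF/F0
(or estimated calcium) trace, and families are compared with
BIC = N·ln(RSS/N) + M·ln(N).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .odor_field import ConcentrationSeries, central_difference

EULER_DT_S = 1.0
#: τ at or above this bound is reported as the pure-integrator limit τ→∞.
TAU_UPPER_BOUND_S = 1e4
#: GCaMP3 calcium dissociation constant (nM).
DEFAULT_KD_NM = 405.0
#: GCaMP3 Hill coefficient; not printed in the source study (cited from the
#: indicator characterization) — ≈2.1 reproduces the printed basal calcium.
DEFAULT_HILL_H = 2.1
#: GCaMP3 dynamic range Fmax/Fmin used as the fitting constraint.
GCAMP3_DYNAMIC_RANGE = 12.0

FAMILIES = ("differential", "leaky", "leaky_delayed", "leaky_generalized")

#: Free-parameter counts per family for BIC: k; (k, τ); (k, τ, Δt);
#: (k, τ, fmin, X_base).
N_FREE_PARAMS = {
    "differential": 1,
    "leaky": 2,
    "leaky_delayed": 3,
    "leaky_generalized": 4,
}


class NeuralModelError(ValueError):
    """Raised for invalid model parameters or trace inputs."""


class HillRangeError(NeuralModelError):
    """ΔF/F0 outside the indicator's dynamic range."""


@dataclass(frozen=True)
class ResponseModel:
    """One member of the response-model family with its parameters.

    ``input_sign`` selects whether the drive is +dC/dt (odor-up responders)
    or −dC/dt (odor-down responders).  ``tau=inf`` is the pure-integrator
    limit.
    """

    family: str
    k: float
    tau: float = np.inf
    delay_s: float = 1.0
    x_base: float = 0.0
    input_sign: int = 1

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise NeuralModelError(f"unknown family {self.family!r}")
        if self.family != "differential":
            if not (self.tau > 0):
                raise NeuralModelError("tau must be positive (inf allowed)")
        if self.family == "leaky_delayed" and self.delay_s < 1:
            raise NeuralModelError("delay must be >= 1 s")
        if self.input_sign not in (1, -1):
            raise NeuralModelError("input_sign must be +1 or -1")


@dataclass(frozen=True)
class HillParams:
    """GCaMP saturation curve: Kd (nM), Hill coefficient h and the
    baseline-relative fluorescence extremes fmin = Fmin/F0, fmax = Fmax/F0."""

    kd: float = DEFAULT_KD_NM
    h: float = DEFAULT_HILL_H
    fmin: float = 0.81
    fmax: float = 9.7

    def __post_init__(self):
        if not (0 < self.fmin < 1 < self.fmax):
            raise NeuralModelError("need fmin < 1 < fmax")
        if self.kd <= 0 or self.h <= 0:
            raise NeuralModelError("Kd and h must be positive")

    @classmethod
    def with_dynamic_range(cls, fmin: float, kd: float = DEFAULT_KD_NM,
                           h: float = DEFAULT_HILL_H) -> "HillParams":
        """Construct with the GCaMP3 constraint fmax = 12·fmin."""
        return cls(kd, h, fmin, GCAMP3_DYNAMIC_RANGE * fmin)


@dataclass(frozen=True)
class FitResult:
    """A fitted model with its goodness of fit."""

    model: ResponseModel
    rss: float
    n: int
    m: int
    bic: float
    converged: bool = True

    @property
    def tau_infinite(self) -> bool:
        return self.model.family != "differential" and \
            self.model.tau >= 0.99 * TAU_UPPER_BOUND_S


@dataclass(frozen=True)
class FluorescenceTrace:
    """Raw indicator record: cell and background intensities vs time, with
    an optional second channel for ratiometric mode."""

    time_s: np.ndarray
    f_cell: np.ndarray
    f_background: np.ndarray
    f_ch2: np.ndarray | None = None
    dff: np.ndarray | None = None
    f0: float | None = None

    def __post_init__(self):
        t = np.asarray(self.time_s, float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "f_cell", np.asarray(self.f_cell, float))
        object.__setattr__(self, "f_background",
                           np.broadcast_to(np.asarray(self.f_background, float),
                                           t.shape).copy())
        if self.f_ch2 is not None:
            object.__setattr__(self, "f_ch2", np.asarray(self.f_ch2, float))
        if self.dff is not None:
            object.__setattr__(self, "dff", np.asarray(self.dff, float))


def _moving_average(v: np.ndarray, half: int) -> np.ndarray:
    if half == 0:
        return v
    csum = np.concatenate(([0.0], np.cumsum(v)))
    idx = np.arange(v.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, v.size - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def process_fluorescence(raw: FluorescenceTrace, stimulus_onset_s: float,
                         mode: str = "dff", baseline_s: float = 60.0,
                         smooth_half_frames: int = 1) -> FluorescenceTrace:
    """Background-subtract, smooth (±1 frame) and baseline-normalize a trace.

    F0 is the mean signal over the ``baseline_s`` seconds preceding stimulus
    onset; the returned trace carries ΔF/F0 = (F − F0)/F0 (``mode='dff'``) or
    the baseline-subtracted channel ratio ΔR (``mode='ratio'``, requires a
    second channel).
    """
    t = raw.time_s
    pre = (t >= stimulus_onset_s - baseline_s) & (t < stimulus_onset_s)
    if not pre.any() or t.min() > stimulus_onset_s - baseline_s + 1e-9:
        raise NeuralModelError(f"need {baseline_s:.0f} s of pre-onset data")
    f = _moving_average(raw.f_cell - raw.f_background, smooth_half_frames)
    if mode == "ratio":
        if raw.f_ch2 is None:
            raise NeuralModelError("ratio mode requires a second channel")
        ch2 = _moving_average(raw.f_ch2 - raw.f_background, smooth_half_frames)
        if np.any(ch2 <= 0):
            raise NeuralModelError("non-positive reference channel")
        ratio = f / ch2
        r0 = float(ratio[pre].mean())
        return replace(raw, dff=ratio - r0, f0=r0)
    if mode != "dff":
        raise NeuralModelError(f"unknown mode {mode!r}")
    f0 = float(f[pre].mean())
    if f0 <= 0:
        raise NeuralModelError("baseline F0 is non-positive")
    return replace(raw, dff=(f - f0) / f0, f0=f0)


def resample_trace_1hz(time_s, values, out_time_s) -> np.ndarray:
    """Bin-average an arbitrary-rate trace onto a 1-Hz time base."""
    t = np.asarray(time_s, float)
    v = np.asarray(values, float)
    out = np.asarray(out_time_s, float)
    edges = np.concatenate((out - 0.5, [out[-1] + 0.5]))
    idx = np.digitize(t, edges) - 1
    res = np.full(out.size, np.nan)
    for i in range(out.size):
        m = idx == i
        if m.any():
            res[i] = v[m].mean()
    return res


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------

def _model_input(model: ResponseModel, stimulus: ConcentrationSeries
                 ) -> np.ndarray:
    """Per-second drive I(t) on the stimulus time base."""
    if stimulus.time_s.size >= 2 and \
            not np.allclose(np.diff(stimulus.time_s), EULER_DT_S):
        raise NeuralModelError("stimulus must be sampled at 1 Hz")
    c = stimulus.value_uM
    t = stimulus.time_s
    if model.family == "leaky_delayed":
        # C(t−Δt); times before the record are filled with the first value
        # (the stimulus plateau extends before the analysis window)
        c_delayed = np.interp(t - model.delay_s, t, c, left=c[0])
        i_drive = (c - c_delayed) / model.delay_s
    else:
        if stimulus.derivative is not None:
            i_drive = stimulus.derivative
        else:
            i_drive = central_difference(stimulus).derivative
    return model.input_sign * i_drive


def simulate_response(model: ResponseModel, stimulus: ConcentrationSeries
                      ) -> np.ndarray:
    """Model response X(t) on the stimulus time base.

    The differential model maps the drive instantaneously; the leaky family
    is advanced by forward Euler with a 1-s step from X(0) = 0 (generalized:
    X(0) = X_base).
    """
    i_drive = _model_input(model, stimulus)
    if model.family == "differential":
        return model.k * i_drive
    x = np.empty_like(i_drive)
    x[0] = model.x_base if model.family == "leaky_generalized" else 0.0
    decay = 0.0 if np.isinf(model.tau) else EULER_DT_S / model.tau
    base = model.x_base if model.family == "leaky_generalized" else 0.0
    for j in range(i_drive.size - 1):
        x[j + 1] = x[j] + EULER_DT_S * model.k * i_drive[j] - decay * (x[j] - base)
    return x


def leaky_closed_form(k: float, tau: float, i_const: float, t) -> np.ndarray:
    """Exact solution X(t) = k·I·τ·(1 − e^(−t/τ)) for constant input from
    X(0) = 0; the analytic reference for the Euler scheme."""
    t = np.asarray(t, float)
    return k * i_const * tau * (1.0 - np.exp(-t / tau))


# ---------------------------------------------------------------------------
# Hill inversion
# ---------------------------------------------------------------------------

def hill_invert(dff, p: HillParams):
    """Intracellular calcium (nM) from ΔF/F0:

        [Ca2+] = Kd·((1 + ΔF/F0 − fmin) / (fmax − 1 − ΔF/F0))^(1/h)
    """
    d = np.asarray(dff, float)
    num = 1.0 + d - p.fmin
    den = p.fmax - 1.0 - d
    if np.any(num <= 0) or np.any(den <= 0):
        raise HillRangeError("ΔF/F0 outside the indicator dynamic range")
    c = p.kd * (num / den) ** (1.0 / p.h)
    return c if c.ndim else float(c)


def hill_forward(calcium_nM, p: HillParams):
    """ΔF/F0 produced by a calcium concentration (nM); exact inverse of
    :func:`hill_invert`."""
    c = np.asarray(calcium_nM, float)
    if np.any(c < 0):
        raise NeuralModelError("calcium concentration must be non-negative")
    q = (c / p.kd) ** p.h
    d = (q * p.fmax + p.fmin) / (1.0 + q) - 1.0
    return d if d.ndim else float(d)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def compute_bic(rss: float, n: int, m: int) -> float:
    """BIC = N·ln(RSS/N) + M·ln(N); lower is better.  RSS = 0 returns −inf
    with a warning (a perfect fit dominates any penalty)."""
    if n <= m:
        raise NeuralModelError("need more samples than free parameters")
    if rss < 0:
        raise NeuralModelError("RSS must be non-negative")
    if rss == 0:
        warnings.warn("RSS = 0: BIC is -inf", RuntimeWarning, stacklevel=2)
        return -np.inf
    return float(n * np.log(rss / n) + m * np.log(n))


def _window_mask(time_s, window):
    if window is None:
        return np.ones(np.asarray(time_s).size, bool)
    t0, t1 = window
    t = np.asarray(time_s, float)
    return (t >= t0) & (t <= t1)


def _fit_linear_gain(basis: np.ndarray, target: np.ndarray) -> tuple:
    denom = float(basis @ basis)
    if denom == 0:
        return 0.0, float(target @ target)
    k = float(basis @ target) / denom
    resid = target - k * basis
    return k, float(resid @ resid)


def _leaky_profile_rss(tau, template_model, stimulus, target, mask):
    probe = replace(template_model, k=1.0, tau=tau)
    u = simulate_response(probe, stimulus)[mask]
    return _fit_linear_gain(u, target)


def fit_response(trace, stimulus: ConcentrationSeries, family: str,
                 input_sign: int | None = None, window=None,
                 delay_grid=range(1, 121), hill: HillParams | None = None
                 ) -> FitResult:
    """Least-squares fit of one model family to a response trace.

    ``trace`` is the measured ΔF/F0 (or, for ``leaky_generalized``, estimated
    calcium handled internally) aligned sample-for-sample with ``stimulus``;
    ``window`` restricts the fitted samples (default: all, conventionally
    onset −60 s through the end of the post phase).  The leaky gain k is
    profiled out in closed form and τ found by bounded scalar minimization
    (multi-start over a log-spaced grid); Δt is a joint integer grid search.
    """
    y_full = np.asarray(trace, float)
    if y_full.size != stimulus.time_s.size:
        raise NeuralModelError("trace and stimulus must be aligned")
    mask = _window_mask(stimulus.time_s, window)
    y = y_full[mask]
    n = int(y.size)
    sign = input_sign if input_sign is not None else \
        (1 if family == "differential" else -1)

    if family == "differential":
        model = ResponseModel("differential", 1.0, input_sign=sign)
        basis = simulate_response(model, stimulus)[mask]
        k, rss = _fit_linear_gain(basis, y)
        fitted = replace(model, k=k)
        return FitResult(fitted, rss, n, 1, compute_bic(rss, n, 1))

    if family in ("leaky", "leaky_delayed"):
        delays = [1.0] if family == "leaky" else list(delay_grid)
        best = None
        for d in delays:
            template = ResponseModel(family, 1.0, 10.0, delay_s=float(d),
                                     input_sign=sign)
            tau, k, rss = _optimize_tau(template, stimulus, y, mask)
            if best is None or rss < best[3]:
                best = (d, tau, k, rss)
        d, tau, k, rss = best
        m = N_FREE_PARAMS[family]
        fitted = ResponseModel(family, k, tau, delay_s=float(d), input_sign=sign)
        return FitResult(fitted, rss, n, m, compute_bic(rss, n, m))

    if family == "leaky_generalized":
        return _fit_generalized(y_full, stimulus, sign, mask, hill)

    raise NeuralModelError(f"unknown family {family!r}")


def _optimize_tau(template, stimulus, y, mask):
    """Profile k out, minimize RSS over τ (log grid + Brent refinement);
    τ at the upper bound is reported as ∞."""
    taus = np.geomspace(0.5, TAU_UPPER_BOUND_S, 80)
    profile = [_leaky_profile_rss(t, template, stimulus, y, mask) for t in taus]
    rss = np.array([p[1] for p in profile])
    i = int(np.argmin(rss))

    lo = np.log10(taus[max(i - 1, 0)])
    hi = np.log10(taus[min(i + 1, taus.size - 1)])
    sol = optimize.minimize_scalar(
        lambda lt: _leaky_profile_rss(10 ** lt, template, stimulus, y, mask)[1],
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10})
    tau = float(10 ** sol.x)
    k, best_rss = _leaky_profile_rss(tau, template, stimulus, y, mask)
    # prefer the exact pure-integrator limit if it is at least as good
    k_inf, rss_inf = _leaky_profile_rss(np.inf, template, stimulus, y, mask)
    if rss_inf <= best_rss * (1 + 1e-12) and tau > 0.5 * TAU_UPPER_BOUND_S:
        return np.inf, k_inf, rss_inf
    if tau >= 0.99 * TAU_UPPER_BOUND_S:
        return np.inf, k_inf, rss_inf
    return tau, k, best_rss


def _fit_generalized(dff_full, stimulus, sign, mask, hill):
    """Fit (k, τ, fmin, X_base) on the calcium scale with fmax = 12·fmin."""
    hill = hill or HillParams.with_dynamic_range(0.81)
    dff = dff_full[mask]
    # fmin bounds keeping every sample strictly inside the dynamic range
    fmin_lo = max((1.0 + dff.max()) / GCAMP3_DYNAMIC_RANGE + 1e-6, 1e-3)
    fmin_hi = min(1.0 + dff.min() - 1e-6, 0.999)
    if fmin_hi <= fmin_lo:
        raise HillRangeError("trace incompatible with the dynamic-range constraint")

    def residuals(p):
        k, tau, fmin, x_base = p
        hp = HillParams.with_dynamic_range(fmin, hill.kd, hill.h)
        target = hill_invert(dff, hp)
        model = ResponseModel("leaky_generalized", k, tau, x_base=x_base,
                              input_sign=sign)
        x = simulate_response(model, stimulus)[mask]
        return x - target

    f0 = float(np.clip(0.81, fmin_lo, fmin_hi))
    x_base0 = hill_invert(0.0, HillParams.with_dynamic_range(f0, hill.kd, hill.h))
    # data-driven gain scale: target calcium excursion over the integrated drive
    probe = ResponseModel("leaky_generalized", 1.0, 20.0, input_sign=sign)
    u = simulate_response(probe, stimulus)[mask]
    target0 = hill_invert(dff, HillParams.with_dynamic_range(f0, hill.kd, hill.h))
    u_span = np.ptp(u)
    k_scale = float(np.ptp(target0) / u_span) if u_span > 0 else 1.0
    starts = [
        [max(k_scale, 1e-3), 20.0, f0, x_base0],
        [max(2 * k_scale, 1e-3), 50.0, f0, x_base0],
        [max(k_scale / 2, 1e-3), 5.0, (fmin_lo + fmin_hi) / 2,
         hill_invert(0.0, HillParams.with_dynamic_range(
             (fmin_lo + fmin_hi) / 2, hill.kd, hill.h))],
    ]
    best = None
    for p0 in starts:
        sol = optimize.least_squares(
            residuals, p0,
            bounds=([0.0, 1e-2, fmin_lo, 0.0],
                    [np.inf, TAU_UPPER_BOUND_S, fmin_hi, np.inf]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        rss = float(sol.fun @ sol.fun)
        if best is None or rss < best[1]:
            best = (sol, rss)
    sol, rss = best
    k, tau, fmin, x_base = sol.x
    n = int(dff.size)
    m = N_FREE_PARAMS["leaky_generalized"]
    model = ResponseModel("leaky_generalized", float(k), float(tau),
                          x_base=float(x_base), input_sign=sign)
    res = FitResult(model, rss, n, m, compute_bic(rss, n, m),
                    converged=bool(sol.success))
    object.__setattr__(res, "fitted_fmin", float(fmin))
    return res


def compare_models(trace, stimulus: ConcentrationSeries,
                   families=("differential", "leaky"), input_sign=None,
                   window=None) -> list:
    """Fit several families to the same trace and rank them by BIC
    (ascending: best first)."""
    results = [fit_response(trace, stimulus, fam, input_sign=input_sign,
                            window=window) for fam in families]
    return sorted(results, key=lambda r: r.bic)


def ranking_table(results) -> pd.DataFrame:
    """Tabulate ranked fits with ΔBIC relative to the best model."""
    best = min(r.bic for r in results)
    return pd.DataFrame([
        {"family": r.model.family, "k": r.model.k, "tau": r.model.tau,
         "delay_s": r.model.delay_s, "rss": r.rss, "n": r.n, "m": r.m,
         "bic": r.bic, "delta_bic": r.bic - best}
        for r in sorted(results, key=lambda r: r.bic)
    ])


def compose_two_component(fast_dff, slow_model: ResponseModel,
                          stimulus: ConcentrationSeries) -> np.ndarray:
    """Two-component composite response: an empirical fast (transient) trace
    plus a simulated slow leaky-integrator component, summed pointwise."""
    fast = np.asarray(fast_dff, float)
    if fast.size != stimulus.time_s.size:
        raise NeuralModelError("fast trace and stimulus must be aligned")
    return fast + simulate_response(slow_model, stimulus)


# ---------------------------------------------------------------------------
# Reference parameter sets (printed fits, for defaults and documentation)
# ---------------------------------------------------------------------------

#: ASH ΔF/F0 time-differential gains (μM⁻¹·s) for the 45/90/180-s up ramps.
ASH_DIFFERENTIAL_K = {45: 56.1, 90: 80.9, 180: 121.9}

#: ASH slow component: leaky integrator of +dC/dt fitted to wild-type up-90.
ASH_SLOW_COMPONENT = ResponseModel("leaky", k=2.96, tau=10.4, input_sign=1)

#: AWB ΔF/F0 leaky-integrator fits (I = −dC/dt) for the down ramps.
AWB_LEAKY = {
    45: ResponseModel("leaky", k=4.6, tau=19.7, input_sign=-1),
    90: ResponseModel("leaky", k=3.6, tau=28.1, input_sign=-1),
    180: ResponseModel("leaky", k=3.0, tau=25.0, input_sign=-1),
}

#: AWB down-45 generalized fit on the calcium scale: fmin 0.81, fmax 9.7,
#: basal calcium 66.1 nM.  The published gain 0.40 is μM calcium per μM
#: odor; this package keeps calcium in nM, hence k = 400 nM·μM⁻¹.
AWB_GENERALIZED_45 = ResponseModel("leaky_generalized", k=400.0, tau=21.1,
                                   x_base=66.1, input_sign=-1)

#: odr-3(n2150) down-90 delayed-input fit: Δt = 67 s.
ODR3_N2150_DELAYED = ResponseModel("leaky_delayed", k=8.71, tau=25.2,
                                   delay_s=67.0, input_sign=-1)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def read_trace(path) -> FluorescenceTrace:
    """Read a raw trace from TSV/CSV with columns t_s, F_cell, F_background
    and optional F_ch2."""
    df = pd.read_csv(path, sep=None, engine="python")
    ch2 = df["F_ch2"].to_numpy(float) if "F_ch2" in df else None
    return FluorescenceTrace(df["t_s"].to_numpy(float),
                             df["F_cell"].to_numpy(float),
                             df["F_background"].to_numpy(float), ch2)


def fit_result_to_dict(res: FitResult) -> dict:
    return {
        "family": res.model.family, "k": res.model.k, "tau": res.model.tau,
        "delay_s": res.model.delay_s, "x_base": res.model.x_base,
        "input_sign": res.model.input_sign, "rss": res.rss, "n": res.n,
        "m": res.m, "bic": res.bic, "tau_infinite": res.tau_infinite,
    }
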