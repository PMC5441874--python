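"""Circular statistics for bearing distributions.

Two nonparametric tests on angles:

* Mardia–Watson–Wheeler uniform-scores test — do two samples of angles come
  from the same circular distribution?  Combined angles are ranked, each
  rank mapped to a uniform score β = 2π·rank/N, and the statistic
  W = 2·(R1²/n1 + R2²/n2) built from the per-sample resultants of the
  scores; under the null W is asymptotically χ²(2).  For small samples a
  seeded permutation p-value is used instead.
* Watson's U² test — is one sample of angles uniform on the circle?  The
  statistic is a rotation-invariant Cramér–von Mises discrepancy; the
  p-value uses the finite-sample-modified statistic with the classical
  alternating exponential series.

Angles are degrees, normalized into (−180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: Below this per-sample size the two-sample test switches to permutation.
SMALL_SAMPLE_N = 10
PERMUTATION_RESAMPLES = 10_000


class CircStatError(ValueError):
    """Raised for invalid angular samples."""


def normalize_angles(angles_deg) -> np.ndarray:
    """Map angles into (−180, 180]."""
    a = np.asarray(angles_deg, float)
    a = (a + 180.0) % 360.0 - 180.0
    return np.where(np.isclose(a, -180.0), 180.0, a)


@dataclass(frozen=True)
class AngularSample:
    """A sample of angles in degrees, normalized into (−180, 180]."""

    angles: np.ndarray

    def __post_init__(self):
        a = normalize_angles(self.angles)
        if a.size < 1:
            raise CircStatError("empty angular sample")
        object.__setattr__(self, "angles", a)

    @property
    def n(self) -> int:
        return int(self.angles.size)


@dataclass(frozen=True)
class CircTestResult:
    statistic: float
    p_value: float
    method: str


def _uniform_scores_w(angles: np.ndarray, labels: np.ndarray) -> float:
    """W from pooled midranks (ties averaged)."""
    n_total = angles.size
    ranks = stats.rankdata(angles, method="average")
    beta = 2.0 * np.pi * ranks / n_total
    w = 0.0
    for g in (0, 1):
        m = labels == g
        c = np.cos(beta[m]).sum()
        s = np.sin(beta[m]).sum()
        w += (c * c + s * s) / m.sum()
    return 2.0 * w


def mardia_watson_wheeler(s1: AngularSample, s2: AngularSample,
                          permutation: bool | None = None,
                          n_resamples: int = PERMUTATION_RESAMPLES,
                          seed: int = 0) -> CircTestResult:
    """Two-sample Mardia–Watson–Wheeler uniform-scores test.

    ``permutation=None`` picks the regime automatically: a seeded label
    permutation when min(n1, n2) < 10, the asymptotic χ²(2) approximation
    otherwise.
    """
    pooled = np.concatenate([s1.angles, s2.angles])
    labels = np.concatenate([np.zeros(s1.n, int), np.ones(s2.n, int)])
    w = _uniform_scores_w(pooled, labels)
    if permutation is None:
        permutation = min(s1.n, s2.n) < SMALL_SAMPLE_N
    if permutation:
        rng = np.random.default_rng(seed)
        count = 0
        lab = labels.copy()
        for _ in range(n_resamples):
            rng.shuffle(lab)
            if _uniform_scores_w(pooled, lab) >= w - 1e-12:
                count += 1
        p = (count + 1) / (n_resamples + 1)
        method = "permutation"
    else:
        if min(s1.n, s2.n) < 4:
            raise CircStatError("need n >= 4 per sample for the asymptotic test")
        p = float(stats.chi2.sf(w, df=2))
        method = "chi2"
    return CircTestResult(float(w), float(p), method)


def _watson_u2_statistic(angles: np.ndarray) -> float:
    n = angles.size
    u = np.sort(((angles % 360.0) / 360.0))
    i = np.arange(1, n + 1)
    ubar = u.mean()
    return float(np.sum((u - (2 * i - 1) / (2 * n)) ** 2)
                 - n * (ubar - 0.5) ** 2 + 1.0 / (12 * n))


def _watson_u2_pvalue(u2: float, n: int) -> float:
    """Finite-sample modification + alternating exponential series."""
    u2_mod = (u2 - 0.1 / n + 0.1 / n**2) * (1.0 + 0.8 / n)
    m = np.arange(1, 51)
    terms = (-1.0) ** (m - 1) * np.exp(-2.0 * m**2 * np.pi**2 * u2_mod)
    return float(np.clip(2.0 * terms.sum(), 0.0, 1.0))


def watson_u2(s: AngularSample, monte_carlo: bool = False,
              n_resamples: int = PERMUTATION_RESAMPLES,
              seed: int = 0) -> CircTestResult:
    """One-sample Watson's U² test of circular uniformity.

    The default p-value uses the modified-statistic series approximation;
    ``monte_carlo=True`` draws uniform samples of the same size instead.
    """
    if s.n < 8:
        raise CircStatError("need n >= 8 for Watson's U2")
    u2 = _watson_u2_statistic(s.angles)
    if monte_carlo:
        rng = np.random.default_rng(seed)
        draws = rng.uniform(0.0, 360.0, size=(n_resamples, s.n))
        null = np.array([_watson_u2_statistic(d) for d in draws])
        p = float((np.sum(null >= u2 - 1e-12) + 1) / (n_resamples + 1))
        method = "monte_carlo"
    else:
        p = _watson_u2_pvalue(u2, s.n)
        method = "series"
    return CircTestResult(u2, p, method)


def read_angles(path) -> AngularSample:
    """Read a one-column text file of angles in degrees."""
    return AngularSample(np.loadtxt(path, ndmin=1))
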