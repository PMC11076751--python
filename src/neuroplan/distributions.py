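"""Small sampling distributions used by skill profiles.

Each distribution exposes ``ppf(u)`` (inverse CDF on the open unit interval)
so the cohort simulator can drive all sampling through a Gaussian copula and
induce within-participant correlation between the pre- and post-training
assessments, and ``mean()`` for calibration checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PointMass",
    "Normal",
    "TruncatedNormal",
    "GammaFromMoments",
    "ScaledBeta",
    "CoverageTarget",
]


@dataclass(frozen=True)
class PointMass:
    """Degenerate distribution: all mass at ``value``."""

    value: float

    def ppf(self, u):
        return np.full_like(np.asarray(u, dtype=float), self.value)

    def mean(self) -> float:
        return self.value


@dataclass(frozen=True)
class Normal:
    mu: float
    sigma: float

    def ppf(self, u):
        return sps.norm.ppf(u, loc=self.mu, scale=self.sigma)

    def mean(self) -> float:
        return self.mu


@dataclass(frozen=True)
class TruncatedNormal:
    """Normal(mu, sigma) truncated to [low, high]."""

    mu: float
    sigma: float
    low: float = 0.0
    high: float = np.inf

    def ppf(self, u):
        a = (self.low - self.mu) / self.sigma
        b = (self.high - self.mu) / self.sigma
        return sps.truncnorm.ppf(u, a, b, loc=self.mu, scale=self.sigma)

    def mean(self) -> float:
        a = (self.low - self.mu) / self.sigma
        b = (self.high - self.mu) / self.sigma
        return float(sps.truncnorm.mean(a, b, loc=self.mu, scale=self.sigma))


@dataclass(frozen=True)
class GammaFromMoments:
    """Gamma distribution parameterized by its mean and standard deviation.

    Used for nonnegative error magnitudes (incision offsets, painted-area
    factors) where the target first two moments come from reported cohort
    summaries; shape k = (m/s)^2, scale = s^2/m reproduce them exactly.
    """

    m: float
    s: float

    def ppf(self, u):
        k = (self.m / self.s) ** 2
        theta = self.s**2 / self.m
        return sps.gamma.ppf(u, k, scale=theta)

    def mean(self) -> float:
        return self.m


@dataclass(frozen=True)
class ScaledBeta:
    """Beta distribution on [low, high] moment-matched to (m, s).

    Natural model for bounded percentages; raises if (m, s) are infeasible
    for the interval.
    """

    m: float
    s: float
    low: float = 0.0
    high: float = 100.0

    def _ab(self) -> tuple[float, float]:
        span = self.high - self.low
        mu = (self.m - self.low) / span
        var = (self.s / span) ** 2
        nu = mu * (1 - mu) / var - 1.0
        if nu <= 0:
            raise ValueError(f"infeasible Beta moments m={self.m}, s={self.s}")
        return mu * nu, (1 - mu) * nu

    def ppf(self, u):
        a, b = self._ab()
        return self.low + (self.high - self.low) * sps.beta.ppf(u, a, b)

    def mean(self) -> float:
        return self.m


@dataclass(frozen=True)
class CoverageTarget:
    """Marker wrapping a distribution of target tumor-coverage percentages.

    When a skill profile uses this for its painted-region shift, the
    annotation simulator samples a coverage percentage from ``dist`` and
    inverts the (monotone) displacement -> coverage map of the phantom by
    bisection, yielding the displacement in mm that realizes the target.
    """

    dist: object  # any distribution with .ppf

    def ppf(self, u):
        return self.dist.ppf(u)

    def mean(self) -> float:
        return self.dist.mean()
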