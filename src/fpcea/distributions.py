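"""Uncertain-parameter distributions calibrated to 95% interval endpoints.

Deterministic sensitivity ranges double as the 2.5th/97.5th percentiles of
the probabilistic distribution assigned to each parameter, so every family
is parameterized by quantile matching rather than by moments:

* ``lognormal`` — closed form: log-mean ``(ln lo + ln hi) / 2``,
  log-sd ``(ln hi - ln lo) / (2 z)`` with ``z = Phi^-1(0.975)``.
* ``gamma`` — the quantile ratio ``q975/q25`` is scale-free and strictly
  decreasing in the shape, so the shape is found by root bracketing and the
  scale recovered from one quantile equation.
* ``beta`` — used for counts per 1000 clients re-expressed as proportions
  (divide by the cohort size, sample, multiply back); for a fixed alpha the
  2.5th percentile is monotone in beta, giving a nested root solve.
* ``fixed`` — degenerate point mass at the base value.

Calibration is verified to 1e-8 relative error in quantile space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .exceptions import CalibrationError, SchemaError

__all__ = [
    "DistributionSpec",
    "CalibratedDistribution",
    "calibrate_distribution",
    "sample",
    "FAMILIES",
]

FAMILIES = ("lognormal", "gamma", "beta", "fixed")

#: z-score of the 97.5th normal percentile, fixing the 95% interval convention.
_Z975 = float(stats.norm.ppf(0.975))

#: relative tolerance required of the calibrated quantiles
_QTOL = 1e-8


@dataclass(frozen=True)
class DistributionSpec:
    """Point estimate, 95% interval and probability family of one parameter.

    Parameters
    ----------
    name
        Dotted identifier, e.g. ``"svc.intervention.implant"``.
    base
        Deterministic point estimate, in natural units.
    lo, hi
        Lower/upper deterministic range, interpreted as the 2.5th/97.5th
        percentile of the probabilistic distribution.
    family
        One of :data:`FAMILIES`.
    units
        Free-text units, for reporting only.
    scale
        Divisor mapping the natural units onto the distribution's support;
        only used by the beta family (counts per 1000 -> proportion uses
        ``scale=1000``).
    """

    name: str
    base: float
    lo: float
    hi: float
    family: str
    units: str = ""
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise SchemaError(
                f"{self.name}: unknown distribution family {self.family!r}"
            )
        for attr in ("base", "lo", "hi"):
            v = getattr(self, attr)
            if not math.isfinite(v):
                raise SchemaError(f"{self.name}: {attr} is not finite")
        if not self.lo <= self.base <= self.hi:
            raise SchemaError(
                f"{self.name}: requires lo <= base <= hi, got "
                f"({self.lo}, {self.base}, {self.hi})"
            )
        if self.scale <= 0:
            raise SchemaError(f"{self.name}: scale must be positive")
        if self.family == "beta" and not (
            0.0 <= self.lo / self.scale and self.hi / self.scale <= 1.0
        ):
            raise SchemaError(
                f"{self.name}: beta bounds outside (0,1) after /{self.scale} rescale"
            )

    @property
    def is_degenerate(self) -> bool:
        return self.lo == self.hi


@dataclass(frozen=True)
class CalibratedDistribution:
    """A :class:`DistributionSpec` with solved shape parameters.

    ``a``/``b`` mean log-mean/log-sd (lognormal), shape/scale (gamma) or
    alpha/beta (beta); they are unused for the fixed family.
    """

    spec: DistributionSpec
    a: float = 0.0
    b: float = 0.0
    _frozen: stats.rv_continuous = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        family = self.spec.family
        if family == "lognormal":
            frozen = stats.lognorm(self.b, scale=math.exp(self.a))
        elif family == "gamma":
            frozen = stats.gamma(self.a, scale=self.b)
        elif family == "beta":
            frozen = stats.beta(self.a, self.b)
        else:
            frozen = None
        object.__setattr__(self, "_frozen", frozen)

    def ppf(self, q: float) -> float:
        """Quantile in the parameter's natural units."""
        if self.spec.family == "fixed":
            return self.spec.base
        x = float(self._frozen.ppf(q))
        return x * self.spec.scale if self.spec.family == "beta" else x

    def cdf(self, x):
        """CDF evaluated in the parameter's natural units (vectorized)."""
        if self.spec.family == "fixed":
            return (np.asarray(x, dtype=float) >= self.spec.base).astype(float)
        if self.spec.family == "beta":
            x = np.asarray(x, dtype=float) / self.spec.scale
        return self._frozen.cdf(x)

    def sample(self, rng: np.random.Generator, size=None):
        """Draw from the calibrated distribution in natural units."""
        family = self.spec.family
        if family == "fixed":
            out = np.full(size, self.spec.base) if size else self.spec.base
            return out
        if family == "lognormal":
            return rng.lognormal(self.a, self.b, size)
        if family == "gamma":
            return rng.gamma(self.a, self.b, size)
        return rng.beta(self.a, self.b, size) * self.spec.scale


def _calibrate_lognormal(spec: DistributionSpec) -> CalibratedDistribution:
    if spec.lo <= 0:
        raise CalibrationError(f"{spec.name}: lognormal requires lo > 0")
    mu = (math.log(spec.lo) + math.log(spec.hi)) / 2.0
    sd = (math.log(spec.hi) - math.log(spec.lo)) / (2.0 * _Z975)
    return CalibratedDistribution(spec, mu, sd)


def _calibrate_gamma(spec: DistributionSpec) -> CalibratedDistribution:
    if spec.lo <= 0:
        raise CalibrationError(f"{spec.name}: gamma requires lo > 0")
    ratio = spec.hi / spec.lo

    def f(log_shape: float) -> float:
        k = math.exp(log_shape)
        with np.errstate(divide="ignore"):
            return stats.gamma.ppf(0.975, k) / stats.gamma.ppf(0.025, k) - ratio

    # The quantile ratio falls from huge values at small shape towards 1 as
    # the shape grows; bracket on log-shape.
    try:
        log_k = optimize.brentq(f, math.log(1e-4), math.log(1e7), xtol=1e-13)
    except ValueError as exc:  # pragma: no cover - extreme ratios only
        raise CalibrationError(f"{spec.name}: gamma shape bracketing failed") from exc
    k = math.exp(log_k)
    scale = spec.lo / float(stats.gamma.ppf(0.025, k))
    return CalibratedDistribution(spec, k, scale)


def _calibrate_beta(spec: DistributionSpec) -> CalibratedDistribution:
    lo, hi = spec.lo / spec.scale, spec.hi / spec.scale
    if not (0.0 < lo and hi < 1.0):
        raise CalibrationError(
            f"{spec.name}: beta requires bounds strictly inside (0,1) "
            f"after /{spec.scale} rescale"
        )

    def beta_for_alpha(alpha: float) -> float:
        g = lambda b: stats.beta.ppf(0.025, alpha, b) - lo
        return optimize.brentq(g, 1e-8, 1e9, xtol=1e-14)

    def outer(log_alpha: float) -> float:
        alpha = math.exp(log_alpha)
        return stats.beta.ppf(0.975, alpha, beta_for_alpha(alpha)) - hi

    try:
        log_a = optimize.brentq(outer, math.log(1e-3), math.log(1e6), xtol=1e-13)
    except ValueError as exc:
        raise CalibrationError(f"{spec.name}: beta calibration failed") from exc
    alpha = math.exp(log_a)
    return CalibratedDistribution(spec, alpha, beta_for_alpha(alpha))


def calibrate_distribution(spec: DistributionSpec) -> CalibratedDistribution:
    """Solve shape parameters so that q2.5 = ``lo`` and q97.5 = ``hi``.

    Raises
    ------
    CalibrationError
        For a degenerate interval (``lo == hi``), unsupported support
        (non-positive ``lo`` for lognormal/gamma, beta bounds outside the
        unit interval) or failure to converge to 1e-8 relative quantile
        error.
    """
    if spec.family == "fixed":
        return CalibratedDistribution(spec)
    if spec.is_degenerate:
        raise CalibrationError(
            f"{spec.name}: degenerate interval lo == hi == {spec.lo}; "
            "use family 'fixed' for point-mass parameters"
        )
    dist = {
        "lognormal": _calibrate_lognormal,
        "gamma": _calibrate_gamma,
        "beta": _calibrate_beta,
    }[spec.family](spec)
    for q, target in ((0.025, spec.lo), (0.975, spec.hi)):
        err = abs(dist.ppf(q) - target) / abs(target)
        if err > _QTOL:
            raise CalibrationError(
                f"{spec.name}: quantile match residual {err:.2e} exceeds {_QTOL}"
            )
    return dist


def sample(dist: CalibratedDistribution, rng: np.random.Generator, size=None):
    """Functional alias for :meth:`CalibratedDistribution.sample`."""
    return dist.sample(rng, size)
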