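"""Inter-event-time distribution (IED) families.

Every family exposes the same renewal-theory quartet

* ``density(t)``   -- the waiting-time density psi(t),
* ``survival(t)``  -- Psi(t) = 1 - F(t),
* ``rate(t)``      -- the hazard (instantaneous rate) lambda(t) = psi / Psi,
* ``sample(n,rng)``-- exact inverse-CDF (or library) draws, used as the
  independent ground-truth oracle when validating the simulation engine.

Each family also declares how its hazard can be bounded from above
(``scenario``), which is what the rejection engine needs to maintain a
dominating rate in O(1):

* ``bounded``              -- a finite constant B >= lambda(t) exists,
* ``increasing_unbounded`` -- lambda grows without bound but monotonically,
  so the oldest clock in the system dominates,
* ``decreasing_unbounded`` -- lambda diverges at the origin; refused by the
  engine unless the user supplies an explicit bound,
* ``piecewise``            -- user-supplied interval bounds.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np
from scipy import integrate, optimize, special, stats

__all__ = [
    "HazardError",
    "IED",
    "ExponentialIED",
    "GammaIED",
    "ParetoIED",
    "WeibullIED",
    "LognormalIED",
    "DelayedExponentialIED",
    "PiecewiseHazard",
    "hazard",
    "median",
    "characteristic_rate",
    "sample_oracle",
    "gamma_hazard",
]

BOUNDED = "bounded"
INCREASING = "increasing_unbounded"
DECREASING = "decreasing_unbounded"
PIECEWISE = "piecewise"


class HazardError(ValueError):
    """Invalid IED parameters or an evaluation outside the support."""


class IED:
    """Base class for inter-event-time distributions."""

    scenario: str = BOUNDED

    # -- renewal quartet -------------------------------------------------
    def rate(self, t: float) -> float:
        raise NotImplementedError

    def density(self, t):
        raise NotImplementedError

    def survival(self, t):
        raise NotImplementedError

    def cdf(self, t):
        return 1.0 - self.survival(t)

    def ppf(self, q):
        raise NotImplementedError

    # -- bound management ------------------------------------------------
    def bound(self) -> float:
        """A finite constant dominating the hazard, if one exists."""
        raise HazardError(f"{type(self).__name__} has no finite hazard bound")

    # -- oracle ----------------------------------------------------------
    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Exact samples from psi, independent of the simulation engine."""
        return self.ppf(rng.random(n))

    def mean(self) -> float:
        raise NotImplementedError

    def median(self) -> float:
        return float(self.ppf(0.5))


class ExponentialIED(IED):
    """Memoryless waiting time: constant hazard ``rate``."""

    scenario = BOUNDED

    def __init__(self, rate: float):
        if rate <= 0:
            raise HazardError(f"exponential rate must be positive, got {rate}")
        self.rate_constant = float(rate)
        self._dist = stats.expon(scale=1.0 / rate)

    def rate(self, t):
        return self.rate_constant * np.ones_like(np.asarray(t, dtype=float))[()] \
            if np.ndim(t) else self.rate_constant

    def density(self, t):
        return self._dist.pdf(t)

    def survival(self, t):
        return self._dist.sf(t)

    def ppf(self, q):
        return self._dist.ppf(q)

    def bound(self):
        return self.rate_constant

    def mean(self):
        return 1.0 / self.rate_constant

    def __repr__(self):
        return f"ExponentialIED(rate={self.rate_constant})"


def gamma_hazard(t, shape: float, rate: float):
    """Gamma hazard psi/(1-F) evaluated stably in log space.

    Uses the regularized upper incomplete gamma function so that the ratio
    does not overflow at large ``t`` (both psi and the survival decay like
    exp(-rate*t); their log-difference stays finite and tends to ``rate``
    for shape 1, ``shape_asymptote`` otherwise).
    """
    def _asymptotic(x):
        # Gamma(s, x) ~ x^(s-1) e^-x [1 + (s-1)/x + (s-1)(s-2)/x^2 + ...]
        s1, s2 = shape - 1.0, (shape - 1.0) * (shape - 2.0)
        return rate / (1.0 + s1 / x + s2 / (x * x))

    t = np.asarray(t, dtype=float)
    if t.ndim == 0:
        if t <= 0:
            # hazard vanishes at the origin for shape > 1, diverges for < 1
            return 0.0 if shape > 1 else (rate if shape == 1 else np.inf)
        x = rate * float(t)
        if x > 500.0:       # survival underflows; use the asymptotic ratio
            return float(_asymptotic(x))
        lognum = shape * math.log(rate) + (shape - 1) * math.log(t) \
            - rate * t - special.gammaln(shape)
        logden = np.log(special.gammaincc(shape, rate * t))
        return float(np.exp(lognum - logden))
    out = np.zeros_like(t)
    x = rate * t
    mid = (t > 0) & (x <= 500.0)
    far = x > 500.0
    tp = t[mid]
    with np.errstate(divide="ignore"):
        lognum = shape * np.log(rate) + (shape - 1) * np.log(tp) \
            - rate * tp - special.gammaln(shape)
        logden = np.log(special.gammaincc(shape, rate * tp))
    out[mid] = np.exp(lognum - logden)
    if np.any(far):
        out[far] = _asymptotic(x[far])
    if shape < 1:
        out[t <= 0] = np.inf
    elif shape == 1:
        out[t <= 0] = rate
    return out


class GammaIED(IED):
    """Gamma waiting time parameterized by its hazard plateau.

    ``shape`` is the Gamma shape parameter and ``rate_scale`` (lambda_0) the
    reciprocal mean: the Gamma rate is ``shape * rate_scale`` so the mean
    waiting time is ``1 / rate_scale`` regardless of shape.  For shape > 1
    the hazard rises from 0 at the origin to the asymptote
    ``shape * rate_scale``, which serves as the channel's bound.
    """

    def __init__(self, shape: float, rate_scale: float):
        if shape <= 0 or rate_scale <= 0:
            raise HazardError(
                f"gamma shape and rate_scale must be positive, got "
                f"shape={shape}, rate_scale={rate_scale}")
        self.shape = float(shape)
        self.rate_scale = float(rate_scale)
        self.gamma_rate = self.shape * self.rate_scale
        self._dist = stats.gamma(a=self.shape, scale=1.0 / self.gamma_rate)
        self.scenario = BOUNDED if shape >= 1 else DECREASING

    def rate(self, t):
        return gamma_hazard(t, self.shape, self.gamma_rate)

    def density(self, t):
        return self._dist.pdf(t)

    def survival(self, t):
        return self._dist.sf(t)

    def ppf(self, q):
        return self._dist.ppf(q)

    def bound(self):
        if self.shape < 1:
            raise HazardError(
                "gamma hazard with shape < 1 decreases without bound at the "
                "origin; supply an explicit lambda_max to override")
        return self.gamma_rate  # monotone increasing to the asymptote

    def mean(self):
        return 1.0 / self.rate_scale

    def __repr__(self):
        return f"GammaIED(shape={self.shape}, rate_scale={self.rate_scale})"


class ParetoIED(IED):
    """Pareto waiting time: psi(t) = a*t_min^a / t^(a+1) on t >= t_min.

    The hazard is a/t for t >= t_min and 0 before (no event can occur inside
    the support gap), hence bounded by a/t_min.  Because the mean diverges for
    a <= 1, the characteristic rate is defined through the median,
    t_med = t_min * 2^(1/a), which stays finite for every a > 0.
    """

    scenario = BOUNDED

    def __init__(self, t_min: float, alpha: float):
        if t_min <= 0 or alpha <= 0:
            raise HazardError(
                f"Pareto t_min and alpha must be positive, got "
                f"t_min={t_min}, alpha={alpha}")
        self.t_min = float(t_min)
        self.alpha = float(alpha)

    @classmethod
    def from_characteristic_rate(cls, rate: float, alpha: float) -> "ParetoIED":
        """Invert t_med = t_min*2^(1/alpha), rate = 1/t_med for t_min."""
        if rate <= 0:
            raise HazardError(f"characteristic rate must be positive, got {rate}")
        return cls(t_min=2.0 ** (-1.0 / alpha) / rate, alpha=alpha)

    def rate(self, t):
        t = np.asarray(t, dtype=float)
        out = np.where(t >= self.t_min, self.alpha / np.maximum(t, self.t_min), 0.0)
        return float(out) if out.ndim == 0 else out

    def density(self, t):
        t = np.asarray(t, dtype=float)
        with np.errstate(divide="ignore"):
            out = np.where(
                t >= self.t_min,
                self.alpha * self.t_min ** self.alpha
                / np.maximum(t, self.t_min) ** (self.alpha + 1), 0.0)
        return float(out) if out.ndim == 0 else out

    def survival(self, t):
        t = np.asarray(t, dtype=float)
        out = np.where(t >= self.t_min,
                       (self.t_min / np.maximum(t, self.t_min)) ** self.alpha, 1.0)
        return float(out) if out.ndim == 0 else out

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        out = self.t_min * (1.0 - q) ** (-1.0 / self.alpha)
        return float(out) if out.ndim == 0 else out

    def bound(self):
        return self.alpha / self.t_min

    def mean(self):
        if self.alpha <= 1:
            return math.inf
        return self.alpha * self.t_min / (self.alpha - 1)

    def median(self):
        return self.t_min * 2.0 ** (1.0 / self.alpha)

    def characteristic_rate(self):
        """Reciprocal median: 2^(-1/alpha)/t_min, finite for all alpha > 0."""
        return 1.0 / self.median()

    def __repr__(self):
        return f"ParetoIED(t_min={self.t_min}, alpha={self.alpha})"


class WeibullIED(IED):
    """Weibull waiting time; hazard (k/s)*(t/s)^(k-1).

    Monotone increasing and unbounded for shape k > 1 (bound tracked through
    the oldest clock in the engine), decreasing and unbounded for k < 1
    (refused without an explicit bound), constant for k = 1.
    """

    def __init__(self, shape: float, scale: float):
        if shape <= 0 or scale <= 0:
            raise HazardError(
                f"Weibull shape and scale must be positive, got "
                f"shape={shape}, scale={scale}")
        self.shape = float(shape)
        self.scale = float(scale)
        self._dist = stats.weibull_min(c=shape, scale=scale)
        if shape > 1:
            self.scenario = INCREASING
        elif shape < 1:
            self.scenario = DECREASING
        else:
            self.scenario = BOUNDED

    def rate(self, t):
        t = np.asarray(t, dtype=float)
        with np.errstate(divide="ignore"):
            out = (self.shape / self.scale) * \
                np.power(np.maximum(t, 0.0) / self.scale, self.shape - 1.0)
        return float(out) if out.ndim == 0 else out

    def density(self, t):
        return self._dist.pdf(t)

    def survival(self, t):
        return self._dist.sf(t)

    def ppf(self, q):
        return self._dist.ppf(q)

    def bound(self):
        if self.shape == 1:
            return 1.0 / self.scale
        raise HazardError(
            "Weibull hazard with shape != 1 is unbounded; the engine tracks "
            "it through the oldest clock (shape > 1) or requires an explicit "
            "lambda_max (shape < 1)")

    def mean(self):
        return float(self._dist.mean())

    def __repr__(self):
        return f"WeibullIED(shape={self.shape}, scale={self.scale})"


class LognormalIED(IED):
    """Log-normal waiting time; hazard rises to a finite peak then decays."""

    scenario = BOUNDED

    def __init__(self, mu: float, sigma: float):
        if sigma <= 0:
            raise HazardError(f"lognormal sigma must be positive, got {sigma}")
        self.mu = float(mu)
        self.sigma = float(sigma)
        self._dist = stats.lognorm(s=sigma, scale=math.exp(mu))
        self._bound = self._find_bound()

    def _find_bound(self) -> float:
        # hazard is unimodal; bracket the peak on a log-spaced grid then polish
        grid = np.exp(np.linspace(self.mu - 8 * self.sigma,
                                  self.mu + 8 * self.sigma, 400))
        vals = self.rate(grid)
        k = int(np.argmax(vals))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(lambda t: -self.rate(t),
                                       bounds=(lo, hi), method="bounded")
        return float(max(vals[k], -res.fun)) * (1.0 + 1e-9)

    def rate(self, t):
        t = np.asarray(t, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(t > 0, self._dist.pdf(t) / self._dist.sf(t), 0.0)
        return float(out) if out.ndim == 0 else out

    def density(self, t):
        return self._dist.pdf(t)

    def survival(self, t):
        return self._dist.sf(t)

    def ppf(self, q):
        return self._dist.ppf(q)

    def bound(self):
        return self._bound

    def mean(self):
        return float(self._dist.mean())

    def __repr__(self):
        return f"LognormalIED(mu={self.mu}, sigma={self.sigma})"


class DelayedExponentialIED(IED):
    """Exponential clock that only starts ticking after a hard delay."""

    scenario = BOUNDED

    def __init__(self, delay: float, rate: float):
        if delay < 0 or rate <= 0:
            raise HazardError(
                f"delay must be >= 0 and rate > 0, got delay={delay}, rate={rate}")
        self.delay = float(delay)
        self.rate_constant = float(rate)

    def rate(self, t):
        t = np.asarray(t, dtype=float)
        out = np.where(t >= self.delay, self.rate_constant, 0.0)
        return float(out) if out.ndim == 0 else out

    def density(self, t):
        t = np.asarray(t, dtype=float)
        out = np.where(t >= self.delay,
                       self.rate_constant
                       * np.exp(-self.rate_constant * np.maximum(t - self.delay, 0.0)),
                       0.0)
        return float(out) if out.ndim == 0 else out

    def survival(self, t):
        t = np.asarray(t, dtype=float)
        out = np.where(t >= self.delay,
                       np.exp(-self.rate_constant * np.maximum(t - self.delay, 0.0)),
                       1.0)
        return float(out) if out.ndim == 0 else out

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        out = self.delay - np.log1p(-q) / self.rate_constant
        return float(out) if out.ndim == 0 else out

    def bound(self):
        return self.rate_constant

    def mean(self):
        return self.delay + 1.0 / self.rate_constant

    def __repr__(self):
        return (f"DelayedExponentialIED(delay={self.delay}, "
                f"rate={self.rate_constant})")


class PiecewiseHazard(IED):
    """Custom hazard given as a callable, with a user-supplied bound.

    The density is reconstructed numerically from the renewal identity
    psi(t) = lambda(t) * exp(-integral_0^t lambda); sampling inverts the
    survival by bisection.  Intended for hazards fitted to data.
    """

    scenario = PIECEWISE

    def __init__(self, rate_fn: Callable[[float], float], bound: float,
                 t_max: float = np.inf):
        if bound <= 0:
            raise HazardError(f"piecewise bound must be positive, got {bound}")
        self._rate_fn = rate_fn
        self._bound = float(bound)
        self.t_max = t_max

    def rate(self, t):
        if np.ndim(t):
            return np.array([self._rate_fn(float(x)) for x in np.asarray(t)])
        return float(self._rate_fn(float(t)))

    def cumulative_hazard(self, t: float) -> float:
        val, _ = integrate.quad(self._rate_fn, 0.0, t, limit=200)
        return val

    def survival(self, t):
        if np.ndim(t):
            return np.exp([-self.cumulative_hazard(float(x)) for x in np.asarray(t)])
        return math.exp(-self.cumulative_hazard(float(t)))

    def density(self, t):
        return self.rate(t) * self.survival(t)

    def ppf(self, q):
        def _one(qi: float) -> float:
            target = -math.log1p(-qi)
            hi = 1.0
            while self.cumulative_hazard(hi) < target:
                hi *= 2.0
                if hi > 1e12:
                    return math.inf
            return optimize.brentq(
                lambda t: self.cumulative_hazard(t) - target, 0.0, hi)
        if np.ndim(q):
            return np.array([_one(float(x)) for x in np.asarray(q)])
        return _one(float(q))

    def bound(self):
        return self._bound


# ---------------------------------------------------------------------------
# Functional aliases matching the operation-level interface.

def hazard(ied: IED, t):
    """Instantaneous rate lambda(t) of an IED."""
    return ied.rate(t)


def median(ied: IED) -> float:
    return ied.median()


def characteristic_rate(ied: IED) -> float:
    """Reciprocal median inter-event time (finite even for heavy tails)."""
    if isinstance(ied, ParetoIED):
        return ied.characteristic_rate()
    return 1.0 / ied.median()


def sample_oracle(ied: IED, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Exact ground-truth samples from psi, bypassing the engine entirely."""
    if n < 1:
        raise HazardError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return np.asarray(ied.sample(n, rng), dtype=float)
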