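"""Seasonal environment of the breeding grounds.

Two opposing logistic curves of arrival date ``x`` set up the central
trade-off for a long-distance migrant:

* expected reproductive output ``R(x) = R0 / (1 + exp((x - r)/sigma_R))``
  *decreases* with arrival date, because late arrival means breeding after
  the seasonal food peak; ``r`` is the half-saturation date and serves as a
  proxy for the food-peak date, while ``sigma_R`` measures the width of the
  temporal resource distribution (small = narrow peak, sharp decline).

* pre-breeding survival ``S(x) = S0 / (1 + exp(-(x - s)/sigma_S))``
  *increases* with arrival date, because early migration is exposed to
  harsh pre-spring conditions; ``s`` is the onset of spring and ``sigma_S``
  controls how fast conditions improve.

Arrival dates of individuals in a cohort with mean arrival date ``mu`` are
uniformly distributed over the window ``[mu - v/2, mu + v/2]``.

Time is measured in dimensionless season units ("days") centred near 0; at
the reference parameterisation spring onset sits at ``s = -1`` and the food
peak at ``r = +1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "SeasonalParams",
    "ArrivalDistribution",
    "reproductive_success",
    "prebreeding_survival",
    "arrival_density",
    "survival_mass",
]


@dataclass(frozen=True)
class SeasonalParams:
    """Constants of the seasonal environment.

    Defaults are the reference baseline used throughout the package.

    Parameters
    ----------
    r : float
        Food-peak date (half-saturation of the reproduction curve), days.
    sigma_R : float
        Resource-distribution width, days; must be positive.
    R0 : float
        Maximal reproductive output (offspring per capita in the best
        territory); must be positive.
    s : float
        Onset of spring (half-saturation of pre-breeding survival), days.
    sigma_S : float
        Survival-improvement rate parameter, days; must be positive.
    S0 : float
        Maximal pre-breeding survival probability, in (0, 1].
    """

    r: float = 1.0
    sigma_R: float = 0.1
    R0: float = 3.0
    s: float = -1.0
    sigma_S: float = 0.4
    S0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("r", "sigma_R", "R0", "s", "sigma_S", "S0"):
            val = getattr(self, name)
            if not np.isfinite(val):
                raise ValueError(f"SeasonalParams.{name} must be finite, got {val!r}")
        if self.sigma_R <= 0:
            raise ValueError(f"sigma_R must be > 0, got {self.sigma_R}")
        if self.sigma_S <= 0:
            raise ValueError(f"sigma_S must be > 0, got {self.sigma_S}")
        if self.R0 <= 0:
            raise ValueError(f"R0 must be > 0, got {self.R0}")
        if not (0.0 < self.S0 <= 1.0):
            raise ValueError(f"S0 must be in (0, 1], got {self.S0}")


@dataclass(frozen=True)
class ArrivalDistribution:
    """Uniform distribution of arrival dates over [mu - v/2, mu + v/2].

    ``mu`` is the (evolving) mean arrival date; ``v`` is the fixed length of
    the arrival window, representing environmentally induced spread.
    """

    mu: float
    v: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise ValueError(f"mu must be finite, got {self.mu!r}")
        if not (np.isfinite(self.v) and self.v > 0):
            raise ValueError(f"v must be positive and finite, got {self.v!r}")

    @property
    def lo(self) -> float:
        return self.mu - self.v / 2.0

    @property
    def hi(self) -> float:
        return self.mu + self.v / 2.0


def _check_dates(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("arrival date(s) must be finite")
    return x


def reproductive_success(x, p: SeasonalParams):
    """Expected reproductive output R(x) in the best available territory.

    Decreasing logistic with half-saturation at the food-peak date ``p.r``:
    ``R(x) = R0 / (1 + exp((x - r)/sigma_R))``.
    """
    x = _check_dates(x)
    out = p.R0 * expit(-(x - p.r) / p.sigma_R)
    return out if out.ndim else float(out)


def prebreeding_survival(x, p: SeasonalParams):
    """Pre-breeding survival probability S(x) for arrival at date ``x``.

    Increasing logistic with half-saturation at the onset of spring ``p.s``:
    ``S(x) = S0 / (1 + exp(-(x - s)/sigma_S))``.
    """
    x = _check_dates(x)
    out = p.S0 * expit((x - p.s) / p.sigma_S)
    return out if out.ndim else float(out)


def arrival_density(x, d: ArrivalDistribution):
    """Uniform arrival density g_mu(x): 1/v inside the window, 0 outside."""
    x = _check_dates(x)
    out = np.where((x >= d.lo) & (x <= d.hi), 1.0 / d.v, 0.0)
    return out if out.ndim else float(out)


def survival_mass(a, b, p: SeasonalParams):
    """Closed-form integral of the survival curve, ``int_a^b S(u) du``.

    Uses the logistic antiderivative
    ``S0 * sigma_S * ln(1 + exp((u - s)/sigma_S))`` evaluated through
    ``log1p(exp(.))`` in its numerically stable softplus form, so the result
    matches adaptive quadrature to near machine precision for any interval.
    """
    a = _check_dates(a)
    b = _check_dates(b)
    if np.any(a > b):
        raise ValueError("survival_mass requires a <= b")
    ta = (a - p.s) / p.sigma_S
    tb = (b - p.s) / p.sigma_S
    out = p.S0 * p.sigma_S * (np.logaddexp(0.0, tb) - np.logaddexp(0.0, ta))
    return out if out.ndim else float(out)
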