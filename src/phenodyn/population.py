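"""Within-year territory competition and the between-year population map.

A monomorphic resident cohort of density ``n`` (returning migrants, arbitrary
density units) arrives uniformly over the window ``[mu - v/2, mu + v/2]``.
Arrivals survive the pre-breeding period with probability ``S(x)`` and then
settle territories by prior residency: the accumulated density of surviving
settlers ``n_S(x)`` degrades the quality ``Q(x)`` of the best territory still
free, linearly down to zero at density ``1/q_c``.  Per-capita reproductive
output at date ``x`` is ``R(x) * Q(x)``.

The between-year map combines winter survival of adults (``s_A``) and of the
juveniles produced before winter (``s_J = k * s_A`` with ``k < 1``):

    n_{t+1} = s_A * N_S + k * s_A * B

where ``N_S`` is the total density of surviving arrivals and ``B`` the
density of recruits produced.  Its fixed point, found by direct iteration,
is the ecological equilibrium for a given mean arrival date.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .seasonal import (
    SeasonalParams,
    prebreeding_survival,
    reproductive_success,
    survival_mass,
)

__all__ = [
    "DemographyParams",
    "AnnualState",
    "EquilibriumResult",
    "SolverOptions",
    "cumulative_survivors",
    "total_survivors",
    "territory_quality",
    "recruits",
    "annual_update",
    "fraction_young",
    "ecological_equilibrium",
]

# quadrature tolerances used for every within-season integral
_EPSABS = 1e-13
_EPSREL = 1e-11


@dataclass(frozen=True)
class DemographyParams:
    """Demography and competition constants.

    Parameters
    ----------
    s_A : float
        Adult winter survival probability, in (0, 1].
    k : float
        Juvenile-to-adult winter-survival ratio (s_J = k * s_A), in (0, 1).
    q_c : float
        Rate of linear territory-quality decline per unit settled density;
        q_c = 1 at baseline sets the density scale.
    v : float
        Length of the arrival window, days.
    """

    s_A: float = 0.5
    k: float = 0.5
    q_c: float = 1.0
    v: float = 0.5

    def __post_init__(self) -> None:
        for name in ("s_A", "k", "q_c", "v"):
            val = getattr(self, name)
            if not np.isfinite(val):
                raise ValueError(f"DemographyParams.{name} must be finite, got {val!r}")
        if not (0.0 < self.s_A <= 1.0):
            raise ValueError(f"s_A must be in (0, 1], got {self.s_A}")
        if not (0.0 < self.k < 1.0):
            raise ValueError(f"k must be in (0, 1), got {self.k}")
        if self.q_c < 0:
            raise ValueError(f"q_c must be >= 0, got {self.q_c}")
        if self.v <= 0:
            raise ValueError(f"v must be > 0, got {self.v}")


@dataclass(frozen=True)
class AnnualState:
    """Resident population at the start of a season: density and strategy."""

    n: float
    mu: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.n) and self.n >= 0):
            raise ValueError(f"density n must be finite and >= 0, got {self.n!r}")
        if not np.isfinite(self.mu):
            raise ValueError(f"mu must be finite, got {self.mu!r}")


@dataclass(frozen=True)
class EquilibriumResult:
    """Outcome of iterating the annual map for a fixed strategy.

    ``f_star`` is NaN when the population is extinct (fraction of young is
    undefined for an empty population).
    """

    n_star: float
    f_star: float
    converged: bool
    extinct: bool
    iterations: int


@dataclass(frozen=True)
class SolverOptions:
    """Iteration and root-finding controls shared across the package.

    ``max_iter`` defaults to the canonical 1000 annual time steps; the
    tolerance and extinction threshold make termination status explicit.
    """

    n0: float = 1.0
    max_iter: int = 1000
    tol: float = 1e-10
    extinction_threshold: float = 1e-12
    bracket: Optional[tuple] = None
    root_xtol: float = 1e-10
    fd_step: float = 1e-4
    grid_points: int = 201
    stability_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.n0 <= 0:
            raise ValueError("initial density n0 must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0 or self.extinction_threshold <= 0:
            raise ValueError("tolerances must be positive")


def _window(state: AnnualState, dp: DemographyParams) -> tuple[float, float]:
    return state.mu - dp.v / 2.0, state.mu + dp.v / 2.0


def cumulative_survivors(x, state: AnnualState, sp: SeasonalParams, dp: DemographyParams):
    """Accumulated density n_S(x) of arrived-and-survived residents by date x.

    Zero before the window opens, flat after it closes; non-decreasing and
    continuous in between.  Uses the closed-form survival integral.
    """
    lo, hi = _window(state, dp)
    xc = np.clip(np.asarray(x, dtype=float), lo, hi)
    out = state.n / dp.v * survival_mass(lo, xc, sp)
    return out if np.ndim(x) else float(out)


def total_survivors(state: AnnualState, sp: SeasonalParams, dp: DemographyParams) -> float:
    """Total density N_S of residents alive after all arrivals are complete."""
    lo, hi = _window(state, dp)
    return float(cumulative_survivors(hi, state, sp, dp))


def territory_quality(x, state: AnnualState, sp: SeasonalParams, dp: DemographyParams):
    """Territory quality Q(x) = max(0, 1 - q_c * n_S(x)), clamped outside the window.

    Q is the prior-residency discount on reproduction: the best free
    territory at date x.  Outside the resident arrival window Q is held at
    its boundary value (rare variants arriving there face the same best
    free territory as at the nearer window edge).
    """
    ns = cumulative_survivors(x, state, sp, dp)  # clipping implements the clamp
    out = np.maximum(0.0, 1.0 - dp.q_c * np.asarray(ns))
    return out if np.ndim(x) else float(out)


def _quality_zero_crossing(
    state: AnnualState, sp: SeasonalParams, dp: DemographyParams
) -> Optional[float]:
    """Date inside the arrival window where Q first hits zero, if any.

    1 - q_c * n_S(x) is strictly decreasing wherever S > 0, so a bracketed
    root is unique.  Returns None when quality stays positive all season.
    """
    lo, hi = _window(state, dp)

    def lin(x: float) -> float:
        return 1.0 - dp.q_c * float(cumulative_survivors(x, state, sp, dp))

    if lin(hi) >= 0.0:
        return None
    return float(brentq(lin, lo, hi, xtol=1e-14, rtol=8.9e-16))


def recruits(state: AnnualState, sp: SeasonalParams, dp: DemographyParams) -> float:
    """Density B of juveniles produced before winter.

    Integrates survivors times discounted reproduction over the arrival
    distribution: ``B = n/v * int S(x) R(x) Q(x) dx``, with Q generated
    self-consistently by the same cohort.  If quality hits zero inside the
    window the integral is truncated at that (bracketed) root, so adaptive
    quadrature only ever sees a smooth integrand.
    """
    if state.n == 0.0:
        return 0.0
    lo, hi = _window(state, dp)
    upper = _quality_zero_crossing(state, sp, dp)
    if upper is None:
        upper = hi

    def integrand(x: float) -> float:
        q = 1.0 - dp.q_c * float(cumulative_survivors(x, state, sp, dp))
        if q <= 0.0:
            return 0.0
        return (
            float(prebreeding_survival(x, sp))
            * float(reproductive_success(x, sp))
            * q
        )

    val, abserr = quad(integrand, lo, upper, epsabs=_EPSABS, epsrel=_EPSREL, limit=200)
    if abserr > max(_EPSABS, 1e-6 * abs(val)) * 1e4:
        raise ArithmeticError(
            f"recruit quadrature failed to converge: value={val!r}, abserr={abserr!r}"
        )
    return state.n / dp.v * val


def annual_update(state: AnnualState, sp: SeasonalParams, dp: DemographyParams) -> float:
    """One application of the between-year map: n_{t+1} = s_A*N_S + k*s_A*B."""
    if state.n == 0.0:
        return 0.0
    ns = total_survivors(state, sp, dp)
    b = recruits(state, sp, dp)
    return dp.s_A * ns + dp.k * dp.s_A * b


def _fraction_from_components(ns: float, b: float, dp: DemographyParams) -> float:
    """Fraction of young among next year's migrants, k*s_A*B / (s_A*N_S + k*s_A*B)."""
    total = dp.s_A * ns + dp.k * dp.s_A * b
    if total <= 0.0:
        return float("nan")
    return dp.k * dp.s_A * b / total


def fraction_young(state: AnnualState, sp: SeasonalParams, dp: DemographyParams) -> float:
    """Fraction of first-year migrants among migrants returning next year.

    Returns NaN when next year's population is empty (the age structure of
    an extinct population is undefined).
    """
    if state.n == 0.0:
        return float("nan")
    ns = total_survivors(state, sp, dp)
    b = recruits(state, sp, dp)
    return _fraction_from_components(ns, b, dp)


def ecological_equilibrium(
    mu: float,
    sp: SeasonalParams,
    dp: DemographyParams,
    opts: Optional[SolverOptions] = None,
) -> EquilibriumResult:
    """Equilibrium of the annual map for a resident with mean arrival ``mu``.

    Iterates the between-year map from ``opts.n0`` for up to ``opts.max_iter``
    steps (default 1000).  Declares extinction when density falls below the
    extinction threshold and convergence when successive densities differ by
    less than ``opts.tol``.  Non-convergence without extinction (e.g. a
    cycle) is reported through the flags, never raised.
    """
    opts = opts or SolverOptions()
    n = float(opts.n0)
    converged = False
    extinct = False
    iterations = 0
    for iterations in range(1, opts.max_iter + 1):
        n_next = annual_update(AnnualState(n, mu), sp, dp)
        if n_next < opts.extinction_threshold:
            n = 0.0
            extinct = True
            converged = True
            break
        if abs(n_next - n) < opts.tol:
            n = n_next
            converged = True
            break
        n = n_next
    if not extinct and n > 0.0 and converged:
        # Guard against mistaking slow geometric decay for a fixed point:
        # per-capita growth declines with density (competition), so growth
        # below 1 at the stopping density proves the population is on its
        # way to extinction, not at equilibrium.
        growth = annual_update(AnnualState(n, mu), sp, dp) / n
        if growth < 1.0 - 1e-6:
            n = 0.0
            extinct = True
    if extinct or n == 0.0:
        return EquilibriumResult(0.0, float("nan"), converged, True, iterations)
    f = fraction_young(AnnualState(n, mu), sp, dp)
    return EquilibriumResult(n, f, converged, False, iterations)
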