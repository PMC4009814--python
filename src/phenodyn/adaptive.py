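"""Invasion fitness, selection gradient, and ESS arrival date.

The framework is standard adaptive dynamics with full ecological feedback.
A rare variant with mean arrival date ``mu'`` invades a resident population
playing ``mu`` that sits at its own ecological equilibrium density ``n*``.
The variant's annual per-capita growth factor is

    W(mu', mu) = 1/v * int_{mu'-v/2}^{mu'+v/2}
                 S(x) * [s_A + k*s_A * R(x) * Q^(x)] dx

where ``Q^`` is the territory-quality profile generated by the resident at
``n*``, held at its boundary value outside the resident arrival window (the
rare variant has no ecological effect of its own).  ``W = 1`` is neutral;
the resident trivially satisfies ``W(mu, mu) = 1`` at equilibrium.

The selection gradient is ``h(mu) = dW/dmu'`` at ``mu' = mu``.  Because the
integrand is continuous, the Leibniz rule collapses the derivative to the
window endpoints:

    h(mu) = 1/v * [F(mu + v/2) - F(mu - v/2)],
    F(x)  = S(x) * (s_A + k*s_A * R(x) * Q(x)).

Sign convention: ``h > 0`` means selection for LATER arrival (larger mu).
An ESS is a root of ``h`` that is both convergence stable (dh/dmu < 0) and
resistant to invasion (``W(mu', mu*) <= 1`` for all variants); every ``h``
evaluation recomputes the resident equilibrium, closing the
eco-evolutionary feedback loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .population import (
    AnnualState,
    DemographyParams,
    EquilibriumResult,
    SolverOptions,
    _quality_zero_crossing,
    ecological_equilibrium,
    territory_quality,
)
from .seasonal import SeasonalParams, prebreeding_survival, reproductive_success, survival_mass

__all__ = [
    "ESSResult",
    "ExtinctResidentError",
    "invasion_fitness",
    "empty_environment_growth",
    "selection_gradient",
    "ess_solve",
    "check_stability",
]

# invasion fitness feeds finite-difference derivative checks with steps of
# ~1e-6, so its quadrature error must sit well below 1e-11
_EPSABS = 1e-14
_EPSREL = 5e-13


class ExtinctResidentError(ValueError):
    """Invasion fitness against an extinct resident is undefined."""


@dataclass(frozen=True)
class ESSResult:
    """A candidate evolutionary endpoint for the mean arrival date.

    ``status`` is ``"ok"`` for a located gradient root, ``"no_sign_change"``
    when the bracket contains no interior singular point, and ``"nonviable"``
    when the resident is extinct throughout the bracket.  Only a root with
    both stability flags true is a bona fide ESS.
    """

    mu_star: float
    equilibrium: Optional[EquilibriumResult]
    convergence_stable: bool
    invasion_resistant: bool
    gradient_residual: float
    status: str = "ok"

    @property
    def is_ess(self) -> bool:
        return self.status == "ok" and self.convergence_stable and self.invasion_resistant


def _resident_equilibrium(
    mu_resident: float,
    sp: SeasonalParams,
    dp: DemographyParams,
    opts: Optional[SolverOptions],
    resident: Optional[EquilibriumResult],
) -> EquilibriumResult:
    if resident is None:
        resident = ecological_equilibrium(mu_resident, sp, dp, opts)
    if resident.extinct:
        raise ExtinctResidentError(
            "resident population is extinct; invasion fitness is undefined "
            "(use empty_environment_growth for growth into an empty habitat)"
        )
    return resident


def invasion_fitness(
    mu_variant: float,
    mu_resident: float,
    sp: SeasonalParams,
    dp: DemographyParams,
    opts: Optional[SolverOptions] = None,
    resident: Optional[EquilibriumResult] = None,
) -> float:
    """Annual per-capita growth factor W(mu', mu) of a rare variant.

    ``resident`` may carry a precomputed equilibrium for the resident
    strategy; otherwise it is recomputed here.  The integration interval is
    split at the resident window edges and at any interior date where
    territory quality reaches zero, so each piece is smooth.
    """
    resident = _resident_equilibrium(mu_resident, sp, dp, opts, resident)
    state = AnnualState(resident.n_star, mu_resident)

    lo_v = mu_variant - dp.v / 2.0
    hi_v = mu_variant + dp.v / 2.0
    lo_r = mu_resident - dp.v / 2.0
    hi_r = mu_resident + dp.v / 2.0

    cuts = [lo_v, hi_v]
    for c in (lo_r, hi_r, _quality_zero_crossing(state, sp, dp)):
        if c is not None and lo_v < c < hi_v:
            cuts.append(c)
    cuts = sorted(cuts)

    def integrand(x: float) -> float:
        q = float(territory_quality(x, state, sp, dp))
        return float(prebreeding_survival(x, sp)) * (
            dp.s_A + dp.k * dp.s_A * float(reproductive_success(x, sp)) * q
        )

    total = 0.0
    for a, b in zip(cuts[:-1], cuts[1:]):
        val, _ = quad(integrand, a, b, epsabs=_EPSABS, epsrel=_EPSREL, limit=200)
        total += val
    return total / dp.v


def empty_environment_growth(
    mu: float, sp: SeasonalParams, dp: DemographyParams
) -> float:
    """Per-capita growth factor of a strategy invading an empty habitat.

    With no competitors every territory has quality 1, so
    ``W0 = 1/v * int S(x) * s_A * (1 + k * R(x)) dx``; values below 1 mean
    the habitat cannot sustain the strategy at all.
    """
    lo = mu - dp.v / 2.0
    hi = mu + dp.v / 2.0

    def integrand(x: float) -> float:
        return float(prebreeding_survival(x, sp)) * dp.s_A * (
            1.0 + dp.k * float(reproductive_success(x, sp))
        )

    val, _ = quad(integrand, lo, hi, epsabs=_EPSABS, epsrel=_EPSREL, limit=200)
    return val / dp.v


def selection_gradient(
    mu: float,
    sp: SeasonalParams,
    dp: DemographyParams,
    opts: Optional[SolverOptions] = None,
    resident: Optional[EquilibriumResult] = None,
) -> float:
    """Selection gradient h(mu) on the mean arrival date, per day.

    Endpoint (Leibniz) form of dW/dmu' at mu' = mu with the resident at its
    ecological equilibrium.  Positive values select for later arrival.
    Raises :class:`ExtinctResidentError` when the resident is extinct.
    """
    resident = _resident_equilibrium(mu, sp, dp, opts, resident)
    state = AnnualState(resident.n_star, mu)

    def boundary_value(x: float) -> float:
        q = float(territory_quality(x, state, sp, dp))
        return float(prebreeding_survival(x, sp)) * (
            dp.s_A + dp.k * dp.s_A * float(reproductive_success(x, sp)) * q
        )

    lo = mu - dp.v / 2.0
    hi = mu + dp.v / 2.0
    return (boundary_value(hi) - boundary_value(lo)) / dp.v


def _gradient_or_none(
    mu: float, sp: SeasonalParams, dp: DemographyParams, opts: Optional[SolverOptions]
) -> Optional[float]:
    try:
        return selection_gradient(mu, sp, dp, opts)
    except ExtinctResidentError:
        return None


def ess_solve(
    sp: SeasonalParams,
    dp: DemographyParams,
    bracket: Optional[tuple] = None,
    opts: Optional[SolverOptions] = None,
    scan_points: int = 41,
) -> ESSResult:
    """Locate the ESS mean arrival date by solving h(mu) = 0.

    The bracket (default ``[s - 2, r + 2]``) is scanned on a coarse grid for
    a viable sign change of the gradient, preferring a downward (+ to -)
    crossing since only those can be convergence stable; Brent's method then
    refines the root, with each gradient evaluation embedding a fresh
    equilibrium computation.  Deterministic for fixed inputs.
    """
    opts = opts or SolverOptions()
    if bracket is None:
        bracket = opts.bracket or (sp.s - 2.0, sp.r + 2.0)
    lo_b, hi_b = float(bracket[0]), float(bracket[1])
    if not lo_b < hi_b:
        raise ValueError("bracket must satisfy lo < hi")

    mus = np.linspace(lo_b, hi_b, scan_points)
    grads = [_gradient_or_none(float(m), sp, dp, opts) for m in mus]

    if all(g is None for g in grads):
        return ESSResult(float("nan"), None, False, False, float("nan"), "nonviable")

    # adjacent viable pairs with a sign change; prefer downward crossings
    crossings: list[tuple[float, float]] = []
    downward: list[tuple[float, float]] = []
    for m0, m1, g0, g1 in zip(mus[:-1], mus[1:], grads[:-1], grads[1:]):
        if g0 is None or g1 is None:
            continue
        if g0 == 0.0 or g0 * g1 < 0.0:
            pair = (float(m0), float(m1))
            crossings.append(pair)
            if g0 > 0.0 >= g1 or g0 == 0.0:
                downward.append(pair)
    if not crossings:
        return ESSResult(float("nan"), None, False, False, float("nan"), "no_sign_change")
    a, b = downward[0] if downward else crossings[0]

    mu_star = float(
        brentq(lambda m: selection_gradient(m, sp, dp, opts), a, b, xtol=opts.root_xtol)
    )
    equilibrium = ecological_equilibrium(mu_star, sp, dp, opts)
    residual = abs(selection_gradient(mu_star, sp, dp, opts, resident=equilibrium))
    conv, inv = check_stability(mu_star, sp, dp, opts)
    return ESSResult(mu_star, equilibrium, conv, inv, residual, "ok")


def check_stability(
    mu_star: float,
    sp: SeasonalParams,
    dp: DemographyParams,
    opts: Optional[SolverOptions] = None,
    scan_halfwidth: Optional[float] = None,
) -> tuple[bool, bool]:
    """Stability diagnostics at a gradient root.

    Convergence stability: central finite difference of h (step
    ``opts.fd_step``, each side with its own resident equilibrium) must be
    negative.  Invasion resistance: W(mu', mu_star) <= 1 + tol on a grid of
    ``opts.grid_points`` variant strategies spanning
    ``mu_star +/- scan_halfwidth``, by default half an arrival window (v/2).

    The default span covers the mutation neighbourhood relevant to gradual
    trait evolution: variants arriving mostly alongside the resident.  For
    strategies whose windows barely overlap the resident's, fitness rests
    entirely on the constant extrapolation of territory quality beyond the
    resident window, and late-arriving strategies there can show W > 1;
    pass a wider ``scan_halfwidth`` to inspect that regime explicitly.
    Raises ValueError if mu_star is not actually a root of h.
    """
    opts = opts or SolverOptions()
    if scan_halfwidth is None:
        scan_halfwidth = dp.v / 2.0
    equilibrium = ecological_equilibrium(mu_star, sp, dp, opts)
    h0 = selection_gradient(mu_star, sp, dp, opts, resident=equilibrium)
    if abs(h0) > 1e3 * opts.stability_tol:
        raise ValueError(
            f"mu_star={mu_star!r} is not a selection-gradient root (h={h0!r})"
        )

    step = opts.fd_step
    h_plus = selection_gradient(mu_star + step, sp, dp, opts)
    h_minus = selection_gradient(mu_star - step, sp, dp, opts)
    convergence_stable = (h_plus - h_minus) / (2.0 * step) < 0.0

    grid = np.linspace(mu_star - scan_halfwidth, mu_star + scan_halfwidth, opts.grid_points)
    w_max = max(
        invasion_fitness(float(m), mu_star, sp, dp, opts, resident=equilibrium)
        for m in grid
    )
    invasion_resistant = w_max <= 1.0 + opts.stability_tol
    return convergence_stable, invasion_resistant
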