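"""Climate-change experiments: sudden seasonal shifts and parameter sweeps.

A population at its historical ecological-and-evolutionary equilibrium is
exposed to a sudden shift of the onset of spring (``s``), of the food-peak
date (``r``), or of both.  Demography is assumed fast relative to evolution:
density re-equilibrates at the OLD mean arrival date, and we record

* the new selection gradient ``h(mu1*)`` in the shifted environment at the
  new equilibrium density,
* the relative density change ``n2*/n1*``,
* the relative change in age structure ``f2/f1`` (fraction of young),
* an extinction flag when the shifted environment cannot sustain the
  population at its old strategy.

The canonical shift magnitude is 0.5 season units, applied as an advance
(negative shift).  :func:`sweep` repeats the experiment along a parameter
grid, reproducing the comparative layout of the baseline characterisation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .adaptive import ESSResult, ess_solve, selection_gradient
from .population import DemographyParams, SolverOptions, ecological_equilibrium
from .seasonal import SeasonalParams

__all__ = [
    "ShiftScenario",
    "ScenarioResponse",
    "STANDARD_SCENARIOS",
    "SWEEPABLE_PARAMS",
    "DEFAULT_GRIDS",
    "run_scenario",
    "sweep",
]


@dataclass(frozen=True)
class ShiftScenario:
    """Sudden shift of the seasonal environment (negative = advance)."""

    delta_s: float = 0.0
    delta_r: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.delta_s) and np.isfinite(self.delta_r)):
            raise ValueError("shifts must be finite")

    @property
    def label(self) -> str:
        if self.delta_s == 0.0 and self.delta_r == 0.0:
            return "none"
        if self.delta_r == 0.0:
            return "shift_s"
        if self.delta_s == 0.0:
            return "shift_r"
        return "shift_both"


#: the three canonical advance scenarios (plus helpers may add the null one)
STANDARD_SCENARIOS: tuple[ShiftScenario, ...] = (
    ShiftScenario(0.0, -0.5),
    ShiftScenario(-0.5, 0.0),
    ShiftScenario(-0.5, -0.5),
)


@dataclass(frozen=True)
class ScenarioResponse:
    """Short-term demographic and selective response to a seasonal shift.

    ``gradient_after`` and ``young_ratio`` are NaN when the shifted
    environment drives the population extinct.
    """

    gradient_after: float
    density_ratio: float
    young_ratio: float
    extinct_after: bool
    n_after: float = float("nan")
    f_after: float = float("nan")


def run_scenario(
    sp: SeasonalParams,
    dp: DemographyParams,
    scenario: ShiftScenario,
    opts: Optional[SolverOptions] = None,
    baseline: Optional[ESSResult] = None,
) -> ScenarioResponse:
    """Apply a sudden seasonal shift to a population at its historical ESS.

    Steps: solve the baseline ESS ``mu1*`` with its equilibrium
    ``(n1*, f1)``; shift ``s`` and ``r``; re-equilibrate density at fixed
    ``mu = mu1*``; evaluate the selection gradient in the new environment at
    the new density.  ``baseline`` may carry a precomputed ESS for (sp, dp).

    Raises ValueError if the baseline admits no viable ESS.  Post-shift
    extinction is a valid outcome, reported through ``extinct_after``.
    """
    opts = opts or SolverOptions()
    if baseline is None:
        baseline = ess_solve(sp, dp, opts=opts)
    if baseline.status != "ok" or baseline.equilibrium is None or baseline.equilibrium.extinct:
        raise ValueError(f"baseline admits no viable ESS (status={baseline.status!r})")

    mu1 = baseline.mu_star
    eq1 = baseline.equilibrium
    sp2 = replace(sp, s=sp.s + scenario.delta_s, r=sp.r + scenario.delta_r)

    # restart the iteration from the historical density: that is the state
    # the population is actually in when the shift hits
    opts2 = replace(opts, n0=eq1.n_star)
    eq2 = ecological_equilibrium(mu1, sp2, dp, opts2)
    if eq2.extinct:
        return ScenarioResponse(
            gradient_after=float("nan"),
            density_ratio=0.0,
            young_ratio=float("nan"),
            extinct_after=True,
            n_after=0.0,
        )
    h2 = selection_gradient(mu1, sp2, dp, opts, resident=eq2)
    return ScenarioResponse(
        gradient_after=h2,
        density_ratio=eq2.n_star / eq1.n_star,
        young_ratio=eq2.f_star / eq1.f_star,
        extinct_after=False,
        n_after=eq2.n_star,
        f_after=eq2.f_star,
    )


#: parameters the sweep knows how to vary, and where each one lives
SWEEPABLE_PARAMS = {
    "s": "seasonal",
    "s_A": "demography",
    "R0": "seasonal",
    "sigma_R": "seasonal",
    "sigma_S": "seasonal",
}

#: default grid ranges, spanning the baseline of each parameter
DEFAULT_GRIDS = {
    "s": (-3.0, 1.0),
    "s_A": (0.2, 0.9),
    "R0": (1.0, 6.0),
    "sigma_R": (0.05, 0.8),
    "sigma_S": (0.1, 1.2),
}

_SWEEP_COLUMNS = [
    "vary_param",
    "vary_value",
    "mu_star",
    "n_star",
    "f_star",
    "scenario",
    "delta_s",
    "delta_r",
    "gradient_after",
    "density_ratio",
    "young_ratio",
    "extinct_after",
    "status",
]


def _apply_vary(
    sp: SeasonalParams, dp: DemographyParams, name: str, value: float
) -> tuple[SeasonalParams, DemographyParams]:
    if name not in SWEEPABLE_PARAMS:
        raise ValueError(
            f"cannot vary {name!r}; choose one of {sorted(SWEEPABLE_PARAMS)}"
        )
    if SWEEPABLE_PARAMS[name] == "seasonal":
        return replace(sp, **{name: value}), dp
    return sp, replace(dp, **{name: value})


def sweep(
    sp: SeasonalParams,
    dp: DemographyParams,
    vary: str,
    grid: Iterable[float],
    scenarios: Sequence[ShiftScenario] = STANDARD_SCENARIOS,
    opts: Optional[SolverOptions] = None,
) -> pd.DataFrame:
    """Baseline ESS and shift responses along a one-parameter grid.

    For each grid value of ``vary`` the baseline ESS, equilibrium density
    and fraction of young are solved, then every scenario is run against
    that baseline.  Returns a tidy long-format table, one row per
    (grid value, scenario); nonviable grid points and post-shift
    extinctions are flagged per row in ``status``, never raised.
    """
    opts = opts or SolverOptions()
    rows: list[dict] = []
    for value in grid:
        value = float(value)
        sp_v, dp_v = _apply_vary(sp, dp, vary, value)
        base = {
            "vary_param": vary,
            "vary_value": value,
            "mu_star": float("nan"),
            "n_star": float("nan"),
            "f_star": float("nan"),
        }
        ess = ess_solve(sp_v, dp_v, opts=opts)
        if ess.status != "ok" or ess.equilibrium is None or ess.equilibrium.extinct:
            for sc in scenarios:
                rows.append(
                    base
                    | {
                        "scenario": sc.label,
                        "delta_s": sc.delta_s,
                        "delta_r": sc.delta_r,
                        "gradient_after": float("nan"),
                        "density_ratio": float("nan"),
                        "young_ratio": float("nan"),
                        "extinct_after": False,
                        "status": "nonviable",
                    }
                )
            continue
        base |= {
            "mu_star": ess.mu_star,
            "n_star": ess.equilibrium.n_star,
            "f_star": ess.equilibrium.f_star,
        }
        for sc in scenarios:
            resp = run_scenario(sp_v, dp_v, sc, opts=opts, baseline=ess)
            rows.append(
                base
                | {
                    "scenario": sc.label,
                    "delta_s": sc.delta_s,
                    "delta_r": sc.delta_r,
                    "gradient_after": resp.gradient_after,
                    "density_ratio": resp.density_ratio,
                    "young_ratio": resp.young_ratio,
                    "extinct_after": resp.extinct_after,
                    "status": "extinct" if resp.extinct_after else "ok",
                }
            )
    return pd.DataFrame(rows, columns=_SWEEP_COLUMNS)
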