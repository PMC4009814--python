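"""Within-year competition, the annual map, and its equilibrium."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.integrate import quad

from phenodyn import (
    AnnualState,
    DemographyParams,
    SeasonalParams,
    SolverOptions,
    annual_update,
    cumulative_survivors,
    ecological_equilibrium,
    fraction_young,
    prebreeding_survival,
    recruits,
    reproductive_success,
    territory_quality,
    total_survivors,
)
from phenodyn.population import _fraction_from_components


@pytest.fixture()
def state(baseline_ess):
    return AnnualState(n=baseline_ess.equilibrium.n_star, mu=baseline_ess.mu_star)


class TestCumulativeSurvivors:
    def test_zero_before_first_arrival(self, sp, dp):
        st = AnnualState(n=1.0, mu=0.0)
        assert cumulative_survivors(st.mu - dp.v / 2, st, sp, dp) == 0.0
        assert cumulative_survivors(st.mu - dp.v, st, sp, dp) == 0.0

    def test_flat_after_window_closes(self, sp, dp):
        st = AnnualState(n=1.0, mu=0.0)
        end = st.mu + dp.v / 2
        total = total_survivors(st, sp, dp)
        assert cumulative_survivors(end, st, sp, dp) == pytest.approx(total)
        assert cumulative_survivors(end + 1.0, st, sp, dp) == pytest.approx(total)

    def test_empty_population_accumulates_nothing(self, sp, dp):
        st = AnnualState(n=0.0, mu=0.0)
        x = np.linspace(-1, 1, 7)
        assert np.all(cumulative_survivors(x, st, sp, dp) == 0.0)

    def test_nondecreasing_and_continuous(self, sp, dp):
        st = AnnualState(n=1.0, mu=0.0)
        x = np.linspace(st.mu - dp.v, st.mu + dp.v, 400)
        ns = cumulative_survivors(x, st, sp, dp)
        assert np.all(np.diff(ns) >= 0)
        assert np.max(np.abs(np.diff(ns))) < 5e-3  # no jumps at this resolution


class TestTotalSurvivors:
    def test_never_exceeds_arrivals(self, sp, dp):
        st = AnnualState(n=1.0, mu=0.0)
        assert total_survivors(st, sp, dp) < st.n

    def test_perfect_survival_limit(self, sp, dp):
        # window far past the spring onset: S ~ S0 = 1, so N_S -> n
        st = AnnualState(n=1.0, mu=sp.s + 100.0)
        assert total_survivors(st, sp, dp) == pytest.approx(st.n, rel=1e-10)

    def test_narrow_window_at_spring_onset_gives_half_survival(self, sp):
        dp = DemographyParams(v=0.01)
        st = AnnualState(n=1.0, mu=sp.s)
        assert total_survivors(st, sp, dp) == pytest.approx(0.5 * sp.S0, abs=1e-4)

    def test_matches_quadrature_oracle(self, sp, dp, state):
        oracle, _ = quad(
            lambda x: prebreeding_survival(x, sp) / dp.v * state.n,
            state.mu - dp.v / 2,
            state.mu + dp.v / 2,
            epsabs=1e-14,
        )
        assert total_survivors(state, sp, dp) == pytest.approx(oracle, rel=1e-10)


class TestTerritoryQuality:
    def test_empty_habitat_has_best_territory(self, sp, dp):
        st = AnnualState(n=0.0, mu=0.0)
        assert territory_quality(0.3, st, sp, dp) == 1.0

    def test_clamped_outside_resident_window(self, sp, dp, state):
        lo = state.mu - dp.v / 2
        hi = state.mu + dp.v / 2
        assert territory_quality(lo - 1.0, state, sp, dp) == pytest.approx(
            territory_quality(lo, state, sp, dp)
        )
        assert territory_quality(lo - 1.0, state, sp, dp) == 1.0
        assert territory_quality(hi + 1.0, state, sp, dp) == pytest.approx(
            territory_quality(hi, state, sp, dp)
        )

    def test_nonincreasing_and_bounded(self, sp, dp, state):
        x = np.linspace(state.mu - dp.v, state.mu + dp.v, 301)
        q = territory_quality(x, state, sp, dp)
        assert np.all(np.diff(q) <= 1e-15)
        assert np.all((q >= 0.0) & (q <= 1.0))

    def test_saturates_at_zero_under_crowding(self, sp, dp):
        # enough settled survivors that 1 - q_c*n_S crosses zero in-window
        st = AnnualState(n=5.0, mu=0.0)
        assert territory_quality(st.mu + dp.v / 2, st, sp, dp) == 0.0


class TestRecruitsAndUpdate:
    def test_no_parents_no_recruits(self, sp, dp):
        assert recruits(AnnualState(0.0, 0.0), sp, dp) == 0.0
        assert annual_update(AnnualState(0.0, 0.0), sp, dp) == 0.0

    def test_competition_free_saturated_limit(self, sp):
        # q_c = 0 and a window where S ~ S0 and R ~ R0: B -> R0*S0*n
        dp = DemographyParams(q_c=0.0)
        mu = sp.s + 60.0
        sp_far = replace(sp, r=mu + 60.0)
        st = AnnualState(n=0.7, mu=mu)
        assert recruits(st, sp_far, dp) == pytest.approx(
            sp.R0 * sp.S0 * st.n, rel=1e-9
        )

    def test_recruits_bounded_by_saturated_reproduction(self, sp, dp, state):
        assert 0.0 <= recruits(state, sp, dp) <= sp.R0 * total_survivors(state, sp, dp)

    def test_riemann_sum_oracle(self, sp, dp, state):
        # midpoint rule with 1e5 panels as the independent integral oracle
        lo = state.mu - dp.v / 2
        hi = state.mu + dp.v / 2
        x = np.linspace(lo, hi, 100_001)
        mid = 0.5 * (x[:-1] + x[1:])
        w = np.diff(x)
        q = territory_quality(mid, state, sp, dp)
        integrand = prebreeding_survival(mid, sp) * reproductive_success(mid, sp) * q
        oracle = state.n / dp.v * float(np.sum(integrand * w))
        assert recruits(state, sp, dp) == pytest.approx(oracle, rel=1e-8)

    def test_fixed_point_of_annual_map(self, sp, dp, baseline_ess):
        n_star = baseline_ess.equilibrium.n_star
        st = AnnualState(n=n_star, mu=baseline_ess.mu_star)
        assert annual_update(st, sp, dp) == pytest.approx(n_star, abs=1e-8)


class TestFractionYoung:
    @pytest.mark.parametrize(
        "ns,b,k,expected",
        [
            (1.0, 0.0, 0.5, 0.0),  # no recruits
            (0.0, 1.0, 0.5, 1.0),  # no surviving adults
            (1.0, 1.0, 0.5, 1.0 / 3.0),  # equal cohorts, juveniles discounted by k
        ],
    )
    def test_cohort_algebra(self, ns, b, k, expected):
        dp = DemographyParams(k=k)
        assert _fraction_from_components(ns, b, dp) == pytest.approx(expected)

    def test_undefined_for_empty_population(self, sp, dp):
        assert np.isnan(fraction_young(AnnualState(0.0, 0.0), sp, dp))

    def test_within_unit_interval_at_baseline(self, sp, dp, state):
        f = fraction_young(state, sp, dp)
        assert 0.0 < f < 1.0


class TestEcologicalEquilibrium:
    def test_low_winter_survival_means_extinction(self, sp):
        # empty-environment growth below one: the habitat cannot be invaded
        dp = DemographyParams(s_A=0.3)
        eq = ecological_equilibrium(0.0, sp, dp)
        assert eq.extinct and eq.n_star == 0.0 and np.isnan(eq.f_star)

    def test_baseline_is_viable_and_converged(self, baseline_ess):
        eq = baseline_ess.equilibrium
        assert not eq.extinct and eq.converged
        assert eq.n_star > 0.0 and 0.0 < eq.f_star < 1.0
        assert eq.iterations <= 1000

    def test_equilibrium_independent_of_initial_density(self, sp, dp, baseline_ess):
        mu = baseline_ess.mu_star
        lo = ecological_equilibrium(mu, sp, dp, SolverOptions(n0=0.2))
        hi = ecological_equilibrium(mu, sp, dp, SolverOptions(n0=2.0))
        assert lo.n_star == pytest.approx(hi.n_star, abs=1e-8)

    def test_decaying_transient_not_mistaken_for_equilibrium(self, sp):
        # far-too-early arrival: survival is tiny, density decays geometrically
        dp = DemographyParams()
        eq = ecological_equilibrium(-2.25, sp, dp)
        assert eq.extinct

    @pytest.mark.parametrize(
        "change,direction",
        [
            ({"s_A": 0.55}, "up"),  # better winter survival -> denser population
            ({"sigma_R": 0.3}, "down"),  # broader food peak -> fewer resources
            ({"sigma_S": 0.55}, "down"),  # slower spring improvement -> lower survival
        ],
    )
    def test_density_response_at_fixed_strategy(self, sp, dp, change, direction):
        mu = -0.23
        base = ecological_equilibrium(mu, sp, dp).n_star
        if "s_A" in change:
            new = ecological_equilibrium(mu, sp, replace(dp, **change)).n_star
        else:
            new = ecological_equilibrium(mu, replace(sp, **change), dp).n_star
        assert (new > base) if direction == "up" else (new < base)


@pytest.mark.parametrize(
    "kwargs", [{"s_A": 0.0}, {"k": 1.0}, {"k": 0.0}, {"q_c": -1.0}, {"v": 0.0}]
)
def test_invalid_demography_rejected(kwargs):
    with pytest.raises(ValueError):
        DemographyParams(**kwargs)


def test_negative_density_rejected():
    with pytest.raises(ValueError):
        AnnualState(n=-0.1, mu=0.0)
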