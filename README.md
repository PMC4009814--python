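# phenodyn

Eco-evolutionary dynamics of arrival timing in migratory birds.

Long-distance migrants face a seasonal dilemma at their breeding grounds:
arrive early and claim a good territory while food is still ahead of its
peak, or arrive late and survive the journey more safely. `phenodyn`
implements a discrete-time eco-evolutionary model of this trade-off —
density-dependent territory competition through prior residency, annual
population dynamics with winter survival, and adaptive-dynamics computation
of the evolutionarily stable (ESS) mean arrival date with full feedback
between the evolving strategy and the equilibrium density it generates. A
scenario layer applies sudden climate-change-like advances of the onset of
spring and of the food peak and reports the resulting selection pressures,
population trends and age-structure changes.

## Model

Arrival date *x* is measured in season time units ("days"). Two logistic
curves describe the seasonal environment:

- reproduction in the best territory, decreasing past the food-peak date
  *r*: `R(x) = R0 / (1 + exp((x − r)/σ_R))`
- pre-breeding survival, increasing after the onset of spring *s*:
  `S(x) = S0 / (1 + exp(−(x − s)/σ_S))`

A cohort of density *n* (returning migrants) with mean arrival date *μ*
arrives uniformly over `[μ − v/2, μ + v/2]`. Surviving settlers accumulate
as `n_S(x)` and degrade the quality of the best free territory linearly,
`Q(x) = max(0, 1 − q_c · n_S(x))` (prior residency). Realized per-capita
reproduction at date *x* is `R(x)·Q(x)`. With adult winter survival `s_A`
and juvenile winter survival `k·s_A` (k < 1), the between-year map is

    n' = s_A · N_S + k·s_A · B,

where `N_S` is the total density of surviving arrivals and `B` the density
of recruits. Its fixed point (by direct iteration, up to 1000 annual steps)
is the ecological equilibrium for a given strategy.

Evolution of *μ* follows adaptive dynamics: a rare variant *μ′* invading a
resident *μ* at its equilibrium density has annual growth factor

    W(μ′, μ) = 1/v ∫ S(x) [ s_A + k·s_A·R(x)·Q̂(x) ] dx

over the variant window, with `Q̂` the resident-generated territory-quality
profile. The selection gradient `h(μ) = ∂W/∂μ′ |_{μ′=μ}` reduces, by the
Leibniz rule, to the difference of the integrand at the window endpoints;
`h > 0` selects for later arrival. The ESS is the root of `h` (each
evaluation recomputing the resident equilibrium — the eco-evolutionary
feedback), checked for convergence stability and local invasion
resistance.

## Worked example

Solve the baseline ESS (onset of spring s = −1, food peak r = 1, adult
winter survival 0.5, maximal reproduction 3, narrow resource peak
σ_R = 0.1):

```sh
$ phenodyn ess --out ess.csv && cat ess.csv
mu_star,n_star,f_star,gradient_residual,convergence_stable,invasion_resistant,status
-0.232745254912,0.295435615327,0.566720152593,5.22615284382e-11,True,True,ok
```

The ESS mean arrival date is μ* ≈ −0.23: the population arrives just
before the season midpoint, well after spring onset (survival at the
window end is ≈0.93) and well before the food peak — territory competition
drags arrival earlier than the survival optimum. The equilibrium density
is n* ≈ 0.295 (in units where q_c = 1) and ≈57% of returning migrants are
first-year birds. The selection gradient vanishes to 5e−11 and the
strategy is convergence stable and uninvadable in its mutation
neighbourhood.

Apply a sudden joint advance of spring and food peak by 0.5 days to this
population (density re-equilibrates at the historical strategy):

```sh
$ phenodyn scenario --delta-s -0.5 --delta-r -0.5 --out sc.csv && cat sc.csv
scenario,delta_s,delta_r,gradient_after,density_ratio,young_ratio,extinct_after
shift_both,-0.5,-0.5,-0.678795985327,1.93005290867,0.919965159651,False
```

Selection now favours earlier arrival (h ≈ −0.68 per day), the population
nearly doubles (n₂*/n₁* ≈ 1.93 — the survival benefit of an earlier spring
overrides the small reproductive cost of the advanced food peak at this
density), and the fraction of young drops by 8% because more adults
survive to return.

Other entry points: `phenodyn equilibrium --mu X`, `phenodyn sweep --vary
s_A --grid 0.45:0.85:9 [--plot]`, `phenodyn selftest`, and the library API
(`phenodyn.ess_solve`, `phenodyn.run_scenario`, `phenodyn.sweep`, ...).
All parameters can be set in a YAML config (`--config`); defaults are the
reference baseline throughout.

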