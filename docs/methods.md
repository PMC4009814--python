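# Methods

## Model

`phenodyn` models a population of long-distance migratory birds competing
for breeding territories. The evolving trait is the population mean
arrival date μ; individual arrival dates are uniformly distributed over
`[μ − v/2, μ + v/2]`, representing environmentally induced spread that is
not under selective control. Time is a dimensionless season axis ("days")
centred near 0.

Two logistic curves define the seasonal trade-off:

| quantity | form | role |
|---|---|---|
| reproduction | `R(x) = R0 / (1 + exp((x − r)/σ_R))` | late arrival means breeding after the food peak; `r` is the half-saturation ("food-peak") date, `σ_R` the width of the temporal resource distribution |
| pre-breeding survival | `S(x) = S0 / (1 + exp(−(x − s)/σ_S))` | early migration is risky; `s` is the onset of spring, `σ_S` the rate at which conditions improve |

These logistic forms are the package's canonical definition of the model;
they satisfy every qualitative property the model requires
(half-saturation at `r` and `s`, maxima `R0` and `S0`, monotone in the
stated directions, slopes controlled by the σ parameters).

Within a year, the daily stream of surviving settlers `n·g_μ(x)·S(x)`
accumulates to `n_S(x)`, computed in closed form through the logistic
antiderivative (softplus), and degrades the best free territory linearly
(prior residency):

    Q(x) = max(0, 1 − q_c · n_S(x)),

held at its boundary values outside the arrival window. Realized
per-capita reproduction at date x is `R(x)·Q(x)`. The between-year map

    n_{t+1} = s_A·N_S + k·s_A·B,

combines adult winter survival `s_A` applied to the surviving arrivals
`N_S` and juvenile winter survival `k·s_A` (k < 1) applied to the recruits
`B = n/v ∫ S·R·Q dx`.

Invasion fitness of a rare variant μ′ against a resident μ at its
ecological equilibrium n* is the annual per-capita growth factor

    W(μ′, μ) = 1/v ∫_{μ′−v/2}^{μ′+v/2} S(x)·[s_A + k·s_A·R(x)·Q̂(x)] dx,

with `Q̂` the resident-generated quality profile (clamped outside the
resident window — exact for a rare variant, which finds the territory
stock as the residents left it). The growth *factor* (neutral value 1) is
used rather than its logarithm so that the fixed-point identity
`W(μ, μ) = 1` is directly testable; the ESS condition is invariant to this
choice. The selection gradient is the Leibniz endpoint form

    h(μ) = 1/v · [F(μ + v/2) − F(μ − v/2)],   F(x) = S(x)(s_A + k·s_A·R(x)·Q(x)),

with the sign convention h > 0 ⇒ selection for later arrival. The test
suite verifies h against one- and two-sided finite differences of W
rather than assuming smoothness: W is continuously differentiable (the
quality clamp introduces curvature jumps at μ′ = μ, but no derivative
jump), which the suite checks both at a fixed step and by step-halving in
the extreme-crowding regime where curvature is largest.

## Parameters and defaults

The package-wide defaults are the reference baseline used in all examples:
`r = 1`, `σ_R = 0.1`, `R0 = 3`, `s = −1`, `σ_S = 0.4`, `S0 = 1`
(seasonal); `s_A = 0.5`, `k = 0.5`, `q_c = 1`, `v = 0.5` (demography).
Density units are arbitrary; `q_c = 1` sets the scale (quality hits zero
at settled density 1). At this baseline the ESS is μ* ≈ −0.233 with
equilibrium density n* ≈ 0.295 and fraction of young f* ≈ 0.567.

Viability is bounded: the low-density growth factor is at most
`s_A·S0·(1 + k·R0)`, so the population cannot persist for `s_A ≲ 0.42` or
`R0 ≲ 2.1` at otherwise-baseline values, nor when spring starts later
than `s ≈ 0.3`. Solvers report such cases as `nonviable` rather than
failing.

## Numerical choices

- **Equilibrium** is found by direct iteration of the annual map from
  `n0 = 1` (up to 1000 steps), stopping when `|Δn| < 1e−10` or density
  falls below `1e−12` (extinct). A per-capita growth guard reclassifies a
  stalled decaying transient as extinct: per-capita growth declines with
  density, so growth < 1 at the stopping density proves decline to zero.
  Equilibrium uniqueness is checked by iterating from multiple starts in
  the tests.
- **Quadrature**: all within-season integrals use adaptive quadrature
  (`epsabs ≤ 1e−13`; `1e−14` for invasion fitness, which feeds
  finite-difference derivative checks). When territory quality reaches
  zero inside a window, the integrand's kink location is found by
  bracketed root finding and the integral is split there, so the
  quadrature only ever sees smooth pieces. The accumulated-survivor
  integral itself is closed-form (softplus), verified against quadrature
  to 1e−10 relative tolerance.
- **ESS root finding**: the gradient is scanned over `[s − 2, r + 2]` on a
  41-point grid for viable sign changes (preferring downward crossings,
  the only convergence-stable kind), then refined by Brent's method with
  `xtol = 1e−10`. Every gradient evaluation recomputes the resident
  equilibrium; nothing is cached across parameter changes.
- **Stability diagnostics**: convergence stability is a central finite
  difference of h (step 1e−4, each side with its own equilibrium);
  invasion resistance scans W over 201 variant strategies spanning
  μ* ± v/2 by default — the mutation neighbourhood of gradual trait
  evolution, variants arriving mostly alongside the resident. The span is
  an explicit argument: widening it to ± v shows that strategies whose
  windows lie entirely after the resident's can reach W ≈ 1.01 at the
  baseline, because survival still improves beyond the resident window
  while reproduction is not yet declining and territory quality is flat
  there. A strategy that far from the resident would rapidly build its own
  competitive environment, which rare-variant fitness deliberately
  ignores; resistance is therefore judged locally, and the far-window
  fitness landscape is reported, not hidden.

## Scenario layer

`run_scenario` applies a sudden shift (Δs, Δr) — canonically advances of
0.5 day — to a population at its historical ESS: demography is fast
relative to evolution, so density re-equilibrates at the old strategy
(restarting the iteration from the historical density), and the package
records the new selection gradient at the old ESS, the density ratio
n₂*/n₁*, the fraction-of-young ratio f₂/f₁, and an extinction flag.
`sweep` repeats this along one-parameter grids and returns a tidy
long-format table; nonviable baselines and post-shift extinctions are
flagged per row.

An exact structural result is worth knowing when reading scenario output:
at any ecological equilibrium the adult share is

    1 − f* = s_A · (1/v) ∫ S(x) dx  over the arrival window,

independent of the reproduction side of the model. A pure food-peak shift
(Δr only) therefore leaves the fraction of young exactly unchanged while
the population persists — reported young ratios differ from 1 only by the
equilibrium-iteration residue (~1e−11). Only shifts that touch `s` (or
drive the population extinct) move the age structure.

Comparative statics across the one-parameter sweep ranges (restricted to
their viable portions: s ∈ [−1.5, 0], s_A ∈ [0.45, 0.85], R0 ∈ [2.5, 6],
σ_R ∈ [0.05, 0.8], σ_S ∈ [0.2, 0.6]) are part of the acceptance suite:
earlier ESS arrival with earlier spring, higher winter survival or
productivity; later with broader food peak or slower spring improvement;
matching density and age-structure responses. The ESS-versus-σ_R relation
has a shallow (~3e−4 day) non-monotone dip near σ_R ≈ 0.15 before the
broad-peak trend takes over; the suite asserts the ordering on a 5-point
grid over the full panel range, where it holds strictly.

## Problem sizes

All computations are desk-scale: one ESS solve (a gradient scan plus
Brent refinement, each step embedding a ~100–300-iteration equilibrium)
takes a few seconds; the full acceptance suite solves ~40 ESS problems.

## Limitations

- The arrival distribution is uniform with fixed width; only the mean
  evolves. Alternative spreads (e.g. Gaussian) are not implemented.
- Environmental change is a sudden shift; gradual or stochastic change is
  out of scope, as are evolutionary trajectories after the shift (the
  canonical equation), genetic variance, and sexual reproduction.
- The population is monomorphic between invasion events; branching
  analysis beyond the two stability flags is not attempted.
- Matching of breeding time to the food peak is implicit in R(x); breeding
  date is not a separate trait.
- The synthetic study conditions are the reference parameterisation and
  its one-parameter neighbourhoods; passing tests demonstrate internal
  consistency and the model's qualitative claims there, not agreement
  with field data.
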