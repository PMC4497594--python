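# Methods

This note records the models implemented, the synthetic study conditions, the
numerical conventions, and the design choices made where the problem was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Models and fitting

**Gravity.** Flows between districts follow
`N_ij = k · pop_i^α · pop_j^β / d(i,j)^γ`. Fitting is Poisson maximum
likelihood with a log link on `(log pop_i, log pop_j, log d)`; the intercept
is `log k`, and `Constant` values of order −20 only make sense on that scale,
which is why the parameter is exposed as `log_k`. Zero observed flows are
retained — they carry a valid Poisson likelihood contribution, and dropping
them would bias the distance-decay estimate. Wald 95% confidence intervals
are reported per parameter. Goodness of fit is the percent reduction in
Poisson deviance relative to an intercept-only model; this definition applies
equally to fitted and parameter-free models, so gravity and radiation are
comparable on it.

**Constrained gravity.** The production-constrained variant replaces the
origin term with balancing factors `A_i` such that predicted row totals equal
observed origin totals; the attraction-constrained variant does the same on
the destination side; the doubly constrained variant alternates
`A_i = O_i / Σ_j B_j f_ij` and `B_j = D_j / Σ_i A_i f_ij`. The seed kernel
`f_ij` keeps the gravity term of each *unconstrained* side (e.g.
`pop_j^β / d^γ` for the production-constrained model), with exponents taken
from the unconstrained Poisson fit on the same table unless supplied.
Balancing iterates until the maximum relative margin error is below 1e−8
(hard cap 10,000 iterations; non-convergence raises with the last error).
Districts whose observed margin is zero get a balancing factor of exactly 0 —
the exact fixed point of the update — with a warning rather than an error,
since sparse yearly tables routinely contain such districts.

**Radiation.** `⟨N_ij⟩ = N_i · pop_i·pop_j / [(pop_i+s_ij)(pop_i+pop_j+s_ij)]`
with `N_i = pop_i·(T_c/T)`. The circle population `s_ij` sums districts
*strictly* inside the circle of radius `d(i,j)` centred at `i`, excluding both
the origin and the destination (the original convention for this model; the
alternative reading that counts the destination is switchable via
`include_dest`). Ties at exactly the radius are excluded, which makes the
construction deterministic. On tie-free instances the row sums obey the
telescoping identity `Σ_j ⟨N_ij⟩ = N_i (1 − pop_i/M)` with `M` the total
population; the tests require it to 1e−10 relative.

**Traveler fraction.** `T_c/T` is fitted by grid search (step 0.001 on
(0, 1]) minimising squared error on the `log1p` scale — robust to flows
spanning several orders of magnitude — with the exact linear-scale
least-squares solution (clipped to the domain) reported alongside. When
observation exceeds the radiation means at `T_c/T = 1`, both land on the
boundary.

**Error, exclusion, choice.** Per-route error is
`log(observed) − log(predicted)`, defined where both are positive; zero-flow
routes are reported as counts. Under the working assumption that errors are
N(0,1), the exclusion rule flags `|error| > 2` per model; a route flagged
under *both* models is unmodelable. An empirical variant (mean ± 2·sample SD)
is switchable because the two readings differ whenever the error distribution
is off-centre. The KS diagnostic tests the pooled errors against a *fixed*
N(0,1), not against estimated moments — the point is to test the assumption,
not to re-centre it. The per-route winner is the model with the smaller
absolute error (exact ties, which have measure zero, go to gravity,
documented). The choice model is a maximum-likelihood logistic regression of
the winner on `X_gm = log10(gm)`, `gm = pop_i·pop_j/d(i,j)`; the log10
transform is used because `gm` spans many orders of magnitude, and a raw-scale
option is retained. Complete separation is detected and falls back to an L2
ridge fit, flagged as such.

**Adjusted R².** The headline R² contrast between models depends on a
definition no standard reference fixes for this use, so it is pinned down
explicitly: OLS of `log(observed)` on `log(predicted)` over routes where both
are positive, adjusted for the interaction model's parameter count (4 for
gravity, 1 for radiation). Sensitivity to the zero-handling choice is
reported by the evaluation alongside the headline number.

## Trip extraction

Each subscriber-day gets one district: the modal routing tower of that day's
calls, ties broken uniformly at random with an RNG keyed by
(seed, subscriber, day) so that re-running one subscriber never reshuffles
another; call-free days inherit the most recent location; days before the
first call are dropped. Days are 0-indexed and the observation window is
half-open `[0, n_days)`. A trip opens whenever the daily district changes;
its duration is the run length of consecutive days then spent in the visited
district. The final run of every subscriber is cut off by the window edge, so
its duration is only a lower bound: such trips carry `truncated=True`, stay
in the `All` stratum, and are excluded from duration bins by default (their
inclusion is a switch), which avoids biasing the bins short.

Duration bins are half-open, in days: Week `[1, 14)`, Biweek `[14, 30)`,
Month `[30, 60)`, Month2 `[60, 90)`, Month3 `[90, 120)`, Month4+ `[120, ∞)`.
The shortest bin deliberately includes *all* sub-two-week trips; a 7-day
floor is the alternative reading, and the edges are an explicit argument so
either is reproducible. `All` is the unstratified table; the six bins
partition the non-truncated trips.

## Distance measures

All geometry is planar, in km (an equirectangular lon/lat→km helper is
provided for real inputs and documented as approximate at country scale).

- **Euclidean**: straight-line distance between centroids, plain or
  population-weighted. Population-weighted centroids are the
  population-weighted mean of cell centres within each district's mask; a
  zero-population district falls back to its geometric centroid with a
  warning; optionally each centroid snaps to the nearest road node (ties to
  the lowest node id).
- **Road**: shortest path over an undirected road graph after snapping
  centroids to their nearest nodes; disconnected components raise, listing
  themselves.
- **Travel time**: least-cost path on the 8-connected cell graph of a
  friction surface. The cost of a move is the mean of the two cells'
  crossing times, ×√2 on diagonals — the standard symmetric least-cost-surface
  convention — solved by Dijkstra (`scipy.sparse.csgraph`). Cell speeds are
  `class_speed · 2^(−slope/10°)`, with cells crossed by a road segment raised
  to the road speed (60 km/h default). The per-class speed table is
  config-supplied; the defaults (5 / 4 / 2.5 / 1.5 km/h for open, cropland,
  forest, wetland) follow the walking-dominated off-road convention of
  accessibility mapping. Impassable cells are NaN/non-positive speeds;
  unreachable pairs get `inf` with a warning and are excluded downstream.
  The matrix is symmetrized (the surface is undirected); on a uniform
  surface the 8-connectivity elongation caps travel time at ≈1.083× the
  straight-line optimum, which the tests exploit as a closed-form bound.

## Synthetic study conditions

The generator's defaults are the study conditions and are not tuned per test:

- **69 districts**, ids ordered by decreasing population so `D00` is always
  the capital.
- **Populations** log-normal `exp(N(12.6, 1.0))`: mean ≈ 4×10⁵, national
  total ≈ 2.7×10⁷, largest district a few million — the heavy-tailed profile
  of a Kenya-like country with one dominant capital.
- **Coordinates** uniform on a 900-km square with 3 planted city clusters
  (SD 60 km) holding the 35% largest districts, so urban/rural contrasts are
  geographically coherent.
- **Flow truth**: gravity with α = β = 1.22, γ = 2.05, log k = −20.06 (the
  published full-table fit these conditions emulate), observed counts drawn
  independently Poisson around the truth means; within-district pairs
  excluded; zero distance between distinct districts raises.
- **Diaries**: each subscriber has a home district; journeys depart home with
  a per-day probability, draw a log-normal duration, and choose a destination
  with gravity-like weights `pop_j^b(dur) / d^g(dur)` whose exponents can
  drift with duration (`duration_beta_slope`, `duration_gamma_slope`) — this
  plants the longer-trips-favour-big-far-destinations trend the stratified
  fits must recover. Ground-truth trips (including return legs and the
  truncated final run) are derived from the run structure at planning time,
  independently of the extraction code they validate. Call records appear
  only on days with ≥1 call (Bernoulli per day); multiple towers per district
  exercise the majority vote; an optional missing-month gap blanks a day
  range.
- **Rasters**: aligned population (Gaussian kernels around centroids,
  mass-conserving), nearest-seed land-class patches, smoothed-noise slope;
  roads = minimum spanning tree plus 3-nearest-neighbour edges over
  centroids, lengths 1.2× Euclidean.
- One RNG substream per generator, spawned from the master seed, so adding a
  generator never shifts another's draws.

**What the generator does not emulate:** real geography or tower density,
operator market share, distance-dependent call propensity, multi-stop
journeys, or overdispersion — flows are exactly Poisson around an exactly
gravity (or radiation) mean. Consequently a correctly specified fit explains
almost all deviance here, unlike on real data, where unmodelled heterogeneity
leaves a large residual; passing tests demonstrate the *machinery* (recovery,
identities, invariances), not model adequacy for any real population.

Two consequences worth noting when reading the analysis drivers' output.
First, because every district hosts the same number of subscribers, diary
origin totals do not scale with population, so origin-population exponents
fitted to diary-derived tables sit near 0 by construction — the planted
duration trend lives in the destination and distance exponents. Second, the
duration-stratified analysis uses a high re-departure rate (0.25/day at
home), keeping home stays short so that return legs land in the shortest
stratum; with long home stays the return legs (whose "visited district" is
home) dominate the month-plus bins and mask any outbound trend — a real
phenomenon of change-point trip definitions, but not the one under test.

## Numerical conventions and degenerate inputs

- Poisson deviance uses the `0·log 0 = 0` convention; reduction in deviance
  is undefined (NaN) when all observations are equal.
- Gravity fitting refuses designs with a constant covariate or collinear
  design matrix (non-identifiability) and requires ≥5 routes.
- Ratio and Dice summaries are computed over positive-positive routes only;
  zero-flow routes are reported as counts, never silently dropped.
- The KS diagnostic requires ≥10 errors.
- IPF convergence tolerance 1e−8 on the maximum relative margin error;
  the acceptance checks require 1e−6 on the doubly constrained margins.
- Circle populations use strict inequality (ties at the radius excluded) and
  are permutation-equivariant in district labels.
- All generators, tie-breaks and fits are deterministic under a fixed seed.

## Problem sizes

The default suite and the acceptance script run at the scale of the study
design they emulate: 69 districts (4,692 ordered routes) for full-table fits,
50 seeded replicates for the two coverage checks, ~1,400–2,400 subscribers ×
365 days for diary round-trips and the stratified trend, and toy grids
(5×5–20×20) where an independent Dijkstra or closed form serves as oracle.
These sizes were chosen so every check runs comfortably on a single CPU while
keeping the replicate counts large enough for coverage assertions to be
meaningful.

## Known limitations

- The adjusted-R² contrast and the mean observed/predicted ratios are
  sensitive to zero-handling and to the R² definition; both are pinned and
  the sensitivity reported, but comparisons across studies using other
  definitions are not exact.
- The travel-time measure is only as good as the friction table; the
  defaults are conventional, not calibrated to any real network.
- The constrained-gravity kernel inherits its exponents from the
  unconstrained fit rather than re-estimating them under the constraints
  (fixed-effect Poisson refits would be the heavier alternative).
- `T_c/T` is identified only up to the grid step (0.001) on the log1p
  objective; the linear-scale solution is exact but less robust to heavy
  tails.
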