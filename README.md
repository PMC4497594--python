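# odmodels

Fitting and systematically evaluating **spatial-interaction models of regional
mobility** — the gravity family and the radiation model — against
origin–destination (OD) travel measured from CDR-style daily-location diaries.

Mobility models of this kind are the standard coupling term in metapopulation
models of infectious-disease spread. In settings with heterogeneous
infrastructure and strongly heavy-tailed population distributions (a dominant
capital, many small rural districts) their adequacy is an empirical question:
each model fails in characteristic ways, and the practical problem is to
quantify *where* each one fails and *which* one to prefer on a given route.
This package implements that whole workflow as a tested library plus a set of
narrative analysis drivers.

## Models

**Gravity** (fitted by Poisson regression with a log link; the constant is the
intercept on the log scale):

    N_ij = k · pop_i^α · pop_j^β / d(i,j)^γ

**Constrained gravity** variants force predicted origin (production) and/or
destination (attraction) totals to match observation through balancing factors
A_i, B_j found by iterative proportional fitting (IPF).

**Radiation** (parameter-free up to the traveler fraction T_c/T):

    ⟨N_ij⟩ = N_i · pop_i·pop_j / [(pop_i + s_ij)(pop_i + pop_j + s_ij)],
    N_i = pop_i · (T_c/T)

where s_ij is the population inside the circle of radius d(i,j) centred at the
origin, excluding both endpoints.

Around these sit: trip extraction from call-record diaries (majority tower per
day, seeded tie-breaks, carry-forward on call-free days), duration
stratification (week up to four-plus months), three distance measures
(Euclidean / road network / least-cost travel time over a friction surface),
a log-error + 2-SD exclusion rule with a KS normality diagnostic, per-route
model choice, and a logistic regression of the winner on the gravity factor
gm = pop_i·pop_j/d(i,j).

Because subscriber-level call records cannot be redistributed, the package
ships a first-class synthetic generator (`odmodels.synthetic`) that produces
districts with log-normal populations and planted urban clusters, Poisson
flows from a known gravity or radiation truth, diaries with known ground-truth
trips and call-frequency gaps, and aligned population/land-cover/slope rasters
plus a road network. Every downstream stage is tested against ground truth
planted there.

## Worked example

```python
from odmodels.synthetic import SyntheticConfig, generate_districts, simulate_flows
from odmodels.models import fit_gravity

cfg = SyntheticConfig(seed=11)          # 69 districts, Kenya-like populations
d   = generate_districts(cfg)
od  = simulate_flows(d, cfg.gravity_truth, seed=11)   # α=β=1.22, γ=2.05, log k=−20.06
p   = fit_gravity(od)
print(f"alpha={p.alpha:.3f} beta={p.beta:.3f} gamma={p.gamma:.3f} log_k={p.log_k:.2f}")
```

prints

```
alpha=1.220 beta=1.223 gamma=2.052 log_k=-20.07
```

i.e. the Poisson fitter recovers the planted exponents (origin and destination
population elasticities and the distance-decay exponent) with the log-scale
constant; `p.conf_int` holds the per-parameter 95% Wald intervals and
`p.reduction_in_deviance_pct` the percent reduction in Poisson deviance versus
an intercept-only model.

The numbered drivers under `analysis/` run the full study on the synthetic
world and print what they find:

```sh
python analysis/01_simulate_world.py   # districts, flows, diaries, rasters, roads
python analysis/02_extract_trips.py    # daily locations -> trips -> OD per duration stratum
python analysis/03_distances.py        # Euclidean / road / travel-time + correlations
python analysis/04_fit_models.py       # gravity (3 distances), constrained, radiation, per-stratum
python analysis/05_evaluate.py         # errors, KS, 2-SD rule, winners, choice regression, subsets
```

Each writes its tables under `results/`. A command-line interface mirrors the
stages (`odmodels simulate|trips|distances|fit|evaluate|run-all`).

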