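"""Gravity-family and radiation spatial-interaction models.

The gravity model describes the flow between districts i and j as

    N_ij = k * pop_i^alpha * pop_j^beta / d(i,j)^gamma

and is fitted by Poisson regression with a log link on (log pop_i, log pop_j,
log d); the intercept is log k.  Constrained variants force predicted origin
(production) and/or destination (attraction) margins to match the observed
ones via iterative proportional fitting (IPF).  The radiation model is
parameter-free up to the traveler fraction T_c/T:

    <N_ij> = N_i * pop_i*pop_j / [(pop_i + s_ij)(pop_i + pop_j + s_ij)],
    N_i    = pop_i * (T_c/T),

where s_ij is the population inside the circle of radius d(i,j) centred at i,
excluding both endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "GravityParams",
    "ConstrainedGravityFit",
    "RadiationSpec",
    "gravity_predict",
    "fit_gravity",
    "fit_constrained_gravity",
    "circle_populations",
    "radiation_predict",
    "fit_radiation_fraction",
    "gravity_factor",
    "poisson_deviance",
    "reduction_in_deviance",
]

OD_COLUMNS = ["origin_id", "dest_id", "pop_orig", "pop_dest", "dist_euclid_km", "trips"]


@dataclass
class GravityParams:
    """Gravity exponents and log-scale constant, with optional Wald CIs."""

    alpha: float
    beta: float
    gamma: float
    log_k: float
    conf_int: dict[str, tuple[float, float]] | None = None
    reduction_in_deviance_pct: float | None = None
    deviance: float | None = None
    null_deviance: float | None = None

    def as_series(self) -> pd.Series:
        return pd.Series(
            {"alpha": self.alpha, "beta": self.beta, "gamma": self.gamma, "log_k": self.log_k}
        )


@dataclass
class ConstrainedGravityFit:
    variant: Literal["production", "attraction", "doubly"]
    a_i: pd.Series | None  # origin balancing factors (None when unconstrained side)
    b_j: pd.Series | None  # destination balancing factors
    params: GravityParams  # distance kernel / free-side exponents used for f_ij
    n_iter: int
    max_margin_rel_err: float
    predictions: pd.DataFrame = field(repr=False, default=None)


@dataclass
class RadiationSpec:
    """Circle populations and traveler fraction for the radiation model."""

    s: np.ndarray  # ordered-pair circle populations, nan diagonal
    tct: float  # traveler fraction T_c/T in (0, 1]
    tct_linear: float | None = None  # linear-scale least-squares alternative
    objective: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.tct <= 1.0:
            raise ValueError("traveler fraction must be in (0, 1]")


# ---------------------------------------------------------------------------
# helpers


def _check_od(od: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in OD_COLUMNS if c not in od.columns]
    if missing:
        raise ValueError(f"OD table missing columns: {missing}")
    if (od["dist_euclid_km"] <= 0).any():
        raise ValueError("OD table has non-positive distances")
    return od


def poisson_deviance(obs: np.ndarray, mu: np.ndarray) -> float:
    """Poisson deviance 2*sum[obs*log(obs/mu) - (obs - mu)] with 0*log0 = 0."""
    obs = np.asarray(obs, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("deviance undefined for non-positive predicted means")
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(obs > 0, obs * np.log(obs / mu), 0.0)
    return float(2.0 * np.sum(term - (obs - mu)))


def reduction_in_deviance(obs: np.ndarray, mu: np.ndarray) -> float:
    """Percent reduction in Poisson deviance vs the intercept-only model.

    The null model predicts the overall mean flow on every route; works for
    fitted and parameter-free models alike.  Returns nan when the null
    deviance is zero (all observations equal).
    """
    obs = np.asarray(obs, dtype=float)
    null = poisson_deviance(obs, np.full_like(obs, obs.mean()))
    if null == 0.0:
        return float("nan")
    return 100.0 * (null - poisson_deviance(obs, mu)) / null


# ---------------------------------------------------------------------------
# gravity


def gravity_predict(
    params: GravityParams, od: pd.DataFrame, distance_col: str = "dist_euclid_km"
) -> np.ndarray:
    """Mean flow exp(log_k) * pop_i^alpha * pop_j^beta / d^gamma per OD row."""
    if (od[distance_col] <= 0).any():
        raise ValueError("gravity prediction undefined at zero distance")
    return np.exp(
        params.log_k
        + params.alpha * np.log(od["pop_orig"].to_numpy(dtype=float))
        + params.beta * np.log(od["pop_dest"].to_numpy(dtype=float))
        - params.gamma * np.log(od[distance_col].to_numpy(dtype=float))
    )


def fit_gravity(od: pd.DataFrame, distance_col: str = "dist_euclid_km") -> GravityParams:
    """Poisson-ML fit of the gravity model (log link), per Flowerdew-style GLM.

    Zero observed flows are retained: they carry a valid Poisson likelihood
    contribution.  Raises on non-identifiable designs (e.g. all populations
    equal).
    """
    import statsmodels.api as sm

    _check_od(od)
    if len(od) < 5:
        raise ValueError("need at least 5 routes to fit the gravity model")
    X = pd.DataFrame(
        {
            "log_pop_orig": np.log(od["pop_orig"].to_numpy(dtype=float)),
            "log_pop_dest": np.log(od["pop_dest"].to_numpy(dtype=float)),
            "log_dist": np.log(od[distance_col].to_numpy(dtype=float)),
        }
    )
    if (X.std(ddof=0) < 1e-12).any():
        raise ValueError("non-identifiable design: a covariate is constant across routes")
    Xc = sm.add_constant(X)
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        raise ValueError("non-identifiable design: collinear covariates")
    model = sm.GLM(od["trips"].to_numpy(dtype=float), Xc, family=sm.families.Poisson())
    res = model.fit()
    ci = res.conf_int()
    conf = {
        "log_k": tuple(ci.loc["const"]),
        "alpha": tuple(ci.loc["log_pop_orig"]),
        "beta": tuple(ci.loc["log_pop_dest"]),
        "gamma": tuple(-ci.loc["log_dist"][::-1]),  # sign flip swaps the bounds
    }
    return GravityParams(
        alpha=float(res.params["log_pop_orig"]),
        beta=float(res.params["log_pop_dest"]),
        gamma=float(-res.params["log_dist"]),
        log_k=float(res.params["const"]),
        conf_int={k: (float(lo), float(hi)) for k, (lo, hi) in conf.items()},
        deviance=float(res.deviance),
        null_deviance=float(res.null_deviance),
        reduction_in_deviance_pct=float(100.0 * (res.null_deviance - res.deviance) / res.null_deviance),
    )


def fit_constrained_gravity(
    od: pd.DataFrame,
    variant: Literal["production", "attraction", "doubly"],
    distance_col: str = "dist_euclid_km",
    params: GravityParams | None = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> ConstrainedGravityFit:
    """Constrained gravity fit: balancing factors by iterative proportional fitting.

    The seed kernel f_ij keeps the gravity term of each *unconstrained* side:
    production-constrained uses pop_j^beta / d^gamma (A_i replaces the origin
    term), attraction-constrained uses pop_i^alpha / d^gamma, and the doubly
    constrained model keeps only the distance kernel 1 / d^gamma.  Exponents
    default to the unconstrained Poisson fit on the same table.  Balancing
    runs until the constrained margins match observation to ``tol`` relative
    error.
    """
    _check_od(od)
    if params is None:
        params = fit_gravity(od, distance_col)
    if variant not in ("production", "attraction", "doubly"):
        raise ValueError(f"unknown variant {variant!r}")

    origins = od["origin_id"].unique()
    dests = od["dest_id"].unique()
    obs = od.pivot_table(index="origin_id", columns="dest_id", values="trips", aggfunc="sum").reindex(
        index=origins, columns=dests
    )
    W = obs.notna().to_numpy()  # routes present in the table
    obs_m = obs.fillna(0.0).to_numpy(dtype=float)

    pop_o = od.groupby("origin_id")["pop_orig"].first().reindex(origins).to_numpy(dtype=float)
    pop_d = od.groupby("dest_id")["pop_dest"].first().reindex(dests).to_numpy(dtype=float)
    dist = od.pivot_table(index="origin_id", columns="dest_id", values=distance_col).reindex(
        index=origins, columns=dests
    ).to_numpy(dtype=float)

    f = np.zeros_like(dist)
    f[W] = np.exp(-params.gamma * np.log(dist[W]))
    if variant == "production":
        f = f * pop_d[None, :] ** params.beta
    elif variant == "attraction":
        f = f * pop_o[:, None] ** params.alpha

    O = obs_m.sum(axis=1)
    D = obs_m.sum(axis=0)
    # zero observed margins are admitted exactly: the balancing factor for a
    # zero-total origin/destination is 0, which satisfies its constraint
    import warnings as _warnings

    if variant in ("production", "doubly") and np.any(O <= 0):
        _warnings.warn("some origins have zero observed totals; their balancing factors are 0", stacklevel=2)
    if variant in ("attraction", "doubly") and np.any(D <= 0):
        _warnings.warn("some destinations have zero observed totals; their balancing factors are 0", stacklevel=2)

    a = np.ones(len(origins))
    b = np.ones(len(dests))
    n_iter = 0
    err = np.inf
    for n_iter in range(1, max_iter + 1):
        if variant in ("production", "doubly"):
            row = (f * b[None, :]).sum(axis=1)
            a = np.where(row > 0, O / row, 0.0)
        if variant in ("attraction", "doubly"):
            col = (f * a[:, None]).sum(axis=0)
            b = np.where(col > 0, D / col, 0.0)
        pred = a[:, None] * b[None, :] * f
        errs = []
        if variant in ("production", "doubly"):
            errs.append(np.max(np.abs(pred.sum(axis=1) - O) / np.maximum(O, 1e-300)))
        if variant in ("attraction", "doubly"):
            errs.append(np.max(np.abs(pred.sum(axis=0) - D) / np.maximum(D, 1e-300)))
        err = max(errs)
        if err < tol:
            break
    else:
        raise RuntimeError(f"IPF did not converge: last max relative margin error {err:.3e}")

    pred = a[:, None] * b[None, :] * f
    long = od[["origin_id", "dest_id"]].copy()
    oi = pd.Index(origins).get_indexer(od["origin_id"])
    dj = pd.Index(dests).get_indexer(od["dest_id"])
    long["predicted"] = pred[oi, dj]
    return ConstrainedGravityFit(
        variant=variant,
        a_i=pd.Series(a, index=origins) if variant in ("production", "doubly") else None,
        b_j=pd.Series(b, index=dests) if variant in ("attraction", "doubly") else None,
        params=params,
        n_iter=n_iter,
        max_margin_rel_err=float(err),
        predictions=long,
    )


# ---------------------------------------------------------------------------
# radiation


def circle_populations(
    districts: pd.DataFrame,
    dist: np.ndarray,
    include_dest: bool = False,
) -> np.ndarray:
    """Population in the circle of radius d(i,j) centred at i, per ordered pair.

    s_ij sums pop_k over districts strictly inside the circle (d(i,k) <
    d(i,j)), excluding the origin i and — by the original radiation-model
    convention, switchable via ``include_dest`` — the destination j.  Ties at
    exactly the radius are excluded (strict inequality).  Diagonal is nan.
    """
    pop = districts["population"].to_numpy(dtype=float)
    n = len(pop)
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    inside = dist[:, None, :] < dist[:, :, None]  # [i, j, k]: d(i,k) < d(i,j)
    s = np.einsum("ijk,k->ij", inside, pop)
    s -= pop[:, None]  # remove origin: d(i,i)=0 is always strictly inside
    if include_dest:
        # paper-ambiguous alternative reading: count the destination too
        s = s + pop[None, :]
    np.fill_diagonal(s, np.nan)
    return s


def radiation_predict(districts: pd.DataFrame, s: np.ndarray, tct: float = 1.0) -> np.ndarray:
    """Radiation mean flows on all ordered pairs (nan diagonal).

    <N_ij> = pop_i*(T_c/T) * pop_i*pop_j / [(pop_i+s_ij)(pop_i+pop_j+s_ij)].
    """
    pop = districts["population"].to_numpy(dtype=float)
    Ni = pop * tct
    num = pop[:, None] * pop[None, :]
    den = (pop[:, None] + s) * (pop[:, None] + pop[None, :] + s)
    mu = Ni[:, None] * num / den
    np.fill_diagonal(mu, np.nan)
    return mu


def fit_radiation_fraction(
    od: pd.DataFrame,
    districts: pd.DataFrame,
    dist: np.ndarray,
    grid_step: float = 0.001,
) -> RadiationSpec:
    """Fit the traveler fraction T_c/T in (0, 1] to observed flows.

    Primary objective: squared error on the log1p scale (robust to the
    heavy-tailed flows), minimised over the grid {grid_step, 2*grid_step, ...,
    1}.  The exact linear-scale least-squares solution (clipped to the
    domain) is reported alongside.
    """
    _check_od(od)
    if (od["trips"] <= 0).all():
        raise ValueError("cannot fit traveler fraction: all observed flows are zero")
    s = circle_populations(districts, dist)
    base = radiation_predict(districts, s, tct=1.0)
    idx = pd.Index(districts["district_id"])
    oi = idx.get_indexer(od["origin_id"])
    dj = idx.get_indexer(od["dest_id"])
    pred1 = base[oi, dj]
    obs = od["trips"].to_numpy(dtype=float)

    grid = np.arange(grid_step, 1.0 + grid_step / 2, grid_step)
    sse = np.array([np.sum((np.log1p(obs) - np.log1p(t * pred1)) ** 2) for t in grid])
    best = int(np.argmin(sse))
    tct_lin = float(np.clip(np.sum(obs * pred1) / np.sum(pred1**2), grid_step, 1.0))
    return RadiationSpec(s=s, tct=float(grid[best]), tct_linear=tct_lin, objective=float(sse[best]))


def gravity_factor(od: pd.DataFrame, distance_col: str = "dist_euclid_km") -> np.ndarray:
    """Parameter-free gravity factor gm = pop_i * pop_j / d(i,j) per route."""
    if (od[distance_col] <= 0).any():
        raise ValueError("gravity factor undefined at zero distance")
    return (
        od["pop_orig"].to_numpy(dtype=float)
        * od["pop_dest"].to_numpy(dtype=float)
        / od[distance_col].to_numpy(dtype=float)
    )
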