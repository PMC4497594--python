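"""Synthetic mobility worlds: districts, flows, diaries and rasters.

Everything downstream of this module (trip extraction, distance measures,
gravity/radiation fitting, model choice) is exercised on data produced here,
so each generator plants a known ground truth and is fully deterministic
under its seed.  The default configuration emulates a Kenya-like setting:
~69 districts with heavy-tailed (log-normal) populations, a few planted
urban clusters on an otherwise uniform plane, and yearly inter-district
flows drawn as Poisson counts around a gravity or radiation mean.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .models import GravityParams, circle_populations, radiation_predict

__all__ = [
    "SyntheticConfig",
    "generate_districts",
    "simulate_flows",
    "TravelPlan",
    "make_travel_plan",
    "simulate_diaries",
    "generate_rasters",
    "write_ascii_grid",
    "read_ascii_grid",
]

# Substreams spawned off the master seed, one per generator, so adding a new
# generator (or re-running a single one) never shifts another's draws.
_STREAM = {"districts": 0, "flows": 1, "plan": 2, "diaries": 3, "rasters": 4}


def _rng(seed: int, stream: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAM[stream], *extra])


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic world.

    Populations are log-normal: ``exp(N(pop_mu, pop_sigma))`` persons; the
    defaults give a mean district of ~400k with a right tail reaching a few
    million, matching a Kenya-like national profile with one dominant
    capital district.  Coordinates are km on a
    ``extent_km`` square with ``n_clusters`` planted city clusters; the
    largest districts are placed inside clusters so that "urban" and "rural"
    are geographically coherent.
    """

    n_districts: int = 69
    pop_mu: float = 12.6
    pop_sigma: float = 1.0
    extent_km: float = 900.0
    n_clusters: int = 3
    cluster_sd_km: float = 60.0
    cluster_frac: float = 0.35
    seed: int = 0
    # truth model for simulate_flows
    truth_model: Literal["gravity", "radiation"] = "gravity"
    gravity_truth: GravityParams = field(
        default_factory=lambda: GravityParams(alpha=1.22, beta=1.22, gamma=2.05, log_k=-20.06)
    )
    radiation_tct: float = 1.0
    # diary side
    subscribers_per_district: int = 20
    call_prob_per_day: float = 0.7
    n_days: int = 365
    towers_per_district: int = 2
    missing_month: tuple[int, int] | None = None  # half-open day range with no records

    def __post_init__(self) -> None:
        if self.n_districts < 2:
            raise ValueError("n_districts must be >= 2")
        if not 0.0 <= self.call_prob_per_day <= 1.0:
            raise ValueError("call_prob_per_day must be in [0, 1]")
        if not 0.0 < self.radiation_tct <= 1.0:
            raise ValueError("radiation_tct must be in (0, 1]")


def generate_districts(cfg: SyntheticConfig) -> pd.DataFrame:
    """Generate a district table: district_id, population, x_km, y_km.

    Deterministic under ``cfg.seed``; ids D00, D01, ... are ordered by
    decreasing population so D00 is always the 'capital'.
    """
    rng = _rng(cfg.seed, "districts")
    n = cfg.n_districts
    pops = np.sort(np.exp(rng.normal(cfg.pop_mu, cfg.pop_sigma, size=n)))[::-1]
    pops = np.maximum(1, np.round(pops)).astype(np.int64)

    centers = rng.uniform(0.15 * cfg.extent_km, 0.85 * cfg.extent_km, size=(cfg.n_clusters, 2))
    n_urban = int(round(cfg.cluster_frac * n))
    xy = np.empty((n, 2))
    # biggest districts cluster around the planted city centres
    which = rng.integers(0, cfg.n_clusters, size=n_urban)
    xy[:n_urban] = centers[which] + rng.normal(0.0, cfg.cluster_sd_km, size=(n_urban, 2))
    xy[n_urban:] = rng.uniform(0.0, cfg.extent_km, size=(n - n_urban, 2))
    xy = np.clip(xy, 0.0, cfg.extent_km)

    # nudge exact duplicates apart (vanishingly rare, but the contract says
    # pairwise distinct coordinates)
    df = pd.DataFrame(
        {
            "district_id": [f"D{i:02d}" for i in range(n)],
            "population": pops,
            "x_km": xy[:, 0],
            "y_km": xy[:, 1],
        }
    )
    while df.duplicated(subset=["x_km", "y_km"]).any():
        dup = df.duplicated(subset=["x_km", "y_km"])
        df.loc[dup, ["x_km", "y_km"]] += rng.normal(0.0, 0.5, size=(int(dup.sum()), 2))
    return df


def _euclid(districts: pd.DataFrame) -> np.ndarray:
    xy = districts[["x_km", "y_km"]].to_numpy()
    diff = xy[:, None, :] - xy[None, :, :]
    return np.hypot(diff[..., 0], diff[..., 1])


def gravity_mean_matrix(districts: pd.DataFrame, params: GravityParams) -> np.ndarray:
    """Gravity mean flows pop_i^a pop_j^b / d^g * k on all ordered pairs (nan diagonal)."""
    pop = districts["population"].to_numpy(dtype=float)
    d = _euclid(districts)
    off = ~np.eye(len(pop), dtype=bool)
    if np.any(d[off] == 0):
        raise ValueError("zero distance between distinct districts: degenerate geometry")
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.exp(
            params.log_k
            + params.alpha * np.log(pop)[:, None]
            + params.beta * np.log(pop)[None, :]
            - params.gamma * np.log(d)
        )
    np.fill_diagonal(mu, np.nan)
    return mu


def simulate_flows(
    districts: pd.DataFrame,
    truth: GravityParams | float | None = None,
    seed: int = 0,
    model: Literal["gravity", "radiation"] = "gravity",
) -> pd.DataFrame:
    """Draw an OD table of independent Poisson counts around the truth-model mean.

    ``truth`` is a :class:`GravityParams` for ``model="gravity"`` or the
    traveler fraction T_c/T for ``model="radiation"``.  Within-district pairs
    are excluded.  Returns the canonical route-level layout
    (origin_id, dest_id, pop_orig, pop_dest, dist_euclid_km, trips).
    """
    rng = _rng(seed, "flows")
    d = _euclid(districts)
    if model == "gravity":
        params = truth if isinstance(truth, GravityParams) else GravityParams(1.22, 1.22, 2.05, -20.06)
        mu = gravity_mean_matrix(districts, params)
    elif model == "radiation":
        tct = 1.0 if truth is None else float(truth)
        s = circle_populations(districts, d)
        mu = radiation_predict(districts, s, tct=tct)
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown truth model {model!r}")

    n = len(districts)
    i, j = np.where(~np.eye(n, dtype=bool))
    means = mu[i, j]
    if not np.all(np.isfinite(means)):
        raise ValueError("non-finite truth means; check parameters and geometry")
    trips = rng.poisson(means)
    ids = districts["district_id"].to_numpy()
    pop = districts["population"].to_numpy()
    return pd.DataFrame(
        {
            "origin_id": ids[i],
            "dest_id": ids[j],
            "pop_orig": pop[i],
            "pop_dest": pop[j],
            "dist_euclid_km": d[i, j],
            "trips": trips,
            "true_mean": means,
        }
    )


# ---------------------------------------------------------------------------
# Diaries


@dataclass
class TravelPlan:
    """A planned daily district per subscriber plus the implied true trips."""

    daily: pd.DataFrame  # subscriber_id, day, district_id
    trips: pd.DataFrame  # subscriber_id, origin, destination, start_day, duration, truncated


def make_travel_plan(
    districts: pd.DataFrame,
    cfg: SyntheticConfig,
    seed: int | None = None,
    trip_rate_per_day: float = 0.01,
    duration_logmean: float = 1.0,
    duration_logsd: float = 1.0,
    dest_beta: float = 1.0,
    dest_gamma: float = 1.5,
    duration_beta_slope: float = 0.0,
    duration_gamma_slope: float = 0.0,
) -> TravelPlan:
    """Assign each subscriber a home district and a set of journeys.

    Destination choice is gravity-like: P(j | i, duration) proportional to
    pop_j^b(dur) / d_ij^g(dur) with b(dur) = dest_beta + duration_beta_slope *
    log(dur) and g(dur) = dest_gamma + duration_gamma_slope * log(dur).
    Positive ``duration_beta_slope`` (negative ``duration_gamma_slope``)
    plants the longer-trips-favour-big-far-destinations trend that the
    duration-stratified fits should recover.
    Trip durations are log-normal in days, truncated to the window.
    """
    rng = _rng(cfg.seed if seed is None else seed, "plan")
    pop = districts["population"].to_numpy(dtype=float)
    ids = districts["district_id"].to_numpy()
    d = _euclid(districts)
    n = len(ids)
    n_subs = cfg.subscribers_per_district * n

    home = np.repeat(np.arange(n), cfg.subscribers_per_district)
    rows_daily: list[pd.DataFrame] = []
    rows_trips: list[tuple] = []
    logpop = np.log(pop)
    for s in range(n_subs):
        h = home[s]
        # build the subscriber's stay sequence as runs of (district, length)
        runs: list[list[int]] = [[h, 1]]  # day 0 at home
        day = 1
        while day < cfg.n_days:
            at_home = runs[-1][0] == h
            if at_home and rng.random() < trip_rate_per_day:
                dur = max(1, int(round(np.exp(rng.normal(duration_logmean, duration_logsd)))))
                b = dest_beta + duration_beta_slope * np.log(dur)
                g = dest_gamma + duration_gamma_slope * np.log(dur)
                with np.errstate(divide="ignore"):
                    w = np.exp(b * logpop - g * np.log(d[h]))
                w[h] = 0.0
                w /= w.sum()
                dest = int(rng.choice(n, p=w))
                take = min(dur, cfg.n_days - day)
                runs.append([dest, take])
                day += take
                if day < cfg.n_days:
                    runs.append([h, 1])
                    day += 1
            else:
                runs[-1][1] += 1
                day += 1

        # ground-truth trips: every run after the first is a change of
        # district, i.e. a trip; the final run is truncated by the window end
        seq_parts = []
        start = 0
        for k, (dist, length) in enumerate(runs):
            seq_parts.append(np.full(length, dist, dtype=np.int64))
            if k > 0:
                rows_trips.append(
                    (
                        f"S{s:05d}",
                        ids[runs[k - 1][0]],
                        ids[dist],
                        start,
                        length,
                        k == len(runs) - 1,
                    )
                )
            start += length
        seq = np.concatenate(seq_parts)
        rows_daily.append(
            pd.DataFrame({"subscriber_id": f"S{s:05d}", "day": np.arange(cfg.n_days), "district_id": ids[seq]})
        )
    daily = pd.concat(rows_daily, ignore_index=True)
    trips = pd.DataFrame(
        rows_trips,
        columns=["subscriber_id", "origin", "destination", "start_day", "duration", "truncated"],
    )
    trips = trips.astype({"start_day": np.int64, "duration": np.int64, "truncated": bool})
    return TravelPlan(daily=daily, trips=trips)


def simulate_diaries(
    districts: pd.DataFrame,
    plan: TravelPlan,
    call_prob: float = 0.7,
    seed: int = 0,
    towers_per_district: int = 1,
    calls_per_active_day: int = 3,
    missing_month: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Turn a travel plan into call records with call-frequency gaps.

    Each subscriber-day emits records only if at least one call happens
    (Bernoulli(call_prob)); an active day emits ``calls_per_active_day``
    records routed through towers of the day's district chosen uniformly, so
    the majority-vote assignment is genuinely exercised when
    ``towers_per_district > 1``.  ``missing_month`` blanks a half-open day
    range for every subscriber, emulating a gap in the observation window.

    Returns (records, tower_map); the ground truth lives in ``plan.trips``.
    """
    if call_prob == 0.0:
        warnings.warn("call_prob=0: no subscriber will emit any record", stacklevel=2)
    rng = _rng(seed, "diaries")
    ids = districts["district_id"].to_numpy()
    towers = pd.DataFrame(
        {
            "tower_id": [f"T_{d}_{k}" for d in ids for k in range(towers_per_district)],
            "district_id": np.repeat(ids, towers_per_district),
        }
    )
    tower_lookup = {d: [f"T_{d}_{k}" for k in range(towers_per_district)] for d in ids}

    daily = plan.daily
    active = rng.random(len(daily)) < call_prob
    if missing_month is not None:
        lo, hi = missing_month
        active &= ~((daily["day"].to_numpy() >= lo) & (daily["day"].to_numpy() < hi))
    act = daily.loc[active]
    reps = np.repeat(act.index.to_numpy(), calls_per_active_day)
    rec = daily.loc[reps, ["subscriber_id", "day", "district_id"]].reset_index(drop=True)
    # uniform tower choice within the day's district
    if towers_per_district == 1:
        rec["tower_id"] = "T_" + rec["district_id"] + "_0"
    else:
        k = rng.integers(0, towers_per_district, size=len(rec))
        rec["tower_id"] = np.array(
            [tower_lookup[d][kk] for d, kk in zip(rec["district_id"], k)], dtype=object
        )
    records = rec[["subscriber_id", "day", "tower_id"]]
    return records, towers


# ---------------------------------------------------------------------------
# Rasters and roads


def write_ascii_grid(path, grid: np.ndarray, cell_km: float, xll: float = 0.0, yll: float = 0.0, nodata: float = -9999.0) -> None:
    """Write a 2-D array as an Esri ASCII grid (row 0 = northern edge)."""
    nrows, ncols = grid.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\nnrows {nrows}\nxllcorner {xll}\nyllcorner {yll}\n")
        fh.write(f"cellsize {cell_km}\nNODATA_value {nodata}\n")
        out = np.where(np.isfinite(grid), grid, nodata)
        for row in out:
            fh.write(" ".join(format(v, "g") for v in row) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    """Read an Esri ASCII grid; returns (array with nodata as nan, header dict)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        key, val = line.split()
        header[key.lower()] = float(val)
    grid = np.loadtxt(lines[6:])
    grid = np.atleast_2d(grid)
    nodata = header.get("nodata_value")
    if nodata is not None:
        grid = np.where(grid == nodata, np.nan, grid)
    return grid, header


def generate_rasters(
    districts: pd.DataFrame,
    cell_km: float = 10.0,
    seed: int = 0,
    extent_km: float | None = None,
    n_land_classes: int = 4,
    road_knn: int = 3,
    road_wiggle: float = 1.2,
) -> dict:
    """Generate aligned population / land-class / slope grids plus a road network.

    All three grids share shape and cell size on [0, extent]^2.  Population is
    spread around each district centroid with a Gaussian kernel (so the
    nearest-centroid district mask has an interior population-weighted
    centroid).  Land classes are nearest-seed patches; slope is smoothed
    noise.  The road network connects district centroids: a spanning tree for
    connectivity plus each centroid's ``road_knn`` nearest neighbours, edge
    length = Euclidean * ``road_wiggle``.
    """
    import networkx as nx
    from scipy import ndimage

    rng = _rng(seed, "rasters")
    if extent_km is None:
        extent_km = float(np.ceil(max(districts["x_km"].max(), districts["y_km"].max()) / 100.0) * 100.0)
    ncells = int(np.ceil(extent_km / cell_km))
    # cell-center coordinates; row r is the northern strip for ASCII output
    cx = (np.arange(ncells) + 0.5) * cell_km
    cy = extent_km - (np.arange(ncells) + 0.5) * cell_km
    X, Y = np.meshgrid(cx, cy)

    xy = districts[["x_km", "y_km"]].to_numpy()
    pop = districts["population"].to_numpy(dtype=float)

    d2 = (X[..., None] - xy[:, 0]) ** 2 + (Y[..., None] - xy[:, 1]) ** 2
    mask = np.argmin(d2, axis=-1)  # district index per cell
    sigma = 3.0 * cell_km
    kern = np.exp(-d2 / (2 * sigma**2))
    kern /= kern.sum(axis=(0, 1), keepdims=True)
    pop_grid = (kern * pop).sum(axis=-1)

    seeds = rng.uniform(0, extent_km, size=(n_land_classes * 6, 2))
    seed_class = rng.integers(0, n_land_classes, size=len(seeds))
    ds = (X[..., None] - seeds[:, 0]) ** 2 + (Y[..., None] - seeds[:, 1]) ** 2
    land_grid = seed_class[np.argmin(ds, axis=-1)].astype(float)

    slope_grid = ndimage.gaussian_filter(rng.normal(size=(ncells, ncells)), sigma=3.0)
    slope_grid = np.abs(slope_grid) / max(np.abs(slope_grid).max(), 1e-12) * 15.0  # degrees

    # road graph over district centroids
    n = len(districts)
    diff = xy[:, None, :] - xy[None, :, :]
    dmat = np.hypot(diff[..., 0], diff[..., 1])
    g = nx.Graph()
    for i in range(n):
        g.add_node(i)
    full = nx.Graph()
    for i in range(n):
        for j in range(i + 1, n):
            full.add_edge(i, j, weight=dmat[i, j])
    mst = nx.minimum_spanning_tree(full)
    g.add_edges_from(mst.edges(data=True))
    order = np.argsort(dmat, axis=1)
    for i in range(n):
        for j in order[i, 1 : road_knn + 1]:
            g.add_edge(i, int(j), weight=dmat[i, int(j)])

    ids = districts["district_id"].to_numpy()
    nodes = pd.DataFrame({"node_id": ids, "x_km": xy[:, 0], "y_km": xy[:, 1]})
    edges = pd.DataFrame(
        [(ids[a], ids[b], dat["weight"] * road_wiggle) for a, b, dat in g.edges(data=True)],
        columns=["node_a", "node_b", "length_km"],
    )
    return {
        "population": pop_grid,
        "land_class": land_grid,
        "slope": slope_grid,
        "district_mask": mask,
        "district_index": ids,
        "cell_km": cell_km,
        "extent_km": extent_km,
        "road_nodes": nodes,
        "road_edges": edges,
    }


def stable_checksum(grid: np.ndarray) -> int:
    """Platform-stable checksum of a float grid (used for determinism checks)."""
    return zlib.crc32(np.ascontiguousarray(grid, dtype=np.float64).tobytes())
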