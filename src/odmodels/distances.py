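"""Distance measures between districts: Euclidean, road, and travel time.

Three measures feed the gravity fits: straight-line distance between
centroids (plain or population-weighted), shortest-path distance over a road
network, and least-cost travel time over a friction surface built from land
cover, slope and the road overlay.  All geometry is planar, in km; a helper
converts lon/lat inputs with an equirectangular approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FrictionSurface",
    "euclidean_matrix",
    "population_weighted_centroids",
    "road_distance_matrix",
    "build_friction_surface",
    "travel_time_matrix",
    "snap_to_nodes",
    "lonlat_to_km",
    "distance_correlations",
    "matrix_to_long",
    "DEFAULT_SPEED_BY_CLASS",
]

# Traversal speed per land-cover class (km/h), before the slope modifier and
# road overlay.  The classes are the synthetic generator's: 0 open/grassland,
# 1 cropland, 2 forest/bush, 3 wetland/rough.  Values follow the common
# accessibility-mapping convention of walking-dominated off-road speeds.
DEFAULT_SPEED_BY_CLASS: dict[int, float] = {0: 5.0, 1: 4.0, 2: 2.5, 3: 1.5}
DEFAULT_ROAD_SPEED = 60.0  # km/h on the road overlay
SLOPE_HALVING_DEG = 10.0  # speed halves every 10 degrees of slope


@dataclass
class FrictionSurface:
    """Per-cell traversal speeds (km/h); nonpositive/nan cells are impassable."""

    speed: np.ndarray
    cell_km: float

    def __post_init__(self) -> None:
        self.speed = np.asarray(self.speed, dtype=float)
        if self.cell_km <= 0:
            raise ValueError("cell size must be positive")

    @property
    def passable(self) -> np.ndarray:
        return np.isfinite(self.speed) & (self.speed > 0)

    def cell_hours(self) -> np.ndarray:
        """Time to cross one cell orthogonally (h); inf where impassable."""
        t = np.full(self.speed.shape, np.inf)
        p = self.passable
        t[p] = self.cell_km / self.speed[p]
        return t


def euclidean_matrix(centroids: pd.DataFrame) -> pd.DataFrame:
    """Symmetric straight-line distance matrix (km) between centroids."""
    from scipy.spatial import distance_matrix as _dm

    xy = centroids[["x_km", "y_km"]].to_numpy(dtype=float)
    ids = centroids["district_id"].to_numpy()
    return pd.DataFrame(_dm(xy, xy), index=ids, columns=ids)


def lonlat_to_km(lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Equirectangular lon/lat -> planar km (approximate, fine at country scale)."""
    lat0 = np.deg2rad(np.mean(lat))
    x = np.deg2rad(lon) * 6371.0 * np.cos(lat0)
    y = np.deg2rad(lat) * 6371.0
    return x - x.min(), y - y.min()


def _cell_centers(shape: tuple[int, int], cell_km: float, extent_y: float | None = None):
    nrows, ncols = shape
    if extent_y is None:
        extent_y = nrows * cell_km
    cx = (np.arange(ncols) + 0.5) * cell_km
    cy = extent_y - (np.arange(nrows) + 0.5) * cell_km  # row 0 = northern edge
    return cx, cy


def population_weighted_centroids(
    pop_grid: np.ndarray,
    district_mask: np.ndarray,
    district_ids: np.ndarray,
    cell_km: float,
    road_nodes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Population-weighted mean of cell centres per district.

    A district whose cells carry zero population falls back to the unweighted
    (geometric) centroid of its cells, with a warning.  When ``road_nodes``
    is given, each centroid is moved to the nearest road node.
    """
    if pop_grid.shape != district_mask.shape:
        raise ValueError("population and district-mask grids are not aligned")
    cx, cy = _cell_centers(pop_grid.shape, cell_km)
    X, Y = np.meshgrid(cx, cy)
    rows = []
    for k, did in enumerate(district_ids):
        sel = district_mask == k
        if not sel.any():
            raise ValueError(f"district {did!r} has no cells in the mask")
        w = pop_grid[sel]
        if w.sum() <= 0:
            warnings.warn(f"district {did!r} has zero gridded population; using geometric centroid", stacklevel=2)
            w = np.ones_like(w)
        rows.append((did, float(np.average(X[sel], weights=w)), float(np.average(Y[sel], weights=w))))
    cent = pd.DataFrame(rows, columns=["district_id", "x_km", "y_km"])
    if road_nodes is not None:
        cent = snap_to_nodes(cent, road_nodes)
    return cent


def snap_to_nodes(centroids: pd.DataFrame, nodes: pd.DataFrame) -> pd.DataFrame:
    """Move each centroid to its nearest road node (ties -> lowest node_id)."""
    nd = nodes.sort_values("node_id").reset_index(drop=True)
    nxy = nd[["x_km", "y_km"]].to_numpy(dtype=float)
    out = centroids.copy()
    cxy = out[["x_km", "y_km"]].to_numpy(dtype=float)
    d = np.hypot(cxy[:, None, 0] - nxy[None, :, 0], cxy[:, None, 1] - nxy[None, :, 1])
    nearest = np.argmin(d, axis=1)  # argmin takes the first (lowest id) on ties
    out["x_km"] = nxy[nearest, 0]
    out["y_km"] = nxy[nearest, 1]
    out["node_id"] = nd["node_id"].to_numpy()[nearest]
    return out


def road_distance_matrix(
    edges: pd.DataFrame, centroids: pd.DataFrame, nodes: pd.DataFrame
) -> pd.DataFrame:
    """Shortest-path road distance (km) between snapped centroids.

    The road graph is undirected; centroids are snapped to the nearest node.
    Raises if the snapped nodes do not share a connected component, listing
    the components.
    """
    import networkx as nx

    g = nx.Graph()
    for _, r in edges.iterrows():
        g.add_edge(r["node_a"], r["node_b"], weight=float(r["length_km"]))
    snapped = snap_to_nodes(centroids, nodes)
    targets = snapped["node_id"].tolist()
    comp = {n: c for c, nodes_ in enumerate(nx.connected_components(g)) for n in nodes_}
    comps = {comp.get(t) for t in targets}
    if len(comps) > 1 or None in comps:
        raise ValueError(f"road network disconnected over snapped centroids (components: {comps})")

    ids = snapped["district_id"].to_numpy()
    n = len(ids)
    out = np.zeros((n, n))
    for a in range(n):
        lengths = nx.single_source_dijkstra_path_length(g, targets[a], weight="weight")
        for b in range(n):
            out[a, b] = lengths[targets[b]]
    return pd.DataFrame(out, index=ids, columns=ids)


def build_friction_surface(
    land_grid: np.ndarray,
    slope_grid: np.ndarray,
    cell_km: float,
    speed_by_class: dict[int, float] | None = None,
    road_edges: pd.DataFrame | None = None,
    road_nodes: pd.DataFrame | None = None,
    road_speed: float = DEFAULT_ROAD_SPEED,
    slope_halving_deg: float = SLOPE_HALVING_DEG,
) -> FrictionSurface:
    """Combine land cover, slope and roads into per-cell travel speeds.

    speed = class_speed * 2^(-slope/slope_halving); cells crossed by a road
    segment take max(speed, road_speed).  Land classes absent from the table
    are impassable.
    """
    if land_grid.shape != slope_grid.shape:
        raise ValueError("land and slope grids are not aligned")
    table = DEFAULT_SPEED_BY_CLASS if speed_by_class is None else speed_by_class
    speed = np.full(land_grid.shape, np.nan)
    for cls, v in table.items():
        speed[land_grid == cls] = v
    speed = speed * 2.0 ** (-np.asarray(slope_grid, dtype=float) / slope_halving_deg)

    if road_edges is not None:
        if road_nodes is None:
            raise ValueError("road_edges given without road_nodes coordinates")
        nrows, _ = land_grid.shape
        coords = road_nodes.set_index("node_id")[["x_km", "y_km"]]
        extent_y = nrows * cell_km
        for _, e in road_edges.iterrows():
            xa, ya = coords.loc[e["node_a"]]
            xb, yb = coords.loc[e["node_b"]]
            npts = max(2, int(np.hypot(xb - xa, yb - ya) / (0.5 * cell_km)) + 1)
            ts = np.linspace(0.0, 1.0, npts)
            xs = xa + ts * (xb - xa)
            ys = ya + ts * (yb - ya)
            cols = np.clip((xs / cell_km).astype(int), 0, land_grid.shape[1] - 1)
            rows = np.clip(((extent_y - ys) / cell_km).astype(int), 0, nrows - 1)
            speed[rows, cols] = np.fmax(speed[rows, cols], road_speed)
    return FrictionSurface(speed=speed, cell_km=cell_km)


def _grid_graph(friction: FrictionSurface):
    """Sparse 8-connected cell graph; edge cost = mean cell-crossing time, x sqrt2 diagonally."""
    from scipy import sparse

    t = friction.cell_hours()
    nrows, ncols = t.shape
    idx = np.arange(nrows * ncols).reshape(nrows, ncols)
    rows_, cols_, vals = [], [], []
    steps = [(0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2.0)), (1, -1, np.sqrt(2.0))]
    for dr, dc, w in steps:
        r0 = slice(max(0, -dr), nrows - max(0, dr))
        r1 = slice(max(0, dr), nrows - max(0, -dr))
        c0 = slice(max(0, -dc), ncols - max(0, dc))
        c1 = slice(max(0, dc), ncols - max(0, -dc))
        a = idx[r0, c0].ravel()
        b = idx[r1, c1].ravel()
        cost = w * 0.5 * (t[r0, c0].ravel() + t[r1, c1].ravel())
        ok = np.isfinite(cost)
        rows_.append(a[ok])
        cols_.append(b[ok])
        vals.append(cost[ok])
    r = np.concatenate(rows_)
    c = np.concatenate(cols_)
    v = np.concatenate(vals)
    n = nrows * ncols
    g = sparse.coo_matrix((np.concatenate([v, v]), (np.concatenate([r, c]), np.concatenate([c, r]))), shape=(n, n))
    return g.tocsr()


def travel_time_matrix(friction: FrictionSurface, centroids: pd.DataFrame) -> pd.DataFrame:
    """Least-cost travel time (hours) between centroid cells via Dijkstra.

    Pairs with no passable path get inf (callers should exclude such routes,
    a warning is emitted).  The surface being undirected, the matrix is
    symmetric.
    """
    from scipy.sparse.csgraph import dijkstra

    t = friction.cell_hours()
    nrows, ncols = t.shape
    extent_y = nrows * friction.cell_km
    cols = np.clip((centroids["x_km"].to_numpy() / friction.cell_km).astype(int), 0, ncols - 1)
    rows = np.clip(
        ((extent_y - centroids["y_km"].to_numpy()) / friction.cell_km).astype(int), 0, nrows - 1
    )
    if not np.all(np.isfinite(t[rows, cols])):
        bad = centroids["district_id"].to_numpy()[~np.isfinite(t[rows, cols])]
        raise ValueError(f"origin/destination cells impassable for districts: {list(bad)}")
    sources = rows * ncols + cols
    g = _grid_graph(friction)
    dist = dijkstra(g, directed=False, indices=sources)
    out = dist[:, sources]
    out = 0.5 * (out + out.T)  # symmetrize away float round-off
    np.fill_diagonal(out, 0.0)
    if np.isinf(out).any():
        warnings.warn("some district pairs have no passable path (travel time = inf)", stacklevel=2)
    ids = centroids["district_id"].to_numpy()
    return pd.DataFrame(out, index=ids, columns=ids)


def matrix_to_long(mat: pd.DataFrame, measure: str, units: str) -> pd.DataFrame:
    """Square matrix -> long format (origin_id, dest_id, measure, value, units)."""
    long = mat.stack().rename("value").reset_index()
    long.columns = ["origin_id", "dest_id", "value"]
    long = long[long["origin_id"] != long["dest_id"]]
    long["measure"] = measure
    long["units"] = units
    return long[["origin_id", "dest_id", "measure", "value", "units"]].reset_index(drop=True)


def distance_correlations(matrices: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pearson correlations among distance measures over off-diagonal pairs."""
    names = list(matrices)
    base = matrices[names[0]]
    n = base.shape[0]
    off = ~np.eye(n, dtype=bool)
    data = {}
    for name in names:
        m = matrices[name].reindex(index=base.index, columns=base.columns).to_numpy(dtype=float)
        data[name] = m[off]
    df = pd.DataFrame(data)
    df = df[np.isfinite(df).all(axis=1)]
    return df.corr()
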