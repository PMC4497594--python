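"""Compute the three distance measures and their correlations.

Euclidean distance between centroids, shortest-path road distance over the
synthetic road network, and least-cost travel time over the friction surface
built from land cover, slope and the road overlay; also the population-
weighted centroid variant of the Euclidean measure.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from odmodels import distances as dd
from odmodels import synthetic as syn

WORLD = Path(__file__).resolve().parents[1] / "results" / "world"
OUT = Path(__file__).resolve().parents[1] / "results" / "distances"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    districts = pd.read_csv(WORLD / "districts.csv")
    nodes = pd.read_csv(WORLD / "road_nodes.csv")
    edges = pd.read_csv(WORLD / "road_edges.csv")
    land, hdr = syn.read_ascii_grid(WORLD / "land_class.asc")
    slope, _ = syn.read_ascii_grid(WORLD / "slope.asc")
    pop_grid, _ = syn.read_ascii_grid(WORLD / "population.asc")
    cell = float(hdr["cellsize"])

    eu = dd.euclidean_matrix(districts)
    road = dd.road_distance_matrix(edges, districts, nodes)
    fric = dd.build_friction_surface(land, slope, cell, road_edges=edges, road_nodes=nodes)
    tt = dd.travel_time_matrix(fric, districts)

    # population-weighted centroids from the gridded population
    ras = syn.generate_rasters(districts, cell_km=cell, seed=20260920)
    pw = dd.population_weighted_centroids(
        ras["population"], ras["district_mask"], ras["district_index"], cell, road_nodes=nodes
    )
    eu_pw = dd.euclidean_matrix(pw)

    long = pd.concat(
        [
            dd.matrix_to_long(eu, "euclidean", "km"),
            dd.matrix_to_long(eu_pw, "euclidean_popweighted", "km"),
            dd.matrix_to_long(road, "road", "km"),
            dd.matrix_to_long(tt, "travel_time", "h"),
        ]
    )
    long.to_csv(OUT / "distances_long.csv", index=False)
    corr = dd.distance_correlations(
        {"euclidean": eu, "euclidean_popweighted": eu_pw, "road": road, "travel_time": tt}
    )
    corr.to_csv(OUT / "distance_correlations.csv")

    print("pairwise correlations among distance measures:")
    print(corr.round(3).to_string())
    ratio = (road.to_numpy() / np.where(eu.to_numpy() == 0, np.nan, eu.to_numpy()))
    print(f"road/Euclidean detour factor: median {np.nanmedian(ratio):.2f}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
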