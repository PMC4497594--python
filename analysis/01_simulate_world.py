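"""Generate the synthetic study world: districts, flows, diaries, rasters, roads.

Builds a 69-district country with log-normal populations and planted urban
clusters, draws one year of inter-district flows from the gravity truth
(alpha = beta = 1.22, gamma = 2.05, log k = -20.06) with Poisson noise, plans
subscriber journeys, emits call-record diaries with call-frequency gaps, and
writes aligned population/land-cover/slope rasters plus a road network.
"""

from pathlib import Path

from odmodels import synthetic as syn

OUT = Path(__file__).resolve().parents[1] / "results" / "world"
SEED = 20260920


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = syn.SyntheticConfig(seed=SEED, subscribers_per_district=20, n_days=365)
    districts = syn.generate_districts(cfg)
    od = syn.simulate_flows(districts, cfg.gravity_truth, seed=SEED)
    plan = syn.make_travel_plan(
        districts,
        cfg,
        trip_rate_per_day=0.25,
        duration_logmean=2.2,
        duration_logsd=1.6,
        dest_beta=0.9,
        dest_gamma=1.8,
        duration_beta_slope=0.25,
        duration_gamma_slope=-0.18,
    )
    records, towers = syn.simulate_diaries(
        districts, plan, call_prob=cfg.call_prob_per_day, seed=SEED, towers_per_district=2
    )
    rasters = syn.generate_rasters(districts, cell_km=10.0, seed=SEED)

    districts.to_csv(OUT / "districts.csv", index=False)
    od.drop(columns="true_mean").to_csv(OUT / "od_table.csv", index=False)
    plan.trips.to_csv(OUT / "true_trips.csv", index=False)
    records.to_csv(OUT / "diaries.csv", index=False)
    towers.to_csv(OUT / "tower_map.csv", index=False)
    for name in ("population", "land_class", "slope"):
        syn.write_ascii_grid(OUT / f"{name}.asc", rasters[name], rasters["cell_km"])
    rasters["road_nodes"].to_csv(OUT / "road_nodes.csv", index=False)
    rasters["road_edges"].to_csv(OUT / "road_edges.csv", index=False)

    print(f"world: {len(districts)} districts, populations "
          f"{districts.population.min():,}-{districts.population.max():,}")
    print(f"flows: {len(od)} routes, {od.trips.sum():,} trips, "
          f"{(od.trips > 0).sum()} routes with positive flow")
    print(f"diaries: {records.subscriber_id.nunique()} subscribers, "
          f"{len(plan.trips)} true trips")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
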