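"""Evaluate the fitted models: errors, exclusion, model choice, subsets.

Computes per-route log errors for gravity and radiation, the KS diagnostic
against the N(0,1) error assumption, the 2-SD exclusion rule, per-route
winners and the logistic choice regression on the gravity factor, plus
gravity refits on route subsets (capital, urban/rural classes) and distance
measures.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from odmodels import evaluate as ev
from odmodels.pipeline import _distance_matrix_from_od, evaluate_models

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "evaluation"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    od = pd.read_csv(ROOT / "world" / "od_table.csv")
    districts = pd.read_csv(ROOT / "world" / "districts.csv")
    long = pd.read_csv(ROOT / "distances" / "distances_long.csv")
    road = long[long["measure"] == "road"][["origin_id", "dest_id", "value"]]
    od = od.merge(road.rename(columns={"value": "dist_road_km"}), on=["origin_id", "dest_id"])

    _, dist = _distance_matrix_from_od(od)
    res = evaluate_models(od, districts, dist)
    tables = res.pop("_tables")
    tables["flags"].to_csv(OUT / "route_flags.csv", index=False)
    with open(OUT / "evaluation.json", "w") as fh:
        json.dump(res, fh, indent=2)

    print("model comparison on the year-total table:")
    for m in ("gravity", "radiation"):
        r = res[f"fit_{m}"]
        print(f"  {m:9s} reduction in deviance {r['reduction_in_deviance_pct']:6.1f}%  "
              f"adjusted R^2 {r['adjusted_r2']:.3f}  mean Dice {r['dice_mean']:.3f}")
    e = res["errors"]
    print(f"errors: KS={e['ks_statistic']:.4f} (p={e['ks_pvalue']:.2g}); "
          f"{e['pct_routes_flagged']:.1f}% of routes flagged by the 2-SD rule")
    if "b1" in res["choice"]:
        c = res["choice"]
        print(f"choice regression: logit(p_gravity) = {c['b0']:.2f} + {c['b1']:.3f} * log10(gm)"
              f"  (pseudo-R^2 {c['pseudo_r2']:.3f})")

    # subset refits: capital routes, urban/rural classes, near/far bands
    classes = ev.density_terciles(districts)
    cap = districts.sort_values("population", ascending=False)["district_id"].iloc[0]
    cls_o = classes.reindex(od["origin_id"]).to_numpy()
    cls_d = classes.reindex(od["dest_id"]).to_numpy()
    subsets = {
        "all": np.ones(len(od), dtype=bool),
        "to_from_capital": (od["origin_id"] == cap) | (od["dest_id"] == cap),
        "urban_urban": (cls_o == "urban") & (cls_d == "urban"),
        "rural_rural": (cls_o == "rural") & (cls_d == "rural"),
        "near_200km": od["dist_euclid_km"] < 200,
        "far_200km": od["dist_euclid_km"] >= 200,
    }
    rep = ev.subset_analysis(od, subsets, ["dist_euclid_km", "dist_road_km"])
    rep.to_csv(OUT / "subset_fits.csv", index=False)
    print("\nreduction in deviance by subset and distance measure:")
    print(
        rep.pivot(index="subset", columns="distance", values="reduction_in_deviance_pct")
        .round(1)
        .to_string()
    )
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
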