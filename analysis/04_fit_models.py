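"""Fit the interaction models to the year-total OD table.

Unconstrained gravity by Poisson regression (per distance measure),
production-/attraction-/doubly constrained variants by IPF balancing, the
radiation model with its fitted traveler fraction, and a separate gravity
fit per trip-duration stratum.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from odmodels import models as im
from odmodels.pipeline import _distance_matrix_from_od

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "fits"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    od = pd.read_csv(ROOT / "world" / "od_table.csv")
    districts = pd.read_csv(ROOT / "world" / "districts.csv")
    long = pd.read_csv(ROOT / "distances" / "distances_long.csv")

    # attach road and travel-time measures to the route table
    for measure, col in (("road", "dist_road_km"), ("travel_time", "travel_time_h")):
        sub = long[long["measure"] == measure][["origin_id", "dest_id", "value"]]
        od = od.merge(sub.rename(columns={"value": col}), on=["origin_id", "dest_id"])

    report: dict = {}
    for col in ("dist_euclid_km", "dist_road_km", "travel_time_h"):
        p = im.fit_gravity(od, distance_col=col)
        report[col] = {
            "alpha": p.alpha, "beta": p.beta, "gamma": p.gamma, "log_k": p.log_k,
            "reduction_in_deviance_pct": p.reduction_in_deviance_pct,
        }
        print(f"gravity[{col}]: alpha={p.alpha:.3f} beta={p.beta:.3f} "
              f"gamma={p.gamma:.3f} log_k={p.log_k:.2f} "
              f"reduction in deviance={p.reduction_in_deviance_pct:.1f}%")

    gp = im.fit_gravity(od)
    obs = od["trips"].to_numpy(dtype=float)
    sse_un = float(np.sum((obs - im.gravity_predict(gp, od)) ** 2))
    report["constrained"] = {"unconstrained_sse": sse_un}
    for variant in ("production", "attraction", "doubly"):
        cf = im.fit_constrained_gravity(od, variant, params=gp)
        sse = float(np.sum((obs - cf.predictions["predicted"].to_numpy()) ** 2))
        report["constrained"][variant] = {
            "n_iter": cf.n_iter, "max_margin_rel_err": cf.max_margin_rel_err, "sse": sse,
        }
        print(f"constrained[{variant}]: {cf.n_iter} IPF iterations, SSE {sse:,.0f} "
              f"(unconstrained {sse_un:,.0f})")

    dist_d, dist = _distance_matrix_from_od(od)
    spec = im.fit_radiation_fraction(od, districts, dist)
    report["radiation"] = {"tct": spec.tct, "tct_linear": spec.tct_linear}
    print(f"radiation: fitted traveler fraction T_c/T = {spec.tct} "
          f"(linear-scale {spec.tct_linear:.4f})")

    # duration-stratified gravity fits from the extracted trips
    rows = []
    for stratum in ("All", "Week", "Biweek", "Month", "Month2", "Month3", "Month4plus"):
        path = ROOT / "trips" / f"od_{stratum}.csv"
        od_s = pd.read_csv(path)
        if (od_s["trips"] > 0).sum() < 50:
            print(f"stratum {stratum}: too few positive routes, skipped")
            continue
        p = im.fit_gravity(od_s)
        rows.append({"stratum": stratum, "alpha": p.alpha, "beta": p.beta,
                     "gamma": p.gamma, "log_k": p.log_k,
                     "reduction_in_deviance_pct": p.reduction_in_deviance_pct})
    strata = pd.DataFrame(rows)
    strata.to_csv(OUT / "gravity_by_duration.csv", index=False)
    print("\ngravity fits by trip duration (destination attraction rises, "
          "distance decay falls with duration):")
    print(strata.round(3).to_string(index=False))

    with open(OUT / "fit_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
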