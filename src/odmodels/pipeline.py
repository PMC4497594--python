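"""Config-driven orchestration: simulate or ingest, fit, evaluate, report.

The pipeline runs in one of three input modes: ``synthetic`` (generate a
world and its flows), ``od-table`` (ingest a deposited route-level table)
or ``diaries`` (ingest call-record diaries plus a tower map and extract the
OD table).  Every run writes its reports, a config echo and a checksummed
manifest into the output directory; all randomness flows from the single
configured seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import models as im
from . import synthetic as syn
from . import trips as tr

log = logging.getLogger("odmodels")

__all__ = ["PipelineConfig", "run_pipeline", "read_od_table", "write_report"]

# Header synonyms accepted when ingesting deposited route-level tables
# (XLSX or CSV); keys are canonical column names.
COLUMN_SYNONYMS: dict[str, list[str]] = {
    "origin_id": ["origin_id", "origin", "from", "district_i", "orig", "origin district"],
    "dest_id": ["dest_id", "destination", "dest", "to", "district_j", "destination district"],
    "pop_orig": ["pop_orig", "origin_pop", "pop_i", "population_origin", "origin population"],
    "pop_dest": ["pop_dest", "dest_pop", "pop_j", "population_destination", "destination population"],
    "dist_euclid_km": ["dist_euclid_km", "distance", "dist", "euclidean", "distance_km", "euclidean distance"],
    "trips": ["trips", "flow", "n_ij", "count", "amount", "travel", "amount of travel"],
}

_ALLOWED_KEYS = {
    "mode",
    "seed",
    "out_dir",
    "od_path",
    "diaries_path",
    "tower_map_path",
    "n_districts",
    "distance_measures",
    "duration_bins",
    "models",
    "exclusion_rule",
    "synthetic",
}


@dataclasses.dataclass
class PipelineConfig:
    mode: str = "synthetic"  # synthetic | od-table | diaries
    seed: int = 0
    out_dir: str = "results/run"
    od_path: str | None = None
    diaries_path: str | None = None
    tower_map_path: str | None = None
    n_districts: int = 69
    distance_measures: tuple[str, ...] = ("dist_euclid_km",)
    duration_bins: tuple | None = None
    models: tuple[str, ...] = ("gravity", "radiation")
    exclusion_rule: str = "fixed"
    synthetic: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if cfg.mode not in ("synthetic", "od-table", "diaries"):
            raise ValueError(f"unknown mode {cfg.mode!r}")
        if cfg.mode == "od-table" and not cfg.od_path:
            raise ValueError("od-table mode requires od_path")
        if cfg.mode == "diaries" and not (cfg.diaries_path and cfg.tower_map_path):
            raise ValueError("diaries mode requires diaries_path and tower_map_path")
        if cfg.exclusion_rule not in ("fixed", "empirical"):
            raise ValueError("exclusion_rule must be 'fixed' or 'empirical'")
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_od_table(path: str | Path) -> pd.DataFrame:
    """Read a route-level OD table from CSV or XLSX into the canonical layout.

    Column names are matched case-insensitively against a synonym map;
    non-numeric flows, non-positive distances and duplicated routes raise.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path)
    else:
        raw = pd.read_csv(path)
    lower = {str(c).strip().lower(): c for c in raw.columns}
    mapping = {}
    for canon, alts in COLUMN_SYNONYMS.items():
        for alt in alts:
            if alt in lower:
                mapping[canon] = lower[alt]
                break
        else:
            raise ValueError(f"no column found for {canon!r}; have {list(raw.columns)}")
    od = raw[[mapping[c] for c in COLUMN_SYNONYMS]].copy()
    od.columns = list(COLUMN_SYNONYMS)
    for col in ("pop_orig", "pop_dest", "dist_euclid_km", "trips"):
        od[col] = pd.to_numeric(od[col], errors="raise")
    dup = od.duplicated(subset=["origin_id", "dest_id"])
    if dup.any():
        raise ValueError(f"duplicated route rows: {od.loc[dup, ['origin_id','dest_id']].values[:5]}")
    if (od["origin_id"] == od["dest_id"]).any():
        raise ValueError("within-district rows are not allowed in an OD table")
    if (od["dist_euclid_km"] <= 0).any():
        raise ValueError("non-positive distances in OD table")
    if (od["trips"] < 0).any():
        raise ValueError("negative flows in OD table")
    return od


def write_report(reports: dict, out_dir: str | Path) -> Path:
    """Serialize a dict of reports (JSON-able values / DataFrames) under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, obj in reports.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out / f"{name}.csv", index=False)
        else:
            with open(out / f"{name}.json", "w") as fh:
                json.dump(obj, fh, indent=2, default=_jsonify)
    return out


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


def _manifest(out: Path) -> pd.DataFrame:
    rows = []
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.csv":
            rows.append({"file": str(p.relative_to(out)), "sha256": hashlib.sha256(p.read_bytes()).hexdigest()})
    return pd.DataFrame(rows)


def _distance_matrix_from_od(od: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Recover a district table and square distance matrix from a route table."""
    ids = pd.unique(pd.concat([od["origin_id"], od["dest_id"]]))
    pop = (
        pd.concat(
            [
                od[["origin_id", "pop_orig"]].rename(columns={"origin_id": "district_id", "pop_orig": "population"}),
                od[["dest_id", "pop_dest"]].rename(columns={"dest_id": "district_id", "pop_dest": "population"}),
            ]
        )
        .groupby("district_id")["population"]
        .first()
        .reindex(ids)
    )
    districts = pd.DataFrame({"district_id": ids, "population": pop.to_numpy()})
    idx = pd.Index(ids)
    n = len(ids)
    dist = np.full((n, n), np.nan)
    oi = idx.get_indexer(od["origin_id"])
    dj = idx.get_indexer(od["dest_id"])
    dist[oi, dj] = od["dist_euclid_km"].to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    # symmetrize any pairs present in only one direction
    miss = np.isnan(dist)
    dist[miss] = dist.T[miss]
    return districts, dist


def evaluate_models(
    od: pd.DataFrame,
    districts: pd.DataFrame,
    dist: np.ndarray,
    exclusion_rule: str = "fixed",
) -> dict:
    """Fit gravity + radiation on one OD table and run the full evaluation."""
    out: dict = {}
    gp = im.fit_gravity(od)
    pred_g = im.gravity_predict(gp, od)
    out["gravity_params"] = {
        "alpha": gp.alpha,
        "beta": gp.beta,
        "gamma": gp.gamma,
        "log_k": gp.log_k,
        "conf_int": gp.conf_int,
        "reduction_in_deviance_pct": gp.reduction_in_deviance_pct,
    }

    spec = im.fit_radiation_fraction(od, districts, dist)
    mu_r = im.radiation_predict(districts, spec.s, tct=spec.tct)
    idx = pd.Index(districts["district_id"])
    pred_r = mu_r[idx.get_indexer(od["origin_id"]), idx.get_indexer(od["dest_id"])]
    out["radiation"] = {"tct": spec.tct, "tct_linear": spec.tct_linear}

    out["fit_gravity"] = ev.fit_statistics(od, pred_g, "gravity", n_parameters=4).to_dict()
    out["fit_radiation"] = ev.fit_statistics(od, pred_r, "radiation", n_parameters=1).to_dict()

    eg = ev.route_errors(od, pred_g, "gravity")
    er = ev.route_errors(od, pred_r, "radiation")
    flags = ev.flag_unmodelable({"gravity": eg, "radiation": er}, rule=exclusion_rule)
    ks_stat, ks_p = ev.ks_normality(
        np.concatenate([eg.table["error"].to_numpy(), er.table["error"].to_numpy()])
    )
    out["errors"] = {
        "ks_statistic": ks_stat,
        "ks_pvalue": ks_p,
        "pct_routes_flagged": 100.0 * float(flags["unmodelable"].mean()),
        "n_routes_compared": int(len(flags)),
    }

    winners = ev.label_better_model(flags)
    wod = od.merge(winners[["origin_id", "dest_id", "winner"]], on=["origin_id", "dest_id"])
    gm = im.gravity_factor(wod)
    try:
        cm = ev.fit_choice_logistic(wod, gm)
        out["choice"] = {
            "b0": cm.b0,
            "b1": cm.b1,
            "pseudo_r2": cm.pseudo_r2,
            "transform": cm.transform,
            "separation": cm.separation,
        }
    except ValueError as exc:
        out["choice"] = {"error": str(exc)}
    out["_tables"] = {"flags": flags, "winners": winners}
    return out


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the configured pipeline end to end; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    try:
        log.info("stage=config hash=%s mode=%s seed=%d", config.config_hash(), config.mode, config.seed)
        if config.mode == "synthetic":
            scfg = syn.SyntheticConfig(
                n_districts=config.n_districts, seed=config.seed, **config.synthetic
            )
            districts = syn.generate_districts(scfg)
            od = syn.simulate_flows(districts, scfg.gravity_truth, seed=config.seed)
            _, dist = _distance_matrix_from_od(od)
        elif config.mode == "od-table":
            od = read_od_table(config.od_path)
            districts, dist = _distance_matrix_from_od(od)
        else:  # diaries
            records = pd.read_csv(config.diaries_path)
            tower_map = pd.read_csv(config.tower_map_path)
            series = tr.assign_daily_locations(records, tower_map, seed=config.seed)
            trips = tr.extract_trips(series)
            if config.od_path:
                base = read_od_table(config.od_path)
                districts, dist = _distance_matrix_from_od(base)
            else:
                raise ValueError("diaries mode also needs od_path for populations/distances")
            od = tr.aggregate_od(trips, districts.assign(x_km=np.nan, y_km=np.nan), dist=dist, zero_fill=True)
        log.info("stage=ingest routes=%d districts=%d", len(od), len(districts))

        results = evaluate_models(od, districts, dist, exclusion_rule=config.exclusion_rule)
        tables = results.pop("_tables")
        results["config"] = dataclasses.asdict(config)
        results["config"]["hash"] = config.config_hash()
        write_report(results, out)
        od.to_csv(out / "od_table.csv", index=False)
        tables["flags"].to_csv(out / "route_flags.csv", index=False)
        _manifest(out).to_csv(out / "manifest.csv", index=False)
        log.info("stage=done out=%s", out)
        return out
    finally:
        log.removeHandler(fh)
        fh.close()
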