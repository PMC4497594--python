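"""From call records to daily locations, trips, durations and OD tables.

A subscriber's location on a day is the district of their majority routing
tower that day (ties broken uniformly at random, seeded); call-free days
inherit the most recent assigned location, and leading call-free days are
dropped.  A trip opens whenever the daily district changes, and its duration
is the number of consecutive days then spent in the visited district.  Trips
are stratified into duration bins (week to four-plus months) and aggregated
into route-level origin-destination tables; within-district movement is
ignored throughout.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

__all__ = [
    "assign_daily_locations",
    "extract_trips",
    "DEFAULT_DURATION_BINS",
    "stratify_by_duration",
    "aggregate_od",
]

# (label, lower, upper) half-open [lower, upper) duration bins in days.
# "Week" includes every sub-two-week trip; see the docs for the alternative
# reading with a 7-day floor.
DEFAULT_DURATION_BINS: tuple[tuple[str, int, int], ...] = (
    ("Week", 1, 14),
    ("Biweek", 14, 30),
    ("Month", 30, 60),
    ("Month2", 60, 90),
    ("Month3", 90, 120),
    ("Month4+", 120, np.iinfo(np.int64).max),
)


def _tie_rng(seed: int, subscriber_id: str, day: int) -> np.random.Generator:
    # keyed per subscriber-day so re-running one subscriber never reshuffles others
    key = zlib.crc32(f"{subscriber_id}|{day}".encode())
    return np.random.default_rng([seed, key])


def assign_daily_locations(
    records: pd.DataFrame,
    tower_map: pd.DataFrame,
    seed: int = 0,
    n_days: int | None = None,
) -> pd.DataFrame:
    """Assign one district per subscriber-day from call records.

    ``records`` has columns (subscriber_id, day, tower_id), one row per call;
    ``tower_map`` maps tower_id -> district_id.  The day's location is the
    district of the modal tower; modal ties are broken uniformly at random
    under ``seed``.  Days without calls inherit the most recent location;
    days before a subscriber's first call are dropped.  Output days are
    contiguous per subscriber up to ``n_days`` (default: max observed day+1).
    """
    required = {"subscriber_id", "day", "tower_id"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    unknown = set(records["tower_id"]) - set(tower_map["tower_id"])
    if unknown:
        raise KeyError(f"towers missing from tower_map: {sorted(unknown)[:10]}")
    if n_days is None:
        n_days = int(records["day"].max()) + 1

    tower_district = tower_map.set_index("tower_id")["district_id"]
    rec = records[["subscriber_id", "day", "tower_id"]].sort_values(["subscriber_id", "day"])

    out: list[pd.DataFrame] = []
    for sub, g in rec.groupby("subscriber_id", sort=True):
        per_day = g.groupby(["day", "tower_id"]).size().unstack(fill_value=0)
        towers = per_day.columns.to_numpy()
        arr = per_day.to_numpy()
        maxv = arr.max(axis=1)
        is_max = arr == maxv[:, None]
        day_index = per_day.index.to_numpy()
        chosen = towers[np.argmax(is_max, axis=1)].astype(object)
        tie_rows = np.flatnonzero(is_max.sum(axis=1) > 1)
        for r in tie_rows:
            modal = np.sort(towers[is_max[r]])
            chosen[r] = _tie_rng(seed, str(sub), int(day_index[r])).choice(modal)
        first = int(day_index[0])
        daily = pd.Series(chosen, index=day_index).map(tower_district)
        # call-free days inherit the most recent assigned location
        daily = daily.reindex(np.arange(first, n_days)).ffill()
        out.append(
            pd.DataFrame(
                {
                    "subscriber_id": sub,
                    "day": np.arange(first, n_days),
                    "district_id": daily.to_numpy(),
                }
            )
        )
    if not out:
        return pd.DataFrame(columns=["subscriber_id", "day", "district_id"])
    return pd.concat(out, ignore_index=True)


def extract_trips(series: pd.DataFrame) -> pd.DataFrame:
    """Extract trips from daily district series.

    A trip opens when the day-t district differs from the day-(t-1) district;
    its duration is the run length of consecutive days in the visited
    district.  The final run of each subscriber is cut off by the end of the
    observation window and is emitted with ``truncated=True``.

    Returns columns (subscriber_id, origin, destination, start_day, duration,
    truncated); an empty input yields an empty frame.
    """
    cols = ["subscriber_id", "origin", "destination", "start_day", "duration", "truncated"]
    if len(series) == 0:
        return pd.DataFrame(columns=cols)
    rows: list[tuple] = []
    for sub, g in series.sort_values(["subscriber_id", "day"]).groupby("subscriber_id", sort=True):
        days = g["day"].to_numpy()
        if not np.all(np.diff(days) == 1):
            raise ValueError(f"days not contiguous for subscriber {sub!r}")
        loc = g["district_id"].to_numpy()
        change = np.flatnonzero(loc[1:] != loc[:-1]) + 1  # run starts after day 0
        bounds = np.concatenate([[0], change, [len(loc)]])
        for k in range(1, len(bounds) - 1):
            start, end = bounds[k], bounds[k + 1]
            rows.append(
                (
                    sub,
                    loc[start - 1],
                    loc[start],
                    int(days[start]),
                    int(end - start),
                    k == len(bounds) - 2,  # last run ends at the window edge
                )
            )
    trips = pd.DataFrame(rows, columns=cols)
    if len(trips):
        trips = trips.astype({"start_day": np.int64, "duration": np.int64, "truncated": bool})
    return trips


def stratify_by_duration(
    trips: pd.DataFrame,
    bins: tuple[tuple[str, int, int], ...] = DEFAULT_DURATION_BINS,
    include_truncated_in_bins: bool = False,
) -> dict[str, pd.DataFrame]:
    """Split trips into duration strata; 'All' keeps every trip.

    Bins are half-open [lower, upper) in days and partition the durations at
    or above the lowest bin floor.  Truncated trips (cut by the window edge,
    so their duration is a lower bound) stay in 'All' but are excluded from
    the bins unless ``include_truncated_in_bins``.
    """
    if len(trips) and (trips["duration"] < 0).any():
        raise ValueError("negative trip duration: corrupt input")
    lows = [lo for _, lo, _ in bins]
    his = [hi for _, _, hi in bins]
    if any(h != l for h, l in zip(his[:-1], lows[1:])):
        raise ValueError("duration bins must be contiguous")
    out = {"All": trips}
    binnable = trips if include_truncated_in_bins else trips[~trips["truncated"]]
    for label, lo, hi in bins:
        out[label] = binnable[(binnable["duration"] >= lo) & (binnable["duration"] < hi)]
    return out


def aggregate_od(
    trips: pd.DataFrame,
    districts: pd.DataFrame,
    dist: np.ndarray | None = None,
    distance_cols: pd.DataFrame | None = None,
    zero_fill: bool = False,
) -> pd.DataFrame:
    """Aggregate trips into a route-level OD table over the whole window.

    Counts are summed per ordered (origin, destination) pair; within-district
    movements are ignored (they cannot occur in ``extract_trips`` output).
    ``dist`` is a square Euclidean distance matrix aligned with ``districts``;
    ``distance_cols`` may add further long-format measures indexed by
    (origin_id, dest_id).  With ``zero_fill``, all ordered pairs appear, with
    zero counts where no trip was observed.
    """
    idx = pd.Index(districts["district_id"])
    used = set(trips["origin"]) | set(trips["destination"]) if len(trips) else set()
    missing = sorted(used - set(idx))
    if missing:
        raise KeyError(f"districts missing population/coordinates: {missing}")

    counts = (
        trips.groupby(["origin", "destination"]).size().rename("trips").reset_index()
        if len(trips)
        else pd.DataFrame(columns=["origin", "destination", "trips"])
    )
    counts = counts[counts["origin"] != counts["destination"]]
    if zero_fill:
        n = len(idx)
        i, j = np.where(~np.eye(n, dtype=bool))
        allpairs = pd.DataFrame({"origin": idx.to_numpy()[i], "destination": idx.to_numpy()[j]})
        counts = allpairs.merge(counts, how="left", on=["origin", "destination"]).fillna({"trips": 0})

    pop = districts.set_index("district_id")["population"]
    od = counts.rename(columns={"origin": "origin_id", "destination": "dest_id"})
    od["pop_orig"] = pop.reindex(od["origin_id"]).to_numpy()
    od["pop_dest"] = pop.reindex(od["dest_id"]).to_numpy()

    if dist is None:
        xy = districts[["x_km", "y_km"]].to_numpy()
        diff = xy[:, None, :] - xy[None, :, :]
        dist = np.hypot(diff[..., 0], diff[..., 1])
    oi = idx.get_indexer(od["origin_id"])
    dj = idx.get_indexer(od["dest_id"])
    od["dist_euclid_km"] = dist[oi, dj]
    if (od["dist_euclid_km"] <= 0).any():
        bad = od.loc[od["dist_euclid_km"] <= 0, ["origin_id", "dest_id"]]
        raise ValueError(f"non-positive distance for pairs: {bad.to_records(index=False)[:10]}")

    if distance_cols is not None:
        od = od.merge(distance_cols, how="left", on=["origin_id", "dest_id"])
        extra = [c for c in distance_cols.columns if c not in ("origin_id", "dest_id")]
        if od[extra].isna().any().any():
            bad = od.loc[od[extra].isna().any(axis=1), ["origin_id", "dest_id"]]
            raise ValueError(f"missing distances for pairs: {bad.to_records(index=False)[:10]}")
    od["trips"] = od["trips"].astype(np.int64)
    return od.reset_index(drop=True)
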