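"""Haulout detection, trip segmentation, track regularization and trip metrics.

A haulout event opens when the tag's wet/dry sensor has been continuously dry
for more than 10 minutes and closes at the first instant it has been
continuously wet for 40 seconds; brief splashes shorter than 40 s do not split
an event.  Trips are the at-sea excursions between consecutive haulout events
of one seal.  Tracks are regularized to a 20-minute lattice by straight-line
interpolation before trip metrics (duration, maximum at-sea extent) are
computed, to reduce sampling bias between areas where fix success differs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SeasonWindows",
    "Trip",
    "detect_haulouts",
    "assign_colony",
    "segment_trips",
    "interpolate_track",
    "filter_trips",
    "trip_metrics",
]

GRAY_EXCLUDED_MONTHS = frozenset({9, 10, 11, 12, 1, 2})   # breeding Sep-Dec + molt Jan-Feb
HARBOR_EXCLUDED_MONTHS = frozenset({6, 7, 8, 9})          # breeding Jun-Jul + molt Aug-Sep


@dataclass(frozen=True)
class SeasonWindows:
    """Months excluded from analysis (breeding + early molt), per species."""

    species: str
    excluded_months: frozenset = field(default_factory=frozenset)

    @classmethod
    def for_species(cls, species: str) -> "SeasonWindows":
        if species == "gray":
            return cls("gray", GRAY_EXCLUDED_MONTHS)
        if species == "harbor":
            return cls("harbor", HARBOR_EXCLUDED_MONTHS)
        raise ValueError(f"unknown species {species!r}")

    def __post_init__(self):
        if any(m < 1 or m > 12 for m in self.excluded_months):
            raise ValueError("months must be in 1..12")


@dataclass
class Trip:
    """One return excursion between two haulout events."""

    seal: str
    departure_end: pd.Timestamp
    arrival_start: pd.Timestamp
    fixes: pd.DataFrame                  # raw at-sea fixes strictly inside the trip
    track: pd.DataFrame | None = None    # regularized 20-min positions
    departure_site: str | None = None
    arrival_site: str | None = None
    colony_return: bool | None = None
    duration_h: float = 0.0
    max_extent_km: float = np.nan

    def __post_init__(self):
        self.duration_h = (self.arrival_start - self.departure_end).total_seconds() / 3600.0


def _runs(values: np.ndarray, t: np.ndarray):
    """Run-length encode a step series: yields (value, t_start, t_end)."""
    change = np.nonzero(np.diff(values))[0]
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [len(values)]])
    for s, e in zip(starts, ends):
        t_end = t[e] if e < len(t) else t[-1]
        yield values[s], t[s], t_end


def detect_haulouts(wetdry: pd.DataFrame, dry_start_min: float = 10.0,
                    wet_end_s: float = 40.0) -> pd.DataFrame:
    """Haulout events from a timestamped binary wet/dry series.

    ``wetdry`` needs columns ``seal``, ``time``, ``dry`` (1 = dry, 0 = wet);
    each value holds until the next timestamp.  An event opens at the start
    of a maximal dry run strictly longer than ``dry_start_min`` minutes and
    closes at the start of the first wet run lasting at least ``wet_end_s``
    seconds.  Returns a DataFrame (seal, start, end).
    """
    vals = wetdry["dry"].to_numpy()
    if not np.isin(vals, [0, 1]).all():
        raise ValueError("wet/dry series must be binary (0 = wet, 1 = dry)")
    events = []
    for seal, sub in wetdry.groupby("seal", sort=True):
        sub = sub.sort_values("time")
        t = pd.to_datetime(sub["time"]).to_numpy()
        v = sub["dry"].to_numpy().astype(int)
        open_start = None
        for val, t0, t1 in _runs(v, t):
            dur_s = (t1 - t0) / np.timedelta64(1, "s")
            if open_start is None:
                if val == 1 and dur_s > dry_start_min * 60.0:
                    open_start = t0
            else:
                if val == 0 and dur_s >= wet_end_s:
                    events.append((seal, open_start, t0))
                    open_start = None
        if open_start is not None:
            events.append((seal, open_start, t[-1]))
    out = pd.DataFrame(events, columns=["seal", "start", "end"])
    return out.sort_values(["seal", "start"]).reset_index(drop=True)


def assign_colony(events: pd.DataFrame, fixes: pd.DataFrame, sites: pd.DataFrame,
                  tagging_site: str, radius_km: float = 50.0) -> pd.DataFrame:
    """Assign each haulout event to its nearest site and flag extra-colony events.

    The event's representative location is the nearest-in-time fix of the
    same seal.  The colony is the set of sites within ``radius_km`` of the
    tagging site; events whose nearest site lies beyond the radius are
    flagged ``extra_colony``.
    """
    if sites.empty:
        raise ValueError("site catalog is empty")
    tag = sites.loc[sites["site"] == tagging_site]
    if tag.empty:
        raise ValueError(f"tagging site {tagging_site!r} not in catalog")
    tx, ty = float(tag["x"].iloc[0]), float(tag["y"].iloc[0])
    site_xy = sites[["x", "y"]].to_numpy(float)
    colony_sites = set(
        sites["site"].to_numpy()[np.hypot(site_xy[:, 0] - tx, site_xy[:, 1] - ty) <= radius_km]
    )

    out = events.copy()
    out["x"] = np.nan
    out["y"] = np.nan
    for seal, sub in out.groupby("seal", sort=False):
        fsub = fixes.loc[fixes["seal"] == seal].sort_values("time")
        if fsub.empty:
            continue
        ft = pd.to_datetime(fsub["time"]).to_numpy().astype("datetime64[ns]").astype(np.int64)
        mid = (pd.to_datetime(sub["start"]).to_numpy().astype("datetime64[ns]").astype(np.int64)
               + pd.to_datetime(sub["end"]).to_numpy().astype("datetime64[ns]").astype(np.int64)) // 2
        idx = np.clip(np.searchsorted(ft, mid), 0, len(ft) - 1)
        prev = np.clip(idx - 1, 0, len(ft) - 1)
        use_prev = np.abs(ft[prev] - mid) < np.abs(ft[idx] - mid)
        nearest = np.where(use_prev, prev, idx)
        out.loc[sub.index, "x"] = fsub["x"].to_numpy()[nearest]
        out.loc[sub.index, "y"] = fsub["y"].to_numpy()[nearest]

    dx = out["x"].to_numpy()[:, None] - site_xy[None, :, 0]
    dy = out["y"].to_numpy()[:, None] - site_xy[None, :, 1]
    dist = np.hypot(dx, dy)
    nearest_site = np.argmin(dist, axis=1)
    out["site"] = sites["site"].to_numpy()[nearest_site]
    out["dist_to_site_km"] = dist[np.arange(len(out)), nearest_site]
    tag_dist = np.hypot(out["x"] - tx, out["y"] - ty)
    out["extra_colony"] = (tag_dist > radius_km) | ~out["site"].isin(colony_sites)
    return out


def segment_trips(fixes: pd.DataFrame, events: pd.DataFrame) -> list[Trip]:
    """One trip per consecutive haulout-event pair with at least one strictly
    intervening at-sea fix; fixes at the boundary instants are excluded."""
    trips: list[Trip] = []
    for seal, esub in events.groupby("seal", sort=True):
        esub = esub.sort_values("start")
        fsub = fixes.loc[fixes["seal"] == seal].sort_values("time")
        ft = pd.to_datetime(fsub["time"])
        for i in range(len(esub) - 1):
            dep = esub.iloc[i]
            arr = esub.iloc[i + 1]
            t0 = pd.Timestamp(dep["end"])
            t1 = pd.Timestamp(arr["start"])
            inside = fsub.loc[(ft > t0) & (ft < t1)]
            if inside.empty:
                continue
            trips.append(
                Trip(
                    seal=seal, departure_end=t0, arrival_start=t1,
                    fixes=inside.reset_index(drop=True),
                    departure_site=dep.get("site"), arrival_site=arr.get("site"),
                    colony_return=(
                        (not dep.get("extra_colony", False))
                        and (not arr.get("extra_colony", False))
                        if "extra_colony" in esub.columns else None
                    ),
                )
            )
    return trips


def interpolate_track(trip: Trip, step_min: float = 20.0) -> pd.DataFrame | None:
    """Regularize a trip's fixes onto a ``step_min`` lattice from departure.

    Positions are linearly interpolated between bracketing fixes; no
    extrapolation beyond the first/last fix.  Single-fix trips are dropped
    (None returned, logged).
    """
    f = trip.fixes
    if len(f) < 2:
        logger.info("interpolate_track: single-fix trip for %s dropped", trip.seal)
        return None
    ft = pd.to_datetime(f["time"]).to_numpy().astype("datetime64[ns]").astype(np.int64)
    step = int(step_min * 60 * 1e9)
    t0 = pd.Timestamp(trip.departure_end).to_datetime64().astype("datetime64[ns]").astype(np.int64)
    lattice = np.arange(t0, ft[-1] + 1, step)
    lattice = lattice[(lattice >= ft[0]) & (lattice <= ft[-1])]
    track = pd.DataFrame(
        {
            "time": pd.to_datetime(lattice),
            "x": np.interp(lattice, ft, f["x"].to_numpy(float)),
            "y": np.interp(lattice, ft, f["y"].to_numpy(float)),
        }
    )
    trip.track = track
    return track


def filter_trips(trips: list[Trip], windows: SeasonWindows, min_duration_h: float = 3.0,
                 return_only: bool = False) -> list[Trip]:
    """Duration, season, and (gray-seal mode) return-to-colony filters.

    Drops trips shorter than ``min_duration_h`` (strict <), trips whose
    departure month is excluded, and — when ``return_only`` — trips not
    departing AND arriving at the tagging colony.
    """
    kept = []
    for tr in trips:
        if tr.duration_h < min_duration_h:
            continue
        if pd.Timestamp(tr.departure_end).month in windows.excluded_months:
            continue
        if return_only and tr.colony_return is not True:
            continue
        kept.append(tr)
    return kept


def trip_metrics(trip: Trip, seagraph=None, origin: tuple[float, float] | None = None,
                 straight_line: bool = False) -> tuple[float, float]:
    """(duration in hours, maximum at-sea extent in km) for one trip.

    The extent is the maximum over regularized track points of the at-sea
    least-cost distance from the departure haulout; ``straight_line=True``
    substitutes the direct distance.
    """
    if trip.track is None or trip.track.empty:
        raise ValueError("trip has no regularized track; call interpolate_track first")
    if origin is None:
        origin = (float(trip.fixes["x"].iloc[0]), float(trip.fixes["y"].iloc[0]))
    x = trip.track["x"].to_numpy(float)
    y = trip.track["y"].to_numpy(float)
    if straight_line or seagraph is None:
        ext = float(np.max(np.hypot(x - origin[0], y - origin[1])))
    else:
        onode = seagraph.snap(*origin)
        node_d = seagraph.distances_from(onode)
        grid = seagraph.distance_grid(node_d)
        d = seagraph.seascape.value_at(grid, x, y)
        for i in np.nonzero(np.isnan(d))[0]:
            # 1-cell snap tolerance for points that fall on a land cell
            try:
                d[i] = node_d[seagraph.snap(x[i], y[i])]
            except ValueError:
                raise ValueError("track point on land beyond snapping tolerance") from None
        ext = float(np.nanmax(d))
    trip.max_extent_km = ext
    return trip.duration_h, ext
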