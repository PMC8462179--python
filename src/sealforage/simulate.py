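"""Simulate central-place-foraging seals on a synthetic seascape.

Each seal alternates haulout bouts at its home site with at-sea return trips.
Within a trip, every dive is a foraging dive with probability ``phi`` (the
mixture weight of the ground-truth preference); foraging-dive locations are
drawn from the true selection surface, so their empirical density over sea
cells is exactly the surface the selection model later tries to recover.
The seal travels between its foraging locations along at-sea shortest paths
(it never crosses land), performing square-profiled (U) dives at foraging
stops and V-shaped transit dives while moving.

Outputs mirror what GPS/GSM tags deliver: a 20-minute fix table with
Bernoulli dropout, a dive table with nine intermediate depth points per dive,
and a wet/dry sensor series in which haulout bouts appear as long dry runs
(with occasional sub-40-s wet splashes).  Ground-truth labels and locations
are kept in a separate truth table for parameter-recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra

from .geo import SeaGraph
from .seascape import Seascape, TruePreference, true_selection_surface

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "SimOutput", "simulate_seals", "sample_use_availability"]

_NS = int(1e9)


@dataclass(frozen=True)
class SimConfig:
    """Observation-process and behaviour parameters of the simulator.

    Defaults emulate SMRU-style GPS/GSM deployments: 20-min nominal fix
    interval with 20% dropout, a 10-s wet/dry sensor, seals travelling at
    about 5 km/h, and multi-hour haulout bouts between trips.
    """

    fix_interval_min: float = 20.0
    fix_dropout: float = 0.20
    wetdry_step_s: float = 10.0
    travel_speed_kmh: float = 5.0
    mean_dives_per_trip: float = 12.0
    haulout_h_range: tuple[float, float] = (2.5, 6.0)
    splash_prob: float = 0.5
    start_time: str = "2010-03-05T00:00:00"
    v_max: float = 2.0           # generator-side max vertical transit speed (m/s)


@dataclass
class SimOutput:
    """Simulated tag data plus ground truth."""

    fixes: pd.DataFrame          # seal, time, x, y
    dives: pd.DataFrame          # seal, dive_id, start, end, duration_s, max_depth_m, t1..t9, d1..d9
    wetdry: pd.DataFrame         # seal, time, dry
    truth: pd.DataFrame          # dive_id, foraging_true, x_true, y_true, trip
    haulout_truth: pd.DataFrame  # seal, start, end
    surface: np.ndarray          # normalized true selection surface
    seascape: Seascape = field(repr=False, default=None)
    pref: TruePreference = None


def _u_profile(rng, depth, v_max):
    """Square (U) dive: interior points hug max depth; modest descent speed."""
    v = rng.uniform(0.60, 0.95) * v_max
    t_desc = depth / v
    bottom = rng.uniform(60.0, 240.0)
    T = 2 * t_desc + bottom
    ts = np.linspace(t_desc, T - t_desc, 9)
    ds = depth * rng.uniform(0.92, 1.0, 9)
    ds[4] = depth
    return T, ts, ds


def _v_profile(rng, depth, v_max):
    """Triangular (V) transit dive: brief spike to max depth."""
    v = rng.uniform(0.35, 0.55) * v_max      # descent rate, below foraging speeds
    T = max(2 * depth / v, rng.uniform(35.0, 90.0))
    ts = np.linspace(0.1 * T, 0.9 * T, 9)
    ds = depth * (1.0 - np.abs(2.0 * ts / T - 1.0))
    ds *= rng.uniform(0.95, 1.0, 9)
    ds[4] = depth
    return T, ts, ds


def _greedy_order(start_xy, pts):
    """Visit order of foraging points: nearest-neighbour tour from the haulout."""
    order = []
    left = list(range(len(pts)))
    cur = np.asarray(start_xy, float)
    while left:
        d = [np.hypot(*(pts[i] - cur)) for i in left]
        j = left.pop(int(np.argmin(d)))
        order.append(j)
        cur = pts[j]
    return order


class _Router:
    """Shortest at-sea paths between points, with per-source tree caching."""

    def __init__(self, graph: SeaGraph):
        self.g = graph
        self._cache: dict[int, np.ndarray] = {}

    def path_coords(self, src_xy, dst_xy) -> np.ndarray:
        g = self.g
        s = g.snap(*src_xy)
        t = g.snap(*dst_xy)
        if s == t:
            return np.array([src_xy, dst_xy])
        if s not in self._cache:
            _, pred = dijkstra(g.adj, directed=False, indices=s, return_predecessors=True)
            self._cache[s] = pred
        pred = self._cache[s]
        nodes = [t]
        while nodes[-1] != s:
            p = pred[nodes[-1]]
            if p < 0:
                raise ValueError("destination unreachable over sea")
            nodes.append(p)
        nodes = nodes[::-1]
        ny, nx = g.seascape.shape
        cells = g.sea_idx[nodes]
        rows, cols = cells // nx, cells % nx
        xs = g.seascape.x0 + (cols + 0.5) * g.seascape.cell_km
        ys = g.seascape.y0 + (rows + 0.5) * g.seascape.cell_km
        coords = np.column_stack([xs, ys]).astype(float)
        coords[0] = src_xy
        coords[-1] = dst_xy
        return coords


def simulate_seals(seascape: Seascape, pref: TruePreference, n_seals: int,
                   n_trips_per_seal: int, seed: int,
                   config: SimConfig = SimConfig()) -> SimOutput:
    """Simulate ``n_seals`` seals making ``n_trips_per_seal`` return trips each."""
    if n_seals < 1:
        raise ValueError("need at least one seal")
    if seascape.haulouts.empty:
        raise ValueError("seascape has no haulout sites")

    rng = np.random.default_rng(seed)
    graph = SeaGraph(seascape)
    router = _Router(graph)

    # all haulout sites must live in one sea component
    site_nodes = {row.site: graph.snap(row.x, row.y) for row in seascape.haulouts.itertuples()}
    comps = {s: graph.component[n] for s, n in site_nodes.items()}
    if len(set(comps.values())) > 1:
        groups: dict[int, list[str]] = {}
        for s, c in comps.items():
            groups.setdefault(c, []).append(s)
        raise ValueError(
            "haulout sites fall in disconnected sea regions: "
            + "; ".join(",".join(v) for v in groups.values())
        )

    surface = true_selection_surface(seascape, pref)
    home_comp = next(iter(comps.values()))
    ny, nx = seascape.shape
    comp_grid = graph.distance_grid(graph.component.astype(float))
    reachable = (comp_grid == home_comp)
    p = np.where(reachable, np.nan_to_num(surface), 0.0).ravel()
    if p.sum() <= 0:
        raise ValueError("no reachable sea cells with positive selection weight")
    p = p / p.sum()
    cell_ids = np.arange(ny * nx)
    cell = seascape.cell_km

    def sample_locations(n):
        cells = rng.choice(cell_ids, size=n, p=p)
        r, c = cells // nx, cells % nx
        x = seascape.x0 + (c + rng.uniform(0.02, 0.98, n)) * cell
        y = seascape.y0 + (r + rng.uniform(0.02, 0.98, n)) * cell
        return np.column_stack([x, y])

    t_start = pd.Timestamp(config.start_time).value  # ns
    step_fix = int(config.fix_interval_min * 60 * _NS)

    fixes_rows, dive_rows, truth_rows, wet_rows, bout_rows = [], [], [], [], []
    dive_counter = 0

    for s in range(n_seals):
        seal = f"S{s:02d}"
        home = seascape.haulouts.iloc[s % len(seascape.haulouts)]
        home_xy = np.array([home.x, home.y], float)

        t = t_start
        wp_t, wp_x, wp_y = [t], [home_xy[0]], [home_xy[1]]  # global position track
        haulout_iv, trip_iv, splashes = [], [], []

        for trip_i in range(n_trips_per_seal):
            # ---- haulout bout (dry)
            dur_h = rng.uniform(*config.haulout_h_range)
            bout_end = t + int(dur_h * 3600 * _NS)
            haulout_iv.append((t, bout_end))
            bout_rows.append((seal, t, bout_end))
            if rng.random() < config.splash_prob and dur_h > 0.6:
                b0 = t + int(rng.uniform(0.2, 0.8) * (bout_end - t))
                splashes.append((b0, b0 + int(20 * _NS)))
            wp_t += [bout_end]; wp_x += [home_xy[0]]; wp_y += [home_xy[1]]
            t = bout_end

            # ---- trip
            n_dives = max(int(rng.poisson(config.mean_dives_per_trip)), 1)
            forage = rng.random(n_dives) < pref.phi
            n_forage = int(forage.sum())
            locs = sample_locations(max(n_forage, 1))
            targets = locs[_greedy_order(home_xy, locs)] if n_forage > 0 else locs

            # route through targets and back, on the sea graph
            legs = []
            cur = home_xy
            for tgt in targets:
                legs.append(router.path_coords(cur, tgt))
                cur = tgt
            legs.append(router.path_coords(cur, home_xy))

            # moving-time axis: cumulative distance / speed
            move_t = [0.0]
            coords = [home_xy]
            arrival_move_t = []          # moving time at each target arrival
            for leg in legs:
                speed = rng.uniform(0.85, 1.15) * config.travel_speed_kmh / 3600.0  # km/s
                seg = np.diff(leg, axis=0)
                dts = np.hypot(seg[:, 0], seg[:, 1]) / speed
                for k in range(1, len(leg)):
                    move_t.append(move_t[-1] + dts[k - 1])
                    coords.append(leg[k])
                arrival_move_t.append(move_t[-1])
            arrival_move_t = arrival_move_t[:-1]  # last entry is the return home
            move_t = np.array(move_t)
            coords = np.array(coords)
            total_move = move_t[-1]

            # dives: foraging at targets (dwell), transit while moving
            trip_t0 = t + int(60 * _NS)
            dwells = []                  # (moving_time, dwell_seconds)
            dives_this_trip = []
            for j in range(n_forage):
                loc = targets[j]
                bathy = float(seascape.value_at(seascape.bathy, *loc))
                depth = max(bathy * rng.uniform(0.88, 0.99), 2.0)
                T, ts, ds = _u_profile(rng, depth, config.v_max)
                surf_iv = rng.uniform(30, 60)
                dwells.append((arrival_move_t[j], T + surf_iv))
                dives_this_trip.append(("F", arrival_move_t[j], loc, depth, T, ts, ds))
            n_transit = n_dives - n_forage
            if total_move > 0:
                for mt in np.sort(rng.uniform(0, total_move, n_transit)):
                    loc = np.array([np.interp(mt, move_t, coords[:, 0]),
                                    np.interp(mt, move_t, coords[:, 1])])
                    bathy = float(seascape.value_at(seascape.bathy, *loc))
                    if np.isnan(bathy):
                        bathy = 10.0
                    depth = float(np.clip(rng.uniform(3.2, 28.0), 1.7, max(1.7, 0.85 * bathy)))
                    T, ts, ds = _v_profile(rng, depth, config.v_max)
                    dives_this_trip.append(("T", mt, loc, depth, T, ts, ds))

            # map moving time -> wall time (dwells stop the clock's motion)
            dwells.sort()
            dw_t = np.array([d[0] for d in dwells])
            dw_s = np.array([d[1] for d in dwells])

            def wall(mt, *, _dw_t=dw_t, _dw_s=dw_s, _t0=trip_t0):
                extra = _dw_s[_dw_t < mt].sum() if len(_dw_t) else 0.0
                return _t0 + int((mt + extra) * _NS)

            last_dive_end = trip_t0
            for kind, mt, loc, depth, T, ts, ds in sorted(dives_this_trip, key=lambda r: r[1]):
                start_ns = wall(mt) + (int(2 * _NS) if kind == "F" else 0)
                dive_id = f"D{dive_counter:06d}"
                dive_counter += 1
                dive_rows.append(
                    (seal, dive_id, start_ns, start_ns + int(T * _NS), T, depth,
                     *ts.tolist(), *ds.tolist())
                )
                truth_rows.append((dive_id, kind == "F", loc[0], loc[1], f"{seal}_trip{trip_i}"))
                last_dive_end = max(last_dive_end, start_ns + int(T * _NS))

            # waypoints in wall time; keep every dive nested inside the wet period
            trip_end = wall(total_move) + (int(np.sum(dw_s[dw_t >= total_move]) * _NS)
                                           if len(dw_t) else 0)
            trip_end = max(trip_end, last_dive_end + int(60 * _NS))
            for k in range(len(move_t)):
                wp_t.append(wall(move_t[k]))
                wp_x.append(coords[k, 0]); wp_y.append(coords[k, 1])
            trip_iv.append((t, trip_end))
            t = trip_end
            wp_t.append(t); wp_x.append(home_xy[0]); wp_y.append(home_xy[1])

        # final haulout bout so the last trip has an arrival event
        final_end = t + int(rng.uniform(*config.haulout_h_range) * 3600 * _NS)
        haulout_iv.append((t, final_end))
        bout_rows.append((seal, t, final_end))
        wp_t.append(final_end); wp_x.append(home_xy[0]); wp_y.append(home_xy[1])

        # ---- fixes on the 20-min lattice with dropout
        wp_t = np.array(wp_t, dtype=np.int64)
        order = np.argsort(wp_t, kind="stable")
        wp_t, wp_x, wp_y = wp_t[order], np.array(wp_x)[order], np.array(wp_y)[order]
        lattice = np.arange(t_start, final_end, step_fix)
        fx = np.interp(lattice, wp_t, wp_x)
        fy = np.interp(lattice, wp_t, wp_y)
        at_sea = np.zeros(len(lattice), bool)
        for a, b in trip_iv:
            at_sea |= (lattice > a) & (lattice < b)
        keep = rng.random(len(lattice)) >= config.fix_dropout
        for a, b in trip_iv:  # protect the first/last at-sea fix of every trip
            idx = np.nonzero((lattice > a) & (lattice < b))[0]
            if idx.size:
                keep[idx[0]] = keep[idx[-1]] = True
        for ti, x_, y_ in zip(lattice[keep], fx[keep], fy[keep]):
            fixes_rows.append((seal, ti, x_, y_))

        # ---- wet/dry series at sensor resolution
        wt = np.arange(t_start, final_end, int(config.wetdry_step_s * _NS))
        dry = np.zeros(len(wt), dtype=int)
        for a, b in haulout_iv:
            dry[(wt >= a) & (wt < b)] = 1
        for a, b in splashes:
            dry[(wt >= a) & (wt < b)] = 0
        for ti, v in zip(wt, dry):
            wet_rows.append((seal, ti, v))

    tcols = [f"t{i}" for i in range(1, 10)]
    dcols = [f"d{i}" for i in range(1, 10)]
    dives = pd.DataFrame(
        dive_rows,
        columns=["seal", "dive_id", "start", "end", "duration_s", "max_depth_m", *tcols, *dcols],
    )
    dives["start"] = pd.to_datetime(dives["start"])
    dives["end"] = pd.to_datetime(dives["end"])
    fixes = pd.DataFrame(fixes_rows, columns=["seal", "time", "x", "y"])
    fixes["time"] = pd.to_datetime(fixes["time"])
    wetdry = pd.DataFrame(wet_rows, columns=["seal", "time", "dry"])
    wetdry["time"] = pd.to_datetime(wetdry["time"])
    truth = pd.DataFrame(truth_rows, columns=["dive_id", "foraging_true", "x_true", "y_true", "trip"])
    bouts = pd.DataFrame(bout_rows, columns=["seal", "start", "end"])
    bouts["start"] = pd.to_datetime(bouts["start"])
    bouts["end"] = pd.to_datetime(bouts["end"])

    logger.info("simulate_seals: %d seals, %d dives (%d foraging), %d fixes",
                n_seals, len(dives), int(truth["foraging_true"].sum()), len(fixes))
    return SimOutput(fixes=fixes, dives=dives, wetdry=wetdry, truth=truth,
                     haulout_truth=bouts, surface=surface, seascape=seascape, pref=pref)


def sample_use_availability(seascape: Seascape, pref: TruePreference, n_presence: int,
                            ratio: int = 2, n_individuals: int = 6,
                            seed: int | None = None) -> pd.DataFrame:
    """Directly sample a use-availability table from the true selection law.

    Presences are drawn from the normalized selection surface, absences
    uniformly over sea — exactly the contrast the use-availability design
    estimates — with covariates read off the seascape rasters.  This skips
    track simulation, so it isolates the model-recovery question from the
    observation process; individuals are assigned round-robin.
    """
    rng = np.random.default_rng(seed)
    surface = true_selection_surface(seascape, pref)
    graph = SeaGraph(seascape)
    dh = graph.distance_from_points(seascape.haulouts[["x", "y"]].to_numpy())
    sea_flat = np.flatnonzero(seascape.sea.ravel() & np.isfinite(dh).ravel())
    p = np.nan_to_num(surface).ravel()[sea_flat]
    p /= p.sum()

    def rows(cells, response):
        ny, nx = seascape.shape
        r, c = cells // nx, cells % nx
        n = len(cells)
        return pd.DataFrame({
            "response": response,
            "bathy": seascape.bathy[r, c],
            "tidal": seascape.tidal[r, c],
            "dist_shore": seascape.dist_shore_km[r, c],
            "dist_haulout": dh[r, c],
            "sediment": seascape.sediment[r, c],
            "individual": [f"i{k % n_individuals}" for k in range(n)],
        })

    pres = sea_flat[rng.choice(len(sea_flat), size=n_presence, p=p)]
    absc = sea_flat[rng.choice(len(sea_flat), size=ratio * n_presence)]
    out = pd.concat([rows(pres, 1), rows(absc, 0)], ignore_index=True)
    return out
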