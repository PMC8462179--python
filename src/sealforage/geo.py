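"""Spatial backbone: at-sea least-cost distances, shore distances, covariate
extraction, minimum convex polygons, availability regions, and pseudo-absence
sampling.

All operations accept either planar-km coordinates (synthetic worlds) or
WGS84 lon/lat; in geographic mode great-circle edge lengths and a local
azimuthal equal-area projection replace the planar metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from shapely import contains_xy
from shapely.affinity import scale as _affine_scale
from shapely.geometry import MultiPoint, Point

from .seascape import Seascape

logger = logging.getLogger(__name__)

__all__ = [
    "SeaGraph",
    "AvailabilityRegion",
    "least_cost_distance",
    "distance_to_shore",
    "extract_covariates",
    "mcp",
    "availability_region",
    "sample_pseudo_absences",
    "haversine_km",
    "equal_area_project",
]

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance (km) between lon/lat points, elementwise."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def equal_area_project(lon, lat, lon0: float, lat0: float):
    """Lambert azimuthal equal-area projection to km, centered at (lon0, lat0)."""
    lam, phi = np.radians(np.asarray(lon, float)), np.radians(np.asarray(lat, float))
    lam0, phi0 = np.radians(lon0), np.radians(lat0)
    denom = 1 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    k = np.sqrt(2.0 / denom)
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_KM * k * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
    )
    return x, y


class SeaGraph:
    """8-connected graph over sea cells with metric edge lengths.

    Realizes the at-sea geodesic ("least-cost") distance: shortest paths are
    constrained to water, so land masses force detours.  Planar mode uses
    cell-center Euclidean edge lengths; geographic mode uses great-circle
    lengths between cell centers.
    """

    _DIAG = np.sqrt(2.0)

    def __init__(self, seascape: Seascape):
        self.seascape = seascape
        land = seascape.land
        ny, nx = land.shape
        self.sea_idx = np.flatnonzero(~land.ravel())
        self.node_of_cell = -np.ones(ny * nx, dtype=np.int64)
        self.node_of_cell[self.sea_idx] = np.arange(self.sea_idx.size)

        rows, cols, wts = [], [], []
        sea = ~land
        X, Y = seascape.cell_centers()
        offsets = [(0, 1, False), (1, 0, False), (1, 1, True), (1, -1, True)]
        for dr, dc, diag in offsets:
            r0s, r0e = max(0, -dr), ny - max(0, dr)
            c0s, c0e = max(0, -dc), nx - max(0, dc)
            a = sea[r0s:r0e, c0s:c0e]
            b = sea[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
            ok = a & b
            rr, cc = np.nonzero(ok)
            rr, cc = rr + r0s, cc + c0s
            i = self.node_of_cell[rr * nx + cc]
            j = self.node_of_cell[(rr + dr) * nx + (cc + dc)]
            if seascape.mode == "geographic":
                w = haversine_km(X[rr, cc], Y[rr, cc], X[rr + dr, cc + dc], Y[rr + dr, cc + dc])
            else:
                w = np.full(i.size, seascape.cell_km * (self._DIAG if diag else 1.0))
            rows.append(i); cols.append(j); wts.append(w)
        if rows:
            i = np.concatenate(rows); j = np.concatenate(cols); w = np.concatenate(wts)
        else:
            i = j = w = np.empty(0)
        n = self.sea_idx.size
        self.adj = coo_matrix(
            (np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(n, n),
        ).tocsr()
        self.n_components, self.component = connected_components(self.adj, directed=False)

    # ------------------------------------------------------------------
    def snap(self, x: float, y: float) -> int:
        """Node index of the sea cell at/nearest (x, y), within 1-cell tolerance."""
        sc = self.seascape
        row, col = sc.cell_index(np.atleast_1d(x), np.atleast_1d(y))
        row, col = int(row[0]), int(col[0])
        ny, nx = sc.shape
        if row < 0:
            raise ValueError(f"point ({x}, {y}) outside raster extent")
        if not sc.land[row, col]:
            return int(self.node_of_cell[row * nx + col])
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                r, c = row + dr, col + dc
                if 0 <= r < ny and 0 <= c < nx and not sc.land[r, c]:
                    return int(self.node_of_cell[r * nx + c])
        raise ValueError(f"point ({x}, {y}) lies on land beyond the 1-cell snap tolerance")

    def distances_from(self, node: int) -> np.ndarray:
        """Shortest-path distance from one node to every sea node (km)."""
        return dijkstra(self.adj, directed=False, indices=node)

    def distance_grid(self, node_dist: np.ndarray) -> np.ndarray:
        """Scatter per-node distances back onto the raster (NaN on land)."""
        ny, nx = self.seascape.shape
        g = np.full(ny * nx, np.nan)
        g[self.sea_idx] = node_dist
        return g.reshape(ny, nx)

    def distance_from_points(self, points: np.ndarray) -> np.ndarray:
        """Raster of least-cost distance to the *nearest* of several points."""
        nodes = sorted({self.snap(px, py) for px, py in np.asarray(points, float)})
        d = dijkstra(self.adj, directed=False, indices=nodes, min_only=True)
        return self.distance_grid(d)


def least_cost_distance(origin, targets, seagraph: SeaGraph) -> np.ndarray:
    """At-sea shortest-path distance (km) from origin to each target point.

    Unreachable targets (separate sea component) come back as +inf with a
    warning; callers drop them.
    """
    onode = seagraph.snap(*origin)
    d = seagraph.distances_from(onode)
    targets = np.atleast_2d(np.asarray(targets, float))
    out = np.empty(len(targets))
    for k, (tx, ty) in enumerate(targets):
        tnode = seagraph.snap(tx, ty)
        out[k] = d[tnode]
    n_inf = np.isinf(out).sum()
    if n_inf:
        logger.warning("least_cost_distance: %d target(s) unreachable from origin", n_inf)
    return out


def distance_to_shore(points, coastline, mode: str = "planar",
                      center: tuple[float, float] | None = None) -> np.ndarray:
    """Straight-line distance (km) from each point to the nearest coast.

    Geographic mode projects coast and points through a local equal-area
    projection centered on ``center`` (default: mean of the points) before
    measuring.
    """
    if coastline is None or getattr(coastline, "is_empty", False):
        raise ValueError("empty coastline")
    pts = np.atleast_2d(np.asarray(points, float))
    if mode == "geographic":
        lon0, lat0 = center if center is not None else tuple(pts.mean(axis=0))
        from shapely.ops import transform
        coastline = transform(lambda x, y: equal_area_project(x, y, lon0, lat0), coastline)
        px, py = equal_area_project(pts[:, 0], pts[:, 1], lon0, lat0)
        pts = np.column_stack([px, py])
    return np.array([coastline.distance(Point(x, y)) for x, y in pts])


def extract_covariates(points: pd.DataFrame, seascape: Seascape,
                       seagraph: SeaGraph | None = None,
                       last_haulout: pd.Series | None = None) -> pd.DataFrame:
    """Environmental covariates at point locations.

    Parameters
    ----------
    points
        DataFrame with ``x``/``y`` columns (plus any id columns, preserved).
    last_haulout
        Per-row haulout site id (string, matching ``seascape.haulouts.site``);
        used for the least-cost distance-to-last-haulout covariate.  If None
        the nearest haulout overall is used for every row.

    Rows with any missing covariate (land, outside extent) are dropped and
    counted; more than 50% dropped raises (extent mismatch guard).
    """
    pts = points.reset_index(drop=True)
    x, y = pts["x"].to_numpy(float), pts["y"].to_numpy(float)
    out = pts.copy()
    out["bathy"] = seascape.value_at(seascape.bathy, x, y)
    out["tidal"] = seascape.value_at(seascape.tidal, x, y)
    out["sediment"] = seascape.value_at(seascape.sediment.astype(float), x, y, fill=-1.0)
    out["dist_shore"] = distance_to_shore(np.column_stack([x, y]), seascape.coastline,
                                          mode=seascape.mode)

    if seagraph is None:
        seagraph = SeaGraph(seascape)
    sites = seascape.haulouts
    out["dist_haulout"] = np.nan
    if last_haulout is None:
        grid = seagraph.distance_from_points(sites[["x", "y"]].to_numpy())
        out["dist_haulout"] = seascape.value_at(grid, x, y)
    else:
        lh = pd.Series(last_haulout).reset_index(drop=True)
        for site, sub in out.groupby(lh):
            srow = sites.loc[sites["site"] == site]
            if srow.empty:
                continue
            node = seagraph.snap(float(srow["x"].iloc[0]), float(srow["y"].iloc[0]))
            grid = seagraph.distance_grid(seagraph.distances_from(node))
            out.loc[sub.index, "dist_haulout"] = seascape.value_at(
                grid, sub["x"].to_numpy(), sub["y"].to_numpy())

    covs = ["bathy", "tidal", "sediment", "dist_shore", "dist_haulout"]
    bad = out[covs].isna().any(axis=1) | ~np.isfinite(out[covs]).all(axis=1) \
        | (out["sediment"] < 0)
    n_drop = int(bad.sum())
    if n_drop:
        logger.info("extract_covariates: dropped %d/%d rows with missing covariates",
                    n_drop, len(out))
    if n_drop > 0.5 * len(out):
        raise ValueError(
            f"extract_covariates: {n_drop}/{len(out)} rows dropped — extent mismatch?")
    out = out.loc[~bad].reset_index(drop=True)
    out["sediment"] = out["sediment"].astype(int)
    return out


def mcp(points, mode: str = "planar", center: tuple[float, float] | None = None):
    """100% Minimum Convex Polygon (convex hull) of a point set.

    Returns a shapely Polygon in the input coordinates; its ``.area`` is km²
    in planar mode.  Geographic inputs should be projected (see
    :func:`equal_area_project`) before area use; here the hull is built on
    projected coordinates and returned in them when ``mode='geographic'``.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if len(pts) < 3:
        raise ValueError("MCP needs at least 3 points")
    if mode == "geographic":
        lon0, lat0 = center if center is not None else tuple(pts.mean(axis=0))
        px, py = equal_area_project(pts[:, 0], pts[:, 1], lon0, lat0)
        pts = np.column_stack([px, py])
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if hull.geom_type != "Polygon":
        raise ValueError("points are collinear; MCP undefined")
    return hull


@dataclass
class AvailabilityRegion:
    """Availability footprint for pseudo-absence sampling.

    The source MCP is scaled about its centroid by sqrt(scale) per axis
    (area x scale, default 3), then clipped to the continental shelf and to
    sea.  All three polygons and their areas are retained for audit.
    """

    mcp: object
    scaled: object
    clipped: object
    scale: float = 3.0

    @property
    def areas(self) -> dict:
        return {"mcp": self.mcp.area, "scaled": self.scaled.area, "clipped": self.clipped.area}


def availability_region(mcp_polygon, shelf, land=None, scale: float = 3.0,
                        linear: bool = False) -> AvailabilityRegion:
    """Buffer the MCP to ``scale`` times its area and clip to shelf and sea.

    ``linear=True`` scales lengths (not areas) by ``scale`` instead — kept for
    sensitivity runs.
    """
    f = scale if linear else np.sqrt(scale)
    scaled = _affine_scale(mcp_polygon, xfact=f, yfact=f, origin="centroid")
    clipped = scaled.intersection(shelf)
    if land is not None and not getattr(land, "is_empty", True):
        clipped = clipped.difference(land)
    if clipped.is_empty:
        raise ValueError("availability region empty after clipping to shelf/sea")
    return AvailabilityRegion(mcp=mcp_polygon, scaled=scaled, clipped=clipped,
                              scale=scale if not linear else scale**2)


def sample_pseudo_absences(region: AvailabilityRegion, dives_per_individual: dict | pd.Series,
                           ratio: int = 2, seed: int | None = None) -> pd.DataFrame:
    """Uniform pseudo-absences over the clipped availability region.

    Exactly ``ratio`` points per foraging dive per individual, by rejection
    sampling from the region's bounding box.  Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    poly = region.clipped
    minx, miny, maxx, maxy = poly.bounds
    counts = dict(dives_per_individual)
    rows = []
    for ind in sorted(counts, key=str):
        need = int(ratio * counts[ind])
        got_x, got_y = [np.empty(0)], [np.empty(0)]
        n_got = n_try = 0
        while n_got < need:
            n = max(4 * need, 1024)
            xs = rng.uniform(minx, maxx, n)
            ys = rng.uniform(miny, maxy, n)
            inside = contains_xy(poly, xs, ys)
            n_try += n
            n_got += int(inside.sum())
            got_x.append(xs[inside]); got_y.append(ys[inside])
            if n_try >= 100 * max(need, 1024) and n_got < 0.01 * n_try:
                raise ValueError("rejection acceptance below 1%: degenerate sliver region")
        xs = np.concatenate(got_x)[:need]
        ys = np.concatenate(got_y)[:need]
        rows.append(pd.DataFrame({"individual": ind, "x": xs, "y": ys}))
    if not rows:
        return pd.DataFrame(columns=["individual", "x", "y"])
    return pd.concat(rows, ignore_index=True)
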