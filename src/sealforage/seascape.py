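"""Synthetic seascapes: co-registered covariate rasters plus vector context.

A :class:`Seascape` is the shared spatial substrate of the whole analysis —
the simulator places seals on it, the covariate extractor samples it, and the
selection model predicts back onto it.  It bundles a bathymetry raster
(positive-down metres), a categorical seabed-sediment raster, a tidal-current
speed raster, a land mask, the coastline and continental-shelf polygons, and a
catalogue of haulout sites.

Synthetic worlds live on a planar kilometre grid (``mode="planar"``); the same
container also carries lon/lat worlds (``mode="geographic"``), in which case
downstream distance/area code switches metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely import unary_union
from shapely.geometry import box

__all__ = [
    "SeascapeParams",
    "TruePreference",
    "Seascape",
    "make_seascape",
    "true_selection_surface",
]


@dataclass(frozen=True)
class SeascapeParams:
    """Parameters of the synthetic seascape generator.

    Attributes
    ----------
    extent_km
        Side length of the square domain (km).
    cell_km
        Raster cell size (km).  Must be positive; the grid must be at least
        10 x 10 cells.
    coast_complexity
        Scalar roughness of the coastline (0 = straight coast; ~1 = strongly
        indented).  Controls the amplitude of the smooth noise added to the
        land/sea boundary.
    max_depth_m
        Asymptotic offshore depth (m).
    n_sediment_classes
        Number of seabed sediment classes (1-6).
    tidal_smoothness_km
        Correlation length of the tidal-current field (km).
    n_haulouts
        Number of haulout sites to place on sea cells adjacent to land.
    shelf_cutoff_m
        Depth (m) bounding the continental shelf polygon.
    """

    extent_km: float = 200.0
    cell_km: float = 2.0
    coast_complexity: float = 0.5
    max_depth_m: float = 150.0
    n_sediment_classes: int = 4
    tidal_smoothness_km: float = 20.0
    n_haulouts: int = 3
    shelf_cutoff_m: float = 200.0


@dataclass(frozen=True)
class TruePreference:
    """Ground-truth habitat preference used to drive the simulator.

    The relative selection weight of a sea cell is ``exp(eta)`` with

    ``eta = beta_bathy * depth + beta_tidal * tidal - d_haulout / haulout_decay_km
            + sediment_logodds[class] + beta_shore * d_shore``

    so a negative ``beta_bathy`` means shallow water is preferred, and a small
    ``haulout_decay_km`` means foraging stays close to the haulouts.

    ``phi`` is the foraging mixture weight: the probability that any given
    dive performed on a trip is a (U-shaped, benthic) foraging dive rather
    than a (V-shaped) transit dive.
    """

    beta_bathy: float = 0.0
    beta_tidal: float = 0.0
    beta_shore: float = 0.0
    haulout_decay_km: float = np.inf
    sediment_logodds: tuple[float, ...] = ()
    phi: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.phi < 1.0):
            raise ValueError(f"phi must lie in (0, 1), got {self.phi}")


@dataclass
class Seascape:
    """Raster stack + vector context for one study area.

    Rasters are ``(ny, nx)`` arrays indexed ``[row, col]`` with row 0 at the
    *south* edge; cell centers sit at ``(x0 + (col+0.5)*cell, y0 + (row+0.5)*cell)``.
    Land cells carry NaN bathymetry/tidal values and sediment class -1.
    """

    cell_km: float
    x0: float
    y0: float
    bathy: np.ndarray          # positive-down depth (m); NaN on land
    sediment: np.ndarray       # int class 0..K-1; -1 on land
    tidal: np.ndarray          # current speed (m/s); NaN on land
    land: np.ndarray           # bool, True on land
    shelf_mask: np.ndarray     # bool, sea cells with depth <= cutoff
    shelf_polygon: object      # shapely (Multi)Polygon
    land_polygon: object       # shapely (Multi)Polygon (empty if no land)
    coastline: object          # shapely boundary geometry
    haulouts: pd.DataFrame     # columns: site, x, y
    mode: str = "planar"       # "planar" (km) | "geographic" (lon/lat)
    params: SeascapeParams | None = None
    seed: int | None = None
    dist_shore_km: np.ndarray = field(default=None, repr=False)  # precomputed per cell

    # ------------------------------------------------------------------ grid
    @property
    def shape(self) -> tuple[int, int]:
        return self.bathy.shape

    @property
    def sea(self) -> np.ndarray:
        return ~self.land

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-center coordinates, shape (ny, nx)."""
        ny, nx = self.shape
        x = self.x0 + (np.arange(nx) + 0.5) * self.cell_km
        y = self.y0 + (np.arange(ny) + 0.5) * self.cell_km
        return np.meshgrid(x, y)

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col); out-of-extent points get -1."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell_km).astype(int)
        row = np.floor((y - self.y0) / self.cell_km).astype(int)
        ny, nx = self.shape
        bad = (col < 0) | (col >= nx) | (row < 0) | (row >= ny)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col

    def value_at(self, raster: np.ndarray, x, y, fill=np.nan) -> np.ndarray:
        """Nearest-cell raster lookup; out-of-extent -> ``fill``."""
        row, col = self.cell_index(x, y)
        out = np.full(np.shape(row), fill, dtype=float)
        ok = row >= 0
        out[ok] = raster[row[ok], col[ok]]
        return out

    def is_sea_xy(self, x, y) -> np.ndarray:
        row, col = self.cell_index(x, y)
        ok = row >= 0
        out = np.zeros(np.shape(row), dtype=bool)
        out[ok] = ~self.land[row[ok], col[ok]]
        return out


def _smooth_noise(rng: np.random.Generator, shape, sigma_cells: float) -> np.ndarray:
    """Unit-variance spatially correlated Gaussian field."""
    z = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_cells, mode="nearest")
    s = z.std()
    return z / s if s > 0 else z


def _cells_polygon(mask: np.ndarray, cell: float, x0: float, y0: float):
    """Union of the square footprints of the True cells (exact cell-count area)."""
    rows, cols = np.nonzero(mask)
    boxes = [
        box(x0 + c * cell, y0 + r * cell, x0 + (c + 1) * cell, y0 + (r + 1) * cell)
        for r, c in zip(rows, cols)
    ]
    return unary_union(boxes)


def make_seascape(params: SeascapeParams, seed: int) -> Seascape:
    """Generate a synthetic coastal seascape.

    Land occupies the western margin with a noisy coastline; bathymetry
    deepens monotonically offshore (plus correlated noise that vanishes at
    the coast); sediment classes are spatially autocorrelated; the tidal
    field is a smooth non-negative speed surface.  Deterministic given
    (params, seed).
    """
    nx = ny = int(round(params.extent_km / params.cell_km))
    if nx < 10 or ny < 10:
        raise ValueError(f"degenerate grid {ny}x{nx}: need at least 10x10 cells")
    if not params.cell_km > 0:
        raise ValueError("cell_km must be positive")
    if not (1 <= params.n_sediment_classes <= 6):
        raise ValueError("n_sediment_classes must be in 1..6")

    rng = np.random.default_rng(seed)
    cell = params.cell_km

    # --- coastline: land where x < coast_x(y), a smooth noisy profile
    base = 0.12 * nx
    wiggle = _smooth_noise(rng, (ny,), sigma_cells=max(ny / 12, 2.0))
    coast_col = base + params.coast_complexity * 0.10 * nx * wiggle
    coast_col = np.clip(coast_col, 1, 0.35 * nx)
    cols = np.arange(nx)[None, :]
    land = cols < coast_col[:, None]

    # --- bathymetry: saturating increase with distance offshore + noise
    d_off = ndimage.distance_transform_edt(~land) * cell          # km offshore
    scale_km = max(params.extent_km / 4.0, 3 * cell)
    trend = params.max_depth_m * (1.0 - np.exp(-d_off / scale_km))
    noise = _smooth_noise(rng, (ny, nx), sigma_cells=max(4.0, 8.0 / cell))
    ramp = 1.0 - np.exp(-d_off / (2 * scale_km))                  # mute noise at coast
    bathy = trend + 0.12 * params.max_depth_m * noise * ramp
    bathy = np.clip(bathy, 0.5, None)
    bathy[land] = np.nan

    # --- sediment: argmax over K correlated fields
    k = params.n_sediment_classes
    if k == 1:
        sediment = np.zeros((ny, nx), dtype=int)
    else:
        fields = np.stack(
            [_smooth_noise(rng, (ny, nx), sigma_cells=max(3.0, 10.0 / cell)) for _ in range(k)]
        )
        sediment = np.argmax(fields, axis=0).astype(int)
    sediment[land] = -1

    # --- tidal current: folded smooth field, m/s
    tidal = np.abs(_smooth_noise(rng, (ny, nx), params.tidal_smoothness_km / cell)) * 0.8
    tidal[land] = np.nan

    # --- vector layers
    land_poly = _cells_polygon(land, cell, 0.0, 0.0) if land.any() else unary_union([])
    coastline = land_poly.boundary
    shelf_mask = (~land) & (bathy <= params.shelf_cutoff_m)
    shelf_poly = _cells_polygon(shelf_mask, cell, 0.0, 0.0)

    # --- haulout sites: sea cells 8-adjacent to land, spread along the coast
    adj = ndimage.binary_dilation(land, structure=np.ones((3, 3), bool)) & ~land
    rr, cc = np.nonzero(adj)
    if rr.size == 0:
        raise ValueError("no sea cells adjacent to land; cannot place haulouts")
    order = np.argsort(rr)  # south to north
    picks = np.linspace(0, rr.size - 1, params.n_haulouts + 2)[1:-1].round().astype(int)
    sites = order[picks]
    haulouts = pd.DataFrame(
        {
            "site": [f"H{i}" for i in range(params.n_haulouts)],
            "x": (cc[sites] + 0.5) * cell,
            "y": (rr[sites] + 0.5) * cell,
        }
    )

    sc = Seascape(
        cell_km=cell, x0=0.0, y0=0.0,
        bathy=bathy, sediment=sediment, tidal=tidal, land=land,
        shelf_mask=shelf_mask, shelf_polygon=shelf_poly,
        land_polygon=land_poly, coastline=coastline,
        haulouts=haulouts, mode="planar", params=params, seed=seed,
    )
    # straight-line distance to the coast, per cell (used by the simulator
    # and the prediction maps; point queries go through geo.distance_to_shore)
    d_land = ndimage.distance_transform_edt(~land) * cell
    sc.dist_shore_km = np.where(land, 0.0, d_land)
    return sc


def true_selection_surface(seascape: Seascape, pref: TruePreference) -> np.ndarray:
    """Relative selection weight per cell, normalized to sum 1 over sea.

    Land cells are NaN.  Adding any constant to the log-weights leaves the
    surface unchanged (normalization removes it).
    """
    from .geo import SeaGraph  # local import: geo depends on this module's types

    sea = seascape.sea
    eta = np.zeros(seascape.shape)
    if pref.beta_bathy != 0.0:
        eta += pref.beta_bathy * np.where(sea, seascape.bathy, 0.0)
    if pref.beta_tidal != 0.0:
        eta += pref.beta_tidal * np.where(sea, seascape.tidal, 0.0)
    if pref.beta_shore != 0.0:
        eta += pref.beta_shore * np.where(sea, seascape.dist_shore_km, 0.0)
    if np.isfinite(pref.haulout_decay_km):
        graph = SeaGraph(seascape)
        d = graph.distance_from_points(seascape.haulouts[["x", "y"]].to_numpy())
        d = np.where(np.isfinite(d), d, np.nanmax(d[np.isfinite(d)]))
        eta -= d / pref.haulout_decay_km
    if pref.sediment_logodds:
        lo = np.asarray(pref.sediment_logodds, dtype=float)
        sed = np.clip(seascape.sediment, 0, len(lo) - 1)
        eta += np.where(sea, lo[sed], 0.0)

    eta = eta - np.nanmax(np.where(sea, eta, -np.inf))
    w = np.where(sea, np.exp(eta), 0.0)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("selection weights are not finite and positive over sea")
    surf = w / total
    return np.where(sea, surf, np.nan)
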