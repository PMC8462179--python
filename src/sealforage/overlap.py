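"""Kernel utilization distributions and Bhattacharyya-affinity overlap.

The spatial usage of each individual is summarized by a kernel utilization
distribution (UD) of its foraging-dive locations: a bivariate Gaussian KDE
evaluated on a grid and normalized so the cells sum to one.  Following
common home-range practice the UD is truncated at its 95% volume contour
(the smallest set of cells holding at least 95% of the probability) and
renormalized before overlap is measured.

Overlap between two UDs p and q on a common grid is the Bhattacharyya
affinity BA = sum_cells sqrt(p * q), ranging from 0 (complete segregation)
to 1 (identical distributions).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["UDGrid", "UD", "kde_ud", "contour95", "bhattacharyya", "pairwise_overlap"]


@dataclass(frozen=True)
class UDGrid:
    """Evaluation grid: origin, cell size, shape (shared by comparable UDs)."""

    x0: float
    y0: float
    cell: float
    nx: int
    ny: int

    def centers(self):
        x = self.x0 + (np.arange(self.nx) + 0.5) * self.cell
        y = self.y0 + (np.arange(self.ny) + 0.5) * self.cell
        return np.meshgrid(x, y)

    @classmethod
    def around(cls, points: np.ndarray, cell: float, pad: float) -> "UDGrid":
        pts = np.atleast_2d(points)
        x0 = pts[:, 0].min() - pad
        y0 = pts[:, 1].min() - pad
        nx = int(np.ceil((pts[:, 0].max() + pad - x0) / cell))
        ny = int(np.ceil((pts[:, 1].max() + pad - y0) / cell))
        return cls(x0, y0, cell, max(nx, 1), max(ny, 1))


@dataclass
class UD:
    """Utilization distribution on a grid (cells sum to 1)."""

    grid: UDGrid
    prob: np.ndarray
    bandwidth: tuple[float, float]
    n_points: int
    mask95: np.ndarray = field(default=None, repr=False)
    prob95: np.ndarray = field(default=None, repr=False)


def _reference_bandwidth(points: np.ndarray) -> tuple[float, float]:
    """Normal-scale (reference) rule per axis: h_j = sigma_j * n^(-1/6)."""
    n = len(points)
    sd = points.std(axis=0, ddof=1)
    return tuple(float(s) * n ** (-1.0 / 6.0) for s in sd)


def kde_ud(points, grid: UDGrid | None = None, bandwidth="auto",
           cell: float | None = None) -> UD:
    """Bivariate Gaussian KDE of a point set, normalized over grid cells.

    ``bandwidth`` is "auto" (normal-scale reference rule) or a scalar /
    (hx, hy) pair in coordinate units.  If no grid is given one is built
    around the points with 3-bandwidth padding.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if len(pts) < 10:
        raise ValueError("kernel UD needs at least 10 points")
    if np.allclose(pts, pts[0]):
        raise ValueError("all points identical; kernel bandwidth undefined")
    if bandwidth == "auto":
        hx, hy = _reference_bandwidth(pts)
    else:
        hx, hy = (bandwidth, bandwidth) if np.isscalar(bandwidth) else bandwidth
    if hx <= 0 or hy <= 0:
        raise ValueError("bandwidth must be positive (degenerate point spread?)")
    if grid is None:
        c = cell if cell is not None else min(hx, hy) / 2.0
        grid = UDGrid.around(pts, c, pad=3.0 * max(hx, hy))
    X, Y = grid.centers()
    dens = np.zeros(X.shape)
    chunk = 256
    for i in range(0, len(pts), chunk):
        px = pts[i:i + chunk, 0][:, None, None]
        py = pts[i:i + chunk, 1][:, None, None]
        dens += np.exp(-0.5 * (((X[None] - px) / hx) ** 2 + ((Y[None] - py) / hy) ** 2)).sum(axis=0)
    total = dens.sum()
    if total <= 0:
        raise ValueError("all probability mass outside the grid")
    ud = UD(grid=grid, prob=dens / total, bandwidth=(hx, hy), n_points=len(pts))
    contour95(ud)
    return ud


def contour95(ud: UD, level: float = 0.95) -> UD:
    """Truncate a UD at its ``level`` volume contour and renormalize.

    Cells are admitted in decreasing density order (row-major on ties) until
    the cumulative probability first reaches ``level``; the truncated UD is
    renormalized over that cell set.  Sets ``ud.mask95``/``ud.prob95``.
    """
    flat = ud.prob.ravel()
    order = np.argsort(-flat, kind="stable")     # stable => row-major tie order
    csum = np.cumsum(flat[order])
    n_keep = int(np.searchsorted(csum, level - 1e-12) + 1)
    n_keep = min(n_keep, flat.size)
    mask = np.zeros(flat.size, bool)
    mask[order[:n_keep]] = True
    mask = mask.reshape(ud.prob.shape)
    trunc = np.where(mask, ud.prob, 0.0)
    trunc = trunc / trunc.sum()
    ud.mask95 = mask
    ud.prob95 = trunc
    return ud


def bhattacharyya(ud1: UD, ud2: UD, truncated: bool = True) -> float:
    """Bhattacharyya affinity between two UDs on a common grid.

    BA = sum sqrt(p1 * p2) over cells, computed on the 95%-truncated and
    renormalized surfaces by default (``truncated=False`` uses the full UDs).
    """
    if ud1.grid != ud2.grid:
        raise ValueError("UDs are on different grids; evaluate both on a common grid")
    p1 = ud1.prob95 if truncated else ud1.prob
    p2 = ud2.prob95 if truncated else ud2.prob
    if truncated and (p1 is None or p2 is None):
        raise ValueError("truncated UDs missing; run contour95 first")
    return float(np.sum(np.sqrt(p1 * p2)))


def pairwise_overlap(points_by_individual: dict[str, np.ndarray],
                     cell: float | None = None, bandwidth="auto",
                     truncated: bool = True) -> tuple[pd.DataFrame, dict]:
    """BA matrix over all unordered pairs of individuals, on one common grid.

    The common grid spans the union bounding box of all point sets at the
    finest per-individual auto cell size.  Returns (matrix, summary) with
    summary = {"mean": ..., "sd": ..., "n_pairs": ...}.
    """
    names = sorted(points_by_individual)
    pts_all = np.vstack([np.atleast_2d(points_by_individual[n]) for n in names])
    bws = {}
    for n in names:
        p = np.atleast_2d(points_by_individual[n])
        bws[n] = _reference_bandwidth(p) if bandwidth == "auto" else (
            (bandwidth, bandwidth) if np.isscalar(bandwidth) else bandwidth)
    hmax = max(max(b) for b in bws.values())
    hmin = min(min(b) for b in bws.values())
    c = cell if cell is not None else max(hmin / 2.0, 1e-6)
    grid = UDGrid.around(pts_all, c, pad=3.0 * hmax)
    uds = {n: kde_ud(points_by_individual[n], grid=grid, bandwidth=bws[n]) for n in names}

    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    vals = []
    for a, b in itertools.combinations(names, 2):
        ba = bhattacharyya(uds[a], uds[b], truncated=truncated)
        mat.loc[a, b] = mat.loc[b, a] = ba
        vals.append(ba)
    summary = {"mean": float(np.mean(vals)) if vals else np.nan,
               "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
               "n_pairs": len(vals)}
    return mat, summary
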