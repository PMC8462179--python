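"""Dive-profile scoring and two-stage foraging classification.

Tags record, per dive, the start/end time, maximum depth ``D``, duration
``T`` and nine intermediate depth points.  Foraging (benthic, "U-shaped")
dives are identified per individual from two criteria:

1.  The Time-Allocation-at-Depth (TAD) index, a [0, 1] dive-shape score.
    With ``A`` the time integral of depth over the dive and ``v_max`` the
    fastest plausible vertical transit speed,

        A_min = D^2 / v_max                (sharpest possible V-dive)
        A_max = D*T - D^2 / v_max          (square dive at fastest transit)
        TAD   = (A - A_min) / (A_max - A_min),  clamped into [0, 1]

    0 means the dive hugged the surface; 1 means a square, bottom-hugging
    profile.
2.  The vertical descent speed — depth of the first recorded profile point
    divided by its time offset from the dive start.  Among the most U-shaped
    dives, the slowest descenders are more likely resting/sleeping than
    foraging and are excluded.

The classification keeps, per individual, the top 25% of TAD values and then
drops the 10% slowest descents within that selection, flagging ~22.5% of
prefiltered dives as foraging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TadParams",
    "ClassificationRule",
    "profile_arrays",
    "tad_index",
    "descent_speed",
    "prefilter",
    "classify_foraging",
    "classify_all",
    "score_dives",
    "interpolate_dive_locations",
]

N_PROFILE_POINTS = 9
TIME_COLS = [f"t{i}" for i in range(1, N_PROFILE_POINTS + 1)]
DEPTH_COLS = [f"d{i}" for i in range(1, N_PROFILE_POINTS + 1)]


@dataclass(frozen=True)
class TadParams:
    """TAD scoring parameters.

    ``v_max`` is the maximum vertical transit speed (m/s).  A dive is only
    scorable if ``2*D/v_max < T`` — otherwise even the fastest V-dive could
    not fit inside the recorded duration and the bounds collapse.
    """

    v_max: float = 2.0
    clamp: bool = True

    def __post_init__(self):
        if not self.v_max > 0:
            raise ValueError("v_max must be positive")


@dataclass(frozen=True)
class ClassificationRule:
    """Prefilter thresholds and two-stage selection fractions."""

    min_depth_m: float = 3.0
    min_duration_s: float = 30.0
    tad_top_fraction: float = 0.25
    slow_descent_fraction: float = 0.10

    def __post_init__(self):
        for f in (self.tad_top_fraction, self.slow_descent_fraction):
            if not (0.0 < f < 1.0):
                raise ValueError("selection fractions must lie in (0, 1)")


def profile_arrays(dives: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Full (time, depth) profiles including the surface endpoints.

    Returns arrays of shape (n, 11): time offsets [0, t1..t9, T] and depths
    [0, d1..d9, 0].  Raises if profile times are not strictly increasing
    within (0, T).
    """
    n = len(dives)
    T = dives["duration_s"].to_numpy(float)
    t = np.column_stack([np.zeros(n), dives[TIME_COLS].to_numpy(float), T])
    d = np.column_stack([np.zeros(n), dives[DEPTH_COLS].to_numpy(float), np.zeros(n)])
    if np.any(np.diff(t, axis=1) <= 0):
        bad = np.nonzero(np.any(np.diff(t, axis=1) <= 0, axis=1))[0]
        raise ValueError(f"non-monotone profile times in dives at rows {bad[:5].tolist()}")
    return t, d


def tad_index(dives: pd.DataFrame, params: TadParams = TadParams()) -> pd.Series:
    """TAD score per dive; NaN where the dive is unscorable (2D/v_max >= T)."""
    t, d = profile_arrays(dives)
    D = dives["max_depth_m"].to_numpy(float)
    T = dives["duration_s"].to_numpy(float)
    A = np.trapezoid(d, t, axis=1)
    a_min = D**2 / params.v_max
    a_max = D * T - a_min
    scorable = 2 * D / params.v_max < T
    with np.errstate(divide="ignore", invalid="ignore"):
        tad = (A - a_min) / (a_max - a_min)
    n_out = int(np.sum(scorable & ((tad < 0) | (tad > 1))))
    if n_out:
        logger.info("tad_index: %d scorable dives outside [0,1] before clamping", n_out)
    if params.clamp:
        tad = np.clip(tad, 0.0, 1.0)
    tad = np.where(scorable, tad, np.nan)
    if (~scorable).any():
        logger.info("tad_index: %d dives unscorable (2D/v_max >= T)", int((~scorable).sum()))
    return pd.Series(tad, index=dives.index, name="tad")


def descent_speed(dives: pd.DataFrame) -> pd.Series:
    """Initial vertical descent speed (m/s): first profile point depth / time."""
    t1 = dives[TIME_COLS[0]].to_numpy(float)
    d1 = dives[DEPTH_COLS[0]].to_numpy(float)
    if np.any(t1 <= 0):
        raise ValueError("first profile point has non-positive time offset")
    return pd.Series(d1 / t1, index=dives.index, name="descent_speed")


def prefilter(dives: pd.DataFrame, rule: ClassificationRule = ClassificationRule()) -> pd.DataFrame:
    """Drop very shallow, very short dives (strict < on both thresholds)."""
    keep = (dives["max_depth_m"].to_numpy(float) >= rule.min_depth_m) & (
        dives["duration_s"].to_numpy(float) >= rule.min_duration_s
    )
    return dives.loc[keep]


def score_dives(dives: pd.DataFrame, params: TadParams = TadParams()) -> pd.DataFrame:
    """Attach `tad` and `descent_speed` columns; drop unscorable dives."""
    out = dives.copy()
    out["tad"] = tad_index(out, params)
    out["descent_speed"] = descent_speed(out)
    n0 = len(out)
    out = out.loc[out["tad"].notna()]
    if len(out) < n0:
        logger.info("score_dives: dropped %d unscorable dives", n0 - len(out))
    return out


def classify_foraging(dives: pd.DataFrame,
                      rule: ClassificationRule = ClassificationRule()) -> pd.DataFrame:
    """Two-stage foraging flag for the dives of ONE individual.

    Stage 1 keeps the ceil(0.25 n) highest-TAD dives; stage 2 removes the
    floor(0.10 k) lowest-descent-speed dives among them.  Ties are broken so
    that the earlier start time is kept first.  With n < 8 the quantiles are
    meaningless: every dive is flagged unclassifiable instead.
    """
    out = dives.copy()
    n = len(out)
    out["foraging"] = False
    if n < 8:
        logger.warning("classify_foraging: only %d dives; flagged unclassifiable", n)
        out["classifiable"] = False
        return out
    out["classifiable"] = True

    start = pd.to_datetime(out["start"]).to_numpy() if "start" in out else np.arange(n)
    k1 = int(np.ceil(rule.tad_top_fraction * n))
    # stage 1: highest TAD; on ties earlier start wins a slot
    order1 = np.lexsort((start, -out["tad"].to_numpy()))
    stage1 = order1[:k1]
    # stage 2: drop slowest descents within the stage-1 set; on ties the
    # earlier start is kept (later starts removed first)
    m = int(np.floor(rule.slow_descent_fraction * k1))
    speeds = out["descent_speed"].to_numpy()[stage1]
    s_start = start[stage1]
    order2 = np.lexsort((-pd.Series(s_start).rank().to_numpy(), speeds))
    removed = stage1[order2[:m]]
    flagged = np.setdiff1d(stage1, removed)
    out.iloc[flagged, out.columns.get_loc("foraging")] = True
    return out


def classify_all(dives: pd.DataFrame, rule: ClassificationRule = ClassificationRule(),
                 by: str = "seal") -> pd.DataFrame:
    """Apply :func:`classify_foraging` per individual (strictly per-seal)."""
    parts = [classify_foraging(sub, rule) for _, sub in dives.groupby(by, sort=True)]
    return pd.concat(parts).loc[dives.index]


def interpolate_dive_locations(dives: pd.DataFrame, fixes: pd.DataFrame,
                               max_gap_h: float = 6.0) -> pd.DataFrame:
    """Linear interpolation of dive locations at the dive midpoint time.

    Each dive needs a GPS fix at or before and at or after its midpoint,
    within ``max_gap_h`` of each other; dives without a valid bracket are
    dropped (count logged).  Works per seal.
    """
    out = []
    n_dropped = 0
    for seal, dsub in dives.groupby("seal", sort=True):
        fsub = fixes.loc[fixes["seal"] == seal].sort_values("time")
        ft = pd.to_datetime(fsub["time"]).to_numpy()
        if len(ft) and np.any(np.diff(ft) < np.timedelta64(0)):
            raise ValueError("fix times not sorted")
        fx = fsub["x"].to_numpy(float)
        fy = fsub["y"].to_numpy(float)
        mid = (pd.to_datetime(dsub["start"]).to_numpy().astype("datetime64[ns]").astype(np.int64)
               + pd.to_datetime(dsub["end"]).to_numpy().astype("datetime64[ns]").astype(np.int64)) // 2
        ftn = ft.astype("datetime64[ns]").astype(np.int64)
        d = dsub.copy()
        if len(ftn) < 2:
            n_dropped += len(d)
            continue
        ins = np.searchsorted(ftn, mid)
        ok = (ins > 0) & (ins < len(ftn))
        # allow exact knot coincidence at the first fix
        at_knot0 = (ins == 0) & np.isin(mid, ftn[:1])
        ok |= at_knot0
        lo = np.clip(ins - 1, 0, len(ftn) - 1)
        hi = np.clip(ins, 0, len(ftn) - 1)
        gap_ok = (ftn[hi] - ftn[lo]) <= int(max_gap_h * 3600 * 1e9)
        ok &= gap_ok | at_knot0
        n_dropped += int((~ok).sum())
        d = d.loc[ok]
        midk = mid[ok]
        d["x"] = np.interp(midk, ftn, fx)
        d["y"] = np.interp(midk, ftn, fy)
        out.append(d)
    if n_dropped:
        logger.info("interpolate_dive_locations: dropped %d dives without valid brackets",
                    n_dropped)
    if not out:
        return dives.iloc[0:0].assign(x=np.nan, y=np.nan)
    return pd.concat(out)
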