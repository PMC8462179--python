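"""End-to-end orchestration: simulate -> trips -> dives -> selection -> overlap.

One :class:`RunConfig` drives the whole per-colony analysis in the fixed
stage order (season filter, haulout/trip segmentation, dive prefilter /
scoring / classification, location interpolation, covariate extraction,
MCP / availability / pseudo-absences, VIF, model fit and selection, term
importance, prediction maps, overlap, trip statistics).  Every stage logs
row counts in and out into a run manifest so record accounting can be
audited, and all artifacts are serialized as plain-text files so any stage
can be re-run from disk.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dives as dv
from . import trips as tp
from .geo import SeaGraph, availability_region, mcp, sample_pseudo_absences, extract_covariates
from .habitat import HabitatSelectionModel, build_table, subsample_one_in_three, vif_screen
from .io import sha256_of, write_ascii_grid, write_sim_output
from .overlap import pairwise_overlap
from .seascape import SeascapeParams, TruePreference, make_seascape
from .simulate import SimConfig, simulate_seals
from .tripstats import assumption_tests, colony_size_models, compare_sites

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "make_report"]


@dataclass
class RunConfig:
    """Configuration of one synthetic-mode pipeline run."""

    outdir: str = "runs/default"
    species: str = "harbor"            # gray -> return-trip filter active
    mode: str = "colony"               # colony | global (1-in-3 subsampling)
    seed: int = 0
    n_seals: int = 6
    n_trips_per_seal: int = 5
    seascape: SeascapeParams = field(default_factory=lambda: SeascapeParams(
        extent_km=100.0, cell_km=2.0, n_haulouts=2))
    pref: TruePreference = field(default_factory=lambda: TruePreference(
        beta_bathy=-0.06, haulout_decay_km=25.0, phi=0.4))
    sim: SimConfig = field(default_factory=SimConfig)
    k: int = 5
    smooth_terms: tuple = ("bathy", "tidal", "dist_shore", "dist_haulout")
    min_trip_h: float = 3.0
    pseudo_absence_ratio: int = 2

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub in (("seascape", SeascapeParams), ("pref", TruePreference),
                         ("sim", SimConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        if "smooth_terms" in raw:
            raw["smooth_terms"] = tuple(raw["smooth_terms"])
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic-mode analysis; returns the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _cfg_dict(config), "stages": {}, "checksums": {}}

    def stage(name, **counts):
        manifest["stages"][name] = counts
        logger.info("stage %-22s %s", name, counts)

    # --- simulate
    sc = make_seascape(config.seascape, seed=config.seed)
    sim = simulate_seals(sc, config.pref, config.n_seals, config.n_trips_per_seal,
                         seed=config.seed + 1, config=config.sim)
    paths = write_sim_output(sim, out / "sim")
    stage("simulate", n_fixes=len(sim.fixes), n_dives=len(sim.dives),
          n_wetdry=len(sim.wetdry))
    graph = SeaGraph(sc)

    # --- haulouts & trips
    events = tp.detect_haulouts(sim.wetdry)
    tagging_site = sc.haulouts["site"].iloc[0]
    events = tp.assign_colony(events, sim.fixes, sc.haulouts, tagging_site)
    trips = tp.segment_trips(sim.fixes, events)
    stage("trips_segmented", n_events=len(events), n_trips=len(trips))

    windows = tp.SeasonWindows.for_species(config.species)
    trips_kept = tp.filter_trips(trips, windows, min_duration_h=config.min_trip_h,
                                 return_only=(config.species == "gray"))
    trip_rows = []
    for i, tr in enumerate(trips_kept):
        if tp.interpolate_track(tr) is None:
            continue
        dur, ext = tp.trip_metrics(tr, seagraph=graph)
        trip_rows.append({"trip": i, "seal": tr.seal, "duration_h": dur,
                          "max_extent_km": ext, "site": tr.departure_site})
    trip_table = pd.DataFrame(trip_rows)
    trip_table.to_csv(out / "trips.csv", index=False)
    stage("trips_filtered", n_in=len(trips), n_kept=len(trips_kept),
          n_with_track=len(trip_table))

    # --- dives: prefilter -> score -> classify -> locate  (fixed order)
    dives0 = sim.dives
    dives1 = dv.prefilter(dives0)
    dives2 = dv.score_dives(dives1)
    dives3 = dv.classify_all(dives2)
    dives4 = dv.interpolate_dive_locations(dives3, sim.fixes)
    stage("dives", n_raw=len(dives0), n_prefiltered=len(dives1), n_scored=len(dives2),
          n_classified=int(dives3["foraging"].sum()), n_located=len(dives4))
    dives4.to_csv(out / "dives_classified.csv", index=False)

    foraging = dives4.loc[dives4["foraging"]].rename(columns={"seal": "individual"})
    if foraging.empty:
        raise RuntimeError("stage dives: no foraging dives identified")

    # --- availability & pseudo-absences
    hull = mcp(dives4[["x", "y"]].to_numpy())
    region = availability_region(hull, sc.shelf_polygon, sc.land_polygon)
    per_ind = foraging.groupby("individual").size()
    absences = sample_pseudo_absences(region, per_ind, ratio=config.pseudo_absence_ratio,
                                      seed=config.seed + 2)
    stage("availability", mcp_km2=hull.area, scaled_km2=region.scaled.area,
          clipped_km2=region.clipped.area, n_absences=len(absences))

    # --- covariates & model table
    fcov = extract_covariates(foraging[["individual", "dive_id", "x", "y"]], sc, graph)
    acov = extract_covariates(absences, sc, graph)
    table = build_table(fcov, acov)
    if config.mode == "global":
        table["site"] = tagging_site
        table = subsample_one_in_three(table)
    stage("table", n_rows=len(table), n_presence=int(table["response"].sum()))
    table.to_csv(out / "use_availability.csv", index=False)

    vif = vif_screen(table, covariates=config.smooth_terms)

    # --- model
    model = HabitatSelectionModel(table, smooths=config.smooth_terms, k=config.k,
                                  mode=config.mode)
    res = model.fit()
    importance = res.term_importance()
    maps = res.predict_map(sc, graph)
    write_ascii_grid(out / "selection_map.asc", maps["probability"], sc.cell_km, sc.x0, sc.y0)
    write_ascii_grid(out / "selection_se.asc", maps["se"], sc.cell_km, sc.x0, sc.y0)
    stage("model", aic=res.aic, explained_deviance=res.explained_deviance,
          edf=res.edf)
    model_summary = {
        "aic": res.aic, "explained_deviance": res.explained_deviance,
        "edf": res.edf, "importance": importance.to_dict(),
        "vif": vif.to_dict(), "lambdas": res.lambdas.tolist(),
        "k": config.k, "mode": config.mode,
        "reference_sediment": res.model.sediment_ref,
    }
    (out / "model.json").write_text(json.dumps(model_summary, indent=2, default=float))

    # --- overlap (within colony, between individuals)
    pts = {ind: sub[["x", "y"]].to_numpy()
           for ind, sub in foraging.groupby("individual") if len(sub) >= 10}
    overlap_summary = None
    if len(pts) >= 2:
        ba, overlap_summary = pairwise_overlap(pts)
        ba.to_csv(out / "ba_matrix.csv")
        stage("overlap", n_individuals=len(pts), **overlap_summary)
    else:
        stage("overlap", n_individuals=len(pts), note="skipped: <2 individuals with >=10 dives")

    # --- trip statistics (only meaningful with several sites; report what we can)
    trip_stats = None
    if not trip_table.empty and trip_table["site"].nunique() >= 2:
        tt = trip_table.copy()
        tt["log_duration"] = np.log(tt["duration_h"])
        rep = assumption_tests(tt, "log_duration")
        cmp_res = compare_sites(tt, "log_duration", parametric=rep.parametric)
        trip_stats = {"branch": cmp_res["branch"], "p": cmp_res["p"]}
        stage("trip_stats", **trip_stats)
    else:
        stage("trip_stats", note="skipped: single site")

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.suffix in {".csv", ".asc", ".json", ".geojson"} \
                and p.name != "manifest.json":
            manifest["checksums"][str(p.relative_to(out))] = sha256_of(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def make_report(manifest: dict, path=None) -> str:
    """Human-readable summary of a pipeline run (markdown)."""
    lines = ["# Run report", ""]
    cfg = manifest.get("config", {})
    lines += [f"- species: {cfg.get('species')}  mode: {cfg.get('mode')}"
              f"  seed: {cfg.get('seed')}", ""]
    lines.append("## Stages")
    for name, counts in manifest.get("stages", {}).items():
        kv = ", ".join(f"{k}={_fmt(v)}" for k, v in counts.items())
        lines.append(f"- **{name}**: {kv}")
    outdir = Path(cfg.get("outdir", "."))
    mj = outdir / "model.json"
    if mj.exists():
        model = json.loads(mj.read_text())
        lines += ["", "## Selection model",
                  f"- explained deviance: {model['explained_deviance']:.1f}%",
                  f"- AIC: {model['aic']:.1f}", "- covariate importance (%):"]
        for k, v in model["importance"].items():
            lines.append(f"    - {k}: {v:.1f}")
    trips_csv = outdir / "trips.csv"
    if trips_csv.exists():
        png = outdir / "trip_boxplots.png"
        try:
            _trip_boxplots(pd.read_csv(trips_csv), png)
            lines += ["", f"Trip-metric boxplots: {png.name}"]
        except Exception as exc:  # plotting must never break reporting
            logger.warning("make_report: boxplots skipped (%s)", exc)
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def _trip_boxplots(trips: pd.DataFrame, path) -> None:
    """Per-site boxplots of trip duration and maximum extent."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, col, label in zip(axes, ("duration_h", "max_extent_km"),
                              ("Trip duration (h)", "Maximum extent (km)")):
        groups = [g[col].to_numpy() for _, g in trips.groupby("site")]
        ax.boxplot(groups, tick_labels=[s for s, _ in trips.groupby("site")])
        ax.set_ylabel(label)
        ax.set_xlabel("site")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _fmt(v):
    if isinstance(v, float):
        return f"{v:.3f}"
    return v


def _cfg_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
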