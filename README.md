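# sealforage

Foraging-habitat-selection analysis for diving central-place foragers —
gray seals (*Halichoerus grypus*) and harbor seals (*Phoca vitulina*)
tracked with GPS/GSM tags from coastal haulout sites.  The package
implements the full analysis chain from raw tag streams to habitat
selection maps and home-range overlap statistics, together with a
synthetic seascape/track generator so every stage can be validated against
a known ground truth.

## What it does

Given per-seal GPS fixes, dive records (max depth, duration, nine
intermediate depth points) and a wet/dry sensor series, plus environmental
rasters (bathymetry, seabed sediment class, tidal current) and a haulout
catalogue:

1. **Haulouts & trips** — haulout events open after >10 min continuously
   dry and close at 40 s continuously wet; trips are segmented between
   events, filtered (duration ≥ 3 h, outside breeding/molt months,
   return-to-colony for gray seals) and regularized to 20-min tracks.
2. **Foraging dives** — dives shallower than 3 m or shorter than 30 s are
   discarded; each remaining dive gets a Time-Allocation-at-Depth score

   `TAD = (A − A_min) / (A_max − A_min)`,  with `A` the time integral of
   depth, `A_min = D²/v_max` (sharpest V-dive) and `A_max = D·T − D²/v_max`
   (square dive at the fastest transit speed `v_max`).  Per individual, the
   top 25% of TAD scores are kept and the 10% slowest descents among them
   removed, flagging ≈22.5% of dives as benthic foraging.  Dive locations
   are interpolated at the dive midpoint between bracketing fixes.
3. **Use-availability design** — the availability region is the colony MCP
   scaled to 3× its area, clipped to the continental shelf and to sea; two
   uniform pseudo-absences are drawn per foraging dive per individual.
4. **Selection model** — a binomial smooth model on the logit scale,

   `logit P(y=1) = α + Σ_j f_j(x_j) + sediment + b_individual`,

   with penalized cubic-spline smooths of bathymetry, tidal current,
   distance to shore and least-cost distance to the last haulout, a forced
   sediment reference level, ridge-penalized individual (and, pooled mode,
   site) random intercepts, AIC model selection, drop-term covariate
   importance, and population-level prediction maps.
5. **Spatial overlap & trip statistics** — 95% kernel utilization
   distributions of foraging locations, Bhattacharyya affinity
   `BA = Σ √(p₁·p₂)` between individuals/species, Kruskal–Wallis/ANOVA site
   comparisons of log trip duration and maximum extent, and the
   colony-size vs latitude linear mixed models.

All distances at sea are least-cost (shortest path over an 8-connected sea
lattice), so land masses force realistic detours.

## Worked example

```python
import sealforage as sf
from sealforage.pipeline import RunConfig, run_pipeline, make_report

cfg = RunConfig(outdir="runs/demo", seed=5)
manifest = run_pipeline(cfg)
print(make_report(manifest))
```

prints (abridged):

```
- **simulate**: n_fixes=2413, n_dives=367, n_wetdry=351963
- **dives**: n_raw=367, n_prefiltered=367, ..., n_classified=89
- **availability**: mcp_km2=1692.959, scaled_km2=5078.876, n_absences=178
- **model**: aic=196.147, explained_deviance=48.176
- **overlap**: n_individuals=6, mean=0.855, sd=0.053, n_pairs=15

## Selection model
- explained deviance: 48.2%
- covariate importance (%):
    - bathy: 18.5
    - dist_haulout: 53.4
    ...
```

Distance to the last haulout dominates the explained deviance and
bathymetry comes second, both with negative effects — seals in this
synthetic world were generated to forage close to their haulouts in
shallow water, and the model recovers exactly that.  The 1,000-dive
classification identity (89 foraging dives from 367 recorded, ≈22.5% of
the prefiltered set per individual) and the 2:1 absence:presence ratio
(178 = 2 × 89) are visible in the stage counts.

The same stages are available from the shell:

```bash
sealforage simulate --out runs/sim --seed 3
sealforage run --config cfg.yaml --out runs/demo --seed 5
sealforage report runs/demo/manifest.json
```

## Layout

```
src/sealforage/
  seascape.py   synthetic seascapes + ground-truth selection surfaces
  simulate.py   seal track/dive/wet-dry simulator, use-availability sampler
  dives.py      TAD, descent speed, prefilter, two-stage classification
  trips.py      haulout automaton, trip segmentation/filtering/metrics
  geo.py        sea graph, least-cost distances, MCP, availability, sampling
  habitat.py    HabitatSelectionModel / HabitatSelectionResults
  overlap.py    kernel UDs, 95% contours, Bhattacharyya affinity
  tripstats.py  site comparisons + colony-size/latitude mixed models
  pipeline.py   orchestration, manifest, report
  cli.py        `sealforage simulate | run | report`
```

See `docs/methods.md` for the modelling details and the design decisions.
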