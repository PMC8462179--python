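# Methods

This note documents the models and procedures implemented in `sealforage`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the choices made where the design was genuinely open.

## Dive classification

Tags record each dive as (start, end, duration `T`, maximum depth `D`, nine
intermediate depth points).  The profile used for scoring is the piecewise
linear curve through the two surface endpoints and the nine interior points.

**TAD (Time Allocation at Depth).**  The index is the area-based dive-shape
score bounded by the fastest physically plausible transits: with `A` the
trapezoidal integral of depth over `[0, T]` (m·s) and `v_max` the maximum
vertical transit speed,

```
A_min = D² / v_max            # sharpest possible V-dive
A_max = D·T − D² / v_max      # square dive at fastest transit
TAD   = (A − A_min) / (A_max − A_min), clamped into [0, 1]
```

0 is a surface-skewed dive, 1 a square bottom-hugging dive.  Dives with
`2·D/v_max ≥ T` are unscorable (the bounds collapse) and are excluded with a
log entry rather than clamped.  `v_max` defaults to 2.0 m/s, is configurable,
and can be estimated per deployment as the 99th percentile of observed
descent speeds.  Values falling outside [0, 1] before clamping (profiles
that transit faster than `v_max`) are counted and logged.

**Descent speed** is the depth of the first recorded profile point divided by
its time offset from the dive start — the surface-to-first-inflection slope.
The definition is isolated behind one function so alternatives (full descent
phase) can be swapped in.

**Two-stage rule.**  After the prefilter (drop dives with `D < 3 m` or
`T < 30 s`; boundary values retained), and strictly per individual: stage 1
keeps the `ceil(0.25·n)` highest-TAD dives; stage 2 removes the
`floor(0.10·k)` lowest-descent-speed dives among them (slow, U-shaped dives
are more likely resting than foraging).  The stage-2 base is the stage-1
selection, so the flagged fraction is 0.25·0.9 = 22.5% of prefiltered dives
up to rounding.  Ties are broken by start time (earlier kept first) to make
the selection deterministic.  Individuals with fewer than 8 dives are flagged
unclassifiable — the quantiles are meaningless at that size.  Dive locations
are interpolated linearly at the dive *midpoint* between bracketing GPS
fixes (max bracket gap 6 h, configurable); unbracketed dives are dropped and
counted.

## Trips

Haulout events are detected from the wet/dry series by an automaton: an
event opens at the start of a maximal dry run strictly longer than 10 min
and closes at the start of the first wet run lasting at least 40 s; shorter
splashes do not split events.  The event start is stamped at the beginning of
the dry run — this affects haulout duration only, never trip topology.

Trips are the intervals between consecutive events with at least one
strictly interior at-sea fix; boundary-instant fixes are excluded.  Tracks
are regularized to a 20-min lattice by straight-line interpolation, without
extrapolation.  Filters: duration < 3 h dropped (strict); trips whose
*departure month* falls in the species' breeding + early-molt window
dropped (gray: Sep–Feb, harbor: Jun–Sep); in gray-seal mode only trips
departing and arriving at the tagging colony are retained (harbor seals are
strongly site-faithful, so the restriction is unnecessary there).  The trip
maximum extent is the maximum over track points of the *least-cost* at-sea
distance from the departure haulout, for consistency with the
distance-to-haulout covariate; a straight-line variant sits behind a flag.

## Spatial backbone

Sea distances run over an 8-connected lattice of sea cells with cell-center
metric edge lengths (planar km in synthetic worlds; great-circle lengths in
geographic mode).  8-connectivity overestimates true geodesics by at most
~8%, which is accepted as the accuracy/speed balance; Dijkstra via
`scipy.sparse.csgraph` with connected components labelled so unreachable
targets are flagged rather than silently infinite.  Haulouts snap to the
nearest sea cell within a 1-cell tolerance.

The availability region is the 100% minimum convex polygon of all dive
locations, scaled about its centroid by √3 per axis (area ×3 — "three times
the size" is read as area, matching the intent of tripling available
habitat; a linear-scale option is kept for sensitivity runs), then
intersected with the continental-shelf polygon and with sea.  Pseudo-absences
are sampled uniformly over the clipped region by rejection from its bounding
box (error if acceptance falls below 1%), exactly two per foraging dive per
individual, with no covariate filtering — they represent pure availability.
Geographic-mode areas use a local Lambert azimuthal equal-area projection
centered on the colony.

## Selection model

The use-availability table (response 1 = foraging dive, 0 = pseudo-absence)
is fitted with a binomial logit model

```
logit P(y=1) = α + Σ_j f_j(x_j) + sediment + b_ind (+ b_site, pooled mode)
```

* Smooths `f_j`: cubic B-splines on quantile knots, basis dimension k = 5
  per covariate (configurable, stamped in outputs), second-difference
  penalty, sum-to-zero constraint absorbed by a null-space projection.
* Sediment: categorical fixed effect; the reference level is forced to the
  most represented class (configurable).
* Random intercepts: ridge-penalized dummy blocks for individual (and site
  in the pooled "global" mode); the implied intercept SD is `1/√λ_re`.
* Fitting: penalized IRLS with step-halving on the penalized deviance
  (keeps the iteration monotone even at near-unpenalized smoothing
  parameters).  Smoothing parameters — one per smooth plus one per random
  block — are selected by minimizing `deviance + 2·EDF` (an AIC/UBRE-type
  criterion; chosen over a full Laplace REML for robustness and speed at
  this problem size) with Nelder–Mead over log λ, λ clipped to [1e-5, 1e5].
  The fit is deterministic given the data.
* AIC uses the effective degrees of freedom `tr[(X'WX+S)⁻¹X'WX]`; model
  selection is all-subsets over the smooth terms (≤ 31 fits for 5 terms),
  minimum AIC, ties broken toward fewer terms.
* Collinearity: VIF per continuous covariate (sediment dummy-coded),
  report-only with a warning threshold of 5.
* Covariate importance: drop-term decomposition — refit without the term
  and take the loss in explained deviance `100·(1 − D_model/D_null)`,
  floored at 0 and normalized to 100%.  An alternative (variance of the
  term's partial linear predictor, no refits) sits behind a flag; the
  drop-term variant is the default because it directly measures each
  covariate's contribution to fit quality.
* Prediction maps: population level (random intercepts at 0), inverse-logit,
  with pointwise SEs from the penalized-fit covariance; the
  distance-to-last-haulout covariate is surrogated on the map by the
  least-cost distance to the nearest colony haulout; cells whose covariates
  fall outside the fitted range are flagged extrapolated.
* Global mode applies a systematic 1-in-3 thinning of foraging dives (with
  their tied pseudo-absences) before fitting, mirroring the convergence
  practice for pooled data.

Separation or a singular penalized system raises an explicit error rather
than returning drifting coefficients.

## Overlap

Utilization distributions are fixed-bandwidth bivariate Gaussian KDEs
evaluated on a grid and normalized over cells.  The default bandwidth is the
per-axis normal-scale rule `h_j = σ_j·n^(−1/6)` — the kernel rule is an
assumption, flagged in output metadata, since nothing in the analysis pins
it down.  The 95% volume contour admits cells in decreasing density order
(row-major on exact ties) until cumulative probability reaches 0.95; the UD
is renormalized on that set.  Bhattacharyya affinity `Σ√(p₁p₂)` is computed
on the truncated, renormalized UDs by default (full-UD variant behind a
flag), with both UDs *evaluated* (not resampled) on a common grid spanning
the union bounding box.

## Trip statistics

Log-transformed trip duration and maximum extent are compared across sites:
Shapiro–Wilk per site plus Bartlett gate the parametric branch (one-way
ANOVA + Tukey HSD) versus the nonparametric branch (Kruskal–Wallis + Dunn
pairwise z tests).  Dunn p-values are Holm-adjusted (configurable; the
adjustment choice is a convention).  Note the gate conjoins k+1 α = 0.05
tests, so its null pass rate is ≈ 0.95^(k+1), not 95%.  The colony-size
question is asked through three ML-fitted linear mixed models with a random
site intercept (`~ n_seals`, `~ latitude`, `~ n_seals + latitude`), compared
by AIC; Wald p-values of the winner are reported with the caveat that
site-level covariates carry only as many effective observations as there
are sites, and that p-values read off an AIC winner are post-selection.
Trips are treated as independent; a seal-level cluster bootstrap is
available as an optional robustness output.

## Synthetic data generator

The generator is the package's test bed: a planar-km seascape (coastal land
strip with noisy shoreline, bathymetry deepening offshore with correlated
noise, spatially autocorrelated sediment classes, smooth non-negative tidal
field, haulouts on coast-adjacent sea cells, shelf polygon = cells above the
depth cutoff) plus seals alternating haulout bouts with return trips.

The key design property: each dive on a trip is a foraging dive with
probability φ, and *foraging-dive locations are drawn i.i.d. from the
normalized true selection surface* `w ∝ exp(η)` over sea cells.  The seal
then travels through those locations over least-cost sea paths, so the
empirical foraging-dive density equals the surface exactly — the
use-availability contrast the selection model estimates, by construction.
Foraging dives are square-profiled (interior depths 92–100% of max depth,
descent speeds 1.2–1.9 m/s, max depth 88–99% of local bathymetry); transit
dives are V-shaped, shallower (≤ 28 m) and slower-descending (0.7–1.1 m/s),
placed along the travel path.  Wet/dry series are sampled at 10 s with
haulout bouts of 2.5–6 h and occasional sub-40-s splashes; fixes follow a
20-min lattice with 20% Bernoulli dropout (a convention — fix-success rates
are not documented for the real tags), with the first and last at-sea fix
of each trip protected so every dive stays bracketed.

What the generator does *not* emulate: spatially correlated GPS error,
tidally phased currents, prey-field dynamics, haulout-site switching
between colonies, or seasonal behaviour changes.  Passing tests therefore
demonstrate the correctness and statistical calibration of the machinery
under the stated generative assumptions, not robustness to every field
pathology.

Default study conditions used by tests and the worked example: 60–100 km
domains at 2 km cells, 3–8 seals, 3–7 trips each, 12–72 dives per trip,
φ = 0.4–0.5, bathymetry preference −0.05 to −0.08 per m and a 20–30 km
haulout decay scale — sizes at which every suite runs in well under a
minute per module on one CPU.

## Numerical conventions

* Stage-1/stage-2 rounding is `ceil`/`floor`, fixed to make counts
  deterministic; 1,000 dives give exactly 225 flagged.
* PIRLS converges on relative change of the penalized deviance < 1e-9 with
  step-halving; a 1e-10 diagonal jitter guards rank-deficient systems.
* The contour tie rule (row-major) matters only for exactly tied densities
  (degenerate UDs).
* All stochastic stages take explicit seeds; identical configuration and
  seeds reproduce every serialized artifact bit-for-bit (checked by
  checksum in the pipeline manifest).

## Known limitations

* The random-intercept variance is a by-product of penalty selection, not a
  full REML variance component; its uncertainty is not quantified.
* Spatial autocorrelation of residuals is not modelled (each dive/absence
  row is treated as independent given the random effects).
* Geographic-mode support covers distances, areas and MCPs; the bundled
  seascape generator itself is planar.
* AIC all-subsets selection admits a pure-noise smooth with probability
  ≈ P(χ²₁ > 2) ≈ 0.16 — inherent to AIC, not a defect of the search.
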