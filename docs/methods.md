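# Methods

`trackfidelity` implements an annual-cycle analysis of satellite-tracked
migratory shorebirds: it turns raw Argos-style location fixes into residency
clusters, kernel home ranges, mean migratory routes, per-latitude
repeatability profiles, and stage-comparison models of between-year site
fidelity. This note describes the models and procedures, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the numerical choices taken where the design was open.

## Geodesy

All distances are geodesics on the WGS84 ellipsoid (Vincenty's inverse
method, vectorised; nearly-antipodal pairs fall back to the spherical
great-circle). A haversine mode is available behind
`distance_method="haversine"` for speed; at the regional scales involved the
two differ by < 0.5%. Kernel densities, contour areas and overlap
computations run in a local Lambert azimuthal equal-area projection
(authalic radius) centred on the data being analysed, so areas are true at
cluster scale.

## Speed filtering

Ground speed between consecutive fixes is geodesic distance over elapsed
time. The filter is a greedy forward pass with a 150 km/h default ceiling:
each fix is tested against the last *kept* fix and dropped if the implied
speed exceeds the ceiling, so the first fix is never removed and the result
is idempotent. For the error structure this targets — isolated Argos
outliers far off the path — the greedy pass returns the maximum-cardinality
valid subsequence, and the test suite verifies agreement with an O(n²)
dynamic-program oracle (`max_valid_subsequence`) on such tracks.
Adversarial geometries exist where greedy keeps fewer fixes than the
optimum; the DP is available when that matters.

## Residency clustering (spatio-temporal DBSCAN)

Two fixes are neighbours when they are within `eps_m` *and* within
`max_lag_d` of each other (a pairwise temporal gate on density
reachability). Core points have at least `min_pts` neighbours including
themselves; clusters are connected components of core points, and border
points attach to the first core point in time order that reaches them —
this removes classical DBSCAN's order ambiguity. The temporal gate makes a
spatial revisit after a gap longer than `max_lag_d` start a new cluster,
separating, e.g., the same wetland used in successive autumns. Defaults are
`min_pts = 3`, `eps_m = 4000`, `max_lag_d = 10` days, with a coarser
alternative (5 / 8000 m / 20 d) and per-bird overrides via the config.
Clusters with tenure strictly greater than 1 day count as residency areas.
The cluster *centre* is the mode of a Gaussian-kernel point intensity on a
250 m grid over the cluster bounding box (ties broken toward the ground
occupied earliest).

## Home ranges and between-year fidelity

Each cluster's utilization distribution is a bivariate Gaussian KDE on
projected coordinates with the ad-hoc reference bandwidth
h = sigma·n^(−1/6) (pooled per-axis SD; 30 m floor for degenerate
clusters). Clusters with fewer than five fixes are padded by cycling their
points to five before fitting. The grid is 200×200 cells padded three
bandwidths beyond the data (cells coarsened if needed); doubling the cell
size changes the 90% area by < 10% on Gaussian fixtures. The home range is
the 90% highest-density region: cells ranked by density and accumulated
until 0.90 of the mass is reached, so the realised mass overshoots by at
most one cell (tested to lie in [0.90, 0.91]).

Between-year fidelity per bird, stage and consecutive-year pair:

* overlap proportion = 2·A(U_x ∩ U_y) / (ΣA_x + ΣA_y), with U the union of
  that year's home ranges — symmetric, 1 for identical geometries, 0 for
  disjoint ones;
* minimum centre distance = the smallest geodesic distance between any
  cross-year pair of cluster centres.

## Migratory routes and band statistics

Clustered fixes are first collapsed onto their cluster centres. Each
migration — bounded by the last day at the longest-tenure residency cluster
in the departure range and the first day at the longest-tenure cluster in
the arrival range (ties: more fixes, then earlier start) — is interpolated
to a regular 15-minute grid. The default interpolator is a
correlated-random-walk Kalman smoother (constant-velocity state,
white-noise acceleration of spectral density 1e-3 m²/s³, independent axes
in a local equal-area frame) with Gaussian observation error by Argos class;
a piecewise great-circle mode exists for already-noise-free input. A grid
position is *valid* only when at least two observed fixes fall in its
surrounding 24-hour window, and only valid positions enter band statistics.

The population mean route has 500 points spanning the corridor. It is
initialised as the pointwise mean of all tracks resampled to 500 points by
cumulative-distance fraction and refined iteratively: every route point
moves to the average of its nearest point on each track (nearest by chord
on the unit sphere, which orders identically to great-circle distance), and
the polyline is re-spaced. Iterations stop when the mean displacement drops
below 1 km, after 100 iterations, or if the objective (mean nearest-track
distance) would increase — so the recorded objective history is
non-increasing. A single input track is returned directly (objective 0).

Per 1° latitudinal band between 8°N and 73°N, two observations per
bird-year and direction: the date of first entry into the band (first valid
position whose latitude falls in the band; re-entries ignored) and the
signed longitudinal deviation — for each mean-route point, the east–west
geodesic distance at that latitude to the nearest track point, west
negative, averaged over the route points in the band.

## Repeatability

Repeatability is the intraclass correlation from the one-way Gaussian
random-intercept model y_ij = mu + a_i + e_ij:
R = sigma²_id / (sigma²_id + sigma²_res). Variance components are REML
estimates; the profiled restricted likelihood is closed-form given the
ratio lambda = sigma²_id/sigma²_res, so the fit reduces to a 1-D
optimisation (grid scan plus Brent refinement; boundary at 0 allowed).
REML agrees with the closed-form balanced-ANOVA components to 1e-6 on
balanced designs and with statsmodels `MixedLM` on unbalanced ones.

Confidence intervals are percentile parametric-bootstrap intervals: data
are regenerated from the fitted model on the observed design and refitted
(vectorised; the bootstrap refit optimises lambda on a dense log grid,
resolving R to ~1e-3 — ample for 2.5/97.5 percentiles). The default is
1000 iterations, configurable upward for production use. Significance is a
likelihood-ratio test of sigma²_id = 0 with the boundary-corrected null
0.5·χ²₀ + 0.5·χ²₁ (ML fits on both sides). Profile p-values are adjusted
by Benjamini–Hochberg FDR. Bands with fewer than two individuals, or no
repeated individual, are skipped.

Event repeatability covers seven timing variables: breeding
arrival/departure, wintering arrival/departure, and south-stopover
start/end/duration (north-bound stopovers are too brief and too rarely
repeated to analyse). Values are fractional days since 1 January of the
cycle year, so a wintering departure the following spring exceeds 365 and
remains comparable across years.

## Stage-comparison models

Overlap proportions are modelled with a zero-inflated beta mixed model:
logit P(y = 0) ~ stage and a beta regression (logit mean, common precision)
~ stage, with one shared per-bird random intercept entering both linear
predictors, integrated out by 20-node Gauss–Hermite quadrature (likelihood
changes < 1e-4 at 40 nodes on fixtures). Exact ones are shrunk to
1 − 1e-6 (open beta support) and counted. Minimum centre distances are
fitted with a Gaussian linear mixed model (REML via statsmodels) with the
same fixed and random structure. Both use treatment contrasts with
breeding as the reference stage and report Wald z-tests.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study conditions of a multi-year Arctic
shorebird tracking data set: 20 birds, 3 annual cycles by default. Each
bird keeps one wintering site across years (2 km jitter — strong wintering
fidelity) and draws a fresh breeding site each year from a Gaussian
dispersal kernel (sd 125 km per axis, giving a mean consecutive-year
displacement of ~157 km); breeding seasons include extra short exploratory
residencies (about two sites per season on average). Southbound migration
includes a long moult-staging stop in the temperate latitudes (bird-level
mean latitude ~45°N) timed so that arrival at the wintering grounds falls
around mid-October; northbound stops are brief (~9 d).

Event timing is population mean + per-bird intercept (between sd, default
8 d) + annual noise (within sd, default 6 d), with per-event multipliers
so that — as in the tracked population — arrival at the wintering site is
the most repeatable event (R_true ≈ 0.88) while breeding-season timing is
noisy (R_true ≈ 0.25). True repeatability per anchored event is recorded
in the ground truth. Positions are reported every 6 h with i.i.d. Argos
classes (34% classes 1–3, 19% class 0, 46% A/B) and isotropic Gaussian
errors of 100–1500 m by class; within-residency movement is 1 km Gaussian
scatter around the site; flight legs are great circles at 65 km/h.

Not emulated: environmental covariates (snow melt, predation), mortality
or tag failure (beyond optional uniform fix dropout), duty-cycle gaps,
heavy-tailed Argos errors, and route choice between discrete flyways.
Passing tests therefore demonstrate correct recovery of the generator's
idealised structure, not robustness to every pathology of real Argos data
— in particular, the manual visual screening step used with real data is
replaced by an optional exclusion list.

## Problem sizes and numerical conventions

Test-suite simulations use 4–12 birds over 2–3 cycles; the acceptance
script uses the full default conditions (20 birds × 3 cycles, ~52,000
fixes), 1000 bootstrap draws per repeatability estimate, and completes in
a few minutes on one CPU. Statistical calibration checks use 200 replicate
datasets of 30 birds × 3 years. Other conventions: polygon boundaries
count as inside (closed ranges); cycle years are labelled by the calendar
year of the breeding season, the wintering season keeping the cycle year
of its autumn; cluster-centre ties break toward the earliest-occupied
ground; the mean-route iteration keeps the previous route if a step fails
to improve the objective.

## Known limitations

* The greedy speed filter can be suboptimal for clustered (non-isolated)
  outliers; the DP variant is exact but O(n²).
* Percentile bootstrap CIs for R undercover slightly at very small numbers
  of individuals (< 15), a known property of variance-ratio bootstraps.
* The deviation statistic matches each mean-route point to the nearest
  track *vertex* (no segment projection); at 15-minute resolution the
  vertex spacing (10–20 km in flight) is small relative to the 1° bands.
* The zero-inflated beta fit can be slow to converge when a stage has no
  zero or no non-zero observations; inestimable stage coefficients are
  flagged rather than silently dropped.
* On strongly fanning corridors (wintering sites spread over tens of
  degrees of longitude) the iterative mean-route averaging contracts the
  route toward the corridor's dense section; deviation statistics then
  cover only the latitudinal bands the mean route spans.
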