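# trackfidelity

Annual-cycle site fidelity and migration repeatability from satellite
telemetry.

Many migratory birds are tracked with Argos satellite transmitters for
several consecutive years. Repeat tracks of the same individual make it
possible to ask *where* in the annual cycle a bird is consistent — does it
return to the same wintering area, the same stopovers, the same breeding
site, and does it keep the same migration schedule? `trackfidelity` is a
tested, reusable pipeline answering these questions for movement
ecologists: from raw location fixes to residency clusters, kernel home
ranges, mean migratory routes, per-latitude repeatability profiles, and
stage-comparison models — exercised end-to-end on a synthetic-track
generator with known ground truth.

## What it computes

Starting from a fix table (bird id, UTC timestamp, lon/lat, Argos location
class) and breeding/wintering range polygons:

1. **Speed filter** — drops fixes implying ground speeds > 150 km/h
   (geodesic on WGS84).
2. **Stage segmentation** — breeding, southward migration, wintering,
   northward migration, from first entry / last exit of the range polygons,
   with a residency-based fallback for birds wintering outside the known
   range.
3. **Residency clusters** — spatio-temporal DBSCAN (MinPts = 3, ε = 4 km,
   maxLag = 10 d by default): fixes are neighbours only if close in both
   space and time, so revisits after a long gap form new clusters.
4. **Home ranges** — per cluster, the 90% utilization distribution
   (bivariate Gaussian KDE on an equal-area projection); between-year
   fidelity as overlap proportion 2·A∩/(ΣA_x + ΣA_y) and minimum
   centre-to-centre distance.
5. **Routes** — cluster-collapsed tracks interpolated every 15 min with a
   correlated-random-walk Kalman smoother; a 500-point population mean
   route; per-1°-latitude-band entry dates and signed east–west route
   deviations.
6. **Repeatability** — for each band and each annual event, the intraclass
   correlation R = σ²_id/(σ²_id + σ²_res) from a random-intercept model
   (fast profiled REML), with parametric-bootstrap 95% CIs,
   boundary-corrected likelihood-ratio tests and Benjamini–Hochberg FDR.
7. **Stage models** — zero-inflated beta mixed model for overlap
   proportion and Gaussian mixed model for centre distance, with stage as
   the fixed effect and bird as a random intercept.

The synthetic generator simulates a population with strong wintering-site
fidelity, exploratory breeding dispersal (~157 km mean between years), a
long southbound moult-staging stop, and event timing with configurable
true repeatability — so every stage of the pipeline can be validated
against known truth. See `docs/methods.md` for the full model
descriptions.

## Worked example

```python
from trackfidelity import SimConfig, PipelineConfig, run_all

cfg = PipelineConfig(seed=1, n_boot=500,
                     sim=SimConfig(n_birds=8, n_years=3, seed=1))
res = run_all(cfg)
print(f"speed-filter removed: {100*res.removed_fraction:.1f}%")
print(res.overlaps.groupby("stage")["any_overlap"].mean().round(2))
print(res.event_rpt[["variable", "R", "ci_low", "ci_high", "p_fdr"]].round(3))
```

prints

```
speed-filter removed: 0.0%
stage
breeding           0.00
north_migration    0.00
south_migration    0.00
wintering          0.94
Name: any_overlap, dtype: float64
                  variable      R  ci_low  ci_high  p_fdr
0         breeding_arrival  0.000   0.000    0.387  1.000
1       breeding_departure  0.233   0.000    0.666  0.266
2        wintering_arrival  0.778   0.360    0.922  0.000
3      wintering_departure  0.408   0.000    0.749  0.083
4     stopover_south_start  0.208   0.000    0.613  0.266
5       stopover_south_end  0.761   0.273    0.922  0.000
6  stopover_south_duration  0.604   0.106    0.849  0.008
```

Between-year home ranges overlap in 94% of wintering comparisons and never
at breeding or stopover sites — the simulated birds reuse their wintering
site but disperse to new breeding sites each year — and the timing of
arrival at the wintering area is the most repeatable annual event
(R = 0.78, CI excluding zero), while breeding-season timing is not
repeatable. Large-noise fixes survive here because the simulated Argos
errors (≤ 1.5 km at 6-h intervals) never imply speeds above the ceiling.

The same pipeline runs from the shell:

```bash
trackfidelity simulate --seed 1 --out sim/
trackfidelity filter sim/fixes.csv --vmax 150 --out filtered.csv
trackfidelity all --seed 1 --out results/
```

`results/report.txt` summarises counts of residency areas, per-stage means,
median home-range sizes and overlap incidences; every number is traceable
to a CSV/GeoJSON artifact written alongside it.

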