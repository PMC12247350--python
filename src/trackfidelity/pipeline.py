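"""End-to-end orchestration: simulate (or load) -> filter -> segment ->
cluster -> home ranges -> routes -> repeatability -> stage models.

``run_all`` is deterministic given the config seed and returns a
``PipelineResult`` holding every intermediate table; ``write_artifacts``
dumps them as CSV/GeoJSON plus a plain-text report so that every number in
the report is traceable to a file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geojson_io
from .clustering import ResidencyCluster, cluster_center, clusters_to_frame, filter_tenure, st_dbscan
from .config import PipelineConfig
from .homerange import HomeRange, home_range, overlap_records
from .io_filtering import speed_filter, split_tracks
from .repeatability import band_repeatability_profile, event_repeatability
from .routes import (InterpolatedTrack, MeanRoute, band_entry_dates,
                     band_lon_deviation, collapse_to_centers, interpolate_track,
                     mean_route)
from .segmentation import (RangePolygons, assign_stages, extract_events,
                           label_clusters, migration_bounds, wintering_fallback)
from .synthetic import SimTruth, generate_population, generate_range_polygons

log = logging.getLogger("trackfidelity")


@dataclass
class PipelineResult:
    config: PipelineConfig
    fixes: pd.DataFrame
    truth: SimTruth | None
    filtered: dict                      # bird_id -> track DataFrame
    removed_fraction: float
    clusters: dict                      # bird_id -> list[ResidencyCluster]
    intervals: pd.DataFrame
    home_ranges: dict                   # bird_id -> list[HomeRange]
    overlaps: pd.DataFrame
    band_obs: pd.DataFrame
    mean_routes: dict                   # direction -> MeanRoute
    band_profiles: pd.DataFrame
    events: pd.DataFrame
    event_rpt: pd.DataFrame
    model_overlap: object | None
    model_distance: object | None
    stage_summary: pd.DataFrame
    dropped: dict = field(default_factory=dict)


def _cluster_cycle_year(c: ResidencyCluster) -> int:
    if c.stage == "wintering" and c.start.month < 6:
        return c.start.year - 1
    return c.start.year


def run_all(cfg: PipelineConfig, fixes: pd.DataFrame | None = None,
            ranges: RangePolygons | None = None,
            truth: SimTruth | None = None) -> PipelineResult:
    rng = np.random.default_rng(cfg.seed)
    if fixes is None:
        log.info("simulating population: %d birds x %d years",
                 cfg.sim.n_birds, cfg.sim.n_years)
        fixes, truth = generate_population(cfg.sim)
    if ranges is None:
        b, w = generate_range_polygons(cfg.sim)
        ranges = RangePolygons(breeding=b, wintering=w)

    # --- speed filter -----------------------------------------------------
    filtered = {}
    n_in = n_removed = 0
    for tr in split_tracks(fixes):
        res = speed_filter(tr, cfg.vmax_kmh, method=cfg.distance_method)
        bird = str(tr["bird_id"].iloc[0])
        filtered[bird] = res.kept
        n_in += len(tr)
        n_removed += len(res.removed)
    removed_fraction = n_removed / n_in if n_in else 0.0
    log.info("speed filter: removed %d/%d fixes (%.1f%%)",
             n_removed, n_in, 100 * removed_fraction)

    # --- clustering + segmentation ---------------------------------------
    clusters: dict[str, list[ResidencyCluster]] = {}
    interval_frames = []
    for bird, tr in filtered.items():
        cl, _ = st_dbscan(tr, cfg.cluster_params_for(bird), method=cfg.distance_method)
        cl = filter_tenure(cl, cfg.min_tenure_d)
        iv = assign_stages(tr, ranges)
        if "wintering" not in set(iv["stage"]):
            fb = wintering_fallback(tr, cl, d_north_km=cfg.d_north_km)
            if fb is not None:
                iv = pd.concat([iv, pd.DataFrame([fb])], ignore_index=True)
                iv = iv.sort_values("start").reset_index(drop=True)
        label_clusters(cl, tr, iv)
        for c in cl:
            c.center = cluster_center(c)
        clusters[bird] = cl
        interval_frames.append(iv)
    intervals = pd.concat(interval_frames, ignore_index=True)

    # --- home ranges & between-year fidelity ------------------------------
    home_ranges: dict[str, list[HomeRange]] = {}
    overlap_frames = []
    skipped_hr = 0
    for bird, cl in clusters.items():
        hrs = []
        for c in cl:
            if c.n_fixes < 3:
                skipped_hr += 1
                continue
            hrs.append(home_range(c, cell_m=cfg.ud_cell_m, mass=cfg.ud_level))
        home_ranges[bird] = hrs
        by_stage: dict[str, dict[int, list[HomeRange]]] = {}
        for hr in hrs:
            st = hr.cluster.stage
            cy = _cluster_cycle_year(hr.cluster)
            by_stage.setdefault(st, {}).setdefault(cy, []).append(hr)
        for st, by_year in by_stage.items():
            if st in (None,):
                continue
            stage_label = {"breeding": "breeding", "wintering": "wintering",
                           "south_migration": "south_migration",
                           "north_migration": "north_migration"}.get(st, st)
            overlap_frames.append(overlap_records(by_year, bird, stage_label))
    overlap_frames = [f for f in overlap_frames if len(f)]
    overlaps = (pd.concat(overlap_frames, ignore_index=True)
                if overlap_frames else pd.DataFrame())

    # --- migratory routes & band observations -----------------------------
    band_frames = []
    tracks_by_dir: dict[str, list[InterpolatedTrack]] = {"south": [], "north": []}
    for bird, tr in filtered.items():
        cl = clusters[bird]
        collapsed = collapse_to_centers(tr, cl)
        years = sorted(intervals[intervals["bird_id"] == bird]["cycle_year"].unique())
        for cy in years:
            bounds = migration_bounds(intervals[intervals["bird_id"] == bird], cl, int(cy))
            for direction in ("south", "north"):
                bd = bounds[direction]
                if bd is None:
                    continue
                sub = collapsed[(collapsed["timestamp"] >= bd[0])
                                & (collapsed["timestamp"] <= bd[1])]
                it = interpolate_track(sub, dt_min=cfg.interp_dt_min,
                                       mode=cfg.interp_mode, bird_id=bird,
                                       cycle_year=int(cy), direction=direction)
                if it is None:
                    continue
                tracks_by_dir[direction].append(it)
                band_frames.append(band_entry_dates(it))

    mean_routes: dict[str, MeanRoute] = {}
    for direction, its in tracks_by_dir.items():
        if not its:
            continue
        mr = mean_route(its, n=cfg.n_route_points, direction=direction)
        mean_routes[direction] = mr
        for it in its:
            band_frames.append(band_lon_deviation(it, mr))
    band_frames = [f for f in band_frames if len(f)]
    band_obs = (pd.concat(band_frames, ignore_index=True)
                if band_frames else pd.DataFrame())

    # --- repeatability ----------------------------------------------------
    profile_frames = []
    for direction in ("south", "north"):
        for kind in ("entry_date", "lon_deviation"):
            if band_obs.empty:
                continue
            prof = band_repeatability_profile(
                band_obs, kind=kind, direction=direction,
                min_ind=cfg.min_ind_per_band, n_boot=cfg.n_boot,
                seed=int(rng.integers(2 ** 31)))
            profile_frames.append(prof)
    profile_frames = [f for f in profile_frames if len(f)]
    band_profiles = (pd.concat(profile_frames, ignore_index=True)
                     if profile_frames else pd.DataFrame())

    event_frames = []
    for bird in filtered:
        iv = intervals[intervals["bird_id"] == bird]
        event_frames.append(extract_events(iv, clusters[bird]))
    event_frames = [f for f in event_frames if len(f)]
    events = (pd.concat(event_frames, ignore_index=True)
              if event_frames else pd.DataFrame(columns=["bird_id", "cycle_year",
                                                         "variable", "value"]))
    event_rpt = event_repeatability(events, n_boot=cfg.n_boot,
                                    seed=int(rng.integers(2 ** 31)))

    # --- stage models -----------------------------------------------------
    model_overlap = model_distance = None
    if len(overlaps) and overlaps["stage"].nunique() >= 2:
        from .stage_models import fit_gaussian_mixed, fit_zib_mixed
        try:
            model_overlap = fit_zib_mixed(overlaps)
        except Exception as exc:            # non-convergence is reported, not fatal
            log.warning("overlap model failed: %s", exc)
        try:
            model_distance = fit_gaussian_mixed(overlaps)
        except Exception as exc:
            log.warning("distance model failed: %s", exc)

    stage_summary = _stage_summary(clusters, home_ranges)
    return PipelineResult(
        config=cfg, fixes=fixes, truth=truth, filtered=filtered,
        removed_fraction=removed_fraction, clusters=clusters,
        intervals=intervals, home_ranges=home_ranges, overlaps=overlaps,
        band_obs=band_obs, mean_routes=mean_routes, band_profiles=band_profiles,
        events=events, event_rpt=event_rpt, model_overlap=model_overlap,
        model_distance=model_distance, stage_summary=stage_summary,
        dropped={"home_range_too_small": skipped_hr})


def _stage_summary(clusters: dict, home_ranges: dict) -> pd.DataFrame:
    """Per-stage residency metrics: counts, areas per bird-year, fix counts
    and median home-range size."""
    rows = []
    for stage in ("breeding", "south_migration", "wintering", "north_migration"):
        birds = set()
        n_areas = 0
        fix_counts = []
        per_bird_year: dict[tuple, int] = {}
        hr_total_by_bird_year: dict[tuple, float] = {}
        for bird, cl in clusters.items():
            for c in cl:
                if c.stage != stage:
                    continue
                birds.add(bird)
                n_areas += 1
                fix_counts.append(c.n_fixes)
                key = (bird, _cluster_cycle_year(c))
                per_bird_year[key] = per_bird_year.get(key, 0) + 1
        for bird, hrs in home_ranges.items():
            for hr in hrs:
                if hr.cluster.stage != stage:
                    continue
                key = (bird, _cluster_cycle_year(hr.cluster))
                hr_total_by_bird_year[key] = hr_total_by_bird_year.get(key, 0.0) + hr.area_km2
        rows.append({
            "stage": stage,
            "n_individuals": len(birds),
            "n_residency_areas": n_areas,
            "mean_areas_per_bird_year": (np.mean(list(per_bird_year.values()))
                                         if per_bird_year else np.nan),
            "mean_fixes_per_area": np.mean(fix_counts) if fix_counts else np.nan,
            "median_home_range_km2": (np.median(list(hr_total_by_bird_year.values()))
                                      if hr_total_by_bird_year else np.nan),
        })
    return pd.DataFrame(rows)


def write_artifacts(result: PipelineResult, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.fixes.to_csv(out / "fixes.csv", index=False)
    pd.concat(result.filtered.values()).to_csv(out / "fixes_filtered.csv", index=False)
    all_clusters = [c for cl in result.clusters.values() for c in cl]
    clusters_to_frame(all_clusters).to_csv(out / "clusters.csv", index=False)
    result.intervals.to_csv(out / "stage_intervals.csv", index=False)
    result.overlaps.to_csv(out / "overlap_records.csv", index=False)
    result.band_obs.to_csv(out / "band_observations.csv", index=False)
    result.band_profiles.to_csv(out / "band_repeatability.csv", index=False)
    result.events.to_csv(out / "events.csv", index=False)
    result.event_rpt.to_csv(out / "event_repeatability.csv", index=False)
    result.stage_summary.to_csv(out / "stage_summary.csv", index=False)
    if result.model_overlap is not None:
        result.model_overlap.coef.to_csv(out / "model_overlap_zib.csv", index=False)
    if result.model_distance is not None:
        result.model_distance.coef.to_csv(out / "model_distance_gaussian.csv", index=False)

    feats = []
    for bird, hrs in result.home_ranges.items():
        for hr in hrs:
            feats.append(geojson_io.feature(
                hr.contour_lonlat,
                {"bird_id": bird, "stage": hr.cluster.stage,
                 "area_km2": hr.area_km2, "contour_mass": hr.contour_mass}))
    geojson_io.write_collection(feats, out / "home_ranges.geojson")
    routes = [geojson_io.linestring_feature(mr.points, {"direction": d,
                                                        "objective_km": mr.objective_km})
              for d, mr in result.mean_routes.items()]
    geojson_io.write_collection(routes, out / "mean_routes.geojson")
    _write_report(result, out / "report.txt")


def _write_report(result: PipelineResult, path) -> None:
    lines = ["trackfidelity pipeline report", "=" * 32, ""]
    lines.append(f"fixes in: {len(result.fixes)}; speed-filter removed fraction: "
                 f"{result.removed_fraction:.3f}")
    lines.append(f"residency clusters (tenure > {result.config.min_tenure_d} d): "
                 f"{sum(len(c) for c in result.clusters.values())}")
    lines += ["", "Per-stage residency summary:",
              result.stage_summary.to_string(index=False)]
    if len(result.overlaps):
        inc = result.overlaps.groupby("stage")["any_overlap"].mean()
        lines += ["", "Between-year overlap incidence by stage:", inc.to_string()]
    if len(result.event_rpt):
        lines += ["", "Event-timing repeatability:",
                  result.event_rpt.to_string(index=False)]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
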