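"""Synthetic Argos-like multi-year shorebird tracks with known ground truth.

The generator emulates the annual cycle of an Arctic-breeding, neotropical-
wintering shorebird population: each bird owns one wintering site reused
every year (small jitter — strong wintering fidelity), draws a fresh
breeding site each year from a dispersal kernel (exploratory breeding), and
travels between them with a prolonged southbound moult-staging stopover in
the temperate latitudes and brief northbound stops.  Event timing combines
a population mean, a per-bird random intercept (between-individual sd) and
annual noise (within-individual sd), so the true timing repeatability
R_true = sigma2_between / (sigma2_between + sigma2_within) of each anchored
event is known by construction.  Positions are reported on a regular duty
cycle with isotropic Gaussian Argos error whose scale depends on an i.i.d.
location class per fix.

Every fix is attributable to one true behavioural segment (residency at a
named site, or flight), recorded in ``SimTruth.fix_labels`` together with
the noise-free coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from . import geo
from .io_filtering import FIX_COLUMNS

DAY_H = 24.0

# population mean day-of-year of anchored events (cycle-year calendar;
# wintering departure belongs to the following calendar year, hence +365)
EVENT_MEAN_DOY = {
    "breeding_arrival_y0": 152.0,     # ~1 June (first tracked season only)
    "breeding_departure": 198.0,      # ~17 July
    "wintering_arrival": 289.0,       # ~16 October
    "wintering_departure": 485.0,     # ~30 April of the next year
}

# per-event (between, within) multipliers applied to the base timing sigmas;
# chosen so that, as in the tracked population, arrival at the wintering
# site is the most repeatable event while breeding-season timing is noisy
DEFAULT_EVENT_MULTIPLIERS = {
    "breeding_departure": (0.65, 1.5),
    "wintering_arrival": (1.75, 0.85),
    "wintering_departure": (1.0, 1.33),
}

DEFAULT_CLASS_PROBS = {"3": 0.08, "2": 0.12, "1": 0.14, "0": 0.19, "A": 0.22, "B": 0.25}
DEFAULT_CLASS_ERROR_SD_M = {"3": 100.0, "2": 300.0, "1": 600.0,
                            "0": 1000.0, "A": 1200.0, "B": 1500.0}


@dataclass
class SimConfig:
    """Study conditions for the synthetic population.

    Defaults mirror the tracked dowitcher population: ~20 birds followed for
    up to several annual cycles, breeding dispersal with a mean consecutive-
    year displacement near 160 km, near-perfect wintering-site reuse, a long
    southbound staging stop (arriving at the wintering grounds in October),
    and Argos location classes with errors of roughly 0.1-1.5 km.
    """
    n_birds: int = 20
    n_years: int = 3
    seed: int = 0
    start_year: int = 2019
    breeding_lon: tuple[float, float] = (-165.0, -145.0)
    breeding_lat: tuple[float, float] = (64.0, 71.0)
    wintering_lon: tuple[float, float] = (-115.0, -92.0)
    wintering_lat: tuple[float, float] = (16.0, 30.0)
    breeding_dispersal_sd_km: float = 125.0
    wintering_dispersal_sd_km: float = 2.0
    n_stopovers_mean: float = 1.5
    n_breeding_sites_mean: float = 2.0
    flight_speed_kmh: float = 65.0
    fix_interval_h: float = 6.0
    residency_scatter_m: float = 1000.0
    timing_sigma_between_d: float = 8.0
    timing_sigma_within_d: float = 6.0
    event_timing_multipliers: dict = field(
        default_factory=lambda: dict(DEFAULT_EVENT_MULTIPLIERS))
    staging_lat_mean: float = 45.0
    staging_lat_between_sd: float = 5.0
    staging_lat_within_sd: float = 3.0
    argos_class_probs: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    argos_error_sd_m: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_ERROR_SD_M))
    fix_dropout: float = 0.0

    def __post_init__(self):
        total = sum(self.argos_class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"argos_class_probs must sum to 1 (got {total})")
        if any(v < 0 for v in self.argos_error_sd_m.values()):
            raise ValueError("argos_error_sd_m entries must be >= 0")
        for name in ("breeding_dispersal_sd_km", "wintering_dispersal_sd_km",
                     "timing_sigma_between_d", "timing_sigma_within_d",
                     "residency_scatter_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_birds < 2 or self.n_years < 2:
            raise ValueError("need n_birds >= 2 and n_years >= 2")
        if self.breeding_lat[0] <= self.wintering_lat[1]:
            raise ValueError("breeding range must lie north of the wintering range")

    def event_sigmas(self, event: str) -> tuple[float, float]:
        mb, mw = self.event_timing_multipliers.get(event, (1.0, 1.0))
        return self.timing_sigma_between_d * mb, self.timing_sigma_within_d * mw

    def r_true(self, event: str) -> float:
        sb, sw = self.event_sigmas(event)
        tot = sb ** 2 + sw ** 2
        return sb ** 2 / tot if tot > 0 else 0.0


@dataclass
class SimTruth:
    wintering_sites: pd.DataFrame     # bird_id, lon, lat
    breeding_sites: pd.DataFrame      # bird_id, cycle_year, lon, lat
    stopover_sites: pd.DataFrame      # bird_id, cycle_year, direction, lon, lat
    timing_intercepts: pd.DataFrame   # bird_id, event, intercept_d
    events: pd.DataFrame              # bird_id, cycle_year, variable, value (days)
    fix_labels: pd.DataFrame          # bird_id, timestamp, segment, site, cycle_year, true_lon, true_lat
    r_true: dict                      # event -> configured R


def generate_range_polygons(cfg: SimConfig) -> tuple[Polygon, Polygon]:
    """Breeding and wintering range rectangles (disjoint, breeding northmost)."""
    b = Polygon([(cfg.breeding_lon[0], cfg.breeding_lat[0]),
                 (cfg.breeding_lon[1], cfg.breeding_lat[0]),
                 (cfg.breeding_lon[1], cfg.breeding_lat[1]),
                 (cfg.breeding_lon[0], cfg.breeding_lat[1])])
    w = Polygon([(cfg.wintering_lon[0], cfg.wintering_lat[0]),
                 (cfg.wintering_lon[1], cfg.wintering_lat[0]),
                 (cfg.wintering_lon[1], cfg.wintering_lat[1]),
                 (cfg.wintering_lon[0], cfg.wintering_lat[1])])
    return b, w


def _point_in_box(rng, lon_rng, lat_rng, margin=0.5):
    return (rng.uniform(lon_rng[0] + margin, lon_rng[1] - margin),
            rng.uniform(lat_rng[0] + margin, lat_rng[1] - margin))


def _jitter_km(rng, lon, lat, sd_km):
    dx, dy = rng.normal(0.0, sd_km * 1000.0, 2)
    return geo.offset_m(lon, lat, dx, dy)


def _clip_to_box(lon, lat, lon_rng, lat_rng, margin=0.1):
    return (float(np.clip(lon, lon_rng[0] + margin, lon_rng[1] - margin)),
            float(np.clip(lat, lat_rng[0] + margin, lat_rng[1] - margin)))


def _flight_days(cfg: SimConfig, a, b) -> float:
    d_km = float(geo.geodesic_km(a[0], a[1], b[0], b[1]))
    return d_km / cfg.flight_speed_kmh / DAY_H


def _route_point_at_lat(a, b, lat_target: float) -> tuple[float, float]:
    """Point near the great circle a->b at the requested latitude."""
    frac = np.linspace(0.0, 1.0, 201)
    lons, lats = geo.gc_interpolate(a[0], a[1], b[0], b[1], frac)
    k = int(np.argmin(np.abs(lats - lat_target)))
    return float(lons[k]), float(lats[k])


def generate_population(cfg: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate the population; returns (fix table, ground truth).

    Deterministic given ``cfg.seed``; fixes are time-ordered per bird.
    """
    rng = np.random.default_rng(cfg.seed)
    breeding_poly, wintering_poly = generate_range_polygons(cfg)

    winter_rows, breed_rows, stop_rows, icept_rows, event_rows = [], [], [], [], []
    fix_frames = []

    anchored = ["breeding_departure", "wintering_arrival", "wintering_departure"]
    for b in range(cfg.n_birds):
        bird = f"bird{b:03d}"
        w_site = _point_in_box(rng, cfg.wintering_lon, cfg.wintering_lat)
        winter_rows.append({"bird_id": bird, "lon": w_site[0], "lat": w_site[1]})

        icepts = {ev: rng.normal(0.0, cfg.event_sigmas(ev)[0]) for ev in anchored}
        for ev, v in icepts.items():
            icept_rows.append({"bird_id": bird, "event": ev, "intercept_d": v})
        stag_lat_i = rng.normal(cfg.staging_lat_mean, cfg.staging_lat_between_sd)
        stag_lon_off_i = rng.normal(0.0, 1.5)

        # yearly breeding sites: fresh draw each year from the dispersal kernel
        b_sites = []
        site = _point_in_box(rng, cfg.breeding_lon, cfg.breeding_lat, margin=2.0)
        for y in range(cfg.n_years):
            if y > 0:
                site = _jitter_km(rng, site[0], site[1], cfg.breeding_dispersal_sd_km)
                site = _clip_to_box(site[0], site[1], cfg.breeding_lon, cfg.breeding_lat)
            b_sites.append(site)
            breed_rows.append({"bird_id": bird, "cycle_year": cfg.start_year + y,
                               "lon": site[0], "lat": site[1]})

        segments = []  # (site_kind, site_name, lon, lat, t_arr, t_dep) in abs days
        prev_arr_breed = None
        for y in range(cfg.n_years):
            year = cfg.start_year + y
            t0 = (pd.Timestamp(f"{year}-01-01", tz="UTC")
                  - pd.Timestamp(f"{cfg.start_year}-01-01", tz="UTC")).days

            def draw(ev):
                sb, sw = cfg.event_sigmas(ev)
                return EVENT_MEAN_DOY[ev] + icepts[ev] + rng.normal(0.0, sw)

            if prev_arr_breed is None:
                arr_breed = t0 + (EVENT_MEAN_DOY["breeding_arrival_y0"]
                                  + rng.normal(0.0, 3.0) + rng.normal(0.0, 3.0))
            else:
                arr_breed = prev_arr_breed
            dep_breed = t0 + draw("breeding_departure")
            dep_breed = max(dep_breed, arr_breed + 12.0)
            arr_winter = t0 + draw("wintering_arrival")
            dep_winter = t0 + draw("wintering_departure")
            dep_winter = max(dep_winter, arr_winter + 45.0)

            # breeding-season residency: primary site plus exploratory visits
            n_extra = int(rng.poisson(max(cfg.n_breeding_sites_mean - 1.0, 0.0)))
            season = dep_breed - arr_breed
            t_cursor = arr_breed
            primary_share = 0.6 if n_extra else 1.0
            visit_sites = [b_sites[y]]
            for _ in range(n_extra):
                ex = _jitter_km(rng, b_sites[y][0], b_sites[y][1], 50.0)
                visit_sites.append(_clip_to_box(ex[0], ex[1], cfg.breeding_lon, cfg.breeding_lat))
            durations = [season * primary_share]
            if n_extra:
                rest = season * (1.0 - primary_share)
                parts = rng.dirichlet(np.ones(n_extra)) * rest
                durations += list(parts)
            for k, (s, dur) in enumerate(zip(visit_sites, durations)):
                kind = "breeding_primary" if k == 0 else "breeding_extra"
                hop = 0.0 if k == 0 else _flight_days(cfg, visit_sites[k - 1], s)
                t_arr = t_cursor + hop
                t_dep = max(t_arr + 0.5, t_arr + dur - hop)
                segments.append((kind, f"breed_{year}_{k}", s[0], s[1], t_arr, t_dep))
                t_cursor = t_dep

            # southbound: main moult-staging stop, optional brief extra stops
            w_jit = _jitter_km(rng, w_site[0], w_site[1], cfg.wintering_dispersal_sd_km)
            stag_lat = float(np.clip(stag_lat_i + rng.normal(0.0, cfg.staging_lat_within_sd),
                                     33.0, 58.0))
            stag = _route_point_at_lat(b_sites[y], w_jit, stag_lat)
            stag = (stag[0] + stag_lon_off_i + rng.normal(0.0, 1.0), stag[1])
            n_extra_s = int(rng.poisson(max(cfg.n_stopovers_mean - 1.0, 0.0)))
            extra_stops = []
            lat_lo, lat_hi = cfg.wintering_lat[1] + 2.0, stag_lat - 3.0
            if lat_hi <= lat_lo:
                n_extra_s = 0
            for k in range(n_extra_s):
                lat_k = rng.uniform(lat_lo, lat_hi)
                p = _route_point_at_lat(stag, w_jit, lat_k)
                extra_stops.append((p[0] + rng.normal(0.0, 1.0), p[1]))
            extra_stops.sort(key=lambda p: -p[1])

            dep_last_breed = segments[-1][5]
            t_arr_stag = dep_last_breed + _flight_days(cfg, visit_sites[-1], stag)
            chain = [stag] + extra_stops + [w_jit]
            travel_rest = sum(_flight_days(cfg, chain[k], chain[k + 1])
                              for k in range(len(chain) - 1))
            dwell_extra = 3.0 * len(extra_stops)
            t_dep_stag = arr_winter - travel_rest - dwell_extra
            if t_dep_stag < t_arr_stag + 1.0:
                extra_stops, dwell_extra = [], 0.0
                chain = [stag, w_jit]
                travel_rest = _flight_days(cfg, stag, w_jit)
                t_dep_stag = arr_winter - travel_rest
                if t_dep_stag < t_arr_stag + 1.0:
                    t_dep_stag = t_arr_stag + 1.0
                    arr_winter = t_dep_stag + travel_rest
                    dep_winter = max(dep_winter, arr_winter + 45.0)
            segments.append(("staging_south", f"stag_{year}", stag[0], stag[1],
                             t_arr_stag, t_dep_stag))
            stop_rows.append({"bird_id": bird, "cycle_year": year, "direction": "south",
                              "lon": stag[0], "lat": stag[1]})
            t_cursor = t_dep_stag
            prev = stag
            for p in extra_stops:
                t_arr_p = t_cursor + _flight_days(cfg, prev, p)
                t_dep_p = t_arr_p + 3.0
                segments.append(("stop_south", f"sstop_{year}", p[0], p[1], t_arr_p, t_dep_p))
                stop_rows.append({"bird_id": bird, "cycle_year": year,
                                  "direction": "south", "lon": p[0], "lat": p[1]})
                t_cursor, prev = t_dep_p, p
            t_arr_w = t_cursor + _flight_days(cfg, prev, w_jit)
            segments.append(("wintering", f"winter_{year}", w_jit[0], w_jit[1],
                             t_arr_w, dep_winter))

            event_rows += [
                {"bird_id": bird, "cycle_year": year, "variable": "breeding_arrival",
                 "value": arr_breed - t0},
                {"bird_id": bird, "cycle_year": year, "variable": "breeding_departure",
                 "value": dep_breed - t0},
                {"bird_id": bird, "cycle_year": year, "variable": "stopover_south_start",
                 "value": t_arr_stag - t0},
                {"bird_id": bird, "cycle_year": year, "variable": "stopover_south_end",
                 "value": t_dep_stag + dwell_extra - t0},
                {"bird_id": bird, "cycle_year": year, "variable": "stopover_south_duration",
                 "value": (t_dep_stag - t_arr_stag) + dwell_extra},
                {"bird_id": bird, "cycle_year": year, "variable": "wintering_arrival",
                 "value": t_arr_w - t0},
                {"bird_id": bird, "cycle_year": year, "variable": "wintering_departure",
                 "value": dep_winter - t0},
            ]

            # northbound to next breeding site
            if y + 1 < cfg.n_years:
                nxt = b_sites[y + 1]
                use_stop = rng.random() < 0.8
                t_cursor = dep_winter
                prev = w_jit
                if use_stop:
                    lat_n = rng.uniform(38.0, 55.0)
                    p = _route_point_at_lat(w_jit, nxt, lat_n)
                    p = (p[0] + rng.normal(0.0, 1.0), p[1])
                    t_arr_p = t_cursor + _flight_days(cfg, prev, p)
                    dwell = max(0.5, rng.normal(9.0, 3.0))
                    segments.append(("stop_north", f"nstop_{year + 1}", p[0], p[1],
                                     t_arr_p, t_arr_p + dwell))
                    stop_rows.append({"bird_id": bird, "cycle_year": year + 1,
                                      "direction": "north", "lon": p[0], "lat": p[1]})
                    t_cursor, prev = t_arr_p + dwell, p
                prev_arr_breed = t_cursor + _flight_days(cfg, prev, nxt)

        fix_frames.append(_sample_fixes(cfg, rng, bird, segments))

    fixes_all = pd.concat(fix_frames, ignore_index=True)
    truth = SimTruth(
        wintering_sites=pd.DataFrame(winter_rows),
        breeding_sites=pd.DataFrame(breed_rows),
        stopover_sites=pd.DataFrame(stop_rows),
        timing_intercepts=pd.DataFrame(icept_rows),
        events=pd.DataFrame(event_rows),
        fix_labels=fixes_all[["bird_id", "timestamp", "segment", "site",
                              "cycle_year", "true_lon", "true_lat"]].copy(),
        r_true={ev: cfg.r_true(ev) for ev in anchored},
    )
    fixes = fixes_all[FIX_COLUMNS].copy()
    return fixes, truth


def _sample_fixes(cfg: SimConfig, rng, bird: str, segments) -> pd.DataFrame:
    """Sample the duty-cycled fix series for one bird from its itinerary."""
    t_start = segments[0][4]
    t_end = segments[-1][5]
    times = np.arange(t_start, t_end, cfg.fix_interval_h / DAY_H)

    seg_arr = np.array([[s[4], s[5]] for s in segments])
    lons = np.empty(len(times))
    lats = np.empty(len(times))
    seg_label = np.empty(len(times), dtype=object)
    site_label = np.empty(len(times), dtype=object)

    for i, t in enumerate(times):
        k = np.searchsorted(seg_arr[:, 0], t, side="right") - 1
        if k >= 0 and t <= seg_arr[k, 1]:
            kind, name, slon, slat, _, _ = segments[k]
            dx, dy = rng.normal(0.0, cfg.residency_scatter_m, 2)
            lon, lat = geo.offset_m(slon, slat, dx, dy)
            lons[i], lats[i] = lon, lat
            seg_label[i] = "residency"
            site_label[i] = name
        else:  # in flight between segment k and k+1
            a, bseg = segments[k], segments[k + 1]
            frac = (t - a[5]) / max(bseg[4] - a[5], 1e-9)
            lon, lat = geo.gc_interpolate(a[2], a[3], bseg[2], bseg[3],
                                          np.array([np.clip(frac, 0.0, 1.0)]))
            lons[i], lats[i] = float(lon[0]), float(lat[0])
            seg_label[i] = "flight"
            site_label[i] = ""

    classes = np.array(list(cfg.argos_class_probs.keys()))
    probs = np.array(list(cfg.argos_class_probs.values()))
    lc = rng.choice(classes, size=len(times), p=probs)
    err_sd = np.array([cfg.argos_error_sd_m[c] for c in lc])
    ex = rng.normal(0.0, 1.0, len(times)) * err_sd
    ey = rng.normal(0.0, 1.0, len(times)) * err_sd
    obs_lon, obs_lat = geo.offset_m(lons, lats, ex, ey)

    base = pd.Timestamp(f"{cfg.start_year}-01-01", tz="UTC")
    ts = base + pd.to_timedelta(np.round(times * 86400.0), unit="s")
    year = np.array([_cycle_year(cfg, t) for t in times])
    df = pd.DataFrame({
        "bird_id": bird, "timestamp": ts, "lon": obs_lon, "lat": obs_lat,
        "lc": lc, "error_radius_m": err_sd * 1.5,
        "segment": seg_label, "site": site_label, "cycle_year": year,
        "true_lon": lons, "true_lat": lats,
    })
    if cfg.fix_dropout > 0:
        df = df[rng.random(len(df)) >= cfg.fix_dropout].reset_index(drop=True)
    return df


def _cycle_year(cfg: SimConfig, t_days: float) -> int:
    """Calendar year containing day offset t, shifted so that the wintering
    season (through ~30 April) still belongs to the preceding cycle."""
    date = pd.Timestamp(f"{cfg.start_year}-01-01") + pd.Timedelta(days=float(t_days))
    y = date.year
    if date.dayofyear < 135:  # before mid-May: part of the previous cycle
        y -= 1
    return int(max(y, cfg.start_year))


def write_truth(truth: SimTruth, outdir) -> None:
    from pathlib import Path
    import json
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.wintering_sites.to_csv(outdir / "truth_wintering_sites.csv", index=False)
    truth.breeding_sites.to_csv(outdir / "truth_breeding_sites.csv", index=False)
    truth.stopover_sites.to_csv(outdir / "truth_stopover_sites.csv", index=False)
    truth.events.to_csv(outdir / "truth_events.csv", index=False)
    truth.fix_labels.to_csv(outdir / "truth_fix_labels.csv", index=False)
    with open(outdir / "truth_r_true.json", "w") as fh:
        json.dump(truth.r_true, fh, indent=2)
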