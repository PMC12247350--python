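"""Migration-route construction and per-latitude-band statistics.

Pipeline order: residency fixes are collapsed onto their cluster centres,
each migration is interpolated onto a regular 15-minute grid with a
correlated-random-walk Kalman smoother (class-dependent Argos observation
error; a piecewise great-circle mode is available as a fallback), the
population mean route is distilled to 500 points spanning the corridor, and
two per-1°-latitudinal-band observations are extracted per bird-year: the
date of first entry into the band and the signed east-west deviation from
the mean route (west negative, east positive).

Interpolated positions are only *valid* — and only valid positions enter
band statistics — when at least two observed fixes fall inside the
surrounding 24-hour window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import geo
from .clustering import ResidencyCluster, cluster_center
from .io_filtering import ts_datetime64, ts_seconds

BAND_LOW = 8      # southernmost band edge, °N
BAND_HIGH = 73    # exclusive northern limit
ARC_RADIUS_KM = 6371.0088

DEFAULT_OBS_SD_M = {"3": 250.0, "2": 500.0, "1": 1000.0,
                    "0": 2000.0, "A": 3000.0, "B": 5000.0}


def collapse_to_centers(track: pd.DataFrame,
                        clusters: list[ResidencyCluster]) -> pd.DataFrame:
    """Replace each clustered fix's coordinates by its cluster centre
    (timestamps untouched; noise fixes pass through unchanged)."""
    out = track.copy()
    ts = ts_seconds(out["timestamp"])
    for c in clusters:
        if c.center is None:
            c.center = cluster_center(c)
        m = np.isin(ts, ts_seconds(c.members["timestamp"]))
        out.loc[m, "lon"] = c.center[0]
        out.loc[m, "lat"] = c.center[1]
    return out


@dataclass
class InterpolatedTrack:
    bird_id: str
    cycle_year: int | None
    direction: str | None
    positions: pd.DataFrame    # timestamp, lon, lat, valid

    @property
    def valid(self) -> pd.DataFrame:
        return self.positions[self.positions["valid"]]


def _validity(grid: np.ndarray, obs_times: np.ndarray,
              window_h: float = 24.0) -> np.ndarray:
    half = np.timedelta64(int(window_h * 1800), "s")  # window/2 in seconds
    lo = np.searchsorted(obs_times, grid - half, side="left")
    hi = np.searchsorted(obs_times, grid + half, side="right")
    return (hi - lo) >= 2


def _kalman_smooth(t_s: np.ndarray, xy_obs: np.ndarray, obs_var: np.ndarray,
                   is_obs: np.ndarray, q: float) -> np.ndarray:
    """RTS-smoothed positions of a correlated-random-walk (constant-velocity
    with white-noise acceleration of spectral density ``q``, m^2/s^3).

    ``t_s``: merged time grid (seconds); observations where ``is_obs``.
    The two coordinates are independent, so a 2-state filter runs per axis.
    """
    n = len(t_s)
    out = np.empty((n, 2))
    for axis in range(2):
        m = np.zeros((n, 2))
        P = np.zeros((n, 2, 2))
        mp = np.zeros((n, 2))
        Pp = np.zeros((n, 2, 2))
        x = np.array([xy_obs[np.argmax(is_obs), axis], 0.0])
        C = np.diag([1e10, 1e4])
        for i in range(n):
            if i > 0:
                dt = t_s[i] - t_s[i - 1]
                F = np.array([[1.0, dt], [0.0, 1.0]])
                Q = q * np.array([[dt ** 3 / 3.0, dt ** 2 / 2.0],
                                  [dt ** 2 / 2.0, dt]])
                x = F @ x
                C = F @ C @ F.T + Q
            mp[i], Pp[i] = x, C
            if is_obs[i]:
                r = max(obs_var[i], 1.0)
                S = C[0, 0] + r
                K = C[:, 0] / S
                x = x + K * (xy_obs[i, axis] - x[0])
                C = C - np.outer(K, C[0, :])
            m[i], P[i] = x, C
        # RTS backward pass
        xs, Cs = m[-1].copy(), P[-1].copy()
        out[-1, axis] = xs[0]
        for i in range(n - 2, -1, -1):
            dt = t_s[i + 1] - t_s[i]
            F = np.array([[1.0, dt], [0.0, 1.0]])
            G = P[i] @ F.T @ np.linalg.inv(Pp[i + 1])
            xs = m[i] + G @ (xs - mp[i + 1])
            Cs = P[i] + G @ (Cs - Pp[i + 1]) @ G.T
            out[i, axis] = xs[0]
    return out


def interpolate_track(track: pd.DataFrame, dt_min: float = 15.0,
                      mode: str = "kalman",
                      obs_sd_by_class: dict | None = None,
                      process_q: float = 1e-3,
                      bird_id: str | None = None,
                      cycle_year: int | None = None,
                      direction: str | None = None) -> InterpolatedTrack | None:
    """Regular-grid positions every ``dt_min`` minutes across a track.

    ``mode="kalman"`` (default) smooths through Argos noise with class-
    dependent observation error; ``mode="linear"`` interpolates piecewise
    along great circles through the fixes (useful when fixes are already
    noise-free, e.g. collapsed cluster centres).  Returns None for tracks
    with fewer than two fixes.
    """
    if len(track) < 2:
        return None
    bird = bird_id or str(track["bird_id"].iloc[0])
    obs_t = ts_datetime64(track["timestamp"])
    step = np.timedelta64(int(dt_min * 60), "s")
    grid = np.arange(obs_t[0], obs_t[-1] + step, step)
    grid = grid[grid <= obs_t[-1]]

    lon = track["lon"].to_numpy()
    lat = track["lat"].to_numpy()
    if mode == "linear":
        pos = np.empty((len(grid), 2))
        seg = np.clip(np.searchsorted(obs_t, grid, side="right") - 1, 0, len(obs_t) - 2)
        for i, (g, k) in enumerate(zip(grid, seg)):
            span = (obs_t[k + 1] - obs_t[k]).astype(float)
            frac = (g - obs_t[k]).astype(float) / span if span > 0 else 0.0
            glon, glat = geo.gc_interpolate(lon[k], lat[k], lon[k + 1], lat[k + 1],
                                            np.array([np.clip(frac, 0.0, 1.0)]))
            pos[i] = glon[0], glat[0]
    elif mode == "kalman":
        sd_map = obs_sd_by_class or DEFAULT_OBS_SD_M
        proj = geo.LocalEqualArea(float(np.mean(lon)), float(np.mean(lat)))
        x, y = proj.forward(lon, lat)
        t_all = np.unique(np.concatenate([obs_t, grid]))
        is_obs = np.isin(t_all, obs_t)
        xy_obs = np.zeros((len(t_all), 2))
        obs_var = np.zeros(len(t_all))
        idx = np.searchsorted(t_all, obs_t)
        xy_obs[idx, 0] = x
        xy_obs[idx, 1] = y
        if "lc" in track.columns:
            sds = np.array([sd_map.get(str(c), 1000.0) for c in track["lc"]])
        else:
            sds = np.full(len(track), 1000.0)
        obs_var[idx] = sds ** 2
        sm = _kalman_smooth(t_all.astype("datetime64[s]").astype(float),
                            xy_obs, obs_var, is_obs, process_q)
        keep = np.searchsorted(t_all, grid)
        glon, glat = proj.inverse(sm[keep, 0], sm[keep, 1])
        pos = np.column_stack([glon, glat])
    else:
        raise ValueError(f"unknown interpolation mode: {mode!r}")

    positions = pd.DataFrame({
        "timestamp": pd.DatetimeIndex(grid, tz="UTC"),
        "lon": pos[:, 0], "lat": pos[:, 1],
        "valid": _validity(grid, obs_t),
    })
    return InterpolatedTrack(bird_id=bird, cycle_year=cycle_year,
                             direction=direction, positions=positions)


# ---------------------------------------------------------------- mean route

def _to_xyz(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    lam, phi = np.radians(lon), np.radians(lat)
    return np.column_stack([np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam),
                            np.sin(phi)])


def _chord_to_arc_km(chord: np.ndarray) -> np.ndarray:
    return 2.0 * ARC_RADIUS_KM * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0))


def resample_route(lon: np.ndarray, lat: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline to ``n`` points equally spaced in cumulative
    great-circle distance fraction."""
    if len(lon) == 1:
        return np.column_stack([np.repeat(lon, n), np.repeat(lat, n)])
    d = geo.geodesic_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    cum = np.concatenate([[0.0], np.cumsum(np.atleast_1d(d))])
    if cum[-1] == 0:
        return np.column_stack([np.repeat(lon[0], n), np.repeat(lat[0], n)])
    frac = cum / cum[-1]
    targets = np.linspace(0.0, 1.0, n)
    out = np.empty((n, 2))
    seg = np.clip(np.searchsorted(frac, targets, side="right") - 1, 0, len(lon) - 2)
    for i, (ft, k) in enumerate(zip(targets, seg)):
        span = frac[k + 1] - frac[k]
        f = (ft - frac[k]) / span if span > 0 else 0.0
        plon, plat = geo.gc_interpolate(lon[k], lat[k], lon[k + 1], lat[k + 1],
                                        np.array([np.clip(f, 0.0, 1.0)]))
        out[i] = plon[0], plat[0]
    return out


@dataclass
class MeanRoute:
    points: np.ndarray          # (n, 2) lon/lat
    direction: str | None
    objective_km: float
    objective_history: list


def mean_route(tracks: list[InterpolatedTrack], n: int = 500,
               direction: str | None = None, tol_km: float = 1.0,
               max_iter: int = 100) -> MeanRoute:
    """Population mean migration route.

    Initialised as the pointwise average of the tracks resampled to ``n``
    points by cumulative-distance fraction, then refined iteratively: each
    route point moves to the average of its nearest points on every track,
    and the route is re-spaced to ``n`` points.  The objective (mean over
    route points of the mean nearest-track distance) is recorded per
    iteration; iterations stop at convergence (< ``tol_km`` mean point
    displacement), on ``max_iter``, or if a step fails to decrease the
    objective (the previous route is kept).
    """
    if not tracks:
        raise ValueError("mean_route requires at least one track")
    arrs = []
    for tr in tracks:
        v = tr.valid
        if len(v) >= 2:
            arrs.append(np.column_stack([v["lon"].to_numpy(), v["lat"].to_numpy()]))
    if not arrs:
        raise ValueError("no track has enough valid positions")
    if len(arrs) == 1:
        pts = resample_route(arrs[0][:, 0], arrs[0][:, 1], n)
        return MeanRoute(points=pts, direction=direction, objective_km=0.0,
                         objective_history=[0.0])

    trees = [cKDTree(_to_xyz(a[:, 0], a[:, 1])) for a in arrs]

    route = np.mean([resample_route(a[:, 0], a[:, 1], n) for a in arrs], axis=0)

    def nearest(route_pts):
        """Per track: (chord distance, matched lon/lat) for each route point."""
        xyz = _to_xyz(route_pts[:, 0], route_pts[:, 1])
        dists, matches = [], []
        for tree, a in zip(trees, arrs):
            dd, ii = tree.query(xyz)
            dists.append(_chord_to_arc_km(dd))
            matches.append(a[ii])
        return np.array(dists), np.array(matches)   # (T, n), (T, n, 2)

    dists, matches = nearest(route)
    obj = float(dists.mean())
    history = [obj]
    for _ in range(max_iter):
        new_route = resample_route(matches[:, :, 0].mean(axis=0),
                                   matches[:, :, 1].mean(axis=0), n)
        d2, m2 = nearest(new_route)
        new_obj = float(d2.mean())
        if new_obj > obj + 1e-9:
            break
        moved = float(np.mean(geo.geodesic_km(route[:, 0], route[:, 1],
                                              new_route[:, 0], new_route[:, 1])))
        route, dists, matches, obj = new_route, d2, m2, new_obj
        history.append(obj)
        if moved < tol_km:
            break
    return MeanRoute(points=route, direction=direction, objective_km=obj,
                     objective_history=history)


# ------------------------------------------------------------- band statistics

def band_entry_dates(it: InterpolatedTrack) -> pd.DataFrame:
    """First entry date into each 1° latitudinal band (valid positions only).

    Values are fractional days since 1 January of the track's cycle year;
    re-entries after wandering are ignored (first entry wins).
    """
    v = it.valid
    if v.empty:
        return _empty_band_frame()
    lat = v["lat"].to_numpy()
    band = np.floor(lat).astype(int)
    ok = (band >= BAND_LOW) & (band < BAND_HIGH)
    t0 = pd.Timestamp(f"{it.cycle_year}-01-01", tz="UTC") if it.cycle_year else v["timestamp"].iloc[0]
    rows = []
    seen = set()
    ts = v["timestamp"].to_numpy()
    for i in np.flatnonzero(ok):
        b = int(band[i])
        if b in seen:
            continue
        seen.add(b)
        val = (pd.Timestamp(ts[i]) - t0).total_seconds() / 86400.0
        rows.append({"bird_id": it.bird_id, "cycle_year": it.cycle_year,
                     "direction": it.direction, "band_low_lat": b,
                     "kind": "entry_date", "value": val})
    return pd.DataFrame(rows, columns=_BAND_COLS)


def band_lon_deviation(it: InterpolatedTrack, mr: MeanRoute) -> pd.DataFrame:
    """Signed east-west deviation (km) of a track from the mean route,
    averaged per 1° latitudinal band over the mean-route points.

    For each mean-route point the nearest valid track point is found; the
    deviation is the geodesic east-west distance at the route point's
    latitude, negative when the track lies west of the mean route.
    """
    v = it.valid
    if v.empty:
        return _empty_band_frame()
    tlon = v["lon"].to_numpy()
    tlat = v["lat"].to_numpy()
    tree = cKDTree(_to_xyz(tlon, tlat))
    rlon, rlat = mr.points[:, 0], mr.points[:, 1]
    _, idx = tree.query(_to_xyz(rlon, rlat))
    dlon = (tlon[idx] - rlon + 180.0) % 360.0 - 180.0
    dist = np.atleast_1d(geo.geodesic_km(rlon, rlat, rlon + dlon, rlat))
    signed = np.sign(dlon) * dist
    band = np.floor(rlat).astype(int)
    rows = []
    for b in np.unique(band):
        if b < BAND_LOW or b >= BAND_HIGH:
            continue
        m = band == b
        rows.append({"bird_id": it.bird_id, "cycle_year": it.cycle_year,
                     "direction": it.direction, "band_low_lat": int(b),
                     "kind": "lon_deviation", "value": float(signed[m].mean())})
    return pd.DataFrame(rows, columns=_BAND_COLS)


_BAND_COLS = ["bird_id", "cycle_year", "direction", "band_low_lat", "kind", "value"]


def _empty_band_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=_BAND_COLS)
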