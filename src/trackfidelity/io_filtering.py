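"""Reading, writing and speed-filtering of Argos fix tables.

A *fix table* is a pandas DataFrame with columns

    bird_id, timestamp (UTC), lon, lat, lc, error_radius_m

and a *track* is a fix table restricted to a single bird, sorted by time
with strictly increasing timestamps.  Location class ``lc`` is one of
3, 2, 1, 0, A, B (stored as string).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geo

FIX_COLUMNS = ["bird_id", "timestamp", "lon", "lat", "lc", "error_radius_m"]
ARGOS_CLASSES = ["3", "2", "1", "0", "A", "B"]


def ts_seconds(series) -> np.ndarray:
    """Timestamps as float seconds since the epoch (handles tz-aware input)."""
    return pd.to_datetime(series, utc=True).astype("int64").to_numpy() / 1e9


def ts_datetime64(series) -> np.ndarray:
    """Timestamps as naive-UTC numpy datetime64[s]."""
    return ts_seconds(series).astype("int64").astype("datetime64[s]")


def as_track(df: pd.DataFrame) -> pd.DataFrame:
    """Sort by time, drop duplicate timestamps (keep first), validate coordinates."""
    if df["bird_id"].nunique() > 1:
        raise ValueError("a track must contain a single bird_id")
    out = df.sort_values("timestamp", kind="mergesort")
    out = out[~out["timestamp"].duplicated(keep="first")].reset_index(drop=True)
    bad_lat = out["lat"].abs() > 90
    bad_lon = out["lon"].abs() > 180
    if bad_lat.any() or bad_lon.any():
        raise ValueError("coordinates outside WGS84 bounds")
    return out


def split_tracks(fixes: pd.DataFrame) -> list[pd.DataFrame]:
    return [as_track(g) for _, g in fixes.groupby("bird_id", sort=True)]


def read_fixes(path) -> list[pd.DataFrame]:
    """Read a fix CSV into a list of per-bird tracks.

    Rows with unparseable coordinates or timestamps are skipped with a
    warning that reports the count.
    """
    df = pd.read_csv(path, dtype={"bird_id": str, "lc": str})
    missing = [c for c in FIX_COLUMNS if c not in df.columns and c != "error_radius_m"]
    if missing:
        raise ValueError(f"missing required columns: {', '.join(missing)}")
    if "error_radius_m" not in df.columns:
        df["error_radius_m"] = np.nan
    n0 = len(df)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, errors="coerce")
    for c in ("lon", "lat"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    ok = df["timestamp"].notna() & df["lon"].notna() & df["lat"].notna()
    ok &= df["lat"].abs().le(90) & df["lon"].abs().le(180)
    n_bad = int(n0 - ok.sum())
    if n_bad:
        warnings.warn(f"skipped {n_bad} unparseable row(s) in {path}", stacklevel=2)
    df = df.loc[ok, FIX_COLUMNS]
    if df.empty:
        return []
    return split_tracks(df)


def write_fixes(tracks, path) -> None:
    df = tracks if isinstance(tracks, pd.DataFrame) else pd.concat(tracks, ignore_index=True)
    out = df[FIX_COLUMNS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def ground_speed_kmh(track: pd.DataFrame, method: str = "ellipsoidal") -> np.ndarray:
    """Ground speed between consecutive fixes; element i is the speed on the
    segment from fix i to fix i+1 (length n-1)."""
    t = ts_seconds(track["timestamp"])
    dt_h = np.diff(t) / 3600.0
    if np.any(dt_h <= 0):
        raise ValueError("duplicate or non-increasing timestamps in track")
    lon = track["lon"].to_numpy()
    lat = track["lat"].to_numpy()
    d_km = geo.geodesic_km(lon[:-1], lat[:-1], lon[1:], lat[1:], method=method)
    return np.atleast_1d(d_km) / dt_h


def pair_speed_kmh(a, b, method: str = "ellipsoidal") -> float:
    """Speed between two fixes (rows or mappings with timestamp/lon/lat)."""
    dt_h = (pd.Timestamp(b["timestamp"]) - pd.Timestamp(a["timestamp"])).total_seconds() / 3600.0
    if dt_h <= 0:
        raise ValueError("second fix must be strictly later than the first")
    return geo.geodesic_km(a["lon"], a["lat"], b["lon"], b["lat"], method=method) / dt_h


@dataclass
class FilterResult:
    kept: pd.DataFrame
    removed: pd.DataFrame
    removed_fraction: float = field(init=False)

    def __post_init__(self):
        n = len(self.kept) + len(self.removed)
        self.removed_fraction = len(self.removed) / n if n else 0.0


def speed_filter(track: pd.DataFrame, vmax_kmh: float = 150.0,
                 method: str = "ellipsoidal") -> FilterResult:
    """Remove fixes implying ground speeds above ``vmax_kmh``.

    Greedy forward pass: starting from the first fix, each subsequent fix is
    tested against the last *kept* fix; violators are dropped and the next
    fix is re-tested against the same anchor.  The first fix is never
    removed, the result is idempotent, and all speeds between consecutive
    kept fixes are <= vmax.
    """
    n = len(track)
    if n <= 1:
        return FilterResult(track.reset_index(drop=True), track.iloc[0:0])
    t = ts_seconds(track["timestamp"])
    lon = track["lon"].to_numpy()
    lat = track["lat"].to_numpy()
    keep = [0]
    for j in range(1, n):
        i = keep[-1]
        dt_h = (t[j] - t[i]) / 3600.0
        if dt_h <= 0:
            raise ValueError("duplicate or non-increasing timestamps in track")
        d_km = float(geo.geodesic_km(lon[i], lat[i], lon[j], lat[j], method=method))
        if d_km / dt_h <= vmax_kmh:
            keep.append(j)
    keep = np.asarray(keep)
    mask = np.zeros(n, dtype=bool)
    mask[keep] = True
    return FilterResult(track.iloc[mask].reset_index(drop=True),
                        track.iloc[~mask].reset_index(drop=True))


def max_valid_subsequence(track: pd.DataFrame, vmax_kmh: float = 150.0,
                          method: str = "ellipsoidal") -> np.ndarray:
    """Indices of the largest time-ordered subset containing the first fix in
    which every consecutive pair respects the speed limit (O(n^2) dynamic
    program; reference/oracle for the greedy filter on short tracks)."""
    n = len(track)
    if n == 0:
        return np.array([], dtype=int)
    t = ts_seconds(track["timestamp"])
    lon = track["lon"].to_numpy()
    lat = track["lat"].to_numpy()
    best = np.full(n, -1, dtype=int)   # chain length ending at i (first fix anchored)
    prev = np.full(n, -1, dtype=int)
    best[0] = 1
    for j in range(1, n):
        for i in range(j):
            if best[i] < 0:
                continue
            dt_h = (t[j] - t[i]) / 3600.0
            d_km = float(geo.geodesic_km(lon[i], lat[i], lon[j], lat[j], method=method))
            if dt_h > 0 and d_km / dt_h <= vmax_kmh and best[i] + 1 > best[j]:
                best[j] = best[i] + 1
                prev[j] = i
    # earliest terminal among maxima for a deterministic oracle
    j = int(np.flatnonzero(best == best.max())[0])
    chain = []
    while j >= 0:
        chain.append(j)
        j = prev[j]
    return np.asarray(chain[::-1])
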