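"""Residency-area detection by spatio-temporal DBSCAN.

Two fixes are *neighbours* when their geodesic separation is <= ``eps_m``
AND their temporal separation is <= ``max_lag_d`` (a pairwise temporal gate
on density reachability).  A fix with at least ``min_pts`` neighbours
(itself included) is a core point; clusters are the connected components of
the core-point reachability graph, with border points attached to the first
core point, in time order, that reaches them.  The temporal gate makes a
spatial revisit after a long absence form a *new* cluster, which is what
separates, say, the same staging wetland used in two different autumns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geo
from .io_filtering import ts_seconds

DAY_S = 86400.0


@dataclass(frozen=True)
class ClusterParams:
    """DBSCAN parameters: defaults follow common practice for Argos shorebird
    tracks (3 points within 4 km, 10-day temporal gate); the coarser
    alternative (5 / 8000 m / 20 d) suits birds using larger areas."""
    min_pts: int = 3
    eps_m: float = 4000.0
    max_lag_d: float = 10.0

    def __post_init__(self):
        if self.min_pts < 2:
            raise ValueError("min_pts must be >= 2")
        if self.eps_m <= 0 or self.max_lag_d <= 0:
            raise ValueError("eps_m and max_lag_d must be positive")

    ALTERNATIVE = None  # set below


ClusterParams.ALTERNATIVE = ClusterParams(min_pts=5, eps_m=8000.0, max_lag_d=20.0)


@dataclass
class ResidencyCluster:
    cluster_id: int
    bird_id: str
    members: pd.DataFrame          # fix rows, time-ordered
    start: pd.Timestamp = field(init=False)
    end: pd.Timestamp = field(init=False)
    tenure_d: float = field(init=False)
    center: tuple[float, float] | None = None   # (lon, lat)
    stage: str | None = None

    def __post_init__(self):
        self.start = self.members["timestamp"].iloc[0]
        self.end = self.members["timestamp"].iloc[-1]
        self.tenure_d = (self.end - self.start).total_seconds() / DAY_S

    @property
    def n_fixes(self) -> int:
        return len(self.members)


def _neighbor_lists(track: pd.DataFrame, p: ClusterParams,
                    method: str = "ellipsoidal") -> list[np.ndarray]:
    """Neighbour indices per fix (pairwise eps/max_lag gate), self excluded.

    Candidates are pruned by the temporal window and a latitude window
    before the exact geodesic distance is evaluated.
    """
    t = ts_seconds(track["timestamp"])
    lon = track["lon"].to_numpy()
    lat = track["lat"].to_numpy()
    n = len(track)
    max_dlat = np.degrees(p.eps_m / 6.335e6) * 1.05  # conservative degree window
    out: list[np.ndarray] = []
    lag_s = p.max_lag_d * DAY_S
    for i in range(n):
        lo = int(np.searchsorted(t, t[i] - lag_s, side="left"))
        hi = int(np.searchsorted(t, t[i] + lag_s, side="right"))
        cand = np.arange(lo, hi)
        cand = cand[cand != i]
        cand = cand[np.abs(lat[cand] - lat[i]) <= max_dlat]
        if cand.size:
            d = geo.geodesic_m(lon[i], lat[i], lon[cand], lat[cand], method=method)
            cand = cand[np.atleast_1d(d) <= p.eps_m]
        out.append(cand)
    return out


def st_dbscan(track: pd.DataFrame, params: ClusterParams | None = None,
              method: str = "ellipsoidal") -> tuple[list[ResidencyCluster], pd.DataFrame]:
    """Cluster a single-bird track into residency areas.

    Returns the cluster list (in order of first occupancy) and the noise
    fixes.  The input track also gains a ``cluster`` column copy in each
    cluster's ``members``; expansion proceeds in time order, so the result
    is deterministic for a given track.
    """
    p = params or ClusterParams()
    n = len(track)
    if n == 0:
        return [], track
    track = track.reset_index(drop=True)
    nbrs = _neighbor_lists(track, p, method=method)
    is_core = np.array([len(nb) + 1 >= p.min_pts for nb in nbrs])
    labels = np.full(n, -1, dtype=int)

    cid = 0
    for i in range(n):                       # seeds visited in time order
        if not is_core[i] or labels[i] != -1:
            continue
        # BFS over core points; border points labelled on first reach
        labels[i] = cid
        frontier = [i]
        while frontier:
            j = frontier.pop(0)
            for k in sorted(nbrs[j]):
                if labels[k] == -1:
                    labels[k] = cid
                    if is_core[k]:
                        frontier.append(k)
        cid += 1

    clusters = []
    bird = str(track["bird_id"].iloc[0])
    for c in range(cid):
        members = track.iloc[np.flatnonzero(labels == c)].copy()
        clusters.append(ResidencyCluster(cluster_id=c, bird_id=bird, members=members))
    clusters.sort(key=lambda c: c.start)
    for new_id, c in enumerate(clusters):
        c.cluster_id = new_id
    noise = track.iloc[np.flatnonzero(labels == -1)].reset_index(drop=True)
    return clusters, noise


def cluster_center(cluster: ResidencyCluster, grid_m: float = 250.0,
                   bandwidth_m: float | None = None) -> tuple[float, float]:
    """Mode of the kernel-smoothed point intensity: the single location with
    the highest number of points per unit area.

    A Gaussian kernel density is evaluated on a grid of spacing ``grid_m``
    over the cluster bounding box in a local equal-area projection.  Ties in
    density are broken toward the cell nearest the earliest member fix
    (earlier-occupied ground wins).
    """
    m = cluster.members
    lon = m["lon"].to_numpy()
    lat = m["lat"].to_numpy()
    if len(m) == 1 or (np.ptp(lon) == 0 and np.ptp(lat) == 0):
        return float(lon[0]), float(lat[0])
    proj = geo.LocalEqualArea(float(np.mean(lon)), float(np.mean(lat)))
    x, y = proj.forward(lon, lat)
    if bandwidth_m is None:
        sd = np.sqrt(0.5 * (np.var(x) + np.var(y)))
        bandwidth_m = max(float(sd) * len(m) ** (-1.0 / 6.0), grid_m)
    # keep the evaluation grid tractable for unusually extended clusters
    span = max(np.ptp(x), np.ptp(y))
    grid_m = max(grid_m, span / 300.0)
    gx = np.arange(x.min(), x.max() + grid_m, grid_m)
    gy = np.arange(y.min(), y.max() + grid_m, grid_m)
    XX, YY = np.meshgrid(gx, gy)
    dens = np.zeros(XX.shape)
    inv2h2 = 1.0 / (2.0 * bandwidth_m ** 2)
    for xi, yi in zip(x, y):
        dens += np.exp(-((XX - xi) ** 2 + (YY - yi) ** 2) * inv2h2)
    top = dens >= dens.max() * (1.0 - 1e-12)
    ti, tj = np.nonzero(top)
    if len(ti) > 1:   # tie: nearest to the earliest fix
        d0 = (XX[ti, tj] - x[0]) ** 2 + (YY[ti, tj] - y[0]) ** 2
        k = int(np.argmin(d0))
        ti, tj = ti[k:k + 1], tj[k:k + 1]
    clon, clat = proj.inverse(XX[ti[0], tj[0]], YY[ti[0], tj[0]])
    return float(clon), float(clat)


def filter_tenure(clusters: list[ResidencyCluster],
                  min_tenure_d: float = 1.0) -> list[ResidencyCluster]:
    """Keep clusters with tenure strictly greater than ``min_tenure_d`` days."""
    return [c for c in clusters if c.tenure_d > min_tenure_d]


def clusters_to_frame(clusters: list[ResidencyCluster]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        lonc, latc = c.center if c.center is not None else (np.nan, np.nan)
        rows.append({"cluster_id": c.cluster_id, "bird_id": c.bird_id,
                     "start": c.start, "end": c.end, "tenure_d": c.tenure_d,
                     "n_fixes": c.n_fixes, "center_lon": lonc, "center_lat": latc,
                     "stage": c.stage})
    return pd.DataFrame(rows, columns=["cluster_id", "bird_id", "start", "end",
                                       "tenure_d", "n_fixes", "center_lon",
                                       "center_lat", "stage"])
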