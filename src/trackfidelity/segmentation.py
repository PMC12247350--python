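"""Annual-stage segmentation from range polygons.

Each bird-year is partitioned into four stages — breeding, southward
migration, wintering, northward migration — from the known breeding and
wintering range polygons: a range season runs from the first entry into the
polygon to the last exit before the bird commits to the next range, and the
migrations are the gaps between seasons, directed by their order.  Fixes on
a polygon boundary count as inside (closed-polygon convention).

Cycle years label the annual cycle by the calendar year of its breeding
season; the wintering season that spans 1 January keeps the cycle year of
the autumn in which it began.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .clustering import ResidencyCluster
from .io_filtering import ts_seconds

STAGES = ["breeding", "south_migration", "wintering", "north_migration"]
DAY_S = 86400.0


@dataclass
class RangePolygons:
    breeding: Polygon
    wintering: Polygon

    def __post_init__(self):
        for name in ("breeding", "wintering"):
            poly = getattr(self, name)
            if not poly.is_valid:
                raise ValueError(f"{name} polygon is invalid")
        if self.breeding.intersects(self.wintering):
            raise ValueError("breeding and wintering polygons must be disjoint")


def _range_state(track: pd.DataFrame, ranges: RangePolygons) -> np.ndarray:
    pts = shapely.points(track["lon"].to_numpy(), track["lat"].to_numpy())
    in_b = shapely.covers(ranges.breeding, pts)
    in_w = shapely.covers(ranges.wintering, pts)
    state = np.where(in_b, "B", np.where(in_w, "W", "-"))
    return state


def _blocks(state: np.ndarray) -> list[tuple[str, int, int]]:
    """Merge range visits into seasonal blocks.

    Consecutive visits to the same range with no visit to the other range in
    between belong to one season (first entry to last exit)."""
    runs = []
    i = 0
    n = len(state)
    while i < n:
        j = i
        while j + 1 < n and state[j + 1] == state[i]:
            j += 1
        if state[i] != "-":
            runs.append([state[i], i, j])
        i = j + 1
    blocks: list[list] = []
    for r in runs:
        if blocks and blocks[-1][0] == r[0]:
            blocks[-1][2] = r[2]
        else:
            blocks.append(list(r))
    return [tuple(b) for b in blocks]


def _cycle_year_of_block(kind: str, start: pd.Timestamp) -> int:
    if kind == "B":
        return start.year
    # wintering: belongs to the cycle that began the preceding summer
    return start.year if start.month >= 6 else start.year - 1


def assign_stages(track: pd.DataFrame, ranges: RangePolygons) -> pd.DataFrame:
    """Stage intervals for one track.

    Returns a DataFrame (bird_id, stage, start, end, cycle_year) whose
    intervals are ordered, non-overlapping and jointly cover every fix.
    Tracks that never enter either range yield a single migration interval
    with a warning.
    """
    bird = str(track["bird_id"].iloc[0])
    t = track["timestamp"]
    state = _range_state(track, ranges)
    blocks = _blocks(state)
    if not blocks:
        warnings.warn(f"{bird}: track never enters either range; "
                      "returning migration-only segmentation", stacklevel=2)
        return pd.DataFrame([{"bird_id": bird, "stage": "south_migration",
                              "start": t.iloc[0], "end": t.iloc[-1],
                              "cycle_year": t.iloc[0].year}])

    rows = []
    eps = pd.Timedelta(seconds=1)
    for k, (kind, i0, i1) in enumerate(blocks):
        start, end = t.iloc[i0], t.iloc[i1]
        cy = _cycle_year_of_block(kind, start)
        stage = "breeding" if kind == "B" else "wintering"
        rows.append({"bird_id": bird, "stage": stage, "start": start, "end": end,
                     "cycle_year": cy})
        if k + 1 < len(blocks):
            nkind, j0, _ = blocks[k + 1]
            mig = "south_migration" if kind == "B" else "north_migration"
            mig_cy = cy if mig == "south_migration" else cy + 1
            if t.iloc[j0] > end:
                rows.append({"bird_id": bird, "stage": mig, "start": end + eps,
                             "end": t.iloc[j0] - eps, "cycle_year": mig_cy})
    # leading / trailing partial migrations
    first_kind, i0, _ = blocks[0]
    if i0 > 0:
        mig = "north_migration" if first_kind == "B" else "south_migration"
        cy = rows[0]["cycle_year"] if mig == "north_migration" else rows[0]["cycle_year"]
        rows.insert(0, {"bird_id": bird, "stage": mig, "start": t.iloc[0],
                        "end": rows[0]["start"] - eps, "cycle_year": cy})
    last_kind, _, i1 = blocks[-1]
    if i1 < len(track) - 1:
        mig = "south_migration" if last_kind == "B" else "north_migration"
        cy = rows[-1]["cycle_year"] + (0 if mig == "south_migration" else 1)
        rows.append({"bird_id": bird, "stage": mig, "start": rows[-1]["end"] + eps,
                     "end": t.iloc[-1], "cycle_year": cy})
    return pd.DataFrame(rows)


def stage_of_fixes(track: pd.DataFrame, intervals: pd.DataFrame) -> pd.Series:
    """Stage label for every fix (each fix falls in exactly one interval)."""
    out = pd.Series(index=track.index, dtype=object)
    for _, iv in intervals.iterrows():
        m = (track["timestamp"] >= iv["start"]) & (track["timestamp"] <= iv["end"])
        out[m] = iv["stage"]
    return out


def northward_onset(track: pd.DataFrame, after: pd.Timestamp,
                    d_north_km: float = 100.0) -> pd.Timestamp | None:
    """First time the bird moves >= ``d_north_km`` poleward within <= 24 h."""
    sub = track[track["timestamp"] >= after].reset_index(drop=True)
    t = ts_seconds(sub["timestamp"])
    lat = sub["lat"].to_numpy()
    for i in range(len(sub)):
        hi = np.searchsorted(t, t[i] + 86400.0, side="right")
        if hi > i + 1:
            dnorth = (lat[i + 1:hi] - lat[i]) * 111.19
            if np.any(dnorth >= d_north_km):
                return sub["timestamp"].iloc[i]
    return None


def wintering_fallback(track: pd.DataFrame, clusters: list[ResidencyCluster],
                       window: tuple[str, str] = ("11-01", "03-01"),
                       d_north_km: float = 100.0) -> dict | None:
    """Wintering interval for a bird that never enters the wintering polygon.

    Wintering starts at the first residency cluster (tenure > 1 d) whose
    midpoint falls in the configured calendar window (default 1 Nov - 1 Mar)
    and ends at the onset of the first sustained northward displacement.
    Returns None (bird flagged) if no qualifying cluster exists.
    """
    for c in sorted(clusters, key=lambda c: c.start):
        if c.tenure_d <= 1.0:
            continue
        mid = c.start + (c.end - c.start) / 2
        m, d = mid.month, mid.day
        lo = tuple(int(x) for x in window[0].split("-"))
        hi = tuple(int(x) for x in window[1].split("-"))
        in_window = (m, d) >= lo or (m, d) < hi   # window wraps the new year
        if not in_window:
            continue
        onset = northward_onset(track, c.end, d_north_km)
        end = onset if onset is not None else track["timestamp"].iloc[-1]
        cy = _cycle_year_of_block("W", c.start)
        return {"bird_id": c.bird_id, "stage": "wintering", "start": c.start,
                "end": end, "cycle_year": cy}
    warnings.warn("no qualifying wintering residency found; bird excluded from "
                  "wintering analyses", stacklevel=2)
    return None


def _longest_cluster(cands: list[ResidencyCluster]) -> ResidencyCluster | None:
    """Longest tenure; ties broken by larger fix count, then earlier start."""
    if not cands:
        return None
    return sorted(cands, key=lambda c: (-c.tenure_d, -c.n_fixes, c.start))[0]


def migration_bounds(intervals: pd.DataFrame, clusters: list[ResidencyCluster],
                     cycle_year: int) -> dict:
    """Migration windows anchored on the longest-tenure residency clusters.

    Southward migration of cycle ``y`` runs from the last date at the
    longest-tenure breeding cluster of cycle ``y`` to the first date at the
    longest-tenure wintering cluster of cycle ``y``; northward migration of
    cycle ``y`` runs from that wintering cluster to the breeding anchor of
    cycle ``y + 1``.  Missing anchors leave the bound as None.
    """
    def anchor(stage: str, cy: int):
        cands = [c for c in clusters if c.stage == stage and
                 _cycle_year_of_block("B" if stage == "breeding" else "W", c.start) == cy]
        return _longest_cluster(cands)

    b0 = anchor("breeding", cycle_year)
    w0 = anchor("wintering", cycle_year)
    b1 = anchor("breeding", cycle_year + 1)
    south = (b0.end, w0.start) if b0 is not None and w0 is not None else None
    north = (w0.end, b1.start) if w0 is not None and b1 is not None else None
    return {"south": south, "north": north}


def extract_events(intervals: pd.DataFrame, clusters: list[ResidencyCluster]) -> pd.DataFrame:
    """Annual-event timing table from stage intervals and residency clusters.

    Values are fractional days since 1 January of the cycle year, so the
    wintering departure the following spring exceeds 365.  South-stopover
    start/end bracket the bird's staging-cluster occupancy in that cycle's
    southward migration; duration is the summed stopover tenure.
    """
    rows = []
    bird = intervals["bird_id"].iloc[0] if len(intervals) else None
    for cy, g in intervals.groupby("cycle_year"):
        t0 = pd.Timestamp(f"{cy}-01-01", tz="UTC")

        def days(ts):
            return (ts - t0).total_seconds() / DAY_S

        for stage, arr_name, dep_name in (
                ("breeding", "breeding_arrival", "breeding_departure"),
                ("wintering", "wintering_arrival", "wintering_departure")):
            sel = g[g["stage"] == stage]
            if len(sel):
                rows.append({"bird_id": bird, "cycle_year": cy,
                             "variable": arr_name, "value": days(sel["start"].iloc[0])})
                rows.append({"bird_id": bird, "cycle_year": cy,
                             "variable": dep_name, "value": days(sel["end"].iloc[-1])})
        smig = g[g["stage"] == "south_migration"]
        if len(smig):
            s0, s1 = smig["start"].iloc[0], smig["end"].iloc[-1]
            stops = [c for c in clusters
                     if c.stage == "south_migration" and c.start >= s0 and c.end <= s1]
            if stops:
                stops.sort(key=lambda c: c.start)
                rows.append({"bird_id": bird, "cycle_year": cy,
                             "variable": "stopover_south_start", "value": days(stops[0].start)})
                rows.append({"bird_id": bird, "cycle_year": cy,
                             "variable": "stopover_south_end", "value": days(stops[-1].end)})
                rows.append({"bird_id": bird, "cycle_year": cy,
                             "variable": "stopover_south_duration",
                             "value": sum(c.tenure_d for c in stops)})
    return pd.DataFrame(rows, columns=["bird_id", "cycle_year", "variable", "value"])


def label_clusters(clusters: list[ResidencyCluster], track: pd.DataFrame,
                   intervals: pd.DataFrame) -> None:
    """Attach the majority stage of member fixes to each cluster (in place)."""
    stages = stage_of_fixes(track, intervals)
    lookup = pd.Series(stages.to_numpy(), index=track["timestamp"].to_numpy())
    for c in clusters:
        lab = lookup.reindex(c.members["timestamp"].to_numpy())
        mode = lab.mode()
        c.stage = mode.iloc[0] if len(mode) else None
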