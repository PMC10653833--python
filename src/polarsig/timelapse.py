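"""Lineage tracking and division-relative cluster timing.

Cells are linked across frames by maximal mask overlap; a frame at which one
cell resolves into two successors is a completed cytokinesis and defines
t = 0 for both daughters. Cluster appearance is the first run of at least
``min_consecutive_frames`` cluster-positive frames (relative to t = 0,
negative for mid-cell clusters that appear in the mother before division);
lifetime runs from that first appearance to the last positive frame before a
permanent all-negative tail, inclusive. A track still positive at its final
frame is censored and excluded from lifetime means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clusters import CellCall, call_cell
from .errors import NoDivisionError
from .geometry import CellMesh
from .params import DetectionParams

__all__ = [
    "CellTrack",
    "TimingResult",
    "track_by_overlap",
    "completion_of_cytokinesis",
    "attach_calls",
    "appearance_offset",
    "cluster_lifetime",
    "score_daughters",
    "timing_summary",
]


@dataclass
class CellTrack:
    """One cell followed across consecutive frames."""

    track_id: int
    parent_track_id: int | None = None
    frames: list = field(default_factory=list)
    meshes: list = field(default_factory=list)
    cell_ids: list = field(default_factory=list)
    division_frame: int | None = None  # first frame at which daughters exist
    daughter_track_ids: list = field(default_factory=list)
    calls: list | None = None  # per-frame CellCall, filled by attach_calls

    def append(self, frame: int, mesh: CellMesh):
        self.frames.append(frame)
        self.meshes.append(mesh)
        self.cell_ids.append(mesh.cell_id)


@dataclass
class TimingResult:
    """Division-relative timing of one daughter's cluster."""

    track_id: int
    cell_id: str
    appearance_offset_min: float = math.nan
    lifetime_min: float = math.nan
    censored: bool = False
    no_appearance: bool = False


def track_by_overlap(meshes_by_frame) -> list[CellTrack]:
    """Greedy maximal-overlap linking of per-frame cell masks into tracks.

    Each cell in frame f+1 is assigned the frame-f track whose mask overlaps
    it most (ties: larger overlap, then smaller track id). A track with two
    successors divides: it ends, its successors become daughter tracks with
    ``parent_track_id`` set. More than two successors keep the two largest
    overlaps as daughters; zero-overlap cells start new tracks.
    """
    meshes_by_frame = [list(ms) for ms in meshes_by_frame]
    tracks: list[CellTrack] = []
    if not meshes_by_frame:
        return tracks

    def new_track(parent=None):
        t = CellTrack(track_id=len(tracks), parent_track_id=parent)
        tracks.append(t)
        return t

    active: list[CellTrack] = []
    for mesh in meshes_by_frame[0]:
        t = new_track()
        t.append(0, mesh)
        active.append(t)

    for f in range(1, len(meshes_by_frame)):
        cur = meshes_by_frame[f]
        if active:
            shape = active[0].meshes[-1].image_shape
            npix = shape[0] * shape[1]
            owner = np.full(npix, -1, dtype=np.int64)
            for t in active:
                owner[t.meshes[-1].pixel_indices()] = t.track_id
        else:
            owner = None

        assignments: dict[int, list] = {}  # parent track_id -> [(cur_idx, overlap)]
        orphans = []
        for ci, mesh in enumerate(cur):
            best_tid, best_ov = None, 0
            if owner is not None:
                ids = owner[mesh.pixel_indices()]
                ids = ids[ids >= 0]
                if ids.size:
                    counts = np.bincount(ids)
                    best_ov = int(counts.max())
                    best_tid = int(np.flatnonzero(counts == best_ov)[0])  # smallest id
            if best_tid is None:
                orphans.append(ci)
            else:
                assignments.setdefault(best_tid, []).append((ci, best_ov))

        next_active = []
        for t in active:
            succ = assignments.get(t.track_id, [])
            if len(succ) == 1:
                t.append(f, cur[succ[0][0]])
                next_active.append(t)
            elif len(succ) >= 2:
                succ.sort(key=lambda x: (-x[1], x[0]))
                t.division_frame = f
                for ci, _ in succ[:2]:
                    d = new_track(parent=t.track_id)
                    d.append(f, cur[ci])
                    t.daughter_track_ids.append(d.track_id)
                    next_active.append(d)
                for ci, _ in succ[2:]:
                    d = new_track()
                    d.append(f, cur[ci])
                    next_active.append(d)
            # len == 0: track ends
        for ci in orphans:
            d = new_track()
            d.append(f, cur[ci])
            next_active.append(d)
        active = next_active
    return tracks


def completion_of_cytokinesis(track: CellTrack) -> int:
    """First frame at which the track's mask has resolved into two daughters."""
    if track.division_frame is None:
        raise NoDivisionError(f"track {track.track_id}: no division event")
    return track.division_frame


def attach_calls(tracks, frames, params: DetectionParams) -> None:
    """Fill ``track.calls`` by running cluster detection on every track frame.

    ``frames`` are background-corrected :class:`FluorFrame` indexed by frame
    number.
    """
    for t in tracks:
        t.calls = [call_cell(mesh, frames[f], params) for f, mesh in zip(t.frames, t.meshes)]


def _first_run(presence, k: int):
    """Index of the first run of >= k consecutive True values, or None."""
    run = 0
    for i, p in enumerate(presence):
        run = run + 1 if p else 0
        if run >= k:
            return i - k + 1
    return None


def appearance_offset(track: CellTrack, params: DetectionParams, frame_interval: float,
                      t0_frame: int, presence=None) -> float | None:
    """Minutes from completion of cytokinesis to first persistent detection.

    The appearance frame is the start of the first run of at least
    ``min_consecutive_frames`` cluster-positive frames; negative offsets mean
    the cluster was already present before completion of cytokinesis. Returns
    None when no qualifying run exists.
    """
    if presence is None:
        if track.calls is None:
            raise ValueError("track has no calls; run attach_calls first")
        presence = [c.has_cluster for c in track.calls]
    i = _first_run(presence, params.min_consecutive_frames)
    if i is None:
        return None
    return (track.frames[i] - t0_frame) * frame_interval


def cluster_lifetime(track: CellTrack, params: DetectionParams, frame_interval: float,
                     presence=None):
    """(lifetime_min, censored) from first persistent appearance to permanent loss.

    Lifetime counts inclusive frames: (last positive frame − appearance frame
    + 1) × frame interval; transient dropouts shorter than the persistence
    requirement do not end a cluster (only the permanent all-negative tail
    does). A track positive at its final frame is censored (lifetime None).
    """
    if presence is None:
        if track.calls is None:
            raise ValueError("track has no calls; run attach_calls first")
        presence = [c.has_cluster for c in track.calls]
    presence = list(presence)
    i = _first_run(presence, params.min_consecutive_frames)
    if i is None:
        return None, False
    if presence[-1]:
        return None, True
    j = max(k for k, p in enumerate(presence) if p)
    return (track.frames[j] - track.frames[i] + 1) * frame_interval, False


def score_daughters(tracks, params: DetectionParams, frame_interval: float):
    """Division-relative timing for every daughter track.

    Each daughter inherits t = 0 from its parent's completion of cytokinesis.
    The scored presence sequence prepends the parent's pre-division frames —
    scored by the mid-cell flag, since pre-division appearance happens at the
    septum — to the daughter's own cluster verdicts, so negative offsets are
    measurable. Each daughter is scored independently.
    """
    by_id = {t.track_id: t for t in tracks}
    results = []
    for t in tracks:
        if t.parent_track_id is None:
            continue
        parent = by_id[t.parent_track_id]
        t0 = completion_of_cytokinesis(parent)
        if parent.calls is None or t.calls is None:
            raise ValueError("tracks have no calls; run attach_calls first")
        frames = parent.frames + t.frames
        presence = [c.midcell for c in parent.calls] + [c.has_cluster for c in t.calls]
        proxy = CellTrack(track_id=t.track_id)
        proxy.frames = frames
        res = TimingResult(track_id=t.track_id, cell_id=t.cell_ids[0])
        off = appearance_offset(proxy, params, frame_interval, t0, presence=presence)
        if off is None:
            res.no_appearance = True
        else:
            res.appearance_offset_min = off
            life, censored = cluster_lifetime(proxy, params, frame_interval, presence=presence)
            res.censored = censored
            if life is not None:
                res.lifetime_min = life
        results.append(res)
    return results


def timing_summary(results) -> pd.DataFrame:
    """Mean ± sample SD (n−1 denominator) of offsets and uncensored lifetimes.

    Censored tracks are excluded from the lifetime mean and counted
    separately; a single value gets SD 0 with n = 1 flagged by the n column.
    """
    results = list(results)

    def stats(values):
        v = np.asarray([x for x in values if not math.isnan(x)], dtype=float)
        if v.size == 0:
            return 0, math.nan, math.nan
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        return int(v.size), float(v.mean()), sd

    n_off, mean_off, sd_off = stats(r.appearance_offset_min for r in results)
    n_life, mean_life, sd_life = stats(
        r.lifetime_min for r in results if not r.censored)
    return pd.DataFrame([
        {"statistic": "appearance_offset_min", "n": n_off, "mean": mean_off, "sd": sd_off,
         "censored": 0, "no_appearance": sum(r.no_appearance for r in results)},
        {"statistic": "lifetime_min", "n": n_life, "mean": mean_life, "sd": sd_life,
         "censored": sum(r.censored for r in results),
         "no_appearance": sum(r.no_appearance for r in results)},
    ])
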