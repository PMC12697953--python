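"""Batched traversal of lineage histories.

Tracking models need per-cell temporal features — past displacement, past
area growth — for every cell in a frame at once.  Rather than chasing parent
pointers cell by cell, the forest is converted to a frame-indexed layout of
flat arrays with a parent-pointer array per frame; ancestor queries then run
as one vectorized gather per ancestor level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .datamodel import Detection, LineageForest, build_forest

ROOT = -1  # parent-pointer sentinel


@dataclass
class FrameArrays:
    """Column arrays for one processed frame, sorted by detection id."""

    ids: np.ndarray          # int64
    x: np.ndarray            # float64
    y: np.ndarray
    area: np.ndarray
    orientation: np.ndarray
    parent_index: np.ndarray  # index into the previous frame's arrays, -1 for roots


@dataclass
class FrameIndexedForest:
    frames: List[FrameArrays]

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def to_indexed(forest: LineageForest) -> FrameIndexedForest:
    """Convert a lineage forest into per-frame column arrays."""
    n_frames = forest.max_frame + 1
    frames: List[FrameArrays] = []
    prev_index: Dict[int, int] = {}
    for t in range(n_frames):
        dets = forest.frame_detections(t)
        ids = np.array([d.id for d in dets], dtype=np.int64)
        parent_index = np.full(len(dets), ROOT, dtype=np.int64)
        for i, d in enumerate(dets):
            p = forest.parent_of(d.id)
            if p is not None:
                parent_index[i] = prev_index[p]
        frames.append(
            FrameArrays(
                ids=ids,
                x=np.array([d.x for d in dets]),
                y=np.array([d.y for d in dets]),
                area=np.array([d.area for d in dets]),
                orientation=np.array([d.orientation for d in dets]),
                parent_index=parent_index,
            )
        )
        prev_index = {int(i): k for k, i in enumerate(ids)}
    return FrameIndexedForest(frames)


def from_indexed(fif: FrameIndexedForest) -> LineageForest:
    """Inverse of :func:`to_indexed` (lossless round trip)."""
    dets: List[Detection] = []
    edges = []
    for t, fa in enumerate(fif.frames):
        for k in range(len(fa.ids)):
            dets.append(
                Detection(
                    id=int(fa.ids[k]),
                    frame=t,
                    x=float(fa.x[k]),
                    y=float(fa.y[k]),
                    area=float(fa.area[k]),
                    orientation=float(fa.orientation[k]),
                )
            )
            pi = int(fa.parent_index[k])
            if pi != ROOT:
                edges.append((int(fif.frames[t - 1].ids[pi]), int(fa.ids[k])))
    return build_forest(edges, dets)


def ancestor_features(
    fif: FrameIndexedForest, frame: int, depth: int
) -> Dict[int, np.ndarray]:
    """Per-detection history of (x, y, area) for up to ``depth`` ancestors.

    Returns, for each detection id in ``frame``, an array of shape
    (1 + n_ancestors, 3) starting with the cell's own features, then its
    parent's, and so on (shorter for young cells).  Runs one batched gather
    per ancestor level; no per-cell recursion.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    fa = fif.frames[frame]
    n = len(fa.ids)
    levels: List[tuple[np.ndarray, np.ndarray]] = []  # (query rows, features)
    idx = np.arange(n, dtype=np.int64)
    rows = np.arange(n, dtype=np.int64)
    t = frame
    for level in range(depth + 1):
        cur = fif.frames[t]
        feats = np.column_stack((cur.x, cur.y, cur.area))
        levels.append((rows, feats[idx]))
        if level == depth or t == 0:
            break
        parents = cur.parent_index[idx]
        keep = parents != ROOT
        rows, idx = rows[keep], parents[keep]
        t -= 1
        if rows.size == 0:
            break
    histories: List[List[np.ndarray]] = [[] for _ in range(n)]
    for rows, feats in levels:
        for r, f in zip(rows, feats):
            histories[r].append(f)
    return {int(fa.ids[i]): np.vstack(histories[i]) for i in range(n)}


def estimate_velocity(fif: FrameIndexedForest, frame: int, dt: float) -> np.ndarray:
    """Per-detection (vx, vy) in px/min for frame ``frame``.

    v = (pos(cell) − pos(parent)) / Δt; roots get (0, 0).  Daughters of a
    division use their own parent edge like any other cell.
    """
    fa = fif.frames[frame]
    n = len(fa.ids)
    v = np.zeros((n, 2))
    if frame == 0 or n == 0:
        return v
    prev = fif.frames[frame - 1]
    has_parent = fa.parent_index != ROOT
    pi = fa.parent_index[has_parent]
    v[has_parent, 0] = (fa.x[has_parent] - prev.x[pi]) / dt
    v[has_parent, 1] = (fa.y[has_parent] - prev.y[pi]) / dt
    return v


def estimate_growth_factor(
    fif: FrameIndexedForest,
    frame: int,
    dt: float,
    colony_rate: float,
    clip: tuple[float, float] = (0.5, 4.0),
) -> np.ndarray:
    """Per-detection area growth factor over one processed interval.

    g = area / parent_area, except that a division daughter is referenced
    against parent_area / 2 (a division halves area; the growth feature must
    not see a spurious 0.5× collapse).  Roots get the colony-level prior
    exp(colony_rate · Δt).  Values are clipped to ``clip`` to tolerate
    segmentation artifacts.
    """
    fa = fif.frames[frame]
    n = len(fa.ids)
    g = np.full(n, float(np.exp(colony_rate * dt)))
    if frame == 0 or n == 0:
        return g
    prev = fif.frames[frame - 1]
    has_parent = fa.parent_index != ROOT
    pi = fa.parent_index[has_parent]
    ref = prev.area[pi].copy()
    # siblings: parents with 2 children in this frame are divisions
    counts = np.bincount(pi, minlength=len(prev.ids))
    is_daughter = counts[pi] == 2
    ref[is_daughter] = ref[is_daughter] / 2.0
    g[has_parent] = fa.area[has_parent] / ref
    return np.clip(g, clip[0], clip[1])


def estimate_colony_growth_rate(
    frames: Sequence[Sequence[Detection]], dt: float
) -> float:
    """Colony-level single-cell area growth rate (per minute).

    Ordinary-least-squares slope of log(total segmented area) against
    physical time — a segmentation-only estimate that needs no tracking.
    """
    totals = [sum(d.area for d in f) for f in frames]
    kept = [(t, a) for t, a in enumerate(totals) if a > 0]
    if len(kept) < 2:
        raise ValueError("need at least 2 frames with positive total area")
    times = np.array([t * dt for t, _ in kept])
    log_area = np.log([a for _, a in kept])
    slope = np.polyfit(times, log_area, 1)[0]
    return float(slope)
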