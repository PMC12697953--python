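"""Synthetic 2D monolayer colony generator with ground-truth lineage.

Emulates time-lapse microscopy of rod-shaped bacteria growing in a
microfluidic chamber: exponential single-cell area growth around a colony
rate, stochastic displacement on top of a deterministic radial colony
expansion flow, orientation diffusion, and divisions into two daughters of
roughly half area, separated by a small distance along the mother axis with
a characteristic "snapping" angle between the daughter major axes.  Frames
are recorded at a base interval (1 min by default) and can be sub-sampled to
longer imaging intervals, composing ground-truth edges across the skipped
frames.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .datamodel import Detection, LineageForest, build_forest


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the synthetic colony.

    Defaults describe a desk-scale colony that is near-trivial to track at
    the 1-minute base interval and degrades visibly by ~16-minute intervals.
    """

    n_frames: int = 65            # base frames (1 min apart by default)
    dt_base: float = 1.0          # minutes between base frames
    n_initial: int = 6            # starting cells
    colony_rate: float = 0.02     # per-min single-cell area growth rate
    growth_noise: float = 0.02    # sd of the per-step growth-rate perturbation
    motion_sd: float = 1.0        # px per sqrt(min) random-walk displacement
    rotation_sd: float = 0.05     # rad per sqrt(min) orientation diffusion
    division_area: float = 200.0  # px² division threshold
    division_area_cv: float = 0.1  # lognormal sd of per-cell threshold jitter
    div_angle_mean: float = 0.0   # rad, snapping angle between daughter axes
    div_angle_sd: float = 0.25    # rad
    div_distance_mean: float = 8.0  # px between daughter centroids
    detection_dropout: float = 0.0  # probability a cell is missed in a frame
    initial_area: float = 100.0   # px² lower bound of initial areas
    initial_spread: float = 40.0  # px sd of initial cell placement
    expansion_flow: bool = True   # advect positions with colony expansion
    max_cells: int = 1000         # population cap; simulation stops early above
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("growth_noise", "motion_sd", "rotation_sd",
                     "division_area_cv", "div_angle_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.detection_dropout <= 0.2):
            raise ValueError("detection_dropout must lie in [0, 0.2]")
        if self.n_frames < 1 or self.n_initial < 1:
            raise ValueError("n_frames and n_initial must be >= 1")


@dataclass
class SimResult:
    frames: List[List[Detection]]       # observed detections per base frame
    forest: LineageForest               # ground truth over observed detections
    params: SimParams
    truncated: bool = False             # population cap reached
    n_unresolved: int = 0               # set by subsampling


class _Cell:
    __slots__ = ("x", "y", "area", "orientation", "threshold", "last_det")

    def __init__(self, x, y, area, orientation, threshold):
        self.x, self.y = x, y
        self.area = area
        self.orientation = orientation
        self.threshold = threshold
        self.last_det: Optional[int] = None  # detection id in previous frame


def simulate(params: SimParams, seed: Optional[int] = None) -> SimResult:
    """Grow a colony and record detections plus the true lineage forest.

    Detection dropout truncates ground-truth tracks: a missed cell's track
    ends and its next observation starts a new root, mirroring segmentation
    artifacts in real data.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    dt = params.dt_base
    sqdt = math.sqrt(dt)

    cells: List[_Cell] = []
    for _ in range(params.n_initial):
        x, y = rng.normal(0.0, params.initial_spread, 2)
        area = params.initial_area * (1.0 + rng.random() * 0.8)
        orient = rng.random() * math.pi
        thr = params.division_area * math.exp(
            rng.normal(0.0, params.division_area_cv) if params.division_area_cv > 0 else 0.0
        )
        cells.append(_Cell(x, y, area, orient, thr))

    frames: List[List[Detection]] = []
    edges: List[Tuple[int, int]] = []
    all_dets: List[Detection] = []
    next_id = 0
    truncated = False

    def record(frame: int) -> None:
        nonlocal next_id
        observed: List[Detection] = []
        for cell in cells:
            parent_det = cell.last_det
            if params.detection_dropout > 0 and rng.random() < params.detection_dropout:
                cell.last_det = None  # gap: truncate track
                continue
            det = Detection(
                id=next_id,
                frame=frame,
                x=float(cell.x),
                y=float(cell.y),
                area=float(cell.area),
                orientation=float(cell.orientation % math.pi),
            )
            next_id += 1
            observed.append(det)
            all_dets.append(det)
            if parent_det is not None:
                edges.append((parent_det, det.id))
            cell.last_det = det.id
        frames.append(observed)

    record(0)
    for frame in range(1, params.n_frames):
        grow = math.exp(params.colony_rate * dt / 2.0) if params.expansion_flow else 1.0
        new_cells: List[_Cell] = []
        for cell in cells:
            # colony expansion flow about the origin, then random walk
            cell.x = cell.x * grow + (rng.normal(0.0, params.motion_sd * sqdt)
                                      if params.motion_sd > 0 else 0.0)
            cell.y = cell.y * grow + (rng.normal(0.0, params.motion_sd * sqdt)
                                      if params.motion_sd > 0 else 0.0)
            if params.rotation_sd > 0:
                cell.orientation = (cell.orientation
                                    + rng.normal(0.0, params.rotation_sd * sqdt)) % math.pi
            rate = params.colony_rate + (rng.normal(0.0, params.growth_noise)
                                         if params.growth_noise > 0 else 0.0)
            cell.area *= math.exp(rate * dt)
            if cell.area > cell.threshold:
                new_cells.extend(_divide(cell, params, rng))
            else:
                new_cells.append(cell)
        cells = new_cells
        if len(cells) > params.max_cells:
            truncated = True
            warnings.warn(
                f"population cap {params.max_cells} exceeded at frame {frame}; "
                "stopping early",
                stacklevel=2,
            )
            break
        record(frame)

    forest = build_forest(edges, all_dets)
    return SimResult(frames=frames, forest=forest, params=params, truncated=truncated)


def _divide(cell: _Cell, params: SimParams, rng: np.random.Generator) -> List[_Cell]:
    """Split a mother into two daughters along its major axis."""
    snap = params.div_angle_mean + (
        rng.normal(0.0, params.div_angle_sd) if params.div_angle_sd > 0 else 0.0
    )
    eps = rng.normal(0.0, params.growth_noise) if params.growth_noise > 0 else 0.0
    areas = (cell.area / 2.0 * math.exp(eps), cell.area / 2.0 * math.exp(-eps))
    ux, uy = math.cos(cell.orientation), math.sin(cell.orientation)
    offset = params.div_distance_mean / 2.0
    daughters = []
    for sign, area, dang in ((1.0, areas[0], snap / 2.0), (-1.0, areas[1], -snap / 2.0)):
        thr = params.division_area * math.exp(
            rng.normal(0.0, params.division_area_cv) if params.division_area_cv > 0 else 0.0
        )
        d = _Cell(
            cell.x + sign * offset * ux,
            cell.y + sign * offset * uy,
            area,
            (cell.orientation + dang) % math.pi,
            thr,
        )
        d.last_det = cell.last_det  # both daughters link to the mother's detection
        daughters.append(d)
    return daughters


# ---------------------------------------------------------------------------
# temporal sub-sampling
# ---------------------------------------------------------------------------

def subsample(
    frames: Sequence[Sequence[Detection]],
    forest: LineageForest,
    factor: int,
) -> Tuple[List[List[Detection]], LineageForest, int]:
    """Keep every ``factor``-th frame and compose ground truth across gaps.

    Kept frames are renumbered consecutively.  A cell at one kept frame is
    linked to its surviving descendants at the next kept frame: one
    descendant gives a migration edge, two give a division.  When more than
    two descendants survive a gap, the pair whose lineages diverge latest
    (the intermediate division closest to the later kept frame) becomes the
    division and the remaining descendants are recorded as unresolvable new
    roots; the count of such cells is returned.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    kept = list(range(0, len(frames), factor))
    new_frames: List[List[Detection]] = []
    remap: Dict[int, Detection] = {}
    for k, base in enumerate(kept):
        row = []
        for det in frames[base]:
            nd = replace(det, frame=k)
            remap[det.id] = nd
            row.append(nd)
        new_frames.append(row)

    if factor == 1:
        return new_frames, forest, 0

    kept_prev = {d.id for base in kept for d in frames[base]}
    edges: List[Tuple[int, int]] = []
    n_unresolved = 0
    for k in range(1, len(kept)):
        prev_ids = {d.id for d in frames[kept[k - 1]]}
        lower, upper = kept[k - 1], kept[k]
        # ancestor path (excluding the ancestor) for each current detection
        groups: Dict[int, List[Tuple[int, List[int]]]] = {}
        for det in frames[kept[k]]:
            path = [det.id]
            node = det.id
            anc = None
            while True:
                p = forest.parent_of(node)
                if p is None:
                    break
                if p in prev_ids:
                    anc = p
                    break
                path.append(p)
                node = p
            if anc is None:
                continue  # appearance on the sub-sampled axis
            groups.setdefault(anc, []).append((det.id, path[::-1]))
        for anc, members in sorted(groups.items()):
            members.sort(key=lambda m: m[0])
            if len(members) == 1:
                edges.append((anc, members[0][0]))
            elif len(members) == 2:
                edges.append((anc, members[0][0]))
                edges.append((anc, members[1][0]))
            else:
                best = None
                for i in range(len(members)):
                    for j in range(i + 1, len(members)):
                        pi, pj = members[i][1], members[j][1]
                        depth = 0
                        while depth < min(len(pi), len(pj)) and pi[depth] == pj[depth]:
                            depth += 1
                        key = (-depth, members[i][0], members[j][0])
                        if best is None or key < best[0]:
                            best = (key, members[i][0], members[j][0])
                assert best is not None
                edges.append((anc, best[1]))
                edges.append((anc, best[2]))
                n_unresolved += len(members) - 2
    new_edges = [(remap[p].id, remap[c].id) for p, c in edges]
    new_forest = build_forest(new_edges, list(remap.values()))
    return new_frames, new_forest, n_unresolved


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def write_fixture(result: SimResult, path) -> None:
    """Persist a simulated dataset (detections CSV, edge list JSON, CTC
    track file, params JSON) to a directory."""
    from . import io_formats

    io_formats.write_dataset_dir(
        path,
        [d for f in result.frames for d in f],
        result.forest,
        meta={
            "params": {k: getattr(result.params, k) for k in SimParams.__dataclass_fields__},
            "truncated": result.truncated,
            "n_unresolved": result.n_unresolved,
        },
    )


def read_fixture(path) -> SimResult:
    from . import io_formats

    dets, forest, meta = io_formats.read_dataset_dir(path)
    params = SimParams(**meta["params"])
    n_frames = max((d.frame for d in dets), default=-1) + 1
    frames: List[List[Detection]] = [[] for _ in range(n_frames)]
    for d in sorted(dets, key=lambda d: d.id):
        frames[d.frame].append(d)
    return SimResult(
        frames=frames,
        forest=forest,
        params=params,
        truncated=bool(meta.get("truncated", False)),
        n_unresolved=int(meta.get("n_unresolved", 0)),
    )
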