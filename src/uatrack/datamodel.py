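"""Core types for detections, cell lineage trees and tracking particles.

A cell lineage tree (CLT) is represented as a forest over per-frame cell
detections: edges connect a cell instance in frame ``t`` to its identity (or
its daughters) in frame ``t + 1``.  A node with two children is a division.
Particles pair one such forest hypothesis with a cumulative log-weight; a set
of particles approximates the posterior distribution over lineage trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Set, Tuple


class LineageError(ValueError):
    """Base class for lineage-forest validation failures."""


class UnknownDetectionError(LineageError):
    """An edge or candidate refers to a detection id that does not exist."""


class DuplicateParentError(LineageError):
    """A detection was assigned more than one parent."""


class TooManyChildrenError(LineageError):
    """A detection was assigned more than two children."""


class FrameGapError(LineageError):
    """An edge does not connect consecutive processed frames."""


class CycleError(LineageError):
    """The edge set contains a cycle."""


class InvalidCoverError(LineageError):
    """A set of assignment candidates is not a valid frame-pair cover."""


@dataclass(frozen=True)
class Detection:
    """One segmented cell instance in one processed frame.

    Coordinates are 0-based pixel centers (x = column, y = row); ``area`` is
    in px² and ``orientation`` is the major-axis angle, axial (direction-free)
    in [0, π).
    """

    id: int
    frame: int
    x: float
    y: float
    area: float
    orientation: float

    def __post_init__(self) -> None:
        if self.id < 0:
            raise ValueError(f"detection id must be non-negative, got {self.id}")
        if self.frame < 0:
            raise ValueError(f"frame must be non-negative, got {self.frame}")
        if not self.area > 0:
            raise ValueError(f"area must be positive, got {self.area}")
        if not (0.0 <= self.orientation < math.pi):
            raise ValueError(
                f"orientation must lie in [0, pi), got {self.orientation}"
            )

    @property
    def pos(self) -> Tuple[float, float]:
        return (self.x, self.y)


_KINDS = ("appear", "disappear", "migrate", "divide")


@dataclass(frozen=True)
class AssignmentCandidate:
    """A typed hypothesis linking detections across one frame pair.

    ``source`` ids live in frame t, ``targets`` in frame t+1.  Arities:
    appear 0→1, disappear 1→0, migrate 1→1, divide 1→2 (distinct daughters).
    """

    kind: str
    source: Tuple[int, ...]
    targets: Tuple[int, ...]
    log_score: float

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown assignment kind {self.kind!r}")
        ns, nt = len(self.source), len(self.targets)
        arity = {"appear": (0, 1), "disappear": (1, 0), "migrate": (1, 1), "divide": (1, 2)}
        if (ns, nt) != arity[self.kind]:
            raise ValueError(
                f"{self.kind} assignment must have arity {arity[self.kind]}, got ({ns}, {nt})"
            )
        if self.kind == "divide" and self.targets[0] == self.targets[1]:
            raise ValueError("divide assignment requires two distinct targets")
        if not math.isfinite(self.log_score):
            raise ValueError("log_score must be finite")

    @property
    def is_unary(self) -> bool:
        return self.kind in ("appear", "disappear")


def migrate(source: int, target: int, log_score: float) -> AssignmentCandidate:
    return AssignmentCandidate("migrate", (source,), (target,), log_score)


def divide(source: int, t1: int, t2: int, log_score: float) -> AssignmentCandidate:
    a, b = sorted((t1, t2))
    return AssignmentCandidate("divide", (source,), (a, b), log_score)


def appear(target: int, log_score: float) -> AssignmentCandidate:
    return AssignmentCandidate("appear", (), (target,), log_score)


def disappear(source: int, log_score: float) -> AssignmentCandidate:
    return AssignmentCandidate("disappear", (source,), (), log_score)


class LineageForest:
    """A bifurcated forest over detections: ≤1 parent, ≤2 children per node,
    edges only between consecutive processed frames."""

    def __init__(self, detections: Iterable[Detection], parent: Mapping[int, int]):
        dets: Dict[int, Detection] = {}
        for d in detections:
            if d.id in dets:
                raise LineageError(f"duplicate detection id {d.id}")
            dets[d.id] = d
        children: Dict[int, List[int]] = {}
        for child_id, parent_id in parent.items():
            if child_id not in dets:
                raise UnknownDetectionError(f"edge child {child_id} is not a detection")
            if parent_id not in dets:
                raise UnknownDetectionError(f"edge parent {parent_id} is not a detection")
            children.setdefault(parent_id, []).append(child_id)
        for pid, kids in children.items():
            if len(kids) > 2:
                raise TooManyChildrenError(
                    f"detection {pid} has {len(kids)} children (max 2)"
                )
        # Cycle check before frame-consecutiveness so that mutually-parented
        # pairs are reported as cycles, not frame gaps.
        state: Dict[int, int] = {}  # 0 = in progress, 1 = done
        for start in parent:
            node, chain = start, []
            while node in parent and state.get(node) != 1:
                if state.get(node) == 0:
                    raise CycleError(f"cycle through detection {node}")
                state[node] = 0
                chain.append(node)
                node = parent[node]
                if node == start:
                    raise CycleError(f"cycle through detection {start}")
            for n in chain:
                state[n] = 1
        for child_id, parent_id in parent.items():
            if dets[child_id].frame != dets[parent_id].frame + 1:
                raise FrameGapError(
                    f"edge {parent_id}->{child_id} spans frames "
                    f"{dets[parent_id].frame}->{dets[child_id].frame}"
                )
        self._detections = dets
        self._parent = dict(parent)
        self._children = {p: sorted(c) for p, c in children.items()}

    # -- accessors -----------------------------------------------------------

    @property
    def detections(self) -> Dict[int, Detection]:
        return self._detections

    @property
    def parent(self) -> Dict[int, int]:
        return dict(self._parent)

    def parent_of(self, det_id: int) -> int | None:
        return self._parent.get(det_id)

    def children_of(self, det_id: int) -> List[int]:
        return list(self._children.get(det_id, []))

    def edges(self) -> Set[Tuple[int, int]]:
        return {(p, c) for c, p in self._parent.items()}

    def roots(self) -> List[int]:
        return sorted(i for i in self._detections if i not in self._parent)

    def frame_detections(self, frame: int) -> List[Detection]:
        return sorted(
            (d for d in self._detections.values() if d.frame == frame),
            key=lambda d: d.id,
        )

    @property
    def max_frame(self) -> int:
        if not self._detections:
            return -1
        return max(d.frame for d in self._detections.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LineageForest):
            return NotImplemented
        return (
            self._detections == other._detections and self._parent == other._parent
        )

    def __len__(self) -> int:
        return len(self._detections)


def build_forest(
    edges: Iterable[Tuple[int, int]], detections: Iterable[Detection]
) -> LineageForest:
    """Build and validate a lineage forest from (parent_id, child_id) edges."""
    parent: Dict[int, int] = {}
    for p, c in edges:
        if c in parent and parent[c] != p:
            raise DuplicateParentError(f"detection {c} has parents {parent[c]} and {p}")
        parent[c] = p
    return LineageForest(detections, parent)


@dataclass
class Particle:
    """One CLT hypothesis plus the cumulative log-weight of its assignments."""

    forest: LineageForest
    log_weight: float = 0.0


def check_cover(
    selected: Iterable[AssignmentCandidate],
    source_ids: Set[int],
    target_ids: Set[int],
) -> None:
    """Raise InvalidCoverError unless every source and target id is covered
    exactly once by ``selected``."""
    src_seen: Dict[int, int] = {i: 0 for i in source_ids}
    tgt_seen: Dict[int, int] = {i: 0 for i in target_ids}
    for cand in selected:
        for s in cand.source:
            if s not in src_seen:
                raise InvalidCoverError(f"candidate covers unknown source {s}")
            src_seen[s] += 1
        for t in cand.targets:
            if t not in tgt_seen:
                raise InvalidCoverError(f"candidate covers unknown target {t}")
            tgt_seen[t] += 1
    bad_src = [i for i, n in src_seen.items() if n != 1]
    bad_tgt = [i for i, n in tgt_seen.items() if n != 1]
    if bad_src or bad_tgt:
        raise InvalidCoverError(
            f"cover is not exact: sources {bad_src}, targets {bad_tgt}"
        )


def extend_particle(
    particle: Particle,
    selected: Iterable[AssignmentCandidate],
    new_detections: Iterable[Detection],
) -> Particle:
    """Extend a particle's forest by one frame using a selected cover.

    Migrate and divide candidates add edges; appear targets become new roots;
    disappear sources become leaves.  The log-weight grows by the sum of the
    selected log-scores.
    """
    selected = list(selected)
    new_dets = {d.id: d for d in new_detections}
    forest = particle.forest
    last_frame = forest.max_frame
    source_ids = {d.id for d in forest.frame_detections(last_frame)}
    if new_dets:
        frames = {d.frame for d in new_dets.values()}
        if len(frames) > 1 or min(frames) <= last_frame:
            raise InvalidCoverError("new detections must share one later frame")
    check_cover(selected, source_ids, set(new_dets))
    parent = forest.parent
    for cand in selected:
        if cand.kind == "migrate":
            parent[cand.targets[0]] = cand.source[0]
        elif cand.kind == "divide":
            parent[cand.targets[0]] = cand.source[0]
            parent[cand.targets[1]] = cand.source[0]
    dets = list(forest.detections.values()) + list(new_dets.values())
    gained = sum(c.log_score for c in selected)
    return Particle(LineageForest(dets, parent), particle.log_weight + gained)


def divisions_of(forest: LineageForest) -> Set[Tuple[int, int]]:
    """All (parent_id, frame) pairs where a detection has exactly 2 children."""
    out = set()
    for det_id, det in forest.detections.items():
        if len(forest.children_of(det_id)) == 2:
            out.add((det_id, det.frame))
    return out
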