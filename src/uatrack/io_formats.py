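"""Readers and writers for detections and lineage forests.

Formats:

* Detection CSV — columns ``id, frame, x, y, area, orientation``; floats
  are serialized with 17 significant digits so round trips are lossless.
* CTC track text — the Cell Tracking Challenge ``res_track.txt`` /
  ``man_track.txt`` dialect of whitespace-separated ``L B E P`` lines
  (track label, begin frame, end frame, parent label or 0).  Because the
  text file alone cannot say which detection belongs to which track (real
  CTC uses label masks), the writer also returns a detection-id → label
  map, persisted alongside as JSON.
* JSON edge list — ``{"edges": [[parent_id, child_id], ...]}`` plus
  optional per-edge marginal probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .datamodel import Detection, LineageForest, build_forest

DETECTION_COLUMNS = ["id", "frame", "x", "y", "area", "orientation"]


class FormatError(ValueError):
    """Malformed input file."""


class MissingColumnError(FormatError):
    pass


class DuplicateIdError(FormatError):
    pass


class InvalidValueError(FormatError):
    pass


# ---------------------------------------------------------------------------
# detection tables
# ---------------------------------------------------------------------------

def write_detections(detections: Iterable[Detection], path) -> None:
    rows = sorted(detections, key=lambda d: (d.frame, d.id))
    df = pd.DataFrame(
        [(d.id, d.frame, d.x, d.y, d.area, d.orientation) for d in rows],
        columns=DETECTION_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_detections(path) -> Set[Detection]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"missing columns: {missing}")
    if df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].tolist()
        raise DuplicateIdError(f"duplicate detection ids: {dup}")
    if (df["area"] <= 0).any():
        raise InvalidValueError("non-positive area in detection table")
    return {
        Detection(
            id=int(r.id),
            frame=int(r.frame),
            x=float(r.x),
            y=float(r.y),
            area=float(r.area),
            orientation=float(r.orientation),
        )
        for r in df.itertuples()
    }


# ---------------------------------------------------------------------------
# CTC track files
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CTCTrackRecord:
    """One ``L B E P`` line: track label, begin/end frame, parent label."""

    label: int
    begin: int
    end: int
    parent: int

    def __post_init__(self) -> None:
        if self.label <= 0:
            raise InvalidValueError(f"track label must be positive, got {self.label}")
        if self.begin > self.end:
            raise InvalidValueError(
                f"track {self.label}: begin {self.begin} > end {self.end}"
            )
        if self.parent < 0:
            raise InvalidValueError("parent label must be >= 0")


def forest_to_ctc(
    forest: LineageForest,
) -> Tuple[List[CTCTrackRecord], Dict[int, int]]:
    """Decompose a forest into CTC tracks.

    A track is a maximal migrate-chain; a division ends the parent track and
    starts two child tracks carrying the parent's label in P.  Labels are
    assigned in order of (begin frame, first detection id).  Returns the
    records and the detection-id → track-label map.
    """
    starts: List[int] = list(forest.roots())
    for det_id in forest.detections:
        if len(forest.children_of(det_id)) == 2:
            starts.extend(forest.children_of(det_id))
    chains: List[List[int]] = []
    for start in starts:
        chain = [start]
        node = start
        while True:
            kids = forest.children_of(node)
            if len(kids) != 1:
                break
            node = kids[0]
            chain.append(node)
        chains.append(chain)
    dets = forest.detections
    chains.sort(key=lambda ch: (dets[ch[0]].frame, ch[0]))
    labels: Dict[int, int] = {}
    for lbl, chain in enumerate(chains, start=1):
        for det_id in chain:
            labels[det_id] = lbl
    records = []
    for lbl, chain in enumerate(chains, start=1):
        parent_det = forest.parent_of(chain[0])
        parent_lbl = labels[parent_det] if parent_det is not None else 0
        records.append(
            CTCTrackRecord(
                label=lbl,
                begin=dets[chain[0]].frame,
                end=dets[chain[-1]].frame,
                parent=parent_lbl,
            )
        )
    return records, labels


def ctc_to_forest(
    records: Sequence[CTCTrackRecord],
    detections: Iterable[Detection],
    labels: Mapping[int, int],
) -> LineageForest:
    """Rebuild a forest from CTC records plus the detection → label map."""
    by_label: Dict[int, List[Detection]] = {}
    dets = list(detections)
    det_by_id = {d.id: d for d in dets}
    for det_id, lbl in labels.items():
        if det_id not in det_by_id:
            raise FormatError(f"label map refers to unknown detection {det_id}")
        by_label.setdefault(lbl, []).append(det_by_id[det_id])
    rec_by_label = {r.label: r for r in records}
    if len(rec_by_label) != len(records):
        raise FormatError("duplicate track labels")
    for r in records:
        if r.parent:
            parent = rec_by_label.get(r.parent)
            if parent is None:
                raise FormatError(f"track {r.label}: unknown parent {r.parent}")
            if parent.end >= r.begin:
                raise FormatError(
                    f"track {r.label}: parent {r.parent} ends at {parent.end}, "
                    f"not before begin {r.begin}"
                )
    edges: List[Tuple[int, int]] = []
    last_of: Dict[int, int] = {}
    for r in records:
        members = sorted(by_label.get(r.label, []), key=lambda d: d.frame)
        if not members:
            raise FormatError(f"track {r.label} has no detections")
        frames = [d.frame for d in members]
        if frames[0] != r.begin or frames[-1] != r.end or len(set(frames)) != len(frames):
            raise FormatError(f"track {r.label}: detections inconsistent with B/E")
        for a, b in zip(members, members[1:]):
            edges.append((a.id, b.id))
        last_of[r.label] = members[-1].id
    for r in records:
        if r.parent:
            first = min(by_label[r.label], key=lambda d: d.frame)
            edges.append((last_of[r.parent], first.id))
    return build_forest(edges, dets)


def write_ctc(records: Sequence[CTCTrackRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.label} {r.begin} {r.end} {r.parent}\n")


def read_ctc(path) -> List[CTCTrackRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise FormatError(f"line {lineno}: expected 'L B E P'")
            l, b, e, p = (int(v) for v in parts)
            records.append(CTCTrackRecord(l, b, e, p))
    seen = set()
    for r in records:
        if r.label in seen:
            raise FormatError(f"track label {r.label} reused")
        seen.add(r.label)
    return records


# ---------------------------------------------------------------------------
# JSON edge lists and dataset directories
# ---------------------------------------------------------------------------

def write_edges_json(
    forest: LineageForest,
    path,
    marginals: Optional[Mapping[Tuple[int, int], float]] = None,
) -> None:
    payload = {"edges": sorted([p, c] for p, c in forest.edges())}
    if marginals is not None:
        payload["marginals"] = [
            [p, c, marginals[(p, c)]] for p, c in sorted(marginals)
        ]
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)
        fh.write("\n")


def read_edges_json(path) -> List[Tuple[int, int]]:
    with open(path) as fh:
        payload = json.load(fh)
    return [(int(p), int(c)) for p, c in payload["edges"]]


def write_dataset_dir(
    path,
    detections: Iterable[Detection],
    forest: LineageForest,
    meta: Optional[dict] = None,
) -> None:
    """Write a dataset directory: detections.csv, edges.json, res_track.txt,
    track_labels.json and meta.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_detections(detections, path / "detections.csv")
    write_edges_json(forest, path / "edges.json")
    records, labels = forest_to_ctc(forest)
    write_ctc(records, path / "res_track.txt")
    with open(path / "track_labels.json", "w") as fh:
        json.dump({str(k): v for k, v in sorted(labels.items())}, fh, sort_keys=True)
        fh.write("\n")
    with open(path / "meta.json", "w") as fh:
        json.dump(meta or {}, fh, sort_keys=True, indent=1)
        fh.write("\n")


def read_dataset_dir(path) -> Tuple[Set[Detection], LineageForest, dict]:
    path = Path(path)
    dets = read_detections(path / "detections.csv")
    edges = read_edges_json(path / "edges.json")
    forest = build_forest(edges, dets)
    meta = {}
    meta_path = path / "meta.json"
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
    return dets, forest, meta
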