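"""Detections linked across time: the in-memory track graph.

A :class:`TrackGraph` stores per-timepoint lists of :class:`Detection` and a
set of directed edges between detections at consecutive timepoints. Every
detection has in-degree at most 1 (a single predecessor) and out-degree at
most 2: one successor for a continuing track, two at a cell division.
Detections are addressed by ``(timepoint, id)`` where ids are 0-based and
unique within a timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Detection", "TrackGraph"]

Key = tuple[int, int]  # (timepoint, id)


@dataclass
class Detection:
    """One nucleus detection: position in voxels (z, y, x), size, score."""

    id: int
    timepoint: int
    center: np.ndarray  # (z, y, x) in voxel units, 0-based
    diameter: float = 0.0
    score: float = 0.0
    name: str | None = None

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=np.float64)
        if self.center.shape != (3,):
            raise ValueError(f"center must be 3 floats (z,y,x), got {self.center}")

    @property
    def key(self) -> Key:
        return (self.timepoint, self.id)


@dataclass
class TrackGraph:
    frames: dict[int, list[Detection]] = field(default_factory=dict)
    edges: set[tuple[Key, Key]] = field(default_factory=set)

    # -- construction ---------------------------------------------------------
    def add_detection(self, det: Detection) -> Detection:
        frame = self.frames.setdefault(det.timepoint, [])
        if any(d.id == det.id for d in frame):
            raise ValueError(f"duplicate detection id {det.id} at t={det.timepoint}")
        frame.append(det)
        return det

    def add_edge(self, a: Key, b: Key) -> None:
        ta, tb = a[0], b[0]
        if tb != ta + 1:
            raise ValueError(f"edges must connect consecutive timepoints: {a} -> {b}")
        if self.get(a) is None or self.get(b) is None:
            raise ValueError(f"edge endpoints must exist: {a} -> {b}")
        if len(self.successors(a)) >= 2:
            raise ValueError(f"{a} already has 2 successors")
        if self.predecessor(b) is not None:
            raise ValueError(f"{b} already has a predecessor")
        self.edges.add((a, b))

    # -- queries --------------------------------------------------------------
    def get(self, key: Key) -> Detection | None:
        for d in self.frames.get(key[0], []):
            if d.id == key[1]:
                return d
        return None

    def timepoints(self) -> list[int]:
        return sorted(self.frames)

    def detections(self, timepoint: int) -> list[Detection]:
        return list(self.frames.get(timepoint, []))

    def all_detections(self) -> list[Detection]:
        return [d for t in self.timepoints() for d in self.frames[t]]

    def n_detections(self) -> int:
        return sum(len(v) for v in self.frames.values())

    def successors(self, key: Key) -> list[Key]:
        return sorted(b for a, b in self.edges if a == key)

    def predecessor(self, key: Key) -> Key | None:
        preds = [a for a, b in self.edges if b == key]
        return preds[0] if preds else None

    def is_division(self, key: Key) -> bool:
        return len(self.successors(key)) == 2

    # -- comparison -----------------------------------------------------------
    def same_topology(self, other: "TrackGraph") -> bool:
        """Equal frame structure (by id) and identical edge sets."""
        if self.timepoints() != other.timepoints():
            return False
        for t in self.timepoints():
            if sorted(d.id for d in self.frames[t]) != sorted(
                d.id for d in other.frames[t]
            ):
                return False
        return self.edges == other.edges
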