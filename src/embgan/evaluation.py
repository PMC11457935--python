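"""Detection and tracking error accounting and performance summaries.

Detections are matched per timepoint by minimum-cost one-to-one assignment
under a distance cutoff (physical units): unmatched predictions are
detection FPs, unmatched reference detections are detection FNs.

Tracking errors follow edge-level conventions with two FN subtypes:

* every reference edge absent from the prediction is one tracking FN -
  classified as *missing-detection* FN if either endpoint is an unmatched
  detection, else as *missed-link* FN;
* every predicted edge whose endpoints do not map onto a connected pair of
  reference detections is one tracking FP (by default this includes edges
  incident to FP detections; ``include_fp_detection_edges=False`` restricts
  the count to mislinked true detections).

All erroneous edges are counted individually, so a two-cell identity swap
across one frame transition contributes exactly 4 errors: 2 FNs for the
missing correct edges and 2 FPs for the crossing ones.

"Accuracy" is TP / (TP + FP + FN), the standard tracking accuracy in the
absence of a true-negative class; precision and recall are the usual ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .trackgraph import Detection, TrackGraph

__all__ = [
    "ErrorTally",
    "PerformanceSeries",
    "match_detections",
    "count_detection_errors",
    "count_tracking_errors",
    "tallies_by_timepoint",
    "tallies_by_depth",
    "performance_by_time",
    "performance_by_depth",
]

_UNMATCHABLE = 1e12


def _rate(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


@dataclass
class ErrorTally:
    det_tp: int = 0
    det_fp: int = 0
    det_fn: int = 0
    trk_tp: int = 0
    trk_fp: int = 0
    trk_fn_missing_detection: int = 0
    trk_fn_missed_link: int = 0

    @property
    def trk_fn(self) -> int:
        return self.trk_fn_missing_detection + self.trk_fn_missed_link

    @property
    def trk_total_errors(self) -> int:
        return self.trk_fp + self.trk_fn

    # detection rates
    @property
    def det_precision(self) -> float:
        return _rate(self.det_tp, self.det_tp + self.det_fp)

    @property
    def det_recall(self) -> float:
        return _rate(self.det_tp, self.det_tp + self.det_fn)

    @property
    def det_accuracy(self) -> float:
        return _rate(self.det_tp, self.det_tp + self.det_fp + self.det_fn)

    @property
    def det_f1(self) -> float:
        p, r = self.det_precision, self.det_recall
        return _rate(2 * p * r, p + r)

    # tracking rates
    @property
    def trk_precision(self) -> float:
        return _rate(self.trk_tp, self.trk_tp + self.trk_fp)

    @property
    def trk_recall(self) -> float:
        return _rate(self.trk_tp, self.trk_tp + self.trk_fn)

    @property
    def trk_accuracy(self) -> float:
        return _rate(self.trk_tp, self.trk_tp + self.trk_fp + self.trk_fn)

    def __iadd__(self, other: "ErrorTally"):
        for f in (
            "det_tp",
            "det_fp",
            "det_fn",
            "trk_tp",
            "trk_fp",
            "trk_fn_missing_detection",
            "trk_fn_missed_link",
        ):
            setattr(self, f, getattr(self, f) + getattr(other, f))
        return self


def match_detections(
    pred: list[Detection],
    truth: list[Detection],
    radius: float,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> list[tuple[int, int]]:
    """Minimum-cost one-to-one matching under a distance cutoff.

    Returns index pairs (i_pred, j_truth) with pair distance <= radius in
    physical units. Unmatched predictions are FPs, unmatched truths FNs.
    """
    if not pred or not truth:
        return []
    sp = np.asarray(spacing)
    pp = np.array([d.center for d in pred]) * sp
    pt = np.array([d.center for d in truth]) * sp
    dist = np.linalg.norm(pp[:, None, :] - pt[None, :, :], axis=2)
    cost = np.where(dist <= radius, dist, _UNMATCHABLE)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if dist[i, j] <= radius]


def _match_graphs(
    pred: TrackGraph, truth: TrackGraph, radius: float, spacing
) -> dict[tuple[int, int], tuple[int, int]]:
    """Per-timepoint detection matching; pred key -> truth key."""
    mapping: dict[tuple[int, int], tuple[int, int]] = {}
    for t in sorted(set(pred.timepoints()) | set(truth.timepoints())):
        p = pred.detections(t)
        g = truth.detections(t)
        for i, j in match_detections(p, g, radius, spacing):
            mapping[p[i].key] = g[j].key
    return mapping


def count_detection_errors(
    pred: TrackGraph,
    truth: TrackGraph,
    radius: float,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> ErrorTally:
    """Tally detection TP/FP/FN over all timepoints."""
    tally = ErrorTally()
    for t in sorted(set(pred.timepoints()) | set(truth.timepoints())):
        p = pred.detections(t)
        g = truth.detections(t)
        matches = match_detections(p, g, radius, spacing)
        tally.det_tp += len(matches)
        tally.det_fp += len(p) - len(matches)
        tally.det_fn += len(g) - len(matches)
    return tally


def count_tracking_errors(
    pred: TrackGraph,
    truth: TrackGraph,
    radius: float,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    include_fp_detection_edges: bool = True,
) -> ErrorTally:
    """Tally detection and edge-level tracking errors (see module docstring)."""
    tally = count_detection_errors(pred, truth, radius, spacing)
    mapping = _match_graphs(pred, truth, radius, spacing)
    reverse = {v: k for k, v in mapping.items()}
    pred_edges_mapped = {
        (mapping[a], mapping[b])
        for a, b in pred.edges
        if a in mapping and b in mapping
    }
    for a, b in truth.edges:
        if (a, b) in pred_edges_mapped:
            tally.trk_tp += 1
        elif a not in reverse or b not in reverse:
            tally.trk_fn_missing_detection += 1
        else:
            tally.trk_fn_missed_link += 1
    for a, b in pred.edges:
        if a not in mapping or b not in mapping:
            if include_fp_detection_edges:
                tally.trk_fp += 1
        elif (mapping[a], mapping[b]) not in truth.edges:
            tally.trk_fp += 1
    return tally


# ---------------------------------------------------------------------------
# per-timepoint / per-depth series
# ---------------------------------------------------------------------------

def tallies_by_timepoint(
    pred: TrackGraph,
    truth: TrackGraph,
    radius: float,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    include_fp_detection_edges: bool = True,
) -> dict[int, ErrorTally]:
    """Per-timepoint tallies; each edge is attributed to its earlier frame."""
    mapping = _match_graphs(pred, truth, radius, spacing)
    reverse = {v: k for k, v in mapping.items()}
    out: dict[int, ErrorTally] = {}
    for t in sorted(set(pred.timepoints()) | set(truth.timepoints())):
        tally = ErrorTally()
        p, g = pred.detections(t), truth.detections(t)
        matched_p = sum(1 for d in p if d.key in mapping)
        tally.det_tp = matched_p
        tally.det_fp = len(p) - matched_p
        tally.det_fn = len(g) - matched_p
        out[t] = tally
    pred_edges_mapped = {
        (mapping[a], mapping[b]): (a, b)
        for a, b in pred.edges
        if a in mapping and b in mapping
    }
    for a, b in truth.edges:
        t = a[0]
        tally = out.setdefault(t, ErrorTally())
        if (a, b) in pred_edges_mapped:
            tally.trk_tp += 1
        elif a not in reverse or b not in reverse:
            tally.trk_fn_missing_detection += 1
        else:
            tally.trk_fn_missed_link += 1
    for a, b in pred.edges:
        t = a[0]
        tally = out.setdefault(t, ErrorTally())
        if a not in mapping or b not in mapping:
            if include_fp_detection_edges:
                tally.trk_fp += 1
        elif (mapping[a], mapping[b]) not in truth.edges:
            tally.trk_fp += 1
    return out


def tallies_by_depth(
    pred: TrackGraph,
    truth: TrackGraph,
    radius: float,
    n_slices: int,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    bin_size: int = 1,
) -> dict[int, ErrorTally]:
    """Detection tallies aggregated by axial position (z bin of each center)."""
    mapping = _match_graphs(pred, truth, radius, spacing)
    matched_truth = set(mapping.values())
    out = {b: ErrorTally() for b in range(int(np.ceil(n_slices / bin_size)))}

    def zbin(det: Detection) -> int:
        return min(int(det.center[0]) // bin_size, max(out) if out else 0)

    for t in truth.timepoints():
        for d in truth.detections(t):
            if d.key in matched_truth:
                out[zbin(d)].det_tp += 1
            else:
                out[zbin(d)].det_fn += 1
    for t in pred.timepoints():
        for d in pred.detections(t):
            if d.key not in mapping:
                out[zbin(d)].det_fp += 1
    return out


@dataclass
class PerformanceSeries:
    """Accuracy/precision/recall per unit (time frame or z bin)."""

    index: list[int]
    accuracy: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    window: int = 1
    raw: pd.DataFrame | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "accuracy": self.accuracy,
                "precision": self.precision,
                "recall": self.recall,
            },
            index=pd.Index(self.index, name="unit"),
        )


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking edge windows; NaNs stay missing
    inside windows that still contain defined values."""
    n = values.size
    if window <= 1:
        return values.copy()
    half_lo = (window - 1) // 2
    half_hi = window // 2
    out = np.empty(n)
    for i in range(n):
        seg = values[max(0, i - half_lo) : min(n, i + half_hi + 1)]
        finite = seg[np.isfinite(seg)]
        out[i] = finite.mean() if finite.size else np.nan
    return out


def _series(tallies: dict[int, ErrorTally], which: str, window: int) -> PerformanceSeries:
    index = sorted(tallies)
    prefix = "trk_" if which == "tracking" else "det_"
    raw = pd.DataFrame(
        {
            m: [getattr(tallies[t], prefix + m) for t in index]
            for m in ("accuracy", "precision", "recall")
        },
        index=pd.Index(index, name="unit"),
    )
    return PerformanceSeries(
        index=index,
        accuracy=_moving_average(raw["accuracy"].to_numpy(), window),
        precision=_moving_average(raw["precision"].to_numpy(), window),
        recall=_moving_average(raw["recall"].to_numpy(), window),
        window=window,
        raw=raw,
    )


def performance_by_time(
    tallies: dict[int, ErrorTally], window: int = 10, which: str = "tracking"
) -> PerformanceSeries:
    """Per-timepoint performance smoothed with a centered moving average
    (10 frames by default); undefined 0/0 frames propagate as missing."""
    return _series(tallies, which, window)


def performance_by_depth(
    tallies: dict[int, ErrorTally], which: str = "detection"
) -> PerformanceSeries:
    """Per-z-bin performance (no smoothing)."""
    return _series(tallies, which, window=1)
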