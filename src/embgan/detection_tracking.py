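"""Difference-of-Gaussians nucleus detection and greedy track linking.

This is a deliberately minimal stand-in for a full lineaging pipeline's
detection and linking stages: band-pass blob detection on the nucleus
probability maps (local maxima of a difference of Gaussians above an
intensity threshold, with non-maximum suppression at the minimum diameter)
and greedy nearest-neighbor linking between consecutive frames with support
for divisions (a parent may claim a second daughter). Distances are computed
in physical units so the axial anisotropy of the stacks is respected.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter, maximum_filter

from .trackgraph import Detection, TrackGraph
from .volumes import ImageVolume

__all__ = ["detect_nuclei", "link_tracks"]


def _physical(center: np.ndarray, spacing: tuple[float, float, float]) -> np.ndarray:
    return np.asarray(center) * np.asarray(spacing)


def _estimate_diameter(
    response: np.ndarray,
    peak: tuple[int, int, int],
    spacing: tuple[float, float, float],
    max_radius_vox: int,
) -> float:
    """Equivalent-sphere diameter of the half-max region around a peak."""
    z, y, x = peak
    r = max_radius_vox
    lo = np.maximum([z - r, y - r, x - r], 0)
    hi = np.minimum([z + r + 1, y + r + 1, x + r + 1], response.shape)
    patch = response[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    above = patch >= 0.5 * response[z, y, x]
    voxel_volume = float(np.prod(spacing))
    volume = above.sum() * voxel_volume
    return float(2.0 * (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0))


def detect_nuclei(
    prob: ImageVolume,
    sigma_small: float,
    sigma_large: float,
    intensity_threshold: float,
    diameter_limits: tuple[float, float],
    exclude_border: int = 1,
) -> list[Detection]:
    """Detect nuclei as DoG local maxima above a threshold.

    ``sigma_small``/``sigma_large`` are in-plane scales in physical units;
    axial sigmas are scaled by the volume's anisotropy. Peaks within
    ``exclude_border`` voxels of the volume faces are discarded (the
    band-pass response is unreliable at the filter boundary). Detections
    closer together than the minimum diameter are suppressed in score order,
    the diameter is estimated from the half-max support of the DoG response,
    and detections outside ``diameter_limits`` (physical units) are dropped.
    Returned sorted by score descending with ids 0..n-1.
    """
    if sigma_small >= sigma_large:
        raise ValueError("sigma_small must be < sigma_large")
    data = np.asarray(prob.data, dtype=np.float64)
    spacing = prob.spacing_um
    sig_s = (sigma_small / spacing[0], sigma_small / spacing[1], sigma_small / spacing[2])
    sig_l = (sigma_large / spacing[0], sigma_large / spacing[1], sigma_large / spacing[2])
    dog = gaussian_filter(data, sig_s) - gaussian_filter(data, sig_l)
    footprint_size = tuple(
        max(3, int(2 * np.ceil(sigma_small / s) + 1)) for s in spacing
    )
    local_max = (dog == maximum_filter(dog, size=footprint_size)) & (
        dog > intensity_threshold
    )
    b = int(exclude_border)
    if b > 0:
        border = np.zeros_like(local_max)
        border[b:-b, b:-b, b:-b] = True
        local_max &= border
    peaks = np.argwhere(local_max)
    if peaks.size == 0:
        return []
    scores = dog[tuple(peaks.T)]
    order = np.argsort(-scores, kind="stable")
    peaks, scores = peaks[order], scores[order]
    # non-maximum suppression at the minimum diameter (physical units)
    min_diam, max_diam = diameter_limits
    kept: list[int] = []
    kept_phys: list[np.ndarray] = []
    for i in range(len(peaks)):
        p = _physical(peaks[i], spacing)
        if all(np.linalg.norm(p - q) >= min_diam for q in kept_phys):
            kept.append(i)
            kept_phys.append(p)
    max_radius_vox = int(np.ceil(max_diam / min(spacing)))
    detections = []
    for i in kept:
        z, y, x = peaks[i]
        diameter = _estimate_diameter(dog, (z, y, x), spacing, max_radius_vox)
        if not (min_diam <= diameter <= max_diam):
            continue
        detections.append(
            Detection(
                id=len(detections),
                timepoint=prob.timepoint,
                center=np.array([z, y, x], dtype=np.float64),
                diameter=diameter,
                score=float(scores[i]),
            )
        )
    return detections


def link_tracks(
    frames: list[list[Detection]],
    max_displacement: float,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> TrackGraph:
    """Greedily link detections across consecutive frames.

    First pass links mutually closest unclaimed pairs within
    ``max_displacement`` (physical units), in order of increasing distance
    with ties broken by the lower (timepoint, id) pair. Second pass assigns
    each remaining detection at t+1 to the nearest already-linked parent
    within range that still has out-degree 1, creating a division edge.
    Orphans (track starts/ends) are allowed.
    """
    graph = TrackGraph()
    for dets in frames:
        for d in dets:
            graph.add_detection(d)
    for t_index in range(len(frames) - 1):
        cur, nxt = frames[t_index], frames[t_index + 1]
        if not cur or not nxt:
            continue
        pc = np.array([_physical(d.center, spacing) for d in cur])
        pn = np.array([_physical(d.center, spacing) for d in nxt])
        dist = np.linalg.norm(pc[:, None, :] - pn[None, :, :], axis=2)
        candidates = [
            (dist[i, j], cur[i].id, nxt[j].id, i, j)
            for i in range(len(cur))
            for j in range(len(nxt))
            if dist[i, j] <= max_displacement
        ]
        candidates.sort()
        used_i: set[int] = set()
        used_j: set[int] = set()
        for _, _, _, i, j in candidates:
            if i in used_i or j in used_j:
                continue
            graph.add_edge(cur[i].key, nxt[j].key)
            used_i.add(i)
            used_j.add(j)
        # division pass: unclaimed daughters attach to the nearest linked parent
        for _, _, _, i, j in candidates:
            if j in used_j:
                continue
            if i not in used_i:
                continue  # an unlinked parent cannot branch
            if len(graph.successors(cur[i].key)) >= 2:
                continue
            graph.add_edge(cur[i].key, nxt[j].key)
            used_j.add(j)
    return graph
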