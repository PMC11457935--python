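"""Pre- and postprocessing around segmentor inference.

The pipeline mirrors common microscopy practice: per-volume linear contrast
adjustment with a bounded saturation budget, conversion to 8-bit, slice-wise
export for the 2D network, reassembly of the per-slice outputs into a stack,
and a clip-and-shift that discards strongly negative scores (the network
output is unbounded; adding a fixed offset and clamping at zero keeps the
weak-negative context while zeroing confident background).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import ImageVolume

__all__ = [
    "ContrastParams",
    "autocontrast_8bit",
    "split_slices",
    "reassemble",
    "clip_shift",
]


@dataclass(frozen=True)
class ContrastParams:
    """Saturation budget for linear autocontrast.

    ``saturated_fraction`` bounds the fraction of pixels allowed to clip to
    pure black or white; the budget is split equally between the two tails.
    The default 0.35% matches the standard Fiji-style contrast adjustment.
    """

    saturated_fraction: float = 0.0035

    def __post_init__(self):
        if not 0.0 <= self.saturated_fraction < 1.0:
            raise ValueError("saturated_fraction must be in [0, 1)")


def _tail_cutoffs(flat_sorted: np.ndarray, budget_per_tail: int):
    """Lowest/highest retained values given a per-tail clipping budget."""
    uniq, counts = np.unique(flat_sorted, return_counts=True)
    cum = np.cumsum(counts)  # cum[i] = #(v <= uniq[i])
    n = flat_sorted.size
    # lo: largest value such that #(v < lo) <= budget
    j = np.searchsorted(cum, budget_per_tail, side="right")
    lo = uniq[min(j, uniq.size - 1)]
    # hi: smallest value such that #(v > hi) <= budget
    i = np.searchsorted(cum, n - budget_per_tail, side="left")
    hi = uniq[min(i, uniq.size - 1)]
    return lo, hi


def autocontrast_8bit(
    volume: ImageVolume, params: ContrastParams = ContrastParams()
) -> ImageVolume:
    """Linearly rescale a volume to 8-bit with a bounded saturation budget.

    Cutoffs are chosen from the intensity histogram so the number of clipped
    pixels (below the low cutoff or above the high one) is maximal subject to
    ``saturated_fraction * N``, split equally between tails. Values between
    the cutoffs map linearly into [1, 254]; only clipped pixels reach 0 or
    255. A constant-valued volume returns mid-gray (128) rather than raising.
    """
    data = np.asarray(volume.data, dtype=np.float64)
    if data.size == 0:
        raise ValueError("empty volume")
    flat = np.sort(data.ravel())
    if flat[0] == flat[-1]:
        return volume.like(np.full(data.shape, 128, dtype=np.uint8))
    budget = int(params.saturated_fraction * flat.size / 2.0)
    lo, hi = _tail_cutoffs(flat, budget)
    if lo >= hi:  # nearly constant: fall back to full range
        lo, hi = flat[0], flat[-1]
    f = (data - lo) / (hi - lo)
    out = np.rint(1.0 + f * 253.0)
    out[data < lo] = 0.0
    out[data > hi] = 255.0
    return volume.like(np.clip(out, 0, 255).astype(np.uint8))


def split_slices(volume: ImageVolume) -> list[np.ndarray]:
    """Export a volume as an ordered list of 2D slices (z ascending)."""
    return [np.array(volume.data[z]) for z in range(volume.n_slices)]


def reassemble(
    slices: list[np.ndarray],
    z_count: int | None = None,
    like: ImageVolume | None = None,
) -> ImageVolume:
    """Stack 2D slices back into a volume; inverse of :func:`split_slices`."""
    if len(slices) == 0:
        raise ValueError("cannot reassemble an empty slice list")
    if z_count is not None and len(slices) != z_count:
        raise ValueError(f"expected {z_count} slices, got {len(slices)}")
    shapes = {np.shape(s) for s in slices}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent slice shapes: {sorted(shapes)}")
    data = np.stack([np.asarray(s) for s in slices], axis=0)
    if like is not None:
        return like.like(data)
    return ImageVolume(data)


def clip_shift(volume: ImageVolume, offset: float = 4.0) -> ImageVolume:
    """Add ``offset`` and clamp negatives to zero: ``max(v + offset, 0)``."""
    data = np.asarray(volume.data, dtype=np.float64)
    return volume.like(np.maximum(data + offset, 0.0))
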