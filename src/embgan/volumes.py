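"""In-memory containers for 3D image and mask volumes.

Conventions used throughout the package: arrays are indexed ``(z, y, x)``
with 0-based voxel coordinates; the z axis is the slice axis of the
multi-page TIFF on disk. Voxel spacing is carried as ``(dz, dy, dx)`` in
micrometres so that downstream linking and matching can work in physical
units despite the axial anisotropy (z steps of 0.75 um vs sub-micron pixels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageVolume", "MaskVolume"]

DEFAULT_SPACING = (0.75, 0.5, 0.5)


@dataclass
class ImageVolume:
    """One 3D grayscale stack at one timepoint."""

    data: np.ndarray
    spacing_um: tuple[float, float, float] = DEFAULT_SPACING
    timepoint: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D (z,y,x), got {self.data.shape}")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def anisotropy(self) -> float:
        """Ratio of z spacing to (mean) in-plane spacing."""
        dz, dy, dx = self.spacing_um
        return dz / ((dy + dx) / 2.0)

    def like(self, data: np.ndarray) -> "ImageVolume":
        """A new volume with the same geometry but different data."""
        return type(self)(data, spacing_um=self.spacing_um, timepoint=self.timepoint)


@dataclass
class MaskVolume(ImageVolume):
    """Per-voxel nucleus label, binary or soft, voxel-aligned with its image."""

    soft: bool = field(default=False)
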