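"""Core volume containers shared across the pipeline.

Volumes are stored as (z, y, x) arrays with per-axis spacing in mm. Thick-
slice clinical studies are strongly anisotropic (typically 5 mm slices with
sub-millimetre in-plane pixels), so every distance computed in the package
goes through `spacing` rather than voxel indices.

Label codes: 0 background, 1 WMH, 2 other intracranial lesion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BACKGROUND, WMH, OTHER_LESION = 0, 1, 2


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive values, got {spacing}")
    return spacing


@dataclass
class ImageVolume:
    """One modality's 3D intensity array with physical spacing."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    modality: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("ImageVolume data must be 3D (z, y, x)")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class LabelVolume:
    """Integer 3D label array, geometry-matched to its images."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("LabelVolume data must be 3D (z, y, x)")
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.array_equal(self.data, np.round(self.data)):
                raise ValueError("LabelVolume data must be integer-valued")
            self.data = self.data.astype(np.int16)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def mask(self, code: int) -> np.ndarray:
        return self.data == code


def check_geometry(*volumes) -> None:
    """Raise if the volumes do not share shape and spacing."""
    ref = volumes[0]
    for v in volumes[1:]:
        if tuple(v.shape) != tuple(ref.shape):
            raise ValueError(f"shape mismatch: {v.shape} vs {ref.shape}")
        sa = getattr(v, "spacing", None)
        sb = getattr(ref, "spacing", None)
        if sa is not None and sb is not None and not np.allclose(sa, sb):
            raise ValueError(f"spacing mismatch: {sa} vs {sb}")


def as_array(volume) -> np.ndarray:
    """Accept an ImageVolume/LabelVolume or a bare ndarray."""
    if isinstance(volume, (ImageVolume, LabelVolume)):
        return volume.data
    return np.asarray(volume)
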