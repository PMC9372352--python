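"""In-package preprocessing: quantile normalization, in-plane resampling,
brain-mask application.

Bias-field correction, inter-modality registration, and skull stripping are
performed by external tools upstream; this module consumes their outputs
and asserts co-registration (identical geometry) instead of re-implementing
them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import ImageVolume, LabelVolume, as_array

__all__ = ["NormalizationParams", "quantile_normalize", "resample_xy",
           "apply_brain_mask", "nearest_rank_quantile"]


@dataclass(frozen=True)
class NormalizationParams:
    """Intensity landmarks of the [0, 1] rescaling: the 0.1% and 99.9%
    quantiles of the (masked) intensity distribution."""

    p_low: float
    p_high: float

    def __post_init__(self):
        if self.p_low > self.p_high:
            raise ValueError("p_low must not exceed p_high")


def nearest_rank_quantile(sorted_values: np.ndarray, q: float) -> float:
    """Nearest-rank quantile on an ascending array: value at rank ceil(q*n)."""
    n = sorted_values.size
    rank = max(int(np.ceil(q * n)), 1)
    return float(sorted_values[rank - 1])


def quantile_normalize(volume: ImageVolume, mask: np.ndarray | None = None
                       ) -> tuple[ImageVolume, NormalizationParams]:
    """Rescale intensities to [0, 1] between the 0.1% and 99.9% quantiles.

    I' = 0 below the low landmark, 1 above the high landmark, and linear in
    between. Quantiles are computed by the nearest-rank rule on the sorted
    intensities of the mask region (whole volume if no mask): after skull
    stripping the background zeros would otherwise dominate the low tail.
    """
    data = volume.data
    region = data[as_array(mask).astype(bool)] if mask is not None else data
    vals = np.sort(region.ravel())
    if vals.size < 2:
        raise ValueError(f"too few voxels to normalize ({volume.modality!r})")
    p_low = nearest_rank_quantile(vals, 0.001)
    p_high = nearest_rank_quantile(vals, 0.999)
    if p_low == p_high:
        raise ValueError(
            f"constant intensities in {volume.modality or 'volume'}: "
            f"quantile normalization undefined")
    out = (data - p_low) / (p_high - p_low)
    np.clip(out, 0.0, 1.0, out=out)
    return (ImageVolume(out, volume.spacing, modality=volume.modality),
            NormalizationParams(p_low, p_high))


def resample_xy(volume, target_xy_spacing: float, interpolation: str = "linear"):
    """Resample the in-plane (y, x) axes to `target_xy_spacing` mm.

    The z axis is untouched (thick slices are left at their native
    thickness). Images use linear interpolation, labels and masks nearest
    neighbour. A volume already at the target spacing is returned unchanged.
    """
    if target_xy_spacing <= 0:
        raise ValueError("target spacing must be positive")
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    sz, sy, sx = volume.spacing
    if np.isclose(sy, target_xy_spacing) and np.isclose(sx, target_xy_spacing):
        return volume
    data = volume.data
    zoom = (1.0, sy / target_xy_spacing, sx / target_xy_spacing)
    order = 1 if interpolation == "linear" else 0
    is_label = isinstance(volume, LabelVolume)
    work = data.astype(np.float64) if not is_label else data
    res = ndimage.zoom(work, zoom, order=0 if is_label else order,
                       mode="nearest", grid_mode=True)
    new_spacing = (sz, target_xy_spacing, target_xy_spacing)
    if is_label:
        return LabelVolume(res, new_spacing)
    return ImageVolume(res, new_spacing, modality=volume.modality)


def apply_brain_mask(volume: ImageVolume, brain_mask: np.ndarray) -> ImageVolume:
    """Zero all voxels outside the brain mask; leave the rest unchanged."""
    mask = as_array(brain_mask).astype(bool)
    if mask.shape != volume.data.shape:
        raise ValueError(f"mask shape {mask.shape} does not match "
                         f"volume shape {volume.data.shape}")
    return ImageVolume(np.where(mask, volume.data, 0.0), volume.spacing,
                       modality=volume.modality)
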