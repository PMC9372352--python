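"""WMH subclassification by distance from the ventricles.

Kim's four-category scheme: juxtaventricular (JVWMH, within 3 mm of the
ventricle), periventricular (PWMH, 3-13 mm), juxtacortical (JCWMH, within
4 mm of the corticomedullary junction), and deep (DWMH, the residual
region between PWMH and JCWMH). Precedence is ventricle-first
(JV -> PV -> JC -> DW) and band edges are inclusive ("within N mm"). The
traditional two-category Fazekas-style split uses a single 10 mm ventricle
threshold. Distances are exact Euclidean distance transforms in physical
mm, honouring anisotropic thick-slice spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import as_array

__all__ = ["DistanceMap", "SubclassMap", "distance_map", "classify_kim4",
           "classify_fazekas2", "subclass_volumes", "SUBCLASS_CODES"]

SUBCLASS_CODES = {"none": 0, "jvwmh": 1, "pwmh": 2, "dwmh": 3, "jcwmh": 4}
_CODE_NAMES = {v: k for k, v in SUBCLASS_CODES.items()}


@dataclass
class DistanceMap:
    distances: np.ndarray  # mm
    reference: str  # "ventricle" or "cortex"
    spacing: tuple[float, float, float]


@dataclass
class SubclassMap:
    labels: np.ndarray
    scheme: str  # "kim4" or "fazekas2"
    spacing: tuple[float, float, float]


def distance_map(reference_mask, brain_mask, spacing,
                 reference: str = "ventricle") -> DistanceMap:
    """Exact anisotropic Euclidean distance (mm) to the reference structure.

    Zero on the reference itself; computed everywhere (the brain mask only
    scopes downstream use, it does not gate the transform).
    """
    ref = as_array(reference_mask).astype(bool)
    brain = as_array(brain_mask).astype(bool)
    if not (ref & brain).any():
        raise ValueError(f"empty {reference} reference mask within brain")
    dist = ndimage.distance_transform_edt(~ref, sampling=spacing)
    return DistanceMap(dist, reference, tuple(float(s) for s in spacing))


def classify_kim4(wmh_mask, ventricle_dist: DistanceMap,
                  cortex_dist: DistanceMap) -> SubclassMap:
    """Partition WMH voxels into JV/PV/DW/JC by Kim's distance criteria."""
    wmh = as_array(wmh_mask).astype(bool)
    vd, cd = ventricle_dist.distances, cortex_dist.distances
    if wmh.shape != vd.shape or wmh.shape != cd.shape:
        raise ValueError("distance maps must match the WMH mask geometry")
    labels = np.zeros(wmh.shape, dtype=np.int8)
    labels[wmh & (vd <= 3.0)] = SUBCLASS_CODES["jvwmh"]
    labels[wmh & (vd > 3.0) & (vd <= 13.0)] = SUBCLASS_CODES["pwmh"]
    rest = wmh & (vd > 13.0)
    labels[rest & (cd <= 4.0)] = SUBCLASS_CODES["jcwmh"]
    labels[rest & (cd > 4.0)] = SUBCLASS_CODES["dwmh"]
    return SubclassMap(labels, "kim4", ventricle_dist.spacing)


def classify_fazekas2(wmh_mask, ventricle_dist: DistanceMap) -> SubclassMap:
    """Two-category split: PWMH within 10 mm of the ventricle, else DWMH."""
    wmh = as_array(wmh_mask).astype(bool)
    vd = ventricle_dist.distances
    if wmh.shape != vd.shape:
        raise ValueError("distance map must match the WMH mask geometry")
    labels = np.zeros(wmh.shape, dtype=np.int8)
    labels[wmh & (vd <= 10.0)] = SUBCLASS_CODES["pwmh"]
    labels[wmh & (vd > 10.0)] = SUBCLASS_CODES["dwmh"]
    return SubclassMap(labels, "fazekas2", ventricle_dist.spacing)


def subclass_volumes(subclass: SubclassMap, spacing=None,
                     icv_mm3: float | None = None) -> pd.DataFrame:
    """Absolute (mm^3) and %ICV volume of each WMH subclass.

    Classes partition the WMH mask, so the per-class volumes sum exactly to
    the total WMH volume.
    """
    sp = tuple(spacing) if spacing is not None else subclass.spacing
    if icv_mm3 is not None and icv_mm3 <= 0:
        raise ValueError("icv_mm3 must be positive")
    voxel = float(np.prod(sp))
    rows = []
    for code in sorted(np.unique(subclass.labels)):
        if code == 0:
            continue
        count = int((subclass.labels == code).sum())
        vol = count * voxel
        rows.append({
            "scheme": subclass.scheme,
            "class": _CODE_NAMES[int(code)],
            "voxels": count,
            "volume_mm3": vol,
            "percent_icv": (vol / icv_mm3 * 100.0) if icv_mm3 else float("nan"),
        })
    return pd.DataFrame(rows, columns=["scheme", "class", "voxels",
                                       "volume_mm3", "percent_icv"])
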