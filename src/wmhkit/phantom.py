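"""Synthetic multi-modal thick-slice brain studies with known ground truth.

Each phantom emulates a routine clinical 2D axial acquisition: an
ellipsoidal brain with lateral-ventricle CSF structures and a cortical
ribbon, imaged in three co-registered modalities (T1-weighted, T2-weighted,
FLAIR) on an anisotropic grid (~5 mm slices, ~1 mm in-plane). WMH lesions
are irregular blobs placed into ventricle-distance bands — juxtaventricular
(<= 3 mm), periventricular (3-13 mm), deep, and juxtacortical (<= 4 mm from
the corticomedullary junction) — and are hyperintense on FLAIR/T2 and
hypointense on T1. "Other lesion" blobs (label 2) sit in cortical /
juxtacortical positions with near-CSF T1 signal, so that only multi-modal
information separates them from WMH.

A pair of simulated raters with controllable boundary disagreement makes
the label-fusion and weighted-loss machinery testable without real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import ImageVolume, LabelVolume, OTHER_LESION, WMH

__all__ = ["PhantomSpec", "PhantomStudy", "generate_phantom", "simulate_raters",
           "BAND_NAMES", "TISSUE_MEANS"]

BAND_NAMES = ("juxtaventricular", "periventricular", "deep", "juxtacortical")

# Per-modality mean intensities on the normalized [0, 1] scale.
# CSF is suppressed on FLAIR; WMH is bright on FLAIR/T2 and dark-ish on T1;
# the "other lesion" class mimics PVS/infarct: near-CSF on T1, bright on T2.
TISSUE_MEANS = {
    #            t1    t2    flair
    "wm":      (0.70, 0.35, 0.40),
    "gm":      (0.55, 0.45, 0.50),
    "csf":     (0.15, 0.90, 0.12),
    "wmh":     (0.45, 0.70, 0.85),
    "other":   (0.20, 0.85, 0.80),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, lesion load, and noise settings of one synthetic study."""

    shape: tuple[int, int, int] = (18, 128, 128)
    spacing: tuple[float, float, float] = (5.0, 1.0, 1.0)
    n_wmh_lesions: int = 6
    n_other_lesions: int = 2
    wmh_distance_profile: tuple[float, float, float, float] = (0.25, 0.35, 0.25, 0.15)
    noise_sigma: float = 0.03
    rater_disagreement: float = 0.3
    seed: int = 0
    flair_margin: float = 0.2  # min FLAIR contrast of WMH over white matter

    def __post_init__(self):
        if any(s <= 0 for s in self.shape):
            raise ValueError("shape must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.spacing[0] < max(self.spacing[1], self.spacing[2]):
            raise ValueError("thick-slice regime requires z-spacing >= in-plane")
        w = self.wmh_distance_profile
        if len(w) != 4 or any(x < 0 for x in w) or not np.isclose(sum(w), 1.0):
            raise ValueError("wmh_distance_profile must be 4 non-negative "
                             "weights summing to 1")
        if not 0.0 <= self.rater_disagreement <= 1.0:
            raise ValueError("rater_disagreement must be in [0, 1]")
        if self.n_wmh_lesions < 0 or self.n_other_lesions < 0:
            raise ValueError("lesion counts must be non-negative")


@dataclass
class PhantomStudy:
    """Co-registered multi-modal phantom with masks and ground truth."""

    t1: ImageVolume
    t2: ImageVolume
    flair: ImageVolume
    brain_mask: np.ndarray
    ventricle_mask: np.ndarray
    truth: LabelVolume
    icv_mm3: float
    spec: PhantomSpec | None = None
    cortex_mask: np.ndarray | None = None

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.t1.spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.t1.shape


class BandPlacementError(RuntimeError):
    """A requested lesion could not be placed in its distance band."""


def _mm_grid(shape, spacing):
    zz, yy, xx = np.meshgrid(
        np.arange(shape[0]) * spacing[0],
        np.arange(shape[1]) * spacing[1],
        np.arange(shape[2]) * spacing[2],
        indexing="ij")
    return zz, yy, xx


def _ellipsoid(shape, spacing, center_mm, semi_mm) -> np.ndarray:
    zz, yy, xx = _mm_grid(shape, spacing)
    return ((zz - center_mm[0]) / semi_mm[0]) ** 2 + \
           ((yy - center_mm[1]) / semi_mm[1]) ** 2 + \
           ((xx - center_mm[2]) / semi_mm[2]) ** 2 <= 1.0


def _anatomy(spec: PhantomSpec):
    """Brain, ventricles, cortical ribbon on the spec's grid."""
    shape, spacing = spec.shape, spec.spacing
    extent = tuple(n * s for n, s in zip(shape, spacing))
    center = tuple(e / 2 for e in extent)
    brain = _ellipsoid(shape, spacing, center,
                       (0.44 * extent[0], 0.44 * extent[1], 0.44 * extent[2]))
    # two mirrored lateral-ventricle lobes, elongated front-to-back
    vz = 0.20 * extent[0]
    vent = np.zeros(shape, dtype=bool)
    for side in (-1, 1):
        c = (center[0], center[1], center[2] + side * 0.10 * extent[2])
        vent |= _ellipsoid(shape, spacing, c,
                           (vz, 0.18 * extent[1], 0.055 * extent[2]))
    vent &= brain
    # cortical ribbon: brain voxels within 3 mm of the outside
    depth = ndimage.distance_transform_edt(brain, sampling=spacing)
    cortex = brain & (depth <= 3.0)
    return brain, vent, cortex


def _blob(rng: np.random.Generator, domain: np.ndarray, spec: PhantomSpec,
          existing: np.ndarray, max_tries: int = 60) -> np.ndarray | None:
    """Grow an irregular blob inside `domain`, disjoint from `existing`.

    Blobs are thresholded smoothed noise around a seed voxel, restricted to
    the slice of the seed (thick-slice lesions are mostly in-plane) and to
    the domain, then reduced to the connected component containing the seed.
    """
    candidates = np.flatnonzero(domain & ~existing)
    if candidates.size == 0:
        return None
    shape = domain.shape
    for _ in range(max_tries):
        seed_flat = rng.choice(candidates)
        z, y, x = np.unravel_index(seed_flat, shape)
        r = int(rng.integers(3, 8))  # in-plane half-extent in voxels
        y0, y1 = max(y - r, 0), min(y + r + 1, shape[1])
        x0, x1 = max(x - r, 0), min(x + r + 1, shape[2])
        noise = rng.normal(size=(y1 - y0, x1 - x0))
        field = ndimage.gaussian_filter(noise, sigma=1.5)
        # radial bump keeps the blob centred on the seed
        yy, xx = np.meshgrid(np.arange(y0, y1), np.arange(x0, x1), indexing="ij")
        rad = np.sqrt((yy - y) ** 2 + (xx - x) ** 2) / max(r, 1)
        field = field - field.mean() + 1.2 * (1.0 - rad)
        blob2d = field > 0.55
        mask = np.zeros(shape, dtype=bool)
        mask[z, y0:y1, x0:x1] = blob2d
        mask &= domain & ~existing
        if not mask[z, y, x]:
            continue
        lab, _ = ndimage.label(mask[z], structure=np.ones((3, 3), dtype=bool))
        comp = lab == lab[y, x]
        mask[:] = False
        mask[z] = comp
        if mask.sum() >= 4:
            return mask
    return None


def generate_phantom(spec: PhantomSpec) -> PhantomStudy:
    """Generate a seeded multi-modal phantom study with ground-truth labels.

    Deterministic for a fixed spec (bit-identical volumes on repeat calls).
    Raises :class:`BandPlacementError` naming the first distance band in
    which a requested WMH lesion could not be placed.
    """
    rng = np.random.default_rng(spec.seed)
    brain, vent, cortex = _anatomy(spec)
    vdist = ndimage.distance_transform_edt(~vent, sampling=spec.spacing)
    cdist = ndimage.distance_transform_edt(~cortex, sampling=spec.spacing)

    white = brain & ~vent & ~cortex
    bands = {
        "juxtaventricular": white & (vdist <= 3.0),
        "periventricular": white & (vdist > 3.0) & (vdist <= 13.0),
        "deep": white & (vdist > 13.0) & (cdist > 4.0),
        "juxtacortical": white & (vdist > 13.0) & (cdist <= 4.0),
    }

    truth = np.zeros(spec.shape, dtype=np.int16)
    lesion_bands = rng.choice(4, size=spec.n_wmh_lesions,
                              p=np.asarray(spec.wmh_distance_profile))
    for band_idx in lesion_bands:
        name = BAND_NAMES[band_idx]
        blob = _blob(rng, bands[name], spec, truth > 0)
        if blob is None:
            raise BandPlacementError(
                f"could not place a WMH lesion in the {name} band")
        truth[blob] = WMH
    other_domain = brain & (cdist <= 6.0) & ~vent
    for _ in range(spec.n_other_lesions):
        blob = _blob(rng, other_domain, spec, truth > 0)
        if blob is None:
            raise BandPlacementError(
                "could not place an other-lesion blob in the cortical band")
        truth[blob] = OTHER_LESION

    # intensity model: tissue means + Gaussian noise, per modality
    tissue = np.zeros(spec.shape, dtype=np.int8)  # 0 bg, 1 wm, 2 gm, 3 csf
    tissue[brain] = 1
    tissue[cortex] = 2
    tissue[vent] = 3
    means = {k: np.asarray(v, dtype=np.float64) for k, v in TISSUE_MEANS.items()}
    wmh_means = means["wmh"].copy()
    wmh_means[2] = means["wm"][2] + max(spec.flair_margin,
                                        wmh_means[2] - means["wm"][2])
    volumes = []
    for mi, modality in enumerate(("t1", "t2", "flair")):
        img = np.zeros(spec.shape, dtype=np.float64)
        img[tissue == 1] = means["wm"][mi]
        img[tissue == 2] = means["gm"][mi]
        img[tissue == 3] = means["csf"][mi]
        img[truth == WMH] = wmh_means[mi]
        img[truth == OTHER_LESION] = means["other"][mi]
        img += rng.normal(0.0, spec.noise_sigma, size=spec.shape)
        img[~brain] = 0.0
        np.clip(img, 0.0, 1.0, out=img)
        volumes.append(ImageVolume(img, spec.spacing, modality=modality))

    icv = float(brain.sum()) * float(np.prod(spec.spacing))
    return PhantomStudy(t1=volumes[0], t2=volumes[1], flair=volumes[2],
                        brain_mask=brain, ventricle_mask=vent,
                        truth=LabelVolume(truth, spec.spacing),
                        icv_mm3=icv, spec=spec, cortex_mask=cortex)


def simulate_raters(truth: LabelVolume, spec: PhantomSpec
                    ) -> tuple[LabelVolume, LabelVolume]:
    """Two simulated delineations of `truth` with boundary disagreement.

    Each rater independently drops a `rater_disagreement` fraction of the
    one-voxel inner boundary shell of the WMH mask, computed per slice
    (disagreement in clinical delineation concentrates on the obscure lesion
    boundary; cores are preserved). Label-2 lesions pass through unchanged.
    With disagreement 0 both raters equal the truth; with disagreement 1
    both reduce to the per-slice eroded core.
    """
    p = spec.rater_disagreement
    wmh = truth.data == WMH
    struct = ndimage.generate_binary_structure(2, 1)
    inner = np.zeros_like(wmh)
    for z in range(wmh.shape[0]):
        if wmh[z].any():
            inner[z] = wmh[z] & ~ndimage.binary_erosion(wmh[z], structure=struct)
    shell_idx = np.flatnonzero(inner)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 911]))
    out = []
    for _ in range(2):
        mask = wmh.copy()
        drop = shell_idx[rng.random(shell_idx.size) < p]
        mask.ravel()[drop] = False
        lab = truth.data.copy()
        lab[wmh] = 0
        lab[mask] = WMH
        out.append(LabelVolume(lab, truth.spacing))
    return out[0], out[1]
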