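"""NIfTI-based study input/output.

Studies live as directories of .nii.gz files (t1, t2, flair, brain_mask,
ventricle_mask, truth) plus a JSON sidecar recording the generating spec
or preprocessing state. Volumes are canonicalized to RAS+ orientation on
load and verified to share shape and spacing: registration is out of
scope, so geometry mismatches are hard errors naming the offending file.

Array axes are (z, y, x); the NIfTI on-disk order is (x, y, z), so arrays
are transposed at the boundary and spacing is permuted consistently.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import ImageVolume, LabelVolume
from .phantom import PhantomSpec, PhantomStudy

__all__ = ["write_study", "read_study", "write_volume", "read_volume",
           "StudyManifest"]

_MODALITIES = ("t1", "t2", "flair")
_MASKS = ("brain_mask", "ventricle_mask")


@dataclasses.dataclass
class StudyManifest:
    subject: str
    paths: dict[str, Path]
    spacing: tuple[float, float, float] | None = None
    preprocessed: bool = False

    @classmethod
    def from_dir(cls, directory) -> "StudyManifest":
        directory = Path(directory)
        paths = {}
        for name in _MODALITIES + _MASKS + ("truth",):
            p = directory / f"{name}.nii.gz"
            if p.exists():
                paths[name] = p
        sidecar = directory / "study.json"
        pre = False
        if sidecar.exists():
            pre = bool(json.loads(sidecar.read_text()).get("preprocessed", False))
        return cls(subject=directory.name, paths=paths, preprocessed=pre)


def _affine(spacing) -> np.ndarray:
    # (z, y, x) array spacing -> NIfTI (x, y, z) diagonal affine
    aff = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    return aff


def write_volume(path, data: np.ndarray, spacing) -> None:
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = nib.Nifti1Image(np.ascontiguousarray(arr.transpose(2, 1, 0)),
                          _affine(spacing))
    nib.save(img, str(path))


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.as_closest_canonical(nib.load(str(path)))
    zooms = img.header.get_zooms()[:3]
    data = np.asarray(img.dataobj).transpose(2, 1, 0)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return data, spacing


def write_study(study: PhantomStudy, directory, extra: dict | None = None) -> Path:
    """Write a phantom study as a directory of NIfTI files + JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sp = study.spacing
    for name in _MODALITIES:
        write_volume(directory / f"{name}.nii.gz",
                     getattr(study, name).data, sp)
    write_volume(directory / "brain_mask.nii.gz", study.brain_mask, sp)
    write_volume(directory / "ventricle_mask.nii.gz", study.ventricle_mask, sp)
    write_volume(directory / "truth.nii.gz", study.truth.data, sp)
    sidecar = {"icv_mm3": study.icv_mm3}
    if study.spec is not None:
        sidecar["spec"] = dataclasses.asdict(study.spec)
        sidecar["seed"] = study.spec.seed
    if extra:
        sidecar.update(extra)
    (directory / "study.json").write_text(json.dumps(sidecar, indent=2))
    return directory


def read_study(source) -> PhantomStudy:
    """Load a study directory (or manifest) back into a PhantomStudy.

    Verifies that all volumes share shape and spacing; a mismatch is a
    hard error naming the offending file.
    """
    manifest = source if isinstance(source, StudyManifest) else \
        StudyManifest.from_dir(source)
    missing = [m for m in _MODALITIES + _MASKS + ("truth",)
               if m not in manifest.paths]
    if missing:
        raise FileNotFoundError(f"study {manifest.subject}: missing {missing}")
    volumes, spacings = {}, {}
    for name, path in manifest.paths.items():
        volumes[name], spacings[name] = read_volume(path)
    ref_name = _MODALITIES[0]
    ref_shape, ref_sp = volumes[ref_name].shape, spacings[ref_name]
    for name, arr in volumes.items():
        if arr.shape != ref_shape:
            raise ValueError(
                f"{manifest.paths[name]}: shape {arr.shape} does not match "
                f"{ref_name} shape {ref_shape} (studies must be co-registered)")
        if not np.allclose(spacings[name], ref_sp, atol=1e-4):
            raise ValueError(
                f"{manifest.paths[name]}: spacing {spacings[name]} does not "
                f"match {ref_name} spacing {ref_sp}")
    sidecar_path = Path(manifest.paths[ref_name]).parent / "study.json"
    icv = None
    spec = None
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        icv = sidecar.get("icv_mm3")
        if "spec" in sidecar:
            d = sidecar["spec"]
            for key in ("shape", "spacing", "wmh_distance_profile"):
                d[key] = tuple(d[key])
            spec = PhantomSpec(**d)
    brain = volumes["brain_mask"].astype(bool)
    if icv is None:
        icv = float(brain.sum()) * float(np.prod(ref_sp))
    return PhantomStudy(
        t1=ImageVolume(volumes["t1"], ref_sp, "t1"),
        t2=ImageVolume(volumes["t2"], ref_sp, "t2"),
        flair=ImageVolume(volumes["flair"], ref_sp, "flair"),
        brain_mask=brain,
        ventricle_mask=volumes["ventricle_mask"].astype(bool),
        truth=LabelVolume(np.rint(volumes["truth"]).astype(np.int16), ref_sp),
        icv_mm3=float(icv), spec=spec)
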