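"""File interchange: NIfTI volumes, YAML configs, JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .phantom import GridSpec, LabeledVolume, PhantomSpec

__all__ = [
    "save_volume_nifti",
    "load_image_nifti",
    "save_labeled_volume",
    "phantom_spec_from_yaml",
    "phantom_spec_to_yaml",
]


def _affine(spacing_mm):
    """Diagonal mm affine; (z, y, x) array order maps to (x, y, z) on disk."""
    sp = list(spacing_mm)
    if len(sp) == 2:
        sp = [1.0] + sp
    aff = np.diag([sp[2], sp[1], sp[0], 1.0])
    return aff


def save_volume_nifti(array: np.ndarray, spacing_mm, path):
    arr = np.asarray(array)
    if arr.ndim == 2:
        arr = arr[None]
    img = nib.Nifti1Image(np.ascontiguousarray(arr.transpose(2, 1, 0)), _affine(spacing_mm))
    nib.save(img, str(path))


def load_image_nifti(path) -> tuple[np.ndarray, tuple]:
    """Returns (array in (z, y, x) order, spacing_mm (z, y, x))."""
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj).transpose(2, 1, 0)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return arr, spacing


def save_labeled_volume(vol: LabeledVolume, out_dir, stem: str = "phantom"):
    """Activity + labels as NIfTI, truth map as JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sp = vol.spacing_mm
    save_volume_nifti(vol.activity, sp, out_dir / f"{stem}_activity.nii.gz")
    save_volume_nifti(vol.labels.astype(np.int16), sp, out_dir / f"{stem}_labels.nii.gz")
    sidecar = {
        "truth_kbq_ml": {str(k): v for k, v in vol.truth.items()},
        "spacing_mm": list(sp),
        "meta": {
            k: v for k, v in vol.meta.items() if not isinstance(v, np.ndarray)
        },
    }
    (out_dir / f"{stem}_truth.json").write_text(json.dumps(sidecar, indent=1))


def phantom_spec_from_yaml(path) -> tuple[PhantomSpec, GridSpec | None]:
    raw = yaml.safe_load(Path(path).read_text())
    grid = None
    if "grid" in raw:
        g = raw.pop("grid")
        grid = GridSpec(tuple(g["shape"]), tuple(g["spacing_mm"]))
    if "sphere_diameters_mm" in raw:
        raw["sphere_diameters_mm"] = tuple(raw["sphere_diameters_mm"])
    return PhantomSpec(**raw), grid


def phantom_spec_to_yaml(spec: PhantomSpec, path, grid: GridSpec | None = None):
    data = {
        "sphere_diameters_mm": list(spec.sphere_diameters_mm),
        "background_activity_kbq_ml": spec.background_activity_kbq_ml,
        "lbr": spec.lbr,
        "lung_insert": spec.lung_insert,
        "lung_diameter_mm": spec.lung_diameter_mm,
        "body_volume_ml": spec.body_volume_ml,
        "body_height_mm": spec.body_height_mm,
        "sphere_ring_radius_mm": spec.sphere_ring_radius_mm,
    }
    if grid is not None:
        data["grid"] = {"shape": list(grid.shape), "spacing_mm": list(grid.spacing_mm)}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
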