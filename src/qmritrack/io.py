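"""NIfTI and table I/O helpers (nibabel-backed)."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .mpm import ParameterMaps

#: filename suffix per parameter map
MAP_SUFFIX = {"MTsat": "_MTsat", "PD": "_PD", "R1": "_R1", "R2s": "_R2s", "A": "_A"}


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def save_volume(path, data: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(voxel_size))
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    vox = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata()), vox


def save_series(path, data4d: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> None:
    save_volume(path, data4d, voxel_size)


def save_parameter_maps(out_dir, stem: str, maps: ParameterMaps, voxel_size) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for p, suffix in MAP_SUFFIX.items():
        path = out_dir / f"{stem}{suffix}.nii.gz"
        save_volume(path, maps[p], voxel_size)
        written.append(path)
    return written


def write_json(path, obj) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
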