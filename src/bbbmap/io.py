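"""NIfTI-1 and sidecar I/O.

Images travel as NIfTI-1 volumes with the voxel size carried in the affine;
acquisition timing and kinetic parameters travel in JSON sidecars (the
sidecar wins over NIfTI time-axis metadata on conflict).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["save_nifti", "load_nifti", "save_json", "load_json", "check_same_grid"]


def save_nifti(path, data: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> Path:
    path = Path(path)
    affine = np.diag([*voxel_size, 1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms(tuple(voxel_size) + (1.0,) * (data.ndim - 3) if data.ndim > 3 else tuple(voxel_size))
    nib.save(img, str(path))
    return path


def load_nifti(path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    return data, tuple(float(z) for z in img.header.get_zooms()[:3])


def save_json(path, obj) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))
    return path


def load_json(path):
    return json.loads(Path(path).read_text())


def check_same_grid(**named_shapes) -> None:
    """Raise naming the offending pair when any two grids differ."""
    items = list(named_shapes.items())
    for (na, sa), (nb, sb) in zip(items, items[1:]):
        if tuple(sa) != tuple(sb):
            raise ValueError(f"grid mismatch between {na} {sa} and {nb} {sb}")
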