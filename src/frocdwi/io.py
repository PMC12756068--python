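"""NIfTI / sidecar / table I/O.

Volumes travel as NIfTI-1 via nibabel with the affine passed through
untouched; b-value sidecars are FSL-style single-line text; tables are
comma-separated UTF-8 CSV with a header row; reports and spec echoes are
JSON.  Coordinate convention: voxel indices, 0-based, axis order
(x, y, z, frame).
"""

from __future__ import annotations

import json
from os import PathLike
from pathlib import Path

import nibabel as nib
import numpy as np

from .fitting import ParameterMaps
from .segmentation import RoiMask

__all__ = ["load_volume", "save_volume", "write_bval", "save_parameter_maps",
           "load_mask", "save_mask", "write_json"]


def load_volume(path: str | PathLike):
    """Return (data array, affine) of a NIfTI volume."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_volume(data, path: str | PathLike, affine=None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def write_bval(b_values, path: str | PathLike) -> None:
    Path(path).write_text(" ".join(f"{b:g}" for b in b_values) + "\n")


def save_parameter_maps(maps: ParameterMaps, out_dir: str | PathLike,
                        prefix: str = "", affine=None) -> dict[str, str]:
    """Write one NIfTI per parameter map plus diagnostic volumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, arr in maps.maps.items():
        p = out / f"{prefix}{maps.model}_{name}.nii"
        save_volume(arr, p, affine)
        written[name] = str(p)
    save_volume(maps.residual, out / f"{prefix}{maps.model}_residual.nii", affine)
    save_volume(maps.mask.astype(np.float64),
                out / f"{prefix}{maps.model}_fitted_mask.nii", affine)
    for flag, arr in maps.flags.items():
        save_volume(arr.astype(np.float64),
                    out / f"{prefix}{maps.model}_flag_{flag}.nii", affine)
    return written


def load_mask(path: str | PathLike, kind: str = "3d") -> RoiMask:
    data, _ = load_volume(path)
    return RoiMask(mask=data > 0.5, kind=kind)


def save_mask(roi: RoiMask, path: str | PathLike, affine=None) -> None:
    save_volume(roi.mask.astype(np.float64), path, affine)


def write_json(obj, path: str | PathLike) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")
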