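"""Volume and table I/O: NIfTI-1 via nibabel, TSV/CSV via pandas.

All phantom volumes live on a 1 mm isotropic grid with an identity
orientation, so the affine is always ``diag(zooms, 1)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


@dataclass
class LabeledVolume:
    """A 3-D scalar grid plus voxel-size metadata.

    Used for subject image channels, integer atlas labels, and
    sensitivity maps alike.
    """

    data: np.ndarray
    zooms: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"LabeledVolume must be 3-D, got shape {self.data.shape}")


def as_array(volume) -> np.ndarray:
    """Accept a LabeledVolume or a bare ndarray and return the array."""
    return np.asarray(getattr(volume, "data", volume))


def _affine(zooms: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = zooms
    return aff


def save_nifti(path: str | Path, volume, zooms=(1.0, 1.0, 1.0)) -> Path:
    data = as_array(volume)
    zooms = getattr(volume, "zooms", zooms)
    if data.dtype.kind in "iu":
        img = nib.Nifti1Image(data.astype(np.int32), _affine(zooms))
    else:
        img = nib.Nifti1Image(data.astype(np.float64), _affine(zooms))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def load_nifti(path: str | Path) -> LabeledVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabeledVolume(data=data, zooms=zooms)


def save_model(path: str | Path, state: list[np.ndarray], meta: dict) -> Path:
    """Write model parameters as .npz plus a JSON sidecar with metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"),
             **{f"p{i:03d}": arr for i, arr in enumerate(state)})
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=_jsonable))
    return path.with_suffix(".npz")


def load_model(path: str | Path) -> tuple[list[np.ndarray], dict]:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as npz:
        state = [npz[k] for k in sorted(npz.files)]
    meta = json.loads(path.with_suffix(".json").read_text())
    return state, meta


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(path: str | Path, obj: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable))
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
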