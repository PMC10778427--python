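"""NIfTI and sidecar I/O helpers (thin wrappers over nibabel)."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["save_volume", "load_volume", "save_sidecar", "load_sidecar"]


def save_volume(path: str | Path, data: np.ndarray, affine: np.ndarray | None = None) -> Path:
    """Write a 3D map or 4D series as NIfTI-1."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data), np.eye(4) if affine is None else affine)
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI file; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_sidecar(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)
    return path


def load_sidecar(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
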