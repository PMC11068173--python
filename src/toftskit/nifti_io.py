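"""NIfTI-1 persistence with JSON sidecars for time-axis metadata.

3-D maps round-trip through nibabel with the grid geometry encoded in
the affine. 4-D series additionally carry a JSON sidecar (same path,
``.json`` suffix) holding the acquisition timing that NIfTI itself does
not store: temporal resolution and baseline-frame count for DCE, flip
angles for VFA stacks, b-values for DWI stacks.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import GridGeometry

__all__ = [
    "save_map", "load_map", "save_series", "load_series",
    "read_bvals", "SIDECAR_KEY_SETS",
]

#: a 4-D series sidecar must contain at least one of these key sets
SIDECAR_KEY_SETS = (
    ("temporal_resolution_s", "n_baseline"),  # DCE
    ("flip_angles_deg",),  # VFA
    ("b_values",),  # DWI
)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + ".json")
    return path.with_suffix(".json")


def save_map(data: np.ndarray, geometry: GridGeometry, path) -> Path:
    """Write a 3-D volume (or mask) as NIfTI-1 with the grid affine."""
    path = Path(path)
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = nib.Nifti1Image(arr, geometry.affine())
    nib.save(img, path)
    return path


def load_map(path) -> tuple[np.ndarray, GridGeometry]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    geom = GridGeometry.from_affine(tuple(data.shape[:3]), img.affine)
    return data, geom


def save_series(data: np.ndarray, geometry: GridGeometry, path,
                sidecar: dict) -> Path:
    """Write a 4-D series plus its JSON timing sidecar."""
    path = Path(path)
    arr = np.asarray(data)
    if arr.ndim != 4:
        raise ValueError("series must be 4-D (x, y, z, t)")
    if not any(all(k in sidecar for k in keys) for keys in SIDECAR_KEY_SETS):
        raise ValueError(_sidecar_error())
    nib.save(nib.Nifti1Image(arr, geometry.affine()), path)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def _sidecar_error() -> str:
    opts = " or ".join("{" + ", ".join(keys) + "}" for keys in SIDECAR_KEY_SETS)
    return (
        "4-D series require a JSON sidecar with one of the key sets "
        f"{opts} describing the fourth axis"
    )


def load_series(path) -> tuple[np.ndarray, GridGeometry, dict]:
    """Load a 4-D series; the sidecar is required and validated."""
    path = Path(path)
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        raise FileNotFoundError(f"missing sidecar {sc_path}: " + _sidecar_error())
    sidecar = json.loads(sc_path.read_text())
    if not any(all(k in sidecar for k in keys) for keys in SIDECAR_KEY_SETS):
        raise ValueError(f"sidecar {sc_path} incomplete: " + _sidecar_error())
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path} is not a 4-D series (shape {data.shape})")
    geom = GridGeometry.from_affine(tuple(data.shape[:3]), img.affine)
    return data, geom, sidecar


def read_bvals(path) -> tuple[float, ...]:
    """Read b-values from FSL-style whitespace-separated ``.bval`` text."""
    text = Path(path).read_text().split()
    if not text:
        raise ValueError(f"no b-values found in {path}")
    return tuple(float(v) for v in text)
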