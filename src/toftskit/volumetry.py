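"""Tumor volumetry from binary ROI masks, and mask transfer across grids.

Volumes are voxel count × voxel volume on the grid the ROI was drawn on
(0.007 mm³ per voxel at the default 0.1 × 0.1 × 0.7 mm geometry). Masks
are strictly binary with the center-in rule — matching manual-ROI
practice, with no fractional partial-volume voxels. Transfer between
sequence grids assumes a shared world field of view and uses
nearest-neighbor lookup of voxel-center coordinates.
"""

from __future__ import annotations

import numpy as np

from .geometry import GridGeometry

__all__ = ["roi_volume", "resample_mask"]


def roi_volume(mask: np.ndarray, geometry: GridGeometry) -> float:
    """ROI volume in mm³: voxel count times voxel volume."""
    mask = np.asarray(mask)
    if mask.shape != geometry.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match grid {geometry.shape}"
        )
    return float(np.count_nonzero(mask)) * geometry.voxel_volume


def resample_mask(mask: np.ndarray, source: GridGeometry,
                  target: GridGeometry) -> np.ndarray:
    """Transfer a binary mask to another grid sharing the same world FOV.

    Each target voxel takes the value of the source voxel containing its
    center (nearest-neighbor). Identity when the grids match.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != source.shape:
        raise ValueError("mask does not match the source grid")
    for ax, (fs, ft) in enumerate(zip(source.fov, target.fov)):
        if not np.isclose(fs, ft, rtol=1e-6):
            raise ValueError(
                f"grids do not share the world FOV on axis {ax}: "
                f"{fs:.4f} mm vs {ft:.4f} mm"
            )
    cx, cy, cz = target.voxel_centers()
    ix = np.clip((cx / source.dx).astype(int), 0, source.nx - 1)
    iy = np.clip((cy / source.dy).astype(int), 0, source.ny - 1)
    iz = np.clip((cz / source.dz).astype(int), 0, source.n_slices - 1)
    return mask[np.ix_(ix, iy, iz)]
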