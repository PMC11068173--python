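"""Voxel-grid geometry shared by the simulator, the fitters and volumetry.

Conventions: voxel indices are 0-based; the world coordinate of voxel
``(i, j, k)`` is the voxel *center*, ``((i + 0.5)·dx, (j + 0.5)·dy,
(k + 0.5)·dz)`` measured from the grid corner. Masks include a voxel iff
its center lies inside the ROI surface (center-in rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridGeometry"]


@dataclass(frozen=True)
class GridGeometry:
    """Regular image grid: matrix size, in-plane spacing and slice stack.

    Defaults follow a 160×160 matrix over a 16×16 mm field of view
    (0.1 mm in-plane) with 0.7 mm contiguous slices, the T2-weighted
    grid used for tumor volumetry.
    """

    nx: int = 160
    ny: int = 160
    n_slices: int = 12
    dx: float = 0.1  # mm
    dy: float = 0.1  # mm
    dz: float = 0.7  # mm slice thickness, no interslice gap

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.n_slices) < 1:
            raise ValueError("matrix size and slice count must be >= 1")
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("voxel spacings must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.n_slices)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.dx, self.dy, self.dz)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (0.007 mm^3 at default spacing)."""
        return self.dx * self.dy * self.dz

    @property
    def fov(self) -> tuple[float, float, float]:
        """World extent (mm) along each axis."""
        return (self.nx * self.dx, self.ny * self.dy, self.n_slices * self.dz)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1-D world coordinates (mm) of voxel centers along each axis."""
        return (
            (np.arange(self.nx) + 0.5) * self.dx,
            (np.arange(self.ny) + 0.5) * self.dy,
            (np.arange(self.n_slices) + 0.5) * self.dz,
        )

    def affine(self) -> np.ndarray:
        """NIfTI affine mapping voxel indices to world mm at voxel centers."""
        aff = np.diag([self.dx, self.dy, self.dz, 1.0])
        aff[:3, 3] = (0.5 * self.dx, 0.5 * self.dy, 0.5 * self.dz)
        return aff

    @classmethod
    def from_affine(cls, shape: tuple[int, int, int], affine: np.ndarray) -> "GridGeometry":
        spacing = np.abs(np.diag(affine)[:3])
        return cls(int(shape[0]), int(shape[1]), int(shape[2]),
                   float(spacing[0]), float(spacing[1]), float(spacing[2]))
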