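"""Measure an ellipsoidal tumor ROI on the T2-weighted volumetry grid.

Rasterizes an ellipsoid with analytic volume 4.85 mm³ (a typical
baseline tumor size) on the 160×160 / 0.1×0.1×0.7 mm grid and compares
the voxel-counting measurement with the analytic value.
"""

import numpy as np

from toftskit import GridGeometry, roi_volume
from toftskit.phantom import rasterize_ellipsoid

grid = GridGeometry()  # 160×160 over 16×16 mm, 12 × 0.7 mm slices
c = 2.1
a = np.sqrt(4.85 * 3 / (4 * np.pi * c))
mask = rasterize_ellipsoid(grid, center_mm=(8.0, 8.0, 4.2), semi_axes_mm=(a, a, c))
vol = roi_volume(mask, grid)

print(f"semi-axes: {a:.3f} x {a:.3f} x {c} mm -> analytic volume 4.85 mm^3")
print(f"rasterized: {int(mask.sum())} voxels x {grid.voxel_volume:.4f} mm^3 "
      f"= {vol:.3f} mm^3  ({100 * (vol - 4.85) / 4.85:+.1f}%)")
# The center-in rule discretizes the surface; on this grid the error is
# dominated by the coarse 0.7 mm slice axis and stays inside one
# surface-voxel layer (about 5%).
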