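"""Isosurface extraction sanity check against an analytic sphere.

Voxelizes a 10 mm sphere at protocol-like anisotropic spacing, extracts
the marching-cubes surface in physical mm, and compares the enclosed
volume with the closed form 4/3 pi r^3.  Binary-mask extraction is
volume-accurate but carries ~8% staircase area inflation; the optional
Gaussian pre-filter removes it.
"""

import numpy as np

from bonequiv import extract_isosurface, mesh_measures, voxelize_shape
from bonequiv.phantom import ImplicitShape

r = 10.0
sphere = ImplicitShape(
    sdf=lambda p: np.linalg.norm(p, axis=1) - r,
    label="patella",
    bounds=np.array([[-r - 1] * 3, [r + 1] * 3]),
)
grid = voxelize_shape(sphere, spacing=(0.3, 0.3, 0.6))
print(f"mask: {grid.data.shape} voxels, occupied volume {grid.foreground_volume:.1f} mm^3")

analytic_v = 4 / 3 * np.pi * r**3
analytic_a = 4 * np.pi * r**2
for sigma, tag in [(None, "raw binary mask"), (0.8, "pre-smoothed (sigma=0.8 voxel)")]:
    m = mesh_measures(extract_isosurface(grid, smooth_sigma=sigma))
    print(f"{tag}: volume {m.volume:.1f} mm^3 ({100 * (m.volume / analytic_v - 1):+.2f}%), "
          f"area {m.area:.1f} mm^2 ({100 * (m.area / analytic_a - 1):+.2f}%), "
          f"watertight={m.watertight}")
print(f"analytic: volume {analytic_v:.1f} mm^3, area {analytic_a:.1f} mm^2")
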