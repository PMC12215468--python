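"""Triangle-mesh extraction from binary segmentation volumes.

A :class:`VoxelGrid` is a binary mask with physical voxel spacing and origin
in millimetres; array axis ``i`` maps to world ``x``, ``j`` to ``y`` and
``k`` to ``z`` (slice axis), so a voxel index ``(i, j, k)`` sits at
``origin + index * spacing``.  Meshes are extracted with marching cubes at
the 0.5 level of the 0/1 mask, after padding one background voxel on every
side so masks that touch the array boundary still produce closed surfaces.
No smoothing is applied by default; an optional Gaussian pre-filter is
available for users who want it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.ndimage import gaussian_filter
from skimage import measure

from .errors import EmptySurfaceError

__all__ = ["VoxelGrid", "extract_isosurface", "orient_outward", "mesh_measures", "MeshMeasures"]


@dataclass
class VoxelGrid:
    """Binary segmentation volume with physical geometry (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.ascontiguousarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3-D")
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be 0/1")
        self.data = self.data.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def foreground_count(self) -> int:
        return int(self.data.sum())

    @property
    def foreground_volume(self) -> float:
        """Occupied-voxel count times voxel volume (mm^3)."""
        return self.foreground_count * self.voxel_volume


def extract_isosurface(grid: VoxelGrid, level: float = 0.5, smooth_sigma: float | None = None) -> trimesh.Trimesh:
    """Marching-cubes isosurface of a binary mask, in world millimetres.

    The Lewiner variant is used so ambiguous cube configurations are
    resolved consistently; the mask is zero-padded by one voxel so closed
    anatomy yields a watertight mesh.  Raises :class:`EmptySurfaceError`
    for all-zero or all-one masks.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    n_fg = grid.foreground_count
    if n_fg == 0 or n_fg == grid.data.size:
        raise EmptySurfaceError("mask contains no 0/1 transition")
    volume = np.pad(grid.data, 1).astype(np.float32)
    if smooth_sigma:
        volume = gaussian_filter(volume, sigma=smooth_sigma)
    verts, faces, _, _ = measure.marching_cubes(volume, level=level, spacing=grid.spacing, method="lewiner")
    # undo the one-voxel pad, then shift into world coordinates
    verts = verts - np.asarray(grid.spacing) + np.asarray(grid.origin)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    return orient_outward(mesh)


def orient_outward(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Ensure consistent winding with outward normals (signed volume > 0).

    Non-watertight meshes get a best-effort orientation and a warning; the
    result carries ``mesh.metadata["orientation_flagged"] = True``.
    """
    mesh = mesh.copy()
    if not mesh.is_winding_consistent:
        trimesh.repair.fix_normals(mesh)
    if not mesh.is_watertight:
        warnings.warn("orienting a non-watertight mesh: best effort only", stacklevel=2)
        mesh.metadata["orientation_flagged"] = True
    if mesh.volume < 0:
        mesh.invert()
    return mesh


@dataclass(frozen=True)
class MeshMeasures:
    area: float  # mm^2
    volume: float  # signed, mm^3
    n_vertices: int
    watertight: bool


def mesh_measures(mesh: trimesh.Trimesh) -> MeshMeasures:
    """Surface area, divergence-theorem signed volume, and QC flags."""
    if len(mesh.vertices) == 0:
        raise ValueError("empty mesh")
    v = mesh.vertices
    tri = v[mesh.faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    area = float(0.5 * np.linalg.norm(cross, axis=1).sum())
    signed_volume = float(np.einsum("ij,ij->i", tri[:, 0], cross).sum() / 6.0)
    return MeshMeasures(area=area, volume=signed_volume, n_vertices=len(v), watertight=bool(mesh.is_watertight))
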