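"""FROI clipping, signed surface distances, and the per-bone pipeline.

Distances are directional: from each retained vertex of the registered
source (cone-beam) mesh to the nearest point on the target (reference)
surface, signed positive where the source vertex lies *outside* the target
— i.e. where the source model is larger.  Inside/outside is decided by the
generalized winding number of the closed target surface, which stays robust
on thin structures (the fibula shaft) where normal-based tests flip sign.

The focused region of interest (FROI) restricts the comparison to anatomy
covered by both scans: the intersection of the two meshes' axial extents,
shrunk by a safety margin at every end where the extents disagree (i.e.
where at least one mesh was cut by its field of view), so the flat
marching-cubes caps at FOV cut planes never enter the statistics.  The
patella is exempt: it is fully contained in both scans, so the original
meshes are compared directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh

from ._mesh_queries import closest_point_on_mesh, winding_number
from .errors import EmptyFroiError
from .phantom import PhantomPair
from .register import ICPParams, RigidTransform, apply_rigid, icp_align
from .summaries import BoneSummary, summarize_values
from .surface import VoxelGrid, extract_isosurface

__all__ = [
    "FroiSpec",
    "DistanceResult",
    "CompareConfig",
    "PairResult",
    "define_froi",
    "signed_distance",
    "summarize_bone",
    "compare_bone_pair",
]


@dataclass
class FroiSpec:
    """How the comparable axial band is chosen."""

    axis: int = 2  # superior-inferior
    margin: float = 2.0  # mm removed at each cut end
    cut_tolerance: float = 1.0  # extents differing by more than this flag a cut end
    exempt_bones: tuple[str, ...] = ("patella",)

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin must be >= 0")


@dataclass
class DistanceResult:
    """Signed distances (mm) over the retained source vertices."""

    distances: np.ndarray  # per retained vertex
    mask: np.ndarray  # boolean over all source vertices
    source_label: str = ""
    target_label: str = ""

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if not np.all(np.isfinite(self.distances)):
            raise ValueError("distances must be finite")


def define_froi(
    source: trimesh.Trimesh,
    target: trimesh.Trimesh,
    spec: FroiSpec | None = None,
    bone: str = "",
) -> tuple[np.ndarray, np.ndarray]:
    """Vertex-retention masks for both meshes (already co-registered)."""
    spec = spec or FroiSpec()
    src_z = np.asarray(source.vertices)[:, spec.axis]
    tgt_z = np.asarray(target.vertices)[:, spec.axis]
    if bone in spec.exempt_bones:
        return np.ones(len(src_z), dtype=bool), np.ones(len(tgt_z), dtype=bool)

    lo = max(src_z.min(), tgt_z.min())
    hi = min(src_z.max(), tgt_z.max())
    # an end is an FOV cut when the two meshes do not end together there
    if abs(src_z.min() - tgt_z.min()) > spec.cut_tolerance:
        lo += spec.margin
    if abs(src_z.max() - tgt_z.max()) > spec.cut_tolerance:
        hi -= spec.margin
    src_mask = (src_z >= lo) & (src_z <= hi)
    tgt_mask = (tgt_z >= lo) & (tgt_z <= hi)
    if not src_mask.any() or not tgt_mask.any():
        raise EmptyFroiError("FROI retained no vertices")
    return src_mask, tgt_mask


def signed_distance(
    source: trimesh.Trimesh,
    target: trimesh.Trimesh,
    source_mask: np.ndarray | None = None,
    sign_method: str = "winding",
) -> DistanceResult:
    """Signed distance from retained source vertices to the target surface.

    ``sign_method="winding"`` (default) requires a watertight target.
    ``sign_method="pseudo_normal"`` is an explicit fallback for
    non-watertight targets, signing by the angle-weighted normal at the
    closest point.
    """
    if source_mask is None:
        source_mask = np.ones(len(source.vertices), dtype=bool)
    source_mask = np.asarray(source_mask, dtype=bool)
    pts = np.asarray(source.vertices, dtype=float)[source_mask]
    if len(pts) == 0:
        raise EmptyFroiError("no source vertices after masking")

    closest, dist, tri_idx = closest_point_on_mesh(target, pts)
    if sign_method == "winding":
        if not target.is_watertight:
            raise ValueError(
                "target mesh is not watertight; winding-number sign is unreliable "
                "(pass sign_method='pseudo_normal' to override)"
            )
        inside = winding_number(target, pts) > 0.5
    elif sign_method == "pseudo_normal":
        normals = np.asarray(target.face_normals)[tri_idx]
        inside = np.einsum("ij,ij->i", pts - closest, normals) < 0
    else:
        raise ValueError(f"unknown sign_method {sign_method!r}")
    signed = np.where(inside, -dist, dist)
    return DistanceResult(
        distances=signed,
        mask=source_mask,
        source_label=str(source.metadata.get("label", "")),
        target_label=str(target.metadata.get("label", "")),
    )


def summarize_bone(result: DistanceResult, bone: str = "") -> BoneSummary:
    """Population summary of the per-vertex signed distances."""
    return summarize_values(result.distances, bone=bone or result.source_label)


@dataclass
class CompareConfig:
    level: float = 0.5
    froi: FroiSpec = field(default_factory=FroiSpec)
    # trimming matters: the moving scan is FOV-truncated, so its flat cut
    # cap has no counterpart on the fixed surface; discarding the worst
    # correspondences keeps the partial-overlap registration unbiased
    icp: ICPParams = field(default_factory=lambda: ICPParams(sample_count=2000, trim_fraction=0.15))
    sign_method: str = "winding"


@dataclass
class PairResult:
    bone: str
    summary: BoneSummary
    distances: DistanceResult
    transform: RigidTransform
    source_mesh: trimesh.Trimesh  # registered, in the target frame
    target_mesh: trimesh.Trimesh
    rms_trace: list[float]


def compare_bone_pair(
    grid_a: VoxelGrid, grid_b: VoxelGrid, config: CompareConfig | None = None, bone: str = ""
) -> PairResult:
    """Full pipeline for one bone pair: mesh, register, clip, measure.

    Grid A (the modality under assessment) is the moving/source scan; grid B
    is the fixed reference.  Distances are A to B, positive where A's model
    is larger.
    """
    config = config or CompareConfig()
    bone = bone or grid_a.label
    mesh_a = extract_isosurface(grid_a, level=config.level)
    mesh_b = extract_isosurface(grid_b, level=config.level)
    mesh_a.metadata["label"] = mesh_b.metadata["label"] = bone

    transform, trace = icp_align(mesh_a, mesh_b, config.icp)
    registered = apply_rigid(mesh_a, transform)

    src_mask, _ = define_froi(registered, mesh_b, config.froi, bone=bone)
    result = signed_distance(registered, mesh_b, src_mask, sign_method=config.sign_method)
    summary = summarize_bone(result, bone=bone)
    return PairResult(
        bone=bone,
        summary=summary,
        distances=result,
        transform=transform,
        source_mesh=registered,
        target_mesh=mesh_b,
        rms_trace=trace,
    )
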