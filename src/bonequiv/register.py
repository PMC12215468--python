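"""Rigid registration of bone meshes: Kabsch step and point-to-surface ICP.

The moving mesh (cone-beam modality) is aligned to the fixed mesh
(reference modality) by iterating closest-point correspondence assignment
against the *surface* of the fixed mesh — not its vertices — followed by a
weighted least-squares rigid update (Kabsch, SVD with reflection excluded).
Point-to-surface correspondence matters because the surface discrepancies
being measured are well below the voxel size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from ._mesh_queries import closest_point_on_mesh
from .errors import DegenerateGeometryError

__all__ = ["RigidTransform", "ICPParams", "kabsch", "icp_align", "apply_rigid"]

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation plus translation, acting as ``p -> R p + t`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=_ORTHO_TOL):
            raise ValueError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        a = np.deg2rad(angle_deg)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)
        return cls(R, np.asarray(translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation, self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    @property
    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def to_dict(self) -> dict:
        return {
            "rotation": [[float(v) for v in row] for row in self.rotation],
            "translation": [float(v) for v in self.translation],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]))

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load_json(cls, path) -> "RigidTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ICPParams:
    max_iterations: int = 100
    tolerance: float = 1e-6  # convergence threshold on RMS change, mm
    trim_fraction: float = 0.0  # worst correspondences discarded per iteration
    init: str = "centroid"  # or "centroid+axes"
    sample_count: int | None = None  # moving-vertex subsample; None = all
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


def kabsch(source: np.ndarray, target: np.ndarray, weights: np.ndarray | None = None) -> RigidTransform:
    """Least-squares rigid transform mapping ``source`` onto ``target``.

    Minimizes the weighted sum of squared residuals over proper rotations;
    reflections are excluded by sign-correcting the smallest singular
    direction.  Raises :class:`DegenerateGeometryError` for fewer than 3
    points or (near-)collinear configurations, where the rotation is not
    identifiable.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("source/target must be matching (N, 3) arrays")
    n = len(src)
    if n < 3:
        raise DegenerateGeometryError("need >= 3 point pairs")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        w = w / w.sum()

    cs = w @ src
    ct = w @ tgt
    src_c = src - cs
    tgt_c = tgt - ct

    # collinearity check on the weighted source scatter
    scatter = (src_c * w[:, None]).T @ src_c
    sv = np.linalg.svd(scatter, compute_uv=False)
    if sv[1] <= 1e-12 * max(sv[0], 1e-300):
        raise DegenerateGeometryError("source points are (near-)collinear")

    H = (src_c * w[:, None]).T @ tgt_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cs
    return RigidTransform(R, t)


def apply_rigid(mesh: trimesh.Trimesh, transform: RigidTransform) -> trimesh.Trimesh:
    """Return a copy of ``mesh`` with vertices mapped by ``R v + t``."""
    out = mesh.copy()
    out.vertices = transform.apply(mesh.vertices)
    return out


def _principal_axis_candidates(moving_pts: np.ndarray, fixed_pts: np.ndarray) -> list[RigidTransform]:
    """Proper-rotation candidates aligning principal axes, all 4 sign flips."""

    def axes(pts):
        c = pts.mean(axis=0)
        _, _, Vt = np.linalg.svd(pts - c)
        A = Vt.T
        if np.linalg.det(A) < 0:
            A[:, 2] *= -1
        return c, A

    cm, Am = axes(moving_pts)
    cf, Af = axes(fixed_pts)
    candidates = []
    for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        S = np.diag([sx, sy, sx * sy])  # keeps det +1
        R = Af @ S @ Am.T
        candidates.append(RigidTransform(R, cf - R @ cm))
    return candidates


def icp_align(
    moving: trimesh.Trimesh, fixed: trimesh.Trimesh, params: ICPParams | None = None
) -> tuple[RigidTransform, list[float]]:
    """Iterative closest point: align ``moving`` onto the ``fixed`` surface.

    Correspondences are exact closest points on the fixed surface.  Returns
    the final transform and the per-iteration RMS trace (mm).
    """
    params = params or ICPParams()
    if len(np.unique(np.asarray(moving.vertices), axis=0)) <= 2 or len(fixed.faces) == 0:
        raise DegenerateGeometryError("degenerate mesh input to ICP")

    pts = np.asarray(moving.vertices, dtype=float)
    if params.sample_count is not None and params.sample_count < len(pts):
        rng = np.random.default_rng(params.seed)
        pts = pts[rng.choice(len(pts), params.sample_count, replace=False)]

    fixed_pts = np.asarray(fixed.vertices, dtype=float)

    def rms_of(transform: RigidTransform) -> float:
        _, d, _ = closest_point_on_mesh(fixed, transform.apply(pts))
        return float(np.sqrt(np.mean(d**2)))

    if params.init == "centroid+axes":
        current = min(_principal_axis_candidates(pts, fixed_pts), key=rms_of)
    elif params.init == "centroid":
        current = RigidTransform(np.eye(3), fixed_pts.mean(axis=0) - pts.mean(axis=0))
    else:
        raise ValueError(f"unknown init mode {params.init!r}")

    trace: list[float] = []
    n_keep = max(3, int(round(len(pts) * (1.0 - params.trim_fraction))))
    for _ in range(params.max_iterations):
        moved = current.apply(pts)
        corr, dist, _ = closest_point_on_mesh(fixed, moved)
        if params.trim_fraction > 0:
            keep = np.argsort(dist)[:n_keep]
        else:
            keep = slice(None)
        current = kabsch(pts[keep], corr[keep])
        rms = float(np.sqrt(np.mean(dist[keep] ** 2)))
        trace.append(rms)
        if len(trace) >= 2 and abs(trace[-2] - trace[-1]) < params.tolerance:
            break
    return current, trace
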