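"""Synthetic paired bone segmentations with known ground truth.

Real scan pairs differ by an unknown rigid pose, a possible systematic
surface offset between modalities, segmentation noise, and different axial
fields of view.  The phantom module reproduces exactly those four effects —
and nothing else — on closed implicit shapes built from analytic primitives
(spheres, capsules, ellipsoids, blended with a smooth minimum).  Anatomical
realism is deliberately out of scope: what matters for testing the pipeline
is closed topology, enough asymmetry that rigid registration is well posed,
and bone-like scale.  Every shape therefore carries a few off-axis bumps.

Sign convention for the surface offset ``delta``: positive ``delta`` means
the first modality's model (the "moving" scan, grid A) is *larger* than the
second (grid B) by ``delta`` mm, so the pipeline's signed A-to-B distance
recovers ``+delta``.  Internally grid B is voxelized from the base surface
eroded by ``delta``.

Surface noise is emulated at the implicit level: a fixed-seed sum of smooth
Gaussian lobes, normalized to zero mean and unit variance over the shape's
bounding region, scaled by ``sigma_noise`` and added to the signed-distance
value.  This displaces the level set by approximately the field value while
keeping the surface closed and smooth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import EmptyMaskError
from .register import RigidTransform
from .surface import VoxelGrid

__all__ = [
    "ImplicitShape",
    "PhantomSpec",
    "GroundTruth",
    "PhantomPair",
    "BONES",
    "generate_bone_shape",
    "offset_surface",
    "perturb_shape",
    "voxelize_shape",
    "generate_study",
    "default_study_specs",
]

BONES = ("femur", "tibia", "fibula", "patella")

# paper-protocol voxel spacings: cone-beam (in-plane 0.30 mm, slice 0.60 mm)
# vs multidetector (in-plane 0.49 mm, slice 0.625 mm)
SPACING_CBCT = (0.30, 0.30, 0.60)
SPACING_MDCT = (0.49, 0.49, 0.625)

# axial field-of-view heights of the two protocols (200 mm vs 376 mm),
# expressed as fractions of the bone's axial extent at phantom scale so the
# shorter FOV truncates the long bones but never the patella
_FOV_FRACTION_A = 200.0 / 376.0
_FOV_FRACTION_B = 1.0


@dataclass
class ImplicitShape:
    """Closed bounded shape defined by a signed-distance-like function (mm).

    ``sdf(points)`` is negative inside; the zero level set is the surface.
    ``bounds`` is an axis-aligned box guaranteed to contain the surface;
    ``primitive_volumes`` lists the analytic volumes of the constituent
    primitives (oracle material for volume checks — blending and overlaps
    make the exact union volume analytically awkward, but their sum bounds
    it to within tens of percent).
    """

    sdf: Callable[[np.ndarray], np.ndarray]
    label: str
    bounds: np.ndarray  # (2, 3) min/max corners, mm
    primitive_volumes: tuple[float, ...] = ()

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.sdf(np.atleast_2d(np.asarray(points, dtype=float)))


# ---------------------------------------------------------------------------
# analytic signed-distance primitives


def _sphere(center, r):
    c = np.asarray(center, dtype=float)
    return lambda p: np.linalg.norm(p - c, axis=1) - r


def _capsule(a, b, r):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    denom = float(ab @ ab)

    def sdf(p):
        t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
        return np.linalg.norm(p - (a + t[:, None] * ab), axis=1) - r

    return sdf


def _ellipsoid(center, radii):
    c = np.asarray(center, dtype=float)
    r = np.asarray(radii, dtype=float)

    def sdf(p):
        q = p - c
        k0 = np.linalg.norm(q / r, axis=1)
        k1 = np.linalg.norm(q / (r * r), axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(k1 > 0, k0 * (k0 - 1.0) / k1, -r.min())
        return d

    return sdf


def _smooth_union(sdfs: Sequence[Callable], k: float):
    """Polynomial smooth minimum; ``k`` is the blend radius (mm)."""

    def sdf(p):
        d = sdfs[0](p)
        for f in sdfs[1:]:
            d2 = f(p)
            h = np.clip(0.5 + 0.5 * (d2 - d) / k, 0.0, 1.0)
            d = d2 + (d - d2) * h - k * h * (1.0 - h)
        return d

    return sdf


def _sphere_vol(r):
    return 4.0 / 3.0 * np.pi * r**3


def _capsule_vol(length, r):
    return np.pi * r**2 * length + _sphere_vol(r)


def _ellipsoid_vol(radii):
    return 4.0 / 3.0 * np.pi * float(np.prod(radii))


def generate_bone_shape(label: str, size: float, seed: int = 0) -> ImplicitShape:
    """Build a closed implicit shape loosely evoking the named knee bone.

    ``size`` is the characteristic scale in mm (roughly the axial extent for
    the long bones).  Deterministic per ``(label, size, seed)``.
    """
    if label not in BONES:
        raise ValueError(f"unknown bone label {label!r}; expected one of {BONES}")
    if size <= 0:
        raise ValueError("size must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([BONES.index(label), seed]))

    parts: list[Callable] = []
    vols: list[float] = []
    if label == "femur":
        shaft_r = 0.16 * size
        half = 0.38 * size
        parts.append(_capsule((0, 0, -half), (0, 0, half), shaft_r))
        vols.append(_capsule_vol(2 * half, shaft_r))
        # condylar bulges at the joint end (+z); the FOV truncation removes
        # shaft (-z), never the joint anatomy, as in a knee scan
        for sx in (-1, 1):
            cr = 0.20 * size
            parts.append(_sphere((sx * 0.17 * size, 0.05 * size, half), cr))
            vols.append(_sphere_vol(cr))
    elif label == "tibia":
        shaft_r = 0.14 * size
        half = 0.38 * size
        parts.append(_capsule((0, 0, -half), (0, 0, half), shaft_r))
        vols.append(_capsule_vol(2 * half, shaft_r))
        radii = (0.30 * size, 0.24 * size, 0.12 * size)  # proximal plateau
        parts.append(_ellipsoid((0.03 * size, 0, half), radii))
        vols.append(_ellipsoid_vol(radii))
    elif label == "fibula":
        # slender, but thick enough (radius >= a few voxels at MDCT spacing)
        # that voxelization does not systematically erode the shaft
        rod_r = 0.14 * size
        half = 0.42 * size
        parts.append(_capsule((0, 0, -half), (0, 0, half), rod_r))
        vols.append(_capsule_vol(2 * half, rod_r))
        head_r = 0.18 * size
        parts.append(_sphere((0.05 * size, 0, half), head_r))
        vols.append(_sphere_vol(head_r))
    else:  # patella: thick lens
        radii = (0.48 * size, 0.40 * size, 0.30 * size)
        parts.append(_ellipsoid((0, 0, 0), radii))
        vols.append(_ellipsoid_vol(radii))

    # asymmetric bumps so the rotation is identifiable under registration;
    # biased toward the joint end (+z) so the asymmetry survives FOV
    # truncation of the long bones
    for _ in range(3):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        if label != "patella":
            direction[2] = abs(direction[2])
        center = direction * 0.30 * size + rng.normal(scale=0.05 * size, size=3)
        br = (0.10 + 0.06 * rng.random()) * size
        parts.append(_sphere(center, br))
        vols.append(_sphere_vol(br))

    blend = 0.05 * size
    sdf = _smooth_union(parts, blend)
    half_extent = 0.62 * size
    bounds = np.array([[-half_extent] * 3, [half_extent] * 3])
    return ImplicitShape(sdf=sdf, label=label, bounds=bounds, primitive_volumes=tuple(vols))


def offset_surface(shape: ImplicitShape, delta: float) -> ImplicitShape:
    """Displace the level set outward by ``delta`` mm (positive = dilation)."""
    base = shape.sdf
    pad = abs(delta)
    return ImplicitShape(
        sdf=lambda p: base(p) - delta,
        label=shape.label,
        bounds=shape.bounds + np.array([[-pad] * 3, [pad] * 3]),
        primitive_volumes=shape.primitive_volumes,
    )


def _noise_field(shape: ImplicitShape, sigma: float, seed, n_lobes: int = 64):
    """Band-limited lobe noise, zero mean and std ``sigma`` over the surface.

    Normalizing against probe points near the level set (rather than the
    whole bounding box) keeps the per-bone *surface average* of the noise
    near zero, so noise perturbs the shape without shifting its mean offset.
    """
    rng = np.random.default_rng(seed)
    lo, hi = shape.bounds
    span = float(np.max(hi - lo))
    centers = rng.uniform(lo, hi, size=(n_lobes, 3))
    widths = span * rng.uniform(0.06, 0.14, size=n_lobes)
    amps = rng.normal(size=n_lobes)

    def raw(p):
        d2 = ((p[:, None, :] - centers[None]) ** 2).sum(axis=2)
        return (amps * np.exp(-d2 / (2.0 * widths**2))).sum(axis=1)

    probe_rng = np.random.default_rng(np.random.default_rng(seed).integers(2**31))
    probes = probe_rng.uniform(lo, hi, size=(65536, 3))
    near = np.abs(shape(probes)) < 0.04 * span  # thin shell around the surface
    if near.sum() < 256:
        near = np.argsort(np.abs(shape(probes)))[:256]
    vals = raw(probes[near])
    mean, std = float(vals.mean()), float(vals.std())
    scale = sigma / std if std > 0 else 0.0

    def sdf_noise(p):
        return (raw(p) - mean) * scale

    return sdf_noise


def perturb_shape(shape: ImplicitShape, sigma_noise: float, seed) -> ImplicitShape:
    """Add smooth surface noise of amplitude ``sigma_noise`` mm."""
    if sigma_noise < 0:
        raise ValueError("sigma_noise must be >= 0")
    if sigma_noise == 0:
        return shape
    noise = _noise_field(shape, sigma_noise, seed)
    base = shape.sdf
    pad = 4.0 * sigma_noise
    return ImplicitShape(
        sdf=lambda p: base(p) + noise(p),
        label=shape.label,
        bounds=shape.bounds + np.array([[-pad] * 3, [pad] * 3]),
        primitive_volumes=shape.primitive_volumes,
    )


def _transformed(shape: ImplicitShape, transform: RigidTransform) -> ImplicitShape:
    """Shape moved by a rigid transform (sdf evaluated in the source frame)."""
    inv = transform.inverse()
    base = shape.sdf
    corners_idx = np.array(np.meshgrid([0, 1], [0, 1], [0, 1])).T.reshape(-1, 3)
    corners = np.array([[shape.bounds[i, d] for d, i in enumerate(c)] for c in corners_idx])
    moved = transform.apply(corners)
    bounds = np.array([moved.min(axis=0), moved.max(axis=0)])
    return ImplicitShape(
        sdf=lambda p: base(inv.apply(p)),
        label=shape.label,
        bounds=bounds,
        primitive_volumes=shape.primitive_volumes,
    )


def voxelize_shape(
    shape: ImplicitShape,
    spacing: Sequence[float],
    fov: Sequence[Sequence[float]] | None = None,
    label: str | None = None,
) -> VoxelGrid:
    """Rasterize a shape: voxel = 1 iff its center lies inside the surface.

    ``fov`` is a ((xmin, ymin, zmin), (xmax, ymax, zmax)) box in mm; defaults
    to the shape's bounds padded by one voxel.  Raises
    :class:`EmptyMaskError` when no voxel center falls inside.
    """
    spacing = np.asarray(spacing, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("spacing must be strictly positive")
    if fov is None:
        fov = shape.bounds + np.array([-spacing, spacing])
    fov = np.asarray(fov, dtype=float)
    if np.any(fov[1] <= fov[0]):
        raise ValueError("fov must be a nonempty box")
    n = np.maximum(np.floor((fov[1] - fov[0]) / spacing).astype(int) + 1, 1)
    axes = [fov[0][d] + spacing[d] * np.arange(n[d]) for d in range(3)]
    mask = np.empty(tuple(n), dtype=np.uint8)
    # evaluate slab by slab to bound memory on fine grids
    jj, kk = np.meshgrid(axes[1], axes[2], indexing="ij")
    plane = np.column_stack([np.zeros(jj.size), jj.ravel(), kk.ravel()])
    for i, x in enumerate(axes[0]):
        plane[:, 0] = x
        mask[i] = (shape(plane) < 0).reshape(n[1], n[2])
    if mask.sum() == 0:
        raise EmptyMaskError(f"field of view contains no part of shape {shape.label!r}")
    return VoxelGrid(mask, spacing=tuple(spacing), origin=tuple(fov[0]), label=label or shape.label)


# ---------------------------------------------------------------------------
# paired-study generation


@dataclass
class PhantomSpec:
    """Recipe for one bone's paired segmentations."""

    bone: str
    size: float  # characteristic scale, mm
    transform: RigidTransform = field(default_factory=RigidTransform.identity)
    delta: float = 0.0  # systematic surface offset, mm (A larger when > 0)
    sigma_noise: float = 0.0  # surface noise amplitude, mm
    spacing_a: tuple[float, float, float] = SPACING_CBCT
    spacing_b: tuple[float, float, float] = SPACING_MDCT
    fov_fraction_a: float = _FOV_FRACTION_A  # axial FOV as fraction of bone extent
    fov_fraction_b: float = _FOV_FRACTION_B
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bone not in BONES:
            raise ValueError(f"unknown bone {self.bone!r}")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be >= 0")
        if any(s <= 0 for s in (*self.spacing_a, *self.spacing_b)):
            raise ValueError("spacings must be strictly positive")
        if not (0 < self.fov_fraction_a <= 1 and 0 < self.fov_fraction_b <= 1):
            raise ValueError("fov fractions must be in (0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """What the pipeline should recover for one phantom pair."""

    bone: str
    transform: RigidTransform  # true pose of grid B relative to the base frame
    delta: float
    sigma_noise: float
    expected_mean: float  # = delta
    seed: int

    def to_dict(self) -> dict:
        return {
            "bone": self.bone,
            "rotation": self.transform.to_dict()["rotation"],
            "translation": self.transform.to_dict()["translation"],
            "delta": self.delta,
            "sigma_noise": self.sigma_noise,
            "expected_mean": self.expected_mean,
            "seed": self.seed,
        }


@dataclass
class PhantomPair:
    bone: str
    grid_a: VoxelGrid
    grid_b: VoxelGrid
    truth: GroundTruth


def _axial_fov(shape: ImplicitShape, spacing, fraction: float, exempt: bool) -> np.ndarray:
    fov = shape.bounds + np.array([-np.asarray(spacing), np.asarray(spacing)])
    if exempt or fraction >= 1.0:
        return fov
    lo_z, hi_z = fov[0][2], fov[1][2]
    height = (hi_z - lo_z) * fraction
    # the short FOV keeps the joint end (+z); the far shaft is cut off
    fov[0][2] = hi_z - height
    return fov


def make_pair(spec: PhantomSpec) -> PhantomPair:
    """Generate one phantom pair plus its ground truth."""
    base = generate_bone_shape(spec.bone, spec.size, seed=spec.seed)
    exempt = spec.bone == "patella"  # the patella is fully inside both FOVs

    grid_a = voxelize_shape(
        base, spec.spacing_a, _axial_fov(base, spec.spacing_a, spec.fov_fraction_a, exempt)
    )

    shape_b = offset_surface(base, -spec.delta)  # B smaller by delta => A->B mean = +delta
    shape_b = perturb_shape(shape_b, spec.sigma_noise, np.random.SeedSequence([spec.seed, 7919]))
    shape_b = _transformed(shape_b, spec.transform)
    grid_b = voxelize_shape(
        shape_b, spec.spacing_b, _axial_fov(shape_b, spec.spacing_b, spec.fov_fraction_b, exempt)
    )

    truth = GroundTruth(
        bone=spec.bone,
        transform=spec.transform,
        delta=spec.delta,
        sigma_noise=spec.sigma_noise,
        expected_mean=spec.delta,
        seed=spec.seed,
    )
    return PhantomPair(bone=spec.bone, grid_a=grid_a, grid_b=grid_b, truth=truth)


def generate_study(specs: Iterable[PhantomSpec]) -> list[PhantomPair]:
    """Generate paired grids and ground truth for every spec, in order."""
    specs = list(specs)
    if not specs:
        raise ValueError("need at least one PhantomSpec")
    return [make_pair(s) for s in specs]


# desk-scale default sizes (mm): small enough that a full multi-subject
# study runs in minutes at the protocol voxel spacings, large enough that
# each bone spans hundreds of voxels per axis dimension
DEFAULT_SIZES = {"femur": 30.0, "tibia": 26.0, "fibula": 20.0, "patella": 12.0}


def default_study_specs(
    n_subjects: int,
    bones: Sequence[str] = BONES,
    delta: float = 0.0,
    sigma_noise: float = 0.1,
    misalign: bool = True,
    seed: int = 0,
) -> list[PhantomSpec]:
    """Specs for a subjects-by-bones study with per-pair random true poses."""
    rng = np.random.default_rng(seed)
    specs = []
    for subject in range(n_subjects):
        for bone in bones:
            if misalign:
                # scan pairs are acquired near-aligned; a few degrees and mm
                # also keeps the tilted FOV-cut caps inside the FROI margin
                axis = rng.normal(size=3)
                angle = rng.uniform(1.0, 4.0)
                translation = rng.uniform(-3.0, 3.0, size=3)
                transform = RigidTransform.from_axis_angle(axis, angle, translation)
            else:
                transform = RigidTransform.identity()
            specs.append(
                PhantomSpec(
                    bone=bone,
                    size=DEFAULT_SIZES[bone],
                    transform=transform,
                    delta=delta,
                    sigma_noise=sigma_noise,
                    seed=int(rng.integers(2**31)),
                )
            )
    return specs
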