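"""FROI clipping, signed surface distances, and the per-pair pipeline."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from bonequiv import (
    CompareConfig,
    FroiSpec,
    PhantomSpec,
    RigidTransform,
    compare_bone_pair,
    define_froi,
    signed_distance,
    summarize_bone,
    voxelize_shape,
)
from bonequiv._mesh_queries import closest_point_on_mesh, winding_number
from bonequiv.compare import DistanceResult
from bonequiv.errors import DegenerateSampleError, EmptyFroiError
from bonequiv.phantom import make_pair

from conftest import sphere_shape


def icosphere(r, subdivisions=4):
    return trimesh.creation.icosphere(subdivisions=subdivisions, radius=r)


def clipped_icosphere(r, z_min):
    """Upper portion of a sphere mesh: only faces fully above z_min."""
    full = icosphere(r)
    keep = (full.vertices[:, 2][full.faces] >= z_min).all(axis=1)
    clipped = full.copy()
    clipped.update_faces(keep)
    clipped.remove_unreferenced_vertices()
    return clipped


class TestClosestPoint:
    def test_exact_on_analytic_sphere(self, icosphere10):
        """Distances from outside points match |p| - r within facet error."""
        rng = np.random.default_rng(0)
        dirs = rng.normal(size=(500, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = dirs * 13.0
        _, dist, _ = closest_point_on_mesh(icosphere10, pts)
        assert np.allclose(dist, 3.0, atol=0.02)

    def test_matches_brute_force_over_all_triangles(self, icosphere10):
        """KD-tree shortlist returns the same minimum as an exhaustive scan."""
        from bonequiv._mesh_queries import _closest_on_triangles

        pts = np.random.default_rng(1).uniform(-12, 12, size=(100, 3))
        _, dist, _ = closest_point_on_mesh(icosphere10, pts)
        tri = np.asarray(icosphere10.triangles)
        brute = np.empty(len(pts))
        for i, p in enumerate(pts):
            rep = np.tile(p, (len(tri), 1))
            cps = _closest_on_triangles(rep, tri[:, 0], tri[:, 1], tri[:, 2])
            brute[i] = np.sqrt(((rep - cps) ** 2).sum(axis=1).min())
        assert np.allclose(dist, brute, atol=1e-12)


class TestWindingNumber:
    def test_sign_correct_on_sphere_and_box(self, icosphere10):
        """Inside/outside from winding matches analytic membership at 10^4 points."""
        rng = np.random.default_rng(2)
        pts = rng.uniform(-12, 12, size=(10_000, 3))
        radii = np.linalg.norm(pts, axis=1)
        clear = np.abs(radii - 10.0) > 0.05  # skip the facet-ambiguous shell
        w = winding_number(icosphere10, pts[clear])
        assert np.array_equal(w > 0.5, radii[clear] < 10.0)

        box = trimesh.creation.box(extents=(6.0, 4.0, 2.0))
        pts = rng.uniform(-4, 4, size=(10_000, 3))
        inside_box = (np.abs(pts) < np.array([3.0, 2.0, 1.0])).all(axis=1)
        on_face = np.isclose(np.abs(pts) / np.array([3.0, 2.0, 1.0]), 1.0, atol=1e-6).any(axis=1)
        w = winding_number(box, pts[~on_face])
        assert np.array_equal(w > 0.5, inside_box[~on_face])

    def test_near_integer_values(self, icosphere10):
        w_in = winding_number(icosphere10, np.array([[0.0, 0.0, 0.0]]))
        w_out = winding_number(icosphere10, np.array([[0.0, 0.0, 20.0]]))
        assert w_in[0] == pytest.approx(1.0, abs=1e-9)
        assert w_out[0] == pytest.approx(0.0, abs=1e-9)


class TestDefineFroi:
    def test_patella_exempt(self, icosphere10):
        src, tgt = define_froi(icosphere10, icosphere10, FroiSpec(), bone="patella")
        assert src.all() and tgt.all()

    def test_identical_full_meshes_all_retained(self, icosphere10):
        src, tgt = define_froi(icosphere10, icosphere10, FroiSpec(margin=0.0), bone="femur")
        assert src.all() and tgt.all()

    def test_clipped_sphere_zone_area(self, icosphere10):
        """Retained area matches the analytic spherical zone 2*pi*r*h for z in [2, 10]."""
        half = clipped_icosphere(10.0, 0.0)
        src_mask, _ = define_froi(half, icosphere10, FroiSpec(margin=2.0), bone="femur")
        n_in = src_mask[half.faces].sum(axis=1)
        # faces straddling the clip plane count half, an O(edge^2) estimate
        retained_area = (half.area_faces * np.where(n_in == 3, 1.0, np.where(n_in > 0, 0.5, 0.0))).sum()
        assert retained_area == pytest.approx(2.0 * np.pi * 10.0 * 8.0, rel=0.05)

    def test_margin_monotonicity(self, icosphere10):
        half = clipped_icosphere(10.0, 0.0)
        counts = [
            define_froi(half, icosphere10, FroiSpec(margin=m), bone="femur")[0].sum()
            for m in (0.0, 1.0, 2.0, 4.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_empty_froi_errors(self, icosphere10):
        shifted = icosphere10.copy()
        shifted.vertices = shifted.vertices + [0, 0, 19.9]  # sliver overlap < margin
        with pytest.raises(EmptyFroiError):
            define_froi(shifted, icosphere10, FroiSpec(margin=5.0), bone="femur")


class TestSignedDistance:
    def test_self_distance_zero(self, icosphere10):
        res = signed_distance(icosphere10, icosphere10)
        assert np.abs(res.distances).max() < 1e-9

    @pytest.mark.parametrize("r_src,expected", [(10.3, 0.30), (9.7, -0.30)])
    def test_concentric_spheres_signed_mean(self, icosphere10, r_src, expected):
        """Source larger -> +0.30 mm; source smaller -> -0.30 mm."""
        res = signed_distance(icosphere(r_src), icosphere10)
        assert res.distances.mean() == pytest.approx(expected, abs=0.02)

    def test_antisymmetry_on_concentric_spheres(self, icosphere10):
        outer = icosphere(10.3)
        fwd = signed_distance(outer, icosphere10).distances.mean()
        rev = signed_distance(icosphere10, outer).distances.mean()
        assert fwd == pytest.approx(-rev, abs=0.02)

    def test_non_watertight_target_rejected_unless_fallback(self, icosphere10):
        half = clipped_icosphere(10.0, 0.0)
        with pytest.raises(ValueError, match="watertight"):
            signed_distance(icosphere10, half)
        res = signed_distance(icosphere10, half, sign_method="pseudo_normal")
        assert np.isfinite(res.distances).all()


class TestSummarizeBone:
    def test_constant_distances(self):
        res = DistanceResult(distances=np.full(10, 0.3), mask=np.ones(10, dtype=bool))
        s = summarize_bone(res, bone="patella")
        assert s.mean == pytest.approx(0.3) and s.std == pytest.approx(0.0, abs=1e-12)
        assert s.lower == pytest.approx(0.3) and s.upper == pytest.approx(0.3)

    def test_symmetric_two_values(self):
        res = DistanceResult(distances=np.array([-1.0, 1.0]), mask=np.ones(2, dtype=bool))
        s = summarize_bone(res)
        assert (s.mean, s.std) == (0.0, 1.0)
        assert s.upper == pytest.approx(1.96)

    def test_single_vertex_errors(self):
        res = DistanceResult(distances=np.array([0.1]), mask=np.ones(1, dtype=bool))
        with pytest.raises(DegenerateSampleError):
            summarize_bone(res)


class TestCompareBonePair:
    def test_identical_grids_near_zero(self):
        grid = voxelize_shape(sphere_shape(8.0, label="patella"), (0.5, 0.5, 0.5))
        res = compare_bone_pair(grid, grid, bone="patella")
        assert abs(res.summary.mean) < 0.05
        voxel_diag = np.sqrt(3 * 0.5**2)
        assert res.summary.std < voxel_diag / 4

    def test_recovers_positive_offset(self):
        """delta = +0.30, identity pose: pipeline mean within 0.30 +- 0.05."""
        pair = make_pair(PhantomSpec(bone="tibia", size=26.0, delta=0.30, sigma_noise=0.0, seed=5))
        res = compare_bone_pair(pair.grid_a, pair.grid_b, bone="tibia")
        assert res.summary.mean == pytest.approx(0.30, abs=0.05)

    def test_registration_removes_misalignment(self):
        """delta = 0 with a 5 deg + (2,-1,3) mm true pose: |mean| < 0.05 mm."""
        t = RigidTransform.from_axis_angle((0.3, 1.0, 0.5), 5.0, (2.0, -1.0, 3.0))
        pair = make_pair(
            PhantomSpec(bone="femur", size=30.0, delta=0.0, sigma_noise=0.0, transform=t, seed=5)
        )
        res = compare_bone_pair(pair.grid_a, pair.grid_b, bone="femur")
        assert abs(res.summary.mean) < 0.05
        err = res.transform.compose(pair.truth.transform.inverse())
        assert err.rotation_angle_deg < 0.5
        assert np.linalg.norm(err.translation) < 0.5

    def test_config_plumbed_through(self):
        grid = voxelize_shape(sphere_shape(6.0, label="patella"), (0.6, 0.6, 0.6))
        cfg = CompareConfig(froi=FroiSpec(margin=1.0))
        res = compare_bone_pair(grid, grid, cfg, bone="patella")
        assert res.distances.mask.all()  # patella exempt from clipping
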