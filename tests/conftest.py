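"""Shared fixtures: analytic shapes, meshes and the packaged reference table."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from bonequiv.phantom import ImplicitShape


def sphere_shape(radius: float, center=(0.0, 0.0, 0.0), label: str = "patella") -> ImplicitShape:
    """Exact signed-distance sphere, the workhorse analytic oracle."""
    c = np.asarray(center, dtype=float)
    pad = radius + 1.0
    return ImplicitShape(
        sdf=lambda p: np.linalg.norm(p - c, axis=1) - radius,
        label=label,
        bounds=np.array([c - pad, c + pad]),
        primitive_volumes=(4.0 / 3.0 * np.pi * radius**3,),
    )


@pytest.fixture(scope="session")
def icosphere10() -> trimesh.Trimesh:
    """Unit-test target: analytic sphere mesh, r = 10 mm."""
    return trimesh.creation.icosphere(subdivisions=4, radius=10.0)


@pytest.fixture(scope="session")
def fixture_table():
    from bonequiv import load_fixture_tables

    return load_fixture_tables()


@pytest.fixture(scope="session")
def group1(fixture_table):
    """Pooled patient + single-knee cadaver per-bone means (n = 56)."""
    from bonequiv import fixture_group

    return fixture_group(fixture_table, "patient+single")


@pytest.fixture(scope="session")
def group2(fixture_table):
    from bonequiv import fixture_group

    return fixture_group(fixture_table, "patient+bilateral")
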