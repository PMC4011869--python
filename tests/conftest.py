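"""Shared fixtures: analytic solids, the synthetic template, a small study."""

from __future__ import annotations

import numpy as np
import pytest

from mandigrow.mesh import TriangleMesh
from mandigrow.synthetic import (
    default_growth_model,
    generate_study,
    generate_template_mesh,
)


def make_cube(size: float = 10.0, origin=(0.0, 0.0, 0.0)) -> TriangleMesh:
    """Axis-aligned cube as 12 outward-oriented triangles."""
    o = np.asarray(origin, dtype=float)
    v = np.array(
        [[x, y, z] for x in (0, size) for y in (0, size) for z in (0, size)],
        dtype=float,
    ) + o
    f = np.array(
        [
            [0, 1, 3], [0, 3, 2], [4, 6, 7], [4, 7, 5],
            [0, 4, 5], [0, 5, 1], [2, 3, 7], [2, 7, 6],
            [0, 2, 6], [0, 6, 4], [1, 5, 7], [1, 7, 3],
        ]
    )
    return TriangleMesh(v, f, fix_orientation=True)


def make_fillet_wedge(r: float = 3.0, extent: float = 10.0, half_width: float = 5.0,
                      n_arc: int = 90, n_face: int = 24, n_y: int = 21) -> TriangleMesh:
    """Rounded right-angle wedge: planes x=0 and z=0 joined by a fillet.

    The solid occupies x >= 0, z >= 0; the exterior corner along the y-axis
    is rounded with a quarter-cylinder of radius ``r`` (arc centre line at
    (r, y, r)). The surface point closest to the corner line sits on the
    fillet at 45 degrees, at distance r*(sqrt(2)-1).
    """
    prof = []
    for z in np.linspace(extent, r, n_face, endpoint=False):
        prof.append((0.0, z))
    for phi in np.linspace(np.pi, 1.5 * np.pi, n_arc):
        prof.append((r + r * np.cos(phi), r + r * np.sin(phi)))
    for x in np.linspace(r, extent, n_face + 1)[1:]:
        prof.append((x, 0.0))
    prof = np.array(prof)
    ys = np.linspace(-half_width, half_width, n_y)
    np_prof = len(prof)
    verts = np.array([[x, y, z] for (x, z) in prof for y in ys])
    faces = []
    for i in range(np_prof - 1):
        for j in range(n_y - 1):
            a = i * n_y + j
            b = a + 1
            c = a + n_y
            d = c + 1
            faces += [[a, c, b], [b, c, d]]
    return TriangleMesh(verts, np.array(faces), validate=True)


def random_rigid_motion(rng: np.random.Generator):
    """A uniformly random rotation matrix and a translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    trans = rng.normal(scale=20.0, size=3)
    return rot, trans


@pytest.fixture()
def unit_cube():
    return make_cube(10.0)


@pytest.fixture(scope="session")
def template():
    """Default-shape template at moderate resolution (shared, read-only)."""
    return generate_template_mesh(resolution=12000)


@pytest.fixture(scope="session")
def small_study():
    """Noise-free 2-subject, 6-timepoint study for detector/measure tests."""
    model = default_growth_model(seed=3, noise_sd=0.0)
    return generate_study(2, 6, model, resolution=12000)


@pytest.fixture(scope="session")
def noisy_study():
    """2-subject, 4-timepoint study with measurement noise (manual channel)."""
    model = default_growth_model(seed=5, noise_sd=0.15)
    return generate_study(2, 4, model, resolution=9000)
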