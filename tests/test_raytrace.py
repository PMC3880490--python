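import math

import numpy as np
import pytest

from fragsig.fixtures import make_box_mesh
from fragsig.raytrace import (
    build_grid,
    next_reflection,
    next_reflection_brute,
    reflect,
    start_ray,
    trace,
)
from fragsig.surface import CONTACT, TriSurface


# ---------------------------------------------------------------------------
# Acceleration grid
# ---------------------------------------------------------------------------

def _single_triangle(verts):
    surf = TriSurface(vertices=np.asarray(verts, dtype=float), faces=np.array([[0, 1, 2]]))
    return surf


def test_triangle_inside_one_cube_gets_one_cube():
    surf = _single_triangle([[0.1, 0.1, 0.1], [0.3, 0.1, 0.1], [0.1, 0.3, 0.1]])
    grid = build_grid(surf, spacing=1.0)
    counts = np.bincount(grid.cell_faces, minlength=1)
    assert counts[0] == 1


def test_triangle_straddling_grid_planes_gets_three_cubes():
    # corners placed in three different cubes of a 1 A grid
    surf = _single_triangle([[0.9, 0.9, 0.5], [1.7, 0.9, 0.5], [0.9, 1.7, 0.5]])
    grid = build_grid(surf, spacing=1.0)
    assert (grid.cell_faces == 0).sum() == 3


def test_every_element_is_registered(box_mesh):
    grid = build_grid(box_mesh, spacing=1.0)
    assert set(np.unique(grid.cell_faces)) == set(range(box_mesh.n_faces))
    # corner membership: 1 to 3 cubes per element
    counts = np.bincount(grid.cell_faces, minlength=box_mesh.n_faces)
    assert counts.min() >= 1 and counts.max() <= 3


# ---------------------------------------------------------------------------
# Ray launch and reflection
# ---------------------------------------------------------------------------

def test_start_ray_uses_contact_elements_antiparallel_to_normal(unit_sphere_mesh):
    rng = np.random.default_rng(0)
    for _ in range(100):
        point, direction = start_ray(unit_sphere_mesh, rng)
        distances = np.linalg.norm(unit_sphere_mesh.face_centers - point, axis=1)
        f = int(np.argmin(distances))
        assert unit_sphere_mesh.face_class[f] == CONTACT
        assert np.dot(direction, unit_sphere_mesh.face_normals[f]) == pytest.approx(-1.0)
    p1, d1 = start_ray(unit_sphere_mesh, np.random.default_rng(7))
    p2, d2 = start_ray(unit_sphere_mesh, np.random.default_rng(7))
    assert np.array_equal(p1, p2) and np.array_equal(d1, d2)


def test_mirror_law():
    n = np.array([0.0, 0.0, 1.0])
    out = reflect(np.array([0.0, 0.0, -1.0]), n, cone_angle=0.0)
    np.testing.assert_allclose(out, [0, 0, 1])
    s = math.sqrt(2) / 2
    out = reflect(np.array([s, 0.0, -s]), n, cone_angle=0.0)
    np.testing.assert_allclose(out, [s, 0, s], atol=1e-15)
    with pytest.raises(ValueError):
        reflect(np.array([0.0, 0.0, 1.0]), n)  # moving away from the surface


def test_cone_perturbation_stays_in_cone_with_uniform_azimuth():
    n = np.array([0.0, 0.0, 1.0])
    d_in = np.array([0.0, 0.0, -1.0])
    rng = np.random.default_rng(123)
    cone = 5.0
    cos_min = math.cos(math.radians(cone))
    cos_dev, azimuths = [], []
    for _ in range(10_000):
        out = reflect(d_in, n, cone_angle=cone, rng=rng)
        out = out / np.linalg.norm(out)
        cos_dev.append(out[2])
        azimuths.append(math.atan2(out[1], out[0]))
    cos_dev = np.asarray(cos_dev)
    assert (cos_dev >= cos_min - 1e-12).all()
    # uniform-on-cap sampling: cos(theta) uniform on [cos(cone), 1]
    u = (1.0 - cos_dev) / (1.0 - cos_min)
    assert abs(u.mean() - 0.5) < 0.02
    assert abs(np.quantile(u, 0.25) - 0.25) < 0.03
    # azimuth uniform on the circle
    az = np.asarray(azimuths)
    assert abs(np.mean(np.cos(az))) < 0.03 and abs(np.mean(np.sin(az))) < 0.03


# ---------------------------------------------------------------------------
# Next reflection
# ---------------------------------------------------------------------------

def test_diameter_chord_in_sphere(unit_sphere_mesh):
    grid = build_grid(unit_sphere_mesh, spacing=1.0)
    # launch from a face center through the middle of the sphere
    f = 0
    point = unit_sphere_mesh.face_centers[f]
    direction = -unit_sphere_mesh.face_normals[f]
    hit = next_reflection(grid, unit_sphere_mesh, point, direction, exclude=f)
    edge = unit_sphere_mesh.max_edge_length()
    assert hit is not None
    assert abs(hit.t - 2.0) < 2 * edge


def test_grid_equals_brute_force_on_random_states(box_mesh):
    rng = np.random.default_rng(5)
    grid = build_grid(box_mesh, spacing=1.0)
    for _ in range(50):
        point = rng.uniform(-4, 4, 3)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        a = next_reflection(grid, box_mesh, point, direction)
        b = next_reflection_brute(box_mesh, point, direction)
        assert a is not None and b is not None
        assert a.element == b.element and a.t == b.t


def test_ray_through_hole_fails():
    surf = make_box_mesh(4.0, resolution=2)
    # open the mesh: drop the face straddling the +x pole
    target = int(np.argmax(surf.face_centers[:, 0] - np.abs(surf.face_centers[:, 1]) - np.abs(surf.face_centers[:, 2])))
    center = surf.face_centers[target]
    open_surf = TriSurface(
        vertices=surf.vertices, faces=np.delete(surf.faces, target, axis=0)
    )
    grid = build_grid(open_surf, spacing=1.0)
    hit = next_reflection(grid, open_surf, np.zeros(3), center / np.linalg.norm(center))
    assert hit is None


# ---------------------------------------------------------------------------
# Full traces
# ---------------------------------------------------------------------------

def test_trace_single_fragment_is_all_intra(unit_sphere_mesh):
    rt = trace(unit_sphere_mesh, n_segments=2000, seed=0)
    assert rt.n_segments == 2000
    assert rt.intra_mask.all()
    assert rt.n_reflections == rt.n_segments + rt.n_runs


def test_trace_is_deterministic_and_seed_sensitive(box_mesh):
    r1 = trace(box_mesh, n_segments=1000, seed=4)
    r2 = trace(box_mesh, n_segments=1000, seed=4)
    assert np.array_equal(r1.positions, r2.positions)
    assert np.array_equal(r1.elements, r2.elements)
    assert np.array_equal(r1.meps, r2.meps)
    r3 = trace(box_mesh, n_segments=1000, seed=5)
    assert not np.array_equal(r1.positions, r3.positions)


def test_trace_independent_of_grid_spacing(box_mesh):
    r1 = trace(box_mesh, n_segments=500, seed=2, grid_spacing=0.5)
    r2 = trace(box_mesh, n_segments=500, seed=2, grid_spacing=1.7)
    assert np.array_equal(r1.positions, r2.positions)


def test_reflections_lie_inside_their_elements(box_mesh):
    rt = trace(box_mesh, n_segments=1000, seed=6)
    v = box_mesh.vertices
    f = box_mesh.faces[rt.elements]
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    # solve for barycentric coordinates of each reflection point
    for i in range(rt.n_reflections):
        m = np.column_stack([b[i] - a[i], c[i] - a[i]])
        uv, *_ = np.linalg.lstsq(m, rt.positions[i] - a[i], rcond=None)
        u, v_ = uv
        assert -1e-6 <= u <= 1 + 1e-6
        assert -1e-6 <= v_ <= 1 + 1e-6
        assert u + v_ <= 1 + 1e-6
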