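"""geometry unit tests: metrics vs oracles, ICP, cross-sections, types."""

import numpy as np
import pytest

from conftest import (
    box_mesh,
    cylinder_mesh,
    oracle_directed_hausdorff,
    oracle_rmse_points_to_surface,
    random_convex_mesh,
)
from kneefit.geometry import (
    Contour2D,
    GeometryError,
    Mesh3D,
    Plane,
    PointCloud3D,
    RigidTransform2,
    RigidTransform3,
    cross_section,
    cross_section_loops,
    directed_hausdorff,
    icp_rigid_2d,
    icp_rigid_3d,
    rmse_points_to_surface,
)


def rot3(axis, deg):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    a = np.radians(deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * K @ K


# ---------------------------------------------------------------------------
# metric oracles (small spot checks; the 50-instance sweep is in acceptance)
# ---------------------------------------------------------------------------


def test_rmse_matches_bruteforce_oracle():
    rng = np.random.default_rng(11)
    mesh = random_convex_mesh(rng, n_points=15)
    pts = rng.normal(0, 25, (40, 3))
    assert rmse_points_to_surface(PointCloud3D(pts), mesh) == pytest.approx(
        oracle_rmse_points_to_surface(pts, mesh), abs=1e-9
    )


def test_rmse_zero_on_surface_points():
    mesh = box_mesh((10, 10, 10))
    on_surface = np.array([[5.0, 0.0, 0.0], [0.0, -5.0, 2.0], [1.0, 2.0, 5.0]])
    assert rmse_points_to_surface(PointCloud3D(on_surface), mesh) < 1e-12


def test_directed_hausdorff_matches_bruteforce():
    rng = np.random.default_rng(7)
    c = rng.normal(0, 10, (60, 2))
    b = rng.normal(0, 10, (80, 2))
    assert directed_hausdorff(c, b) == pytest.approx(
        oracle_directed_hausdorff(c, b), abs=1e-12
    )


def test_directed_hausdorff_is_asymmetric():
    # b is a superset cross shape; every c-point is near b but not vice versa
    c = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
    b = np.vstack([c, [[0.0, 50.0]]])
    assert directed_hausdorff(c, b) == pytest.approx(0.0, abs=1e-12)
    assert directed_hausdorff(b, c) == pytest.approx(50.0, abs=1e-12)
    assert directed_hausdorff(c, b) != directed_hausdorff(b, c)


def test_directed_hausdorff_densifies_contours():
    # coarse square vs its 1 mm inward offset: corner-only sampling would
    # miss the mid-edge maximum entirely on a zero-offset pair
    outer = Contour2D(np.array([[0, 0], [40, 0], [40, 40], [0, 40]], float))
    inner = Contour2D(np.array([[1, 1], [39, 1], [39, 39], [1, 39]], float))
    assert directed_hausdorff(outer, inner) == pytest.approx(np.sqrt(2), abs=0.05)


# ---------------------------------------------------------------------------
# cross sections
# ---------------------------------------------------------------------------


def test_cross_section_unit_cube():
    mesh = box_mesh((1, 1, 1))
    sec = cross_section(mesh, Plane(origin=(0, 0, 0.2), normal=(0, 0, 1)))
    assert sec.area() == pytest.approx(1.0, abs=1e-9)
    assert sec.closed


def test_cross_section_cylinder_area():
    r = 13.0
    mesh = cylinder_mesh(r, 40.0, sections=512)
    sec = cross_section(mesh, Plane(origin=(0, 0, 3.0), normal=(0, 0, 1)))
    assert sec.area() == pytest.approx(np.pi * r**2, rel=0.01)


def test_cross_section_misses_mesh():
    mesh = box_mesh((1, 1, 1))
    with pytest.raises(GeometryError, match="misses"):
        cross_section(mesh, Plane(origin=(0, 0, 5.0), normal=(0, 0, 1)))


def test_cross_section_open_loop_error():
    tm_mesh = box_mesh((10, 10, 10))
    # remove the faces of the +Z cap so a z-plane section crosses a boundary
    keep = ~np.all(tm_mesh.vertices[tm_mesh.faces][:, :, 2] > 4.9, axis=1)
    open_mesh = Mesh3D(tm_mesh.vertices, tm_mesh.faces[keep])
    with pytest.raises(GeometryError, match="open loop"):
        cross_section_loops(open_mesh, Plane(origin=(0, 0, 4.95), normal=(0.3, 0, 1)))


def test_cross_section_refinement_oracle():
    from kneefit.fitting import tibia_resection_plane
    from kneefit.synthetic import generate_bone

    bone = generate_bone("tibia", 74, 50, [0, 0, 0, 0], 0.0, seed=3)
    plane = tibia_resection_plane(bone)
    area = cross_section(bone, plane).area()
    fine = bone.to_trimesh().subdivide().subdivide()
    fine_mesh = Mesh3D(np.asarray(fine.vertices), np.asarray(fine.faces))
    area_fine = cross_section(fine_mesh, plane).area()
    assert area == pytest.approx(area_fine, rel=0.005)


# ---------------------------------------------------------------------------
# rigid registration
# ---------------------------------------------------------------------------


def test_icp_rigid_3d_identity():
    mesh = box_mesh((20, 30, 40))
    src = PointCloud3D(mesh.vertices)
    tf = icp_rigid_3d(src, mesh)
    moved = tf.apply(src.points)
    assert np.sqrt(np.mean((moved - src.points) ** 2)) < 1e-6


def test_icp_rigid_3d_recovers_perturbation():
    rng = np.random.default_rng(3)
    mesh = random_convex_mesh(rng, n_points=60, scale=30.0)
    # anisotropic stretch so the principal axes are unambiguous
    mesh = Mesh3D(mesh.vertices * [1.6, 1.0, 0.6], mesh.faces)
    samples = mesh.surface_points(800)
    R = rot3([0.3, 1.0, 0.2], 12.0)
    t = np.array([6.0, -4.0, 8.0])
    src = PointCloud3D(samples @ R.T + t)
    # ICP maps perturbed points back onto the surface
    tf = icp_rigid_3d(src, mesh)
    d = rmse_points_to_surface(PointCloud3D(tf.apply(src.points)), mesh)
    assert d < 0.1


def test_icp_rigid_2d_identity():
    sq = Contour2D(np.array([[0, 0], [30, 0], [30, 18], [0, 18]], float))
    tf = icp_rigid_2d(sq, sq)
    assert abs(tf.theta) < 1e-6
    assert abs(tf.tx) < 1e-6 and abs(tf.ty) < 1e-6


def test_icp_rigid_2d_recovers_rotation_shift():
    rng = np.random.default_rng(5)
    ang = np.sort(rng.uniform(0, 2 * np.pi, 100))
    pts = np.column_stack([30 * np.cos(ang), 18 * np.sin(ang)])
    src = Contour2D(pts)
    true = RigidTransform2(np.radians(8.0), 4.0, -2.0)
    tgt = Contour2D(true.apply(pts))
    tf = icp_rigid_2d(src, tgt)
    assert abs(np.degrees(tf.theta - true.theta)) < 0.1
    moved = tf.apply(pts)
    assert np.abs(moved - tgt.points).max() < 0.05


def test_icp_rigid_2d_circle_theta_tiebreak():
    ang = np.arange(0, 2 * np.pi, 0.02)
    circ = np.column_stack([10 * np.cos(ang), 10 * np.sin(ang)])
    src = Contour2D(circ)
    tgt = Contour2D(circ + [7.0, -3.0])
    tf = icp_rigid_2d(src, tgt)
    assert tf.theta == 0.0
    assert tf.tx == pytest.approx(7.0, abs=1e-3)
    assert tf.ty == pytest.approx(-3.0, abs=1e-3)


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


def test_rigid_transform3_rejects_improper_rotation():
    with pytest.raises(GeometryError):
        RigidTransform3(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
    with pytest.raises(GeometryError):
        RigidTransform3(2 * np.eye(3), np.zeros(3))


def test_plane_normalizes_and_rejects_zero_normal():
    p = Plane(origin=(0, 0, 0), normal=(0, 0, 5.0))
    assert np.linalg.norm(p.normal) == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(GeometryError):
        Plane(origin=(0, 0, 0), normal=(0, 0, 0))


def test_plane_coordinate_roundtrip():
    p = Plane(origin=(1, 2, 3), normal=(0.3, -0.2, 0.9))
    rng = np.random.default_rng(0)
    pts2 = rng.normal(0, 5, (20, 2))
    back = p.to_plane_coords(p.to_world(pts2))
    assert np.abs(back - pts2).max() < 1e-9


def test_contour_normalization_ccw_and_dedup():
    cw = np.array([[0, 0], [0, 1], [1, 1], [1, 1], [1, 0], [0, 0]], float)
    c = Contour2D(cw)
    assert len(c.points) == 4
    # normalized to counter-clockwise: positive signed area
    x, y = c.points[:, 0], c.points[:, 1]
    assert 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) > 0


def test_mesh_mirrored_flips_x_and_winding():
    mesh = box_mesh((2, 4, 6), center=(5, 0, 0))
    m = mesh.mirrored()
    assert m.vertices[:, 0].max() == pytest.approx(-4.0)
    v = m.to_trimesh().volume
    assert v == pytest.approx(mesh.to_trimesh().volume, rel=1e-9)
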