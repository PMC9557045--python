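"""model-training tests: correspondence, Procrustes, SSM PCA, PDM."""

import numpy as np
import pytest

from kneefit.geometry import GeometryError, Mesh3D, PointCloud3D
from kneefit.training import (
    MIN_TRAINING_SET,
    build_pdm,
    build_ssm,
    establish_correspondence,
    generalized_procrustes,
)

from conftest import box_mesh, random_convex_mesh, sphere_mesh


def rot3(axis, deg):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    a = np.radians(deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * K @ K


# ---------------------------------------------------------------------------
# correspondence
# ---------------------------------------------------------------------------


def test_correspondence_on_rigid_copies():
    base = sphere_mesh(25.0, subdivisions=3)
    template = Mesh3D(base.vertices * [1.5, 1.0, 0.7], base.faces)
    meshes = []
    for k in range(4):
        R = rot3([0.2, 1.0, 0.1 * k], 2.0 * k)
        meshes.append(Mesh3D(template.vertices @ R.T + [2.0 * k, -k, 0.5], template.faces))
    clouds = establish_correspondence(meshes, template)
    assert len(clouds) == 4
    for cloud, mesh in zip(clouds, meshes):
        pts = cloud.points if isinstance(cloud, PointCloud3D) else cloud
        assert pts.shape == template.vertices.shape
        # rigid copies: projected template vertices land near the true ones
        assert np.abs(pts - mesh.vertices).max() < 0.1


def test_correspondence_requires_min_set():
    mesh = box_mesh((10, 10, 10))
    with pytest.raises(GeometryError):
        establish_correspondence([mesh, mesh], mesh)


# ---------------------------------------------------------------------------
# generalized Procrustes
# ---------------------------------------------------------------------------


def test_procrustes_aligns_similarity_copies():
    rng = np.random.default_rng(4)
    base = rng.normal(0, 10, (50, 3))
    clouds = [
        1.2 * base @ rot3([0, 0, 1], 10).T + [5, 0, 0],
        base,
        0.9 * base @ rot3([1, 0, 0], -7).T + [0, 3, -2],
    ]
    aligned, mean = generalized_procrustes(clouds)
    for a in aligned:
        assert np.abs(a - mean).max() < 1e-6
    # the mean keeps millimetre scale: average centroid size preserved
    sizes = [np.linalg.norm(c - c.mean(axis=0)) for c in clouds]
    assert np.linalg.norm(mean - mean.mean(axis=0)) == pytest.approx(
        np.mean(sizes), rel=1e-6
    )


# ---------------------------------------------------------------------------
# SSM construction
# ---------------------------------------------------------------------------


def test_build_ssm_identical_clouds_zero_variance():
    mesh = sphere_mesh(10.0, subdivisions=2)
    clouds = [PointCloud3D(mesh.vertices) for _ in range(5)]
    ssm = build_ssm(clouds, "femur", faces=mesh.faces)
    assert np.all(ssm.eigenvalues < 1e-12)
    assert np.abs(ssm.mean_shape - mesh.vertices).max() < 1e-9


def test_build_ssm_rank_one_family():
    # clouds = base + c_k * u with a fixed unit direction field u:
    # exactly one nonzero eigenvalue equal to the coefficient variance
    rng = np.random.default_rng(8)
    mesh = sphere_mesh(20.0, subdivisions=2)
    base = mesh.vertices
    u = rng.normal(0, 1, base.shape)
    u -= u.mean(axis=0)  # keep centroids identical: no similarity leakage
    u /= np.linalg.norm(u)
    # tiny coefficients so the Procrustes similarity stage is ~identity
    coeffs = np.array([-0.02, -0.01, 0.0, 0.01, 0.02])
    clouds = [PointCloud3D(base + c * u) for c in coeffs]
    ssm = build_ssm(clouds, "femur", faces=mesh.faces)
    lam = ssm.eigenvalues
    assert lam[0] == pytest.approx(np.var(coeffs), rel=1e-2)
    assert np.all(lam[1:] < 1e-6 * lam[0])
    # leading mode parallel to u up to sign (the Procrustes similarity stage
    # removes the small rotation/scale component of the random direction u)
    m0 = ssm.modes[:, 0].reshape(-1, 3)
    assert abs(np.sum(m0 * u)) > 0.99


def test_build_ssm_order_invariance():
    rng = np.random.default_rng(9)
    mesh = sphere_mesh(15.0, subdivisions=2)
    clouds = [
        PointCloud3D(mesh.vertices + rng.normal(0, 0.5, mesh.vertices.shape))
        for _ in range(6)
    ]
    a = build_ssm(clouds, "tibia", faces=mesh.faces)
    b = build_ssm(list(reversed(clouds)), "tibia", faces=mesh.faces)
    # the spectrum is order-invariant; the mean shape agrees up to the
    # rotational gauge freedom of the Procrustes frame, so compare sizes
    assert np.allclose(a.eigenvalues, b.eigenvalues, atol=1e-9)
    assert np.linalg.norm(a.mean_shape - a.mean_shape.mean(0)) == pytest.approx(
        np.linalg.norm(b.mean_shape - b.mean_shape.mean(0)), rel=1e-9
    )


def test_build_ssm_requires_min_set():
    mesh = sphere_mesh(10.0, subdivisions=1)
    clouds = [PointCloud3D(mesh.vertices)] * (MIN_TRAINING_SET - 1)
    with pytest.raises(GeometryError):
        build_ssm(clouds, "femur")


# ---------------------------------------------------------------------------
# PDM construction
# ---------------------------------------------------------------------------


def test_build_pdm_sphere_depth_profile():
    # sphere silhouette generator lies in the sphere's mid-plane, so a sphere
    # centred at out-of-plane offset d has a constant depth profile of d
    centred = sphere_mesh(25.0, subdivisions=3)
    pdm0 = build_pdm([centred] * 3, "AP", "femur", P=90)
    assert pdm0.P == 90
    assert pdm0.train_mean_extent == pytest.approx(50.0, rel=0.02)
    assert np.abs(pdm0.mean_depth).max() < 0.3

    shifted = Mesh3D(centred.vertices + [0.0, 7.0, 0.0], centred.faces)
    pdm7 = build_pdm([shifted] * 3, "AP", "femur", P=90)
    assert np.allclose(pdm7.mean_depth, 7.0, atol=0.3)


def test_build_pdm_requires_min_set():
    with pytest.raises(GeometryError):
        build_pdm([sphere_mesh(10.0)], "AP", "femur")


def test_build_pdm_rejects_bad_tags():
    meshes = [sphere_mesh(10.0, subdivisions=2) for _ in range(3)]
    with pytest.raises(GeometryError):
        build_pdm(meshes, "oblique", "femur")
    with pytest.raises(GeometryError):
        build_pdm(meshes, "AP", "patella")
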