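"""synthetic-data tests: bone generator, silhouettes, population sampling."""

import numpy as np
import pytest

from kneefit.geometry import GeometryError
from kneefit.reconstruction import mask_to_contour
from kneefit.synthetic import (
    DemographicsConfig,
    _subject_dims,
    generate_bone,
    generate_population,
    generate_subject,
    project_silhouette,
)

from conftest import sphere_mesh


# ---------------------------------------------------------------------------
# bone generator
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("bone", ["femur", "tibia"])
def test_generate_bone_exact_dimensions(bone):
    mesh = generate_bone(bone, 68.0, 47.0, [1.0, -0.5, 0.25, 0.1], 0.0, seed=5)
    ml, ap, _ = mesh.extents
    assert ml == pytest.approx(68.0, abs=1e-9)
    assert ap == pytest.approx(47.0, abs=1e-9)
    assert mesh.vertices[:, 2].min() == pytest.approx(0.0, abs=1e-9)


def test_generate_bone_determinism():
    a = generate_bone("tibia", 72.0, 48.0, [0.5, 0, 0, 0], 1.0, seed=42)
    b = generate_bone("tibia", 72.0, 48.0, [0.5, 0, 0, 0], 1.0, seed=42)
    assert np.array_equal(a.vertices, b.vertices)
    assert np.array_equal(a.faces, b.faces)
    c = generate_bone("tibia", 72.0, 48.0, [0.5, 0, 0, 0], 1.0, seed=43)
    assert not np.array_equal(a.vertices, c.vertices)


def test_generate_bone_noise_statistics_interior():
    sd = 0.8
    clean = generate_bone("femur", 66.0, 58.0, (), 0.0, seed=10)
    noisy = generate_bone("femur", 66.0, 58.0, (), sd, seed=10)
    disp = np.linalg.norm(noisy.vertices - clean.vertices, axis=1)
    # the noise taper is inactive where the gap to every bounding plane
    # exceeds 3.5 sd; there the displacement magnitude is half-normal with
    # mean sd * sqrt(2/pi)
    v = clean.vertices
    gap = np.minimum.reduce(
        [
            v[:, 0] - v[:, 0].min(),
            v[:, 0].max() - v[:, 0],
            v[:, 1] - v[:, 1].min(),
            v[:, 1].max() - v[:, 1],
            v[:, 2] - v[:, 2].min(),
            v[:, 2].max() - v[:, 2],
        ]
    )
    interior = gap >= 3.5 * sd
    assert interior.sum() > 500
    mean = disp[interior].mean()
    expect = sd * np.sqrt(2 / np.pi)
    assert mean == pytest.approx(expect, rel=0.1)
    # extents still exact under noise
    assert noisy.extents[0] == pytest.approx(66.0, abs=1e-9)
    assert noisy.extents[1] == pytest.approx(58.0, abs=1e-9)


def test_generate_bone_validation():
    with pytest.raises(GeometryError, match="out of range"):
        generate_bone("tibia", 30.0, 50.0)
    with pytest.raises(GeometryError, match="bone"):
        generate_bone("patella", 50.0, 50.0)
    with pytest.raises(GeometryError):
        generate_bone("femur", 60.0, 55.0, noise_sd=-1.0)
    with pytest.raises(GeometryError, match="coefficients"):
        generate_bone("femur", 60.0, 55.0, [1, 1, 1, 1, 1])


# ---------------------------------------------------------------------------
# silhouette projection
# ---------------------------------------------------------------------------


def test_project_silhouette_sphere_area():
    mesh = sphere_mesh(24.0, subdivisions=3)
    for view in ("AP", "lateral"):
        mask = project_silhouette(mesh, view, spacing=0.5)
        assert mask.foreground_area == pytest.approx(np.pi * 24.0**2, rel=0.02)


def test_project_silhouette_spacing_consistency():
    mesh = generate_bone("femur", 64.0, 56.0, [1.0, 0, 0, 0], 0.0, seed=1)
    coarse = project_silhouette(mesh, "AP", spacing=1.0)
    fine = project_silhouette(mesh, "AP", spacing=0.25)
    assert coarse.foreground_area == pytest.approx(fine.foreground_area, rel=0.01)


def test_silhouette_contour_roundtrip_extents():
    mesh = generate_bone("tibia", 70.0, 46.0, (), 0.0, seed=2)
    spacing = 0.5
    mask = project_silhouette(mesh, "AP", spacing=spacing, bone="tibia")
    c = mask_to_contour(mask)
    # contour extents match the mesh's projected extents within 2 px
    assert np.ptp(c.points[:, 0]) == pytest.approx(70.0, abs=2 * spacing)
    assert np.ptp(c.points[:, 1]) == pytest.approx(
        float(np.ptp(mesh.vertices[:, 2])), abs=2 * spacing
    )


def test_project_silhouette_rejects_bad_spacing():
    mesh = sphere_mesh(10.0, subdivisions=2)
    with pytest.raises(GeometryError):
        project_silhouette(mesh, "AP", spacing=5.0)


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------


def test_subject_dims_marginals():
    cfg = DemographicsConfig()
    rng = np.random.default_rng(123)
    draws = [_subject_dims(rng, cfg) for _ in range(500)]
    sexes = [d[0] for d in draws]
    fml = np.array([d[1] for d in draws])
    fap = np.array([d[2] for d in draws])
    tml = np.array([d[3] for d in draws])
    tap = np.array([d[4] for d in draws])
    frac_f = sexes.count("F") / len(sexes)
    assert abs(frac_f - cfg.female_fraction) < 0.08
    mixed_mean = (cfg.femur_ml_mean["F"] + cfg.femur_ml_mean["M"]) / 2
    assert fml.mean() == pytest.approx(mixed_mean, abs=1.0)
    assert np.all((fml >= cfg.femur_ml_range[0]) & (fml <= cfg.femur_ml_range[1]))
    assert np.all((fap >= cfg.femur_ap_range[0]) & (fap <= cfg.femur_ap_range[1]))
    assert np.all((tml >= cfg.tibia_ml_range[0]) & (tml <= cfg.tibia_ml_range[1]))
    assert np.all((tap >= cfg.tibia_ap_range[0]) & (tap <= cfg.tibia_ap_range[1]))
    # aspect ratios roughly at the configured means
    assert (fap / fml).mean() == pytest.approx(cfg.femur_aspect_mean, abs=0.02)
    assert (tap / tml).mean() == pytest.approx(cfg.tibia_aspect_mean, abs=0.02)


def test_generate_subject_structure_and_determinism():
    s1 = generate_subject(3, seed=77)
    s2 = generate_subject(3, seed=77)
    assert s1.checksum() == s2.checksum()
    assert s1.side in ("left", "right")
    assert set(s1.masks) == {
        ("femur", "AP"),
        ("femur", "lateral"),
        ("tibia", "AP"),
        ("tibia", "lateral"),
    }
    assert s1.femur_mesh.extents[0] == pytest.approx(s1.true_ML_femur, abs=1e-9)
    assert s1.tibia_mesh.extents[1] == pytest.approx(s1.true_AP_tibia, abs=1e-9)
    s3 = generate_subject(4, seed=77)
    assert s3.checksum() != s1.checksum()


def test_generate_population_validation():
    with pytest.raises(GeometryError):
        generate_population(0)
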