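"""reconstruction tests: masks -> contours -> aligned 3D references -> SSM."""

import numpy as np
import pytest

from kneefit.geometry import Contour2D, GeometryError, PointCloud3D
from kneefit.reconstruction import (
    PDM,
    SSM,
    AlignedContour,
    MaskImage,
    align_contours_3d,
    anatomical_start_index,
    apply_pdm,
    fit_ssm,
    mask_to_contour,
    segment_grayscale,
)

from conftest import box_mesh


# ---------------------------------------------------------------------------
# masks and contours
# ---------------------------------------------------------------------------


def square_mask(n=100, spacing=0.5, view="AP", side="right"):
    px = np.ones((n, n), dtype=bool)
    return MaskImage(px, spacing, view, "femur", side)


def test_mask_to_contour_square_dimensions():
    c = mask_to_contour(square_mask(n=100, spacing=0.5))
    # 100 px at 0.5 mm/px: the half-pixel boundary spans exactly 50 mm
    assert np.ptp(c.points[:, 0]) == pytest.approx(50.0, abs=1e-9)
    assert np.ptp(c.points[:, 1]) == pytest.approx(50.0, abs=1e-9)
    assert c.closed


def test_mask_contour_area_matches_foreground_area():
    # disk: polygon area within 2% of pixel-count area
    n, spacing, r = 160, 0.5, 70.0
    i, j = np.mgrid[0:n, 0:n]
    px = (i - n / 2) ** 2 + (j - n / 2) ** 2 < r**2
    mask = MaskImage(px, spacing, "AP", "tibia", "right")
    c = mask_to_contour(mask)
    assert c.area() == pytest.approx(mask.foreground_area, rel=0.02)


def test_mask_to_contour_empty_raises():
    mask = MaskImage(np.zeros((10, 10), bool), 0.5, "AP", "femur", "right")
    with pytest.raises(GeometryError, match="empty"):
        mask_to_contour(mask)


def test_mask_to_contour_equal_components_raise():
    px = np.zeros((10, 10), bool)
    px[1:3, 1:3] = True
    px[6:8, 6:8] = True
    mask = MaskImage(px, 0.5, "AP", "femur", "right")
    with pytest.raises(GeometryError, match="equal-size"):
        mask_to_contour(mask)


def test_left_ap_mask_is_mirrored():
    px = np.zeros((20, 30), bool)
    px[5:15, 10:25] = True
    right = mask_to_contour(MaskImage(px, 1.0, "AP", "femur", "right"))
    left = mask_to_contour(MaskImage(px, 1.0, "AP", "femur", "left"))
    assert np.isclose(left.points[:, 0].min(), -right.points[:, 0].max())
    # lateral view is mirror-invariant: no flip
    lat = mask_to_contour(MaskImage(px, 1.0, "lateral", "femur", "left"))
    assert np.isclose(lat.points[:, 0].min(), right.points[:, 0].min())


def test_mask_image_validation():
    with pytest.raises(GeometryError):
        MaskImage(np.ones((4, 4)), -1.0, "AP", "femur", "right")
    with pytest.raises(GeometryError):
        MaskImage(np.ones((4, 4)), 0.5, "oblique", "femur", "right")
    with pytest.raises(GeometryError):
        MaskImage(np.ones(16), 0.5, "AP", "femur", "right")


def test_segment_grayscale_otsu_largest_component():
    img = np.full((60, 60), 10.0)
    img[10:40, 10:40] = 200.0  # main blob
    img[50:52, 50:52] = 200.0  # small distractor, dropped
    mask = segment_grayscale(img, 0.5, "AP", "femur")
    assert mask.pixels[20, 20] and not mask.pixels[51, 51]
    assert mask.pixels.sum() == 900
    with pytest.raises(GeometryError, match="constant"):
        segment_grayscale(np.zeros((10, 10)), 0.5, "AP", "femur")


# ---------------------------------------------------------------------------
# contour alignment
# ---------------------------------------------------------------------------


def rect_contour(w, h, du=0.0, dv=0.0):
    pts = np.array([[0, 0], [w, 0], [w, h], [0, h]], float) + [du, dv]
    return Contour2D(pts, closed=True)


def test_align_contours_centres_scales_and_datums():
    ap = rect_contour(60, 80, du=5.0, dv=3.0)
    lat = rect_contour(40, 88, du=-9.0, dv=12.0)  # 10% taller -> scaled down
    a_ap, a_lat = align_contours_3d(ap, lat, "femur")
    for a in (a_ap, a_lat):
        u = a.contour.points[:, 0]
        assert (u.min() + u.max()) / 2 == pytest.approx(0.0, abs=1e-9)
        assert np.ptp(a.contour.points[:, 1]) == pytest.approx(80.0, abs=1e-9)
    # femur datum: most distal (min v) points coincide within 0.5 mm
    assert abs(
        a_ap.contour.points[:, 1].min() - a_lat.contour.points[:, 1].min()
    ) < 0.5
    # tibia datum: most proximal points coincide
    t_ap, t_lat = align_contours_3d(ap, lat, "tibia")
    assert abs(
        t_ap.contour.points[:, 1].max() - t_lat.contour.points[:, 1].max()
    ) < 0.5


def test_align_contours_rejects_inconsistent_views():
    ap = rect_contour(60, 80)
    lat = rect_contour(40, 110)  # ratio 1.375 > 1.25
    with pytest.raises(GeometryError, match="inconsistent"):
        align_contours_3d(ap, lat, "femur")


def test_aligned_contour_embedding_axes():
    c = Contour2D(np.array([[1, 2], [3, 2], [3, 5], [1, 5]], float), closed=True)
    ap = AlignedContour(c, "AP", "femur")
    assert np.allclose(ap.points3d(7.0)[:, 1], 7.0)  # AP depth along Y
    assert np.allclose(ap.points3d()[:, [0, 2]], c.points)
    lat = AlignedContour(c, "lateral", "femur")
    assert np.allclose(lat.points3d(-4.0)[:, 0], -4.0)  # lateral depth along X
    assert np.allclose(lat.points3d()[:, [1, 2]], c.points)


def test_anatomical_start_index_ties_break_by_u():
    sq = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)
    # tibia: most proximal (max v); tie between (10,10) and (0,10) -> max u
    k = anatomical_start_index(sq, "tibia")
    assert tuple(sq[k]) == (10.0, 10.0)
    # femur: most distal (min v); tie -> max u
    k = anatomical_start_index(sq, "femur")
    assert tuple(sq[k]) == (10.0, 0.0)


# ---------------------------------------------------------------------------
# PDM depth lift
# ---------------------------------------------------------------------------


def test_apply_pdm_scales_depth_with_contour_extent():
    P = 64
    pdm = PDM(
        view="AP",
        bone="tibia",
        mean_depth=np.full(P, 6.0),
        depth_modes=np.zeros((P, 0)),
        variances=np.zeros(0),
        train_mean_extent=40.0,
    )
    aligned = AlignedContour(rect_contour(30, 80), "AP", "tibia")
    refs = apply_pdm(aligned, pdm)
    # contour Z extent 80 vs training mean 40 -> depths doubled
    assert np.allclose(refs.points[:, 1], 12.0)
    assert len(refs.points) == P
    # in-plane coordinates stay on the contour polyline
    assert refs.points[:, 0].min() >= -1e-9 and refs.points[:, 0].max() <= 30 + 1e-9


def test_apply_pdm_rejects_mismatched_tags():
    pdm = PDM("AP", "tibia", np.zeros(8), np.zeros((8, 0)), np.zeros(0), 40.0)
    with pytest.raises(GeometryError, match="does not match"):
        apply_pdm(AlignedContour(rect_contour(10, 10), "lateral", "tibia"), pdm)
    with pytest.raises(GeometryError, match="does not match"):
        apply_pdm(AlignedContour(rect_contour(10, 10), "AP", "femur"), pdm)


# ---------------------------------------------------------------------------
# SSM fit
# ---------------------------------------------------------------------------


def tiny_ssm():
    mesh = box_mesh((20, 30, 40))
    V = len(mesh.vertices)
    mode = np.zeros(3 * V)
    mode[::3] = 1.0  # uniform +X displacement direction
    mode /= np.linalg.norm(mode)
    return SSM(
        mean_shape=mesh.vertices,
        faces=mesh.faces,
        modes=mode[:, None],
        eigenvalues=np.array([4.0]),
        bone="femur",
    )


def test_fit_ssm_trivial_coefficients_near_zero():
    ssm = tiny_ssm()
    refs = PointCloud3D(ssm.mean_shape)
    mesh, info = fit_ssm(refs, ssm, full_output=True)
    assert info["objective"] < 1e-12
    assert np.abs(info["coeffs"]).max() < 1e-6
    assert info["scale"] == pytest.approx(1.0, abs=1e-9)


def test_fit_ssm_clamps_coefficients():
    ssm = tiny_ssm()
    # references displaced far along the mode: coefficient clamped at 3 sd
    refs = PointCloud3D(ssm.shape(np.array([100.0])))
    _, info = fit_ssm(refs, ssm, full_output=True)
    # the similarity stage may absorb some offset; the mode stays in bounds
    assert abs(info["coeffs"][0]) <= 3.0 * np.sqrt(4.0) + 1e-9


def test_fit_ssm_input_validation():
    ssm = tiny_ssm()
    with pytest.raises(GeometryError, match="at least 7"):
        fit_ssm(PointCloud3D(np.zeros((5, 3))), ssm)
    with pytest.raises(GeometryError, match="max_iter"):
        fit_ssm(PointCloud3D(ssm.mean_shape), ssm, max_iter=0)


def test_ssm_validation():
    mesh = box_mesh((1, 1, 1))
    V = len(mesh.vertices)
    with pytest.raises(GeometryError, match="orthonormal"):
        SSM(mesh.vertices, mesh.faces, np.ones((3 * V, 1)), np.array([1.0]), "femur")
    with pytest.raises(GeometryError, match="non-increasing"):
        good = np.zeros((3 * V, 2))
        good[0, 0] = 1.0
        good[1, 1] = 1.0
        SSM(mesh.vertices, mesh.faces, good, np.array([1.0, 2.0]), "femur")
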