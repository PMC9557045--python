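"""2D-to-3D reconstruction: mask -> contour -> bi-planar alignment -> sparse
3D reference points (point depth model) -> statistical-shape-model fit.

All quantities are millimetres in the canonical right-knee frame
(X medial-lateral with +X lateral, Y anterior-posterior with +Y anterior,
Z +proximal).  Left-side masks are mirrored to the right-knee convention on
ingest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label

from .geometry import Contour2D, GeometryError, Mesh3D, PointCloud3D

__all__ = [
    "MaskImage",
    "SSM",
    "PDM",
    "AlignedContour",
    "segment_grayscale",
    "mask_to_contour",
    "align_contours_3d",
    "apply_pdm",
    "fit_ssm",
    "reconstruct_bone",
    "anatomical_start_index",
    "resample_anatomical",
]

_VIEWS = ("AP", "lateral")
_BONES = ("femur", "tibia")
_SIDES = ("left", "right")


@dataclass
class MaskImage:
    """Binary silhouette image.

    ``pixels[i, j]`` covers the physical point
    ``(u, v) = (origin[0] + j*spacing, origin[1] + i*spacing)`` where (u, v)
    are the in-plane view coordinates: (X, Z) for the AP view and (Y, Z) for
    the lateral view.
    """

    pixels: np.ndarray
    spacing: float
    view: str
    bone: str
    side: str
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise GeometryError("mask pixels must be a 2D array")
        if not self.spacing > 0:
            raise GeometryError("mask spacing must be positive")
        if self.view not in _VIEWS:
            raise GeometryError(f"view must be one of {_VIEWS}")
        if self.bone not in _BONES:
            raise GeometryError(f"bone must be one of {_BONES}")
        if self.side not in _SIDES:
            raise GeometryError(f"side must be one of {_SIDES}")

    @property
    def foreground_area(self) -> float:
        """Foreground pixel count times pixel area, in mm^2."""
        return float(self.pixels.sum()) * self.spacing**2


@dataclass
class SSM:
    """Statistical shape model: mean shape plus orthonormal PCA modes."""

    mean_shape: np.ndarray  # (V, 3) mm
    faces: np.ndarray  # (F, 3) triangle indices into the mean shape
    modes: np.ndarray  # (3V, M), orthonormal columns
    eigenvalues: np.ndarray  # (M,), non-increasing, >= 0
    bone: str

    def __post_init__(self):
        self.mean_shape = np.asarray(self.mean_shape, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        self.modes = np.asarray(self.modes, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        V = len(self.mean_shape)
        if self.mean_shape.ndim != 2 or self.mean_shape.shape[1] != 3:
            raise GeometryError("mean_shape must be (V, 3)")
        if self.modes.shape[0] != 3 * V:
            raise GeometryError("modes must have 3V rows")
        if self.modes.shape[1] != len(self.eigenvalues):
            raise GeometryError("one eigenvalue per mode required")
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise GeometryError("eigenvalues must be non-increasing")
        if np.any(self.eigenvalues < -1e-9):
            raise GeometryError("eigenvalues must be non-negative")
        gram = self.modes.T @ self.modes
        if not np.allclose(gram, np.eye(self.modes.shape[1]), atol=1e-6):
            raise GeometryError("mode columns must be orthonormal")
        if self.bone not in _BONES:
            raise GeometryError(f"bone must be one of {_BONES}")

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def shape(self, coeffs: np.ndarray) -> np.ndarray:
        """mean + sum_k b_k * mode_k, returned as (V, 3) vertices."""
        b = np.zeros(self.n_modes)
        b[: len(coeffs)] = coeffs
        return self.mean_shape + (self.modes @ b).reshape(-1, 3)

    def mesh(self, coeffs=()) -> Mesh3D:
        return Mesh3D(self.shape(np.asarray(coeffs, dtype=float)), self.faces)


@dataclass
class PDM:
    """Point depth model: mean out-of-plane depth profile along the contour,
    indexed by arc-length-uniform contour position, scaled by contour size."""

    view: str
    bone: str
    mean_depth: np.ndarray  # (P,) mm
    depth_modes: np.ndarray  # (P, K)
    variances: np.ndarray  # (K,)
    train_mean_extent: float  # mean training-contour Z extent, mm

    def __post_init__(self):
        self.mean_depth = np.asarray(self.mean_depth, dtype=float)
        self.depth_modes = np.asarray(self.depth_modes, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if self.view not in _VIEWS:
            raise GeometryError(f"view must be one of {_VIEWS}")
        if self.bone not in _BONES:
            raise GeometryError(f"bone must be one of {_BONES}")
        if not np.all(np.isfinite(self.mean_depth)):
            raise GeometryError("mean_depth must be finite")
        if self.depth_modes.shape[0] != self.P:
            raise GeometryError("depth_modes must have P rows")
        if not self.train_mean_extent > 0:
            raise GeometryError("train_mean_extent must be positive")

    @property
    def P(self) -> int:
        return len(self.mean_depth)


@dataclass
class AlignedContour:
    """A view contour embedded in its canonical 3D plane.

    AP contours live in the XZ plane (out-of-plane axis Y); lateral contours
    live in the YZ plane (out-of-plane axis X).  ``contour`` holds the
    in-plane (u, v) coordinates in mm.
    """

    contour: Contour2D
    view: str
    bone: str

    def points3d(self, depth: np.ndarray | float = 0.0) -> np.ndarray:
        pts = self.contour.points
        d = np.broadcast_to(np.asarray(depth, dtype=float), (len(pts),))
        if self.view == "AP":
            return np.column_stack([pts[:, 0], d, pts[:, 1]])
        return np.column_stack([d, pts[:, 0], pts[:, 1]])


def segment_grayscale(
    image: np.ndarray,
    spacing: float,
    view: str,
    bone: str,
    side: str = "right",
    origin: tuple = (0.0, 0.0),
) -> MaskImage:
    """Fallback segmentation for synthetic grayscale projections: Otsu
    threshold (bone brighter than background) then keep only the largest
    connected foreground component."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise GeometryError("grayscale image must be a 2D array")
    if np.ptp(img) == 0:
        raise GeometryError("constant image: nothing to segment")
    fg = img > threshold_otsu(img)
    if not fg.any():
        raise GeometryError("empty segmentation")
    labels, n = label(fg, return_num=True, connectivity=1)
    sizes = np.bincount(labels.ravel())[1:]
    fg = labels == int(np.argmax(sizes)) + 1
    return MaskImage(fg, spacing, view, bone, side, origin)


def mask_to_contour(mask: MaskImage) -> Contour2D:
    """Outer boundary of the largest foreground component, in view mm.

    Left-side AP masks are mirrored about u = 0 to the right-knee
    convention (the lateral silhouette is mirror-invariant).
    """
    labels, n = label(mask.pixels, return_num=True, connectivity=1)
    if n == 0:
        raise GeometryError("empty mask")
    sizes = np.bincount(labels.ravel())[1:]
    order = np.argsort(sizes)[::-1]
    if n > 1 and sizes[order[0]] == sizes[order[1]]:
        raise GeometryError("multiple equal-size foreground components")
    comp = labels == order[0] + 1

    padded = np.pad(comp, 1).astype(float)
    loops = find_contours(padded, 0.5)
    if not loops:  # pragma: no cover - nonempty component always has a loop
        raise GeometryError("no boundary contour found")

    def loop_area(rc):
        x, y = rc[:, 1], rc[:, 0]
        return 0.5 * abs(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))

    rc = max(loops, key=loop_area)
    if not np.allclose(rc[0], rc[-1]):  # pragma: no cover
        raise GeometryError("boundary contour is not closed")
    rc = rc[:-1]
    u = mask.origin[0] + (rc[:, 1] - 1) * mask.spacing
    v = mask.origin[1] + (rc[:, 0] - 1) * mask.spacing
    if mask.side == "left" and mask.view == "AP":
        u = -u
    return Contour2D(np.column_stack([u, v]), closed=True)


def align_contours_3d(
    ap: Contour2D, lat: Contour2D, bone: str
) -> tuple[AlignedContour, AlignedContour]:
    """Embed an AP/lateral contour pair into the XZ / YZ planes.

    The lateral contour is uniformly scaled so both views share the same
    Z extent, both are centred in-plane (u midrange at 0), and the views
    are registered vertically at a shared anatomical datum: the most distal
    point for the femur, the most proximal point for the tibia.
    """
    if bone not in _BONES:
        raise GeometryError(f"bone must be one of {_BONES}")
    za = float(np.ptp(ap.points[:, 1]))
    zl = float(np.ptp(lat.points[:, 1]))
    if za <= 0 or zl <= 0:
        raise GeometryError("degenerate contour: zero Z extent")
    ratio = zl / za
    if not (0.8 <= ratio <= 1.25):
        raise GeometryError(
            f"views inconsistent: lateral/AP Z-extent ratio {ratio:.3f} "
            "outside [0.8, 1.25]"
        )

    def centred(points):
        u = points[:, 0]
        return points - [(u.min() + u.max()) / 2, 0.0]

    ap_pts = centred(ap.points)
    lat_pts = centred(lat.points * (za / zl))

    if bone == "femur":  # datum: most distal point
        datum_ap = ap_pts[:, 1].min()
        datum_lat = lat_pts[:, 1].min()
    else:  # tibia datum: most proximal point
        datum_ap = ap_pts[:, 1].max()
        datum_lat = lat_pts[:, 1].max()
    lat_pts = lat_pts + [0.0, datum_ap - datum_lat]

    return (
        AlignedContour(Contour2D(ap_pts, closed=True), "AP", bone),
        AlignedContour(Contour2D(lat_pts, closed=True), "lateral", bone),
    )


def anatomical_start_index(points: np.ndarray, bone: str) -> int:
    """Index of the arc-length start point: most distal (femur) or most
    proximal (tibia) contour point; ties broken by largest u.

    The tie band is 5% of the contour's v extent, not machine precision:
    the extremal edge of a bone silhouette is nearly flat (tibial plateau,
    paired femoral condyles), so the v-argmin alone lands on an arbitrary
    surface bump and the start point would jump between subjects.  Within
    the band the most-anterior/lateral (largest u) point is a stable corner.
    """
    v = points[:, 1]
    key = v if bone == "femur" else -v
    tol = 1e-9 + 0.05 * float(np.ptp(v))
    cand = np.flatnonzero(key <= key.min() + tol)
    return int(cand[np.argmax(points[cand, 0])])


def resample_anatomical(contour: Contour2D, P: int, bone: str) -> np.ndarray:
    """Resample a closed contour to P arc-length-uniform points starting at
    the anatomical datum point, in the contour's CCW direction."""
    dense = Contour2D(contour.densified(0.25), closed=True)
    start = anatomical_start_index(dense.points, bone)
    return dense.resample(P, start_index=start).points


def apply_pdm(aligned: AlignedContour, pdm: PDM) -> PointCloud3D:
    """Sparse 3D reference points: resampled contour points lifted out of
    plane by the size-scaled mean depth profile."""
    if aligned.view != pdm.view or aligned.bone != pdm.bone:
        raise GeometryError(
            f"PDM tag ({pdm.view}, {pdm.bone}) does not match contour "
            f"({aligned.view}, {aligned.bone})"
        )
    pts = resample_anatomical(aligned.contour, pdm.P, aligned.bone)
    extent = float(np.ptp(pts[:, 1]))
    if extent <= 0:
        raise GeometryError("degenerate contour: zero Z extent")
    depths = pdm.mean_depth * (extent / pdm.train_mean_extent)
    resampled = AlignedContour(Contour2D(pts, closed=True), aligned.view, aligned.bone)
    return PointCloud3D(resampled.points3d(depths))


def _similarity_from_pairs(src: np.ndarray, dst: np.ndarray):
    """Umeyama similarity transform (s, R, t) minimizing ||s R src + t - dst||."""
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    sc = src - mu_s
    dc = dst - mu_d
    cov = dc.T @ sc / len(src)
    U, S, Vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    var_s = (sc**2).sum() / len(src)
    if var_s <= 0:
        raise GeometryError("degenerate reference points")
    s = float(np.trace(np.diag(S) @ D) / var_s)
    t = mu_d - s * (R @ mu_s)
    return s, R, t


def fit_ssm(
    refs: PointCloud3D,
    ssm: SSM,
    max_iter: int = 30,
    clamp: float = 3.0,
    tol: float = 1e-6,
    full_output: bool = False,
):
    """Fit an SSM to sparse 3D reference points.

    Alternates (1) a similarity (rigid + uniform scale) transform of the
    current model instance onto the references by closest-point least
    squares with (2) a linear solve for the mode coefficients, each clamped
    to +/- clamp * sqrt(eigenvalue).  The closest-point objective is
    non-increasing over accepted iterates; the best iterate is returned.

    Returns the morphed mesh in the reference frame, or
    ``(mesh, info dict)`` if ``full_output``.
    """
    R = np.asarray(refs.points if isinstance(refs, PointCloud3D) else refs, dtype=float)
    if R.ndim != 2 or R.shape[1] != 3 or len(R) < 7:
        raise GeometryError("need at least 7 reference points (N, 3)")
    if max_iter < 1:
        raise GeometryError("max_iter must be >= 1")
    if clamp <= 0:
        raise GeometryError("clamp must be positive")

    M = ssm.n_modes
    sd = np.sqrt(np.maximum(ssm.eigenvalues, 0.0))
    b = np.zeros(M)
    s, rot, t = 1.0, np.eye(3), np.zeros(3)

    def instance(bvec):
        return ssm.mean_shape + (ssm.modes @ bvec).reshape(-1, 3)

    def objective(verts):
        d, _ = cKDTree(verts).query(R)
        return float(np.mean(d**2))

    best = {
        "b": b.copy(),
        "s": s,
        "rot": rot.copy(),
        "t": t.copy(),
        "obj": objective(instance(b)),
    }
    trace = [best["obj"]]
    converged = False
    for _ in range(max_iter):
        verts = s * (instance(b) @ rot.T) + t
        _, idx = cKDTree(verts).query(R)

        # (1) similarity transform of the untransformed instance onto refs
        src = instance(b)[idx]
        try:
            s, rot, t = _similarity_from_pairs(src, R)
        except np.linalg.LinAlgError:  # pragma: no cover
            break

        # (2) coefficients: rows are s * R @ mode_k at the matched vertices
        modes_v = ssm.modes.reshape(-1, 3, M)[idx]  # (N, 3, M)
        A = (s * np.einsum("ij,njm->nim", rot, modes_v)).reshape(-1, M)
        rhs = (R - (s * (ssm.mean_shape[idx] @ rot.T) + t)).reshape(-1)
        b_new, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        b_new = np.clip(b_new, -clamp * sd, clamp * sd)

        verts_new = s * (instance(b_new) @ rot.T) + t
        obj = objective(verts_new)
        trace.append(obj)
        if obj <= best["obj"]:
            gain = best["obj"] - obj
            best = {"b": b_new.copy(), "s": s, "rot": rot.copy(), "t": t.copy(), "obj": obj}
            b = b_new
            if gain < tol:
                converged = True
                break
        else:
            converged = True
            break

    if not converged:
        warnings.warn("fit_ssm did not converge within max_iter; returning best iterate")

    verts = best["s"] * (instance(best["b"]) @ best["rot"].T) + best["t"]
    mesh = Mesh3D(verts, ssm.faces)
    if full_output:
        info = {
            "coeffs": best["b"],
            "scale": best["s"],
            "rotation": best["rot"],
            "translation": best["t"],
            "objective": best["obj"],
            "trace": np.array(trace),
            "converged": converged,
        }
        return mesh, info
    return mesh


def reconstruct_bone(
    ap_mask: MaskImage, lat_mask: MaskImage, ssm: SSM, pdms: dict
) -> Mesh3D:
    """Full 2D-to-3D pipeline: bi-planar masks -> contours -> aligned 3D
    reference points (PDM depth lift) -> SSM fit.

    ``pdms`` maps view name ("AP", "lateral") to the matching :class:`PDM`.
    The returned mesh is in the canonical right-knee frame.
    """
    bone = ap_mask.bone
    if lat_mask.bone != bone:
        raise GeometryError("AP and lateral masks are for different bones")
    ap_c = mask_to_contour(ap_mask)
    lat_c = mask_to_contour(lat_mask)
    a_ap, a_lat = align_contours_3d(ap_c, lat_c, bone)
    refs = np.vstack(
        [apply_pdm(a_ap, pdms["AP"]).points, apply_pdm(a_lat, pdms["lateral"]).points]
    )
    with warnings.catch_warnings():
        # the best-iterate result is used regardless; the non-convergence
        # warning is only informative for direct fit_ssm callers
        warnings.filterwarnings("ignore", message="fit_ssm did not converge")
        return fit_ssm(PointCloud3D(refs), ssm)
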