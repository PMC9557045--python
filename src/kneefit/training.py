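"""Model training: dense correspondence, statistical shape models (SSM),
and point depth models (PDM) from sets of 3D bone meshes.

All meshes are expected in the canonical right-knee frame (X medial-lateral
with +X lateral, Y anterior-posterior with +Y anterior, Z +proximal),
millimetre units.
"""

from __future__ import annotations

import warnings

import numpy as np

from .geometry import GeometryError, Mesh3D, PointCloud3D, icp_similarity_3d
from .projection import ray_middepth, silhouette_contour
from .reconstruction import PDM, SSM, resample_anatomical

__all__ = [
    "establish_correspondence",
    "build_ssm",
    "build_pdm",
    "generalized_procrustes",
    "train_models",
    "DEFAULT_SSM_MODES",
    "DEFAULT_PDM_MESHES",
]

MIN_TRAINING_SET = 3

# Retained SSM mode count.  The synthetic population varies each bone by four
# smooth deformation modes plus an anisotropic (ML, AP) rescale, i.e. about
# six true shape degrees of freedom; modes beyond that mostly encode surface
# noise and closest-point correspondence artifacts (rim smearing), which
# degrade downstream resection-plane estimates.
DEFAULT_SSM_MODES = 6
# Depth models are trained on a 20-mesh subset (smaller dedicated depth
# training set, matching the two-tier training data sizes).
DEFAULT_PDM_MESHES = 20


# ---------------------------------------------------------------------------
# correspondence
# ---------------------------------------------------------------------------


def establish_correspondence(
    meshes: list[Mesh3D], template: Mesh3D
) -> list[PointCloud3D]:
    """Dense correspondence by template projection.

    The template is aligned to each mesh with a similarity (rigid + uniform
    scale) ICP, then every aligned template vertex is projected to its exact
    closest point on that mesh.  Every output cloud has exactly V points in
    template vertex order.  Meshes whose alignment fails are skipped with a
    warning; fewer than 3 successes is an error.
    """
    if len(meshes) < MIN_TRAINING_SET:
        raise GeometryError(
            f"need at least {MIN_TRAINING_SET} meshes, got {len(meshes)}"
        )
    clouds = []
    for i, mesh in enumerate(meshes):
        try:
            R, t, s = icp_similarity_3d(template.vertices, mesh)
            aligned = s * (template.vertices @ R.T) + t
            projected, _ = mesh.surface_query().closest(aligned)
        except GeometryError as exc:
            warnings.warn(f"correspondence failed for mesh {i}: {exc}")
            continue
        clouds.append(PointCloud3D(projected))
    if len(clouds) < MIN_TRAINING_SET:
        raise GeometryError(
            f"correspondence succeeded for only {len(clouds)} of "
            f"{len(meshes)} meshes (need {MIN_TRAINING_SET})"
        )
    return clouds


# ---------------------------------------------------------------------------
# statistical shape model
# ---------------------------------------------------------------------------


def _similarity_align(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Umeyama similarity alignment of known pairs: returns src mapped onto
    dst minimizing ||s R src + t - dst||^2."""
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
        raise GeometryError("degenerate cloud: zero spread")
    s = float(np.trace(np.diag(S) @ D) / var_s)
    return s * (sc @ R.T) + mu_d


def generalized_procrustes(
    clouds: list[np.ndarray], max_iter: int = 20, tol: float = 1e-9
) -> tuple[list[np.ndarray], np.ndarray]:
    """Generalized Procrustes analysis with similarity alignment.

    Iteratively aligns every cloud to the current mean and recomputes the
    mean; the mean is rescaled each round to the average centroid size of
    the input clouds so the result stays in millimetres.  Returns
    ``(aligned clouds, mean)``.
    """
    arrs = [np.asarray(c, dtype=float) for c in clouds]
    sizes = [float(np.linalg.norm(a - a.mean(axis=0))) for a in arrs]
    target_size = float(np.mean(sizes))
    mean = arrs[0] - arrs[0].mean(axis=0)
    aligned = arrs
    prev = np.inf
    for _ in range(max_iter):
        aligned = [_similarity_align(a, mean) for a in arrs]
        new_mean = np.mean(aligned, axis=0)
        new_mean = new_mean - new_mean.mean(axis=0)
        size = float(np.linalg.norm(new_mean))
        if size <= 0:
            raise GeometryError("degenerate mean shape")
        new_mean *= target_size / size
        change = float(np.linalg.norm(new_mean - mean)) if mean.shape == new_mean.shape else np.inf
        mean = new_mean
        if change < tol or abs(prev - change) < tol:
            break
        prev = change
    aligned = [_similarity_align(a, mean) for a in arrs]
    return aligned, mean


def build_ssm(
    clouds: list[PointCloud3D],
    bone: str,
    faces: np.ndarray | None = None,
    n_modes: int | None = None,
) -> SSM:
    """PCA shape model from correspondent point clouds.

    Clouds are brought into a common frame with generalized Procrustes
    (similarity) alignment, then the centered shape vectors are decomposed
    with PCA.  ``M = min(n - 1, n_modes)`` modes are retained; eigenvalues
    are the sample variances (1/n convention) along each mode,
    non-increasing.  ``faces`` supplies the correspondent triangulation
    (template topology) so SSM instances are meshes.
    """
    pts = [np.asarray(c.points if isinstance(c, PointCloud3D) else c, float) for c in clouds]
    if len(pts) < MIN_TRAINING_SET:
        raise GeometryError(f"need at least {MIN_TRAINING_SET} clouds, got {len(pts)}")
    V = len(pts[0])
    if any(len(p) != V for p in pts):
        raise GeometryError("all clouds must have equal point counts")

    aligned, mean = generalized_procrustes(pts)
    X = np.stack([(a - mean).reshape(-1) for a in aligned])  # (n, 3V)
    n = len(X)
    M = n - 1 if n_modes is None else min(n - 1, int(n_modes))
    if M < 1:
        raise GeometryError("need at least 2 clouds for one mode")
    _, S, Vt = np.linalg.svd(X, full_matrices=False)
    eigenvalues = (S**2) / n
    if faces is None:
        faces = np.zeros((0, 3), dtype=int)
    return SSM(
        mean_shape=mean,
        faces=np.asarray(faces, dtype=int),
        modes=Vt[:M].T,
        eigenvalues=eigenvalues[:M],
        bone=bone,
    )


# ---------------------------------------------------------------------------
# point depth model
# ---------------------------------------------------------------------------


def _contour_depths(mesh: Mesh3D, view: str, bone: str, P: int):
    """Silhouette contour resampled to P anatomical arc-length points and the
    out-of-plane depth of the silhouette generator at each point."""
    contour = silhouette_contour(mesh, view)
    pts = resample_anatomical(contour, P, bone)
    # silhouette rays graze the surface; probe marginally inside the contour
    # so the entry/exit interval is well defined
    centroid = pts.mean(axis=0)
    inward = centroid - pts
    norms = np.linalg.norm(inward, axis=1)
    probe = pts + inward / np.maximum(norms, 1e-12)[:, None] * 0.05
    depths, hit = ray_middepth(mesh, view, probe)
    if not hit.any():
        raise GeometryError("silhouette rays miss the mesh")
    if not hit.all():
        # fill rare grazing misses from the nearest hit along the contour
        idx = np.arange(P)
        miss = ~hit
        order = np.argsort(np.abs(idx[miss][:, None] - idx[hit][None, :]), axis=1)
        depths[miss] = depths[hit][order[:, 0]]
    extent = float(np.ptp(pts[:, 1]))
    return depths, extent


def build_pdm(
    meshes: list[Mesh3D],
    view: str,
    bone: str,
    P: int = 200,
    n_modes: int | None = None,
) -> PDM:
    """Point depth model: pointwise mean (plus PCA residual modes) of the
    out-of-plane silhouette-generator depth along the arc-length-resampled
    silhouette contour.  Meshes whose silhouette extraction fails are
    skipped with a warning."""
    if len(meshes) < MIN_TRAINING_SET:
        raise GeometryError(
            f"need at least {MIN_TRAINING_SET} meshes, got {len(meshes)}"
        )
    profiles, extents = [], []
    for i, mesh in enumerate(meshes):
        try:
            depths, extent = _contour_depths(mesh, view, bone, P)
        except GeometryError as exc:
            warnings.warn(f"silhouette extraction failed for mesh {i}: {exc}")
            continue
        profiles.append(depths)
        extents.append(extent)
    if len(profiles) < MIN_TRAINING_SET:
        raise GeometryError(
            f"silhouette extraction succeeded for only {len(profiles)} of "
            f"{len(meshes)} meshes (need {MIN_TRAINING_SET})"
        )
    D = np.stack(profiles)  # (n, P)
    train_mean_extent = float(np.mean(extents))
    # depths scale with bone size; build the mean in normalized units so the
    # stored profile corresponds to the training-mean extent
    scale = train_mean_extent / np.asarray(extents)
    Dn = D * scale[:, None]
    mean_depth = Dn.mean(axis=0)
    resid = Dn - mean_depth
    n = len(Dn)
    M = n - 1 if n_modes is None else min(n - 1, int(n_modes))
    _, S, Vt = np.linalg.svd(resid, full_matrices=False)
    return PDM(
        view=view,
        bone=bone,
        mean_depth=mean_depth,
        depth_modes=Vt[:M].T,
        variances=(S[:M] ** 2) / n,
        train_mean_extent=train_mean_extent,
    )


# ---------------------------------------------------------------------------
# training pipeline
# ---------------------------------------------------------------------------


def train_models(
    meshes: list[Mesh3D],
    bone: str,
    ssm_modes: int = DEFAULT_SSM_MODES,
    pdm_meshes: int = DEFAULT_PDM_MESHES,
    pdm_points: int = 200,
) -> tuple[SSM, dict]:
    """Full training pipeline for one bone: template selection, dense
    correspondence, SSM, and one PDM per view.

    The template is the training mesh whose medial-lateral extent is closest
    to the set mean (a representative mid-size shape).  PDMs use the first
    ``pdm_meshes`` meshes.  Returns ``(ssm, {"AP": pdm, "lateral": pdm})``.
    """
    if len(meshes) < MIN_TRAINING_SET:
        raise GeometryError(
            f"need at least {MIN_TRAINING_SET} meshes, got {len(meshes)}"
        )
    mean_ml = float(np.mean([m.extents[0] for m in meshes]))
    template = min(meshes, key=lambda m: abs(float(m.extents[0]) - mean_ml))
    clouds = establish_correspondence(meshes, template)
    ssm = build_ssm(clouds, bone, faces=template.faces, n_modes=ssm_modes)
    subset = meshes[: max(pdm_meshes, MIN_TRAINING_SET)]
    pdms = {v: build_pdm(subset, v, bone, P=pdm_points) for v in ("AP", "lateral")}
    return ssm, pdms
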