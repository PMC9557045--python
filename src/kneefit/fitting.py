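"""Virtual implant fitting: tibial resection, per-size registration, fit
metrics, and best-size selection.

Femur components are registered in 3D (unconstrained 6-DOF ICP of the
articular surface samples onto the bone); tibia plates are fitted in 2D
(3-DOF in-plane ICP of the plate profile onto the resection cross-section —
no flexion/extension of the plate is permitted).  Each fit is scored by the
global RMSE metric (RMS closest-point distance) and by the maximum
over/underhang metric (directed Hausdorff distance from component edges to
bone edges).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .geometry import (
    Contour2D,
    GeometryError,
    Mesh3D,
    Plane,
    PointCloud3D,
    RigidTransform2,
    RigidTransform3,
    cross_section,
    directed_hausdorff,
    icp_rigid_2d,
    icp_rigid_3d,
    rmse_points_to_polyline,
    rmse_points_to_surface,
)
from .implants import ImplantComponent, SizeChart, SizeChartEntry, build_component

__all__ = [
    "FitResult",
    "SizePrediction",
    "DOWNSIZE_TIEBREAK_TOL",
    "tibia_resection_plane",
    "fit_tibia_plate",
    "fit_femur_component",
    "fit_component",
    "predict_sizes",
    "select_best",
]

logger = logging.getLogger(__name__)

DOWNSIZE_TIEBREAK_TOL = 0.05  # mm

# resection plane: 2 mm below the widest medial-condyle point
RESECTION_OFFSET = 2.0  # mm
PLATEAU_NORMAL_Z_MIN = 0.8
PLATEAU_MIN_VERTICES = 50


@dataclass
class FitResult:
    """Outcome of fitting one component size to one bone."""

    manufacturer: str
    model: str
    component: str
    size_id: str
    transform: RigidTransform3 | RigidTransform2
    rmse: float
    max_ouh: float

    def __post_init__(self):
        if not (np.isfinite(self.rmse) and self.rmse >= 0):
            raise GeometryError("rmse must be finite and >= 0")
        if not (np.isfinite(self.max_ouh) and self.max_ouh >= 0):
            raise GeometryError("max_ouh must be finite and >= 0")


@dataclass
class SizePrediction:
    """Best sizes (per metric) of one implant model/component chart."""

    manufacturer: str
    model: str
    component: str
    best_by_rmse: str
    best_by_ouh: str
    all_fits: list
    failures: list = field(default_factory=list)  # (size_id, message)


@lru_cache(maxsize=None)
def cached_component(entry: SizeChartEntry) -> ImplantComponent:
    """Chart entries are immutable, so built components are shared."""
    return build_component(entry)


# ---------------------------------------------------------------------------
# tibial resection
# ---------------------------------------------------------------------------


def tibia_resection_plane(tibia: Mesh3D) -> Plane:
    """Resection plane: parallel to the medial plateau, passing 2 mm below
    the widest point of the medial condyle (canonical right knee: medial is
    -X).  The plateau is estimated by a least-squares plane through
    upward-facing medial-half vertices (vertex normal Z > 0.8)."""
    verts = tibia.vertices
    normals = np.asarray(tibia.to_trimesh().vertex_normals)
    medial = verts[:, 0] < 0
    plateau = medial & (normals[:, 2] > PLATEAU_NORMAL_Z_MIN)
    if plateau.sum() < PLATEAU_MIN_VERTICES:
        raise GeometryError(
            f"plateau not identifiable: {int(plateau.sum())} upward-facing "
            f"medial vertices (need {PLATEAU_MIN_VERTICES})"
        )
    p = verts[plateau]
    # least squares z = a x + b y + c  ->  normal prop to (-a, -b, 1)
    A = np.column_stack([p[:, 0], p[:, 1], np.ones(len(p))])
    (a, b, _), *_ = np.linalg.lstsq(A, p[:, 2], rcond=None)
    n = np.array([-a, -b, 1.0])
    n /= np.linalg.norm(n)

    widest = verts[medial][np.argmin(verts[medial, 0])]
    return Plane(origin=widest - RESECTION_OFFSET * n, normal=n)


# ---------------------------------------------------------------------------
# per-size fitting
# ---------------------------------------------------------------------------


def fit_tibia_plate(
    tibia: Mesh3D, component: ImplantComponent, plane: Plane | None = None
) -> FitResult:
    """3-DOF in-plane fit of a tibia plate profile onto the resection
    cross-section.  Pass ``plane`` to reuse a precomputed resection plane."""
    if component.component != "tibia":
        raise GeometryError("component is not a tibia plate")
    if plane is None:
        plane = tibia_resection_plane(tibia)
    section = cross_section(tibia, plane)

    profile = component.edges["profile"]
    tf = icp_rigid_2d(profile, section)
    rmse = rmse_points_to_polyline(tf.apply(component.surface_samples_2d), section)
    max_ouh = directed_hausdorff(component.edges["ouh"].transformed(tf), section)
    e = component.size
    return FitResult(e.manufacturer, e.model, "tibia", e.size_id, tf, rmse, max_ouh)


def _plane_section_points(mesh: Mesh3D, plane: Plane, max_spacing: float = 0.2) -> np.ndarray:
    """All mesh/plane intersection segments, densified to ``max_spacing``,
    as unordered 3D points (sufficient for directed Hausdorff targets)."""
    sd = (mesh.vertices - plane.origin) @ plane.normal
    tri = mesh.faces
    s = sd[tri]  # (F, 3)
    pos = s > 0
    npos = pos.sum(axis=1)
    crossing = (npos > 0) & (npos < 3)
    if not crossing.any():
        raise GeometryError("plane misses mesh")
    f = tri[crossing]
    sf = s[crossing]

    # per-face edge crossings for edges (0,1), (1,2), (2,0); a vertex exactly
    # on the plane yields t = 0 or 1, i.e. the vertex itself
    i_idx = np.array([0, 1, 2])
    j_idx = np.array([1, 2, 0])
    si = sf[:, i_idx]  # (Fc, 3)
    sj = sf[:, j_idx]
    hit = (si > 0) != (sj > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(hit, si / np.where(si == sj, 1.0, si - sj), 0.0)
    vi = mesh.vertices[f[:, i_idx]]  # (Fc, 3, 3)
    vj = mesh.vertices[f[:, j_idx]]
    p_edge = vi + t[:, :, None] * (vj - vi)

    # generic crossing faces have exactly 2 crossing edges; take the first two
    ok = hit.sum(axis=1) >= 2
    if not ok.any():
        raise GeometryError("plane misses mesh")
    hit = hit[ok]
    p_edge = p_edge[ok]
    first = np.argmax(hit, axis=1)
    hit2 = hit.copy()
    hit2[np.arange(len(hit)), first] = False
    second = np.argmax(hit2, axis=1)
    rows = np.arange(len(hit))
    a = p_edge[rows, first]
    b = p_edge[rows, second]

    # densify every segment to max_spacing, vectorized over segments
    length = np.linalg.norm(b - a, axis=1)
    k = np.maximum(np.ceil(length / max_spacing).astype(int), 1)
    npts = k + 1
    seg_id = np.repeat(np.arange(len(a)), npts)
    offsets = np.concatenate([[0], np.cumsum(npts)[:-1]])
    within = np.arange(npts.sum()) - np.repeat(offsets, npts)
    tv = within / np.repeat(k, npts)
    return a[seg_id] + tv[:, None] * (b - a)[seg_id]


def _femur_ouh(femur: Mesh3D, component: ImplantComponent, tf: RigidTransform3) -> float:
    """Directed Hausdorff from the component's bone-interface boundary rim
    to the bone silhouette rims at the five mating-face resection levels."""
    rim_world = tf.apply(component.mating_rim)
    bone_pts = []
    for _name, plane in component.mating_planes:
        world_plane = Plane(
            origin=tf.apply(plane.origin[None, :])[0],
            normal=tf.rotation @ plane.normal,
        )
        try:
            bone_pts.append(_plane_section_points(femur, world_plane))
        except GeometryError:
            continue
    if not bone_pts:
        raise GeometryError("no mating plane intersects the bone")
    return directed_hausdorff(rim_world, np.vstack(bone_pts))


def fit_femur_component(femur: Mesh3D, component: ImplantComponent) -> FitResult:
    """Unconstrained 6-DOF ICP fit of the femur component's articular
    surface samples onto the distal femur."""
    if component.component != "femur":
        raise GeometryError("component is not a femur component")
    samples = component.surface_samples.points

    # init: axes aligned (both canonical), component box centred on the
    # distal region of equal proximal extent
    comp_lo, comp_hi = samples.min(axis=0), samples.max(axis=0)
    zmin = femur.vertices[:, 2].min()
    distal = femur.vertices[femur.vertices[:, 2] <= zmin + 1.05 * (comp_hi[2] - comp_lo[2])]
    t0 = (distal.min(axis=0) + distal.max(axis=0)) / 2 - (comp_lo + comp_hi) / 2
    init = RigidTransform3(np.eye(3), t0)

    # register on a deterministic subsample (the pose problem is heavily
    # over-determined); metrics are evaluated on the full sample set
    sub = samples[:: max(len(samples) // 500, 1)]
    tf = icp_rigid_3d(PointCloud3D(sub), femur, init=init, tol=1e-2)
    rmse = rmse_points_to_surface(tf.apply(samples), femur)
    max_ouh = _femur_ouh(femur, component, tf)
    e = component.size
    return FitResult(e.manufacturer, e.model, "femur", e.size_id, tf, rmse, max_ouh)


def fit_component(bone_mesh: Mesh3D, component: ImplantComponent, **kw) -> FitResult:
    if component.component == "femur":
        return fit_femur_component(bone_mesh, component, **kw)
    return fit_tibia_plate(bone_mesh, component, **kw)


# ---------------------------------------------------------------------------
# best-size selection
# ---------------------------------------------------------------------------


def select_best(fits: list, metric: str, tol: float = DOWNSIZE_TIEBREAK_TOL) -> FitResult:
    """Argmin of ``metric`` over fits (in chart ordinal order) with the
    downsize tie-break: any size whose value is within ``tol`` of the minimum
    ties with it, and the smallest such ordinal wins."""
    if not fits:
        raise GeometryError("no successful fits to select from")
    vals = [getattr(f, metric) for f in fits]
    best = min(vals)
    for f, v in zip(fits, vals):
        if v < best + tol:
            return f
    raise AssertionError("unreachable")  # pragma: no cover


def predict_sizes(
    femur: Mesh3D | None,
    tibia: Mesh3D | None,
    charts: list,
    downsize_tiebreak_tol: float = DOWNSIZE_TIEBREAK_TOL,
) -> list:
    """Fit every size of every chart and select the best per metric.

    Pass ``None`` for a bone to skip charts of that component.  Single
    size-fit failures are recorded on the prediction and excluded from
    selection; a chart where every size fails raises.
    """
    if downsize_tiebreak_tol <= 0:
        raise GeometryError("downsize_tiebreak_tol must be positive")
    meshes = {"femur": femur, "tibia": tibia}
    resection = None
    if tibia is not None and any(c.component == "tibia" for c in charts):
        resection = tibia_resection_plane(tibia)
    predictions = []
    for chart in charts:
        mesh = meshes.get(chart.component)
        if mesh is None:
            continue
        fits, failures = [], []
        for entry in chart.entries:
            try:
                component = cached_component(entry)
                if chart.component == "tibia":
                    fit = fit_tibia_plate(mesh, component, plane=resection)
                else:
                    fit = fit_femur_component(mesh, component)
                fits.append(fit)
                logger.info(
                    "%s %s %s size %s: rmse=%.3f mm, max_ouh=%.3f mm",
                    entry.manufacturer, entry.model, entry.component,
                    entry.size_id, fit.rmse, fit.max_ouh,
                )
            except GeometryError as exc:
                failures.append((entry.size_id, str(exc)))
                logger.warning(
                    "%s %s %s size %s failed: %s",
                    entry.manufacturer, entry.model, entry.component,
                    entry.size_id, exc,
                )
        if not fits:
            raise GeometryError(
                f"all sizes failed for {chart.manufacturer} {chart.model} "
                f"{chart.component}: {failures}"
            )
        predictions.append(
            SizePrediction(
                manufacturer=chart.manufacturer,
                model=chart.model,
                component=chart.component,
                best_by_rmse=select_best(fits, "rmse", downsize_tiebreak_tol).size_id,
                best_by_ouh=select_best(fits, "max_ouh", downsize_tiebreak_tol).size_id,
                all_fits=fits,
                failures=failures,
            )
        )
    if not predictions:
        raise GeometryError("no chart matched the provided bones")
    return predictions
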