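"""Synthetic ground-truth data: parametric distal femora and proximal
tibiae, orthographic silhouette masks, and reproducible study populations.

Every artifact is fully deterministic given its arguments and seed.  The
femur is a lofted solid (an articular sagittal profile swept medial-laterally
with superellipse end rounding); the tibia is an implicit surface (union of
plateau lobes tapering to the shaft) polygonised by marching cubes.  Both are
deformed by a fixed four-mode smooth deformation basis, rescaled so the
medial-lateral (X) and anterior-posterior (Y) extents match the requested
dimensions exactly, and optionally perturbed by Gaussian vertex noise along
normals (tapered near the X/Y extremes so the extents survive).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import marching_cubes

from .geometry import GeometryError, Mesh3D
from .projection import rasterize_polygon, silhouette_polygon
from .reconstruction import MaskImage

__all__ = [
    "DemographicsConfig",
    "SyntheticSubject",
    "generate_bone",
    "project_silhouette",
    "generate_population",
    "N_SHAPE_MODES",
    "deformation_basis",
]

N_SHAPE_MODES = 4

# femur template: lofted solid.  The sagittal cross-section is the native
# articular J-curve (the profile family that knee implants are designed to
# replicate) closed over the top by a metaphysis/shaft cap; slices shrink
# toward the medial/lateral ends by a superellipse factor (condylar
# rounding) with a mild central waist (trochlear-groove analogue).
_FEMUR_TOP_CLOSURE = np.array(  # native (y, z) mm, anterior -> posterior
    [(22.0, 51.0), (12.0, 56.0), (-16.0, 56.0), (-24.0, 44.0)]
)
_FEMUR_END_EXPONENT = 20.0  # superellipse exponent of the ML rounding
_FEMUR_WAIST_DEPTH = 0.015  # fractional central shrink
_FEMUR_WAIST_WIDTH = 0.30  # waist Gaussian width, fraction of half-ML

# tibia template: plateau lobes as (cx, cy, ax, ay) fractions of (W, D),
# radially tapered toward the shaft and clipped flat at the plateau.
_TIBIA_LOBES = (
    (-0.22, -0.04, 0.28, 0.46),  # medial plateau lobe
    (+0.22, -0.04, 0.28, 0.46),  # lateral plateau lobe
    (0.00, 0.08, 0.40, 0.42),  # anterior bridge
)
_TIBIA_TAPER = 0.30  # radial shrink factor at the distal cut
_TIBIA_HEIGHT_RATIO = 0.90  # H = ratio * AP


def deformation_basis(vertices: np.ndarray, extents: np.ndarray, zmin: float) -> np.ndarray:
    """Fixed four-mode smooth deformation basis, evaluated at vertices.

    Returns a (4, V, 3) displacement array for unit (1 mm) coefficients, in
    normalized coordinates xn = 2x/ML, yn = 2y/AP, zn = (z - zmin)/height:

    - mode 0: distal medial-lateral flare   dx = xn * (1 - zn)
    - mode 1: distal anterior-posterior flare  dy = yn * (1 - zn)
    - mode 2: distal varus/valgus shear     dz = xn * (1 - zn)
    - mode 3: axial twist                   (dx, dy) = (-yn, xn) * (zn - 1/2)
    """
    W, D, H = extents
    xn = 2.0 * vertices[:, 0] / W
    yn = 2.0 * vertices[:, 1] / D
    zn = (vertices[:, 2] - zmin) / H
    V = len(vertices)
    basis = np.zeros((N_SHAPE_MODES, V, 3))
    basis[0, :, 0] = xn * (1 - zn)
    basis[1, :, 1] = yn * (1 - zn)
    basis[2, :, 2] = xn * (1 - zn)
    basis[3, :, 0] = -yn * (zn - 0.5)
    basis[3, :, 1] = xn * (zn - 0.5)
    return basis


def _femur_native_profile() -> np.ndarray:
    """Closed native sagittal bone profile: articular outer curve plus the
    metaphysis/shaft top closure, shifted so the distal apex is at z = 0."""
    from .implants import FEMUR_NATIVE_AP, femur_template_profile, _contiguous_run

    prof = femur_template_profile()
    ring = prof[["y", "z"]].to_numpy()
    outer = _contiguous_run(ring, prof["is_outer"].to_numpy().astype(bool))
    # outer runs posterior-top -> distal -> anterior-top; append the closure
    # anterior -> posterior so the polygon closes back to the start
    closed = np.vstack([outer, _FEMUR_TOP_CLOSURE])
    closed[:, 1] -= outer[:, 1].min()
    assert abs(np.ptp(outer[:, 0]) - FEMUR_NATIVE_AP) < 1e-6
    return closed


def _femur_loft(W: float, D: float, grid_mm: float) -> Mesh3D:
    """Swept femur solid: the scaled sagittal profile lofted along X with
    superellipse end rounding and a central waist."""
    from .implants import FEMUR_NATIVE_AP, FEMUR_NATIVE_ML

    from .geometry import Contour2D

    native = _femur_native_profile()
    sy = D / FEMUR_NATIVE_AP
    sz = 0.5 * (W / FEMUR_NATIVE_ML + sy)
    prof2d = Contour2D(native * np.array([sy, sz]), closed=True)
    n_prof = max(int(round(prof2d.perimeter / grid_mm)), 48)
    ring = prof2d.resample(n_prof).points  # (P, 2) in (y, z)
    lo = ring.min(axis=0)
    hi = ring.max(axis=0)
    centre = (lo + hi) / 2

    n_slices = max(int(round(W / grid_mm)), 16)
    # cosine spacing: slices concentrate where the rounding is fastest
    u = np.cos(np.pi * np.arange(1, n_slices) / n_slices)[::-1]  # (-1, 1)
    pe = _FEMUR_END_EXPONENT
    rho = (1.0 - np.abs(u) ** pe) ** (1.0 / pe)
    rho *= 1.0 - _FEMUR_WAIST_DEPTH * np.exp(-((u / _FEMUR_WAIST_WIDTH) ** 2))
    xs = 0.5 * W * u

    rings = centre + rho[:, None, None] * (ring - centre)  # (S, P, 2)
    verts = np.concatenate(
        [
            np.column_stack([np.repeat(xs, n_prof), rings.reshape(-1, 2)]),
            [[-0.5 * W, centre[0], centre[1]], [0.5 * W, centre[0], centre[1]]],
        ]
    )
    S, P = len(xs), n_prof
    faces = []
    for k in range(S - 1):
        a = k * P + np.arange(P)
        b = k * P + (np.arange(P) + 1) % P
        c = a + P
        d = b + P
        faces.append(np.column_stack([a, b, d]))
        faces.append(np.column_stack([a, d, c]))
    apex_lo, apex_hi = S * P, S * P + 1
    a = np.arange(P)
    b = (a + 1) % P
    faces.append(np.column_stack([np.full(P, apex_lo), b, a]))  # x = -W/2 fan
    last = (S - 1) * P
    faces.append(np.column_stack([np.full(P, apex_hi), last + a, last + b]))
    return Mesh3D(verts, np.vstack(faces))


def _tibia_field(pts, W, D, H):
    zn = np.clip(pts[..., 2] / H, 0.0, 1.0)
    rho = 1.0 - _TIBIA_TAPER * (1.0 - zn) ** 2
    x = pts[..., 0] / rho
    y = pts[..., 1] / rho
    q = np.minimum.reduce(
        [
            ((x - cx * W) / (ax * W)) ** 2 + ((y - cy * D) / (ay * D)) ** 2 - 1.0
            for cx, cy, ax, ay in _TIBIA_LOBES
        ]
    )
    q = np.maximum(q, (pts[..., 2] - H) / (0.1 * H))  # flat plateau
    return np.maximum(q, -pts[..., 2] / (0.1 * H))  # flat distal cut


def _tibia_marching_cubes(W: float, D: float, H: float, grid_mm: float) -> Mesh3D:
    lo = np.array([-0.56 * W, -0.56 * D, -0.06 * H])
    hi = np.array([0.56 * W, 0.56 * D, 1.06 * H])
    counts = np.maximum(np.ceil((hi - lo) / grid_mm).astype(int) + 1, 8)
    axes = [np.linspace(lo[i], hi[i], counts[i]) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    field = _tibia_field(grid, W, D, H)
    spacing = tuple((hi[i] - lo[i]) / (counts[i] - 1) for i in range(3))
    verts, faces, _, _ = marching_cubes(field, 0.0, spacing=spacing)
    verts = verts + lo
    tm = Mesh3D(verts, faces).to_trimesh()
    parts = tm.split(only_watertight=False)
    if len(parts) > 1:  # pragma: no cover - template is connected
        tm = max(parts, key=lambda p: len(p.vertices))
    return Mesh3D.from_trimesh(tm)


def generate_bone(
    bone: str,
    ML: float,
    AP: float,
    shape_coeffs=(),
    noise_sd: float = 0.0,
    seed: int = 0,
    grid_mm: float = 2.0,
) -> Mesh3D:
    """Deterministic parametric bone with exact (ML, AP) extents.

    ``shape_coeffs`` (up to 4, in mm) weight the fixed deformation basis;
    ``noise_sd`` adds Gaussian displacement along vertex normals.  Noise and
    deformation are applied before the final exact X/Y rescale, so measured
    extents always match the request.
    """
    if bone not in ("femur", "tibia"):
        raise GeometryError("bone must be 'femur' or 'tibia'")
    if not (40.0 <= ML <= 100.0 and 40.0 <= AP <= 100.0):
        raise GeometryError(f"dimensions out of range [40, 100] mm: ML={ML}, AP={AP}")
    if noise_sd < 0:
        raise GeometryError("noise_sd must be >= 0")
    coeffs = np.zeros(N_SHAPE_MODES)
    cs = np.asarray(shape_coeffs, dtype=float)
    if cs.size > N_SHAPE_MODES:
        raise GeometryError(f"at most {N_SHAPE_MODES} shape coefficients supported")
    coeffs[: cs.size] = cs

    if bone == "femur":
        mesh = _femur_loft(ML, AP, grid_mm)
    else:
        mesh = _tibia_marching_cubes(ML, AP, _TIBIA_HEIGHT_RATIO * AP, grid_mm)
    verts = mesh.vertices.copy()

    zmin = verts[:, 2].min()
    basis = deformation_basis(verts, np.array([ML, AP, float(np.ptp(verts[:, 2]))]), zmin)
    verts = verts + np.tensordot(coeffs, basis, axes=1)

    # exact rescale of X (ML) and Y (AP) about the box center; distal end at z=0
    for axis, target in ((0, ML), (1, AP)):
        lo, hi = verts[:, axis].min(), verts[:, axis].max()
        mid = (lo + hi) / 2
        verts[:, axis] = (verts[:, axis] - mid) * (target / (hi - lo))
    verts[:, 2] -= verts[:, 2].min()

    if noise_sd > 0:
        # Noise along vertex normals, tapered to zero near the six bounding
        # planes (and draws clipped at 3.5 sd) so the bone's measured extents
        # survive the perturbation: a vertex at distance d from an extreme
        # plane moves at most d toward it, and the extreme vertices
        # themselves do not move.  Without the Z taper the height would grow
        # by roughly the extreme noise draw (~3 sd) at each end, which is a
        # sampling artifact rather than anatomy.
        rng = np.random.default_rng(seed)
        normals = np.asarray(Mesh3D(verts, mesh.faces).to_trimesh().vertex_normals)
        z = np.clip(rng.normal(0.0, 1.0, len(verts)), -3.5, 3.5)
        gap = np.minimum.reduce(
            [
                verts[:, 0] - verts[:, 0].min(),
                verts[:, 0].max() - verts[:, 0],
                verts[:, 1] - verts[:, 1].min(),
                verts[:, 1].max() - verts[:, 1],
                verts[:, 2] - verts[:, 2].min(),
                verts[:, 2].max() - verts[:, 2],
            ]
        )
        w = np.clip(gap / (3.5 * noise_sd), 0.0, 1.0)
        verts = verts + (noise_sd * z * w)[:, None] * normals
    return Mesh3D(verts, mesh.faces)


def project_silhouette(
    mesh: Mesh3D,
    view: str,
    spacing: float = 0.5,
    bone: str = "femur",
    side: str = "right",
) -> MaskImage:
    """Orthographic binary silhouette of a mesh (AP: along Y; lateral: along X)."""
    if not (0.1 < spacing <= 1.0):
        raise GeometryError("spacing must be in (0.1, 1.0] mm/px")
    poly = silhouette_polygon(mesh, view)
    pixels, origin = rasterize_polygon(poly, spacing, pad=2 * spacing)
    return MaskImage(pixels, spacing, view, bone, side, origin)


@dataclass
class DemographicsConfig:
    """Population study conditions (defaults emulate a TKR-age cohort whose
    bone dimensions span the union of the packaged size-chart ranges)."""

    female_fraction: float = 0.5
    femur_ml_mean: dict = field(default_factory=lambda: {"F": 60.0, "M": 70.0})
    femur_ml_sd: float = 4.0
    femur_ml_range: tuple = (54.0, 82.0)
    femur_aspect_mean: float = 0.88  # AP / ML
    femur_aspect_sd: float = 0.025
    femur_ap_range: tuple = (50.0, 75.0)
    tibia_ml_offset_mean: float = 2.0  # tibia ML - femur ML
    tibia_ml_offset_sd: float = 2.0
    tibia_ml_range: tuple = (56.0, 88.0)
    tibia_aspect_mean: float = 0.67
    tibia_aspect_sd: float = 0.025
    tibia_ap_range: tuple = (40.0, 59.0)
    age_range: tuple = (46.0, 79.0)
    shape_sd: tuple = (2.0, 1.5, 1.0, 0.75)  # mm, one per deformation mode
    noise_sd: float = 1.0  # mm, vertex noise along normals
    mask_spacing: float = 0.5  # mm/px
    grid_mm: float = 2.0

    def __post_init__(self):
        if not 0.0 <= self.female_fraction <= 1.0:
            raise GeometryError("female_fraction must be in [0, 1]")
        if self.noise_sd < 0 or self.mask_spacing <= 0 or self.grid_mm <= 0:
            raise GeometryError("noise_sd, mask_spacing and grid_mm must be positive")
        if len(self.shape_sd) != N_SHAPE_MODES:
            raise GeometryError(f"shape_sd needs {N_SHAPE_MODES} entries")


@dataclass
class SyntheticSubject:
    """One synthetic study subject: bones, true dimensions, and 4 masks."""

    subject_id: str
    sex: str  # 'F' | 'M'
    age: float
    side: str  # 'left' | 'right'
    femur_mesh: Mesh3D
    tibia_mesh: Mesh3D
    true_ML_femur: float
    true_AP_femur: float
    true_ML_tibia: float
    true_AP_tibia: float
    masks: dict  # (bone, view) -> MaskImage
    seed: int

    def checksum(self) -> str:
        """Deterministic digest of meshes and masks (reproducibility probe)."""
        h = hashlib.sha256()
        for mesh in (self.femur_mesh, self.tibia_mesh):
            h.update(np.ascontiguousarray(np.round(mesh.vertices, 9)).tobytes())
            h.update(np.ascontiguousarray(mesh.faces).tobytes())
        for key in sorted(self.masks):
            h.update(np.packbits(self.masks[key].pixels).tobytes())
        return h.hexdigest()


def _subject_dims(rng: np.random.Generator, cfg: DemographicsConfig):
    sex = "F" if rng.random() < cfg.female_fraction else "M"
    fml = np.clip(rng.normal(cfg.femur_ml_mean[sex], cfg.femur_ml_sd), *cfg.femur_ml_range)
    fap = np.clip(fml * rng.normal(cfg.femur_aspect_mean, cfg.femur_aspect_sd), *cfg.femur_ap_range)
    tml = np.clip(fml + rng.normal(cfg.tibia_ml_offset_mean, cfg.tibia_ml_offset_sd), *cfg.tibia_ml_range)
    tap = np.clip(tml * rng.normal(cfg.tibia_aspect_mean, cfg.tibia_aspect_sd), *cfg.tibia_ap_range)
    return sex, float(fml), float(fap), float(tml), float(tap)


def generate_subject(index: int, seed: int, config: DemographicsConfig | None = None) -> SyntheticSubject:
    """Deterministically generate subject ``index`` of the population ``seed``."""
    cfg = config or DemographicsConfig()
    rng = np.random.default_rng([seed, index])
    sex, fml, fap, tml, tap = _subject_dims(rng, cfg)
    age = float(rng.uniform(*cfg.age_range))
    side = "left" if rng.random() < 0.5 else "right"
    coeffs = rng.normal(0.0, cfg.shape_sd)
    noise_seeds = rng.integers(0, 2**31 - 1, size=2)

    femur = generate_bone("femur", fml, fap, coeffs, cfg.noise_sd, int(noise_seeds[0]), cfg.grid_mm)
    tibia = generate_bone("tibia", tml, tap, coeffs, cfg.noise_sd, int(noise_seeds[1]), cfg.grid_mm)
    if side == "left":
        femur = femur.mirrored()
        tibia = tibia.mirrored()

    masks = {}
    for bone_name, mesh in (("femur", femur), ("tibia", tibia)):
        for view in ("AP", "lateral"):
            masks[(bone_name, view)] = project_silhouette(
                mesh, view, cfg.mask_spacing, bone=bone_name, side=side
            )
    return SyntheticSubject(
        subject_id=f"S{seed:05d}-{index:04d}",
        sex=sex,
        age=age,
        side=side,
        femur_mesh=femur,
        tibia_mesh=tibia,
        true_ML_femur=fml,
        true_AP_femur=fap,
        true_ML_tibia=tml,
        true_AP_tibia=tap,
        masks=masks,
        seed=seed,
    )


def generate_population(
    n: int, demographics: DemographicsConfig | None = None, seed: int = 0
) -> list[SyntheticSubject]:
    """Reproducible cohort of ``n`` synthetic subjects."""
    if n < 1:
        raise GeometryError("population size must be >= 1")
    cfg = demographics or DemographicsConfig()
    return [generate_subject(i, seed, cfg) for i in range(n)]
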