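"""Generic implant component geometry and manufacturer size charts.

Five commercial femur-component / tibia-plate models are represented by two
generic base templates scaled anisotropically to each chart entry's
medial-lateral (ML) and anterior-posterior (AP) dimensions:

* femur component — an extruded sagittal J-profile whose bone interface is
  five planar mating faces (anterior, anterior chamfer, distal, posterior
  chamfer, posterior); the articular (outer) surface is the smooth offset of
  that polyline at the component thickness. The superior-inferior (Z) extent
  scales with the mean of the ML and AP scale factors, keeping the component
  proportional.
* tibia plate — a symmetric kidney-shaped 2D outline (two posterior lobes, a
  shallow posterior notch); only the 2D profile is used because the plate
  interfaces with the bone on a single flat resection face. The notch is not
  part of the fit analysis: in the edge set used for over/underhang it is
  replaced by its chordal closure.

Exact manufacturer geometries are proprietary; these templates are
version-pinned as packaged profile CSVs so every downstream number is
reproducible.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
import shapely.affinity
from shapely.geometry import LineString, Point, Polygon

from .geometry import Contour2D, GeometryError, Mesh3D, Plane, PointCloud3D

# ---------------------------------------------------------------------------
# size charts
# ---------------------------------------------------------------------------

_CHART_COLUMNS = ["manufacturer", "model", "component", "size_id", "ML", "AP"]


@dataclass(frozen=True)
class SizeChartEntry:
    manufacturer: str
    model: str
    component: str  # 'femur' | 'tibia'
    size_id: str
    ML: float
    AP: float
    ordinal: int  # 0-based position in printed chart order


@dataclass
class SizeChart:
    entries: list

    def __post_init__(self):
        if len(self.entries) < 5:
            raise GeometryError("size chart needs at least 5 entries")
        mls = [e.ML for e in self.entries]
        aps = [e.AP for e in self.entries]
        if any(np.diff(mls) < 0) or any(np.diff(aps) < 0):
            raise ValueError("chart dimensions must be non-decreasing with ordinal")

    @property
    def manufacturer(self) -> str:
        return self.entries[0].manufacturer

    @property
    def model(self) -> str:
        return self.entries[0].model

    @property
    def component(self) -> str:
        return self.entries[0].component

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def entry(self, size_id: str) -> SizeChartEntry:
        for e in self.entries:
            if e.size_id == size_id:
                return e
        raise KeyError(size_id)


def _data_path(name: str):
    return resources.files("kneefit.data").joinpath(name)


def load_size_charts(path=None) -> list:
    """Load the packaged (or a user-supplied) size-chart CSV.

    Returns one :class:`SizeChart` per (manufacturer, component), in file
    order, with entries in printed chart order.
    """
    src = path if path is not None else _data_path("size_charts.csv")
    df = pd.read_csv(src, dtype={"size_id": str})
    missing = [c for c in _CHART_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"size chart missing column(s): {missing}")
    charts: dict[tuple, list] = {}
    seen = set()
    for i, row in df.iterrows():
        if row["component"] not in ("femur", "tibia"):
            raise ValueError(f"row {i}: component must be femur or tibia")
        if not (row["ML"] > 0 and row["AP"] > 0):
            raise ValueError(f"row {i}: non-positive dimension")
        key = (row["manufacturer"], row["component"])
        dup = key + (row["size_id"],)
        if dup in seen:
            raise ValueError(f"row {i}: duplicate size_id {row['size_id']!r} in chart {key}")
        seen.add(dup)
        entries = charts.setdefault(key, [])
        entries.append(SizeChartEntry(
            manufacturer=row["manufacturer"], model=row["model"],
            component=row["component"], size_id=str(row["size_id"]),
            ML=float(row["ML"]), AP=float(row["AP"]), ordinal=len(entries)))
    return [SizeChart(v) for v in charts.values()]


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

# Native femur template: Zimmer Biomet 'D' dimensions. Sagittal profile in
# (y, z) mm: posterior at y=-29, anterior +29; distal-most at z=-4.
FEMUR_NATIVE_ML = 68.0
FEMUR_NATIVE_AP = 58.0
FEMUR_THICKNESS = 9.0
# Bone-interface polyline: anterior/posterior cuts vertical, chamfers at 45
# degrees, distal cut horizontal (posterior-top -> anterior-top).
FEMUR_MATING_POLYLINE = np.array([
    (-20.0, 28.0),   # posterior face, top
    (-20.0, 14.0),   # posterior face, bottom
    (-11.0, 5.0),    # posterior chamfer -> distal
    (11.0, 5.0),     # distal -> anterior chamfer
    (20.0, 14.0),    # anterior chamfer -> anterior face
    (20.0, 45.0),    # anterior face (flange), top
])
FEMUR_NATIVE_Z = 49.0  # z extent of the native profile (-4 .. 45)

# Native tibia template: Zimmer Biomet '4' dimensions (ML x AP).
TIBIA_NATIVE_ML = 70.0
TIBIA_NATIVE_AP = 46.0
# Kidney outline as a union of ellipses: (cx, cy, semi_x, semi_y) as
# fractions of (ML, AP). Shared with the synthetic tibia plateau.
TIBIA_LOBES = (
    (-0.22, -0.04, 0.28, 0.46),  # medial lobe
    (+0.22, -0.04, 0.28, 0.46),  # lateral lobe
    (0.0, 0.08, 0.40, 0.42),     # anterior body
)
# posterior notch (fraction of ML/AP): bites into the inter-lobe boundary
TIBIA_NOTCH = (0.0, -0.34, 0.085, 0.10)


def _ellipse(cx, cy, ax, ay, quad_segs=64) -> Polygon:
    disc = Point(0, 0).buffer(1.0, quad_segs=quad_segs)
    return shapely.affinity.translate(
        shapely.affinity.scale(disc, ax, ay, origin=(0, 0)), cx, cy)


def _densify_ring(coords: np.ndarray, max_spacing: float) -> np.ndarray:
    out = []
    n = len(coords)
    for i in range(n):
        a, b = coords[i], coords[(i + 1) % n]
        L = np.linalg.norm(b - a)
        k = max(int(np.ceil(L / max_spacing)), 1)
        t = np.arange(k) / k
        out.append(a + t[:, None] * (b - a))
    return np.vstack(out)


def _ccw_ring(poly: Polygon) -> np.ndarray:
    ring = np.asarray(poly.exterior.coords)[:-1]
    x, y = ring[:, 0], ring[:, 1]
    if 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) < 0:
        ring = ring[::-1]
    return ring


def build_native_femur_profile() -> pd.DataFrame:
    """Construct the native femur sagittal cross-section.

    Returns a DataFrame of the material outline (columns ``y``, ``z``,
    ``is_outer``) ordered counter-clockwise; ``is_outer`` marks points on the
    smooth articular offset curve (used for surface sampling).
    """
    polyline = LineString(FEMUR_MATING_POLYLINE)
    band = polyline.buffer(FEMUR_THICKNESS, cap_style="flat", quad_segs=32)
    bone_side = Polygon(FEMUR_MATING_POLYLINE)
    material = band.difference(bone_side)
    if material.geom_type != "Polygon":  # pragma: no cover
        material = max(material.geoms, key=lambda g: g.area)
    ring = _densify_ring(_ccw_ring(material), max_spacing=1.2)
    d = np.array([polyline.distance(Point(p)) for p in ring])
    is_outer = np.abs(d - FEMUR_THICKNESS) < 1e-6
    return pd.DataFrame({"y": ring[:, 0], "z": ring[:, 1], "is_outer": is_outer})


def build_native_tibia_profile() -> pd.DataFrame:
    """Construct the native tibia plate outline.

    Returns a DataFrame (columns ``x``, ``y``, ``on_notch``) of the plate
    boundary, counter-clockwise, with the bounding box normalized to exactly
    (TIBIA_NATIVE_ML x TIBIA_NATIVE_AP) centered on the origin. ``on_notch``
    marks the posterior-notch points excluded from the fit-edge set.
    """
    W, D = TIBIA_NATIVE_ML, TIBIA_NATIVE_AP
    body = shapely.union_all([_ellipse(cx * W, cy * D, ax * W, ay * D)
                              for cx, cy, ax, ay in TIBIA_LOBES])
    # normalize bounding box exactly before cutting the notch
    minx, miny, maxx, maxy = body.bounds
    body = shapely.affinity.scale(body, W / (maxx - minx), D / (maxy - miny), origin=(0, 0))
    minx, miny, maxx, maxy = body.bounds
    body = shapely.affinity.translate(body, -(minx + maxx) / 2, -(miny + maxy) / 2)
    cx, cy, ax, ay = TIBIA_NOTCH
    notch = _ellipse(cx * W, cy * D, ax * W, ay * D)
    plate = body.difference(notch)
    ring = _densify_ring(_ccw_ring(plate), max_spacing=0.8)
    notch_zone = notch.buffer(1e-7)
    on_notch = np.array([notch_zone.covers(Point(p)) for p in ring])
    # boundary normalization can leave sub-nm bbox error; snap exactly
    return pd.DataFrame({"x": ring[:, 0], "y": ring[:, 1], "on_notch": on_notch})


def _load_profile(name: str, builder) -> pd.DataFrame:
    path = _data_path(name)
    if path.is_file():
        return pd.read_csv(path)
    return builder()  # pragma: no cover - packaged file normally present


def femur_template_profile() -> pd.DataFrame:
    return _load_profile("femur_profile.csv", build_native_femur_profile)


def tibia_template_profile() -> pd.DataFrame:
    return _load_profile("tibia_profile.csv", build_native_tibia_profile)


# ---------------------------------------------------------------------------
# triangulation / extrusion helpers
# ---------------------------------------------------------------------------


def triangulate_polygon_2d(points: np.ndarray) -> np.ndarray:
    """Ear-clipping triangulation of a simple CCW polygon; (T, 3) indices."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    idx = list(range(n))
    tris = []

    def cross(o, a, b):
        return ((pts[a, 0] - pts[o, 0]) * (pts[b, 1] - pts[o, 1])
                - (pts[a, 1] - pts[o, 1]) * (pts[b, 0] - pts[o, 0]))

    def point_in_tri(p, a, b, c):
        d1 = (pts[p, 0] - pts[b, 0]) * (pts[a, 1] - pts[b, 1]) - (pts[a, 0] - pts[b, 0]) * (pts[p, 1] - pts[b, 1])
        d2 = (pts[p, 0] - pts[c, 0]) * (pts[b, 1] - pts[c, 1]) - (pts[b, 0] - pts[c, 0]) * (pts[p, 1] - pts[c, 1])
        d3 = (pts[p, 0] - pts[a, 0]) * (pts[c, 1] - pts[a, 1]) - (pts[c, 0] - pts[a, 0]) * (pts[p, 1] - pts[a, 1])
        neg = (d1 < 0) or (d2 < 0) or (d3 < 0)
        pos = (d1 > 0) or (d2 > 0) or (d3 > 0)
        return not (neg and pos)

    guard = 0
    while len(idx) > 3:
        guard += 1
        if guard > 10 * n:  # pragma: no cover
            raise GeometryError("ear clipping failed (non-simple polygon?)")
        m = len(idx)
        clipped = False
        for k in range(m):
            a, b, c = idx[(k - 1) % m], idx[k], idx[(k + 1) % m]
            if cross(a, b, c) <= 1e-12:
                continue  # reflex or collinear
            others = [j for j in idx if j not in (a, b, c)]
            if any(point_in_tri(j, a, b, c) for j in others):
                continue
            tris.append((a, b, c))
            idx.pop(k)
            clipped = True
            break
        if not clipped:  # pragma: no cover - numeric fallback
            a, b, c = idx[0], idx[1], idx[2]
            tris.append((a, b, c))
            idx.pop(1)
    tris.append(tuple(idx))
    return np.array(tris, dtype=np.int64)


def extrude_profile(ring_yz: np.ndarray, half_width: float,
                    cap_tris: np.ndarray | None = None) -> Mesh3D:
    """Extrude a CCW (y, z) polygon along X to x in [-half_width, half_width]."""
    n = len(ring_yz)
    if cap_tris is None:
        cap_tris = triangulate_polygon_2d(ring_yz)
    v_lo = np.column_stack([np.full(n, -half_width), ring_yz])
    v_hi = np.column_stack([np.full(n, half_width), ring_yz])
    verts = np.vstack([v_lo, v_hi])
    faces = []
    for i in range(n):
        j = (i + 1) % n
        # side quad (i, j) between the two caps
        faces.append((i, j, n + j))
        faces.append((i, n + j, n + i))
    # medial cap (x = -hw) faces -X: reverse CCW cap winding
    faces.extend((a, c, b) for a, b, c in cap_tris)
    # lateral cap faces +X
    faces.extend((n + a, n + b, n + c) for a, b, c in cap_tris)
    return Mesh3D(verts, np.array(faces, dtype=np.int64))


# ---------------------------------------------------------------------------
# implant components
# ---------------------------------------------------------------------------


@dataclass
class ImplantComponent:
    """A chart-scaled implant component ready for virtual fitting."""

    component: str
    size: SizeChartEntry
    geometry: object  # Mesh3D (femur) or Contour2D (tibia)
    edges: dict
    surface_samples: PointCloud3D | None = None
    surface_samples_2d: np.ndarray | None = None
    mating_planes: list = field(default_factory=list)
    mating_rim: np.ndarray | None = None  # densified 3D rim of the bone interface
    central_axis: np.ndarray | None = None  # tibia rotation-axis point


def build_femur_component(entry: SizeChartEntry, n_samples: int = 2400,
                          ml_offset: float = 0.0) -> ImplantComponent:
    """Scale the femur template to a chart entry.

    X extent equals ``entry.ML + ml_offset`` (the offset models per-design
    differences in where the transepicondylar width is measured; default 0),
    Y extent equals ``entry.AP``, and the Z scale factor is the mean of the X
    and Y factors.
    """
    if entry.component != "femur":
        raise GeometryError("entry is not a femur size")
    prof = femur_template_profile()
    ring = prof[["y", "z"]].to_numpy()
    is_outer = prof["is_outer"].to_numpy().astype(bool)

    ml = entry.ML + ml_offset
    sx = ml / FEMUR_NATIVE_ML
    sy = entry.AP / FEMUR_NATIVE_AP
    sz = 0.5 * (sx + sy)
    ring_s = ring * np.array([sy, sz])
    half = ml / 2.0
    mesh = extrude_profile(ring_s, half)

    # articular (outer) band: ordered sub-path of the ring
    outer = _contiguous_run(ring_s, is_outer)
    samples = _sample_femur_surface(outer, ring_s, half, n_samples)

    poly_s = FEMUR_MATING_POLYLINE * np.array([sy, sz])
    rim = _mating_rim(poly_s, half)
    planes = _mating_planes(poly_s)
    edges = {
        "mating_rim_medial": Contour2D(poly_s, closed=False),
        "mating_rim_lateral": Contour2D(poly_s, closed=False),
    }
    return ImplantComponent(
        component="femur", size=entry, geometry=mesh, edges=edges,
        surface_samples=PointCloud3D(samples), mating_planes=planes, mating_rim=rim)


def _contiguous_run(ring: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Extract the (single) contiguous True run of ``mask`` along the ring."""
    n = len(ring)
    if mask.all():
        return ring
    # rotate so the ring starts just after a False
    start = int(np.argmin(mask))
    m = np.roll(mask, -start)
    r = np.roll(ring, -start, axis=0)
    i0 = int(np.argmax(m))
    i1 = i0 + int(np.argmin(m[i0:])) if not m[i0:].all() else n
    return r[i0:i1]


def _sample_femur_surface(outer: np.ndarray, ring: np.ndarray, half: float,
                          n_samples: int) -> np.ndarray:
    """Uniform-area deterministic sampling of the articular band and the two
    exposed end caps."""
    seg = np.diff(outer, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    arclen = float(seglen.sum())
    band_area = arclen * 2 * half
    cap_tris = triangulate_polygon_2d(ring)
    tri = ring[cap_tris]
    cap_area = float(np.abs(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])).sum() / 2)
    total = band_area + 2 * cap_area

    n_band = max(int(round(n_samples * band_area / total)), 1)
    n_cap = max(int(round(n_samples * cap_area / total)), 1)

    # band: regular (arc-length x width) grid
    n_s = max(int(round(np.sqrt(n_band * arclen / (2 * half)))), 2)
    n_x = max(int(round(n_band / n_s)), 2)
    s = (np.arange(n_s) + 0.5) * arclen / n_s
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    k = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seglen) - 1)
    frac = (s - cum[k]) / np.where(seglen[k] > 0, seglen[k], 1.0)
    band_yz = outer[k] + frac[:, None] * seg[k]
    xs = -half + (np.arange(n_x) + 0.5) * (2 * half) / n_x
    band = np.column_stack([
        np.repeat(xs, n_s),
        np.tile(band_yz[:, 0], n_x),
        np.tile(band_yz[:, 1], n_x),
    ])

    # caps: deterministic area-weighted barycentric samples
    rng = np.random.default_rng(0)
    w = np.abs(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])) / 2
    pick = rng.choice(len(tri), size=n_cap, p=w / w.sum())
    r1, r2 = rng.random(n_cap), rng.random(n_cap)
    swap = r1 + r2 > 1
    r1[swap], r2[swap] = 1 - r1[swap], 1 - r2[swap]
    pts = tri[pick, 0] + r1[:, None] * (tri[pick, 1] - tri[pick, 0]) \
        + r2[:, None] * (tri[pick, 2] - tri[pick, 0])
    cap_lo = np.column_stack([np.full(n_cap, -half), pts])
    cap_hi = np.column_stack([np.full(n_cap, half), pts])
    return np.vstack([band, cap_lo, cap_hi])


def _mating_rim(poly_s: np.ndarray, half: float, spacing: float = 0.2) -> np.ndarray:
    """Densified 3D coverage rim of the bone interface: the two sagittal
    J-polylines at the medial/lateral component ends.

    The proximal transverse edges of the anterior/posterior faces are
    deliberately excluded: at any sensible pose they lie interior to the
    bone (the bone continues proximally past them), so they have no
    bone-silhouette counterpart and would only add a size-independent
    offset to the over/underhang metric."""
    pieces = []
    c = Contour2D(poly_s, closed=False)
    dens = c.densified(spacing)
    for x in (-half, half):
        pieces.append(np.column_stack([np.full(len(dens), x), dens]))
    return np.vstack(pieces)


def _mating_planes(poly_s: np.ndarray) -> list:
    """(name, Plane) for the five mating faces, in component coordinates."""
    names = ["posterior", "posterior_chamfer", "distal", "anterior_chamfer", "anterior"]
    planes = []
    for name, a, b in zip(names, poly_s[:-1], poly_s[1:]):
        mid = (a + b) / 2
        dy, dz = (b - a) / np.linalg.norm(b - a)
        planes.append((name, Plane(origin=[0.0, mid[0], mid[1]], normal=[0.0, -dz, dy])))
    return planes


def build_tibia_profile(entry: SizeChartEntry) -> ImplantComponent:
    """Scale the tibia plate template outline to a chart entry (width = ML,
    depth = AP); the fit-edge contour replaces the posterior notch with its
    chordal closure."""
    if entry.component != "tibia":
        raise GeometryError("entry is not a tibia size")
    prof = tibia_template_profile()
    ring = prof[["x", "y"]].to_numpy()
    on_notch = prof["on_notch"].to_numpy().astype(bool)
    sx = entry.ML / TIBIA_NATIVE_ML
    sy = entry.AP / TIBIA_NATIVE_AP
    ring_s = ring * np.array([sx, sy])
    geometry = Contour2D(ring_s, closed=True)

    # "profile" (closed; notch run replaced by the straight chord across its
    # mouth) drives the in-plane registration; "ouh" (open; notch region
    # dropped entirely) is the over/underhang edge set — the notch straddles
    # the eminence rather than resting on a bone edge, so neither its arc nor
    # its mouth chord is a coverage edge.
    if on_notch.any():
        keep = _replace_notch_with_chord(ring_s, on_notch)
        ouh = _drop_notch_open(ring_s, on_notch)
    else:  # pragma: no cover
        keep = ring_s
        ouh = ring_s
    edges = {
        "profile": Contour2D(keep, closed=True),
        "ouh": Contour2D(ouh, closed=False),
    }
    # Fit samples use the chord-closed outline: the notch straddles the
    # eminence rather than resting on resected bone, so it carries no
    # coverage information and would only add a size-independent residual.
    return ImplantComponent(
        component="tibia", size=entry, geometry=geometry, edges=edges,
        surface_samples_2d=edges["profile"].densified(0.5),
        central_axis=np.zeros(2))


def _replace_notch_with_chord(ring: np.ndarray, on_notch: np.ndarray) -> np.ndarray:
    start = int(np.argmin(on_notch))
    m = np.roll(on_notch, -start)
    r = np.roll(ring, -start, axis=0)
    if not m.any():
        return ring
    i0 = int(np.argmax(m))                      # first notch point
    i1 = i0 + int(np.argmin(m[i0:])) if not m[i0:].all() else len(m)
    return np.vstack([r[:i0], r[i1:]])


def _drop_notch_open(ring: np.ndarray, on_notch: np.ndarray) -> np.ndarray:
    """Open polyline: the ring traversed from just after the notch run to
    just before it (the notch and its mouth chord are both omitted)."""
    start = int(np.argmin(on_notch))
    m = np.roll(on_notch, -start)
    r = np.roll(ring, -start, axis=0)
    if not m.any():  # pragma: no cover
        return ring
    i0 = int(np.argmax(m))
    i1 = i0 + int(np.argmin(m[i0:])) if not m[i0:].all() else len(m)
    return np.vstack([r[i1:], r[:i0]])


def build_component(entry: SizeChartEntry, **kw) -> ImplantComponent:
    if entry.component == "femur":
        return build_femur_component(entry, **kw)
    return build_tibia_profile(entry)
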