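"""Orthographic silhouette helpers shared by the synthetic generator and
model training.

View conventions (canonical right-knee frame: X = medial-lateral with +X
lateral, Y = anterior-posterior with +Y anterior, Z = +proximal):

- ``AP`` view: projection along Y; in-plane coordinates (u, v) = (X, Z).
- ``lateral`` view: projection along X; in-plane coordinates (u, v) = (Y, Z).
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Polygon

from .geometry import Contour2D, GeometryError, Mesh3D

__all__ = [
    "VIEW_AXES",
    "silhouette_polygon",
    "silhouette_contour",
    "rasterize_polygon",
    "ray_middepth",
]

# view -> (u axis, v axis, depth axis) as indices into (x, y, z)
VIEW_AXES = {"AP": (0, 2, 1), "lateral": (1, 2, 0)}


def _check_view(view: str) -> tuple[int, int, int]:
    if view not in VIEW_AXES:
        raise GeometryError(f"unknown view {view!r}; expected 'AP' or 'lateral'")
    return VIEW_AXES[view]


def silhouette_polygon(mesh: Mesh3D, view: str) -> Polygon:
    """Exact orthographic silhouette: union of all projected triangles."""
    ui, vi, _ = _check_view(view)
    tri = mesh.vertices[mesh.faces][:, :, (ui, vi)]
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    area2 = np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
    tri = tri[area2 > 1e-10]
    if len(tri) == 0:
        raise GeometryError("empty projection: no non-degenerate triangles")
    union = shapely.union_all(shapely.make_valid(shapely.polygons(tri)))
    if isinstance(union, MultiPolygon):
        union = max(union.geoms, key=lambda g: g.area)
    if union.is_empty or not isinstance(union, Polygon):
        raise GeometryError("empty projection")
    return union


def silhouette_contour(mesh: Mesh3D, view: str) -> Contour2D:
    """Outer silhouette boundary as a closed contour in view (u, v) mm."""
    poly = silhouette_polygon(mesh, view)
    ring = np.asarray(poly.exterior.coords)[:-1]
    return Contour2D(ring, closed=True)


def rasterize_polygon(
    poly: Polygon, spacing: float, pad: float = 1.0
) -> tuple[np.ndarray, tuple[float, float]]:
    """Pixel-center rasterization of a polygon.

    Returns ``(pixels, origin)`` where ``pixels[i, j]`` is True iff the
    center ``(origin[0] + j*spacing, origin[1] + i*spacing)`` lies inside
    the polygon.
    """
    if spacing <= 0:
        raise GeometryError("spacing must be positive")
    minx, miny, maxx, maxy = poly.bounds
    minx -= pad
    miny -= pad
    maxx += pad
    maxy += pad
    us = np.arange(minx + spacing / 2, maxx, spacing)
    vs = np.arange(miny + spacing / 2, maxy, spacing)
    uu, vv = np.meshgrid(us, vs, indexing="xy")
    shapely.prepare(poly)
    inside = shapely.contains_xy(poly, uu.ravel(), vv.ravel())
    pixels = inside.reshape(len(vs), len(us))
    if not pixels.any():
        raise GeometryError("empty projection: no pixel center inside silhouette")
    return pixels, (float(us[0]), float(vs[0]))


def ray_middepth(
    mesh: Mesh3D, view: str, points_uv: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mid-depth of the mesh along the view axis at in-plane points.

    For each (u, v) point, casts the orthographic ray along the depth axis
    and returns the midpoint of the [entry, exit] interval of intersection
    depths.  Returns ``(depths, hit)``; ``depths`` is NaN where the ray
    misses the mesh.
    """
    ui, vi, di = _check_view(view)
    pts = np.asarray(points_uv, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise GeometryError("points_uv must be (N, 2)")
    tri_uv = mesh.vertices[mesh.faces][:, :, (ui, vi)]
    tri_d = mesh.vertices[mesh.faces][:, :, di]

    a, b, c = tri_uv[:, 0], tri_uv[:, 1], tri_uv[:, 2]
    v0 = b - a
    v1 = c - a
    den = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
    ok = np.abs(den) > 1e-12

    depths = np.full(len(pts), np.nan)
    hit = np.zeros(len(pts), dtype=bool)
    # chunk over rays to bound memory: rays x triangles barycentric test
    chunk = max(1, int(2_000_000 / max(len(tri_uv), 1)))
    for s in range(0, len(pts), chunk):
        p = pts[s : s + chunk]  # (n, 2)
        v2 = p[:, None, :] - a[None, :, :]  # (n, T, 2)
        l1 = (v2[:, :, 0] * v1[None, :, 1] - v2[:, :, 1] * v1[None, :, 0]) / np.where(
            ok, den, 1.0
        )
        l2 = (v0[None, :, 0] * v2[:, :, 1] - v0[None, :, 1] * v2[:, :, 0]) / np.where(
            ok, den, 1.0
        )
        inside = ok[None, :] & (l1 >= -1e-9) & (l2 >= -1e-9) & (l1 + l2 <= 1 + 1e-9)
        d = (
            tri_d[None, :, 0]
            + l1 * (tri_d[None, :, 1] - tri_d[None, :, 0])
            + l2 * (tri_d[None, :, 2] - tri_d[None, :, 0])
        )
        d = np.where(inside, d, np.nan)
        any_hit = inside.any(axis=1)
        lo = np.min(np.where(inside, d, np.inf), axis=1)
        hi = np.max(np.where(inside, d, -np.inf), axis=1)
        with np.errstate(invalid="ignore"):
            depths[s : s + chunk] = np.where(any_hit, (lo + hi) / 2, np.nan)
        hit[s : s + chunk] = any_hit
    return depths, hit
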