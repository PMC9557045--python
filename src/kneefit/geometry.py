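"""Core geometric primitives for implant-to-bone fitting.

Meshes, planar contours, rigid transforms, plane cross-sections, and the two
fit metrics used throughout the package:

* global fit — the root-mean-squared closest-point distance between sampled
  component surface points and the bone surface (``rmse_points_to_surface``),
* worst local over/underhang — the directed Hausdorff distance from the
  component edges to the bone edges (``directed_hausdorff``).

All coordinates are millimetres in a right-knee frame: X medial→lateral
(+lateral), Y posterior→anterior (+anterior), Z distal→proximal (+proximal).
Left knees are mirrored about the YZ plane on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation as ScipyRotation

CANONICAL_FRAME = "right-knee X=ML(+lat) Y=AP(+ant) Z=(+prox)"


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent geometric input."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Mesh3D:
    """Triangulated surface in mm.

    ``frame_note`` records the axis convention the mesh is expressed in; the
    canonical convention is :data:`CANONICAL_FRAME`.
    """

    vertices: np.ndarray
    faces: np.ndarray
    frame_note: str = CANONICAL_FRAME
    _surface_query: "object" = field(default=None, repr=False, compare=False)
    _sample_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise GeometryError("vertices must be (V, 3)")
        if len(self.vertices) < 4:
            raise GeometryError("mesh needs at least 4 vertices")
        if not np.all(np.isfinite(self.vertices)):
            raise GeometryError("non-finite vertex coordinates")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise GeometryError("faces must be (F, 3)")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= len(self.vertices):
            raise GeometryError("face index out of range")

    # -- convenience -------------------------------------------------------

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, frame_note: str = CANONICAL_FRAME) -> "Mesh3D":
        return cls(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces), frame_note)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @property
    def extents(self) -> np.ndarray:
        """Axis-aligned (X, Y, Z) bounding-box sizes in mm."""
        return self.vertices.max(axis=0) - self.vertices.min(axis=0)

    @property
    def bounds(self) -> np.ndarray:
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def surface_query(self) -> "_SurfaceQuery":
        if self._surface_query is None:
            self._surface_query = _SurfaceQuery(self)
        return self._surface_query

    def surface_points(self, n: int = 20000) -> np.ndarray:
        """Deterministic dense point sampling of the surface (vertices plus
        uniform-area face samples); cached per requested size."""
        if n not in self._sample_cache:
            tm = self.to_trimesh()
            extra = max(n - len(self.vertices), 0)
            if extra:
                pts, _ = trimesh.sample.sample_surface(tm, extra, seed=0)
                pts = np.vstack([self.vertices, pts])
            else:
                pts = self.vertices
            self._sample_cache[n] = (pts, cKDTree(pts))
        return self._sample_cache[n][0]

    def surface_point_tree(self, n: int = 20000) -> cKDTree:
        self.surface_points(n)
        return self._sample_cache[n][1]

    def transformed(self, tf: "RigidTransform3") -> "Mesh3D":
        return Mesh3D(tf.apply(self.vertices), self.faces, self.frame_note)

    def mirrored(self) -> "Mesh3D":
        """Mirror about the YZ plane (left/right conversion); winding fixed."""
        v = self.vertices.copy()
        v[:, 0] *= -1.0
        return Mesh3D(v, self.faces[:, ::-1], self.frame_note)


@dataclass
class Contour2D:
    """Closed or open ordered polygon/polyline in mm.

    Consecutive duplicates are removed; closed contours are normalized to
    counter-clockwise orientation and do not repeat the first point.
    """

    points: np.ndarray
    closed: bool = True

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise GeometryError("contour points must be (N, 2)")
        if not np.all(np.isfinite(pts)):
            raise GeometryError("non-finite contour coordinates")
        if self.closed and len(pts) > 1 and np.linalg.norm(pts[0] - pts[-1]) < 1e-9:
            pts = pts[:-1]
        keep = np.ones(len(pts), dtype=bool)
        if len(pts) > 1:
            keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9
        pts = pts[keep]
        if len(pts) < 3:
            raise GeometryError("contour needs at least 3 distinct points")
        if self.closed and _signed_area(pts) < 0:
            pts = pts[::-1]
        self.points = pts

    @property
    def segments(self) -> np.ndarray:
        """(K, 2, 2) array of consecutive segments (closing segment included
        for closed contours)."""
        p = self.points
        q = np.roll(p, -1, axis=0) if self.closed else p[1:]
        a = p if self.closed else p[:-1]
        return np.stack([a, q], axis=1)

    @property
    def perimeter(self) -> float:
        seg = self.segments
        return float(np.linalg.norm(seg[:, 1] - seg[:, 0], axis=1).sum())

    def area(self) -> float:
        if not self.closed:
            raise GeometryError("area undefined for open contour")
        return abs(_signed_area(self.points))

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def densified(self, max_spacing: float = 0.2) -> np.ndarray:
        """Points resampled so consecutive spacing is at most ``max_spacing``."""
        seg = self.segments
        lengths = np.linalg.norm(seg[:, 1] - seg[:, 0], axis=1)
        out = []
        for (a, b), L in zip(seg, lengths):
            k = max(int(np.ceil(L / max_spacing)), 1)
            t = np.arange(k) / k
            out.append(a + t[:, None] * (b - a))
        if not self.closed:
            out.append(self.points[-1:])
        return np.vstack(out)

    def resample(self, n: int, start_index: int = 0) -> "Contour2D":
        """Arc-length uniform resampling of a closed contour to ``n`` points,
        beginning at vertex ``start_index``."""
        if not self.closed:
            raise GeometryError("resample requires a closed contour")
        p = np.roll(self.points, -start_index, axis=0)
        p = np.vstack([p, p[:1]])
        seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        targets = np.arange(n) * total / n
        idx = np.searchsorted(s, targets, side="right") - 1
        idx = np.clip(idx, 0, len(seg) - 1)
        frac = (targets - s[idx]) / np.where(seg[idx] > 0, seg[idx], 1.0)
        pts = p[idx] + frac[:, None] * (p[idx + 1] - p[idx])
        c = Contour2D.__new__(Contour2D)
        c.points = pts
        c.closed = True
        return c

    def transformed(self, tf: "RigidTransform2") -> "Contour2D":
        c = Contour2D.__new__(Contour2D)
        c.points = tf.apply(self.points)
        c.closed = self.closed
        return c


def _signed_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass
class PointCloud3D:
    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise GeometryError("points must be (N, 3)")
        if len(self.points) < 1:
            raise GeometryError("empty point cloud")
        if not np.all(np.isfinite(self.points)):
            raise GeometryError("non-finite coordinates")

    def transformed(self, tf: "RigidTransform3") -> "PointCloud3D":
        return PointCloud3D(tf.apply(self.points))


@dataclass
class RigidTransform3:
    """Proper rigid transform x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-9 or abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise GeometryError("rotation must be orthonormal with determinant +1")

    @classmethod
    def identity(cls) -> "RigidTransform3":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform3") -> "RigidTransform3":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform3(self.rotation @ other.rotation,
                               self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform3":
        return RigidTransform3(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class RigidTransform2:
    """In-plane 3-DOF transform: rotation ``theta`` about the origin followed
    by translation (tx, ty)."""

    theta: float
    tx: float
    ty: float

    def __post_init__(self):
        t = float(self.theta)
        t = (t + np.pi) % (2.0 * np.pi) - np.pi
        if t == -np.pi:
            t = np.pi
        self.theta = t

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.theta), np.sin(self.theta)
        return np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.matrix.T + np.array([self.tx, self.ty])

    def inverse(self) -> "RigidTransform2":
        R = self.matrix
        t = -R.T @ np.array([self.tx, self.ty])
        return RigidTransform2(-self.theta, t[0], t[1])


@dataclass
class Plane:
    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-9:
            if n < 1e-12:
                raise GeometryError("zero plane normal")
            self.normal = self.normal / n

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """In-plane orthonormal axes (u, v) with u the projection of global X
        (falling back to global Y when the plane is normal to X), so that the
        in-plane first coordinate tracks ML and the second AP."""
        n = self.normal
        for ref in (np.array([1.0, 0, 0]), np.array([0, 1.0, 0])):
            u = ref - np.dot(ref, n) * n
            if np.linalg.norm(u) > 1e-8:
                u = u / np.linalg.norm(u)
                return u, np.cross(n, u)
        raise GeometryError("degenerate plane basis")  # pragma: no cover

    def to_plane_coords(self, points: np.ndarray) -> np.ndarray:
        u, v = self.basis()
        d = np.asarray(points, dtype=float) - self.origin
        return np.stack([d @ u, d @ v], axis=1)

    def to_world(self, points2d: np.ndarray) -> np.ndarray:
        u, v = self.basis()
        p = np.asarray(points2d, dtype=float)
        return self.origin + p[:, :1] * u + p[:, 1:2] * v


# ---------------------------------------------------------------------------
# exact point-to-surface distance
# ---------------------------------------------------------------------------


def _closest_on_triangles(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Closest point on triangle (a,b,c) to p, pairwise (Ericson, Real-Time
    Collision Detection §5.1.5), fully vectorized."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m

    m = ~done & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    with np.errstate(invalid="ignore", divide="ignore"):
        m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
        denom = d1 - d3
        v = np.where(denom != 0, d1 / np.where(denom == 0, 1.0, denom), 0.0)
        out[m] = a[m] + v[m, None] * ab[m]
        done |= m

        m = ~done & (d6 >= 0) & (d5 <= d6)
        out[m] = c[m]
        done |= m

        vb = d5 * d2 - d1 * d6
        m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
        denom = d2 - d6
        w = np.where(denom != 0, d2 / np.where(denom == 0, 1.0, denom), 0.0)
        out[m] = a[m] + w[m, None] * ac[m]
        done |= m

        va = d3 * d6 - d5 * d4
        m = ~done & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
        denom = (d4 - d3) + (d5 - d6)
        w = np.where(denom != 0, (d4 - d3) / np.where(denom == 0, 1.0, denom), 0.0)
        out[m] = b[m] + w[m, None] * (c[m] - b[m])
        done |= m

        m = ~done
        denom = va + vb + vc
        denom = np.where(denom == 0, 1.0, denom)
        v = vb / denom
        w = vc / denom
        out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


try:  # optional JIT kernel; the numpy path below is the reference
    from numba import njit as _njit

    @_njit(cache=True)
    def _closest_candidates_jit(points, tri, flat, offsets):  # pragma: no cover
        n = points.shape[0]
        cp = np.empty((n, 3))
        dmin = np.empty(n)
        for i in range(n):
            px, py, pz = points[i, 0], points[i, 1], points[i, 2]
            best = np.inf
            bx = by = bz = 0.0
            for k in range(offsets[i], offsets[i + 1]):
                t = tri[flat[k]]
                ax, ay, az = t[0, 0], t[0, 1], t[0, 2]
                abx, aby, abz = t[1, 0] - ax, t[1, 1] - ay, t[1, 2] - az
                acx, acy, acz = t[2, 0] - ax, t[2, 1] - ay, t[2, 2] - az
                apx, apy, apz = px - ax, py - ay, pz - az
                d1 = abx * apx + aby * apy + abz * apz
                d2 = acx * apx + acy * apy + acz * apz
                if d1 <= 0.0 and d2 <= 0.0:
                    qx, qy, qz = ax, ay, az
                else:
                    bpx, bpy, bpz = px - t[1, 0], py - t[1, 1], pz - t[1, 2]
                    d3 = abx * bpx + aby * bpy + abz * bpz
                    d4 = acx * bpx + acy * bpy + acz * bpz
                    if d3 >= 0.0 and d4 <= d3:
                        qx, qy, qz = t[1, 0], t[1, 1], t[1, 2]
                    else:
                        vc = d1 * d4 - d3 * d2
                        if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
                            v = d1 / (d1 - d3) if d1 != d3 else 0.0
                            qx, qy, qz = ax + v * abx, ay + v * aby, az + v * abz
                        else:
                            cpx, cpy, cpz = px - t[2, 0], py - t[2, 1], pz - t[2, 2]
                            d5 = abx * cpx + aby * cpy + abz * cpz
                            d6 = acx * cpx + acy * cpy + acz * cpz
                            if d6 >= 0.0 and d5 <= d6:
                                qx, qy, qz = t[2, 0], t[2, 1], t[2, 2]
                            else:
                                vb = d5 * d2 - d1 * d6
                                if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
                                    w = d2 / (d2 - d6) if d2 != d6 else 0.0
                                    qx, qy, qz = ax + w * acx, ay + w * acy, az + w * acz
                                else:
                                    va = d3 * d6 - d5 * d4
                                    if va <= 0.0 and d4 - d3 >= 0.0 and d5 - d6 >= 0.0:
                                        den = (d4 - d3) + (d5 - d6)
                                        w = (d4 - d3) / den if den != 0.0 else 0.0
                                        qx = t[1, 0] + w * (t[2, 0] - t[1, 0])
                                        qy = t[1, 1] + w * (t[2, 1] - t[1, 1])
                                        qz = t[1, 2] + w * (t[2, 2] - t[1, 2])
                                    else:
                                        den = va + vb + vc
                                        if den == 0.0:
                                            den = 1.0
                                        v = vb / den
                                        w = vc / den
                                        qx = ax + v * abx + w * acx
                                        qy = ay + v * aby + w * acy
                                        qz = az + v * abz + w * acz
                dx, dy, dz = px - qx, py - qy, pz - qz
                dd = dx * dx + dy * dy + dz * dz
                if dd < best:
                    best = dd
                    bx, by, bz = qx, qy, qz
            cp[i, 0], cp[i, 1], cp[i, 2] = bx, by, bz
            dmin[i] = np.sqrt(best)
        return cp, dmin

    @_njit(cache=True)
    def _closest_block_jit(points, tri, radius, idx, dk, ub, rmax, exhaustive):  # pragma: no cover
        """Rectangular-candidate variant: ``idx``/``dk`` are the K nearest
        face centroids per point sorted by distance, enabling an early break
        once no remaining centroid ball can beat the current bound.

        Returns ``(cp, dmin, complete)``; rows with ``complete`` False (the
        K-th centroid was still within reach of the bound and the candidate
        block covers only part of the mesh) must be re-resolved exactly.
        """
        n = points.shape[0]
        K = idx.shape[1]
        cp = np.empty((n, 3))
        dmin = np.empty(n)
        complete = np.empty(n, dtype=np.bool_)
        for i in range(n):
            px, py, pz = points[i, 0], points[i, 1], points[i, 2]
            bnd = ub[i]  # proven upper bound on the true distance
            best = np.inf
            bx = by = bz = 0.0
            done = exhaustive
            for j in range(K):
                dc = dk[i, j]
                if dc - rmax > bnd:
                    done = True
                    break
                f = idx[i, j]
                if dc - radius[f] > bnd:
                    continue
                t = tri[f]
                ax, ay, az = t[0, 0], t[0, 1], t[0, 2]
                abx, aby, abz = t[1, 0] - ax, t[1, 1] - ay, t[1, 2] - az
                acx, acy, acz = t[2, 0] - ax, t[2, 1] - ay, t[2, 2] - az
                apx, apy, apz = px - ax, py - ay, pz - az
                d1 = abx * apx + aby * apy + abz * apz
                d2 = acx * apx + acy * apy + acz * apz
                if d1 <= 0.0 and d2 <= 0.0:
                    qx, qy, qz = ax, ay, az
                else:
                    bpx, bpy, bpz = px - t[1, 0], py - t[1, 1], pz - t[1, 2]
                    d3 = abx * bpx + aby * bpy + abz * bpz
                    d4 = acx * bpx + acy * bpy + acz * bpz
                    if d3 >= 0.0 and d4 <= d3:
                        qx, qy, qz = t[1, 0], t[1, 1], t[1, 2]
                    else:
                        vc = d1 * d4 - d3 * d2
                        if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
                            v = d1 / (d1 - d3) if d1 != d3 else 0.0
                            qx, qy, qz = ax + v * abx, ay + v * aby, az + v * abz
                        else:
                            cpx, cpy, cpz = px - t[2, 0], py - t[2, 1], pz - t[2, 2]
                            d5 = abx * cpx + aby * cpy + abz * cpz
                            d6 = acx * cpx + acy * cpy + acz * cpz
                            if d6 >= 0.0 and d5 <= d6:
                                qx, qy, qz = t[2, 0], t[2, 1], t[2, 2]
                            else:
                                vb = d5 * d2 - d1 * d6
                                if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
                                    w = d2 / (d2 - d6) if d2 != d6 else 0.0
                                    qx, qy, qz = ax + w * acx, ay + w * acy, az + w * acz
                                else:
                                    va = d3 * d6 - d5 * d4
                                    if va <= 0.0 and d4 - d3 >= 0.0 and d5 - d6 >= 0.0:
                                        den = (d4 - d3) + (d5 - d6)
                                        w = (d4 - d3) / den if den != 0.0 else 0.0
                                        qx = t[1, 0] + w * (t[2, 0] - t[1, 0])
                                        qy = t[1, 1] + w * (t[2, 1] - t[1, 1])
                                        qz = t[1, 2] + w * (t[2, 2] - t[1, 2])
                                    else:
                                        den = va + vb + vc
                                        if den == 0.0:
                                            den = 1.0
                                        v = vb / den
                                        w = vc / den
                                        qx = ax + v * abx + w * acx
                                        qy = ay + v * aby + w * acy
                                        qz = az + v * abz + w * acz
                dx, dy, dz = px - qx, py - qy, pz - qz
                dd = dx * dx + dy * dy + dz * dz
                if dd < best:
                    best = dd
                    bx, by, bz = qx, qy, qz
                    d = np.sqrt(dd)
                    if d < bnd:
                        bnd = d
            cp[i, 0], cp[i, 1], cp[i, 2] = bx, by, bz
            dmin[i] = np.sqrt(best)
            complete[i] = done
        return cp, dmin, complete

except ImportError:  # pragma: no cover
    _closest_candidates_jit = None
    _closest_block_jit = None


class _SurfaceQuery:
    """Exact closest-point queries against a triangle mesh, pruned with a
    nearest-vertex upper bound and a face-centroid KD-tree."""

    def __init__(self, mesh: Mesh3D):
        tri = mesh.vertices[mesh.faces]
        area2 = np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
        ok = area2 > 1e-14
        if not ok.any():
            raise GeometryError("all target faces are degenerate")
        tri = tri[ok]
        # Long sliver triangles blow up the candidate-ball radius; subdivide
        # them (the union of sub-triangles is geometrically identical, and
        # face identity is not reported) until radii are commensurate.
        radius = np.linalg.norm(tri - tri.mean(axis=1, keepdims=True), axis=2).max(axis=1)
        cap = max(2.0 * float(np.median(radius)), 1e-6)
        while radius.max() > cap:
            big = radius > cap
            t = tri[big]
            mab = (t[:, 0] + t[:, 1]) / 2
            mbc = (t[:, 1] + t[:, 2]) / 2
            mca = (t[:, 2] + t[:, 0]) / 2
            children = np.concatenate(
                [
                    np.stack([t[:, 0], mab, mca], axis=1),
                    np.stack([mab, t[:, 1], mbc], axis=1),
                    np.stack([mca, mbc, t[:, 2]], axis=1),
                    np.stack([mab, mbc, mca], axis=1),
                ]
            )
            tri = np.concatenate([tri[~big], children])
            radius = np.linalg.norm(tri - tri.mean(axis=1, keepdims=True), axis=2).max(axis=1)
        self.tri = tri
        self.centroids = self.tri.mean(axis=1)
        self.radius = radius
        self.rmax = float(self.radius.max())
        self.vtree = cKDTree(mesh.vertices)
        self.ctree = cKDTree(self.centroids)

    def closest(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        points = np.asarray(points, dtype=float)
        ub, _ = self.vtree.query(points)
        if _closest_block_jit is not None:
            K = min(32, len(self.tri))
            dk, idx = self.ctree.query(points, k=K)
            dk = np.asarray(dk, dtype=float).reshape(len(points), -1)
            idx = np.asarray(idx, dtype=np.int64).reshape(len(points), -1)
            cp, d, complete = _closest_block_jit(
                points, self.tri, self.radius, idx, dk, ub, self.rmax,
                K == len(self.tri),
            )
            if not complete.all():
                sub = ~complete
                cp[sub], d[sub] = self._closest_ball(points[sub], ub[sub])
            return cp, d
        return self._closest_ball(points, ub)

    def _closest_ball(self, points: np.ndarray, ub: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lists = self.ctree.query_ball_point(points, ub + self.rmax + 1e-9, return_sorted=False)
        counts = np.fromiter((len(l) for l in lists), dtype=np.int64, count=len(points))
        if counts.min() == 0:  # pragma: no cover - ub guarantees candidates
            raise GeometryError("no candidate faces")
        flat = np.concatenate([np.asarray(l, dtype=np.int64) for l in lists])
        rep = np.repeat(np.arange(len(points)), counts)
        # a face can hold the closest point only if its centroid ball can
        # reach inside the per-point upper bound; the face touching the
        # nearest vertex always survives, so no point loses all candidates
        reach = np.linalg.norm(points[rep] - self.centroids[flat], axis=1)
        keep = reach <= ub[rep] + self.radius[flat] + 1e-9
        flat = flat[keep]
        rep = rep[keep]
        counts = np.bincount(rep, minlength=len(points))
        if _closest_candidates_jit is not None:
            offsets = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
            return _closest_candidates_jit(points, self.tri, flat, offsets)
        tri = self.tri[flat]
        cp = _closest_on_triangles(points[rep], tri[:, 0], tri[:, 1], tri[:, 2])
        d2 = np.einsum("ij,ij->i", points[rep] - cp, points[rep] - cp)
        offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
        dmin = np.minimum.reduceat(d2, offsets)
        # argmin per query point: sort by (query, distance), take firsts
        order = np.lexsort((d2, rep))
        firsts = np.searchsorted(rep[order], np.arange(len(points)))
        best = order[firsts]
        return cp[best], np.sqrt(dmin)


def rmse_points_to_surface(samples: PointCloud3D, target: Mesh3D) -> float:
    """Root-mean-squared Euclidean distance from each sample point to its
    closest point on the target surface (the global-fit metric)."""
    if isinstance(samples, PointCloud3D):
        pts = samples.points
    else:
        pts = np.asarray(samples, dtype=float)
    if len(pts) == 0:
        raise GeometryError("no sample points")
    _, d = target.surface_query().closest(pts)
    return float(np.sqrt(np.mean(d ** 2)))


def rmse_points_to_polyline(points: np.ndarray, contour: Contour2D) -> float:
    """2D analogue of the global-fit metric: RMS closest-point distance from
    ``points`` to the (closed) polyline of ``contour``."""
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        raise GeometryError("no sample points")
    d = _dist_points_to_segments(points, contour.segments)
    return float(np.sqrt(np.mean(d ** 2)))


def _dist_points_to_segments(points: np.ndarray, segments: np.ndarray) -> np.ndarray:
    """Min distance from each 2D point to any segment; exact, chunked."""
    a = segments[:, 0]
    ab = segments[:, 1] - segments[:, 0]
    ab2 = np.einsum("ij,ij->i", ab, ab)
    ab2 = np.where(ab2 == 0, 1.0, ab2)
    out = np.empty(len(points))
    chunk = max(1, int(2e6 // max(len(segments), 1)))
    for lo in range(0, len(points), chunk):
        p = points[lo:lo + chunk]
        ap = p[:, None, :] - a[None, :, :]
        t = np.clip(np.einsum("pkj,kj->pk", ap, ab) / ab2, 0.0, 1.0)
        diff = ap - t[:, :, None] * ab[None, :, :]
        out[lo:lo + chunk] = np.sqrt(np.einsum("pkj,pkj->pk", diff, diff).min(axis=1))
    return out


# ---------------------------------------------------------------------------
# directed Hausdorff (max over/underhang)
# ---------------------------------------------------------------------------


def _edge_points(edges, max_spacing: float):
    if isinstance(edges, Contour2D):
        return edges.densified(max_spacing), 2
    if isinstance(edges, PointCloud3D):
        return edges.points, 3
    arr = np.asarray(edges, dtype=float)
    if arr.ndim != 2 or arr.shape[1] not in (2, 3) or len(arr) == 0:
        raise GeometryError("edges must be Contour2D, PointCloud3D, or (N,2|3) array")
    return arr, arr.shape[1]


def directed_hausdorff(component_edges, bone_edges, max_spacing: float = 0.2) -> float:
    """Directed Hausdorff distance h(C, B) = max_{c in C} min_{b in B} d(c, b).

    Contour inputs are densified to at most ``max_spacing`` point spacing
    before evaluation so that sampling cannot dominate the 3 mm clinical
    threshold. The metric is unsigned — over- and underhang both contribute —
    and deliberately asymmetric in its arguments (component first).
    """
    c, dc = _edge_points(component_edges, max_spacing)
    b, db = _edge_points(bone_edges, max_spacing)
    if dc != db:
        raise GeometryError("mixed 2D/3D edge sets")
    if len(c) == 0 or len(b) == 0:
        raise GeometryError("empty edge set")
    d, _ = cKDTree(b).query(c)
    return float(d.max())


# ---------------------------------------------------------------------------
# rigid registration (ICP)
# ---------------------------------------------------------------------------


def _kabsch(source: np.ndarray, target: np.ndarray, scale: bool = False):
    """Least-squares similarity/rigid alignment source -> target (Umeyama)."""
    mu_s = source.mean(axis=0)
    mu_t = target.mean(axis=0)
    s0 = source - mu_s
    t0 = target - mu_t
    H = s0.T @ t0 / len(source)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0] * (H.shape[0] - 1) + [d])
    R = Vt.T @ D @ U.T
    if scale:
        var = np.einsum("ij,ij->", s0, s0) / len(source)
        k = float(np.trace(np.diag(S) @ D) / var) if var > 0 else 1.0
    else:
        k = 1.0
    t = mu_t - k * R @ mu_s
    return R, t, k


def _principal_axes_inits(source: np.ndarray, target_pts: np.ndarray):
    """Candidate rigid inits aligning centroids and principal axes (all four
    proper sign choices)."""
    mu_s = source.mean(axis=0)
    mu_t = target_pts.mean(axis=0)
    _, _, Vs = np.linalg.svd(source - mu_s, full_matrices=False)
    _, _, Vt = np.linalg.svd(target_pts - mu_t, full_matrices=False)
    cands = [RigidTransform3(np.eye(3), mu_t - mu_s)]
    for sx in (1.0, -1.0):
        for sy in (1.0, -1.0):
            signs = np.diag([sx, sy, sx * sy])
            R = Vt.T @ signs @ Vs
            if np.linalg.det(R) < 0:
                R = Vt.T @ (signs * -1.0) @ Vs
            cands.append(RigidTransform3(R, mu_t - R @ mu_s))
    return cands


def _check_rank(points: np.ndarray):
    c = points - points.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if len(points) < 3 or s[1] <= 1e-9 * max(s[0], 1.0):
        raise GeometryError("rank-deficient correspondence")


def icp_rigid_3d(source: PointCloud3D, target: Mesh3D, init: RigidTransform3 | None = None,
                 max_iter: int = 50, tol: float = 1e-4, target_samples: int = 20000,
                 full_output: bool = False):
    """Rigid 6-DOF iterative-closest-point registration of a point cloud onto
    a mesh surface.

    Correspondences are nearest neighbors in a dense, deterministic surface
    sampling of the target (mesh vertices plus uniform-area face samples), so
    the per-iteration objective — RMS closest-point distance — is
    non-increasing. Terminates when the objective improves by less than
    ``tol`` (mm) or ``max_iter`` is reached; returns the best transform seen.
    """
    src = source.points if isinstance(source, PointCloud3D) else np.asarray(source, dtype=float)
    _check_rank(src)
    tree = target.surface_point_tree(target_samples)
    pts = target.surface_points(target_samples)

    def objective(tf):
        d, _ = tree.query(tf.apply(src))
        return float(np.sqrt(np.mean(d ** 2)))

    if init is None:
        # refine every candidate on a subsample until near convergence;
        # flipped principal-axes candidates converge to distant minima with
        # similar early scores, so refine long enough for the true basin to
        # reach its (much lower) floor before scoring
        cands = _principal_axes_inits(src, pts)
        sub = src[:: max(len(src) // 400, 1)]
        refined, scores = [], []
        for tf0 in cands:
            cur = tf0
            prev = np.inf
            for _ in range(30):
                _, idx = tree.query(cur.apply(sub))
                R, t, _ = _kabsch(sub, pts[idx])
                cur = RigidTransform3(R, t)
                d, _ = tree.query(cur.apply(sub))
                obj = float(np.sqrt(np.mean(d ** 2)))
                if prev - obj < 10 * tol:
                    break
                prev = obj
            refined.append(cur)
            scores.append(obj)
        tf = refined[int(np.argmin(scores))]
    else:
        tf = init

    trace = [objective(tf)]
    best_tf, best_obj = tf, trace[0]
    for _ in range(max_iter):
        moved = tf.apply(src)
        _, idx = tree.query(moved)
        R, t, _ = _kabsch(src, pts[idx])
        tf = RigidTransform3(R, t)
        obj = objective(tf)
        if obj < best_obj:
            best_tf, best_obj = tf, obj
        trace.append(min(obj, trace[-1]))
        if trace[-2] - obj < tol:
            break

    # polish against exact surface closest points: the discrete target
    # sampling biases the converged pose by a fraction of its point spacing.
    # Tangential sliding makes plain point-to-point updates converge at a
    # rate close to 1, so each accepted update is extrapolated along its
    # screw axis (Besl-McKay style) and the best multiple is kept. The same
    # ``tol`` governs this stage, so loose-tolerance callers pay for at most
    # one or two exact-surface iterations.
    query = target.surface_query()
    tf = best_tf

    def exact_objective(tf):
        _, d = query.closest(tf.apply(src))
        return float(np.sqrt(np.mean(d ** 2)))

    best_obj = exact_objective(best_tf)
    prev = best_obj
    for _ in range(15):
        cp, _ = query.closest(tf.apply(src))
        R, t, _ = _kabsch(src, cp)
        step = RigidTransform3(R, t)
        obj = exact_objective(step)
        if obj < best_obj:
            best_tf, best_obj = step, obj
            trace.append(obj)
        if prev - best_obj >= tol:
            dR = step.rotation @ tf.rotation.T
            dt = step.translation - dR @ tf.translation
            rv = ScipyRotation.from_matrix(dR).as_rotvec()
            for k in (2.0, 4.0, 8.0):
                Rk = ScipyRotation.from_rotvec(k * rv).as_matrix()
                cand = RigidTransform3(Rk @ tf.rotation, Rk @ tf.translation + k * dt)
                cobj = exact_objective(cand)
                if cobj < best_obj:
                    best_tf, best_obj = cand, cobj
                    trace.append(cobj)
        tf = best_tf
        if prev - best_obj < tol:
            break
        prev = best_obj
    if full_output:
        return best_tf, trace
    return best_tf


def icp_similarity_3d(source: np.ndarray, target: Mesh3D, max_iter: int = 50,
                      tol: float = 1e-4, target_samples: int = 20000):
    """Similarity (rigid + uniform scale) ICP; returns (R, t, scale)."""
    src = np.asarray(source, dtype=float)
    _check_rank(src)
    tree = target.surface_point_tree(target_samples)
    pts = target.surface_points(target_samples)
    # init: centroid + bbox-diagonal scale
    k = float(np.linalg.norm(np.ptp(pts, axis=0)) / max(np.linalg.norm(np.ptp(src, axis=0)), 1e-12))
    R = np.eye(3)
    t = pts.mean(axis=0) - k * src.mean(axis=0)
    best = (R, t, k)
    best_obj = np.inf
    prev = np.inf
    for _ in range(max_iter):
        moved = k * src @ R.T + t
        d, idx = tree.query(moved)
        obj = float(np.sqrt(np.mean(d ** 2)))
        if obj < best_obj:
            best, best_obj = (R, t, k), obj
        if prev - obj < tol:
            break
        prev = obj
        R, t, k = _kabsch(src, pts[idx], scale=True)
    return best


def icp_rigid_2d(source: Contour2D, target: Contour2D, max_iter: int = 60,
                 tol: float = 1e-5, full_output: bool = False):
    """3-DOF (theta, tx, ty) in-plane ICP of one closed contour onto another.

    The in-plane rotation models the tibia plate's single rotational degree
    of freedom about its central axis. When the rotation is unidentifiable
    (e.g. a circle), a zero-rotation solution of equal objective is preferred.
    """
    if not (source.closed and target.closed):
        raise GeometryError("2D ICP requires closed contours")
    src = source.points
    tgt = target.densified(0.1)
    tree = cKDTree(tgt)
    nxt = np.roll(np.arange(len(tgt)), -1)
    prv = np.roll(np.arange(len(tgt)), 1)

    def correspond(moved):
        """Exact-to-polyline correspondence: nearest densified point, refined
        by projection onto its two incident segments."""
        _, idx = tree.query(moved)
        best = tgt[idx]
        bd = np.einsum("ij,ij->i", moved - best, moved - best)
        for a_i, b_i in ((prv[idx], idx), (idx, nxt[idx])):
            a, b = tgt[a_i], tgt[b_i]
            ab = b - a
            ab2 = np.einsum("ij,ij->i", ab, ab)
            t = np.clip(np.einsum("ij,ij->i", moved - a, ab) / np.where(ab2 == 0, 1, ab2), 0, 1)
            cand = a + t[:, None] * ab
            cd = np.einsum("ij,ij->i", moved - cand, moved - cand)
            better = cd < bd
            best[better] = cand[better]
            bd[better] = cd[better]
        return best, np.sqrt(bd)

    def run(theta0, txy0, rotate=True):
        tf = RigidTransform2(theta0, *txy0)
        trace = []
        best_tf, best_obj = tf, np.inf
        for _ in range(max_iter + 1):
            moved = tf.apply(src)
            corr, d = correspond(moved)
            obj = float(np.sqrt(np.mean(d ** 2)))
            trace.append(obj if not trace else min(obj, trace[-1]))
            if obj < best_obj:
                best_tf, best_obj = tf, obj
            if len(trace) > 1 and trace[-2] - obj < tol:
                break
            if rotate:
                R, t, _ = _kabsch(src, corr)
                tf = RigidTransform2(float(np.arctan2(R[1, 0], R[0, 0])), t[0], t[1])
            else:
                t = (corr - src).mean(axis=0)
                tf = RigidTransform2(0.0, t[0], t[1])
        return best_tf, best_obj, trace

    t0 = tgt.mean(axis=0) - src.mean(axis=0)
    tf, obj, trace = run(0.0, t0)
    # zero-rotation tie-break: if a translation-only fit is as good, take it
    if abs(tf.theta) > 1e-12:
        tf0, obj0, _ = run(0.0, t0, rotate=False)
        if obj0 <= obj + 1e-6:
            tf = tf0
    if full_output:
        return tf, trace
    return tf


# ---------------------------------------------------------------------------
# plane cross-sections
# ---------------------------------------------------------------------------


def cross_section(mesh: Mesh3D, plane: Plane) -> Contour2D:
    """Largest closed intersection loop of ``mesh`` with ``plane``, expressed
    in the plane's 2D coordinates (first axis tracks ML, second AP) and
    oriented counter-clockwise."""
    loops = cross_section_loops(mesh, plane)
    areas = [abs(_signed_area(l)) for l in loops]
    return Contour2D(loops[int(np.argmax(areas))], closed=True)


def cross_section_loops(mesh: Mesh3D, plane: Plane) -> list[np.ndarray]:
    """All closed intersection loops in plane coordinates."""
    tm = mesh.to_trimesh()
    sec = tm.section(plane_origin=plane.origin, plane_normal=plane.normal)
    if sec is None:
        raise GeometryError("plane misses mesh")
    loops = []
    open_loops = 0
    for d in sec.discrete:
        pts = np.asarray(d, dtype=float)
        if len(pts) >= 4 and np.linalg.norm(pts[0] - pts[-1]) < 1e-6:
            loops.append(plane.to_plane_coords(pts[:-1]))
        else:
            open_loops += 1
    if not loops:
        # Path3D.discrete only yields closed cycles; detect open chains (the
        # plane crossing a mesh boundary) from the entities directly
        for ent in sec.entities:
            pts = np.asarray(ent.discrete(sec.vertices), dtype=float)
            if len(pts) < 3 or np.linalg.norm(pts[0] - pts[-1]) >= 1e-6:
                open_loops += 1
    if not loops:
        if open_loops:
            raise GeometryError(
                f"cross-section produced {open_loops} open loop(s); "
                "the plane crosses a mesh boundary")
        raise GeometryError("plane misses mesh")
    return loops
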