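"""Shared fixtures and independent reference implementations (oracles)."""

import numpy as np
import pytest
import trimesh

from kneefit.geometry import Mesh3D
from kneefit.implants import load_size_charts


def canonical(subject, bone):
    """Subject's bone mesh in the canonical right-knee frame."""
    mesh = getattr(subject, f"{bone}_mesh")
    return mesh.mirrored() if subject.side == "left" else mesh


def box_mesh(extents, center=(0.0, 0.0, 0.0)) -> Mesh3D:
    tm = trimesh.creation.box(extents=extents)
    tm.apply_translation(center)
    return Mesh3D(np.asarray(tm.vertices), np.asarray(tm.faces))


def sphere_mesh(radius, subdivisions=3) -> Mesh3D:
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return Mesh3D(np.asarray(tm.vertices), np.asarray(tm.faces))


def cylinder_mesh(radius, height, sections=128) -> Mesh3D:
    tm = trimesh.creation.cylinder(radius=radius, height=height, sections=sections)
    return Mesh3D(np.asarray(tm.vertices), np.asarray(tm.faces))


def random_convex_mesh(rng, n_points=40, scale=20.0) -> Mesh3D:
    """Random non-degenerate closed mesh: convex hull of a random cloud."""
    hull = trimesh.Trimesh(vertices=rng.normal(0, scale, (n_points, 3))).convex_hull
    return Mesh3D(np.asarray(hull.vertices), np.asarray(hull.faces))


def flat_plateau_mesh(ml=74.0, ap=50.0, height=40.0, sections=96) -> Mesh3D:
    """Elliptical prism with an analytically flat top cap.

    Subdividing twice creates interior top-cap vertices whose averaged vertex
    normals are exactly (0, 0, 1), so the plateau least-squares plane is known
    in closed form.  The widest medial point is the unique vertex at
    (-ml/2, 0, height)."""
    ang = np.linspace(0.0, 2 * np.pi, sections, endpoint=False)
    # include the exact angle pi so x = -ml/2 is hit by a single vertex
    ang = np.union1d(ang, [np.pi])
    ring = np.column_stack([ml / 2 * np.cos(ang), ap / 2 * np.sin(ang)])
    n = len(ring)
    top = np.column_stack([ring, np.full(n, height)])
    bot = np.column_stack([ring, np.zeros(n)])
    verts = np.vstack([top, bot, [[0, 0, height]], [[0, 0, 0]]])
    ct, cb = 2 * n, 2 * n + 1
    i = np.arange(n)
    j = (i + 1) % n
    faces = np.vstack(
        [
            np.column_stack([i, j, np.full(n, ct)]),  # top fan, CCW from above
            np.column_stack([n + j, n + i, np.full(n, cb)]),  # bottom fan
            np.column_stack([i, i + n, j]),  # walls
            np.column_stack([j, i + n, j + n]),
        ]
    )
    tm = trimesh.Trimesh(verts, faces, process=False).subdivide().subdivide()
    return Mesh3D(np.asarray(tm.vertices), np.asarray(tm.faces))


# ---------------------------------------------------------------------------
# brute-force oracles (independent derivations, no pruning, no vectorized
# shortcuts shared with the package implementation)
# ---------------------------------------------------------------------------


def oracle_closest_point_triangle(p, a, b, c):
    """Closest point on one triangle by case enumeration: project onto the
    triangle plane; if the projection's barycentric coordinates are all
    non-negative it is the answer, otherwise take the best clamped projection
    onto each of the three edges."""
    n = np.cross(b - a, c - a)
    nn = np.dot(n, n)
    candidates = []
    if nn > 0:
        q = p - np.dot(p - a, n) / nn * n
        # barycentric coordinates of q
        v0, v1, v2 = b - a, c - a, q - a
        d00, d01, d11 = np.dot(v0, v0), np.dot(v0, v1), np.dot(v1, v1)
        d20, d21 = np.dot(v2, v0), np.dot(v2, v1)
        den = d00 * d11 - d01 * d01
        if den > 0:
            v = (d11 * d20 - d01 * d21) / den
            w = (d00 * d21 - d01 * d20) / den
            if v >= 0 and w >= 0 and v + w <= 1:
                candidates.append(q)
    for e0, e1 in ((a, b), (b, c), (c, a)):
        d = e1 - e0
        dd = np.dot(d, d)
        t = 0.0 if dd == 0 else float(np.clip(np.dot(p - e0, d) / dd, 0.0, 1.0))
        candidates.append(e0 + t * d)
    dists = [np.linalg.norm(p - q) for q in candidates]
    return candidates[int(np.argmin(dists))]


def oracle_rmse_points_to_surface(points, mesh: Mesh3D) -> float:
    tri = mesh.vertices[mesh.faces]
    dmin = np.full(len(points), np.inf)
    for i, p in enumerate(np.asarray(points, dtype=float)):
        for a, b, c in tri:
            q = oracle_closest_point_triangle(p, a, b, c)
            dmin[i] = min(dmin[i], np.linalg.norm(p - q))
    return float(np.sqrt(np.mean(dmin**2)))


def oracle_directed_hausdorff(comp_pts, bone_pts) -> float:
    comp_pts = np.asarray(comp_pts, dtype=float)
    bone_pts = np.asarray(bone_pts, dtype=float)
    worst = 0.0
    for c in comp_pts:
        best = min(float(np.linalg.norm(c - b)) for b in bone_pts)
        worst = max(worst, best)
    return worst


def oracle_spearman(x, y) -> float:
    """Spearman rho from the plain rank formula with midrank ties."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        r = np.empty(len(v))
        for i, vi in enumerate(v):
            less = np.sum(v < vi)
            equal = np.sum(v == vi)
            r[i] = less + (equal + 1) / 2.0
        return r

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    den = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    return float(np.sum(rx * ry) / den)


@pytest.fixture(scope="session")
def charts():
    return load_size_charts()


@pytest.fixture(scope="session")
def chart_by_model(charts):
    return {(c.model, c.component): c for c in charts}
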