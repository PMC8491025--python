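"""Shared computational-geometry primitives.

Exact minimal enclosing circle (Welzl's move-to-front algorithm), algebraic
circle fits, convex-hull caliper widths, total-least-squares line fits and
discrete curvature. These back several trait definitions, so they are written
for exactness first and speed second; the enclosing-circle path reduces to
hull vertices before running Welzl, which keeps it exact and fast for large
pixel sets.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import ConvexHull, QhullError

_EPS = 1e-12


# ---------------------------------------------------------------------------
# minimal enclosing circle (exact, Welzl move-to-front)
# ---------------------------------------------------------------------------

def _circle_two(p, q):
    cx = (p[0] + q[0]) / 2.0
    cy = (p[1] + q[1]) / 2.0
    r = math.hypot(p[0] - q[0], p[1] - q[1]) / 2.0
    return (cx, cy, r)


def _circumcircle(a, b, c):
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < _EPS:
        return None
    ux = ((ax * ax + ay * ay) * (by - cy) + (bx * bx + by * by) * (cy - ay)
          + (cx * cx + cy * cy) * (ay - by)) / d
    uy = ((ax * ax + ay * ay) * (cx - bx) + (bx * bx + by * by) * (ax - cx)
          + (cx * cx + cy * cy) * (bx - ax)) / d
    r = math.hypot(ax - ux, ay - uy)
    return (ux, uy, r)


def _in_circle(c, p, tol=1e-9):
    return math.hypot(p[0] - c[0], p[1] - c[1]) <= c[2] * (1.0 + tol) + tol


def _mec_two_boundary(points, p, q):
    circ = _circle_two(p, q)
    left = None
    right = None
    px, py = p
    qx, qy = q
    for r in points:
        if _in_circle(circ, r):
            continue
        cross = (qx - px) * (r[1] - py) - (qy - py) * (r[0] - px)
        c = _circumcircle(p, q, r)
        if c is None:
            continue
        ccross = (qx - px) * (c[1] - py) - (qy - py) * (c[0] - px)
        if cross > 0.0 and (left is None or ccross > (qx - px) * (left[1] - py)
                            - (qy - py) * (left[0] - px)):
            left = c
        elif cross < 0.0 and (right is None or ccross < (qx - px) * (right[1] - py)
                              - (qy - py) * (right[0] - px)):
            right = c
    if left is None and right is None:
        return circ
    if left is None:
        return right
    if right is None:
        return left
    return left if left[2] <= right[2] else right


def _mec_one_boundary(points, p):
    c = (p[0], p[1], 0.0)
    for i, q in enumerate(points):
        if not _in_circle(c, q):
            if c[2] == 0.0:
                c = _circle_two(p, q)
            else:
                c = _mec_two_boundary(points[:i], p, q)
    return c


def min_enclosing_circle(points: np.ndarray) -> tuple[tuple[float, float], float]:
    """Exact smallest enclosing circle of a 2D point set.

    Returns ``((cx, cy), radius)``.  Runs Welzl's randomized move-to-front
    algorithm on the convex-hull vertices (the enclosing circle is determined
    by hull points), so it is exact and near-linear even for 10^5 pixels.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("min_enclosing_circle expects a non-empty N x 2 array")
    if len(pts) == 1:
        return (float(pts[0, 0]), float(pts[0, 1])), 0.0
    if len(pts) > 8:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass  # degenerate (collinear) input: run Welzl on all points
    rng = np.random.default_rng(0)
    order = rng.permutation(len(pts))
    shuffled = [tuple(pts[i]) for i in order]
    c = None
    for i, p in enumerate(shuffled):
        if c is None or not _in_circle(c, p):
            c = _mec_one_boundary(shuffled[:i], p)
    return (c[0], c[1]), c[2]


# ---------------------------------------------------------------------------
# least-squares circle fit (Kasa algebraic fit)
# ---------------------------------------------------------------------------

def fit_circle_lsq(points: np.ndarray) -> tuple[tuple[float, float], float]:
    """Algebraic (Kasa) least-squares circle through 2D points.

    Suitable for annular cross-sections whose pixels sample a circle.
    Raises ``ValueError`` on fewer than 3 points or a degenerate system.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("circle fit needs >= 3 points")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones(len(pts))])
    b = x * x + y * y
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r2 = c + cx * cx + cy * cy
    if r2 <= 0 or not np.isfinite(r2):
        raise ValueError("degenerate circle fit")
    return (float(cx), float(cy)), float(math.sqrt(r2))


# ---------------------------------------------------------------------------
# convex hull calipers
# ---------------------------------------------------------------------------

def _hull_vertices(points: np.ndarray) -> np.ndarray | None:
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        return None
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return None
    return pts[hull.vertices]


def caliper_widths(points: np.ndarray) -> tuple[float, float]:
    """(min, max) caliper width of the convex hull of 2D points.

    Max width is the hull diameter; min width is the smallest distance
    between parallel supporting lines (min over hull edges of the farthest
    vertex distance to the edge line).  Degenerate inputs raise ValueError.
    """
    verts = _hull_vertices(points)
    if verts is None:
        raise ValueError("caliper widths need >= 3 non-collinear points")
    n = len(verts)
    diffs = verts[:, None, :] - verts[None, :, :]
    max_w = float(np.sqrt((diffs ** 2).sum(-1)).max())
    edges = np.roll(verts, -1, axis=0) - verts
    lengths = np.linalg.norm(edges, axis=1)
    keep = lengths > _EPS
    normals = np.column_stack([-edges[keep, 1], edges[keep, 0]]) / lengths[keep, None]
    # distance of every vertex to every edge line; width per edge = max
    rel = verts[None, :, :] - verts[keep][:, None, :]
    d = np.abs(np.einsum("eij,ej->ei", rel, normals))
    min_w = float(d.max(axis=1).min())
    return min_w, max_w


def convex_hull_area(points: np.ndarray) -> float:
    """Area of the convex hull of 2D points (0 for degenerate input)."""
    verts = _hull_vertices(points)
    if verts is None:
        return 0.0
    x, y = verts[:, 0], verts[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


# ---------------------------------------------------------------------------
# polylines: TLS line fit, arc length, discrete curvature
# ---------------------------------------------------------------------------

def tls_line_direction(points: np.ndarray) -> np.ndarray:
    """Total-least-squares line direction (unit vector) through 2D/3D points."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("line fit needs >= 2 points")
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0] / np.linalg.norm(vt[0])


def arc_length(points: np.ndarray) -> float:
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def circumradius_curvature(a, b, c) -> float:
    """Curvature (1/circumradius) of three points in 2D or 3D; 0 if collinear."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    ab = b - a
    ac = c - a
    bc = c - b
    cross = np.cross(ab, ac)
    area2 = float(np.linalg.norm(cross)) if cross.ndim else abs(float(cross))
    denom = (np.linalg.norm(ab) * np.linalg.norm(ac) * np.linalg.norm(bc))
    if denom < _EPS:
        return 0.0
    return float(2.0 * area2 / denom)
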