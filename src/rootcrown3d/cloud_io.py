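"""Point-cloud I/O and canonical orientation for excavated root crowns.

A root crown arrives as a PLY point cloud in an arbitrary pose.  Everything
downstream slices it top-down, so this module establishes the canonical
frame: coordinates in mm, depth increasing along +z, the stem top at depth 0.

The PLY reader handles ASCII and binary-little-endian vertex elements with at
least x, y, z properties (optional red/green/blue colors are preserved
exactly); malformed files raise :class:`PLYParseError` naming the offending
line or byte offset.  The writer emits ASCII by default for diff-ability.

Alignment finds the depth axis among the principal axes of the point
covariance.  For a wide, shallow crown the largest eigenvalue can be
horizontal, so the axis is selected by the end-spread ratio (the stem end is
the narrow extremity) and then refined with a PCA of the stem-only top
window, which pins the axis to the stem cylinder.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class PLYParseError(ValueError):
    """Raised for malformed or truncated PLY files."""


class EmptyPointCloudError(ValueError):
    """Raised when a PLY file declares zero vertices."""


class AlignmentError(ValueError):
    """Raised when the cloud geometry is too degenerate to orient."""


@dataclass
class RigidTransform:
    """Similarity transform ``aligned = scale * (rotation @ p) + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * (np.asarray(points, float) @ self.rotation.T) + self.translation


@dataclass
class RootPointCloud:
    """3D root-crown point cloud in mm; depth increases along +z after alignment."""

    points: np.ndarray
    colors: np.ndarray | None = None
    depth_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be N x 3")
        if len(self.points) < 1:
            raise EmptyPointCloudError("point cloud has no points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points contain non-finite coordinates")
        if self.colors is not None:
            self.colors = np.asarray(self.colors)
            if self.colors.shape != self.points.shape:
                raise ValueError("colors must match points shape")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def depths(self) -> np.ndarray:
        return self.points[:, 2]


# ---------------------------------------------------------------------------
# PLY reading / writing
# ---------------------------------------------------------------------------

_PLY_DTYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


def _parse_header(lines: list[str]):
    if not lines or lines[0].strip() != "ply":
        raise PLYParseError("line 1: missing 'ply' magic")
    fmt = None
    elements = []  # (name, count, [(prop_name, dtype_str)])
    for ln, raw in enumerate(lines[1:], start=2):
        tokens = raw.strip().split()
        if not tokens or tokens[0] == "comment":
            continue
        if tokens[0] == "format":
            if len(tokens) < 2 or tokens[1] not in ("ascii", "binary_little_endian"):
                raise PLYParseError(f"line {ln}: unsupported format {raw.strip()!r}")
            fmt = tokens[1]
        elif tokens[0] == "element":
            if len(tokens) != 3:
                raise PLYParseError(f"line {ln}: malformed element declaration")
            try:
                count = int(tokens[2])
            except ValueError as exc:
                raise PLYParseError(f"line {ln}: bad element count {tokens[2]!r}") from exc
            elements.append((tokens[1], count, []))
        elif tokens[0] == "property":
            if not elements:
                raise PLYParseError(f"line {ln}: property before any element")
            if tokens[1] == "list":
                if len(tokens) != 5:
                    raise PLYParseError(f"line {ln}: malformed list property")
                elements[-1][2].append((tokens[4], ("list", tokens[2], tokens[3])))
            else:
                if len(tokens) != 3 or tokens[1] not in _PLY_DTYPES:
                    raise PLYParseError(f"line {ln}: malformed property {raw.strip()!r}")
                elements[-1][2].append((tokens[2], _PLY_DTYPES[tokens[1]]))
        elif tokens[0] == "end_header":
            if fmt is None:
                raise PLYParseError(f"line {ln}: end_header before format line")
            return fmt, elements, ln
        else:
            raise PLYParseError(f"line {ln}: unknown header keyword {tokens[0]!r}")
    raise PLYParseError("header truncated: no end_header")


def read_point_cloud(path: str | Path) -> RootPointCloud:
    """Read a PLY point cloud (ASCII or binary-little-endian vertex data)."""
    path = Path(path)
    data = path.read_bytes()
    header_end = data.find(b"end_header")
    if header_end < 0:
        raise PLYParseError("header truncated: no end_header")
    nl = data.find(b"\n", header_end)
    if nl < 0:
        raise PLYParseError("header truncated after end_header")
    header_text = data[:nl].decode("ascii", errors="replace")
    fmt, elements, _ = _parse_header(header_text.splitlines())
    body = data[nl + 1:]

    vertex = next((e for e in elements if e[0] == "vertex"), None)
    if vertex is None:
        raise PLYParseError("no vertex element declared")
    _, n_vertices, props = vertex
    if n_vertices == 0:
        raise EmptyPointCloudError(f"{path.name}: zero vertices declared")
    names = [p[0] for p in props]
    for coord in ("x", "y", "z"):
        if coord not in names:
            raise PLYParseError(f"vertex element lacks {coord!r} property")
    if any(isinstance(p[1], tuple) for p in props):
        raise PLYParseError("list properties on vertex element are unsupported")
    has_color = all(c in names for c in ("red", "green", "blue"))

    if elements[0][0] != "vertex":
        raise PLYParseError("vertex must be the first element for this reader")

    if fmt == "ascii":
        lines = body.split(b"\n")
        rows = []
        header_lines = header_text.count("\n") + 1
        for i in range(n_vertices):
            if i >= len(lines) or not lines[i].strip():
                raise PLYParseError(
                    f"body truncated at line {header_lines + i + 1}: "
                    f"expected {n_vertices} vertices, found {i}")
            tokens = lines[i].split()
            if len(tokens) < len(props):
                raise PLYParseError(
                    f"line {header_lines + i + 1}: expected {len(props)} values, "
                    f"got {len(tokens)}")
            rows.append(tokens[:len(props)])
        arr = np.array(rows, dtype=float)
        cols = {name: arr[:, i] for i, (name, _) in enumerate(props)}
        colors = None
        if has_color:
            colors = np.column_stack([cols["red"], cols["green"], cols["blue"]]).astype(np.uint8)
    else:  # binary_little_endian
        dtype = np.dtype([(name, "<" + d) for name, d in props])
        nbytes = dtype.itemsize * n_vertices
        if len(body) < nbytes:
            raise PLYParseError(
                f"body truncated at byte {nl + 1 + len(body)}: expected "
                f"{nbytes} vertex bytes, found {len(body)}")
        rec = np.frombuffer(body[:nbytes], dtype=dtype)
        cols = {name: rec[name] for name, _ in props}
        colors = None
        if has_color:
            colors = np.column_stack([cols["red"], cols["green"], cols["blue"]]).astype(np.uint8)

    points = np.column_stack([cols["x"], cols["y"], cols["z"]]).astype(float)
    return RootPointCloud(points=points, colors=colors)


def write_point_cloud(path: str | Path, cloud: RootPointCloud, binary: bool = False) -> None:
    """Write a PLY point cloud; ASCII by default for diff-ability."""
    path = Path(path)
    has_color = cloud.colors is not None
    header = ["ply",
              "format binary_little_endian 1.0" if binary else "format ascii 1.0",
              f"element vertex {len(cloud)}",
              "property float x", "property float y", "property float z"]
    if has_color:
        header += ["property uchar red", "property uchar green", "property uchar blue"]
    header.append("end_header")
    pts = cloud.points.astype(np.float32)
    if binary:
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode("ascii"))
            for i in range(len(cloud)):
                fh.write(struct.pack("<fff", *pts[i]))
                if has_color:
                    fh.write(struct.pack("<BBB", *(int(v) for v in cloud.colors[i])))
    else:
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            for i in range(len(cloud)):
                line = f"{pts[i, 0]:.9g} {pts[i, 1]:.9g} {pts[i, 2]:.9g}"
                if has_color:
                    c = cloud.colors[i]
                    line += f" {int(c[0])} {int(c[1])} {int(c[2])}"
                fh.write(line + "\n")


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

def _end_spreads(points: np.ndarray, axis: np.ndarray, frac: float = 0.10):
    """(RMS radial spread, point fraction) in the terminal windows of *axis*."""
    proj = points @ axis
    lo, hi = proj.min(), proj.max()
    window = max((hi - lo) * frac, 1e-9)
    radial = points - np.outer(proj, axis)
    out = []
    for sel in (proj <= lo + window, proj >= hi - window):
        sub = radial[sel]
        centered = sub - sub.mean(axis=0)
        spread = float(np.sqrt((centered ** 2).sum(axis=1).mean()))
        out.append((spread, len(sub) / len(points)))
    return out  # [(spread, frac) at low end, (spread, frac) at high end]


def _theil_sen_slope(z: np.ndarray, v: np.ndarray) -> float:
    dz = z[:, None] - z[None, :]
    dv = v[:, None] - v[None, :]
    iu = np.triu_indices(len(z), k=1)
    dz, dv = dz[iu], dv[iu]
    keep = np.abs(dz) > 1e-9
    return float(np.median(dv[keep] / dz[keep])) if keep.any() else 0.0


def _slab_centroid_axis(points: np.ndarray, slab_mm: float = 2.0,
                        skip_mm: float = 2.0,
                        window_frac: float = 0.5) -> np.ndarray | None:
    """Axis estimate from robust regression of slab centroids on depth."""
    z = points[:, 2]
    lo = z.min() + skip_mm
    hi = z.min() + max(window_frac * (z.max() - z.min()), 10.0)
    sel = (z > lo) & (z <= hi)
    if sel.sum() < 100:
        return None
    sub = points[sel]
    bins = ((sub[:, 2] - lo) / slab_mm).astype(int)
    order = np.argsort(bins)
    sub, bins = sub[order], bins[order]
    splits = np.searchsorted(bins, np.arange(bins[-1] + 1))
    cents = []
    for b in range(bins[-1] + 1):
        s, e = splits[b], splits[b + 1] if b + 1 < len(splits) else len(sub)
        if e - s >= 30:
            cents.append(sub[s:e].mean(axis=0))
    if len(cents) < 5:
        return None
    cents = np.asarray(cents)
    sx = _theil_sen_slope(cents[:, 2], cents[:, 0])
    sy = _theil_sen_slope(cents[:, 2], cents[:, 1])
    axis = np.array([sx, sy, 1.0])
    return axis / np.linalg.norm(axis)


def _stem_window(points: np.ndarray, slab_mm: float = 2.0) -> tuple[float, float] | None:
    """Depth range [lo, hi] of the stem-only region in an aligned frame.

    The 95th-percentile radius per depth slab is flat (≈ stem radius) above
    the first whorl and jumps once nodal roots appear."""
    z = points[:, 2]
    z0 = z.min()
    n_slabs = int((z.max() - z0) / slab_mm)
    if n_slabs < 3:
        return None
    r95 = []
    for b in range(n_slabs):
        sel = (z >= z0 + b * slab_mm) & (z < z0 + (b + 1) * slab_mm)
        if sel.sum() < 20:
            break
        r = np.hypot(points[sel, 0] - np.median(points[sel, 0]),
                     points[sel, 1] - np.median(points[sel, 1]))
        r95.append(np.percentile(r, 95))
    if len(r95) < 3:
        return None
    stem_r = np.median(r95[:3])
    hi = len(r95)
    for b in range(1, len(r95)):
        if r95[b] > 1.25 * stem_r:
            hi = b
            break
    if hi * slab_mm < 6.0:
        return None
    # start below the stem-top cap: cap points scatter around their plane,
    # and z0 is an extreme-value statistic of that scatter
    return z0 + 2.5, z0 + hi * slab_mm - 1.0


def _cylinder_fit(points: np.ndarray) -> tuple[np.ndarray, float] | None:
    """Least-squares cylinder axis through *points* (direction, rms residual).

    Uses the full shell circularity, so the axis of even a stubby stem
    segment is recovered far more precisely than from slab centroids."""
    from scipy.optimize import least_squares

    c0 = points.mean(axis=0)
    rel = points - c0

    def residuals(params):
        a, b, cx, cy = params
        u = np.array([a, b, 1.0])
        u = u / np.linalg.norm(u)
        d = rel - np.array([cx, cy, 0.0])
        cross = np.cross(d, u)
        r = np.linalg.norm(cross, axis=1)
        return r - r.mean()

    try:
        sol = least_squares(residuals, x0=np.zeros(4), method="lm",
                            max_nfev=200)
    except Exception:
        return None
    a, b = sol.x[0], sol.x[1]
    axis = np.array([a, b, 1.0])
    axis /= np.linalg.norm(axis)
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    return axis, rms


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit *axis* to +z (minimal rotation)."""
    axis = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    c = float(axis @ z)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def align_vertical(cloud: RootPointCloud, angle_tol_deg: float = 1.0,
                   refine: bool = True) -> tuple[RootPointCloud, RigidTransform]:
    """Rotate the crown so depth increases along +z and the stem top is at 0.

    The depth axis is the principal axis with the most asymmetric end spread
    (stem end narrow); orientation puts the narrow end at depth 0.  A second
    PCA restricted to the top window then locks the axis onto the stem.
    """
    pts = cloud.points
    if len(pts) < 3:
        raise AlignmentError("need at least 3 points to align")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] <= 1e-12 * max(evals[2], 1.0):
        raise AlignmentError("degenerate geometry: points are collinear")

    # Depth-axis candidates: the principal axes and their pairwise/triple
    # combinations (a crown with near-degenerate eigenvalues has no single
    # eigenvector near the true vertical).  The stem end is the narrow,
    # densely sampled extremity; terminal windows holding almost no points
    # (isolated root tips along a horizontal axis) are uninformative and
    # must not win on a spuriously tiny spread.
    min_end_frac = max(0.01, 3.0 / len(pts))
    e = [evecs[:, k] for k in range(3)]
    candidates = list(e)
    for i in range(3):
        for j in range(i + 1, 3):
            candidates += [e[i] + e[j], e[i] - e[j]]
    for s1 in (1, -1):
        for s2 in (1, -1):
            candidates.append(e[0] + s1 * e[1] + s2 * e[2])
    candidates = [c / np.linalg.norm(c) for c in candidates]

    def coarse_score(axis):
        (lo_s, lo_f), (hi_s, hi_f) = _end_spreads(centered, axis)
        lo_s, hi_s = max(lo_s, 1e-9), max(hi_s, 1e-9)
        ratio = max(lo_s, hi_s) / min(lo_s, hi_s)
        if min(lo_f, hi_f) < min_end_frac:
            ratio *= 0.1
        return ratio, (axis if lo_s <= hi_s else -axis)

    scored = sorted((coarse_score(c) for c in candidates),
                    key=lambda sc: -sc[0])

    def refine_from(axis):
        # Three-stage refine.  (1) slab centroids: every planar cut of the
        # stem cylinder is an ellipse centered on the axis and whorl root
        # rings are roughly azimuthally balanced, so a robust Theil-Sen
        # line through slab centroids removes most of the coarse tilt.
        # (2) the stem-only depth window is found from the radial profile.
        # (3) a cylinder fit to that window pins the axis precisely.  The
        # cylinder stage is a guarded refiner, never a searcher: the
        # correction must be small and the fitted radius must look like a
        # stem (a root tube is also a clean thin cylinder, so an ungated
        # fit could lock onto a single root).
        R0 = _rotation_to_z(axis)
        rot = centered @ R0.T
        stem_found = False
        if refine:
            for _ in range(2):
                stem_axis = _slab_centroid_axis(rot)
                if stem_axis is None:
                    break
                R_fix = _rotation_to_z(stem_axis)
                rot = rot @ R_fix.T
                R0 = R_fix @ R0
            for _ in range(2):
                window = _stem_window(rot)
                if window is None:
                    break
                z = rot[:, 2]
                sel = (z >= window[0]) & (z <= window[1])
                if sel.sum() < 100:
                    break
                fit = _cylinder_fit(rot[sel])
                if fit is None:
                    break
                stem_axis, rms = fit
                if stem_axis[2] < 0:
                    stem_axis = -stem_axis
                radial = np.hypot(rot[sel, 0] - rot[sel, 0].mean(),
                                  rot[sel, 1] - rot[sel, 1].mean())
                radius = float(np.mean(radial))
                angle_change = np.degrees(np.arccos(min(1.0, abs(stem_axis[2]))))
                if not (4.0 <= radius <= 40.0 and rms < 0.25 * radius
                        and angle_change < 3.0):
                    break
                R_fix = _rotation_to_z(stem_axis)
                rot = rot @ R_fix.T
                R0 = R_fix @ R0
                stem_found = True
        ratio, _ = coarse_score(R0.T @ np.array([0.0, 0.0, 1.0]))
        score = ratio * (3.0 if stem_found else 1.0)
        return score, R0, rot

    best = None
    for _, axis in scored[:5]:
        score, R0, rot = refine_from(axis)
        if best is None or score > best[0]:
            best = (score, R0, rot)
    _, R, rotated = best

    # stem top at depth 0; x,y origin at the stem-top centroid
    z = rotated[:, 2]
    window = min(max(0.10 * (z.max() - z.min()), 2.0), 15.0)
    top = rotated[z <= z.min() + window]
    translation = np.array([-top[:, 0].mean(), -top[:, 1].mean(), -z.min()])
    aligned_pts = rotated + translation
    transform = RigidTransform(rotation=R,
                               translation=translation - R @ pts.mean(axis=0),
                               scale=1.0)
    aligned = RootPointCloud(points=aligned_pts, colors=cloud.colors)
    return aligned, transform


def scale_to_mm(cloud: RootPointCloud, scale: float) -> RootPointCloud:
    """Uniformly scale coordinates into mm (colors untouched)."""
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    return RootPointCloud(points=cloud.points * scale, colors=cloud.colors,
                          depth_axis=cloud.depth_axis.copy())
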