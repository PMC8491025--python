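"""The 18 root-crown architecture traits (plus auxiliary stem diameter).

Traits split into individual-root measures read off the structure graph
(whorl distances, per-whorl nodal angle/diameter/length/count, occupancy,
lateral diameter, total volume) and whole-crown measures read off the
level-set stack (crown diameter, eccentricity, density, excavated depth,
projection radius).  Undetectable traits are explicit missing values (NaN),
never zero, and every missing trait is listed in the QC report with its
cause.

Angles follow the proximal-line convention: a total-least-squares 3D line is
fitted through the proximal 70% (by arc length from emergence) of the root
polyline and its angle to the horizontal plane is reported, in [0, 90]
degrees.  Lengths are cubic B-spline arc lengths; diameters are
slope-corrected fitted-circle diameters (see ``structure``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
from scipy.interpolate import splev, splprep

from ._geometry import (caliper_widths, convex_hull_area, min_enclosing_circle,
                        tls_line_direction)
from .levelset import LevelSetStack
from .structure import StructureGraph, Whorl, corrected_track_diameters
from .tracking import RootTrack

_UNITS = {
    "whorl_distance_1_2": "mm", "whorl_distance_2_3": "mm",
    "nodal_angle_youngest": "deg", "nodal_angle_second": "deg",
    "nodal_diameter_youngest": "mm", "nodal_diameter_second": "mm",
    "lateral_diameter": "mm", "nodal_length_youngest": "mm",
    "n_nodal_youngest": "count", "n_nodal_occluded": "count",
    "occupancy_youngest": "ratio", "occupancy_second": "ratio",
    "rc_diameter": "mm", "rc_eccentricity": "ratio", "rc_density": "ratio",
    "rc_depth": "mm", "rc_projection_radius": "mm", "rc_volume": "mm3",
    "stem_diameter": "mm",
}


@dataclass
class TraitTable:
    """The 18 named architecture traits with units, plus stem diameter."""

    whorl_distance_1_2: float = math.nan
    whorl_distance_2_3: float = math.nan
    nodal_angle_youngest: float = math.nan
    nodal_angle_second: float = math.nan
    nodal_diameter_youngest: float = math.nan
    nodal_diameter_second: float = math.nan
    lateral_diameter: float = math.nan
    nodal_length_youngest: float = math.nan
    n_nodal_youngest: float = math.nan
    n_nodal_occluded: float = math.nan
    occupancy_youngest: float = math.nan
    occupancy_second: float = math.nan
    rc_diameter: float = math.nan
    rc_eccentricity: float = math.nan
    rc_density: float = math.nan
    rc_depth: float = math.nan
    rc_projection_radius: float = math.nan
    rc_volume: float = math.nan
    stem_diameter: float = math.nan   # auxiliary, not one of the 18
    qc: dict = field(default_factory=dict, repr=False)

    TRAIT_NAMES = tuple(n for n in _UNITS if n != "stem_diameter")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if f.name in _UNITS}

    def to_csv(self, path: str | Path, label: str = "crown") -> None:
        names = list(_UNITS)
        with open(path, "w") as fh:
            fh.write("crown," + ",".join(names) + "\n")
            fh.write("unit," + ",".join(_UNITS[n] for n in names) + "\n")
            vals = [getattr(self, n) for n in names]
            fh.write(label + "," + ",".join(
                "" if isinstance(v, float) and math.isnan(v) else f"{v:.6g}"
                for v in vals) + "\n")


# ---------------------------------------------------------------------------
# individual-root traits
# ---------------------------------------------------------------------------

def whorl_distances(whorls: list[Whorl]) -> tuple[float, float]:
    """Consecutive whorl depth gaps from the youngest; missing = NaN."""
    d12 = whorls[1].depth - whorls[0].depth if len(whorls) >= 2 else math.nan
    d23 = whorls[2].depth - whorls[1].depth if len(whorls) >= 3 else math.nan
    return d12, d23


def nodal_angle(polyline_mm: np.ndarray, fraction: float = 0.70) -> float:
    """Angle (deg, [0, 90]) of the TLS line through the proximal *fraction*
    of the root's arc length to the horizontal plane."""
    pts = np.asarray(polyline_mm, float)
    if len(pts) < 2:
        return math.nan
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        return math.nan
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    keep = cum <= fraction * total
    keep[:2] = True  # at least two points
    sub = pts[keep]
    direction = tls_line_direction(sub)
    return float(np.degrees(np.arcsin(min(1.0, abs(direction[2])
                                          / np.linalg.norm(direction)))))


def _members(whorl: Whorl, graph: StructureGraph) -> list[RootTrack]:
    by_id = {t.track_id: t for t in graph.nodal}
    return [by_id[i] for i in whorl.member_ids if i in by_id]


def _member_diameter_at_whorl(track: RootTrack, whorl: Whorl,
                              graph: StructureGraph) -> float:
    """One member root's fitted diameter at the whorl location.

    Uses the detections within a few mm below the whorl depth and discards
    partial sections (the first slices of an emerging tube cut only part of
    its ellipse, so their area ramps up from near zero).
    """
    diams = corrected_track_diameters(track, graph.pixel_mm, graph.thickness)
    if len(diams) == 0:
        return math.nan
    whorl_slice = (whorl.depth - graph.depth0) / graph.thickness
    idx = track.slice_indices
    areas = np.array([c.area for _, c in track.detections])
    near = ((idx >= whorl_slice - 1.0 / graph.thickness)
            & (idx <= whorl_slice + 5.0 / graph.thickness))
    if not near.any():
        near = np.zeros(len(idx), dtype=bool)
        near[:max(1, int(2.0 / graph.thickness))] = True
    full = near & (areas >= 0.6 * areas[near].max())
    sel = full if full.any() else near
    return float(diams[sel].mean())


def nodal_diameter(whorl: Whorl, graph: StructureGraph) -> float:
    """Mean member fitted-circle diameter measured at the whorl location."""
    vals = [_member_diameter_at_whorl(t, whorl, graph)
            for t in _members(whorl, graph)]
    vals = [v for v in vals if not math.isnan(v)]
    return float(np.mean(vals)) if vals else math.nan


def lateral_diameter(graph: StructureGraph) -> float:
    """Mean over laterals of the per-track median diameter; no laterals = NaN."""
    vals = [float(np.median(corrected_track_diameters(t, graph.pixel_mm,
                                                      graph.thickness)))
            for t in graph.laterals if len(t)]
    return float(np.mean(vals)) if vals else math.nan


def spline_arc_length(polyline_mm: np.ndarray, max_deviation: float = 1.0) -> float:
    """Arc length of a cubic B-spline fit to the polyline.

    Smoothing is chosen from heavy to none, accepting the smoothest fit
    whose max deviation from the vertices stays within ``max_deviation``
    mm; heavy-first matters because an interpolating spline would follow
    centroid jitter and overstate the length.  If no smoothing level meets
    the bound, the one with the smallest deviation is used.
    """
    pts = np.asarray(polyline_mm, float)
    if len(pts) < 2:
        return 0.0
    if len(pts) < 4:
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    # deduplicate consecutive equal vertices (splprep rejects zero chords)
    keep = np.concatenate([[True], np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9])
    pts = pts[keep]
    if len(pts) < 4:
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    best = None  # (deviation, tck)
    for s in (4.0 * len(pts), len(pts), 0.25 * len(pts), 0.0):
        try:
            tck, u = splprep(pts.T, k=3, s=s)
        except (ValueError, TypeError):
            continue
        fitted = np.array(splev(u, tck)).T
        dev = float(np.linalg.norm(fitted - pts, axis=1).max())
        if best is None or dev < best[0]:
            best = (dev, tck)
        if dev <= max_deviation:
            best = (dev, tck)
            break
    if best is None:
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    dense = np.array(splev(np.linspace(0, 1, max(200, 4 * len(pts))), best[1])).T
    return float(np.linalg.norm(np.diff(dense, axis=0), axis=1).sum())


def root_polyline(graph: StructureGraph, track: RootTrack,
                  partial_frac: float = 0.5) -> np.ndarray:
    """Track polyline with partial end sections trimmed.

    The first and last slices of a root cut only part of its cross-section
    ellipse; their centroids hook off the centerline and would bias angle
    and length fits, so leading/trailing detections with area below
    ``partial_frac`` x the track median are dropped.
    """
    areas = np.array([c.area for _, c in track.detections])
    if len(areas) < 5:
        return graph.polyline(track)
    full = areas >= partial_frac * np.median(areas)
    if not full.any():
        return graph.polyline(track)
    lo = int(np.argmax(full))
    hi = len(full) - int(np.argmax(full[::-1]))
    poly = graph.polyline(track)
    return poly[lo:hi]


def nodal_length_youngest(graph: StructureGraph) -> float:
    if not graph.whorls:
        return math.nan
    lengths = [spline_arc_length(root_polyline(graph, t))
               for t in _members(graph.whorls[0], graph)]
    return float(np.mean(lengths)) if lengths else math.nan


def nodal_counts(graph: StructureGraph) -> tuple[float, float]:
    """(youngest-whorl count, all other nodal roots)."""
    if not graph.whorls:
        return math.nan, math.nan
    n_young = graph.whorls[0].n_members
    total = len(graph.nodal)
    return float(n_young), float(total - n_young)


def occupancy_index(whorl: Whorl, graph: StructureGraph) -> float:
    """Sum of member diameters at the whorl over the stem perimeter."""
    if graph.stem_diameter <= 0:
        raise ValueError("stem diameter must be positive")
    vals = [_member_diameter_at_whorl(t, whorl, graph)
            for t in _members(whorl, graph)]
    vals = [v for v in vals if not math.isnan(v)]
    return float(np.sum(vals) / (math.pi * graph.stem_diameter))


# ---------------------------------------------------------------------------
# whole-crown traits from the stack
# ---------------------------------------------------------------------------

def _slice_pixels_mm(stack: LevelSetStack, i: int, corners: bool = False) -> np.ndarray:
    rows, cols = np.nonzero(stack.images[i])
    if len(rows) == 0:
        return np.empty((0, 2))
    pts = stack.pixel_to_mm(cols, rows)
    if not corners:
        return pts
    h = stack.pixel_mm / 2.0
    offs = np.array([[-h, -h], [-h, h], [h, -h], [h, h]])
    return (pts[:, None, :] + offs[None, :, :]).reshape(-1, 2)


def rc_diameter(stack: LevelSetStack) -> float:
    """Mean over 10 equidistant depths of the minimal-bounding-circle
    diameter of that slice's foreground; empty slices are excluded."""
    n = stack.n_slices
    idxs = sorted(set(np.linspace(0, n - 1, min(10, n)).astype(int)))
    vals = []
    for i in idxs:
        pts = _slice_pixels_mm(stack, i, corners=True)
        if len(pts) == 0:
            continue
        _, r = min_enclosing_circle(pts)
        vals.append(2.0 * r)
    return float(np.mean(vals)) if vals else math.nan


def rc_eccentricity(stack: LevelSetStack) -> float:
    """mean(min caliper width) / mean(max caliper width) over slices, in (0,1].

    Pixels enter as their 4 corners, so a single-pixel slice is a square
    with min = max width (eccentricity 1), never a degenerate point.
    """
    mins, maxs = [], []
    for i in range(stack.n_slices):
        centers = _slice_pixels_mm(stack, i)
        if len(centers) == 0:
            continue
        if len(centers) == 1:  # degenerate single-pixel slice: round section
            mins.append(stack.pixel_mm)
            maxs.append(stack.pixel_mm)
            continue
        w_min, w_max = caliper_widths(_slice_pixels_mm(stack, i, corners=True))
        mins.append(w_min)
        maxs.append(w_max)
    if not maxs or np.mean(maxs) <= 0:
        return math.nan
    return float(np.mean(mins) / np.mean(maxs))


def rc_density(stack: LevelSetStack) -> float:
    """Mean over slices of foreground area / convex hull area, in (0,1]."""
    vals = []
    for i in range(stack.n_slices):
        centers = _slice_pixels_mm(stack, i)
        if len(centers) < 3:
            continue
        centered = centers - centers.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
            continue  # collinear pixels: skip slice
        hull_area = convex_hull_area(_slice_pixels_mm(stack, i, corners=True))
        if hull_area <= 0:
            continue
        area = len(centers) * stack.pixel_mm ** 2
        vals.append(min(1.0, area / hull_area))
    return float(np.mean(vals)) if vals else math.nan


def rc_depth(stack: LevelSetStack) -> float:
    """Pre-interpolation slice count x slice thickness (mm)."""
    return float(stack.n_slices * stack.thickness)


def rc_projection_radius(stack: LevelSetStack) -> float:
    """Radius of the exact minimal enclosing circle of all foreground pixels
    projected onto the horizontal plane."""
    union = stack.images.astype(bool).any(axis=0)
    rows, cols = np.nonzero(union)
    if len(rows) == 0:
        raise ValueError("empty stack")
    pts = stack.pixel_to_mm(cols, rows)
    _, r = min_enclosing_circle(pts)
    return float(r)


def rc_volume(graph: StructureGraph) -> float:
    """Sum over roots (incl. stem) of pi (d/2)^2 x spline arc length."""
    tracks = [graph.stem] + graph.nodal + graph.laterals
    if not tracks:
        raise ValueError("empty structure graph")
    total = 0.0
    for t in tracks:
        d = float(np.median(corrected_track_diameters(t, graph.pixel_mm,
                                                      graph.thickness)))
        length = spline_arc_length(root_polyline(graph, t))
        total += math.pi * (d / 2.0) ** 2 * length
    return float(total)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def compute_all_traits(graph: StructureGraph, raw_stack: LevelSetStack) -> TraitTable:
    """Populate the full trait table; failures become NaN + a QC entry.

    ``raw_stack`` is the pre-interpolation stack (depth and descriptor
    conventions are defined on it); graph geometry carries its own, possibly
    finer, slice thickness.
    """
    table = TraitTable()
    qc: dict[str, str] = {}

    def attempt(name, fn):
        try:
            val = fn()
        except Exception as exc:  # propagate as missing, never as 0
            qc[name] = f"{type(exc).__name__}: {exc}"
            return
        setattr(table, name, val)
        if isinstance(val, float) and math.isnan(val):
            qc[name] = "undetectable"

    whorls = graph.whorls
    d12, d23 = whorl_distances(whorls)
    table.whorl_distance_1_2 = d12
    table.whorl_distance_2_3 = d23
    if math.isnan(d12):
        qc["whorl_distance_1_2"] = "fewer than 2 whorls detected"
    if math.isnan(d23):
        qc["whorl_distance_2_3"] = "fewer than 3 whorls detected"

    def whorl_angle(k):
        members = _members(whorls[k], graph)
        angles = [nodal_angle(root_polyline(graph, t)) for t in members]
        angles = [a for a in angles if not math.isnan(a)]
        return float(np.mean(angles)) if angles else math.nan

    attempt("nodal_angle_youngest",
            lambda: whorl_angle(0) if whorls else math.nan)
    attempt("nodal_angle_second",
            lambda: whorl_angle(1) if len(whorls) >= 2 else math.nan)
    attempt("nodal_diameter_youngest",
            lambda: nodal_diameter(whorls[0], graph) if whorls else math.nan)
    attempt("nodal_diameter_second",
            lambda: nodal_diameter(whorls[1], graph) if len(whorls) >= 2 else math.nan)
    attempt("lateral_diameter", lambda: lateral_diameter(graph))
    attempt("nodal_length_youngest", lambda: nodal_length_youngest(graph))
    n_young, n_occ = nodal_counts(graph)
    table.n_nodal_youngest = n_young
    table.n_nodal_occluded = n_occ
    if math.isnan(n_young):
        qc["n_nodal_youngest"] = qc["n_nodal_occluded"] = "no whorls detected"
    attempt("occupancy_youngest",
            lambda: occupancy_index(whorls[0], graph) if whorls else math.nan)
    attempt("occupancy_second",
            lambda: occupancy_index(whorls[1], graph) if len(whorls) >= 2 else math.nan)
    attempt("rc_diameter", lambda: rc_diameter(raw_stack))
    attempt("rc_eccentricity", lambda: rc_eccentricity(raw_stack))
    attempt("rc_density", lambda: rc_density(raw_stack))
    attempt("rc_depth", lambda: rc_depth(raw_stack))
    attempt("rc_projection_radius", lambda: rc_projection_radius(raw_stack))
    attempt("rc_volume", lambda: rc_volume(graph))
    table.stem_diameter = graph.stem_diameter
    table.qc = qc
    return table
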