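"""Assembling root tracks into a structure graph of the crown.

The tracker returns depth-ordered trajectories, some of them fragments of
one root broken by occlusion.  This stage (i) merges fragments whose ends
are close, whose curvatures agree and whose union continues one smooth
curve, (ii) identifies the stem (the large section present at the very top
of the stack), (iii) classifies the remaining roots into nodal roots
(emerging at the stem) and laterals, (iv) finds the whorls as the rise
onsets of the cumulative nodal cross-section area over depth -- the area
jumps when a whorl's roots emerge and plateaus in between -- and (v)
attaches leftover fragments by walking them back onto the structure.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._geometry import circumradius_curvature
from .levelset import LevelSetStack
from .tracking import RootTrack, TrackingParams


class StructureError(ValueError):
    """Raised when no plausible stem or structure can be assembled."""


@dataclass
class StructureParams:
    curvature_tol: float = 0.02        # 1/mm
    gap_tol: float = 10.0              # mm
    deviation_tol: float = 2.0         # mm
    min_whorl_separation: float = 2.0  # mm (resolution limit of the method)
    plateau_eps: float = 0.02          # fraction of curve range per slice
    attach_radius_factor: float = 1.5  # x stem radius for nodal classification
    top_window_frac: float = 0.10
    min_branch_length: float = 5.0     # mm of arc for a back-tracked lateral


@dataclass
class Whorl:
    depth: float                      # mm from stem top
    member_ids: list[int]
    index_from_youngest: int          # 1 = youngest = shallowest

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


@dataclass
class StructureGraph:
    stem: RootTrack
    stem_diameter: float
    whorls: list[Whorl]
    nodal: list[RootTrack]
    laterals: list[RootTrack]
    edges: list[tuple[int, int, float]] = field(default_factory=list)
    unattached: list[RootTrack] = field(default_factory=list)
    pixel_mm: float = 0.5
    thickness: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    depth0: float = 0.0

    def polyline(self, track: RootTrack) -> np.ndarray:
        return track.polyline_mm(self.pixel_mm, self.thickness, self.origin,
                                 self.depth0)

    def whorl_of(self, track_id: int) -> Whorl | None:
        for w in self.whorls:
            if track_id in w.member_ids:
                return w
        return None

    def to_dict(self) -> dict:
        def poly(t):
            return np.round(self.polyline(t), 4).tolist()

        return {
            "stem": {"track_id": self.stem.track_id,
                     "diameter_mm": round(self.stem_diameter, 4),
                     "polyline_mm": poly(self.stem)},
            "whorls": [{"depth_mm": round(w.depth, 4),
                        "index_from_youngest": w.index_from_youngest,
                        "member_ids": w.member_ids} for w in self.whorls],
            "nodal_roots": [{"track_id": t.track_id, "polyline_mm": poly(t)}
                            for t in self.nodal],
            "laterals": [{"track_id": t.track_id, "polyline_mm": poly(t)}
                         for t in self.laterals],
            "edges": [{"parent": p, "child": c, "depth_mm": round(d, 4)}
                      for p, c, d in self.edges],
            "unattached": [t.track_id for t in self.unattached],
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def save_polyline_ply(self, path: str | Path) -> None:
        """Colored polyline vertices (stem white, nodal by whorl, laterals gray)."""
        palette = [(228, 26, 28), (55, 126, 184), (77, 175, 74), (152, 78, 163),
                   (255, 127, 0), (255, 255, 51)]
        pts, cols = [], []
        for t in [self.stem]:
            p = self.polyline(t)
            pts.append(p)
            cols.append(np.tile([255, 255, 255], (len(p), 1)))
        for t in self.nodal:
            w = self.whorl_of(t.track_id)
            color = palette[(w.index_from_youngest - 1) % len(palette)] if w else (0, 0, 0)
            p = self.polyline(t)
            pts.append(p)
            cols.append(np.tile(color, (len(p), 1)))
        for t in self.laterals:
            p = self.polyline(t)
            pts.append(p)
            cols.append(np.tile([128, 128, 128], (len(p), 1)))
        from .cloud_io import RootPointCloud, write_point_cloud
        cloud = RootPointCloud(points=np.vstack(pts),
                               colors=np.vstack(cols).astype(np.uint8))
        write_point_cloud(path, cloud)


# ---------------------------------------------------------------------------
# curvature and trace connection
# ---------------------------------------------------------------------------

def track_curvature(polyline_mm: np.ndarray) -> np.ndarray:
    """Per-interior-vertex curvature (1/mm): inverse circumradius of each
    consecutive point triple; collinear triples give 0."""
    pts = np.asarray(polyline_mm, float)
    if len(pts) < 3:
        return np.empty(0)
    return np.array([circumradius_curvature(pts[i - 1], pts[i], pts[i + 1])
                     for i in range(1, len(pts) - 1)])


def _resample_polyline(poly: np.ndarray, step: float = 2.0) -> np.ndarray:
    """Resample to ~``step`` mm arc spacing; averages out centroid jitter
    that would otherwise dominate curvature and extrapolation tests."""
    poly = np.asarray(poly, float)
    if len(poly) < 3:
        return poly
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(poly, axis=0),
                                                          axis=1))])
    if arc[-1] <= step:
        return poly[[0, -1]]
    n = max(2, int(round(arc[-1] / step)) + 1)
    targets = np.linspace(0.0, arc[-1], n)
    out = np.column_stack([np.interp(targets, arc, poly[:, d])
                           for d in range(poly.shape[1])])
    return out


def _extrapolate_deviation(tail: np.ndarray, head: np.ndarray, m: int = 6) -> float:
    """Max distance of *head*'s first points from the polynomial continuation
    of *tail*'s last points (chord-length parametrized, degree <= 3).
    Operates on ~2 mm resampled polylines so centroid jitter cancels."""
    tail = _resample_polyline(tail)[-m:]
    head = _resample_polyline(head)[:m]
    if len(tail) < 2:
        return float("inf")
    t_tail = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(tail, axis=0), axis=1))])
    gap = float(np.linalg.norm(head[0] - tail[-1]))
    t_head = t_tail[-1] + gap + np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(head, axis=0), axis=1))])
    deg = min(3, len(tail) - 1)
    pred = np.empty_like(head)
    for d in range(tail.shape[1]):
        coef = np.polyfit(t_tail, tail[:, d], deg)
        pred[:, d] = np.polyval(coef, t_head)
    return float(np.linalg.norm(pred - head, axis=1).max())


def _continuation_score(head: np.ndarray, tail: np.ndarray,
                        horizon_mm: float = 15.0) -> float:
    """Mean distance of *tail*'s first ``horizon_mm`` of arc from the
    quadratic continuation curve of *head*'s last ``horizon_mm``.

    The distance is point-to-curve (nearest sample on the extrapolated
    curve), so overlapping or gapped junctions score sensibly.  The horizon
    matters: identity mix-ups between near-parallel roots only become
    geometrically visible well past the contact point."""
    if len(head) < 3 or len(tail) == 0:
        return 0.0
    h_arc = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(head, axis=0), axis=1))])
    keep_h = h_arc >= h_arc[-1] - horizon_mm
    head_w = head[keep_h]
    t_head = h_arc[keep_h] - h_arc[keep_h][0]
    deg = min(2, len(head_w) - 1)
    if deg < 1 or t_head[-1] <= 0:
        return 0.0
    gap = float(np.linalg.norm(tail[0] - head[-1]))
    tail_arc = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(tail, axis=0), axis=1))])
    tail_w = tail[tail_arc <= horizon_mm]
    t_samp = np.linspace(0.0, t_head[-1] + gap + horizon_mm + 2.0, 150)
    curve = np.empty((len(t_samp), head.shape[1]))
    for d in range(head.shape[1]):
        coef = np.polyfit(t_head, head_w[:, d], deg)
        curve[:, d] = np.polyval(coef, t_samp)
    dists = np.linalg.norm(tail_w[:, None, :] - curve[None, :, :], axis=2).min(axis=1)
    return float(dists.mean())


def _merge_compatible(poly_a: np.ndarray, poly_b: np.ndarray,
                      params: StructureParams) -> bool:
    """Curvature similarity + smooth-continuation test for a candidate merge."""
    curv_a = track_curvature(_resample_polyline(poly_a))
    curv_b = track_curvature(_resample_polyline(poly_b))
    if len(curv_a) and len(curv_b):
        if abs(np.median(curv_a) - np.median(curv_b)) > params.curvature_tol:
            return False
    dev = min(_extrapolate_deviation(poly_a, poly_b),
              _extrapolate_deviation(poly_b[::-1], poly_a[::-1]))
    return dev <= params.deviation_tol


def connect_traces(tracks: list[RootTrack], params: StructureParams,
                   pixel_mm: float, thickness: float, origin=(0.0, 0.0),
                   depth0: float = 0.0,
                   forbidden: set[tuple[int, int]] | None = None
                   ) -> list[RootTrack]:
    """Greedily merge broken traces (smallest endpoint gap first) to fixpoint.

    A pair merges iff the 3D endpoint gap is within ``gap_tol``, median
    curvatures agree within ``curvature_tol`` and each fragment continues
    the other's extrapolated curve within ``deviation_tol``.  Each track
    merges at most once per pass; passes repeat until no merge happens.
    """
    tracks = list(tracks)
    forbidden = forbidden or set()
    changed = True
    while changed:
        changed = False
        polys = {t.track_id: t.polyline_mm(pixel_mm, thickness, origin, depth0)
                 for t in tracks}
        overlap_slices = max(1, int(round(3.0 / thickness)))
        candidates = []
        for a in tracks:
            for b in tracks:
                if a.track_id == b.track_id:
                    continue
                # b continues a downward; a truncated track and its
                # continuation fragment may overlap by a few slices where
                # both straddled an entanglement, so allow a small overlap
                # (the overlapping head of b is trimmed on merge)
                if b.detections[0][0] <= a.detections[-1][0] - overlap_slices:
                    continue
                if b.detections[-1][0] <= a.detections[-1][0]:
                    continue
                gap = float(np.linalg.norm(polys[b.track_id][0] - polys[a.track_id][-1]))
                if gap <= params.gap_tol:
                    candidates.append((gap, a.track_id, b.track_id))
        by_id_pre = {t.track_id: t for t in tracks}
        candidates.sort()
        used = set()
        merges = []
        for gap, ida, idb in candidates:
            if ida in used or idb in used:
                continue
            # contiguity fast path: a fragment resuming within a couple of
            # slices and a tube diameter of a track's end IS its
            # continuation -- no other root can occupy the same tube, and
            # endpoint geometry at an entanglement is too corrupted for
            # the curvature test to be meaningful there
            slice_gap = (by_id_pre[idb].detections[0][0]
                         - by_id_pre[ida].detections[-1][0])
            contiguous = (slice_gap <= 3 and gap <= 2.0
                          and (ida, idb) not in forbidden)
            if (ida, idb) in forbidden:
                continue
            if contiguous or _merge_compatible(polys[ida], polys[idb], params):
                merges.append((ida, idb))
                used.add(ida)
                used.add(idb)
        if merges:
            changed = True
            by_id = {t.track_id: t for t in tracks}
            for ida, idb in merges:
                a, b = by_id[ida], by_id[idb]
                cut = a.detections[-1][0]
                a.detections = a.detections + [d for d in b.detections
                                               if d[0] > cut]
                a.status = "merged"
                del by_id[idb]
            tracks = list(by_id.values())
    return tracks


def split_entangled_tracks(tracks: list[RootTrack], params: StructureParams,
                           pixel_mm: float, thickness: float,
                           origin=(0.0, 0.0), depth0: float = 0.0,
                           area_ratio: float = 1.5,
                           partner_tracks: list[RootTrack] | None = None
                           ) -> tuple[list[RootTrack], set[tuple[int, int]]]:
    """Split tracks that absorbed an entangled partner.

    When two roots run nearly parallel their sections merge for many
    slices; one track follows the merged blob and can exit the zone on the
    *other* root.  The zone is visible in the track's own section-area
    profile (area jumps to roughly the sum while merged), and a composite
    is distinguished from a clean pass-through by the continuation score
    across the zone: if the post-zone polyline does not continue the
    pre-zone curve, the track is cut at the zone exit and the remainder
    becomes a separate fragment for trace connection to reclaim.

    A merged zone only counts as an identity mix-up when some *other*
    track dies inside it (the dying partner's root is what the composite
    absorbed); zones crossed while other roots keep their own tracks --
    e.g. a deeper whorl emerging through -- are left intact.  Returns the
    track list and the set of (head_id, tail_id) pairs that were cut;
    trace connection must not re-glue those.
    """
    from scipy.ndimage import median_filter

    def _poly(track):
        return track.polyline_mm(pixel_mm, thickness, origin, depth0)

    partner_ends = []  # (end_slice, end_xyz) of every candidate partner
    for pt in (partner_tracks if partner_tracks is not None else tracks):
        if pt.detections:
            partner_ends.append((pt.track_id, pt.detections[-1][0], _poly(pt)[-1]))

    out: list[RootTrack] = []
    forbidden: set[tuple[int, int]] = set()
    next_id = max((t.track_id for t in tracks), default=0) + 1
    queue = list(tracks)
    while queue:
        t = queue.pop(0)
        dets = t.detections
        n = len(dets)
        if n < 40:
            out.append(t)
            continue
        areas = median_filter(np.array([c.area for _, c in dets], float), size=7)
        poly = t.polyline_mm(pixel_mm, thickness, origin, depth0)
        split_at = None
        # skip the emergence ramp: scanning may only start once the section
        # has reached its established full size, else the ramp's low median
        # makes the first full sections look like a merged zone
        baseline = np.median(areas)
        ramp_end = int(np.argmax(areas >= 0.8 * baseline))
        i = max(15, ramp_end + 10)
        while i < n - 10:
            pre_med = np.median(areas[max(0, i - 25):i])
            if areas[i] > area_ratio * pre_med:
                # inside a merged zone: find the exit (area re-stabilizes)
                j = i + 1
                while j < n - 5 and areas[j] > 1.25 * np.median(areas[j:j + 20]):
                    j += 1
                if j >= n - 5:
                    break
                score = _continuation_score(poly[:i], poly[j:])
                if score > params.deviation_tol:
                    # demand a dying partner inside the zone
                    zone_slices = (dets[i][0], dets[min(j, n - 1)][0])
                    zone_pts = poly[i:j + 1]
                    margin = int(round(5.0 / thickness))
                    has_partner = False
                    for pid, end_slice, end_xyz in partner_ends:
                        if pid == t.track_id:
                            continue
                        if not (zone_slices[0] - margin <= end_slice
                                <= zone_slices[1] + margin):
                            continue
                        d = np.linalg.norm(zone_pts - end_xyz, axis=1).min()
                        if d <= 6.0:
                            has_partner = True
                            break
                    if has_partner:
                        split_at = j
                        break
                i = j + 1
            else:
                i += 1
        if split_at is None:
            out.append(t)
            continue
        tail = RootTrack(track_id=next_id, detections=dets[split_at:],
                         status=t.status)
        forbidden.add((t.track_id, tail.track_id))
        next_id += 1
        t.detections = dets[:split_at]
        out.append(t)
        queue.append(tail)
    return out, forbidden


def resolve_crossings(tracks: list[RootTrack], params: StructureParams,
                      pixel_mm: float, thickness: float, origin=(0.0, 0.0),
                      depth0: float = 0.0, contact_mm: float = 5.0,
                      margin_mm: float = 1.0, max_passes: int = 3
                      ) -> list[RootTrack]:
    """Undo identity swaps where two tracks passed through each other.

    When two roots travel through the same region their sections entangle
    and the tracker can exchange their continuations.  A swap leaves a
    geometric signature: each composite polyline bends off the smooth
    continuation of its proximal part exactly at the contact.  For every
    track pair that comes within ``contact_mm`` at a common slice, both
    pairings of (proximal head, distal tail) are scored by the smooth-
    continuation deviation and the tails are exchanged when the swapped
    pairing is smoother by more than ``margin_mm``.
    """
    for _ in range(max_passes):
        swapped_any = False
        polys = {t.track_id: t.polyline_mm(pixel_mm, thickness, origin, depth0)
                 for t in tracks}
        slice_maps = {t.track_id: {s: i for i, (s, _) in enumerate(t.detections)}
                      for t in tracks}
        for ai in range(len(tracks)):
            for bi in range(ai + 1, len(tracks)):
                a, b = tracks[ai], tracks[bi]
                pa, pb = polys[a.track_id], polys[b.track_id]
                sa = np.array([s for s, _ in a.detections])
                sb = np.array([s for s, _ in b.detections])
                lo = max(sa[0], sb[0])
                hi = min(sa[-1], sb[-1])
                if hi <= lo:
                    continue
                # interpolate across detection gaps: the closest approach
                # often falls inside a coasting gap where neither track has
                # detections (the sections were merged there)
                grid = np.arange(lo, hi + 1)
                xa = np.interp(grid, sa, pa[:, 0])
                ya = np.interp(grid, sa, pa[:, 1])
                xb = np.interp(grid, sb, pb[:, 0])
                yb = np.interp(grid, sb, pb[:, 1])
                dist = np.hypot(xa - xb, ya - yb)
                contact = dist <= contact_mm
                if not contact.any():
                    continue
                k = int(grid[int(np.argmin(dist))])
                a_head = [d for d in a.detections if d[0] <= k]
                a_tail = [d for d in a.detections if d[0] > k]
                b_head = [d for d in b.detections if d[0] <= k]
                b_tail = [d for d in b.detections if d[0] > k]
                if not a_head or not b_head or (not a_tail and not b_tail):
                    continue

                def poly_of(dets):
                    if not dets:
                        return None
                    idx = np.array([s for s, _ in dets])
                    xy = np.array([c.centroid for _, c in dets])
                    out = np.empty((len(xy), 3))
                    out[:, 0] = origin[0] + (xy[:, 0] + 0.5) * pixel_mm
                    out[:, 1] = origin[1] + (xy[:, 1] + 0.5) * pixel_mm
                    out[:, 2] = depth0 + idx * thickness
                    return out

                def dev(head, tail):
                    if tail is None:
                        return 0.0
                    return _continuation_score(head, tail)

                pa_h, pa_t = poly_of(a_head), poly_of(a_tail)
                pb_h, pb_t = poly_of(b_head), poly_of(b_tail)
                s_keep = dev(pa_h, pa_t) + dev(pb_h, pb_t)
                s_swap = dev(pa_h, pb_t) + dev(pb_h, pa_t)
                if s_swap + margin_mm < s_keep:
                    a.detections = a_head + b_tail
                    b.detections = b_head + a_tail
                    polys[a.track_id] = poly_of(a.detections)
                    polys[b.track_id] = poly_of(b.detections)
                    slice_maps[a.track_id] = {s: i for i, (s, _)
                                              in enumerate(a.detections)}
                    slice_maps[b.track_id] = {s: i for i, (s, _)
                                              in enumerate(b.detections)}
                    swapped_any = True
        if not swapped_any:
            break
    return [t for t in tracks if t.detections]


# ---------------------------------------------------------------------------
# stem, classification, whorls
# ---------------------------------------------------------------------------

def track_inclinations(track: RootTrack, pixel_mm: float,
                       thickness: float) -> np.ndarray:
    """sin(inclination from horizontal) at each detection (1 = vertical)."""
    poly = track.polyline_mm(pixel_mm, thickness)
    n = len(poly)
    if n < 2:
        return np.ones(n)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - 1), min(n - 1, i + 1)
        d = poly[hi] - poly[lo]
        norm = np.linalg.norm(d)
        out[i] = abs(d[2]) / norm if norm > 0 else 1.0
    return out


def corrected_track_diameters(track: RootTrack, pixel_mm: float,
                              thickness: float) -> np.ndarray:
    """Per-detection diameters corrected for slope and rasterization.

    A root crossing the slicing plane at inclination gamma shows an ellipse
    whose equivalent-circle diameter inflates by 1/sqrt(sin gamma); point-in-
    pixel occupancy additionally dilates the section by about half a pixel
    per side.  Both biases are removed here; ``fit_diameter`` itself stays
    the plain fitted-circle definition.
    """
    raw = np.array([c.diameter for _, c in track.detections])
    sin_g = np.clip(track_inclinations(track, pixel_mm, thickness), 0.2, 1.0)
    return np.maximum(raw * np.sqrt(sin_g) - pixel_mm, 0.5 * pixel_mm)


def detect_stem(tracks: list[RootTrack], stack: LevelSetStack,
                params: StructureParams | None = None) -> tuple[RootTrack, float]:
    """Stem = the track in the topmost slice with the largest median area.

    Stem diameter is the median corrected fitted-circle diameter over the
    stem's detections in the top window of the stack.
    """
    params = params or StructureParams()
    n = stack.n_slices
    window = max(1, int(np.ceil(params.top_window_frac * n)))
    in_window = [t for t in tracks if t.detections[0][0] < window]
    if not in_window:
        raise StructureError("no track reaches the top window of the stack")
    topmost = min(t.detections[0][0] for t in in_window)
    candidates = [t for t in in_window if t.detections[0][0] == topmost]
    stem = max(candidates, key=lambda t: np.median([c.area for _, c in t.detections]))
    diams = corrected_track_diameters(stem, stack.pixel_mm, stack.thickness)
    sel = stem.slice_indices < window
    stem_diameter = float(np.median(diams[sel] if sel.any() else diams))
    return stem, stem_diameter


def emergence_index(track: RootTrack) -> int:
    """Index of the first full cross-section of a track.

    The very first detections of an emerging root are partial slivers of
    its tube shoulder, up to a tube radius above the true emergence; the
    first detection whose area reaches half the track median marks the
    centerline actually crossing the slicing plane.
    """
    areas = np.array([c.area for _, c in track.detections])
    if len(areas) < 3:
        return 0
    full = areas >= 0.25 * np.median(areas)
    return int(np.argmax(full)) if full.any() else 0


def _stem_axis_xy(stem: RootTrack, slice_index: int) -> np.ndarray:
    idx = stem.slice_indices
    pos = np.searchsorted(idx, slice_index)
    pos = min(pos, len(idx) - 1)
    return np.asarray(stem.detections[pos][1].centroid)


def classify_tracks(tracks: list[RootTrack], stem: RootTrack, stem_diameter: float,
                    stack: LevelSetStack, params: StructureParams | None = None
                    ) -> tuple[list[RootTrack], list[RootTrack]]:
    """Nodal iff the emergence lies near the stem axis at that depth.

    The emergence position is the minimum stem-axis distance over the first
    few detections: the very first section of an emerging root is a partial
    ellipse whose centroid can sit well outside the root's true position.
    """
    params = params or StructureParams()
    radius_px = params.attach_radius_factor * (stem_diameter / 2.0) / stack.pixel_mm
    nodal, lateral = [], []
    for t in tracks:
        if t.track_id == stem.track_id:
            continue
        # edge distance: the centroid sits one section radius outside the
        # emergence point, which matters for fat roots on slim stems
        e0 = emergence_index(t)
        dist = min(
            float(np.linalg.norm(np.asarray(comp.centroid)
                                 - _stem_axis_xy(stem, s)))
            - math.sqrt(comp.area / math.pi)
            for s, comp in t.detections[max(0, e0 - 3):e0 + 10])
        (nodal if dist <= radius_px else lateral).append(t)
    return nodal, lateral


def cumulative_nodal_area(nodal: list[RootTrack], stack: LevelSetStack) -> np.ndarray:
    """Cumulative newly-added nodal cross-section area (mm^2) per slice.

    Each nodal root contributes its emergence-slice area once, at its
    emergence slice; the running sum rises when a whorl's roots emerge and
    plateaus in between.
    """
    added = np.zeros(stack.n_slices)
    for t in nodal:
        s0, comp0 = t.detections[emergence_index(t)]
        added[min(s0, stack.n_slices - 1)] += comp0.area * stack.pixel_mm ** 2
    return np.cumsum(added)


def detect_whorls(curve: np.ndarray, nodal: list[RootTrack], stack: LevelSetStack,
                  params: StructureParams | None = None) -> list[Whorl]:
    """Whorls from rise onsets of the cumulative nodal-area curve.

    An onset is a slice where the per-slice increment rises above
    ``plateau_eps`` x curve range after a plateau; onsets closer than
    ``min_whorl_separation`` merge (the stated resolution limit).  Members
    are the nodal roots whose emergence depth falls in [onset, next onset).
    """
    params = params or StructureParams()
    curve = np.asarray(curve, float)
    if curve.size == 0 or curve[-1] <= 0:
        return []
    rng = curve[-1] - curve[0]
    eps = params.plateau_eps * rng
    inc = np.diff(np.concatenate([[0.0], curve]))
    rising = inc > eps
    onsets = [i for i in range(len(curve))
              if rising[i] and (i == 0 or not rising[i - 1])]
    if not onsets:
        return []
    # rise magnitude of each onset's contiguous rising run
    def rise_of(onset):
        j = onset
        while j < len(curve) - 1 and rising[j + 1]:
            j += 1
        return curve[j] - (curve[onset - 1] if onset > 0 else 0.0)

    rises = {o: rise_of(o) for o in onsets}
    min_sep_slices = params.min_whorl_separation / stack.thickness

    def rise_window(o):
        # total curve gain within one resolution limit below the onset: a
        # genuine whorl keeps rising there, a lone straggler does not
        j = min(len(curve) - 1, int(o + min_sep_slices))
        return curve[j] - (curve[o - 1] if o > 0 else 0.0)

    # merge onsets closer than the resolution limit (strict, with fp guard);
    # also fold in stragglers: an onset just below a whorl whose nearby
    # total rise is a small fraction of that whorl's rise is a
    # late-detected member of it, not a new whorl
    merged = [onsets[0]]
    acc_rise = [rises[onsets[0]]]  # rise of each whorl incl. folded onsets
    for o in onsets[1:]:
        gap = o - merged[-1]
        if gap < min_sep_slices * (1.0 - 1e-9):
            acc_rise[-1] += rises[o]
            continue
        if gap <= 2.0 * min_sep_slices and rise_window(o) < 0.3 * acc_rise[-1]:
            acc_rise[-1] += rises[o]
            continue
        merged.append(o)
        acc_rise.append(rises[o])
    # a root reaching its full section marginally above the curve onset of
    # its whorl still belongs to it: shift windows up by a small guard band
    guard = min(1.0, params.min_whorl_separation / 2.0) / stack.thickness
    bounds = merged + [stack.n_slices + 1]
    whorls = []
    emergences = {t.track_id: t.detections[emergence_index(t)][0] for t in nodal}
    for k, onset in enumerate(merged):
        lo = -np.inf if k == 0 else bounds[k] - guard
        members = [t.track_id for t in nodal
                   if lo <= emergences[t.track_id] < bounds[k + 1] - guard]
        if members:
            whorls.append(Whorl(depth=float(stack.slice_depth(onset)),
                                member_ids=members,
                                index_from_youngest=len(whorls) + 1))
    return whorls


# ---------------------------------------------------------------------------
# back-tracking attachment of leftovers
# ---------------------------------------------------------------------------

def back_track_attach(unattached: list[RootTrack], graph: StructureGraph,
                      params: StructureParams | None = None) -> StructureGraph:
    """Walk each leftover fragment up to the nearest structure point.

    Within ``gap_tol`` of a root's bottom tip and passing the smooth-
    continuation test, the fragment extends that root; otherwise it attaches
    as a new branching (lateral) root.  Fragments with no structure point in
    reach stay in ``graph.unattached``.
    """
    params = params or StructureParams()
    for frag in unattached:
        frag_poly = graph.polyline(frag)
        top = frag_poly[0]
        best = None  # (dist, track, vertex_index)
        for t in [graph.stem] + graph.nodal + graph.laterals:
            poly = graph.polyline(t)
            d = np.linalg.norm(poly - top, axis=1)
            j = int(np.argmin(d))
            if best is None or d[j] < best[0]:
                best = (float(d[j]), t, j)
        if best is None or best[0] > params.gap_tol:
            graph.unattached.append(frag)
            continue
        dist, host, j = best
        host_poly = graph.polyline(host)
        at_tip = j >= len(host_poly) - 2
        if (at_tip and frag.detections[0][0] > host.detections[-1][0]
                and _merge_compatible(host_poly, frag_poly, params)):
            host.detections = host.detections + frag.detections
        elif _polyline_length(frag_poly) >= params.min_branch_length:
            graph.laterals.append(frag)
            graph.edges.append((host.track_id, frag.track_id, float(host_poly[j, 2])))
        else:
            # too short to be a credible branching root: report instead
            graph.unattached.append(frag)
    return graph


def _polyline_length(poly: np.ndarray) -> float:
    if len(poly) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum())


# ---------------------------------------------------------------------------
# full assembly
# ---------------------------------------------------------------------------

def build_structure_graph(tracks: list[RootTrack], stack: LevelSetStack,
                          params: StructureParams | None = None,
                          tracking_params: TrackingParams | None = None
                          ) -> tuple[StructureGraph, np.ndarray]:
    """Assemble the structure graph; returns (graph, cumulative-area curve)."""
    params = params or StructureParams()
    tracking_params = tracking_params or TrackingParams()
    accepted = [t for t in tracks if len(t) >= tracking_params.min_track_length]
    short = [t for t in tracks if len(t) < tracking_params.min_track_length]
    if not accepted:
        raise StructureError("no accepted tracks")
    accepted, forbidden = split_entangled_tracks(
        accepted, params, stack.pixel_mm, stack.thickness, stack.origin,
        stack.depth0, partner_tracks=accepted + short)
    accepted = resolve_crossings(accepted, params, stack.pixel_mm,
                                 stack.thickness, stack.origin, stack.depth0)
    accepted = connect_traces(accepted, params, stack.pixel_mm, stack.thickness,
                              stack.origin, stack.depth0, forbidden=forbidden)
    stem, stem_diameter = detect_stem(accepted, stack, params)
    nodal, laterals = classify_tracks(accepted, stem, stem_diameter, stack, params)
    curve = cumulative_nodal_area(nodal, stack)
    whorls = detect_whorls(curve, nodal, stack, params)
    graph = StructureGraph(stem=stem, stem_diameter=stem_diameter, whorls=whorls,
                           nodal=nodal, laterals=laterals,
                           pixel_mm=stack.pixel_mm, thickness=stack.thickness,
                           origin=stack.origin, depth0=stack.depth0)
    graph = back_track_attach(short, graph, params)
    return graph, curve
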