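"""Per-slice detection of individual roots in level-set images.

Each level-set image shows the cross-sections of every root crossing that
depth: ideally one roundish blob (or annulus) per root, but entangled roots
merge into single connected components.  The detection chain is

    binarize (Otsu) -> clean (fill holes, drop specks) -> label components
    -> watershed split of merged components (EDT markers)

with an optional active-contour refinement pass that circumscribes each
component with a closed snake.  The snake here is the greedy Williams-Shah
formulation: each vertex moves within a 3x3 neighborhood to the position
minimizing continuity + curvature + image energy, which makes the total
energy trace available and non-increasing by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import find_contours
from skimage.segmentation import watershed

from ._geometry import fit_circle_lsq, min_enclosing_circle

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class CrossSectionComponent:
    """One detected root cross-section in one slice."""

    slice_index: int
    label: int
    centroid: tuple[float, float]        # (x=col, y=row) px
    area: float                          # px^2
    diameter: float                      # mm, fitted circle
    bbox: tuple[int, int, int, int]      # (row0, col0, row1, col1)
    mask: np.ndarray = field(repr=False)  # cropped boolean support
    annular: bool = False

    def boundary(self) -> np.ndarray:
        """Closed boundary polygon in full-image (col, row) px coordinates."""
        padded = np.pad(self.mask, 1)
        contour = max(find_contours(padded.astype(float), 0.5), key=len)
        rows = contour[:, 0] - 1 + self.bbox[0]
        cols = contour[:, 1] - 1 + self.bbox[1]
        poly = np.column_stack([cols, rows])
        if not np.allclose(poly[0], poly[-1]):
            poly = np.vstack([poly, poly[0]])
        return poly


# ---------------------------------------------------------------------------
# binarization and component labeling
# ---------------------------------------------------------------------------

def binarize_otsu(image: np.ndarray) -> np.ndarray:
    """Otsu threshold (maximum between-class variance); foreground = above.

    Computed exactly over the observed gray levels (vectorized prefix
    sums), so the threshold equals an exhaustive search; a binned
    histogram Otsu can shift the cut between sparse levels.
    """
    image = np.asarray(image, dtype=float)
    values, counts = np.unique(image, return_counts=True)
    if values.size < 2:
        warnings.warn("constant image: empty Otsu mask", stacklevel=2)
        return np.zeros(image.shape, dtype=bool)
    w0 = np.cumsum(counts)[:-1]
    w1 = image.size - w0
    sums = np.cumsum(values * counts)
    mu0 = sums[:-1] / w0
    mu1 = (sums[-1] - sums[:-1]) / w1
    between = w0 * w1 * (mu0 - mu1) ** 2
    thr = values[int(np.argmax(between))]
    return image > thr


def clean_mask(mask: np.ndarray, min_area: int = 2,
               fill_holes: bool = True) -> np.ndarray:
    """Close 1-px sampling gaps, fill enclosed holes (tube walls become solid
    sections) and drop sub-``min_area`` specks."""
    mask = mask.astype(bool)
    if fill_holes:
        closed = ndi.binary_closing(mask, structure=_EIGHT, border_value=0)
        mask = ndi.binary_fill_holes(closed) | mask
    if min_area > 1 and mask.any():
        lbl, n = ndi.label(mask, structure=_EIGHT)
        counts = np.bincount(lbl.ravel())
        keep = counts >= min_area
        keep[0] = False
        mask = keep[lbl]
    return mask


def _components_from_labels(lbl: np.ndarray, n: int, slice_index: int,
                            pixel_mm: float) -> list[CrossSectionComponent]:
    comps = []
    objects = ndi.find_objects(lbl)
    for label in range(1, n + 1):
        sl = objects[label - 1]
        if sl is None:
            continue
        sub = lbl[sl] == label
        area = float(sub.sum())
        rows, cols = np.nonzero(sub)
        cy = rows.mean() + sl[0].start
        cx = cols.mean() + sl[1].start
        comp = CrossSectionComponent(
            slice_index=slice_index, label=label, centroid=(float(cx), float(cy)),
            area=area, diameter=0.0,
            bbox=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop), mask=sub)
        comp.annular = _is_annular(sub)
        comp.diameter = fit_diameter(comp, pixel_mm)
        comps.append(comp)
    return comps


def label_components(mask: np.ndarray, slice_index: int = 0,
                     pixel_mm: float = 1.0) -> list[CrossSectionComponent]:
    """Maximal 8-connected foreground regions of a binary mask."""
    mask = np.asarray(mask).astype(bool)
    lbl, n = ndi.label(mask, structure=_EIGHT)
    return _components_from_labels(lbl, n, slice_index, pixel_mm)


# ---------------------------------------------------------------------------
# watershed separation of entangled roots
# ---------------------------------------------------------------------------

def watershed_split(mask: np.ndarray, min_marker_distance: int = 5,
                    merge_ridge_ratio: float = 0.9) -> np.ndarray:
    """Split merged cross-sections by flooding the negated EDT from its maxima.

    Markers are EDT local maxima separated by >= ``min_marker_distance``
    within each connected component.  Adjacent watershed labels whose shared
    ridge is nearly as deep as the shallower marker peak (ratio above
    ``merge_ridge_ratio``) are remerged: such a pair has no real valley
    between it and is a single elongated section, not two entangled roots.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    comp_lbl, n_comp = ndi.label(mask, structure=_EIGHT)
    edt = ndi.distance_transform_edt(mask)
    coords = peak_local_max(edt, min_distance=int(min_marker_distance),
                            labels=comp_lbl, exclude_border=False)
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    # ensure every component has a marker (tiny components may lack peaks)
    marked = set(np.unique(comp_lbl[markers > 0]))
    next_id = len(coords) + 1
    for comp in range(1, n_comp + 1):
        if comp not in marked:
            rs, cs = np.nonzero(comp_lbl == comp)
            best = np.argmax(edt[rs, cs])
            markers[rs[best], cs[best]] = next_id
            next_id += 1
    labels = watershed(-edt, markers, mask=mask)

    # valley-depth merge guard
    peak_height = ndi.maximum(edt, labels=labels, index=np.arange(1, next_id))
    parent = list(range(next_id))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    shifted = [np.roll(labels, 1, axis=0), np.roll(labels, 1, axis=1),
               np.roll(np.roll(labels, 1, axis=0), 1, axis=1),
               np.roll(np.roll(labels, 1, axis=0), -1, axis=1)]
    pair_ridge: dict[tuple[int, int], float] = {}
    for sh in shifted:
        touch = (labels > 0) & (sh > 0) & (labels != sh)
        if not touch.any():
            continue
        a = labels[touch]
        b = sh[touch]
        ridge = edt[touch]
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        for la, lb, rv in zip(lo, hi, ridge):
            key = (int(la), int(lb))
            if rv > pair_ridge.get(key, -1.0):
                pair_ridge[key] = float(rv)
    for (la, lb), ridge in pair_ridge.items():
        shallower = min(peak_height[la - 1], peak_height[lb - 1])
        if shallower > 0 and ridge >= merge_ridge_ratio * shallower:
            ra, rb = find(la), find(lb)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    remap = np.zeros(next_id, dtype=np.int32)
    roots = {}
    nxt = 1
    for label in range(1, next_id):
        r = find(label)
        if r not in roots:
            roots[r] = nxt
            nxt += 1
        remap[label] = roots[r]
    return remap[labels]


def detect_components(image: np.ndarray, slice_index: int = 0,
                      pixel_mm: float = 1.0, min_area: int = 2,
                      min_marker_distance: int = 5,
                      merge_ridge_ratio: float = 0.9) -> list[CrossSectionComponent]:
    """Full per-slice detection chain used by the pipeline."""
    mask = image.astype(bool) if image.dtype != bool else image
    mask = clean_mask(mask, min_area=min_area)
    if not mask.any():
        return []
    labels = watershed_split(mask, min_marker_distance=min_marker_distance,
                             merge_ridge_ratio=merge_ridge_ratio)
    comps = _components_from_labels(labels, int(labels.max()), slice_index, pixel_mm)
    return [c for c in comps if c.area >= min_area]


def save_labeled_png(labels: np.ndarray, path) -> None:
    """Debug export: color-coded component labels of one slice."""
    from imageio.v3 import imwrite
    from matplotlib import colormaps

    cmap = colormaps["tab20"]
    rgb = np.zeros(labels.shape + (3,), dtype=np.uint8)
    for label in range(1, int(labels.max()) + 1):
        color = (np.array(cmap((label - 1) % 20)[:3]) * 255).astype(np.uint8)
        rgb[labels == label] = color
    imwrite(path, rgb)


# ---------------------------------------------------------------------------
# fitted-circle diameter
# ---------------------------------------------------------------------------

def _is_annular(sub_mask: np.ndarray) -> bool:
    filled = ndi.binary_fill_holes(sub_mask)
    return filled.sum() >= 1.5 * sub_mask.sum()


def fit_diameter(component: CrossSectionComponent, pixel_mm: float) -> float:
    """Fitted-circle diameter in mm.

    Filled sections: equivalent-area circle, ``2*sqrt(area/pi)*pixel_mm``.
    Annular (hollow) sections: least-squares circle through the ring pixels.
    """
    if component.area < 1:
        raise ValueError("component must have area >= 1 px^2")
    if component.annular:
        rows, cols = np.nonzero(component.mask)
        try:
            _, radius = fit_circle_lsq(np.column_stack([cols, rows]))
            return float(2.0 * radius * pixel_mm)
        except ValueError:
            pass
    return float(2.0 * math.sqrt(component.area / math.pi) * pixel_mm)


# ---------------------------------------------------------------------------
# greedy active-contour (snake) refinement
# ---------------------------------------------------------------------------

@dataclass
class SnakeResult:
    contour: np.ndarray           # closed polygon, (n+1, 2) (x, y) px, first = last
    converged: bool
    energies: np.ndarray          # total energy after each iteration
    enclosed_foreground: float    # px^2 of mask foreground inside the contour


def init_circles(mask: np.ndarray, dilate_px: int = 5) -> list[tuple[float, float, float]]:
    """One initialization circle per component: its minimum enclosing circle
    dilated by ``dilate_px`` (circle-seeded snakes, one per root section)."""
    circles = []
    for comp in label_components(mask):
        rows, cols = np.nonzero(comp.mask)
        pts = np.column_stack([cols + comp.bbox[1], rows + comp.bbox[0]])
        (cx, cy), r = min_enclosing_circle(pts)
        circles.append((cx, cy, r + dilate_px))
    return circles


def _edge_distance_field(image: np.ndarray) -> np.ndarray:
    mask = image.astype(bool) if image.dtype == bool else image > 0.5
    if not mask.any():
        return np.full(image.shape, float(max(image.shape)))
    eroded = ndi.binary_erosion(mask, structure=_EIGHT, border_value=0)
    edge = mask & ~eroded
    return ndi.distance_transform_edt(~edge)


def _bilinear(field: np.ndarray, xy) -> float:
    x = float(np.clip(xy[0], 0, field.shape[1] - 1.001))
    y = float(np.clip(xy[1], 0, field.shape[0] - 1.001))
    c0, r0 = int(x), int(y)
    fx, fy = x - c0, y - r0
    return float(field[r0, c0] * (1 - fx) * (1 - fy)
                 + field[r0, c0 + 1] * fx * (1 - fy)
                 + field[r0 + 1, c0] * (1 - fx) * fy
                 + field[r0 + 1, c0 + 1] * fx * fy)


def _snake_energy(verts: np.ndarray, ext: np.ndarray, alpha: float, beta: float,
                  w_ext: float) -> float:
    prev = np.roll(verts, 1, axis=0)
    nxt = np.roll(verts, -1, axis=0)
    spacing = np.linalg.norm(verts - prev, axis=1)
    dbar = spacing.mean()
    cont = alpha * (dbar - spacing) ** 2
    curv = beta * ((prev - 2 * verts + nxt) ** 2).sum(axis=1)
    ext_term = np.array([_bilinear(ext, v) for v in verts])
    return float((cont + curv + w_ext * ext_term).sum())


def snake_refine(image: np.ndarray, init_contours: list[tuple[float, float, float]],
                 alpha: float = 0.015, beta: float = 0.1, w_ext: float = 1.0,
                 max_iter: int = 500, search_margin: float = 3.0,
                 min_area: float = 2.0) -> list[SnakeResult]:
    """Greedy snake refinement of circle-initialized contours.

    Each vertex moves within its 3x3 neighborhood to the minimum of
    continuity + curvature + edge-distance energy; a full sweep that fails
    to lower the total energy is reverted, so the energy trace is
    non-increasing.  Vertices are confined to the init circle dilated by
    ``search_margin``.  Contours enclosing less than ``min_area`` px^2 of
    foreground are discarded (returned as None entries are filtered out).
    """
    image = np.asarray(image, dtype=float)
    mask = image > 0.5
    ext = _edge_distance_field(image)
    results = []
    for (cx, cy, r) in init_contours:
        n = max(16, int(2 * math.pi * r / 2.0))
        theta = np.linspace(0, 2 * math.pi, n, endpoint=False)
        verts = np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])
        max_r = r + search_margin
        energies = [_snake_energy(verts, ext, alpha, beta, w_ext)]
        converged = False
        # two greedy phases: whole-pixel moves, then half-pixel polish
        # (bilinear sampling of the edge-distance field)
        phases = [np.array([[dx, dy] for dx in (-1, 0, 1)
                            for dy in (-1, 0, 1)], float),
                  0.5 * np.array([[dx, dy] for dx in (-1, 0, 1)
                                  for dy in (-1, 0, 1)], float)]
        it = 0
        for moves in phases:
            step = np.abs(moves).max()
            while it < max_iter:
                it += 1
                prev_verts = verts.copy()
                for i in range(n):
                    best_e, best_v = np.inf, verts[i]
                    prev_v = verts[i - 1]
                    next_v = verts[(i + 1) % n]
                    spacing_all = np.linalg.norm(
                        verts - np.roll(verts, 1, axis=0), axis=1)
                    dbar = spacing_all.mean()
                    for mv in moves:
                        cand = verts[i] + mv
                        if (cand[0] - cx) ** 2 + (cand[1] - cy) ** 2 > max_r ** 2:
                            continue
                        e = (alpha * (dbar - np.linalg.norm(cand - prev_v)) ** 2
                             + alpha * (dbar - np.linalg.norm(next_v - cand)) ** 2
                             + beta * ((prev_v - 2 * cand + next_v) ** 2).sum()
                             + w_ext * _bilinear(ext, cand))
                        if e < best_e - 1e-12:
                            best_e, best_v = e, cand
                    verts[i] = best_v
                total = _snake_energy(verts, ext, alpha, beta, w_ext)
                if total > energies[-1] + 1e-9:
                    verts = prev_verts  # revert: keeps the trace monotone
                    converged = True
                    break
                energies.append(total)
                if np.abs(verts - prev_verts).max() < 0.1 * step:
                    converged = True
                    break
        closed = np.vstack([verts, verts[:1]])
        enclosed = _enclosed_foreground(closed, mask)
        results.append(SnakeResult(contour=closed, converged=converged,
                                   energies=np.array(energies),
                                   enclosed_foreground=enclosed))
    return [r for r in results if r.enclosed_foreground >= min_area]


def _enclosed_foreground(contour: np.ndarray, mask: np.ndarray) -> float:
    from matplotlib.path import Path as MplPath

    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        return 0.0
    inside = MplPath(contour).contains_points(np.column_stack([cols, rows]))
    return float(inside.sum())
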