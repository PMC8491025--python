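"""Level-set scanning: top-down raster cross-sections of an aligned crown.

A sliding horizontal plane scans the aligned cloud from the stem top
downward; each slab of thickness ``t`` becomes a binary occupancy raster (a
pixel is foreground iff at least one point falls in it).  The stack can then
be densified by inter-slice interpolation, which smooths the sequence and
closes contours that are broken in a single slice by under-sampling.

Interpolation morphs signed Euclidean distance transforms of neighboring
binarized slices and re-thresholds at zero.  Before morphing (for k >= 1), a
temporal closing pass adds any pixel that is foreground in both neighbors of
a slice: a contour gap present in one slice but absent above and below it is
an under-sampling artifact, and pairwise morphing alone cannot bridge it
because the broken slice is an endpoint of every morph it takes part in.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .cloud_io import RootPointCloud


@dataclass
class LevelSetStack:
    """Ordered top-down stack of binary cross-section rasters.

    ``images`` is (n, H, W) uint8; slice ``i`` covers the half-open depth bin
    ``[depth0 + i*thickness, depth0 + (i+1)*thickness)``.
    """

    images: np.ndarray
    thickness: float
    pixel_mm: float
    origin: tuple[float, float] = (0.0, 0.0)
    depth0: float = 0.0

    def __post_init__(self):
        self.images = np.asarray(self.images)
        if self.images.ndim != 3 or len(self.images) < 1:
            raise ValueError("images must be a non-empty (n, H, W) array")
        if self.thickness <= 0 or self.pixel_mm <= 0:
            raise ValueError("thickness and pixel_mm must be positive")

    @property
    def n_slices(self) -> int:
        return len(self.images)

    def slice_depth(self, i: int | np.ndarray) -> float | np.ndarray:
        """Depth (mm) of the top of slice ``i``."""
        return self.depth0 + np.asarray(i) * self.thickness

    def foreground_areas_mm2(self) -> np.ndarray:
        return self.images.reshape(self.n_slices, -1).astype(bool).sum(axis=1) \
            * self.pixel_mm ** 2

    def pixel_to_mm(self, cols: np.ndarray, rows: np.ndarray) -> np.ndarray:
        """Map (col, row) pixel centers to (x, y) mm."""
        x = self.origin[0] + (np.asarray(cols) + 0.5) * self.pixel_mm
        y = self.origin[1] + (np.asarray(rows) + 0.5) * self.pixel_mm
        return np.column_stack([x, y])


def slice_stack(cloud: RootPointCloud, thickness: float = 1.0,
                pixel_mm: float = 0.5, margin_px: int = 2) -> LevelSetStack:
    """Bin points into depth slabs and rasterize each slab's (x, y) occupancy."""
    if thickness <= 0 or pixel_mm <= 0:
        raise ValueError("thickness and pixel_mm must be positive")
    pts = cloud.points
    if len(pts) == 0:
        raise ValueError("cannot slice an empty cloud")
    z = pts[:, 2]
    depth0 = float(z.min())
    extent = float(z.max() - depth0)
    n_slices = max(1, math.ceil(extent / thickness)) if extent > 0 else 1
    if extent > 0 and thickness > extent:
        warnings.warn("slice thickness exceeds depth extent; single-slice stack",
                      stacklevel=2)
    idx = np.clip(((z - depth0) / thickness).astype(int), 0, n_slices - 1)

    x, y = pts[:, 0], pts[:, 1]
    x0 = float(x.min()) - margin_px * pixel_mm
    y0 = float(y.min()) - margin_px * pixel_mm
    W = int(math.floor((x.max() - x0) / pixel_mm)) + 1 + margin_px
    H = int(math.floor((y.max() - y0) / pixel_mm)) + 1 + margin_px
    cols = np.clip(((x - x0) / pixel_mm).astype(int), 0, W - 1)
    rows = np.clip(((y - y0) / pixel_mm).astype(int), 0, H - 1)

    images = np.zeros((n_slices, H, W), dtype=np.uint8)
    images[idx, rows, cols] = 1
    return LevelSetStack(images=images, thickness=thickness, pixel_mm=pixel_mm,
                         origin=(x0, y0), depth0=depth0)


def save_stack_png(stack: LevelSetStack, directory) -> None:
    """Export the stack as numbered PNGs plus a JSON sidecar with the
    geometry (thickness, pixel size, origin, depth of slice 0)."""
    import json
    from pathlib import Path

    from imageio.v3 import imwrite

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, img in enumerate(stack.images):
        imwrite(directory / f"slice_{i:04d}.png",
                (img.astype(np.uint8) * 255))
    sidecar = {"n_slices": stack.n_slices, "thickness_mm": stack.thickness,
               "pixel_mm": stack.pixel_mm, "origin_mm": list(stack.origin),
               "depth0_mm": stack.depth0}
    (directory / "stack.json").write_text(json.dumps(sidecar, indent=1))


def _signed_edt(mask: np.ndarray) -> np.ndarray:
    """Signed distance: positive inside the foreground, negative outside."""
    fg = mask.astype(bool)
    if not fg.any():
        return -np.full(mask.shape, max(mask.shape), dtype=float)
    if fg.all():
        return np.full(mask.shape, max(mask.shape), dtype=float)
    return ndi.distance_transform_edt(fg) - ndi.distance_transform_edt(~fg)


def interpolate_stack(stack: LevelSetStack, k: int = 2) -> LevelSetStack:
    """Insert ``k`` morphed frames in every slice gap (k = 0 is the identity).

    Returns a stack of ``n + (n-1)*k`` slices with thickness ``t/(k+1)``.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return LevelSetStack(images=stack.images.copy(), thickness=stack.thickness,
                             pixel_mm=stack.pixel_mm, origin=stack.origin,
                             depth0=stack.depth0)
    masks = stack.images.astype(bool)
    n = len(masks)
    if n < 2:
        raise ValueError("interpolation needs at least 2 slices")

    # temporal closing: repair contour breaks using the neighbors above and
    # below; the second-order pass covers breaks in two adjacent slices
    # (a structure present 2 mm above and below a gap spans it)
    repaired = masks.copy()
    repaired[1:-1] |= masks[:-2] & masks[2:]

    sdts = [_signed_edt(m) for m in repaired]
    out = []
    for i in range(n - 1):
        out.append(repaired[i])
        for j in range(1, k + 1):
            w = j / (k + 1)
            out.append(((1.0 - w) * sdts[i] + w * sdts[i + 1]) > 0)
    out.append(repaired[-1])
    images = np.stack(out).astype(np.uint8)
    return LevelSetStack(images=images, thickness=stack.thickness / (k + 1),
                         pixel_mm=stack.pixel_mm, origin=stack.origin,
                         depth0=stack.depth0)
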