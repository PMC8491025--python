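"""Capture pre-processing for structure-from-motion reconstruction.

The scanner captures a circular sequence of images around the crown; before
handing them to external SfM software we (i) reject blurred frames by their
high-frequency FFT content, (ii) normalize illumination with a
luminance-weighted gray-world balance, (iii) segment the root from the
background by color distance to a batch background model, and (iv) plan the
feature-matching pair list: instead of all n(n-1) ordered pairs, only pairs
within a sliding window over the circular capture order are matched.

Reconstruction itself (feature detection, RANSAC, bundle adjustment) is
delegated to external SfM packages; this module only prepares their inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np


# ---------------------------------------------------------------------------
# blur detection
# ---------------------------------------------------------------------------

def blur_score(image: np.ndarray, lowfreq_radius_frac: float = 0.125) -> float:
    """Sharpness score: mean log-magnitude of FFT coefficients outside a
    centered low-frequency disc.  Higher = sharper; constant image = 0.
    Excluding the disc (DC included) makes the score invariant to adding a
    constant offset to all pixels.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 16:
        raise ValueError("blur_score expects a grayscale image >= 16x16")
    if np.ptp(img) == 0:
        return 0.0
    # remove the mean and apply a Hann window: boundary discontinuities
    # otherwise leak broadband energy that swamps the true high frequencies
    img = img - img.mean()
    win = (np.hanning(img.shape[0])[:, None] * np.hanning(img.shape[1])[None, :])
    F = np.fft.fftshift(np.fft.fft2(img * win))
    h, w = img.shape
    yy, xx = np.mgrid[:h, :w]
    r = np.hypot(yy - h // 2, xx - w // 2)
    outside = r > lowfreq_radius_frac * min(h, w)
    mag = np.abs(F[outside])
    return float(np.mean(np.log1p(mag)))


def flag_blurry(scores, k: float = 3.0) -> np.ndarray:
    """Batch classifier: flag images whose score < median - k * MAD."""
    scores = np.asarray(scores, float)
    med = np.median(scores)
    mad = np.median(np.abs(scores - med))
    return scores < med - k * mad


# ---------------------------------------------------------------------------
# illumination normalization
# ---------------------------------------------------------------------------

_LUMA = np.array([0.299, 0.587, 0.114])


def gray_world_normalize(image: np.ndarray) -> np.ndarray:
    """Luminance-weighted gray-world white balance.

    Channel gains are chosen so the luminance-weighted channel means
    equalize; bright pixels dominate the estimate, so dark background does
    not skew the balance.  Output is clipped to the input range.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    if (img @ _LUMA).sum() <= 0:
        warnings.warn("all-black image: returned unchanged", stacklevel=2)
        return image.copy()
    out = img.astype(float)
    # the luminance weights change with the gains, so iterate to the
    # fixpoint where the weighted channel means are equal
    for _ in range(8):
        luma = out @ _LUMA
        means = (out * luma[..., None]).reshape(-1, 3).sum(axis=0) / luma.sum()
        target = means.mean()
        gains = np.where(means > 0, target / np.maximum(means, 1e-12), 1.0)
        out = out * gains
        if np.abs(gains - 1.0).max() < 1e-4:
            break
    lo, hi = (0.0, 255.0) if image.dtype == np.uint8 else (img.min(), img.max())
    out = np.clip(out, lo, max(hi, out.min()))
    return out.astype(image.dtype) if image.dtype == np.uint8 else out


# ---------------------------------------------------------------------------
# content-based foreground segmentation
# ---------------------------------------------------------------------------

@dataclass
class BackgroundModel:
    """Robust per-channel background color statistics for an image batch."""

    color: np.ndarray   # (3,) background color
    spread: float       # robust scale of background color distances

    @classmethod
    def from_images(cls, images, border: int = 10) -> "BackgroundModel":
        samples = []
        for img in images:
            img = np.asarray(img, float)
            b = min(border, img.shape[0] // 4, img.shape[1] // 4)
            edge = np.concatenate([
                img[:b].reshape(-1, 3), img[-b:].reshape(-1, 3),
                img[:, :b].reshape(-1, 3), img[:, -b:].reshape(-1, 3)])
            samples.append(edge)
        samples = np.vstack(samples)
        color = np.median(samples, axis=0)
        dist = np.linalg.norm(samples - color, axis=1)
        spread = float(np.median(np.abs(dist - np.median(dist))) + 1e-6)
        return cls(color=color, spread=spread)


def segment_foreground(image: np.ndarray, background: BackgroundModel,
                       min_component_area: int = 20,
                       threshold: float | None = None) -> np.ndarray:
    """Foreground = pixels whose color distance to the background model
    exceeds an Otsu-selected (or explicitly given) threshold, cleaned by
    small-component removal.  Raising the threshold never grows the mask.
    """
    from scipy import ndimage as ndi
    from skimage.filters import threshold_otsu

    img = np.asarray(image, float)
    dist = np.linalg.norm(img - background.color, axis=-1)
    if threshold is None:
        if np.ptp(dist) == 0:
            return np.zeros(dist.shape, dtype=bool)
        threshold = float(threshold_otsu(dist))
    mask = dist > threshold
    if mask.any() and min_component_area > 1:
        lbl, _ = ndi.label(mask, structure=np.ones((3, 3), int))
        counts = np.bincount(lbl.ravel())
        keep = counts >= min_component_area
        keep[0] = False
        mask = keep[lbl]
    return mask


# ---------------------------------------------------------------------------
# match-pair planning
# ---------------------------------------------------------------------------

@dataclass
class PairList:
    pairs: list[tuple[int, int]]
    n_images: int
    window: int

    def __len__(self) -> int:
        return len(self.pairs)

    def write(self, path: str | Path) -> None:
        """Two-column text pair list, the de-facto SfM match-list format."""
        with open(path, "w") as fh:
            for i, j in self.pairs:
                fh.write(f"{i} {j}\n")


def pair_count_full(n: int, r: int = 2, ordered: bool = True) -> int:
    """Number of image pairs under full matching: the falling product
    n!/(n-r)! for ordered pairs (default), n!/(r!(n-r)!) unordered."""
    if not (isinstance(n, (int, np.integer)) and isinstance(r, (int, np.integer))):
        raise TypeError("n and r must be integers")
    if r < 1 or n < r:
        raise ValueError(f"need n >= r >= 1, got n={n}, r={r}")
    perms = 1
    for i in range(n, n - r, -1):
        perms *= i
    if ordered:
        return perms
    fact_r = 1
    for i in range(2, r + 1):
        fact_r *= i
    return perms // fact_r


def sliding_window_pairs(n: int, w: int) -> PairList:
    """All ordered pairs (i, j), i != j, within circular index distance
    w - 1 on the capture circle; w >= n degenerates to full matching."""
    if n < 2 or w < 2:
        raise ValueError("need n >= 2 and w >= 2")
    pairs = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = abs(i - j)
            if min(d, n - d) <= w - 1:
                pairs.append((i, j))
    return PairList(pairs=pairs, n_images=n, window=w)
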