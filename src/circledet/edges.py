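"""Parameter-free edge extraction.

The detector needs a one-pixel-wide binary edge map with *no per-image
hyperparameters*: connected chains of edge pixels, thinned to unit width.
The front end combines

1. a 5×5 Gaussian smoothing kernel (σ = 1) and Sobel gradients,
2. gradient-direction non-maximum suppression and hysteresis linking
   (via the Canny machinery) with **data-driven** thresholds: the strong
   threshold is the larger of Otsu's split of the gradient magnitudes
   and an a-contrario noise floor σ̂·√(2·ln N) — σ̂ being the robust
   (median-absolute-deviation) estimate of the noise gradient spread —
   chosen so that a pure-noise image yields fewer than one false edgel
   in expectation,
3. chain validation: connected chains too short to be perceptually
   meaningful are discarded as accidental alignments,
4. morphological thinning to enforce unit width.

The stage is deliberately pluggable: any routine producing a binary edge
map (including an externally computed one) can be substituted upstream
of the detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import canny
from skimage.filters import threshold_otsu
from skimage.morphology import thin as _sk_thin

from .geometry import PointSet

__all__ = ["EdgeMap", "detect_edges", "thin"]

# chains shorter than this are treated as accidental and dropped
_MIN_CHAIN_LEN = 8


@dataclass(frozen=True)
class EdgeMap:
    """Binary edge raster; ON pixels form one-pixel-wide chains."""

    mask: np.ndarray  # bool, shape (H, W)

    def __post_init__(self):
        if self.mask.ndim != 2 or self.mask.dtype != bool:
            raise ValueError("EdgeMap mask must be a 2-D boolean array")

    @property
    def height(self) -> int:
        return self.mask.shape[0]

    @property
    def width(self) -> int:
        return self.mask.shape[1]

    @property
    def n_on(self) -> int:
        return int(self.mask.sum())

    def points(self) -> np.ndarray:
        """ON pixels as an (n, 2) array of (x, y) = (col, row)."""
        ys, xs = np.nonzero(self.mask)
        return np.column_stack([xs, ys]).astype(np.int64)

    def point_set(self) -> PointSet:
        return PointSet.from_array(self.points())


def _edge_thresholds(img: np.ndarray) -> tuple:
    """Strong/weak gradient thresholds from the image itself.

    Otsu separates edge from non-edge magnitudes when real structure
    dominates; under heavy noise the MAD-based floor takes over, sized so
    that the expected number of above-threshold pixels in a noise-only
    image is below one (the a-contrario / Helmholtz rationale).
    """
    smooth = ndimage.gaussian_filter(img, sigma=1.0, truncate=2.0, mode="nearest")
    gx = ndimage.sobel(smooth, axis=1, mode="nearest")
    gy = ndimage.sobel(smooth, axis=0, mode="nearest")
    mag = np.hypot(gx, gy)
    pos = mag[mag > 1e-12]
    if pos.size == 0 or np.ptp(pos) == 0:
        return None
    otsu = threshold_otsu(pos)
    sg = np.median(np.abs(gx - np.median(gx))) / 0.6745
    noise_floor = sg * np.sqrt(2.0 * np.log(img.size))
    high = max(otsu, noise_floor)
    return high / 2.0, high


def detect_edges(image: np.ndarray) -> EdgeMap:
    """Extract a one-pixel-wide binary edge map from a grayscale image.

    Deterministic for a fixed image; a constant image yields an empty
    map.  Values are expected in [0, 1] but any finite single-channel
    raster is accepted — all thresholds are data-driven.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("detect_edges expects a single-channel image")
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite values")

    empty = EdgeMap(np.zeros(img.shape, dtype=bool))
    if img.size == 0 or min(img.shape) < 3 or img.max() == img.min():
        return empty

    thresholds = _edge_thresholds(img)
    if thresholds is None:
        return empty
    low, high = thresholds
    mask = canny(img, sigma=1.0, low_threshold=low, high_threshold=high)
    if not mask.any():
        return empty

    # chain validation: chains too short to be perceptually meaningful
    labels, n_lab = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    sizes = ndimage.sum_labels(mask, labels, np.arange(1, n_lab + 1))
    keep = np.zeros(n_lab + 1, dtype=bool)
    keep[1:] = sizes >= _MIN_CHAIN_LEN
    mask = keep[labels]

    return thin(mask)


def thin(mask: np.ndarray | EdgeMap) -> EdgeMap:
    """Morphologically thin a binary raster to one-pixel-wide skeletons.

    Two-subiteration thinning; idempotent, and the ON set of the result
    is a subset of the input ON set.
    """
    if isinstance(mask, EdgeMap):
        mask = mask.mask
    arr = np.asarray(mask)
    if arr.dtype != bool:
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("thin expects a binary raster")
        arr = arr.astype(bool)
    return EdgeMap(_sk_thin(arr))
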