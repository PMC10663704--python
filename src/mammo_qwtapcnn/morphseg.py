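"""Morphological mass segmentation.

Binary masks and structuring elements are finite subsets of a pixel frame;
erosion, dilation and internal boundary extraction are implemented directly
from their set definitions:

    erode(M, N)   = { q : N translated by q is contained in M }
    dilate(M, N)  = { q : (N reflected, then translated by q) meets M }
    boundary(M,N) = M minus erode(M, N)

Translations that leave the frame fail the containment test, so erosion
shrinks at the borders (the frame is the universe).

Candidate masses are found by clustering every pixel's two features --
brightness and Sobel edge magnitude, each scaled to [0, 1] -- into K segments
with Lloyd-style alternating minimization of the summed squared Euclidean
distance to the segment centers, then cleaning the brightest segment by
morphological opening and keeping its largest connected component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from .synth_io import validate_gray_image

__all__ = [
    "StructuringElement",
    "SegmentationResult",
    "MassROI",
    "DegenerateInputError",
    "sobel_edges",
    "erode",
    "dilate",
    "boundary",
    "reflect",
    "segment",
    "extract_mass_roi",
    "MorphSegmenter",
]


class DegenerateInputError(ValueError):
    """Fewer distinct feature rows than requested segments."""


@dataclass(frozen=True)
class StructuringElement:
    """A set of integer (dy, dx) offsets; the origin is (0, 0)."""

    offsets: Tuple[Tuple[int, int], ...]

    def __post_init__(self):
        if len(self.offsets) == 0:
            raise ValueError("structuring element must be nonempty")

    @classmethod
    def disc(cls, radius: int) -> "StructuringElement":
        """Euclidean disc of the given radius (includes the origin)."""
        offs = [
            (dy, dx)
            for dy in range(-radius, radius + 1)
            for dx in range(-radius, radius + 1)
            if dy * dy + dx * dx <= radius * radius
        ]
        return cls(tuple(offs))

    @classmethod
    def square(cls, size: int) -> "StructuringElement":
        r = size // 2
        return cls(tuple((dy, dx) for dy in range(-r, r + 1) for dx in range(-r, r + 1)))

    def to_array(self):
        """0/1 array and the origin's index within it (for scipy cross-checks)."""
        dys = [o[0] for o in self.offsets]
        dxs = [o[1] for o in self.offsets]
        y0, x0 = -min(dys), -min(dxs)
        arr = np.zeros((max(dys) - min(dys) + 1, max(dxs) - min(dxs) + 1), dtype=bool)
        for dy, dx in self.offsets:
            arr[dy + y0, dx + x0] = True
        return arr, (y0, x0)


def reflect(se: StructuringElement) -> StructuringElement:
    """Reflection of the structuring element through its origin."""
    return StructuringElement(tuple((-dy, -dx) for dy, dx in se.offsets))


def _as_mask(M: np.ndarray) -> np.ndarray:
    arr = np.asarray(M)
    if arr.ndim != 2:
        raise ValueError("mask must be 2-D")
    return arr.astype(bool)


def _shift(mask: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """mask translated by (-dy, -dx) so out[q] = mask[q + (dy, dx)];
    out-of-frame reads are False."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    ys = slice(max(0, -dy), min(h, h - dy))
    xs = slice(max(0, -dx), min(w, w - dx))
    ys_src = slice(max(0, dy), min(h, h + dy))
    xs_src = slice(max(0, dx), min(w, w + dx))
    out[ys, xs] = mask[ys_src, xs_src]
    return out


def erode(M: np.ndarray, se: StructuringElement) -> np.ndarray:
    """{q : for every offset o in N, q + o is inside the frame and in M}."""
    mask = _as_mask(M)
    out = np.ones_like(mask)
    for dy, dx in se.offsets:
        out &= _shift(mask, dy, dx)
    return out


def dilate(M: np.ndarray, se: StructuringElement) -> np.ndarray:
    """{q : reflected N translated by q intersects M}; equivalently the union
    of M translated by every offset of N."""
    mask = _as_mask(M)
    out = np.zeros_like(mask)
    for dy, dx in se.offsets:
        out |= _shift(mask, -dy, -dx)
    return out


def boundary(M: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Internal boundary: M minus its erosion."""
    mask = _as_mask(M)
    return mask & ~erode(mask, se)


def opening(M: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Erosion followed by dilation; anti-extensive (never grows the mask)."""
    return dilate(erode(M, se), se)


# ---------------------------------------------------------------------------
# Edges
# ---------------------------------------------------------------------------

def sobel_edges(image: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude sqrt(Gx^2 + Gy^2), standard 3x3 kernels,
    replicate boundary."""
    img = np.asarray(image, dtype=np.float64)
    gy = ndimage.sobel(img, axis=0, mode="nearest")
    gx = ndimage.sobel(img, axis=1, mode="nearest")
    return np.hypot(gy, gx)


# ---------------------------------------------------------------------------
# K-segment clustering of (brightness, edge) features
# ---------------------------------------------------------------------------

@dataclass
class SegmentationResult:
    """Solved K-segment clustering over per-pixel (brightness, edge) features."""

    features: np.ndarray       # N x 2, scaled to [0, 1]
    centers: np.ndarray        # K x 2
    labels: np.ndarray         # H x W integer segment labels
    fitness_trace: List[float] # summed squared distances per iteration
    n_iterations: int
    shape: Tuple[int, int]

    @property
    def fitness(self) -> float:
        return self.fitness_trace[-1]


def pixel_features(image: np.ndarray) -> np.ndarray:
    """N x 2 feature matrix: brightness and Sobel magnitude, each in [0, 1].

    A 3x3 median prefilter despeckles the image before the features are
    computed; without it, residual noise grain after restoration forms its
    own clusters and starves the (small) mass segment of a center.
    """
    img = validate_gray_image(image).astype(np.float64)
    img = ndimage.median_filter(img, size=3)
    edges = sobel_edges(img)
    brightness = img / 255.0
    emax = edges.max()
    edges = edges / emax if emax > 0 else edges
    return np.column_stack([brightness.ravel(), edges.ravel()])


def segment(image: np.ndarray, K: int = 5, max_iters: int = 50,
            seed: int = 0) -> SegmentationResult:
    """Cluster pixels into K segments by alternating minimization.

    Centers are initialized deterministically at the K mid-quantiles of the
    *distinct* brightness values (edge component at the global mean) --
    quantiles of the brightness scale rather than of the pixel mass, so the
    heavily unbalanced segments of a mammogram (a small bright mass against
    large tissue and background modes) still receive separate initial
    centers.  Lloyd iterations then alternate nearest-center assignment
    (Euclidean) and center recomputation until the assignment reaches a
    fixpoint or ``max_iters``.  The summed squared distance (fitness) is
    non-increasing per iteration.  ``seed`` is accepted for interface
    symmetry; the procedure is deterministic.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    img = validate_gray_image(image)
    feats = pixel_features(img)
    n_distinct = np.unique(feats, axis=0).shape[0]
    if K > n_distinct:
        raise DegenerateInputError(
            f"K={K} exceeds the {n_distinct} distinct feature rows"
        )
    qs = (2 * np.arange(K) + 1) / (2 * K)
    distinct_brightness = np.unique(feats[:, 0])
    centers = np.column_stack([
        np.quantile(distinct_brightness, qs),
        np.full(K, feats[:, 1].mean()),
    ])

    labels = None
    trace: List[float] = []
    for it in range(max_iters):
        d2 = ((feats[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        trace.append(float(d2[np.arange(len(feats)), new_labels].sum()))
        if labels is not None and np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
        for k in range(K):
            sel = labels == k
            if sel.any():
                centers[k] = feats[sel].mean(axis=0)
    return SegmentationResult(
        features=feats, centers=centers,
        labels=labels.reshape(img.shape), fitness_trace=trace,
        n_iterations=len(trace), shape=img.shape,
    )


# ---------------------------------------------------------------------------
# Mass ROI extraction
# ---------------------------------------------------------------------------

@dataclass
class MassROI:
    """Candidate mass region: cleaned mask, its internal boundary, bounding
    box (ymin, xmin, ymax, xmax) and centroid; ``found`` is False when the
    brightest segment vanishes after opening (a no-mass image)."""

    found: bool
    mask: np.ndarray
    boundary: np.ndarray
    bbox: Optional[Tuple[int, int, int, int]] = None
    centroid: Optional[Tuple[float, float]] = None


def extract_mass_roi(image: np.ndarray, seg: SegmentationResult,
                     se_radius: int = 2,
                     max_area_fraction: float = 0.2) -> MassROI:
    """Clean the brightest segment and keep its largest connected component.

    Opening (erode then dilate with a disc of ``se_radius``) removes specks.
    An empty result -- or a candidate covering more than
    ``max_area_fraction`` of the frame, which is breast tissue rather than a
    localized lesion -- flags the image as containing no mass.
    """
    bright = int(np.argmax(seg.centers[:, 0]))
    mask = seg.labels == bright
    se = StructuringElement.disc(se_radius)
    opened = opening(mask, se)
    if not opened.any():
        empty = np.zeros_like(mask)
        return MassROI(found=False, mask=empty, boundary=empty)
    comp, n = ndimage.label(opened, structure=np.ones((3, 3), dtype=int))
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
    largest = comp == (1 + int(np.argmax(sizes)))
    if largest.sum() > max_area_fraction * largest.size:
        empty = np.zeros_like(mask)
        return MassROI(found=False, mask=empty, boundary=empty)
    ys, xs = np.nonzero(largest)
    return MassROI(
        found=True,
        mask=largest,
        boundary=boundary(largest, se),
        bbox=(int(ys.min()), int(xs.min()), int(ys.max()), int(xs.max())),
        centroid=(float(ys.mean()), float(xs.mean())),
    )


class MorphSegmenter(BaseEstimator):
    """Estimator-style wrapper: K-segment clustering + morphological cleanup.

    ``transform`` maps image(s) to :class:`MassROI` result(s).
    """

    def __init__(self, K: int = 5, max_iters: int = 50, se_radius: int = 2,
                 seed: int = 0):
        self.K = K
        self.max_iters = max_iters
        self.se_radius = se_radius
        self.seed = seed

    def fit(self, X=None, y=None):
        if self.K < 2:
            raise ValueError("K must be >= 2")
        self.n_features_in_ = 0
        return self

    def segment_image(self, image: np.ndarray):
        seg = segment(image, K=self.K, max_iters=self.max_iters, seed=self.seed)
        roi = extract_mass_roi(image, seg, se_radius=self.se_radius)
        return seg, roi

    def transform(self, X):
        self.fit()
        if isinstance(X, np.ndarray) and X.ndim == 2:
            return self.segment_image(X)[1]
        return [self.segment_image(img)[1] for img in X]
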