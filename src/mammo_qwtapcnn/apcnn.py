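"""Atrous-pyramid classifier with pseudoinverse training, CRF refinement and
particle-filter localization.

The feature stack is a fixed (randomly initialized, never trained)
convolutional pipeline: a 9x9 convolution bank, stochastic "random" pooling
over 7x7 windows, a second 9x9 convolution, 5x5 max pooling, then an atrous
pyramid -- the same 9x9 filter bank applied at seven dilation rates -- whose
outputs are globally averaged per channel into the feature vector.  Only the
output weights are learned, in closed form: with hidden activations G and
one-hot targets z, beta = pinv(G) z is the minimum-norm least-squares
solution (extreme-learning-machine training; no iterative weight updates).

Per-pixel class probabilities are refined by a dense conditional random
field with two Gaussian pairwise kernels (an appearance kernel over position
and intensity, and a smoothness kernel over position only) under a Potts
compatibility, solved by mean-field iteration with exact (dense) pairwise
sums on desk-scale images.

Mass centers are localized by a bootstrap particle filter: particles are
initialized from the first detection-score map, propagated by a Gaussian
random walk, weighted by a two-dimensional Gaussian observation model
evaluated on the score maps, normalized, and systematically resampled.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist
from scipy.special import expit, softmax
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .morphseg import MorphSegmenter, SegmentationResult, MassROI
from .synth_io import validate_gray_image

__all__ = [
    "APCNNConfig",
    "CRFParams",
    "ParticleFilterConfig",
    "ClassDecision",
    "FeatureResult",
    "LocalizationResult",
    "dilate_kernel",
    "conv_bank",
    "build_features",
    "solve_output_weights",
    "APCNNClassifier",
    "crf_refine",
    "crf_energy",
    "localize",
    "bayes_posterior",
    "mass_probability_map",
    "refine_mass_mask",
    "predict_image",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class APCNNConfig:
    """Architecture of the fixed feature stack and the trained head.

    Window sizes: 9x9 convolutions, 7x7 random pooling, 5x5 max pooling.
    ``fc_window`` and ``softmax_window`` record the fully-connected (CRF) and
    softmax stage windowing; the refinement here is dense, so they are
    metadata.  ``atrous_rates`` must list exactly seven dilation rates;
    ``hidden_units`` are the two dense random layers between the feature
    vector and the pseudoinverse-solved output weights.
    """

    conv_window: int = 9
    random_pool_window: int = 7
    max_pool_window: int = 5
    fc_window: int = 9
    softmax_window: int = 7
    atrous_rates: Tuple[int, ...] = (1, 2, 3, 4, 6, 9, 12)
    n_filters: int = 4
    hidden_units: Tuple[int, ...] = (10, 2)
    activation: str = "sigmoid"
    tau: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if len(self.atrous_rates) != 7:
            raise ValueError("exactly 7 atrous rates are required")
        if any(r < 1 for r in self.atrous_rates):
            raise ValueError("atrous rates must be positive")
        for w in (self.conv_window, self.random_pool_window, self.max_pool_window,
                  self.fc_window, self.softmax_window):
            if w <= 0 or w % 2 == 0:
                raise ValueError("window sizes must be odd and positive")


def _activation(name: str):
    if name == "sigmoid":
        return expit
    if name in ("sin", "sinusoidal"):
        return np.sin
    if name == "relu":
        return lambda x: np.maximum(x, 0.0)
    raise ValueError(f"unknown activation {name!r}")


# ---------------------------------------------------------------------------
# Convolution / pooling primitives
# ---------------------------------------------------------------------------

def dilate_kernel(kernel: np.ndarray, rate: int) -> np.ndarray:
    """Insert ``rate - 1`` zeros between kernel taps (atrous dilation)."""
    if rate < 1:
        raise ValueError("rate must be >= 1")
    if rate == 1:
        return kernel
    k = kernel.shape[0]
    size = k + (k - 1) * (rate - 1)
    out = np.zeros((size, size), dtype=kernel.dtype)
    out[::rate, ::rate] = kernel
    return out


def conv_bank(maps: np.ndarray, kernels: np.ndarray, rate: int = 1) -> np.ndarray:
    """Multi-channel filtering: (C,H,W) maps x (O,C,k,k) kernels -> (O,H,W).

    Kernels are applied as cross-correlations with replicate boundary; the
    dilation ``rate`` spaces the taps without adding parameters.
    """
    n_out = kernels.shape[0]
    out = np.zeros((n_out, maps.shape[1], maps.shape[2]))
    for o in range(n_out):
        acc = np.zeros(maps.shape[1:])
        for c in range(maps.shape[0]):
            acc += ndimage.correlate(
                maps[c], dilate_kernel(kernels[o, c], rate), mode="nearest"
            )
        out[o] = acc
    return out


def _window_view(maps: np.ndarray, window: int):
    """Crop to a multiple of ``window`` and reshape into non-overlapping
    windows: (C, H, W) -> (C, nh, nw, window*window)."""
    c, h, w = maps.shape
    nh, nw = max(h // window, 1), max(w // window, 1)
    win_h, win_w = min(window, h), min(window, w)
    cropped = maps[:, : nh * win_h, : nw * win_w]
    view = cropped.reshape(c, nh, win_h, nw, win_w).transpose(0, 1, 3, 2, 4)
    return view.reshape(c, nh, nw, win_h * win_w)


def random_pool(maps: np.ndarray, window: int,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Stochastic pooling over non-overlapping windows.

    With an ``rng`` (training), one activation per window is sampled with
    probability proportional to its magnitude; without (inference), the
    magnitude-weighted expectation is returned.  All-zero windows pool to 0.
    """
    wins = _window_view(maps, window)
    mags = np.abs(wins)
    totals = mags.sum(axis=-1, keepdims=True)
    safe = np.where(totals > 0, totals, 1.0)
    probs = np.where(totals > 0, mags / safe, 1.0 / wins.shape[-1])
    if rng is None:
        return np.where(
            totals[..., 0] > 0, (probs * wins).sum(axis=-1), 0.0
        )
    gumbel = rng.gumbel(size=wins.shape)
    idx = (np.log(np.maximum(probs, 1e-300)) + gumbel).argmax(axis=-1)
    return np.take_along_axis(wins, idx[..., None], axis=-1)[..., 0]


def max_pool(maps: np.ndarray, window: int) -> np.ndarray:
    """Max over non-overlapping windows."""
    return _window_view(maps, window).max(axis=-1)


def _make_kernels(rng: np.random.Generator, n_out: int, n_in: int, k: int) -> np.ndarray:
    """Zero-mean random kernels scaled for unit-order responses."""
    kk = rng.normal(size=(n_out, n_in, k, k))
    kk -= kk.mean(axis=(2, 3), keepdims=True)
    return kk / (k * np.sqrt(n_in))


@dataclass
class FeatureResult:
    """Feature vector plus the per-pixel (per-cell) maps kept for refinement."""

    vector: np.ndarray
    atrous_maps: Dict[int, np.ndarray]   # rate -> (n_filters, h, w)
    pooled: np.ndarray                   # map entering the atrous pyramid


def build_features(image: np.ndarray, config: Optional[APCNNConfig] = None,
                   rng: Optional[np.random.Generator] = None) -> FeatureResult:
    """Run the fixed feature stack on one image.

    Pipeline: conv(9x9) -> random pooling (7x7) -> conv(9x9) -> max pooling
    (5x5) -> atrous pyramid (seven dilation rates on one 9x9 bank) -> global
    average per channel.  Filters are frozen functions of ``config.seed``;
    pass ``rng`` to sample the stochastic pooling (training mode), omit it
    for the deterministic expectation (inference mode).
    """
    config = config or APCNNConfig()
    img = validate_gray_image(image)
    if img.shape[0] < 64 or img.shape[1] < 64:
        raise ValueError("image must be at least 64x64 for the feature stack")
    x = img.astype(np.float64)[None] / 255.0

    krng = np.random.default_rng(config.seed)
    k = config.conv_window
    nf = config.n_filters
    bank1 = _make_kernels(krng, nf, 1, k)
    bank2 = _make_kernels(krng, nf, nf, k)
    bank_atrous = _make_kernels(krng, nf, nf, k)
    g = _activation(config.activation)

    h1 = g(conv_bank(x, bank1))
    p1 = random_pool(h1, config.random_pool_window, rng)
    h2 = g(conv_bank(p1, bank2))
    p2 = max_pool(h2, config.max_pool_window)

    atrous_maps = {}
    features = []
    for rate in config.atrous_rates:
        m = g(conv_bank(p2, bank_atrous, rate=rate))
        atrous_maps[rate] = m
        features.append(m.mean(axis=(1, 2)))
    return FeatureResult(np.concatenate(features), atrous_maps, p2)


# ---------------------------------------------------------------------------
# Pseudoinverse (ELM) training
# ---------------------------------------------------------------------------

def solve_output_weights(G: np.ndarray, targets: np.ndarray,
                         rcond: float = 1e-10, ridge: float = 1e-6) -> np.ndarray:
    """Minimum-norm least-squares output weights beta = pinv(G) @ targets.

    The pseudoinverse uses an SVD with singular values below
    ``rcond * sigma_max`` cut off.  A degenerate G (an all-zero column) emits
    a warning and falls back to a ridge-regularized normal-equation solve.
    """
    G = np.asarray(G, dtype=np.float64)
    T = np.asarray(targets, dtype=np.float64)
    if G.shape[0] != T.shape[0]:
        raise ValueError("G and targets must have the same number of rows")
    if not np.all(G.any(axis=0)):
        warnings.warn("degenerate hidden matrix (all-zero column); using ridge solve")
        d = G.shape[1]
        return np.linalg.solve(G.T @ G + ridge * np.eye(d), G.T @ T)
    return np.linalg.pinv(G, rcond=rcond) @ T


class APCNNClassifier(BaseEstimator, ClassifierMixin):
    """Random-projection classifier head trained by a single linear solve.

    The feature vector is standardized and propagated through frozen random
    dense layers (``hidden_units``, default 10 then 2 units, sigmoid); the
    hidden matrix G collects the activations of every random layer plus a
    bias column.  Training solves beta = pinv(G) @ one_hot(y) once; the
    random input weights are never updated.

    ``tau`` is the three-way decision threshold: a case whose best softmax
    score falls below ``tau`` is labelled ``suspicious`` by
    :meth:`predict_with_suspicious`.
    """

    def __init__(self, hidden_units: Tuple[int, ...] = (10, 2),
                 activation: str = "sigmoid", tau: float = 0.6,
                 rcond: float = 1e-10, ridge: float = 1e-6, seed: int = 0):
        self.hidden_units = hidden_units
        self.activation = activation
        self.tau = tau
        self.rcond = rcond
        self.ridge = ridge
        self.seed = seed

    # -- internals ---------------------------------------------------------

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.feature_mean_) / self.feature_scale_

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        g = _activation(self.activation)
        h = self._standardize(X)
        collected = []
        for W, b in self.input_weights_:
            h = g(h @ W + b)
            collected.append(h)
        return np.column_stack(collected + [np.ones(len(h))])

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per target")
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]
        self.feature_mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        self.feature_scale_ = np.where(scale > 1e-12, scale, 1.0)

        rng = np.random.default_rng(self.seed)
        self.input_weights_ = []
        d = X.shape[1]
        for m in self.hidden_units:
            W = rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, m))
            b = rng.uniform(-0.5, 0.5, size=m)
            self.input_weights_.append((W, b))
            d = m
        G = self._hidden(X)
        T = (y[:, None] == self.classes_[None, :]).astype(np.float64)
        self.output_weights_ = solve_output_weights(G, T, self.rcond, self.ridge)
        self.hidden_matrix_shape_ = G.shape
        return self

    def decision_function(self, X):
        check_is_fitted(self, "output_weights_")
        X = np.asarray(X, dtype=np.float64)
        return self._hidden(X) @ self.output_weights_

    def predict_proba(self, X):
        return softmax(self.decision_function(X), axis=1)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)]

    def predict_with_suspicious(self, X, tau: Optional[float] = None):
        """Three-way decision: the argmax class, or ``suspicious`` when no
        class score reaches the threshold."""
        tau = self.tau if tau is None else tau
        proba = self.predict_proba(X)
        labels = self.classes_[proba.argmax(axis=1)].astype(object)
        labels[proba.max(axis=1) < tau] = "suspicious"
        return labels


# ---------------------------------------------------------------------------
# Dense CRF refinement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CRFParams:
    """Dense-CRF parameters: two Gaussian kernel weights, their bandwidths
    (theta_alpha/theta_beta for the appearance kernel's position/intensity,
    theta_gamma for the smoothness kernel's position) and the number of
    mean-field iterations.  Kernels use exp(-d^2 / theta^2)."""

    w1: float = 1.0
    w2: float = 0.3
    theta_alpha: float = 5.0
    theta_beta: float = 20.0
    theta_gamma: float = 3.0
    iterations: int = 5
    max_pixels: int = 96 * 96

    def __post_init__(self):
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("kernel weights must be >= 0")
        if min(self.theta_alpha, self.theta_beta, self.theta_gamma) <= 0:
            raise ValueError("bandwidths must be > 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


_SPATIAL_KERNEL_CACHE: dict = {}


def _spatial_kernels(h: int, w: int, theta_alpha: float, theta_gamma: float):
    """exp(-|s_i - s_j|^2 / theta^2) matrices, cached per (shape, bandwidth)
    since they do not depend on the image."""
    key = (h, w, theta_alpha, theta_gamma)
    if key not in _SPATIAL_KERNEL_CACHE:
        ys, xs = np.mgrid[0:h, 0:w]
        pos = np.column_stack([ys.ravel(), xs.ravel()]).astype(np.float64)
        ds = cdist(pos, pos, "sqeuclidean").astype(np.float32)
        _SPATIAL_KERNEL_CACHE.clear()  # keep at most one shape resident
        _SPATIAL_KERNEL_CACHE[key] = (
            np.exp(-ds / np.float32(theta_alpha ** 2)),
            np.exp(-ds / np.float32(theta_gamma ** 2)),
        )
    return _SPATIAL_KERNEL_CACHE[key]


def crf_kernel_matrix(image: np.ndarray, params: CRFParams) -> np.ndarray:
    """Dense pairwise kernel K[i, j] = w1 k1 + w2 k2 with zero diagonal.

    k1 (appearance) couples nearby pixels of similar intensity; k2
    (smoothness) couples nearby pixels regardless of intensity.
    """
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    n = h * w
    if n > params.max_pixels:
        raise ValueError(
            f"dense CRF limited to {params.max_pixels} pixels, got {n}; crop first"
        )
    spatial_alpha, k2 = _spatial_kernels(h, w, params.theta_alpha, params.theta_gamma)
    e = img.ravel()
    de = np.subtract.outer(e, e).astype(np.float32) ** 2
    k1 = spatial_alpha * np.exp(-de / np.float32(params.theta_beta ** 2))
    K = np.float32(params.w1) * k1 + np.float32(params.w2) * k2
    np.fill_diagonal(K, 0.0)
    return K


def crf_energy(labels: np.ndarray, unary_neglog: np.ndarray, K: np.ndarray) -> float:
    """E(Y) = sum_i psi_u(y_i) + sum_{i != j} K_ij [y_i != y_j]
    (ordered pairs; K has zero diagonal)."""
    lab = np.asarray(labels).ravel()
    n, L = unary_neglog.shape
    e_unary = float(unary_neglog[np.arange(n), lab].sum())
    onehot = np.zeros((n, L), dtype=K.dtype)
    onehot[np.arange(n), lab] = 1.0
    same = float(np.sum((K @ onehot) * onehot, dtype=np.float64))
    return e_unary + float(K.sum(dtype=np.float64)) - same


def crf_refine(unary_probs: np.ndarray, image: np.ndarray,
               params: Optional[CRFParams] = None):
    """Mean-field refinement of per-pixel class probabilities.

    ``unary_probs`` is (H, W, L) with rows summing to 1.  Returns the refined
    (H, W) label map and the energy trace (initial argmax energy first, then
    the argmax energy after each mean-field iteration).  The returned
    labeling is the best-energy one among the initial argmax and every
    iteration's argmax, so refinement never increases the energy.
    """
    params = params or CRFParams()
    probs = np.asarray(unary_probs, dtype=np.float64)
    img = np.asarray(image, dtype=np.float64)
    if probs.ndim != 3 or probs.shape[:2] != img.shape:
        raise ValueError("unary_probs must be (H, W, n_labels) matching the image")
    flat = probs.reshape(-1, probs.shape[2])
    if not np.allclose(flat.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("unary probabilities must sum to 1 per pixel")

    h, w, L = probs.shape
    psi_u = -np.log(flat + 1e-12)
    K = crf_kernel_matrix(img, params)
    rowsum = K.sum(axis=1, dtype=np.float64)

    best_labels = psi_u.argmin(axis=1)
    best_energy = crf_energy(best_labels, psi_u, K)
    trace = [best_energy]

    Q = flat.astype(np.float32)
    for _ in range(params.iterations):
        msg = K @ Q                        # expected same-label agreement
        cost = psi_u + rowsum[:, None] - msg   # Potts pairwise expectation
        Q = softmax(-cost, axis=1).astype(np.float32)
        labels = Q.argmax(axis=1)
        e = crf_energy(labels, psi_u, K)
        trace.append(e)
        if e < best_energy:
            best_energy, best_labels = e, labels
    return best_labels.reshape(h, w), trace


# ---------------------------------------------------------------------------
# Particle-filter localization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParticleFilterConfig:
    """Bootstrap particle filter: ``process_std`` is the Gaussian random-walk
    step (pixels); ``sigma1``/``sigma2`` the row/column bandwidths of the
    two-dimensional Gaussian observation model."""

    n_particles: int = 200
    process_std: float = 2.0
    sigma1: float = 2.0
    sigma2: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_particles < 10:
            raise ValueError("need at least 10 particles")


@dataclass
class LocalizationResult:
    trajectory: List[Tuple[float, float]]
    estimate: Tuple[float, float]
    particles: np.ndarray
    weights: np.ndarray


def _systematic_resample(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = len(weights)
    positions = (np.arange(n) + rng.uniform()) / n
    return np.searchsorted(np.cumsum(weights), positions)


def localize(score_maps: Sequence[np.ndarray],
             config: Optional[ParticleFilterConfig] = None) -> LocalizationResult:
    """Track the mass center through a sequence of detection-score maps.

    Sequential importance resampling: particles are initialized by sampling
    pixel locations from the first map (uniform fallback when it is all
    zero), propagated by a Gaussian random walk, weighted by the Gaussian-
    smoothed score interpolated at each particle, normalized, and
    systematically resampled.  The per-frame estimate is the weighted mean.
    """
    config = config or ParticleFilterConfig()
    maps = [np.asarray(m, dtype=np.float64) for m in score_maps]
    if not maps:
        raise ValueError("need at least one score map")
    rng = np.random.default_rng(config.seed)
    h, w = maps[0].shape
    n = config.n_particles

    p0 = np.clip(maps[0], 0, None).ravel()
    if p0.sum() > 0:
        idx = rng.choice(h * w, size=n, p=p0 / p0.sum())
    else:
        idx = rng.integers(h * w, size=n)
    particles = np.column_stack([idx // w, idx % w]).astype(np.float64)

    trajectory = []
    weights = np.full(n, 1.0 / n)
    for frame, m in enumerate(maps):
        if frame > 0 and config.process_std > 0:
            particles += rng.normal(0.0, config.process_std, particles.shape)
            particles[:, 0] = np.clip(particles[:, 0], 0, h - 1)
            particles[:, 1] = np.clip(particles[:, 1], 0, w - 1)
        smoothed = ndimage.gaussian_filter(
            np.clip(m, 0, None), sigma=(config.sigma1, config.sigma2)
        )
        lik = ndimage.map_coordinates(
            smoothed, particles.T, order=1, mode="nearest"
        )
        lik = np.clip(lik, 0.0, None)
        if lik.sum() <= 0:
            weights = np.full(n, 1.0 / n)       # documented all-zero fallback
        else:
            weights = lik / lik.sum()
        estimate = tuple(weights @ particles)
        trajectory.append(estimate)
        particles = particles[_systematic_resample(weights, rng)]
    return LocalizationResult(trajectory, trajectory[-1], particles, weights)


def bayes_posterior(likelihood: float, prior: float, evidence: float) -> float:
    """posterior = likelihood * prior / evidence (all inputs in (0, 1])."""
    for name, v in (("likelihood", likelihood), ("prior", prior)):
        if not 0.0 < v <= 1.0:
            raise ValueError(f"{name} must lie in (0, 1]")
    if evidence <= 0:
        raise ValueError("evidence must be > 0")
    return likelihood * prior / evidence


# ---------------------------------------------------------------------------
# Per-image decision
# ---------------------------------------------------------------------------

@dataclass
class ClassDecision:
    """Three-way decision for one image, with the refined mass mask and the
    particle-filter center estimate (None when no mass region was found)."""

    label: str
    scores: Dict[str, float]
    refined_mask: np.ndarray
    center_estimate: Optional[Tuple[float, float]] = None


def mass_probability_map(image: np.ndarray, seg: SegmentationResult,
                         sharpness: float = 0.08) -> np.ndarray:
    """Soft per-pixel mass probability from the clustering geometry.

    Two-class softmax over squared feature distances to the brightest
    segment center versus the nearest other center, with Gaussian scale
    ``sharpness`` (feature units).
    """
    bright = int(np.argmax(seg.centers[:, 0]))
    d2 = ((seg.features[:, None, :] - seg.centers[None, :, :]) ** 2).sum(axis=2)
    d_mass = d2[:, bright]
    others = [k for k in range(len(seg.centers)) if k != bright]
    d_other = d2[:, others].min(axis=1)
    s2 = 2.0 * sharpness ** 2
    logits = np.column_stack([-d_other / s2, -d_mass / s2])
    return softmax(logits, axis=1)[:, 1].reshape(seg.shape)


def refine_mass_mask(image: np.ndarray, seg: SegmentationResult, roi: MassROI,
                     crf_params: Optional[CRFParams] = None, crop: int = 64):
    """CRF-refine the mass mask on a crop around the ROI centroid.

    Returns (refined full-frame mask, energy trace).  Images with no ROI get
    an empty mask and an empty trace.
    """
    img = validate_gray_image(image)
    if not roi.found:
        return np.zeros(img.shape, dtype=bool), []
    crf_params = crf_params or CRFParams()
    h, w = img.shape
    size = min(crop, h, w)
    cy, cx = roi.centroid
    y0 = int(np.clip(round(cy - size / 2), 0, h - size))
    x0 = int(np.clip(round(cx - size / 2), 0, w - size))
    window = (slice(y0, y0 + size), slice(x0, x0 + size))

    p_mass = mass_probability_map(img, seg)[window]
    unary = np.stack([1.0 - p_mass, p_mass], axis=-1)
    labels, trace = crf_refine(unary, img[window].astype(np.float64), crf_params)
    refined = np.zeros(img.shape, dtype=bool)
    refined[window] = labels == 1
    return refined, trace


def predict_image(clf: APCNNClassifier, image: np.ndarray,
                  attributes: Optional[np.ndarray] = None,
                  config: Optional[APCNNConfig] = None,
                  segmenter: Optional[MorphSegmenter] = None,
                  crf_params: Optional[CRFParams] = None,
                  pf_config: Optional[ParticleFilterConfig] = None,
                  n_frames: int = 3) -> ClassDecision:
    """Full per-image decision: segment, extract features (optionally with
    the nine tabular attributes), score the trained head, refine the mask and
    localize the mass center."""
    check_is_fitted(clf, "output_weights_")
    config = config or APCNNConfig()
    segmenter = segmenter or MorphSegmenter()
    seg, roi = segmenter.segment_image(image)

    feats = build_features(image, config).vector
    if attributes is not None:
        feats = np.concatenate([feats, np.asarray(attributes, dtype=np.float64)])
    proba = clf.predict_proba(feats[None])[0]
    scores = dict(zip(map(str, clf.classes_), map(float, proba)))
    label = str(clf.classes_[int(proba.argmax())])
    if proba.max() < clf.tau:
        label = "suspicious"

    refined, _ = refine_mass_mask(image, seg, roi, crf_params)
    center = None
    if roi.found:
        score_map = mass_probability_map(image, seg)
        result = localize([score_map] * n_frames, pf_config)
        center = result.estimate
    return ClassDecision(label, scores, refined, center)


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------

def save_model(path, clf: APCNNClassifier,
               feature_config: Optional[APCNNConfig] = None) -> None:
    """Serialize a fitted classifier (and the feature-stack configuration it
    was trained with, so inference rebuilds the same frozen filters) to an
    .npz archive."""
    check_is_fitted(clf, "output_weights_")
    arrays = {
        "classes": clf.classes_.astype(str),
        "feature_mean": clf.feature_mean_,
        "feature_scale": clf.feature_scale_,
        "output_weights": clf.output_weights_,
    }
    for i, (W, b) in enumerate(clf.input_weights_):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    meta = dict(
        hidden_units=list(clf.hidden_units), activation=clf.activation,
        tau=clf.tau, rcond=clf.rcond, ridge=clf.ridge, seed=clf.seed,
        n_layers=len(clf.input_weights_), n_features_in=clf.n_features_in_,
        feature_config=asdict(feature_config) if feature_config else None,
    )
    arrays["meta_json"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)


def load_model(path) -> APCNNClassifier:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta_json"]))
        clf = APCNNClassifier(
            hidden_units=tuple(meta["hidden_units"]), activation=meta["activation"],
            tau=meta["tau"], rcond=meta["rcond"], ridge=meta["ridge"],
            seed=meta["seed"],
        )
        clf.classes_ = data["classes"]
        clf.feature_mean_ = data["feature_mean"]
        clf.feature_scale_ = data["feature_scale"]
        clf.output_weights_ = data["output_weights"]
        clf.n_features_in_ = int(meta["n_features_in"])
        clf.input_weights_ = [
            (data[f"W{i}"], data[f"b{i}"]) for i in range(int(meta["n_layers"]))
        ]
        clf.hidden_matrix_shape_ = (0, clf.output_weights_.shape[0])
        fc = meta.get("feature_config")
        if fc is not None:
            fc["atrous_rates"] = tuple(fc["atrous_rates"])
            fc["hidden_units"] = tuple(fc["hidden_units"])
            clf.feature_config_ = APCNNConfig(**fc)
        else:
            clf.feature_config_ = None
    return clf
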