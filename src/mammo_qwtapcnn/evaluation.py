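"""Evaluation metrics, cross-validation and the end-to-end experiment.

Metrics: MSE and PSNR (peak 255), accuracy / sensitivity / specificity /
positive predictive value from confusion matrices, Dice overlap, and ROC /
AUC from an explicit threshold sweep (trapezoidal area; ties included
simultaneously).  The splitter produces a stratified 70/30 train/test split
plus stratified k-fold assignments.

``run_pipeline`` executes the whole study on synthetic phantoms: optional
noise injection and denoising, morphological segmentation with CRF mask
refinement, feature extraction, pseudoinverse training on the training
split, and hold-out + k-fold evaluation, returning a serializable report.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import apcnn, denoise as dn, morphseg, synth_io

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "PipelineConfig",
    "mse",
    "psnr",
    "confusion_matrix",
    "classification_metrics",
    "dice",
    "roc_auc",
    "roc_curve",
    "split_and_cv",
    "generate_cohort",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# Image-quality metrics
# ---------------------------------------------------------------------------

def mse(x: np.ndarray, ref: np.ndarray) -> float:
    """Mean squared pixel difference (gray-level^2)."""
    a = np.asarray(x, dtype=np.float64)
    b = np.asarray(ref, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def psnr(x: np.ndarray, ref: np.ndarray, peak: float = 255.0) -> float:
    """Peak signal-to-noise ratio 10 log10(peak^2 / MSE) in dB.

    Identical images return ``inf`` (serialized as null by the report).
    """
    m = mse(x, ref)
    if m == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak ** 2 / m))


# ---------------------------------------------------------------------------
# Classification metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Rows = truth, columns = predicted."""

    counts: np.ndarray
    labels: Tuple[str, ...]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(truths: Sequence, preds: Sequence,
                     labels: Optional[Sequence[str]] = None) -> ConfusionMatrix:
    truths = [str(t) for t in truths]
    preds = [str(p) for p in preds]
    if labels is None:
        labels = sorted(set(truths) | set(preds))
    labels = tuple(str(l) for l in labels)
    index = {l: i for i, l in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(truths, preds):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, labels)


def classification_metrics(cm: ConfusionMatrix,
                           positive: str | Sequence[str] = "malignant") -> Dict[str, float]:
    """Accuracy, sensitivity, specificity and PPV from a confusion matrix.

    ``positive`` names the class(es) collapsed to "positive"; all others are
    negative.  For three-way outputs, predicted ``suspicious`` counts as a
    positive prediction (a suspicious case is recalled, not cleared), which
    only affects the binary sensitivity/specificity bookkeeping -- the full
    matrix is kept alongside.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    positives = {positive} if isinstance(positive, str) else set(positive)
    pred_positive = positives | {"suspicious"}
    tp = fn = fp = tn = 0
    for i, t in enumerate(cm.labels):
        for j, p in enumerate(cm.labels):
            c = int(cm.counts[i, j])
            if t in positives:
                if p in pred_positive:
                    tp += c
                else:
                    fn += c
            else:
                if p in pred_positive:
                    fp += c
                else:
                    tn += c
    accuracy = float(np.trace(cm.counts)) / cm.total
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    return {
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "positive_predictive_value": ppv,
    }


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity 2|A∩B| / (|A| + |B|); two empty masks give 1.0."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * float(np.logical_and(a, b).sum()) / denom


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores: Sequence[float], truths: Sequence[int]):
    """ROC points and trapezoidal AUC from a threshold sweep.

    Thresholds are the unique scores in decreasing order (tied scores enter
    together), plus the (0,0) and (1,1) endpoints.  Requires at least one
    positive and one negative truth.
    """
    s = np.asarray(scores, dtype=np.float64)
    t = np.asarray(truths).astype(int)
    n_pos = int((t == 1).sum())
    n_neg = int((t == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative case")
    order = np.argsort(-s, kind="stable")
    s_sorted, t_sorted = s[order], t[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(s_sorted)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            tp += int(t_sorted[j] == 1)
            fp += int(t_sorted[j] == 0)
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    auc = float(np.trapezoid(ys, xs))
    return points, auc


def roc_curve(scores: Sequence[float], truths: Sequence[int]):
    """(fpr, tpr, threshold) triples for the same sweep as :func:`roc_auc`.

    The leading (0, 0) point carries threshold +inf (no case called
    positive); each following point uses its inclusion threshold.
    """
    s = np.asarray(scores, dtype=np.float64)
    points, _ = roc_auc(s, truths)
    thresholds = [float("inf")] + sorted({float(v) for v in s}, reverse=True)
    return [(x, y, t) for (x, y), t in zip(points, thresholds)]


# ---------------------------------------------------------------------------
# Splits and cross-validation
# ---------------------------------------------------------------------------

def split_and_cv(labels: Sequence, train_frac: float = 0.7, k: int = 5,
                 seed: int = 0):
    """Stratified 70/30-style split plus stratified k-fold assignment.

    Returns ``(train_idx, test_idx, fold_of)`` where ``fold_of`` maps each
    case index to a fold in 0..k-1.  Folds partition the cases with sizes
    within one of each other and per-class ratios preserved within one case.
    A class with fewer than ``k`` cases triggers a warning and an
    unstratified fallback.  Deterministic given ``seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    y = np.asarray([str(l) for l in labels])
    n = len(y)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)

    stratify = bool((counts >= k).all())
    if not stratify:
        warnings.warn("a class has fewer cases than k; falling back to unstratified")

    fold_of = np.empty(n, dtype=np.int64)
    train_mask = np.zeros(n, dtype=bool)
    if stratify:
        groups = [np.flatnonzero(y == c) for c in classes]
    else:
        groups = [np.arange(n)]
    offset = 0
    for idx in groups:
        perm = idx[rng.permutation(len(idx))]
        n_train = int(round(train_frac * len(perm)))
        train_mask[perm[:n_train]] = True
        # round-robin fold assignment, offset so folds stay balanced globally
        fold_of[perm] = (np.arange(len(perm)) + offset) % k
        offset += len(perm)
    train_idx = np.flatnonzero(train_mask)
    test_idx = np.flatnonzero(~train_mask)
    return train_idx, test_idx, fold_of


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Study conditions for the synthetic end-to-end experiment."""

    n_phantoms: int = 200
    size: int = 256
    class_mix: Tuple[str, ...] = ("benign", "malignant")
    noise: Optional[synth_io.NoiseSpec] = None
    denoise: bool = True
    K: int = 5
    se_radius: int = 2
    train_frac: float = 0.7
    k_folds: int = 5
    tau: float = 0.6
    use_attributes: bool = True
    refine_masks: bool = True
    localize: bool = True
    seed: int = 0


@dataclass
class EvalReport:
    """Everything the experiment measured, JSON-serializable."""

    accuracy: float
    sensitivity: float
    specificity: float
    positive_predictive_value: float
    auc: float
    roc_points: List[Tuple[float, float]]
    roc_thresholds: List[float]
    mean_dice: float
    cv_accuracies: List[float]
    confusion: List[List[int]]
    confusion_labels: List[str]
    confusion_3way: List[List[int]]
    confusion_3way_labels: List[str]
    fold_assignments: List[int]
    suspicious_rate: float
    mean_psnr_noisy: Optional[float]
    mean_psnr_denoised: Optional[float]
    mean_localization_error: Optional[float]
    n_train: int
    n_test: int
    timings: Dict[str, float] = field(default_factory=dict)

    def to_dict(self, include_timings: bool = True) -> dict:
        d = asdict(self)
        for key in ("mean_psnr_noisy", "mean_psnr_denoised"):
            if d[key] is not None and np.isinf(d[key]):
                d[key] = None
        # the leading ROC threshold is +inf; keep the JSON strictly valid
        d["roc_thresholds"] = [None if np.isinf(t) else t for t in d["roc_thresholds"]]
        if not include_timings:
            d.pop("timings")
        return d


def generate_cohort(config: PipelineConfig) -> List[synth_io.Phantom]:
    """Deterministically generate the phantom cohort: classes interleaved
    evenly from ``class_mix``, per-case seeds derived from ``config.seed``."""
    phantoms = []
    for i in range(config.n_phantoms):
        label = config.class_mix[i % len(config.class_mix)]
        phantoms.append(
            synth_io.generate_phantom(
                size=config.size, label=label,
                seed=(config.seed * 100003 + i) % (2 ** 31),
            )
        )
    return phantoms


def run_pipeline(config: Optional[PipelineConfig] = None,
                 phantoms: Optional[List[synth_io.Phantom]] = None) -> EvalReport:
    """Run the full synthetic experiment and evaluate it.

    Stages: (optional) noise injection -> (optional) denoising ->
    segmentation + ROI + CRF mask refinement -> feature extraction (atrous
    stack, plus the nine tabular attributes when enabled) -> stratified
    train/test split -> pseudoinverse training -> hold-out metrics, ROC/AUC
    (malignant score), k-fold cross-validation, mass Dice and
    particle-filter localization error.
    """
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    timings: Dict[str, float] = {}

    if phantoms is None:
        phantoms = generate_cohort(config)
    timings["generate"] = time.perf_counter() - t0

    apcfg = apcnn.APCNNConfig(tau=config.tau, seed=config.seed)
    segmenter = morphseg.MorphSegmenter(K=config.K, se_radius=config.se_radius)
    denoiser = dn.QWTDenoiser(seed=config.seed)

    images, psnrs_noisy, psnrs_denoised = [], [], []
    t = time.perf_counter()
    for i, ph in enumerate(phantoms):
        img = ph.image
        if config.noise is not None:
            spec = synth_io.NoiseSpec(
                family=config.noise.family, sigma=config.noise.sigma,
                mean=config.noise.mean, density=config.noise.density,
                seed=(config.seed * 99991 + i) % (2 ** 31),
            )
            img = synth_io.add_noise(img, spec)
            psnrs_noisy.append(psnr(img, ph.image))
        if config.denoise:
            img = denoiser.denoise_image(img).image
            if config.noise is not None:
                psnrs_denoised.append(psnr(img, ph.image))
        images.append(img)
    timings["denoise"] = time.perf_counter() - t

    t = time.perf_counter()
    dices, loc_errors, features = [], [], []
    for ph, img in zip(phantoms, images):
        seg, roi = segmenter.segment_image(img)
        if config.refine_masks:
            refined, _ = apcnn.refine_mass_mask(img, seg, roi)
        else:
            refined = roi.mask
        dices.append(dice(refined, ph.mask))
        if config.localize and roi.found and ph.record.radius is not None:
            score_map = apcnn.mass_probability_map(img, seg)
            pf = apcnn.ParticleFilterConfig(seed=config.seed)
            est = apcnn.localize([score_map] * 3, pf).estimate
            true = (ph.record.center_y, ph.record.center_x)
            loc_errors.append(float(np.hypot(est[0] - true[0], est[1] - true[1])))
        vec = apcnn.build_features(img, apcfg).vector
        if config.use_attributes:
            vec = np.concatenate([vec, ph.attributes])
        features.append(vec)
    X = np.vstack(features)
    y = np.array([ph.label for ph in phantoms])
    timings["segment_features"] = time.perf_counter() - t

    t = time.perf_counter()
    train_idx, test_idx, fold_of = split_and_cv(
        y, train_frac=config.train_frac, k=config.k_folds, seed=config.seed
    )
    clf = apcnn.APCNNClassifier(tau=config.tau, seed=config.seed)
    clf.fit(X[train_idx], y[train_idx])

    preds = clf.predict(X[test_idx])
    preds3 = clf.predict_with_suspicious(X[test_idx])
    proba = clf.predict_proba(X[test_idx])
    cm = confusion_matrix(y[test_idx], preds, labels=sorted(set(y)))
    cm3 = confusion_matrix(
        y[test_idx], preds3, labels=sorted(set(y) | {"suspicious"})
    )
    metrics = classification_metrics(cm, positive="malignant")

    mal_col = list(clf.classes_).index("malignant") if "malignant" in clf.classes_ else -1
    mal_scores = proba[:, mal_col]
    mal_truths = (y[test_idx] == "malignant").astype(int)
    roc_points, auc = roc_auc(mal_scores, mal_truths)
    roc_thresholds = [t for _, _, t in roc_curve(mal_scores, mal_truths)]

    cv_accuracies = []
    for fold in range(config.k_folds):
        tr = fold_of != fold
        te = ~tr
        fold_clf = apcnn.APCNNClassifier(tau=config.tau, seed=config.seed)
        fold_clf.fit(X[tr], y[tr])
        cv_accuracies.append(float(np.mean(fold_clf.predict(X[te]) == y[te])))
    timings["train_eval"] = time.perf_counter() - t
    timings["total"] = time.perf_counter() - t0

    return EvalReport(
        accuracy=metrics["accuracy"],
        sensitivity=metrics["sensitivity"],
        specificity=metrics["specificity"],
        positive_predictive_value=metrics["positive_predictive_value"],
        auc=auc,
        roc_points=[(float(a), float(b)) for a, b in roc_points],
        roc_thresholds=roc_thresholds,
        mean_dice=float(np.mean(dices)) if dices else 1.0,
        cv_accuracies=cv_accuracies,
        confusion=cm.counts.tolist(),
        confusion_labels=list(cm.labels),
        confusion_3way=cm3.counts.tolist(),
        confusion_3way_labels=list(cm3.labels),
        fold_assignments=fold_of.tolist(),
        suspicious_rate=float(np.mean(preds3 == "suspicious")),
        mean_psnr_noisy=float(np.mean(psnrs_noisy)) if psnrs_noisy else None,
        mean_psnr_denoised=float(np.mean(psnrs_denoised)) if psnrs_denoised else None,
        mean_localization_error=float(np.mean(loc_errors)) if loc_errors else None,
        n_train=len(train_idx),
        n_test=len(test_idx),
        timings=timings,
    )
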