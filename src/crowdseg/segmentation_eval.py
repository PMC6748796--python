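"""Pixel-level evaluation of segmentation predictions and the
training-set-size (learning-curve) experiment harness.

Predictions are per-class score planes over the truth grid; hard labels are
the per-pixel argmax. Evaluation follows the five-class scheme — tumor,
stroma, inflammatory infiltrate, necrosis and a pooled "other" — with
one-vs-rest pixel ROC AUC (midrank tie handling), Dice, binary accuracy, a
micro-averaged AUC pooling all pixel-class decisions and a confusion matrix in
percent of total evaluated pixels. Pixels labeled 0 (outside the ROI) are
excluded from every metric.

The learning-curve harness measures how macro-averaged AUC grows with the
number of training slides using a deliberately shallow pluggable patch
classifier: the experimental design under test is the sampling and the strict
slide-level train/test separation, not the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_model import ClassTaxonomy, LabelMask, TaxonomyEntry
from .synthetic_annotators import CohortBundle, render_rgb_image

__all__ = [
    "FIVE_CLASSES",
    "five_class_taxonomy",
    "collapse_to_five",
    "ScoreMap",
    "MetricsReport",
    "LearningCurvePoint",
    "class_auc",
    "evaluate_prediction",
    "extract_patches",
    "shift_crop_augment",
    "PatchClassifier",
    "ColorGradientPatchClassifier",
    "learning_curve",
]

FIVE_CLASSES = ("tumor", "stroma", "inflammatory", "necrosis", "other")

_DEFAULT_FIVE_MAP = {
    "tumor": "tumor",
    "stroma": "stroma",
    "lymphocytic_infiltrate": "inflammatory",
    "plasma_cells": "inflammatory",
    "necrosis": "necrosis",
}


def five_class_taxonomy() -> ClassTaxonomy:
    e = TaxonomyEntry
    return ClassTaxonomy((
        e("tumor", "predominant", (255, 0, 0), 1),
        e("stroma", "predominant", (255, 165, 0), 2, is_default=True),
        e("inflammatory", "predominant", (0, 0, 255), 3),
        e("necrosis", "predominant", (255, 255, 0), 4),
        e("other", "non_predominant", (128, 128, 128), 5),
    ))


def collapse_to_five(mask: LabelMask, mapping: Mapping[str, str] | None = None) -> LabelMask:
    """Collapse an arbitrary taxonomy mask to the five-way evaluation scheme.

    Classes absent from the mapping fall into "other"; label 0 stays 0. The
    mapping is overridable for taxonomies with different class names.
    """
    mapping = dict(_DEFAULT_FIVE_MAP if mapping is None else mapping)
    five = five_class_taxonomy()
    out = np.zeros_like(mask.labels)
    for entry in mask.taxonomy.entries:
        target = mapping.get(entry.class_name, "other")
        out[mask.labels == entry.label_code] = five.code(target)
    return LabelMask(out, five)


@dataclass
class ScoreMap:
    """Per-class prediction score planes over one truth grid."""

    class_names: tuple[str, ...]
    scores: np.ndarray  # (n_classes, H, W) in [0, 1]

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 3 or s.shape[0] != len(self.class_names):
            raise ValueError("scores must be (n_classes, H, W) matching class_names")
        if s.min() < 0 or s.max() > 1:
            raise ValueError("scores must lie in [0, 1]")
        self.scores = s

    def plane(self, class_name: str) -> np.ndarray:
        return self.scores[self.class_names.index(class_name)]

    def argmax_mask(self, taxonomy: ClassTaxonomy) -> LabelMask:
        """Hard prediction: per-pixel argmax, encoded with taxonomy codes."""
        codes = np.array([taxonomy.code(c) for c in self.class_names])
        return LabelMask(codes[np.argmax(self.scores, axis=0)], taxonomy)

    @classmethod
    def from_mask(cls, mask: LabelMask, class_names: Sequence[str]) -> "ScoreMap":
        """Indicator scores of a hard mask — the perfect predictor of itself."""
        planes = np.stack([mask.channel(c).astype(float) for c in class_names])
        return cls(tuple(class_names), planes)


def _rank_auc(scores: np.ndarray, positives: np.ndarray) -> float:
    """One-vs-rest ROC AUC as the midrank statistic; NaN when degenerate."""
    n_pos = int(positives.sum())
    n_neg = positives.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    return float((ranks[positives].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def class_auc(scores: ScoreMap, truth: LabelMask, class_name: str) -> float:
    """Pixel one-vs-rest ROC AUC of one class. NaN when the class is absent
    from (or fills all of) the evaluated pixels — undefined, not 0."""
    if scores.scores.shape[1:] != truth.shape:
        raise ValueError("score and truth shapes differ")
    valid = truth.labels != 0
    y = truth.channel(class_name)[valid]
    s = scores.plane(class_name)[valid]
    return _rank_auc(s, y)


@dataclass
class MetricsReport:
    """Per-class and aggregate pixel metrics for one prediction/truth pair."""

    class_names: tuple[str, ...]
    auc: dict[str, float]
    dice: dict[str, float]
    accuracy: dict[str, float]
    micro_auc: float
    macro_auc: float
    confusion_percent: pd.DataFrame  # rows = truth, cols = predicted, sums to 100

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"auc": self.auc, "dice": self.dice, "accuracy": self.accuracy}
        ).loc[list(self.class_names)]


def evaluate_prediction(scores: ScoreMap, truth: LabelMask) -> MetricsReport:
    """Full metric panel: per-class AUC/Dice/accuracy, micro and macro AUC,
    and the confusion matrix as percentages of total evaluated pixels."""
    if scores.scores.shape[1:] != truth.shape:
        raise ValueError("score and truth shapes differ")
    valid = truth.labels != 0
    n_valid = int(valid.sum())
    pred = scores.argmax_mask(truth.taxonomy)

    auc: dict[str, float] = {}
    dice: dict[str, float] = {}
    acc: dict[str, float] = {}
    pooled_scores, pooled_truth = [], []
    for c in scores.class_names:
        y = truth.channel(c)[valid]
        p = pred.channel(c)[valid]
        s = scores.plane(c)[valid]
        auc[c] = _rank_auc(s, y)
        denom = int(y.sum()) + int(p.sum())
        dice[c] = 2.0 * int((y & p).sum()) / denom if denom else float("nan")
        acc[c] = float((y == p).mean()) if n_valid else float("nan")
        pooled_scores.append(s)
        pooled_truth.append(y)
    micro = _rank_auc(np.concatenate(pooled_scores), np.concatenate(pooled_truth))
    macro = float(np.nanmean(list(auc.values())))

    conf = np.zeros((len(scores.class_names), len(scores.class_names)))
    for i, ct in enumerate(scores.class_names):
        for j, cp in enumerate(scores.class_names):
            conf[i, j] = int((truth.channel(ct) & pred.channel(cp) & valid).sum())
    conf = conf / max(n_valid, 1) * 100.0
    confusion = pd.DataFrame(conf, index=list(scores.class_names),
                             columns=list(scores.class_names))
    return MetricsReport(tuple(scores.class_names), auc, dice, acc, micro, macro, confusion)


# ---------------------------------------------------------------------------
# Patch extraction and augmentation
# ---------------------------------------------------------------------------

def extract_patches(
    image: np.ndarray,
    mask: LabelMask,
    patch_px: int,
    purity: float = 0.9,
    stride: int | None = None,
    classes: Sequence[str] | None = None,
) -> list[tuple[np.ndarray, str]]:
    """Tile an RGB image into (patch, class_label) pairs.

    A tile qualifies when the modal class of its mask window covers at least
    ``purity`` of the window; the label is that modal class. ``classes``
    restricts the output to a subset (e.g. the three predominant classes).
    """
    if patch_px < 8:
        raise ValueError("patch_px must be >= 8")
    stride = stride or patch_px
    h, w = mask.shape
    keep = set(classes) if classes is not None else None
    out: list[tuple[np.ndarray, str]] = []
    for r in range(0, h - patch_px + 1, stride):
        for c in range(0, w - patch_px + 1, stride):
            window = mask.labels[r : r + patch_px, c : c + patch_px]
            counts = np.bincount(window.ravel())
            counts[0] = 0  # outside-ROI pixels can never be the label
            modal = int(counts.argmax())
            if counts[modal] < purity * window.size:
                continue
            name = mask.taxonomy.name_of(modal)
            if keep is not None and name not in keep:
                continue
            out.append((image[r : r + patch_px, c : c + patch_px], name))
    return out


def shift_crop_augment(patch: np.ndarray, max_shift_px: int, seed: int = 0) -> np.ndarray:
    """Shift-and-crop augmentation: reflect-pad, translate by a random integer
    offset of at most ``max_shift_px`` per axis, crop back to the original
    size. Deterministic given the seed; a zero shift budget is the identity."""
    if max_shift_px < 0:
        raise ValueError("max_shift_px must be >= 0")
    if max_shift_px == 0:
        return patch.copy()
    rng = np.random.default_rng(seed)
    dr, dc = rng.integers(-max_shift_px, max_shift_px + 1, size=2)
    pad = [(max_shift_px, max_shift_px), (max_shift_px, max_shift_px)]
    if patch.ndim == 3:
        pad.append((0, 0))
    padded = np.pad(patch, pad, mode="reflect")
    h, w = patch.shape[:2]
    r0 = max_shift_px + dr
    c0 = max_shift_px + dc
    return padded[r0 : r0 + h, c0 : c0 + w].copy()


# ---------------------------------------------------------------------------
# Learning-curve harness
# ---------------------------------------------------------------------------

class PatchClassifier(Protocol):
    """Minimal patch-classifier interface for the learning-curve harness."""

    def fit(self, patches: Sequence[np.ndarray], labels: Sequence[str]) -> None: ...

    def score(self, patches: Sequence[np.ndarray]) -> np.ndarray:
        """(n_patches, n_classes) scores, column order = self.classes_."""
        ...

    classes_: Sequence[str]


def _patch_features(patch: np.ndarray) -> np.ndarray:
    p = patch.astype(float)
    feats = [p.reshape(-1, p.shape[-1]).mean(0), p.reshape(-1, p.shape[-1]).std(0)]
    grad = np.abs(np.diff(p, axis=0)).mean(axis=(0, 1)) + np.abs(np.diff(p, axis=1)).mean(axis=(0, 1))
    feats.append(grad)
    return np.concatenate(feats)


class ColorGradientPatchClassifier:
    """Baseline shallow classifier: pooled per-channel color statistics and
    gradient magnitudes fed to an L2-regularized multinomial logistic model."""

    def __init__(self, C: float = 1.0, seed: int = 0):
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        self._model = make_pipeline(
            StandardScaler(), LogisticRegression(C=C, max_iter=2000, random_state=seed)
        )
        self.classes_: tuple[str, ...] = ()

    def fit(self, patches: Sequence[np.ndarray], labels: Sequence[str]) -> None:
        X = np.stack([_patch_features(p) for p in patches])
        self._model.fit(X, np.asarray(labels))
        self.classes_ = tuple(self._model[-1].classes_)

    def score(self, patches: Sequence[np.ndarray]) -> np.ndarray:
        X = np.stack([_patch_features(p) for p in patches])
        return self._model.predict_proba(X)


@dataclass(frozen=True)
class LearningCurvePoint:
    n_slides: int
    replicate: int
    macro_auc: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.macro_auc <= 1.0 or np.isnan(self.macro_auc)):
            raise ValueError("macro_auc must lie in [0, 1]")


def _macro_patch_auc(probs: np.ndarray, classes: Sequence[str], labels: np.ndarray) -> float:
    aucs = []
    for k, c in enumerate(classes):
        a = _rank_auc(probs[:, k], labels == c)
        if not np.isnan(a):
            aucs.append(a)
    return float(np.mean(aucs)) if aucs else float("nan")


def learning_curve(
    bundle: CohortBundle,
    classifier: PatchClassifier,
    slide_counts: Sequence[int],
    replicates: int,
    seed: int = 0,
    patch_px: int = 16,
    purity: float = 0.85,
    stride: int | None = None,
    classes: Sequence[str] = ("tumor", "stroma", "lymphocytic_infiltrate"),
    test_fraction: float = 1 / 3,
) -> list[LearningCurvePoint]:
    """Macro patch-classification AUC as a function of training-slide count.

    Core-set slides are split once (seeded) into a training pool and a fixed
    held-out test set — strict slide-level separation. For each
    (count, replicate) the harness samples that many pool slides without
    replacement, fits the classifier on their patches, and scores the test
    patches. Patches come from seeded synthetic RGB renderings of the truth
    masks, one stain/noise realization per slide.
    """
    rng = np.random.default_rng(seed)
    core = list(bundle.core_rois)
    if len(core) < 2:
        raise ValueError("need at least 2 core slides")
    order = rng.permutation(len(core))
    n_test = max(1, int(round(test_fraction * len(core))))
    test_idx = set(order[:n_test].tolist())
    pool = [core[i] for i in range(len(core)) if i not in test_idx]
    test = [core[i] for i in sorted(test_idx)]
    if max(slide_counts) > len(pool):
        raise ValueError(
            f"largest slide count {max(slide_counts)} exceeds the {len(pool)}-slide training pool"
        )

    def slide_patches(roi) -> list[tuple[np.ndarray, str]]:
        mask = bundle.truth_masks[roi.roi_id]
        img = render_rgb_image(mask, seed=int(rng.integers(2**31)))
        return extract_patches(img, mask, patch_px, purity, stride, classes)

    # render each slide once, up front, so train/test pixels never mix
    patches_by_slide = {roi.roi_id: slide_patches(roi) for roi in (*pool, *test)}
    test_patches = [p for roi in test for p in patches_by_slide[roi.roi_id]]
    test_X = [p for p, _ in test_patches]
    test_y = np.asarray([lab for _, lab in test_patches])

    points: list[LearningCurvePoint] = []
    for n in slide_counts:
        for rep in range(replicates):
            chosen = rng.choice(len(pool), size=n, replace=False)
            train = [p for i in chosen for p in patches_by_slide[pool[i].roi_id]]
            X = [p for p, _ in train]
            y = [lab for _, lab in train]
            if len(set(y)) < 2:
                points.append(LearningCurvePoint(n, rep, float("nan")))
                continue
            classifier.fit(X, y)
            probs = classifier.score(test_X)
            macro = _macro_patch_auc(probs, classifier.classes_, test_y)
            points.append(LearningCurvePoint(n, rep, macro))
    return points
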