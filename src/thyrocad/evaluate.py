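"""Leave-one-out cross-validation harness, confusion metrics and ROC/AUC.

Malignant is the positive class throughout; a probability >= threshold (tie
included) predicts positive.  The "dice coefficient" reported here is the
classification F1 on the positive class, ``2TP / (2TP + FP + FN)`` — it is
*not* a segmentation overlap.  The ROC curve pools the held-out probabilities
of all folds into a single curve (per-fold curves are meaningless at n=1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .io import Manifest, ValidationError
from .network import (
    NetworkConfig,
    TrainedModel,
    _predict_cached,
    _subset_cols,
    build_model,
    class_weights,
    precompute_l1_cols,
    train_model,
)
from .preprocess import ChannelPlan, NoduleSample, make_sample

__all__ = [
    "FoldResult",
    "CVReport",
    "confusion_counts",
    "metrics",
    "roc_auc",
    "report_from_probs",
    "loocv",
    "loocv_probs",
]


@dataclass
class FoldResult:
    patient_id: str
    probability: float
    label: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValidationError(f"probability {self.probability} outside [0, 1]")


@dataclass
class CVReport:
    """Pooled LOOCV outcome: per-fold probabilities, confusion, metrics, ROC."""

    folds: list[FoldResult]
    confusion: tuple[int, int, int, int]  # TP, FP, TN, FN
    metrics: dict[str, float | None]
    roc_points: np.ndarray  # ordered (FPR, TPR) pairs
    auc: float
    threshold: float = 0.5

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([f.probability for f in self.folds])

    @property
    def labels(self) -> np.ndarray:
        return np.array([f.label for f in self.folds])


def confusion_counts(probabilities: Sequence[float], labels: Sequence[int],
                     threshold: float = 0.5) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) with malignant positive and ``prob >= threshold`` positive."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValidationError("probabilities and labels length mismatch")
    pred = p >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    return tp, fp, tn, fn


def metrics(counts: tuple[int, int, int, int]) -> dict[str, float | None]:
    """Standard confusion-matrix metrics; undefined ratios are ``None``, not 0.

    ``recall`` is an alias of ``sensitivity``; ``dice`` is the positive-class F1.
    """
    tp, fp, tn, fn = counts
    n = tp + fp + tn + fn
    if n <= 0:
        raise ValidationError("empty confusion table")

    def _ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    out: dict[str, float | None] = {
        "accuracy": (tp + tn) / n,
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "precision": _ratio(tp, tp + fp),
        "dice": _ratio(2 * tp, 2 * tp + fp + fn),
    }
    out["recall"] = out["sensitivity"]
    return out


def roc_auc(probabilities: Sequence[float], labels: Sequence[int]) -> tuple[np.ndarray, float]:
    """ROC points swept over the unique scores, and trapezoidal AUC.

    The trapezoidal area equals the pairwise Mann–Whitney concordance with
    ties counted 1/2.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs both classes present")
    thresholds = np.concatenate(([np.inf], np.unique(p)[::-1], [-np.inf]))
    pts = []
    for t in thresholds:
        pred = p >= t
        tpr = np.sum(pred & (y == 1)) / n_pos
        fpr = np.sum(pred & (y == 0)) / n_neg
        pts.append((fpr, tpr))
    points = np.array(pts)
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    return points, auc


def report_from_probs(patient_ids: Sequence[str], probabilities: Sequence[float],
                      labels: Sequence[int], threshold: float = 0.5) -> CVReport:
    """Assemble a :class:`CVReport` from pooled per-case probabilities."""
    folds = [
        FoldResult(pid, float(p), int(l))
        for pid, p, l in zip(patient_ids, probabilities, labels)
    ]
    counts = confusion_counts(probabilities, labels, threshold)
    points, auc = roc_auc(probabilities, labels)
    return CVReport(folds=folds, confusion=counts, metrics=metrics(counts),
                    roc_points=points, auc=auc, threshold=threshold)


def loocv_probs(
    samples: Sequence[NoduleSample],
    config: NetworkConfig,
    seed: int = 0,
    progress: Callable[[int, int], None] | None = None,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Leave-one-out predicted probabilities for standardized samples.

    One fold per case; the held-out case influences neither training, the
    validation split, nor the class weights of its fold (standardization is
    per-sample, so no statistics leak).  Per-fold class weights are recomputed
    from the remaining labels and the per-fold seed is ``seed + fold_index``.
    """
    labels = np.array([s.label for s in samples], dtype=int)
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise ValidationError("LOOCV needs at least 2 cases per class")
    c1 = samples[0].t2_block.shape[-1]
    c2 = samples[0].adc_block.shape[-1]
    # first-layer im2col patches depend only on the inputs; share across folds
    cache = precompute_l1_cols(build_model(config, c1, c2), samples)
    ids, probs = [], []
    for k, held_out in enumerate(samples):
        keep = [i for i in range(len(samples)) if i != k]
        train_set = [samples[i] for i in keep]
        cw = class_weights([s.label for s in train_set], config.weight_convention)
        fold_config = replace(config, seed=seed + k)
        model = build_model(fold_config, c1, c2)
        model.fold_tag = f"fold{k:03d}:{held_out.patient_id}"
        train_model(model, train_set, fold_config, weights=cw,
                    l1_cols=_subset_cols(cache, keep))
        ids.append(held_out.patient_id)
        probs.append(float(_predict_cached(model.net, _subset_cols(cache, [k]), 1)[0]))
        if progress is not None:
            progress(k + 1, len(samples))
    return ids, np.asarray(probs), labels


def loocv(
    manifest: Manifest,
    config: NetworkConfig,
    seed: int = 0,
    channel_plan: ChannelPlan | None = None,
    samples: Sequence[NoduleSample] | None = None,
    progress: Callable[[int, int], None] | None = None,
) -> CVReport:
    """Full leave-one-out evaluation of the CNN over a manifest."""
    plan = channel_plan or ChannelPlan.default()
    if samples is None:
        samples = [make_sample(case, plan) for case in manifest]
    ids, probs, labels = loocv_probs(samples, config, seed=seed, progress=progress)
    return report_from_probs(ids, probs, labels)
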