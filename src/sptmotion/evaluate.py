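"""Model evaluation: confusion matrices, per-class metrics, importances.

Per-class metrics follow the usual definitions (precision = column
diagonal over column sum, recall = row diagonal over row sum, F1 their
harmonic mean).  The confidence score of a class is its row-normalized
diagonal — identical to recall — and the prediction error is its
complement.  One-vs-rest permutation importance measures, per motion
class, the increase in out-of-bag error of a bagged binary classifier when
one feature column is shuffled, normalized to [0, 1] within each class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .classify import fit_ensemble, oob_error
from .features import FEATURE_NAMES
from .simulate import MOTION_LABELS, InvalidParameterError, Trajectory3D

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "confusion",
    "accuracy",
    "class_metrics",
    "permutation_importance_ovr",
    "project_2d",
]

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray
    label_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        c = len(self.label_order)
        if self.counts.shape != (c, c):
            raise InvalidParameterError("confusion matrix shape does not match labels")
        if np.any(self.counts < 0):
            raise InvalidParameterError("negative confusion counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_percent(self) -> np.ndarray:
        """Row-normalized percentages (how each true class is predicted)."""
        rows = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / rows
        return np.where(rows > 0, pct, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.label_order), columns=list(self.label_order)
        )

    def cell(self, true_label: str, pred_label: str) -> int:
        i = self.label_order.index(true_label)
        j = self.label_order.index(pred_label)
        return int(self.counts[i, j])


@dataclass
class ClassMetrics:
    """Per-class precision/recall/F1/confidence and overall accuracy (%)."""

    per_class: pd.DataFrame  # rows = classes; columns below
    accuracy: float

    COLUMNS = ("precision", "recall", "f1", "confidence_score", "prediction_error")


def confusion(
    true_labels: Sequence[str],
    pred_labels: Sequence[str],
    label_order: Sequence[str] = MOTION_LABELS,
) -> ConfusionMatrix:
    """Build the confusion matrix in canonical label order."""
    true_arr = np.asarray(true_labels, dtype=object)
    pred_arr = np.asarray(pred_labels, dtype=object)
    if len(true_arr) != len(pred_arr):
        raise InvalidParameterError("label sequences differ in length")
    known = set(label_order)
    unknown = (set(true_arr) | set(pred_arr)) - known
    if unknown:
        raise InvalidParameterError(f"unknown label(s): {sorted(unknown)}")
    counts = _sk_confusion(true_arr, pred_arr, labels=list(label_order))
    return ConfusionMatrix(counts, tuple(label_order))


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall accuracy in percent: 100 * trace / total."""
    if cm.total == 0:
        raise InvalidParameterError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Per-class precision, recall, F1, confidence score and prediction error.

    The confidence score equals recall by construction (diagonal over row
    total); prediction error is 1 - confidence.  Empty rows/columns yield 0
    with a warning.
    """
    counts = cm.counts.astype(float)
    diag = np.diag(counts)
    col_sum = counts.sum(axis=0)
    row_sum = counts.sum(axis=1)
    if np.any(col_sum == 0) or np.any(row_sum == 0):
        warnings.warn("empty row/column in confusion matrix; metrics set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col_sum > 0, diag / col_sum, 0.0)
        recall = np.where(row_sum > 0, diag / row_sum, 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2.0 * precision * recall / np.where(pr > 0, pr, 1.0), 0.0)
    frame = pd.DataFrame(
        {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "confidence_score": recall,
            "prediction_error": 1.0 - recall,
        },
        index=list(cm.label_order),
    )
    return ClassMetrics(per_class=frame, accuracy=accuracy(cm))


def permutation_importance_ovr(
    train: pd.DataFrame,
    n_trees: int = 200,
    seed: int = 0,
    n_repeats: int = 5,
    max_depth: int | None = 10,
    min_leaf: int = 1,
    feature_names: Sequence[str] | None = None,
    label_order: Sequence[str] = MOTION_LABELS,
) -> pd.DataFrame:
    """One-vs-rest permutation importance heatmap (classes x features).

    For each motion class a bagged binary (class vs rest) ensemble is
    fitted; the importance of feature f is the mean increase in out-of-bag
    error over ``n_repeats`` seeded shuffles of f's column.  Negative
    changes are floored at zero and each class row is normalized so its
    maximum is 1 (rows with no positive change stay at 0).
    """
    if feature_names is None:
        feature_names = [c for c in FEATURE_NAMES if c in train.columns]
    rng = np.random.default_rng(seed)
    rows = {}
    y_full = train["center_label"].to_numpy(dtype=object).astype(str)
    for cls in label_order:
        n_cls = int((y_full == cls).sum())
        if n_cls < 2 * min_leaf or n_cls == 0:
            warnings.warn(f"class {cls!r} too small for one-vs-rest importance; skipped")
            continue
        binary = train.copy()
        binary["center_label"] = np.where(y_full == cls, cls, "rest")
        binary["source_class"] = binary["center_label"]
        model = fit_ensemble(
            binary,
            method="bagged_trees",
            n_trees=n_trees,
            max_depth=max_depth,
            min_leaf=min_leaf,
            seed=seed,
            feature_names=feature_names,
        )
        base = oob_error(model, binary)
        deltas = np.zeros(len(feature_names))
        for j, feat in enumerate(feature_names):
            acc = 0.0
            for _ in range(n_repeats):
                shuffled = binary.copy()
                col = shuffled[feat].to_numpy().copy()
                rng.shuffle(col)
                shuffled[feat] = col
                acc += oob_error(model, shuffled) - base
            deltas[j] = acc / n_repeats
        rows[cls] = np.maximum(deltas, 0.0)
    heat = pd.DataFrame(rows, index=list(feature_names)).T
    row_max = heat.max(axis=1)
    scale = row_max.where(row_max > 0, 1.0)
    return heat.div(scale, axis=0)


def project_2d(traj: Trajectory3D) -> Trajectory3D:
    """Drop the z coordinate (set to 0), preserving labels and times.

    Downstream feature extraction should then use ``dim=2`` so the
    dimension-dependent constants match the projection.
    """
    pos = traj.pos.copy()
    pos[:, 2] = 0.0
    return Trajectory3D(
        id=traj.id,
        t=traj.t.copy(),
        pos=pos,
        labels=traj.labels.copy(),
        motion_class=traj.motion_class,
    )
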