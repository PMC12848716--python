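"""Tree-ensemble classifiers over window feature tables.

Four methods are provided: a single CART tree, a random forest (bootstrap +
sqrt(p) feature subsampling per split), bagged trees (bootstrap, all
features considered at each split — the classic bagging ensemble), and
multiclass adaptive boosting of shallow trees.  Trees come from
scikit-learn; this module adds majority-vote aggregation with a fixed
canonical tie-break (DM < ND < AD < CD), grouped/stratified dataset
splitting, grouped k-fold cross-validation loss, and out-of-bag error
computed from the stored per-tree bootstrap membership.

A "feature table" throughout is a DataFrame with one row per window,
feature columns (any subset of the canonical 14), a ``center_label`` target
column, and ``source_id``/``source_class`` columns identifying the parent
trajectory (used to keep all windows of one trajectory on the same side of
any split).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES
from .simulate import MOTION_LABELS, InvalidParameterError

__all__ = [
    "METHODS",
    "SplitSpec",
    "EnsembleModel",
    "SchemaError",
    "split_dataset",
    "fit_ensemble",
    "predict",
    "kfold_cv_loss",
    "oob_error",
]

logger = logging.getLogger(__name__)

METHODS = ("single_tree", "random_forest", "boosted_trees", "bagged_trees")


class SchemaError(KeyError):
    """A required column is missing from a feature table."""


@dataclass
class SplitSpec:
    """Train/test split configuration.

    ``grouped=True`` (default) places all windows of one source trajectory
    on the same side, stratified by trajectory class — stricter than
    splitting windows, since step-1 windows overlap heavily.  ``grouped=
    False`` splits individual windows stratified by center label.
    """

    train_fraction: float = 0.9
    seed: int = 0
    stratified: bool = True
    grouped: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise InvalidParameterError("train_fraction must be in (0, 1)")


@dataclass
class EnsembleModel:
    """A fitted tree ensemble plus everything needed to apply and audit it."""

    method: str
    n_trees: int
    max_depth: int | None
    min_leaf: int
    feature_names: tuple[str, ...]
    classes: tuple[str, ...]
    estimator: object
    seed: int = 0
    oob_membership: list[np.ndarray] | None = field(default=None, repr=False)
    n_train: int = 0


def _feature_columns(tab: pd.DataFrame, feature_names: Sequence[str] | None) -> list[str]:
    if feature_names is None:
        feature_names = [c for c in FEATURE_NAMES if c in tab.columns]
    missing = [c for c in feature_names if c not in tab.columns]
    if missing:
        raise SchemaError(f"feature table is missing column(s): {missing}")
    return list(feature_names)


def _present_classes(labels: Sequence[str]) -> tuple[str, ...]:
    present = set(labels)
    canonical = [c for c in MOTION_LABELS if c in present]
    extra = sorted(present - set(MOTION_LABELS))  # e.g. "rest" in one-vs-rest
    return tuple(canonical + extra)


def split_dataset(
    tab: pd.DataFrame, spec: SplitSpec = SplitSpec()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test partition of a feature table.

    With grouping, whole trajectories are assigned to a side (stratified by
    their trajectory class); otherwise windows are split directly.
    """
    if len(tab) < 10:
        raise InvalidParameterError("need at least 10 rows to split")
    rng = np.random.default_rng(spec.seed)
    if spec.grouped:
        groups = tab.groupby("source_id", sort=True)["source_class"].first()
        train_ids: list[str] = []
        strata = groups.groupby(groups) if spec.stratified else [("all", groups)]
        for _, members in strata:
            ids = np.array(members.index)
            rng.shuffle(ids)
            n_train = int(round(spec.train_fraction * len(ids)))
            train_ids.extend(ids[:n_train])
        mask = tab["source_id"].isin(set(train_ids)).to_numpy()
    else:
        idx = np.arange(len(tab))
        labels = tab["center_label"].to_numpy()
        mask = np.zeros(len(tab), dtype=bool)
        if spec.stratified:
            for lab in np.unique(labels):
                sub = idx[labels == lab]
                rng.shuffle(sub)
                mask[sub[: int(round(spec.train_fraction * len(sub)))]] = True
        else:
            rng.shuffle(idx)
            mask[idx[: int(round(spec.train_fraction * len(idx)))]] = True
    train, test = tab[mask], tab[~mask]
    for side, name in ((train, "train"), (test, "test")):
        got = set(side["center_label"])
        absent = [c for c in MOTION_LABELS if c not in got]
        if absent:
            warnings.warn(f"class(es) {absent} absent from the {name} split")
    return train, test


def fit_ensemble(
    train: pd.DataFrame,
    method: str = "bagged_trees",
    n_trees: int = 100,
    max_depth: int | None = 10,
    min_leaf: int = 1,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> EnsembleModel:
    """Fit a tree ensemble on a training feature table.

    All trees are CART with Gini impurity and axis-aligned splits, stopped
    by ``max_depth`` and ``min_leaf``.  ``max_depth=None`` means unlimited
    (used by the tuned bagged model, which regularizes via leaf size).
    """
    if method not in METHODS:
        raise InvalidParameterError(f"unknown method {method!r}; choose from {METHODS}")
    if len(train) == 0:
        raise InvalidParameterError("empty training table")
    if n_trees < 1 or min_leaf < 1 or (max_depth is not None and max_depth < 1):
        raise InvalidParameterError("ensemble parameters must be positive")
    cols = _feature_columns(train, feature_names)
    X = train[cols].to_numpy(dtype=np.float32)
    y = train["center_label"].to_numpy(dtype=object).astype(str)

    tree_kw = dict(criterion="gini", max_depth=max_depth, min_samples_leaf=min_leaf)
    if method == "single_tree":
        est = DecisionTreeClassifier(random_state=seed, **tree_kw)
    elif method == "random_forest":
        est = BaggingClassifier(
            DecisionTreeClassifier(max_features="sqrt", **tree_kw),
            n_estimators=n_trees, random_state=seed, n_jobs=1,
        )
    elif method == "bagged_trees":
        est = BaggingClassifier(
            DecisionTreeClassifier(max_features=None, **tree_kw),
            n_estimators=n_trees, random_state=seed, n_jobs=1,
        )
    else:  # boosted_trees: adaptive boosting of shallow (depth-3) trees
        est = AdaBoostClassifier(
            DecisionTreeClassifier(
                max_depth=3 if max_depth is None else min(3, max_depth),
                min_samples_leaf=min_leaf, criterion="gini",
            ),
            n_estimators=n_trees, random_state=seed,
        )
    est.fit(X, y)

    oob = None
    if method in ("random_forest", "bagged_trees"):
        oob = [np.asarray(s) for s in est.estimators_samples_]
    return EnsembleModel(
        method=method,
        n_trees=n_trees if method != "single_tree" else 1,
        max_depth=max_depth,
        min_leaf=min_leaf,
        feature_names=tuple(cols),
        classes=_present_classes(y),
        estimator=est,
        seed=seed,
        oob_membership=oob,
        n_train=len(train),
    )


def _vote_fractions_from_trees(
    bag: BaggingClassifier, X: np.ndarray, classes: Sequence[str]
) -> np.ndarray:
    """Fraction of trees voting for each class, columns in canonical order.

    BaggingClassifier label-encodes y before fitting its base trees, so the
    inner trees predict indices into ``bag.classes_``; those indices are
    remapped to canonical-order columns here.
    """
    index = {c: j for j, c in enumerate(classes)}
    enc_to_col = np.array([index[c] for c in bag.classes_])
    counts = np.zeros((len(X), len(classes)))
    rows = np.arange(len(X))
    for tree in bag.estimators_:
        pred = tree.predict(X)
        if pred.dtype.kind in "iuf":
            cols = enc_to_col[pred.astype(int)]
        else:  # tree fitted on raw labels
            cols = np.fromiter((index[p] for p in pred), dtype=int, count=len(pred))
        counts[rows, cols] += 1.0
    return counts / len(bag.estimators_)


def _canonical_argmax(fractions: np.ndarray, classes: Sequence[str]) -> np.ndarray:
    # classes are already in canonical order; argmax takes the first
    # maximum, implementing the DM < ND < AD < CD tie-break
    idx = np.argmax(fractions, axis=1)
    return np.asarray([classes[i] for i in idx], dtype=object)


def predict(
    model: EnsembleModel, tab: pd.DataFrame
) -> tuple[np.ndarray, pd.DataFrame]:
    """Majority-vote prediction: (labels, per-class vote fractions).

    Vote fractions sum to one per row.  Ties break toward the earlier class
    in canonical label order.
    """
    cols = _feature_columns(tab, model.feature_names)
    X = tab[cols].to_numpy(dtype=np.float32)
    classes = model.classes
    est = model.estimator
    if model.method in ("random_forest", "bagged_trees"):
        frac = _vote_fractions_from_trees(est, X, classes)
    elif model.method == "single_tree":
        proba = est.predict_proba(X)
        order = [list(est.classes_).index(c) for c in classes]
        frac = proba[:, order]
    else:  # boosted: weighted vote expressed through SAMME probabilities
        proba = est.predict_proba(X)
        order = [list(est.classes_).index(c) for c in classes]
        frac = proba[:, order]
    frac = frac / frac.sum(axis=1, keepdims=True)
    labels = _canonical_argmax(frac, classes)
    return labels, pd.DataFrame(frac, columns=list(classes), index=tab.index)


def kfold_cv_loss(
    tab: pd.DataFrame,
    method: str = "bagged_trees",
    params: Mapping[str, object] | None = None,
    k: int = 5,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
    grouped: bool = True,
) -> float:
    """Mean misclassification rate over k cross-validation folds.

    Folds are grouped by source trajectory (windows of one trajectory never
    straddle a fold boundary) and stratified by center label.
    """
    if k < 2:
        raise InvalidParameterError("k must be >= 2")
    params = dict(params or {})
    y = tab["center_label"].to_numpy(dtype=object).astype(str)
    if grouped:
        groups = tab["source_id"].to_numpy()
    else:
        groups = np.arange(len(tab))
    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    losses = []
    for fold, (tr, te) in enumerate(splitter.split(np.zeros(len(tab)), y, groups)):
        train, test = tab.iloc[tr], tab.iloc[te]
        if set(test["center_label"]) - set(train["center_label"]):
            warnings.warn(f"fold {fold}: class missing from the training side")
        model = fit_ensemble(
            train, method=method, seed=seed + fold, feature_names=feature_names, **params
        )
        pred, _ = predict(model, test)
        losses.append(float(np.mean(pred != test["center_label"].to_numpy())))
    return float(np.mean(losses))


def oob_error(model: EnsembleModel, train: pd.DataFrame) -> float:
    """Out-of-bag misclassification rate of a bagging-type ensemble.

    Each training sample is voted on only by trees whose bootstrap sample
    excluded it; samples that every tree saw are skipped (their count is
    logged).  Requires the model to have been fitted on ``train``.
    """
    if model.oob_membership is None:
        raise InvalidParameterError(
            f"{model.method} does not support out-of-bag error"
        )
    cols = list(model.feature_names)
    X = train[cols].to_numpy(dtype=np.float32)
    y = train["center_label"].to_numpy(dtype=object).astype(str)
    n = len(X)
    classes = model.classes
    index = {c: j for j, c in enumerate(classes)}
    enc_to_col = np.array([index[c] for c in model.estimator.classes_])
    counts = np.zeros((n, len(classes)))
    for tree, sampled in zip(model.estimator.estimators_, model.oob_membership):
        in_bag = np.zeros(n, dtype=bool)
        in_bag[sampled] = True
        oob_idx = np.nonzero(~in_bag)[0]
        if oob_idx.size == 0:
            continue
        pred = tree.predict(X[oob_idx])
        if pred.dtype.kind in "iuf":
            cols_j = enc_to_col[pred.astype(int)]
        else:
            cols_j = np.fromiter((index[p] for p in pred), dtype=int, count=len(pred))
        counts[oob_idx, cols_j] += 1.0
    voted = counts.sum(axis=1) > 0
    n_skipped = int(n - voted.sum())
    if n_skipped:
        logger.info("%d samples were never out of bag; skipped", n_skipped)
    pred_lab = _canonical_argmax(counts[voted], classes)
    return float(np.mean(pred_lab != y[voted]))
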