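"""The reference classification study, end to end, at configurable scale.

Runs the complete ladder on self-generated data: simulate the labeled
trajectory set, segment into 29-frame windows, extract the 14 features,
train the 14-feature baseline bagged ensemble, select the consensus
reduced feature set (mRMR + NCA + ReliefF top-3 union), train and
cross-validate the reduced model, tune (learning cycles, minimum leaf
size) by Bayesian optimization and by random search, and compute
per-class metrics and one-vs-rest permutation importances.

The default scale (1000 trajectories, tuning objective on a stratified
window subsample, tuned refits on a capped subsample) keeps a full run in
the tens of minutes on one CPU; scale parameters are explicit so larger
runs are one argument away.  The train/test split and CV folds here are
window-level (the reference protocol splits the window dataset itself);
the stricter grouped-by-trajectory splitting remains the library default
elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import SplitSpec, fit_ensemble, kfold_cv_loss, predict, split_dataset
from .evaluate import class_metrics, confusion, permutation_importance_ovr
from .features import FEATURE_NAMES, compute_feature_table
from .hyperopt import SearchSpace, bayes_optimize, cv_objective, random_search
from .pipeline import stratified_window_subset
from .segment import segment_dataset
from .selection import rank_all
from .simulate import SimulationConfig, generate_dataset

__all__ = ["StudyScale", "run_reference_study"]


@dataclass
class StudyScale:
    """Problem sizes for one study run (defaults: the desk-scale study)."""

    n_trajectories: int = 1000
    n_frames: int = 100
    window: int = 29
    step: int = 1
    baseline_trees: int = 100
    baseline_depth: int = 10
    cv_folds: int = 5
    opt_budget: int = 30
    opt_initial: int = 10
    rs_budget: int = 25
    opt_subset_rows: int = 2000
    refit_rows: int = 30000
    importance_rows: int = 20000
    importance_trees: int = 100
    importance_repeats: int = 2


def _eval_model(model, test) -> dict:
    pred, _ = predict(model, test)
    cm = confusion(test["center_label"], pred)
    metrics = class_metrics(cm)
    row_pct = cm.row_percent()
    order = list(cm.label_order)
    return {
        "accuracy_percent": metrics.accuracy,
        "per_class": metrics.per_class,
        "confusion": cm,
        "nd_to_cd_percent": float(row_pct[order.index("ND"), order.index("CD")]),
    }


def run_reference_study(seed: int = 1, scale: StudyScale = StudyScale()) -> dict:
    """Run the full study and return every reported quantity.

    All randomness derives from ``seed`` (per-stage seeds are fixed offsets
    of it, kept below 2**31).
    """
    s = lambda off: (seed * 1000 + off) % (2**31 - 1)  # noqa: E731

    sim_cfg = SimulationConfig(
        n_trajectories=scale.n_trajectories, n_frames=scale.n_frames, seed=s(0)
    )
    trajs = generate_dataset(sim_cfg)
    stack = segment_dataset(trajs, window=scale.window, step=scale.step)
    table = compute_feature_table(stack, dim=3)

    train, test = split_dataset(
        table, SplitSpec(train_fraction=0.9, seed=s(1), grouped=False)
    )

    out: dict = {
        "n_trajectories": scale.n_trajectories,
        "n_windows": len(table),
        "n_train": len(train),
        "n_test": len(test),
    }

    # --- baseline: all 14 features --------------------------------------
    baseline = fit_ensemble(
        train, "bagged_trees", n_trees=scale.baseline_trees,
        max_depth=scale.baseline_depth, seed=s(2), feature_names=list(FEATURE_NAMES),
    )
    out["baseline"] = _eval_model(baseline, test)

    # --- consensus feature selection -------------------------------------
    rankings, consensus = rank_all(train, top_k=3, seed=s(3))
    feature_set = [f for f in FEATURE_NAMES if f in consensus]
    out["rankings"] = {r.method: r.order for r in rankings}
    out["consensus"] = feature_set

    # --- reduced model ----------------------------------------------------
    reduced = fit_ensemble(
        train, "bagged_trees", n_trees=scale.baseline_trees,
        max_depth=scale.baseline_depth, seed=s(2), feature_names=feature_set,
    )
    out["reduced"] = _eval_model(reduced, test)
    out["reduced"]["cv_loss"] = kfold_cv_loss(
        train, "bagged_trees",
        params={"n_trees": scale.baseline_trees, "max_depth": scale.baseline_depth},
        k=scale.cv_folds, seed=s(4), feature_names=feature_set, grouped=False,
    )

    # --- hyperparameter tuning -------------------------------------------
    space = SearchSpace()
    subset = stratified_window_subset(train, scale.opt_subset_rows, s(5))

    def objective(params):
        return cv_objective(
            subset, params, k=scale.cv_folds, seed=s(5), feature_names=feature_set
        )

    out["untuned_subset_cv_loss"] = objective((scale.baseline_trees, 1))

    refit_tab = stratified_window_subset(train, scale.refit_rows, s(6))

    def tuned_entry(result):
        model = fit_ensemble(
            refit_tab, "bagged_trees", n_trees=result.best_params[0], max_depth=None,
            min_leaf=result.best_params[1], seed=s(2), feature_names=feature_set,
        )
        entry = _eval_model(model, test)
        entry["best_params"] = result.best_params
        entry["best_cv_loss"] = result.best_loss
        entry["running_minimum"] = result.running_minimum()
        return entry

    bayes = bayes_optimize(
        objective, space, n_iter=scale.opt_budget, n_initial=scale.opt_initial, seed=s(7)
    )
    out["bayes"] = tuned_entry(bayes)
    rand = random_search(objective, space, n_samples=scale.rs_budget, seed=s(8))
    out["random"] = tuned_entry(rand)

    # --- one-vs-rest permutation importance ------------------------------
    imp_tab = stratified_window_subset(train, scale.importance_rows, s(9))
    out["importance"] = permutation_importance_ovr(
        imp_tab, n_trees=scale.importance_trees, seed=s(10),
        n_repeats=scale.importance_repeats, max_depth=scale.baseline_depth,
    )
    return out
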