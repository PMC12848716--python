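"""End-to-end orchestration: simulate -> segment -> features -> select ->
train -> (optimize) -> evaluate, as one reproducible, seeded run.

A single master seed fans out to per-stage seeds by fixed offsets, so a run
is exactly replayable from its manifest.  Each stage logs the object counts
it produced (trajectories, windows, rows) to make silent data loss visible.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import SplitSpec, fit_ensemble, kfold_cv_loss, predict, split_dataset
from .evaluate import class_metrics, confusion
from .features import FEATURE_NAMES, compute_feature_table
from .hyperopt import SearchSpace, bayes_optimize, cv_objective, random_search
from .io import write_features, write_report, write_trajectories
from .segment import segment_dataset
from .selection import rank_all
from .simulate import SimulationConfig, generate_dataset

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets from the master seed
_SEED_OFFSETS = {
    "simulate": 0,
    "split": 1,
    "select": 2,
    "train": 3,
    "optimize": 4,
    "cv": 5,
}


@dataclass
class PipelineConfig:
    """Everything a full run needs; defaults mirror the reference study."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    window: int = 29
    step: int = 1
    dim: int = 3
    train_fraction: float = 0.9
    grouped_split: bool = True
    select_features: bool = True
    top_k: int = 3
    baseline_trees: int = 100
    baseline_depth: int = 10
    cv_folds: int = 5
    run_cv: bool = True
    optimizer: str | None = None  # "bayes", "random" or None
    opt_budget: int = 30
    opt_initial: int = 10
    opt_subset_windows: int = 20000
    opt_refit_windows: int | None = None
    space: SearchSpace = field(default_factory=SearchSpace)
    master_seed: int = 1


def _stage_seed(config: PipelineConfig, stage: str) -> int:
    return (config.master_seed * 100 + _SEED_OFFSETS[stage]) % (2**31 - 1)


def stratified_window_subset(
    tab: pd.DataFrame, n_rows: int, seed: int
) -> pd.DataFrame:
    """Seeded class-stratified subsample of a feature table's rows."""
    if n_rows >= len(tab):
        return tab
    rng = np.random.default_rng(seed)
    y = tab["center_label"].to_numpy(dtype=object)
    keep = []
    for cls in pd.unique(y):
        idx = np.nonzero(y == cls)[0]
        take = max(int(round(n_rows * len(idx) / len(tab))), 1)
        keep.append(rng.choice(idx, size=min(take, len(idx)), replace=False))
    return tab.iloc[np.sort(np.concatenate(keep))]


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full classification pipeline; return the run manifest.

    The manifest records the configuration, per-stage seeds and timings,
    artifact paths, and the baseline / reduced / tuned model metrics.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "seeds": {s: _stage_seed(config, s) for s in _SEED_OFFSETS},
        "stages": {},
        "artifacts": {},
    }

    def _stage(name):
        t0 = time.time()

        def done(**counts):
            manifest["stages"][name] = {"seconds": round(time.time() - t0, 3), **counts}
            logger.info("stage %s: %s", name, counts)

        return done

    # --- simulate -------------------------------------------------------
    done = _stage("simulate")
    sim_cfg = config.simulation.replace(seed=_stage_seed(config, "simulate"))
    trajs = generate_dataset(sim_cfg)
    done(trajectories=len(trajs), frames=sum(t.n_frames for t in trajs))
    if out is not None:
        path = out / "trajectories.csv"
        write_trajectories(trajs, path)
        manifest["artifacts"]["trajectories"] = str(path)

    # --- segment + features --------------------------------------------
    done = _stage("features")
    stack = segment_dataset(trajs, window=config.window, step=config.step)
    table = compute_feature_table(stack, dim=config.dim)
    done(windows=len(stack), feature_rows=len(table))
    if out is not None:
        path = out / "features.csv"
        write_features(table, path)
        manifest["artifacts"]["features"] = str(path)

    # --- split ----------------------------------------------------------
    done = _stage("split")
    spec = SplitSpec(
        train_fraction=config.train_fraction,
        seed=_stage_seed(config, "split"),
        grouped=config.grouped_split,
    )
    train, test = split_dataset(table, spec)
    done(train_rows=len(train), test_rows=len(test))

    # --- feature selection ----------------------------------------------
    feature_set = list(FEATURE_NAMES)
    if config.select_features:
        done = _stage("select")
        rankings, consensus = rank_all(
            train, top_k=config.top_k, seed=_stage_seed(config, "select")
        )
        feature_set = [f for f in FEATURE_NAMES if f in consensus]
        manifest["selection"] = {
            "rankings": {r.method: r.order for r in rankings},
            "scores": {r.method: r.scores for r in rankings},
            "consensus": feature_set,
        }
        done(n_selected=len(feature_set))

    # --- baseline and reduced models -------------------------------------
    seed_train = _stage_seed(config, "train")
    results = {}
    model_specs = {"baseline_14feat": list(FEATURE_NAMES)}
    if config.select_features:
        model_specs["reduced_consensus"] = feature_set
    for name, feats in model_specs.items():
        done = _stage(f"train_{name}")
        model = fit_ensemble(
            train,
            method="bagged_trees",
            n_trees=config.baseline_trees,
            max_depth=config.baseline_depth,
            seed=seed_train,
            feature_names=feats,
        )
        pred, _ = predict(model, test)
        cm = confusion(test["center_label"], pred)
        metrics = class_metrics(cm)
        entry = {
            "features": feats,
            "test_accuracy_percent": metrics.accuracy,
            "confusion": cm.to_frame(),
            "per_class": metrics.per_class,
        }
        if config.run_cv:
            entry["cv_loss"] = kfold_cv_loss(
                train,
                method="bagged_trees",
                params={"n_trees": config.baseline_trees, "max_depth": config.baseline_depth},
                k=config.cv_folds,
                seed=_stage_seed(config, "cv"),
                feature_names=feats,
            )
        results[name] = entry
        done(accuracy=round(metrics.accuracy, 2))

    # --- hyperparameter optimization -------------------------------------
    if config.optimizer:
        done = _stage("optimize")
        seed_opt = _stage_seed(config, "optimize")
        subset = stratified_window_subset(train, config.opt_subset_windows, seed_opt)

        def objective(params):
            return cv_objective(
                subset, params, k=config.cv_folds, seed=seed_opt, feature_names=feature_set
            )

        if config.optimizer == "bayes":
            opt = bayes_optimize(
                objective, config.space, n_iter=config.opt_budget,
                n_initial=config.opt_initial, seed=seed_opt,
            )
        elif config.optimizer == "random":
            opt = random_search(objective, config.space, n_samples=config.opt_budget, seed=seed_opt)
        else:
            raise ValueError(f"unknown optimizer {config.optimizer!r}")
        refit_tab = train
        if config.opt_refit_windows is not None:
            refit_tab = stratified_window_subset(train, config.opt_refit_windows, seed_opt + 1)
        model = fit_ensemble(
            refit_tab,
            method="bagged_trees",
            n_trees=opt.best_params[0],
            max_depth=None,
            min_leaf=opt.best_params[1],
            seed=seed_train,
            feature_names=feature_set,
        )
        pred, _ = predict(model, test)
        cm = confusion(test["center_label"], pred)
        metrics = class_metrics(cm)
        results["tuned"] = {
            "features": feature_set,
            "optimizer": opt.method,
            "best_params": {"n_cycles": opt.best_params[0], "min_leaf": opt.best_params[1]},
            "best_cv_loss": opt.best_loss,
            "history": [[list(p), lo] for p, lo in opt.history],
            "test_accuracy_percent": metrics.accuracy,
            "confusion": cm.to_frame(),
            "per_class": metrics.per_class,
        }
        done(accuracy=round(metrics.accuracy, 2))

    manifest["results"] = results
    if out is not None:
        path = out / "report.json"
        write_report(manifest, path)
        manifest["artifacts"]["report"] = str(path)
    return manifest
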