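"""Hyperparameter tuning of the bagged ensemble.

Two tuners over the integer box (learning cycles in [150, 500], minimum
leaf size in [20, 50]) against a user-supplied objective — by default the
5-fold cross-validated misclassification loss of a bagged-tree ensemble:

* :func:`bayes_optimize`: sequential model-based optimization with a
  Gaussian-process surrogate (Matern 5/2) and expected-improvement
  acquisition evaluated exhaustively on the integer grid;
* :func:`random_search`: uniform sampling with replacement.

Both return the full evaluation history so convergence traces can be
plotted; the running minimum is monotone non-increasing by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from scipy.stats import norm as _norm

from .classify import kfold_cv_loss
from .simulate import InvalidParameterError

__all__ = [
    "SearchSpace",
    "HyperoptResult",
    "cv_objective",
    "bayes_optimize",
    "random_search",
]

logger = logging.getLogger(__name__)


@dataclass
class SearchSpace:
    """Integer search box for (learning cycles, minimum leaf size)."""

    n_cycles: tuple[int, int] = (150, 500)
    min_leaf: tuple[int, int] = (20, 50)

    def __post_init__(self) -> None:
        for name in ("n_cycles", "min_leaf"):
            lo, hi = getattr(self, name)
            if not (int(lo) == lo and int(hi) == hi and lo < hi):
                raise InvalidParameterError(f"{name} must be an integer interval lo < hi")

    def grid(self) -> np.ndarray:
        """All integer points of the box, shape (n_points, 2)."""
        c = np.arange(self.n_cycles[0], self.n_cycles[1] + 1)
        l = np.arange(self.min_leaf[0], self.min_leaf[1] + 1)
        return np.stack(np.meshgrid(c, l, indexing="ij"), axis=-1).reshape(-1, 2)

    def contains(self, params: tuple[int, int]) -> bool:
        c, l = params
        return (
            self.n_cycles[0] <= c <= self.n_cycles[1]
            and self.min_leaf[0] <= l <= self.min_leaf[1]
        )


@dataclass
class HyperoptResult:
    """Best point and full history of a hyperparameter search."""

    method: str
    best_params: tuple[int, int]
    best_loss: float
    history: list[tuple[tuple[int, int], float]] = field(repr=False)

    @property
    def n_evaluations(self) -> int:
        return len(self.history)

    def running_minimum(self) -> np.ndarray:
        """Best loss seen after each evaluation (failures carried forward)."""
        vals = np.array([lo for _, lo in self.history], dtype=float)
        vals = np.where(np.isfinite(vals), vals, np.inf)
        return np.minimum.accumulate(vals)


def cv_objective(
    train: pd.DataFrame,
    params: tuple[int, int],
    k: int = 5,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
    max_depth: int | None = None,
) -> float:
    """5-fold cross-validated loss of a bagged ensemble at (cycles, leaf)."""
    n_cycles, min_leaf = int(params[0]), int(params[1])
    return kfold_cv_loss(
        train,
        method="bagged_trees",
        params={"n_trees": n_cycles, "min_leaf": min_leaf, "max_depth": max_depth},
        k=k,
        seed=seed,
        feature_names=feature_names,
    )


def _evaluate(objective: Callable, params: tuple[int, int]) -> float:
    try:
        return float(objective(params))
    except Exception as exc:  # noqa: BLE001 - a failed point must not kill the search
        logger.warning("objective failed at %s: %s", params, exc)
        return float("nan")


def _finish(method: str, history: list[tuple[tuple[int, int], float]]) -> HyperoptResult:
    finite = [(p, lo) for p, lo in history if np.isfinite(lo)]
    if not finite:
        raise InvalidParameterError("all objective evaluations failed")
    best_params, best_loss = min(finite, key=lambda h: h[1])
    return HyperoptResult(method, tuple(int(v) for v in best_params), best_loss, history)


def random_search(
    objective: Callable[[tuple[int, int]], float],
    space: SearchSpace = SearchSpace(),
    n_samples: int = 100,
    seed: int = 0,
) -> HyperoptResult:
    """Uniform random search (sampling with replacement) over the box."""
    if n_samples < 1:
        raise InvalidParameterError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    history = []
    for _ in range(n_samples):
        params = (
            int(rng.integers(space.n_cycles[0], space.n_cycles[1] + 1)),
            int(rng.integers(space.min_leaf[0], space.min_leaf[1] + 1)),
        )
        history.append((params, _evaluate(objective, params)))
    return _finish("random", history)


def bayes_optimize(
    objective: Callable[[tuple[int, int]], float],
    space: SearchSpace = SearchSpace(),
    n_iter: int = 60,
    n_initial: int = 10,
    seed: int = 0,
) -> HyperoptResult:
    """Gaussian-process Bayesian optimization with expected improvement.

    ``n_initial`` seeded quasi-random points initialize the surrogate; each
    subsequent round fits a Matern-5/2 GP to the observed losses (inputs
    scaled to the unit square) and evaluates the point of maximal expected
    improvement over the full integer grid, excluding already-visited
    points.  Failed evaluations are recorded as NaN and ignored by the
    surrogate.
    """
    if n_iter < n_initial:
        raise InvalidParameterError("n_iter must be at least the initial design size")
    rng = np.random.default_rng(seed)
    grid = space.grid()
    lo = grid.min(axis=0).astype(float)
    span = grid.max(axis=0) - lo
    grid_unit = (grid - lo) / span

    history: list[tuple[tuple[int, int], float]] = []
    visited: set[tuple[int, int]] = set()

    def record(params: tuple[int, int]) -> None:
        history.append((params, _evaluate(objective, params)))
        visited.add(params)

    # initial design: stratified (latin-hypercube style) jittered grid
    init_c = np.linspace(0, 1, n_initial, endpoint=False) + rng.uniform(0, 1 / n_initial, n_initial)
    init_l = rng.permutation(
        np.linspace(0, 1, n_initial, endpoint=False) + rng.uniform(0, 1 / n_initial, n_initial)
    )
    for u, v in zip(init_c, init_l):
        params = (
            int(round(space.n_cycles[0] + u * (space.n_cycles[1] - space.n_cycles[0]))),
            int(round(space.min_leaf[0] + v * (space.min_leaf[1] - space.min_leaf[0]))),
        )
        record(params)

    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=[0.3, 0.3], length_scale_bounds=(1e-2, 1e2), nu=2.5
    ) + WhiteKernel(1e-6, (1e-10, 1e-1))
    while len(history) < n_iter:
        pts = np.array([p for p, lo_ in history if np.isfinite(lo_)], dtype=float)
        vals = np.array([lo_ for _, lo_ in history if np.isfinite(lo_)])
        if len(pts) < 2:
            cand = grid[rng.integers(len(grid))]
            record((int(cand[0]), int(cand[1])))
            continue
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, random_state=seed, n_restarts_optimizer=1
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit((pts - lo) / span, vals)
            mu, sd = gp.predict(grid_unit, return_std=True)
        best = vals.min()
        sd = np.maximum(sd, 1e-12)
        z = (best - mu) / sd
        ei = (best - mu) * _norm.cdf(z) + sd * _norm.pdf(z)
        mask = np.array([(int(c), int(l)) in visited for c, l in grid])
        ei[mask] = -np.inf
        cand = grid[int(np.argmax(ei))]
        record((int(cand[0]), int(cand[1])))
    return _finish("bayes", history)
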