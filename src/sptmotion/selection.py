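"""Filter-style feature ranking and the consensus reduced feature set.

Three independent rankers are applied to the labeled feature table:

* mRMR (minimum-redundancy maximum-relevance), greedy forward selection on
  mutual information with the MID (difference) criterion, MI estimated on
  equal-frequency discretized features;
* ReliefF, the multiclass neighbor-margin weighting of Kononenko, with
  prior-weighted miss contributions and min-max feature normalization;
* NCA (neighborhood component analysis) with a diagonal weighting vector,
  optimized by gradient ascent on the leave-one-out stochastic
  nearest-neighbor objective with L2 regularization.

The consensus set is the plain union of each method's top-k features
(k = 3 by default), mirroring how a reduced 6-feature model is built from
three rankers that agree on most but not all of their leaders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score
from sklearn.neighbors import NearestNeighbors

from .features import FEATURE_NAMES
from .simulate import InvalidParameterError

__all__ = [
    "RankedFeatures",
    "mrmr_rank",
    "relieff_rank",
    "nca_rank",
    "consensus_select",
    "rank_all",
]

logger = logging.getLogger(__name__)


@dataclass
class RankedFeatures:
    """One ranker's output: features ordered best-first with their scores."""

    method: str
    order: list[str]
    scores: list[float]

    def top(self, k: int) -> list[str]:
        return self.order[:k]


def _feature_matrix(tab: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    names = [c for c in FEATURE_NAMES if c in tab.columns]
    if len(names) < 1:
        raise InvalidParameterError("feature table has no known feature columns")
    X = tab[names].to_numpy(dtype=float)
    y = tab["center_label"].to_numpy(dtype=object).astype(str)
    return X, y, names


def _discretize(col: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning; constant columns collapse to one bin."""
    qs = np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(np.unique(qs), col, side="right")


def mrmr_rank(tab: pd.DataFrame, n_bins: int = 10) -> RankedFeatures:
    """Greedy mRMR ordering with the MID (relevance - mean redundancy) score.

    Mutual information is estimated from contingency tables of
    equal-frequency discretized features.  A constant feature has zero
    relevance and is ranked last.
    """
    X, y, names = _feature_matrix(tab)
    p = len(names)
    binned = np.column_stack([_discretize(X[:, j], n_bins) for j in range(p)])
    relevance = np.array([mutual_info_score(binned[:, j], y) for j in range(p)])
    constant = X.std(axis=0) == 0  # zero relevance by construction: rank last
    if p == 1:
        return RankedFeatures("mRMR", [names[0]], [float(relevance[0])])
    mi_ff = np.zeros((p, p))
    order: list[int] = []
    scores: list[float] = []
    remaining = [j for j in range(p) if not constant[j]]
    tail = [j for j in range(p) if constant[j]]
    if not remaining:
        return RankedFeatures("mRMR", [names[j] for j in tail], [0.0] * len(tail))
    first = int(np.argmax(relevance))
    order.append(first)
    scores.append(float(relevance[first]))
    remaining.remove(first)
    computed = np.zeros((p, p), dtype=bool)
    while remaining:
        last = order[-1]
        for j in remaining:
            if not computed[last, j]:
                mi_ff[last, j] = mi_ff[j, last] = mutual_info_score(
                    binned[:, last], binned[:, j]
                )
                computed[last, j] = computed[j, last] = True
        best_j, best_s = None, -np.inf
        for j in remaining:
            s = relevance[j] - mi_ff[np.array(order), j].mean()
            if s > best_s:
                best_j, best_s = j, s
        order.append(best_j)
        scores.append(float(best_s))
        remaining.remove(best_j)
    order.extend(tail)
    scores.extend([0.0] * len(tail))
    return RankedFeatures("mRMR", [names[j] for j in order], scores)


def relieff_rank(
    tab: pd.DataFrame,
    k_neighbors: int = 10,
    n_samples: int | None = None,
    seed: int = 0,
) -> RankedFeatures:
    """Multiclass ReliefF feature weights.

    For each sampled instance, the weight of feature f decreases by its mean
    absolute difference to the k nearest same-class hits and increases by
    the class-prior-weighted mean difference to the k nearest misses of each
    other class.  Features are min-max normalized first so all differences
    live on [0, 1].
    """
    X, y, names = _feature_matrix(tab)
    n, p = X.shape
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    Xn = (X - lo) / span
    classes, counts = np.unique(y, return_counts=True)
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}
    for c, cnt in zip(classes, counts):
        if cnt < k_neighbors + 1:
            raise InvalidParameterError(
                f"class {c!r} has {cnt} members; needs at least {k_neighbors + 1}"
            )
    nn_by_class = {
        c: NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xn[y == c]) for c in classes
    }
    idx_by_class = {c: np.nonzero(y == c)[0] for c in classes}
    rng = np.random.default_rng(seed)
    if n_samples is None or n_samples >= n:
        sample_idx = np.arange(n)
    else:
        sample_idx = rng.choice(n, size=n_samples, replace=False)
    W = np.zeros(p)
    m = len(sample_idx)
    # process per class so hit queries can drop the instance itself
    for c in classes:
        sel = sample_idx[y[sample_idx] == c]
        if sel.size == 0:
            continue
        Q = Xn[sel]
        _, hit_idx = nn_by_class[c].kneighbors(Q)  # includes self at distance 0
        hits = Xn[idx_by_class[c][hit_idx[:, 1:]]]  # (m_c, k, p)
        W -= np.abs(hits - Q[:, None, :]).mean(axis=1).sum(axis=0) / m
        for other in classes:
            if other == c:
                continue
            _, miss_idx = nn_by_class[other].kneighbors(Q, n_neighbors=k_neighbors)
            misses = Xn[idx_by_class[other][miss_idx]]
            wgt = priors[other] / (1.0 - priors[c])
            W += wgt * np.abs(misses - Q[:, None, :]).mean(axis=1).sum(axis=0) / m
    order = np.argsort(-W, kind="stable")
    return RankedFeatures("ReliefF", [names[j] for j in order], [float(W[j]) for j in order])


def _nca_objective_grad(
    w: np.ndarray, diff2: np.ndarray, same: np.ndarray, lam: float
) -> tuple[float, np.ndarray]:
    """Leave-one-out NCA objective and gradient for diagonal weights.

    d_w(i,j) = sum_f w_f^2 (x_if - x_jf)^2; p_ij = softmax(-d_w) over j != i;
    objective = mean_i sum_{j in class(i)} p_ij  -  lam * sum w^2.
    ``diff2`` is the precomputed (p, n, n) stack of squared per-feature
    differences.
    """
    p, n, _ = diff2.shape
    w2 = w * w
    d2 = np.tensordot(w2, diff2, axes=(0, 0))
    np.fill_diagonal(d2, np.inf)
    d2 -= d2.min(axis=1, keepdims=True)  # softmax stabilization
    K = np.exp(-d2)
    P = K / K.sum(axis=1, keepdims=True)
    p_i = (P * same).sum(axis=1)
    obj = float(p_i.mean()) - lam * float(w2.sum())
    Psame = P * same
    grad = np.empty(p)
    for f in range(p):
        e_all = np.einsum("ij,ij->i", P, diff2[f])
        e_same = np.einsum("ij,ij->i", Psame, diff2[f])
        # d obj / d w_f = 2 w_f * mean_i [ p_i * E_P[diff2] - E_{P,same}[diff2] ]
        grad[f] = 2.0 * w[f] * float(np.mean(p_i * e_all - e_same)) - 2.0 * lam * w[f]
    return obj, grad


def nca_rank(
    tab: pd.DataFrame,
    regularization: float | None = None,
    max_iter: int = 120,
    learning_rate: float = 0.05,
    seed: int = 0,
    max_rows: int = 2000,
) -> RankedFeatures:
    """Diagonal-weight NCA ranking by |weight| after gradient ascent.

    Features are z-scored before optimization; the default L2 penalty is
    1/n_rows.  Ascent uses Adam-style adaptive steps (robust to the widely
    varying gradient scales of the softmax objective).  Rows are subsampled
    (stratified, seeded) above ``max_rows`` since the objective is quadratic
    in the number of rows.
    """
    X, y, names = _feature_matrix(tab)
    n = len(X)
    rng = np.random.default_rng(seed)
    if n > max_rows:
        keep: list[np.ndarray] = []
        for c in np.unique(y):
            idx = np.nonzero(y == c)[0]
            take = max(int(round(max_rows * len(idx) / n)), 1)
            keep.append(rng.choice(idx, size=min(take, len(idx)), replace=False))
        sel = np.sort(np.concatenate(keep))
        X, y = X[sel], y[sel]
        n = len(X)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    X = (X - mu) / np.where(sd > 0, sd, 1.0)
    lam = 1.0 / n if regularization is None else regularization
    same = (y[:, None] == y[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)
    p = X.shape[1]
    diff2 = np.empty((p, n, n), dtype=np.float32)
    for f in range(p):
        d = X[:, f][:, None] - X[:, f][None, :]
        diff2[f] = (d * d).astype(np.float32)
    w = np.ones(p)
    best_w, best_obj = w.copy(), -np.inf
    m = np.zeros(p)
    v = np.zeros(p)
    b1, b2, eps = 0.9, 0.999, 1e-8
    for it in range(max_iter):
        obj, grad = _nca_objective_grad(w, diff2, same, lam)
        if obj > best_obj:
            best_obj, best_w = obj, w.copy()
        m = b1 * m + (1 - b1) * grad
        v = b2 * v + (1 - b2) * grad * grad
        mhat = m / (1 - b1 ** (it + 1))
        vhat = v / (1 - b2 ** (it + 1))
        w = w + learning_rate * mhat / (np.sqrt(vhat) + eps)
    obj, _ = _nca_objective_grad(w, diff2, same, lam)
    if obj > best_obj:
        best_obj, best_w = obj, w.copy()
    weights = np.abs(best_w)
    order = np.argsort(-weights, kind="stable")
    return RankedFeatures("NCA", [names[j] for j in order], [float(weights[j]) for j in order])


def consensus_select(rankings: list[RankedFeatures], top_k: int = 3) -> set[str]:
    """Union of each ranker's top-k features."""
    if not rankings:
        raise InvalidParameterError("need at least one ranking")
    out: set[str] = set()
    for r in rankings:
        out.update(r.top(top_k))
    return out


def rank_all(
    tab: pd.DataFrame,
    top_k: int = 3,
    seed: int = 0,
    relieff_samples: int | None = 4000,
    nca_rows: int = 2000,
) -> tuple[list[RankedFeatures], set[str]]:
    """Run all three rankers and form the consensus set.

    ReliefF samples ``relieff_samples`` instances and NCA optimizes on a
    stratified ``nca_rows``-row subsample when the table is larger; both
    draws are seeded, so rankings are reproducible.
    """
    rankings = [
        mrmr_rank(tab),
        nca_rank(tab, seed=seed, max_rows=nca_rows),
        relieff_rank(tab, n_samples=relieff_samples, seed=seed),
    ]
    return rankings, consensus_select(rankings, top_k)
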