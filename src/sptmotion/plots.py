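"""Optional matplotlib renderings of evaluation artifacts."""

from __future__ import annotations

import numpy as np

from .evaluate import ConfusionMatrix

__all__ = ["plot_confusion", "plot_importance_heatmap", "plot_convergence"]


def plot_confusion(cm: ConfusionMatrix, ax=None, row_percent: bool = True):
    """Render a confusion matrix; row-normalized percentages by default."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    data = cm.row_percent() if row_percent else cm.counts
    im = ax.imshow(data, cmap="Blues")
    labels = list(cm.label_order)
    ax.set_xticks(range(len(labels)), labels)
    ax.set_yticks(range(len(labels)), labels)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fmt = "{:.0f}%" if row_percent else "{:d}"
    for i in range(len(labels)):
        for j in range(len(labels)):
            ax.text(j, i, fmt.format(data[i, j]), ha="center", va="center", fontsize=8)
    ax.figure.colorbar(im, ax=ax, fraction=0.046)
    return ax


def plot_importance_heatmap(heat, ax=None):
    """Render the class x feature permutation-importance map."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    im = ax.imshow(heat.to_numpy(), cmap="viridis", vmin=0, vmax=1, aspect="auto")
    ax.set_yticks(range(len(heat.index)), list(heat.index))
    ax.set_xticks(range(len(heat.columns)), list(heat.columns), rotation=60, ha="right")
    ax.figure.colorbar(im, ax=ax, fraction=0.02)
    return ax


def plot_convergence(running_minimum, ax=None):
    """Render the running-minimum CV-loss trace of a hyperparameter search."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    rm = np.asarray(running_minimum, dtype=float)
    ax.step(np.arange(1, len(rm) + 1), rm, where="post")
    ax.set_xlabel("evaluation")
    ax.set_ylabel("best CV loss so far")
    return ax
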