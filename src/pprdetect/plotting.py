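"""Boxplots and ROC curves for experiment results."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["boxplot_metrics", "roc_plot"]


def _axes(ax):
    if ax is not None:
        return ax.figure, ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt.subplots()


def boxplot_metrics(metrics: pd.DataFrame, family: str, param: int, ax=None):
    """Boxplot of ACC/SENS/SPEC across repetitions, split by test set."""
    fig, ax = _axes(ax)
    sub = metrics[(metrics["family"] == family) & (metrics["param"] == param)]
    data, labels = [], []
    for test_set, g in sub.groupby("test_set"):
        for metric in ("acc", "sens", "spec"):
            data.append(g[metric].dropna().to_numpy())
            labels.append(f"{metric.upper()}\n{test_set}")
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("proportion")
    ax.set_title(f"{family} (param={param})")
    return ax


def roc_plot(roc_points: np.ndarray, label: str = "", ax=None):
    """Plot one ROC curve (FPR, TPR) with the chance diagonal."""
    fig, ax = _axes(ax)
    pts = np.asarray(roc_points)
    ax.plot(pts[:, 0], pts[:, 1], label=label or None)
    ax.plot([0, 1], [0, 1], linestyle=":", color="grey", linewidth=1)
    ax.set_xlabel("false-positive rate")
    ax.set_ylabel("true-positive rate")
    if label:
        ax.legend()
    return ax


def save_figure(ax, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ax.figure.savefig(path, bbox_inches="tight")
    return path
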