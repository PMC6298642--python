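"""Figure rendering: sharing-matrix heatmaps, scheme bars, parameter curves."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .leakage_audit import SharingMatrix, imbalance_class

__all__ = [
    "plot_sharing_matrix",
    "plot_scheme_comparison",
    "plot_train_test_curves",
]


def plot_sharing_matrix(matrix: SharingMatrix, out_path: str, fold_threshold: float = 2.0):
    """Heatmap of group counts by (n_pos, n_neg).

    Cell edges are coloured by imbalance class: blue for >=2-fold positive
    skew, red for negative skew, grey for balanced groups — the skewed
    cells are the ones a promoter-memorizing rule predicts well.
    """
    if not matrix.cells:
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.set_title("empty sharing matrix")
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
        return
    max_pos = max(a for a, _ in matrix.cells)
    max_neg = max(b for _, b in matrix.cells)
    grid = np.zeros((max_neg + 1, max_pos + 1))
    for (a, b), c in matrix.cells.items():
        grid[b, a] = c
    fig, ax = plt.subplots(figsize=(6, 5))
    logged = np.full_like(grid, np.nan, dtype=float)
    np.log10(grid, out=logged, where=grid > 0)
    im = ax.imshow(
        np.ma.masked_invalid(logged), origin="lower", cmap="viridis",
        interpolation="nearest",
    )
    for (a, b), c in matrix.cells.items():
        cls = imbalance_class(a, b, fold_threshold)
        edge = {"pos_skew": "tab:blue", "neg_skew": "tab:red", "balanced": "0.6"}[cls]
        ax.add_patch(
            plt.Rectangle((a - 0.5, b - 0.5), 1, 1, fill=False, edgecolor=edge, lw=1.2)
        )
    ax.set_xlabel("positive EP pairs per promoter")
    ax.set_ylabel("negative EP pairs per promoter")
    unit = "EP pairs" if matrix.weighting == "pair" else "promoters"
    ax.set_title(f"promoter sharing profile ({unit})")
    fig.colorbar(im, ax=ax, label=f"log10 {unit}")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def plot_scheme_comparison(summary: pd.DataFrame, out_path: str, metric: str = "f1"):
    """Bar chart of a fold-averaged test metric per scheme and feature set."""
    col = f"test_{metric}"
    piv = summary.pivot_table(index="blocks", columns="scheme", values=col)
    fig, ax = plt.subplots(figsize=(6, 4))
    piv.plot.bar(ax=ax, rot=0)
    ax.set_ylabel(f"mean test {metric.upper()}")
    ax.set_ylim(0, 1)
    ax.set_title("test performance by CV scheme and feature blocks")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def plot_train_test_curves(
    table: pd.DataFrame,
    out_path: str,
    x: str,
    metric: str = "f1",
    group_by: Optional[str] = "scheme",
):
    """Train (dashed) vs test (solid) metric as a hyperparameter varies."""
    fig, ax = plt.subplots(figsize=(6, 4))
    groups = table.groupby(group_by) if group_by else [("all", table)]
    for name, sub in groups:
        agg = sub.groupby(x)[[f"train_{metric}", f"test_{metric}"]].mean()
        ax.plot(agg.index, agg[f"train_{metric}"], "--", label=f"{name} train")
        ax.plot(agg.index, agg[f"test_{metric}"], "-", label=f"{name} test")
    if table[x].min() > 0 and table[x].max() / max(table[x].min(), 1e-12) > 50:
        ax.set_xscale("log")
    ax.set_xlabel(x)
    ax.set_ylabel(metric.upper())
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
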