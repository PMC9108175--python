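"""Figure export: confusion heat maps and misclassification-direction bars."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .agreement import CLASS_NAMES  # noqa: E402

__all__ = ["plot_confusion_heatmaps", "plot_direction_bars"]


def plot_confusion_heatmaps(confusions: dict[str, "pd.DataFrame"],
                            path: str | Path) -> Path:
    """One row-normalized heat map per cut-point set (rows = measured)."""
    n = len(confusions)
    ncol = min(n, 4)
    nrow = -(-n // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 3.0 * nrow),
                             squeeze=False)
    for ax in axes.flat[n:]:
        ax.axis("off")
    for ax, (name, df) in zip(axes.flat, confusions.items()):
        counts = np.asarray(df, dtype=float)
        rowsum = counts.sum(axis=1, keepdims=True)
        pct = np.divide(counts, rowsum, out=np.zeros_like(counts), where=rowsum > 0)
        ax.imshow(pct, cmap="Blues", vmin=0, vmax=1)
        for i in range(4):
            for j in range(4):
                ax.text(j, i, f"{100 * pct[i, j]:.0f}", ha="center", va="center",
                        fontsize=8, color="black" if pct[i, j] < 0.6 else "white")
        ax.set_xticks(range(4), CLASS_NAMES, fontsize=7)
        ax.set_yticks(range(4), CLASS_NAMES, fontsize=7)
        ax.set_title(name, fontsize=9)
        ax.set_xlabel("predicted", fontsize=7)
        ax.set_ylabel("measured", fontsize=7)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_direction_bars(direction: pd.DataFrame, path: str | Path) -> Path:
    """Stacked over/correct/under bars per activity, one panel per set.

    ``direction`` is the long table with columns cutpoint, activity,
    over, correct, under.
    """
    sets = list(direction["cutpoint"].unique())
    ncol = min(len(sets), 4)
    nrow = -(-len(sets) // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.6 * ncol, 2.8 * nrow),
                             squeeze=False, sharey=True)
    for ax in axes.flat[len(sets):]:
        ax.axis("off")
    for ax, name in zip(axes.flat, sets):
        sub = direction[direction["cutpoint"] == name]
        x = np.arange(len(sub))
        ax.bar(x, sub["under"], color="#4575b4", label="under")
        ax.bar(x, sub["correct"], bottom=sub["under"], color="#cccccc", label="correct")
        ax.bar(x, sub["over"], bottom=sub["under"] + sub["correct"],
               color="#d73027", label="over")
        ax.set_xticks(x, sub["activity"], fontsize=6, rotation=90)
        ax.set_title(name, fontsize=9)
        ax.set_ylim(0, 1)
    axes.flat[0].legend(fontsize=6)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
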