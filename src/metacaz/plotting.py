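"""Minimal vector-graphic exports: fold-change heatmap and PCA scatter."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .profiles import FoldChangeResult, PCAResult


def plot_fold_change_heatmap(
    result: FoldChangeResult, path: str | Path, floor: float = -10.0
) -> None:
    """log2 fold-change heatmap (rows x enzymes); -inf cells drawn at ``floor``."""
    data = result.display(floor=floor)
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.22 * data.shape[1]), max(2.5, 0.4 * data.shape[0]))
    )
    vmax = float(abs(data.to_numpy()).max()) or 1.0
    im = ax.imshow(data.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_yticks(range(data.shape[0]), labels=[str(i) for i in data.index])
    ax.set_xticks(range(data.shape[1]), labels=[str(c) for c in data.columns],
                  rotation=90, fontsize=5)
    fig.colorbar(im, ax=ax, label="log2 fold change vs mean")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_pca_scores(
    result: PCAResult, path: str | Path, groups: pd.Series | None = None
) -> None:
    """Scatter of the first two PCA score columns, optionally coloured by group."""
    scores = result.scores.iloc[:, :2]
    fig, ax = plt.subplots(figsize=(5, 4))
    if groups is not None:
        for name in sorted(set(groups)):
            sel = scores.loc[[i for i in scores.index if groups[i] == name]]
            ax.scatter(sel.iloc[:, 0], sel.iloc[:, 1], label=str(name))
        ax.legend(fontsize=7)
    else:
        ax.scatter(scores.iloc[:, 0], scores.iloc[:, 1])
    for label, (x, y) in scores.iterrows():
        ax.annotate(str(label), (x, y), fontsize=7)
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"{scores.columns[0]} ({evr[0]:.1%})")
    if len(evr) > 1:
        ax.set_ylabel(f"{scores.columns[1]} ({evr[1]:.1%})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
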