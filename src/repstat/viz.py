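"""Minimal static plot export (optional; TSV tables are the primary output)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def _pyplot():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def save_group_box(values: pd.Series, groups: pd.Series, title: str, path) -> Path:
    """Box + strip plot of a per-sample metric split by a 2-level feature."""
    plt = _pyplot()
    levels = sorted(groups.dropna().unique())
    data = [values[groups == g].dropna().to_numpy() for g in levels]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.boxplot(data, tick_labels=[str(g) for g in levels])
    for i, vals in enumerate(data, start=1):
        ax.plot([i] * len(vals), vals, "o", alpha=0.5, markersize=4)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def save_heatmap(matrix: pd.DataFrame, title: str, path) -> Path:
    """Heatmap of a symmetric pairwise-metric matrix."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(matrix.to_numpy(), cmap="viridis")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.index)), matrix.index, fontsize=7)
    fig.colorbar(im, ax=ax)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
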