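"""Optional heatmap helper for log2-transformed epitope frequencies."""

from __future__ import annotations

import pandas as pd


def plot_log2_heatmap(log2: pd.DataFrame, path=None, cmap: str = "viridis"):
    """Render a genotypes x epitopes heatmap of log2(frequency + 1) values.

    Requires matplotlib (``pip install gliascan[plot]``).  Returns the Axes;
    saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(0.35 * len(log2.columns) + 2, 0.4 * len(log2.index) + 2)
    )
    im = ax.imshow(log2.to_numpy(), aspect="auto", cmap=cmap)
    ax.set_xticks(range(len(log2.columns)), log2.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(log2.index)), log2.index, fontsize=8)
    fig.colorbar(im, ax=ax, label="log2(frequency + 1)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax
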