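"""Basic plotting helpers (matplotlib is an optional runtime dependency)."""
from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd


def plot_mi_heatmap(table: pd.DataFrame, column: str, out_path: Optional[str] = None):
    """Pseudo-color map of one MI feature over (channel, window start).

    Returns the matplotlib figure; saves to *out_path* when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = table.pivot_table(index="channel", columns="window_start", values=column)
    fig, ax = plt.subplots(figsize=(10, 0.6 * len(pivot) + 2))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", interpolation="nearest", cmap="viridis")
    ax.set_yticks(np.arange(len(pivot.index)), labels=pivot.index)
    ax.set_xlabel("window start (s)")
    ax.set_title(column)
    fig.colorbar(im, ax=ax, label="MI")
    if out_path is not None:
        fig.savefig(out_path, dpi=100, bbox_inches="tight")
        plt.close(fig)
    return fig
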