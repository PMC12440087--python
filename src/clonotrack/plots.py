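"""Minimal plotting helpers (Agg backend; outputs PNG/SVG)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .diversity import OverlapMatrix  # noqa: E402

__all__ = ["plot_overlap_heatmap"]


def plot_overlap_heatmap(overlap: OverlapMatrix, path) -> None:
    """Heatmap of a pairwise overlap matrix, saved to ``path``."""
    values = overlap.values
    fig, ax = plt.subplots(figsize=(max(4, 0.35 * len(values)),) * 2)
    im = ax.imshow(values.to_numpy(), cmap="viridis", vmin=0)
    ax.set_xticks(range(len(values)), values.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(values)), values.index, fontsize=6)
    ax.set_title(overlap.statistic)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
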