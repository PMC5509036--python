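"""Thin plotting conveniences over the emitted matrices (untested surface)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .stats import NTA_NUCLEOTIDES, NtaProfile  # noqa: E402


def plot_heatmap(matrix: pd.DataFrame, path: str | Path) -> None:
    """Render an isoform-fraction matrix (rows=miRNA, cols=sample x length)."""
    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * matrix.shape[1]), max(3, 0.25 * matrix.shape[0]))
    )
    im = ax.imshow(matrix.to_numpy(dtype=float), aspect="auto", cmap="viridis")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="fraction of reads")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_nta_pie(profile: NtaProfile, position: int, path: str | Path) -> None:
    """Pie of tail-nucleotide percentages at one terminal position."""
    values = [profile.percentages.get((position, nt), 0.0) for nt in NTA_NUCLEOTIDES]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.pie(values, labels=NTA_NUCLEOTIDES, autopct="%1.1f%%")
    ax.set_title(f"{profile.mature_id}: additions at position {position}")
    fig.savefig(path, dpi=150)
    plt.close(fig)
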