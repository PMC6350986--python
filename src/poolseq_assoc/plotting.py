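"""Manhattan-style plots of gene-wise association scores."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def manhattan_plot(
    gene_tables: Mapping[str, pd.DataFrame],
    path: str | Path,
    focal_interval: tuple[str, int, int] | None = None,
    cutoff: float | None = 4.0,
) -> None:
    """Gene midpoint vs score, one panel per chromosome, collections overlaid.

    The focal interval (e.g. the sodium-channel locus) is shaded when it
    falls on a plotted chromosome; the gene-score cutoff is drawn as a
    horizontal line.
    """
    chroms = sorted(
        {c for t in gene_tables.values() for c in t["chrom"].unique()}
    )
    fig, axes = plt.subplots(
        1, len(chroms), figsize=(4 * len(chroms), 3.2), sharey=True, squeeze=False
    )
    markers = ["o", "s", "^", "D", "v"]
    for ax, chrom in zip(axes[0], chroms):
        for (label, table), marker in zip(gene_tables.items(), markers):
            sub = table[(table["chrom"] == chrom) & table["score"].notna()]
            ax.scatter(
                sub["position_midpoint"] / 1e6, sub["score"], s=12,
                marker=marker, alpha=0.6, label=label, edgecolors="none",
            )
        if cutoff is not None:
            ax.axhline(cutoff, color="grey", lw=0.8, ls="--")
        if focal_interval is not None and focal_interval[0] == chrom:
            ax.axvspan(
                focal_interval[1] / 1e6, focal_interval[2] / 1e6,
                color="red", alpha=0.2,
            )
        ax.set_title(f"chromosome {chrom}")
        ax.set_xlabel("gene midpoint (Mb)")
    axes[0][0].set_ylabel("gene score (mean top 5% $-\\log_{10} p$)")
    axes[0][-1].legend(fontsize=8, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
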