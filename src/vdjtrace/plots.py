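"""Optional SVG figures: clonality bars and clonotype-rank plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .clonality import ClonalityReport


def plot_dominant_fractions(reports: list[ClonalityReport], path: str | Path) -> None:
    """Per-sample stacked bars: dominant vs other clonotypes (percent)."""
    ids = [r.sample_id for r in reports]
    dom = [r.dominant_frequency_pct for r in reports]
    other = [r.other_clonotypes_pct for r in reports]
    fig, ax = plt.subplots(figsize=(max(4, 0.45 * len(ids)), 3.2))
    ax.bar(ids, dom, label="dominant clonotype", color="#4878a8")
    ax.bar(ids, other, bottom=dom, label="other clonotypes", color="#c44e52")
    ax.set_ylabel("% of V(D)J-rearranged cells")
    ax.set_ylim(0, 100)
    ax.legend(frameon=False, fontsize=8)
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def plot_clonotype_ranks(
    ranks: pd.DataFrame, path: str | Path, highlight_key: str | None = None
) -> None:
    """Abundance bar plot of ranked clonotypes; the target clonotype (by its
    serialized chain key) is highlighted."""
    colors = [
        "#c44e52" if highlight_key is not None and k == highlight_key else "#777777"
        for k in ranks["chain_keys"]
    ]
    fig, ax = plt.subplots(figsize=(max(4, 0.06 * len(ranks)), 3.0))
    ax.bar(ranks["rank"], ranks["n_cells"], color=colors, width=1.0)
    ax.set_xlabel("clonotype rank")
    ax.set_ylabel("cells (barcodes)")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
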