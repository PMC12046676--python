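"""Diagnostic plots: CNA heatmap, spatial cluster map, DEG dot plot,
arm-profile bars and concordance heatmap. All plots are side effects of a
run; nothing downstream reads them."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .types import BinSet, CloneAssignment


def plot_cna_heatmap(binset: BinSet, assignment: CloneAssignment, path: str | Path) -> None:
    """Bins x genes CNA scores, genes in genomic order, bins grouped by
    cluster; amplification > 1 red, deletion < 1 blue."""
    order = assignment.labels.sort_values().index
    scores = binset.cna.loc[order]
    fig, ax = plt.subplots(figsize=(10, 6))
    im = ax.imshow(
        scores.to_numpy(), aspect="auto", cmap="RdBu_r",
        vmin=binset.cap_low, vmax=binset.cap_high, interpolation="nearest",
    )
    boundaries = np.flatnonzero(np.diff(assignment.labels.loc[order].to_numpy()))
    for b in boundaries:
        ax.axhline(b + 0.5, color="black", lw=0.6)
    ax.set_xlabel("genes (genomic order)")
    ax.set_ylabel("bins (grouped by cluster)")
    fig.colorbar(im, ax=ax, label="CNA score")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_spatial_clusters(binset: BinSet, assignment: CloneAssignment, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 6))
    labels = assignment.labels
    for cluster in sorted(labels.unique()):
        bins = labels.index[labels == cluster]
        marker = "cluster %d%s" % (cluster, " (normal)" if cluster == assignment.normal_cluster else "")
        ax.scatter(binset.info.loc[bins, "x"], binset.info.loc[bins, "y"], s=14, label=marker)
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.legend(fontsize=8)
    ax.set_aspect("equal")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_dge_dotplot(dge_table: pd.DataFrame, path: str | Path, top_n: int = 10) -> None:
    """Top DEGs per cluster, dot size = pct expressing, colour = log2 FC."""
    sig = dge_table[dge_table.get("significant", True)]
    top = (
        sig.sort_values("log2_fold_change", ascending=False)
        .groupby("cluster").head(top_n)
    )
    if top.empty:
        top = dge_table.head(top_n)
    genes = top["gene"].unique()
    clusters = sorted(top["cluster"].unique())
    fig, ax = plt.subplots(figsize=(max(4, len(genes) * 0.4), 1 + len(clusters) * 0.6))
    for yi, cluster in enumerate(clusters):
        sub = top[top["cluster"] == cluster].set_index("gene")
        for xi, gene in enumerate(genes):
            if gene in sub.index:
                row = sub.loc[gene]
                ax.scatter(xi, yi, s=40 + 260 * row["pct_expressing"],
                           c=[row["log2_fold_change"]], cmap="RdBu_r", vmin=-2, vmax=2)
    ax.set_xticks(range(len(genes)), genes, rotation=90, fontsize=7)
    ax.set_yticks(range(len(clusters)), [f"cluster {c}" for c in clusters])
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_arm_profiles(profiles: pd.DataFrame, path: str | Path) -> None:
    """Grouped bars of mean CNA score per arm, one group per profile row."""
    fig, ax = plt.subplots(figsize=(max(6, profiles.shape[1] * 0.45), 4))
    width = 0.8 / max(1, profiles.shape[0])
    xs = np.arange(profiles.shape[1])
    for i, (name, row) in enumerate(profiles.iterrows()):
        ax.bar(xs + i * width, row.to_numpy() - 1.0, width, bottom=1.0, label=str(name))
    ax.axhline(1.0, color="grey", lw=0.8)
    ax.set_xticks(xs + 0.4, profiles.columns, rotation=90, fontsize=7)
    ax.set_ylabel("mean CNA score")
    ax.legend(fontsize=8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_concordance(matrix: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(matrix.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(len(matrix)), matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix)), matrix.index, fontsize=7)
    for i in range(len(matrix)):
        for j in range(len(matrix)):
            v = matrix.iloc[i, j]
            ax.text(j, i, "na" if np.isnan(v) else f"{v:.2f}", ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
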