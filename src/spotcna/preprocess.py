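"""Count filtering and transformation into capped, reference-centred log expression.

Order of operations is fixed: gene filter -> bead filter -> per-bead TPM ->
log2(x+1) -> reference centring -> cap -> chrM/chrY removal (and intersection
with the gene-position table). "TPM" here is counts-per-million per bead: UMI
counts carry no gene-length bias, so no length term enters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import GenePositions, IntensityMatrix, SpatialExpression, ValidationError

log = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Thresholds for the quality filters.

    min_counts_per_gene: genes with total counts <= this are removed (default
      300, matching conservative single-nucleus filtering).
    bead_min_counts: a bead counts as "low quality" below this UMI total
      (default 100).
    max_low_bead_fraction: low-quality beads are removed, poorest first, only
      until the surviving fraction of such beads is at most this (default 0.35).
    log_cap: symmetric cap on centred log2 expression (default 3.0).
    """

    min_counts_per_gene: int = 300
    bead_min_counts: int = 100
    max_low_bead_fraction: float = 0.35
    log_cap: float = 3.0

    def __post_init__(self) -> None:
        if min(self.min_counts_per_gene, self.bead_min_counts, self.log_cap) < 0:
            raise ValidationError("preprocess thresholds must be >= 0")
        if not 0.0 <= self.max_low_bead_fraction <= 1.0:
            raise ValidationError("max_low_bead_fraction must be in [0, 1]")


@dataclass
class FilterReport:
    genes_removed: int
    beads_removed: int
    n_genes: int
    n_beads: int


def filter_matrix(
    se: SpatialExpression, cfg: PreprocessConfig | None = None
) -> tuple[SpatialExpression, FilterReport]:
    """Remove low-count genes, then trim low-count beads.

    Beads with fewer than ``bead_min_counts`` UMIs are removed in ascending
    count order (ties broken by bead id) only until the fraction of such beads
    among survivors drops to ``max_low_bead_fraction``, or none remain.
    """
    cfg = cfg or PreprocessConfig()
    if se.n_beads == 0 or se.n_genes == 0:
        raise ValidationError("empty matrix")

    gene_totals = se.counts.sum(axis=0)
    keep_genes = gene_totals.index[gene_totals > cfg.min_counts_per_gene]
    genes_removed = se.n_genes - len(keep_genes)
    counts = se.counts.loc[:, keep_genes]

    umi = counts.sum(axis=1)
    # beads with no counts at all can never be TPM-normalized; always drop
    empty = umi.index[umi == 0]
    counts = counts.drop(index=empty)
    umi = umi.drop(index=empty)
    low = umi.index[umi < cfg.bead_min_counts]
    # poorest first; bead id breaks ties deterministically
    order = umi.loc[low].sort_values(kind="mergesort").index
    n_beads = len(umi)
    n_low = len(low)
    removed: list = []
    for bead in order:
        if n_beads and n_low / n_beads <= cfg.max_low_bead_fraction:
            break
        removed.append(bead)
        n_low -= 1
        n_beads -= 1
    keep_beads = umi.index.difference(pd.Index(removed))
    if len(keep_beads) == 0:
        raise ValidationError("all beads removed by quality filter")
    beads_removed = len(removed) + len(empty)
    log.info(
        "filter_matrix: removed %d/%d genes and %d/%d beads",
        genes_removed, se.n_genes, beads_removed, se.n_beads,
    )
    out = SpatialExpression(
        counts.loc[keep_beads], se.coords.loc[keep_beads], se.bead_type.loc[keep_beads]
    )
    report = FilterReport(genes_removed, beads_removed, out.n_genes, out.n_beads)
    return out, report


def log_tpm(se: SpatialExpression) -> pd.DataFrame:
    """log2(TPM + 1) per bead: counts scaled to sum 1e6, then log2(x+1)."""
    totals = se.counts.sum(axis=1)
    if (totals == 0).any():
        raise ValidationError("bead with zero total counts; filter first")
    tpm = se.counts.div(totals, axis=0) * 1e6
    return np.log2(tpm + 1.0)


def center_and_cap(
    logexpr: pd.DataFrame,
    reference_beads: pd.Index,
    gene_positions: GenePositions,
    cap: float = 3.0,
) -> IntensityMatrix:
    """Centre each gene on its mean over reference beads and clamp to [-cap, cap].

    Mitochondrial (chrM) and chrY genes are then removed, and the gene set is
    intersected with the position table (genes without a position are flagged
    and dropped — they cannot be smoothed along a chromosome).
    """
    reference_beads = pd.Index(reference_beads)
    if len(reference_beads) == 0:
        raise ValidationError("reference population required")
    centered = logexpr - logexpr.loc[reference_beads].mean(axis=0)
    centered = centered.clip(lower=-cap, upper=cap)

    table = gene_positions.table
    unplaced = centered.columns.difference(table.index)
    if len(unplaced):
        log.warning("center_and_cap: %d genes missing from the position table; dropped", len(unplaced))
    placed = table.loc[table.index.intersection(centered.columns)]
    keep = placed.loc[~placed["chromosome"].isin(["chrM", "chrY"]), "gene"]
    gp = gene_positions.subset(keep)
    ordered = centered.loc[:, list(gp.genes)]
    return IntensityMatrix(ordered, "log_centered", gp)
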