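"""Core domain containers for spatial CNA inference.

The pipeline moves a bead x gene matrix through a fixed series of shapes:
raw counts with spatial coordinates and malignancy annotations
(:class:`SpatialExpression`), reference-centred log expression and relative
expression intensities (:class:`IntensityMatrix`), spatio-molecular bins
carrying CNA scores (:class:`BinSet`), and finally per-bin clone labels
(:class:`CloneAssignment`). Everything is backed by pandas so labels travel
with the values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: bead annotation labels accepted throughout the package
BEAD_TYPES = ("reference", "non_reference_normal", "malignant")

#: karyotype ordering used whenever genes are sorted genomically
KARYOTYPE = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY", "chrM")


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


class FormatError(ValueError):
    """Raised when an on-disk file cannot be parsed as its declared format."""


def karyotype_rank(chromosome: str) -> int:
    """Sort key for chromosome labels: chr1..chr22, chrX, chrY, chrM, then
    any unknown label alphabetically after the known set."""
    try:
        return KARYOTYPE.index(chromosome)
    except ValueError:
        return len(KARYOTYPE)


@dataclass
class GenePositions:
    """Ordered genomic coordinates per gene.

    ``table`` has columns ``gene, chromosome, start, end, arm`` and is kept
    sorted by (karyotype order, start). The ordering defines both the
    smoothing order along chromosomes and chromosome-arm membership.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "chromosome", "start", "end", "arm"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"gene position table missing columns {sorted(missing)}")
        if self.table["gene"].duplicated().any():
            dups = self.table.loc[self.table["gene"].duplicated(), "gene"].tolist()
            raise ValidationError(f"duplicate gene symbols: {dups[:5]}")
        if (self.table["start"] > self.table["end"]).any():
            raise ValidationError("gene with start > end")
        self.table = self._sorted(self.table).set_index("gene", drop=False)

    @staticmethod
    def _sorted(table: pd.DataFrame) -> pd.DataFrame:
        key = table["chromosome"].map(karyotype_rank)
        # stable sort on (karyotype rank, chromosome label, start, gene) so the
        # order is deterministic even for unknown chromosome labels
        return table.assign(_k=key).sort_values(
            ["_k", "chromosome", "start", "gene"], kind="mergesort"
        ).drop(columns="_k").reset_index(drop=True)

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.table["gene"])

    def subset(self, genes) -> "GenePositions":
        """Restrict to ``genes`` (order re-derived from genomic position)."""
        keep = self.table.loc[self.table["gene"].isin(set(genes))].reset_index(drop=True)
        return GenePositions(keep)

    def chromosomes(self):
        """Iterate (chromosome, gene index) in karyotype order."""
        for chrom in self.table["chromosome"].unique():
            yield chrom, pd.Index(self.table.loc[self.table["chromosome"] == chrom, "gene"])

    def arm_of(self) -> pd.Series:
        """gene -> arm label like ``1p`` (chromosome without 'chr' + p/q)."""
        chrom = self.table["chromosome"].str.replace("^chr", "", regex=True)
        return pd.Series((chrom + self.table["arm"]).values, index=self.table["gene"].values)


@dataclass
class SpatialExpression:
    """Bead x gene counts with spatial coordinates and malignancy annotations.

    counts: non-negative integer DataFrame, beads in rows.
    coords: DataFrame with columns x, y (micrometres, arbitrary planar frame).
    bead_type: Series with values in :data:`BEAD_TYPES`.
    """

    counts: pd.DataFrame
    coords: pd.DataFrame
    bead_type: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValidationError("duplicate bead ids in counts")
        if self.counts.columns.duplicated().any():
            raise ValidationError("duplicate gene ids in counts")
        if not self.counts.index.equals(self.coords.index) or not self.counts.index.equals(
            self.bead_type.index
        ):
            raise ValidationError("counts, coords and bead_type must share the same bead index")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValidationError("negative counts")
        if not np.isfinite(self.coords.to_numpy()).all():
            raise ValidationError("non-finite coordinates")
        bad = set(self.bead_type.unique()) - set(BEAD_TYPES)
        if bad:
            raise ValidationError(f"unknown bead types {sorted(bad)}")

    @property
    def n_beads(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def umi_per_bead(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def is_reference(self) -> pd.Series:
        return self.bead_type == "reference"

    @property
    def is_malignant(self) -> pd.Series:
        return self.bead_type == "malignant"

    def require_populations(self) -> None:
        """The pipeline needs at least one reference and one malignant bead."""
        if int(self.is_reference.sum()) < 1:
            raise ValidationError("reference population required")
        if int(self.is_malignant.sum()) < 1:
            raise ValidationError("at least one malignant bead required")

    def subset_beads(self, beads) -> "SpatialExpression":
        return SpatialExpression(
            self.counts.loc[beads], self.coords.loc[beads], self.bead_type.loc[beads]
        )

    def subset_genes(self, genes) -> "SpatialExpression":
        return SpatialExpression(self.counts.loc[:, genes], self.coords, self.bead_type)


STAGES = ("log_centered", "smoothed", "rescaled")


@dataclass
class IntensityMatrix:
    """Bead x gene expression intensities at a given pipeline stage.

    ``log_centered``: log2(TPM+1), reference-centred and capped to [-cap, cap].
    ``smoothed``: after per-chromosome pyramidal moving average.
    ``rescaled``: strictly positive relative intensities, copy-neutral ~= 1.
    """

    values: pd.DataFrame
    stage: str
    gene_order: GenePositions

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        order = [g for g in self.gene_order.genes if g in self.values.columns]
        if list(self.values.columns) != order:
            raise ValidationError("intensity columns are not in genomic order")
        if self.stage == "rescaled" and (self.values.to_numpy() <= 0).any():
            raise ValidationError("rescaled intensities must be strictly positive")


@dataclass
class BinSet:
    """Spatio-molecular bins: a partition of beads plus bin-level summaries.

    membership: Series bead -> bin_id.
    info: DataFrame indexed by bin_id with columns x, y, umi, type, n_beads.
    cna: bin x gene CNA scores in [cap_low, cap_high]; None until scored.
    """

    membership: pd.Series
    info: pd.DataFrame
    cna: pd.DataFrame | None = None
    cap_low: float = 0.6
    cap_high: float = 1.4
    expression: pd.DataFrame | None = None  # bin x gene mean intensities, pre-capping

    def __post_init__(self) -> None:
        if self.membership.isna().any():
            raise ValidationError("bead without a bin")
        if not set(self.membership.unique()) <= set(self.info.index):
            raise ValidationError("membership refers to unknown bins")
        if self.cna is not None:
            vals = self.cna.to_numpy()
            if vals.size and (vals < self.cap_low - 1e-12).any() or (
                vals.size and (vals > self.cap_high + 1e-12).any()
            ):
                raise ValidationError("CNA scores outside cap range")

    @property
    def bin_ids(self) -> pd.Index:
        return self.info.index

    @property
    def n_bins(self) -> int:
        return len(self.info)

    def malignant_bins(self) -> pd.Index:
        return self.info.index[self.info["type"] == "malignant"]


@dataclass
class CloneAssignment:
    """Per-bin clone labels after silhouette-selected Ward clustering.

    labels: Series bin_id -> cluster in 1..k_all; exactly one cluster is the
    designated non-malignant cluster.
    """

    labels: pd.Series
    k_malignant: int
    normal_cluster: int
    silhouette_trace: dict[int, float] = field(default_factory=dict)

    @property
    def k_all(self) -> int:
        return self.k_malignant + 1


@dataclass
class DGEResult:
    """Per-gene differential expression table between CNA clusters.

    table columns: gene, cluster, log2_fold_change, p_value, p_adjusted,
    pct_expressing, flagged; ordered by decreasing log2 fold change.
    """

    table: pd.DataFrame
    n_tests: int
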