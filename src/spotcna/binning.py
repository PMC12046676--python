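"""Spatio-molecular binning and bin-level CNA scores.

Beads are grouped into bins — separately for malignant and non-malignant
populations — by Ward agglomeration (the ward.D2 criterion) on a
pseudo-distance that linearly combines physical and expression-space
Euclidean distances:

    X_pseudo = k_spatial * X_spatial + k_expression * X_expression

Bin intensities are bead means, adjusted for bin UMI depth and clamped to a
fixed band around copy-neutral to give CNA scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform

from .types import BinSet, IntensityMatrix, SpatialExpression, ValidationError

log = logging.getLogger(__name__)


@dataclass
class BinningConfig:
    """k_spatial/k_expression: weights of the two distance terms (defaults
    55 and 1, prioritising spatial proximity); beads_per_bin: target bin
    occupancy (default 12); spatial_mode=False drops the spatial term
    entirely (for non-spatial data); umi_scaling: "shrink" damps deviations
    from 1 in low-UMI bins by the size factor umi/median(umi), "none" (the
    default) leaves intensities untouched before capping — per-bead baseline
    centring upstream already removes depth-driven intensity shifts, and the
    shrinkage variant distorts CNA signal wherever depth correlates with
    space."""

    k_spatial: float = 55.0
    k_expression: float = 1.0
    beads_per_bin: int = 12
    spatial_mode: bool = True
    cna_cap_high: float = 1.4
    cna_cap_low: float = 0.6
    umi_scaling: str = "none"

    def __post_init__(self) -> None:
        if self.k_spatial < 0 or self.k_expression < 0:
            raise ValidationError("distance weights must be >= 0")
        if self.k_spatial == 0 and self.k_expression == 0:
            raise ValidationError("k_spatial and k_expression cannot both be 0")
        if self.beads_per_bin < 1:
            raise ValidationError("beads_per_bin must be >= 1")
        if not self.cna_cap_low < 1.0 < self.cna_cap_high:
            raise ValidationError("caps must bracket 1")
        if self.umi_scaling not in ("shrink", "none"):
            raise ValidationError("umi_scaling must be 'shrink' or 'none'")


def pseudo_distance(
    intensities: IntensityMatrix,
    coords: pd.DataFrame,
    cfg: BinningConfig | None = None,
) -> pd.DataFrame:
    """Combined spatial + expression pairwise distance over one bead group."""
    cfg = cfg or BinningConfig()
    beads = intensities.values.index
    if not beads.equals(coords.index):
        raise ValidationError("intensities and coordinates cover different beads")
    if not np.isfinite(coords.to_numpy()).all():
        raise ValidationError("non-finite coordinates")
    x_expr = pdist(intensities.values.to_numpy(), metric="euclidean")
    combined = cfg.k_expression * x_expr
    if cfg.spatial_mode:
        x_spatial = pdist(coords.to_numpy(), metric="euclidean")
        combined = combined + cfg.k_spatial * x_spatial
    return pd.DataFrame(squareform(combined), index=beads, columns=beads)


def _n_bins(n_beads: int, beads_per_bin: int) -> int:
    # round-half-to-even, minimum one bin per non-empty group
    return max(1, round(n_beads / beads_per_bin))


def assign_bins(
    pseudo_by_group: dict[str, pd.DataFrame],
    cfg: BinningConfig | None = None,
) -> pd.Series:
    """Cut a Ward (ward.D2) tree per bead group into ~n/beads_per_bin bins.

    ``pseudo_by_group`` maps a group label (e.g. "malignant") to that group's
    pseudo-distance matrix. Returns a bead -> bin_id Series; bin ids are
    globally unique across groups so malignant and non-malignant beads never
    share a bin.
    """
    cfg = cfg or BinningConfig()
    membership = {}
    offset = 0
    for group in sorted(pseudo_by_group):
        pseudo = pseudo_by_group[group]
        n = pseudo.shape[0]
        if n == 0:
            log.info("assign_bins: group %s has no beads; skipped", group)
            continue
        k = _n_bins(n, cfg.beads_per_bin)
        if n == 1:
            labels = np.array([1])
        else:
            link = sch.linkage(squareform(pseudo.to_numpy(), checks=False), method="ward")
            labels = sch.fcluster(link, t=k, criterion="maxclust")
        for bead, lab in zip(pseudo.index, labels):
            membership[bead] = offset + int(lab)
        offset += int(labels.max())
    if not membership:
        raise ValidationError("no beads to bin")
    return pd.Series(membership, name="bin")


def aggregate_bins(
    intensities: IntensityMatrix,
    se: SpatialExpression,
    membership: pd.Series,
) -> BinSet:
    """Summarize each bin: mean intensities and coordinates, summed UMI,
    modal bead type (ties broken by label sort order)."""
    beads = membership.index
    expr = intensities.values.loc[beads].groupby(membership).mean()
    xy = se.coords.loc[beads].groupby(membership).mean()
    umi = se.umi_per_bead.loc[beads].groupby(membership).sum()
    sizes = membership.groupby(membership).size()

    def _mode(types: pd.Series) -> str:
        tab = types.value_counts()
        top = tab[tab == tab.iloc[0]].index.sort_values()
        if len(top) > 1:
            log.info("aggregate_bins: type tie %s resolved to %s", list(top), top[0])
        return top[0]

    btype = se.bead_type.loc[beads].groupby(membership).agg(_mode)
    info = pd.DataFrame(
        {"x": xy["x"], "y": xy["y"], "umi": umi, "type": btype, "n_beads": sizes}
    )
    info.index.name = "bin"
    return BinSet(membership, info, expression=expr)


def cna_scores(binset: BinSet, cfg: BinningConfig | None = None) -> BinSet:
    """UMI-adjust bin intensities and clamp to the CNA score band.

    With umi_scaling="shrink", a bin's deviation from copy-neutral 1 is
    multiplied by min(1, umi_bin / median umi): sparse bins, whose intensity
    deviations are noise-dominated, are pulled toward neutral; bins at or
    above median depth are untouched.
    """
    cfg = cfg or BinningConfig()
    expr = binset.expression
    if expr is None:
        raise ValidationError("aggregate_bins must run before cna_scores")
    umi = binset.info["umi"]
    if (umi <= 0).any():
        raise ValidationError("bin with zero UMI")
    if cfg.umi_scaling == "shrink":
        size_factor = (umi / umi.median()).clip(upper=1.0)
        adjusted = 1.0 + (expr - 1.0).mul(size_factor, axis=0)
    else:
        adjusted = expr
    scores = adjusted.clip(lower=cfg.cna_cap_low, upper=cfg.cna_cap_high)
    return BinSet(
        binset.membership, binset.info, scores,
        cfg.cna_cap_low, cfg.cna_cap_high, expression=expr,
    )


def bin_beads(
    intensities: IntensityMatrix,
    se: SpatialExpression,
    cfg: BinningConfig | None = None,
) -> BinSet:
    """Full binning stage: pseudo-distance per population, Ward bins, scores."""
    cfg = cfg or BinningConfig()
    groups = {}
    for name, mask in (
        ("malignant", se.is_malignant),
        ("non_malignant", ~se.is_malignant),
    ):
        beads = se.counts.index[mask]
        if len(beads) == 0:
            continue
        sub = IntensityMatrix(
            intensities.values.loc[beads], intensities.stage, intensities.gene_order
        )
        groups[name] = pseudo_distance(sub, se.coords.loc[beads], cfg)
    membership = assign_bins(groups, cfg)
    binset = aggregate_bins(intensities, se, membership)
    return cna_scores(binset, cfg)
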