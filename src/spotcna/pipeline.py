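"""End-to-end orchestration: preprocess -> smooth -> bin -> clones -> evaluate.

`run_pipeline` is the single entry point the CLI wraps; it returns all
intermediate objects so library users can inspect any stage, and optionally
writes the output tables (and a run manifest) to a directory. Inference is
fully deterministic given its inputs; the only randomness in the package
lives in the simulator.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .binning import BinningConfig, bin_beads
from .clones import CloneConfig, beads_to_clusters, call_clones, differential_expression
from .evaluate import (
    arm_sign_agreement,
    bin_truth_labels,
    clone_arm_profiles,
    match_clusters_to_clones,
    matched_accuracy,
    profile_truth_correlation,
)
from .preprocess import PreprocessConfig, center_and_cap, filter_matrix, log_tpm
from .smooth import SmoothingConfig, recenter_and_rescale, smooth_genome
from .types import BinSet, CloneAssignment, DGEResult, GenePositions, SpatialExpression

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    smooth: SmoothingConfig = field(default_factory=SmoothingConfig)
    binning: BinningConfig = field(default_factory=BinningConfig)
    clones: CloneConfig = field(default_factory=CloneConfig)
    signal_threshold: float = 0.02
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = {}
        for name, sub in (
            ("preprocess", PreprocessConfig),
            ("smooth", SmoothingConfig),
            ("binning", BinningConfig),
            ("clones", CloneConfig),
        ):
            if name in raw:
                kwargs[name] = sub(**raw[name])
        for name in ("signal_threshold", "seed"):
            if name in raw:
                kwargs[name] = raw[name]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    se: SpatialExpression           # after quality filtering
    intensities: "pd.DataFrame"     # rescaled bead x gene intensities
    binset: BinSet
    assignment: CloneAssignment
    arm_profiles: pd.DataFrame      # cluster x arm mean CNA scores
    dge: DGEResult | None
    filter_report: object


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(
    se: SpatialExpression,
    gene_positions: GenePositions,
    cfg: RunConfig | None = None,
    outdir: str | Path | None = None,
    dge: bool = True,
) -> PipelineResult:
    """Run the full CNA inference pipeline on annotated spatial counts."""
    cfg = cfg or RunConfig()
    se.require_populations()

    filtered, report = _stage("preprocess.filter")(filter_matrix)(se, cfg.preprocess)
    logexpr = _stage("preprocess.log_tpm")(log_tpm)(filtered)
    ref = filtered.counts.index[filtered.is_reference]
    centered = _stage("preprocess.center_and_cap")(center_and_cap)(
        logexpr, ref, gene_positions, cfg.preprocess.log_cap
    )
    smoothed = _stage("smooth")(smooth_genome)(centered, cfg.smooth)
    rescaled = _stage("smooth.rescale")(recenter_and_rescale)(smoothed, ref)
    filtered = filtered.subset_genes(rescaled.values.columns)
    binset = _stage("bin_cna")(bin_beads)(rescaled, filtered, cfg.binning)
    assignment = _stage("clones")(call_clones)(binset, cfg.clones)
    profiles = _stage("evaluate.arm_aggregate")(clone_arm_profiles)(
        binset, assignment, rescaled.gene_order
    )
    dge_result = None
    if dge:
        clusters = beads_to_clusters(binset, assignment)
        dge_result = _stage("clones.dge")(differential_expression)(filtered, clusters)

    result = PipelineResult(
        filtered, rescaled.values, binset, assignment, profiles, dge_result, report
    )
    if outdir is not None:
        write_outputs(result, cfg, Path(outdir))
    return result


def write_outputs(result: PipelineResult, cfg: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    binset, assignment = result.binset, result.assignment
    bins = binset.info.copy()
    bins["cluster"] = assignment.labels
    bins["is_normal_cluster"] = bins["cluster"] == assignment.normal_cluster
    bins.to_csv(outdir / "bins.tsv", sep="\t")
    binset.cna.to_csv(outdir / "cna_scores.tsv", sep="\t")
    binset.membership.rename("bin").to_csv(outdir / "bead_bins.tsv", sep="\t")
    pd.Series(assignment.silhouette_trace, name="mean_silhouette").rename_axis("k").to_csv(
        outdir / "silhouette_trace.tsv", sep="\t"
    )
    result.arm_profiles.rename_axis("cluster").to_csv(outdir / "arm_profiles.tsv", sep="\t")
    if result.dge is not None:
        result.dge.table.to_csv(outdir / "dge.tsv", sep="\t", index=False)
    manifest = {
        "package": "spotcna",
        "version": __version__,
        "config": cfg.to_dict(),
        "n_beads": int(result.se.n_beads),
        "n_genes": int(result.se.n_genes),
        "n_bins": int(binset.n_bins),
        "k_malignant": int(assignment.k_malignant),
        "normal_cluster": int(assignment.normal_cluster),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    try:
        from .plotting import plot_cna_heatmap, plot_spatial_clusters

        plot_cna_heatmap(binset, assignment, outdir / "cna_heatmap.png")
        plot_spatial_clusters(binset, assignment, outdir / "spatial_clusters.png")
    except Exception as exc:  # plots are side effects, never inputs
        log.warning("plotting failed: %s", exc)


# ---------------------------------------------------------------------------
# simulation recovery benchmark

@dataclass
class RecoveryMetrics:
    k_malignant: int
    accuracy: float
    sign_agreement: float
    n_altered_arms: int
    truth_correlation: float  # worst clone's Spearman rho vs true fold changes
    per_clone_correlation: dict


def run_recovery(bundle, cfg: RunConfig | None = None, dge: bool = False):
    """Run the pipeline on a simulation bundle and score ground-truth recovery.

    Returns (PipelineResult, RecoveryMetrics): silhouette-selected clone
    number, Hungarian-matched bin clone accuracy, the direction agreement on
    truly altered arms, and per-clone Spearman correlation between inferred
    and implanted arm profiles.
    """
    result = run_pipeline(bundle.se, bundle.genome, cfg, dge=dge)
    truth_bins = bin_truth_labels(
        result.binset, bundle.truth.dominant, bundle.truth.bead_fractions
    )
    accuracy = matched_accuracy(truth_bins, result.assignment.labels)
    mapping = match_clusters_to_clones(truth_bins, result.assignment.labels)

    signs, rhos = [], {}
    for cluster, clone in mapping.items():
        if clone == "normal":
            continue
        inferred = result.arm_profiles.loc[cluster]
        true_fc = bundle.truth.arm_fc.loc[clone]
        frac, n_alt = arm_sign_agreement(inferred, true_fc)
        signs.append((frac, n_alt))
        rhos[clone] = profile_truth_correlation(inferred, true_fc)
    total_alt = sum(n for _, n in signs)
    sign_frac = sum(f * n for f, n in signs) / total_alt if total_alt else float("nan")
    metrics = RecoveryMetrics(
        k_malignant=result.assignment.k_malignant,
        accuracy=accuracy,
        sign_agreement=sign_frac,
        n_altered_arms=total_alt,
        truth_correlation=min(rhos.values()) if rhos else float("nan"),
        per_clone_correlation=rhos,
    )
    return result, metrics
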