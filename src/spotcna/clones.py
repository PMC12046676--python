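"""Clone determination over malignant bins and differential expression.

The number of putative malignant clones k_malignant is chosen by cutting a
Ward (ward.D2) tree over the malignant bins' CNA score rows at k = 2..10 and
maximizing the mean silhouette width. All bins are then re-clustered jointly
at k_all = k_malignant + 1, with one cluster designated the non-malignant
population. Differential expression between the resulting bead clusters uses
a negative binomial GLM on raw counts with a log total-UMI offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import statsmodels.api as sm
from scipy.spatial.distance import pdist
from sklearn.metrics import silhouette_score

from .types import BinSet, CloneAssignment, DGEResult, SpatialExpression, ValidationError

log = logging.getLogger(__name__)


@dataclass
class CloneConfig:
    k_min: int = 2
    k_max: int = 10


def _ward_cut(values: np.ndarray, k: int) -> np.ndarray:
    link = sch.linkage(pdist(values, metric="euclidean"), method="ward")
    return sch.fcluster(link, t=k, criterion="maxclust")


def select_k_malignant(
    malignant_cna: pd.DataFrame, cfg: CloneConfig | None = None
) -> tuple[int, dict[int, float]]:
    """Choose the number of malignant clones by mean silhouette width.

    Ward tree on Euclidean distances between the malignant bins' CNA rows;
    k is searched over 2..min(10, n_bins - 1); ties go to the smallest k.
    """
    cfg = cfg or CloneConfig()
    n = malignant_cna.shape[0]
    if n < 3:
        raise ValidationError("too few bins for clone calling")
    values = malignant_cna.to_numpy()
    trace: dict[int, float] = {}
    for k in range(cfg.k_min, min(cfg.k_max, n - 1) + 1):
        labels = _ward_cut(values, k)
        if len(np.unique(labels)) < 2:
            continue
        trace[k] = float(silhouette_score(values, labels, metric="euclidean"))
    if not trace:
        raise ValidationError("silhouette undefined for every k")
    best = max(trace, key=lambda k: (trace[k], -k))
    return best, trace


def assign_clones(binset: BinSet, k_malignant: int) -> CloneAssignment:
    """Cluster all bins jointly at k_all = k_malignant + 1 clusters.

    The cluster with the greatest fraction of non-malignant bins is
    designated the normal cluster.
    """
    if binset.cna is None:
        raise ValidationError("bins must carry CNA scores")
    values = binset.cna.to_numpy()
    if np.allclose(values, values[0]):
        log.warning("assign_clones: all bins identical; cluster labels are degenerate")
    k_all = k_malignant + 1
    labels = pd.Series(_ward_cut(values, k_all), index=binset.cna.index, name="cluster")
    non_mal = binset.info["type"] != "malignant"
    frac = non_mal.groupby(labels).mean().sort_index()
    normal_cluster = int(frac.idxmax())
    return CloneAssignment(labels, k_malignant, normal_cluster)


def call_clones(binset: BinSet, cfg: CloneConfig | None = None) -> CloneAssignment:
    """Silhouette-selected k over malignant bins, then joint assignment."""
    mal = binset.malignant_bins()
    k, trace = select_k_malignant(binset.cna.loc[mal], cfg)
    assignment = assign_clones(binset, k)
    assignment.silhouette_trace.update(trace)
    return assignment


# ---------------------------------------------------------------------------
# differential expression

def beads_to_clusters(binset: BinSet, assignment: CloneAssignment) -> pd.Series:
    """bead -> cluster label, through each bead's bin."""
    return binset.membership.map(assignment.labels)


def _nb_alpha(y: np.ndarray, mu: np.ndarray) -> float:
    """Cameron–Trivedi moment estimate of the NB2 dispersion alpha
    (variance = mu + alpha * mu^2) from a Poisson fit."""
    num = ((y - mu) ** 2 - mu).sum()
    den = (mu ** 2).sum()
    return float(num / den) if den > 0 else 0.0


def _test_gene(y: np.ndarray, exog: np.ndarray, offset: np.ndarray):
    """Wald test of the group indicator in an NB GLM with log-UMI offset.

    Returns (coef, p_value, flagged). Dispersion is estimated from a Poisson
    fit; a non-positive estimate falls back to the Poisson family.
    """
    flagged = False
    try:
        pois = sm.GLM(y, exog, family=sm.families.Poisson(), offset=offset).fit()
        alpha = _nb_alpha(y, pois.fittedvalues)
        if alpha > 0:
            fam = sm.families.NegativeBinomial(alpha=alpha)
            res = sm.GLM(y, exog, family=fam, offset=offset).fit(start_params=pois.params)
        else:
            res = pois
        coef = float(res.params[1])
        pval = float(res.pvalues[1])
        if not np.isfinite(coef) or not np.isfinite(pval):
            raise ValueError("non-finite estimate")
    except Exception:  # separation / non-convergence on degenerate genes
        coef, pval, flagged = np.nan, 1.0, True
    return coef, pval, flagged


def differential_expression(
    se: SpatialExpression,
    bead_clusters: pd.Series,
    alpha_level: float = 0.05,
    min_beads: int = 3,
    pseudocount: float = 1.0,
) -> DGEResult:
    """One-vs-rest NB GLM differential expression on raw bead counts.

    For every cluster and gene with any counts, fit
    ``count ~ 1 + in_cluster`` with a log(total UMI) offset and take the Wald
    p-value of the indicator. P-values are Bonferroni-corrected over all
    genes x clusters tested. The reported log2 fold change is the
    pseudocounted ratio of mean normalized expression (finite even when one
    side is all zero; such genes are flagged).
    """
    clusters = bead_clusters.dropna()
    counts = se.counts.loc[clusters.index]
    sizes = clusters.value_counts()
    valid = sizes.index[sizes >= min_beads]
    if len(valid) < 2:
        raise ValidationError("need >= 2 clusters with enough beads for DGE")
    totals = counts.sum(axis=1).to_numpy(dtype=float)
    offset = np.log(totals)
    cpm = counts.div(counts.sum(axis=1), axis=0) * 1e4  # per-10k normalization

    rows = []
    for cluster in sorted(valid):
        indicator = (clusters == cluster).to_numpy(dtype=float)
        exog = np.column_stack([np.ones_like(indicator), indicator])
        in_c = indicator.astype(bool)
        for gene in counts.columns:
            y = counts[gene].to_numpy(dtype=float)
            if y.sum() == 0:
                continue
            coef, pval, flagged = _test_gene(y, exog, offset)
            mean_in = cpm.loc[in_c, gene].mean()
            mean_out = cpm.loc[~in_c, gene].mean()
            lfc = float(np.log2((mean_in + pseudocount) / (mean_out + pseudocount)))
            if (y[in_c].sum() == 0) != (y[~in_c].sum() == 0):
                flagged = True  # one-sided zero group: GLM estimate unreliable
            rows.append(
                {
                    "gene": gene,
                    "cluster": cluster,
                    "log2_fold_change": lfc,
                    "p_value": pval,
                    "pct_expressing": float((counts.loc[in_c, gene] > 0).mean()),
                    "flagged": flagged,
                }
            )
    table = pd.DataFrame(rows)
    n_tests = len(table)
    if n_tests:
        table["p_adjusted"] = np.minimum(1.0, table["p_value"] * n_tests)
        table = table.sort_values("log2_fold_change", ascending=False).reset_index(drop=True)
        table["significant"] = table["p_adjusted"] < alpha_level
    return DGEResult(table, n_tests)
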