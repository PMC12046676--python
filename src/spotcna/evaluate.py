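"""Chromosome-arm aggregation and cross-profile concordance.

CNA profiles from different methods, modalities or clones are compared on a
common footing: the mean CNA score per chromosome arm. Pairwise agreement is
Spearman's rank correlation restricted to arms that carry signal
(|score - 1| above a small threshold) in both profiles. Segment-level copy
ratios (e.g. from exome CNA callers) are folded to the same representation by
length-weighted arm means centred so the genome-wide mean is copy-neutral 1.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import spearmanr

from .types import BinSet, CloneAssignment, GenePositions, ValidationError

log = logging.getLogger(__name__)

#: |arm mean - 1| below this counts as "no CNA signal" on that arm
DEFAULT_SIGNAL_THRESHOLD = 0.02


def arm_aggregate(
    cna_scores: pd.DataFrame,
    gene_positions: GenePositions,
    group_by: pd.Series | None = None,
) -> pd.DataFrame:
    """Mean CNA score per chromosome arm, optionally per group of rows.

    Returns a profiles x arms DataFrame (one row when ``group_by`` is None).
    Arms with no genes in the score matrix are simply absent.
    """
    arm_of = gene_positions.arm_of()
    genes = cna_scores.columns.intersection(arm_of.index)
    if len(genes) == 0:
        raise ValidationError("no gene maps to any chromosome arm")
    scores = cna_scores.loc[:, genes]
    arms = arm_of.loc[genes]
    by_arm = scores.T.groupby(arms.values).mean().T  # rows x arms
    if group_by is None:
        return pd.DataFrame(by_arm.mean(axis=0)).T.set_axis(["all"], axis=0)
    return by_arm.groupby(group_by).mean()


def clone_arm_profiles(
    binset: BinSet, assignment: CloneAssignment, gene_positions: GenePositions
) -> pd.DataFrame:
    """Per-cluster arm profile from bin CNA scores (rows: cluster labels)."""
    return arm_aggregate(binset.cna, gene_positions, assignment.labels)


def concordance(
    profiles: pd.DataFrame,
    signal_threshold: float = DEFAULT_SIGNAL_THRESHOLD,
    min_shared_arms: int = 3,
) -> pd.DataFrame:
    """Pairwise Spearman correlation over arms with signal in both profiles.

    ``profiles`` is profiles x arms. Arms where either profile sits within
    ``signal_threshold`` of copy-neutral are excluded pair by pair. Pairs
    sharing fewer than ``min_shared_arms`` signal arms get NaN (flagged),
    never a fabricated value. Ties get average ranks (scipy default).
    """
    if profiles.shape[0] < 2:
        raise ValidationError("need >= 2 profiles for concordance")
    names = profiles.index
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    has_signal = (profiles - 1.0).abs() >= signal_threshold
    for a, b in itertools.combinations(names, 2):
        shared = profiles.columns[has_signal.loc[a] & has_signal.loc[b]]
        shared = shared[profiles.loc[a, shared].notna() & profiles.loc[b, shared].notna()]
        if len(shared) < min_shared_arms:
            log.warning("concordance %s vs %s: only %d shared signal arms; undefined",
                        a, b, len(shared))
            rho = np.nan
        else:
            rho = spearmanr(profiles.loc[a, shared], profiles.loc[b, shared]).statistic
        out.loc[a, b] = out.loc[b, a] = rho
    return out


def center_segment_profile(
    segments: pd.DataFrame, gene_positions: GenePositions | None = None
) -> pd.Series:
    """Fold segment-level copy ratios to centred arm means.

    ``segments`` needs columns ``arm``, ``value``, ``length``. Arm values are
    length-weighted means; the profile is then divided by its genome-wide
    length-weighted mean so copy-neutral sits at 1.
    """
    for col in ("arm", "value", "length"):
        if col not in segments.columns:
            raise ValidationError(f"segments missing column {col!r}")
    total = segments["length"].sum()
    if total <= 0:
        raise ValidationError("zero total segment length")
    weighted = segments.assign(w=segments["value"] * segments["length"])
    arm_means = weighted.groupby("arm").apply(
        lambda t: t["w"].sum() / t["length"].sum(), include_groups=False
    )
    genome_mean = weighted["w"].sum() / total
    return arm_means / genome_mean


# ---------------------------------------------------------------------------
# ground-truth recovery metrics (used by the simulation benchmarks)

def bin_truth_labels(
    binset: BinSet,
    dominant_bead_clone: pd.Series,
    bead_fractions: pd.DataFrame | None = None,
) -> pd.Series:
    """Per-bin true clone: mode of member beads' dominant clones.

    Modal ties are resolved by the bin's summed kernel-weight fractions when
    available (the actual ground truth of what the bin's expression
    contains), falling back to label sort order."""
    beads = binset.membership.index
    out = {}
    for bin_id, members in binset.membership.groupby(binset.membership).groups.items():
        tab = dominant_bead_clone.loc[members].value_counts()
        top = tab.index[tab == tab.iloc[0]]
        if len(top) > 1 and bead_fractions is not None:
            out[bin_id] = bead_fractions.loc[members, list(top)].sum(axis=0).idxmax()
        else:
            out[bin_id] = sorted(top)[0]
    return pd.Series(out)


def matched_accuracy(truth: pd.Series, predicted: pd.Series) -> float:
    """Clustering accuracy after optimal one-to-one label matching
    (Hungarian assignment on the contingency table)."""
    truth, predicted = truth.align(predicted, join="inner")
    table = pd.crosstab(truth, predicted)
    rows, cols = linear_sum_assignment(-table.to_numpy())
    return float(table.to_numpy()[rows, cols].sum() / len(truth))


def match_clusters_to_clones(
    truth: pd.Series, predicted: pd.Series
) -> dict:
    """Optimal mapping predicted cluster -> true clone label."""
    truth, predicted = truth.align(predicted, join="inner")
    table = pd.crosstab(truth, predicted)
    rows, cols = linear_sum_assignment(-table.to_numpy())
    return {table.columns[c]: table.index[r] for r, c in zip(rows, cols)}


def arm_sign_agreement(
    inferred_profile: pd.Series, true_fc: pd.Series
) -> tuple[float, int]:
    """Fraction of truly altered arms whose inferred deviation from 1 has the
    right direction. Returns (fraction, n_altered_arms)."""
    altered = true_fc.index[true_fc != 1.0]
    altered = altered.intersection(inferred_profile.index)
    if len(altered) == 0:
        raise ValidationError("no altered arms to evaluate")
    agree = (
        np.sign(inferred_profile.loc[altered] - 1.0) == np.sign(true_fc.loc[altered] - 1.0)
    )
    return float(agree.mean()), int(len(altered))


def profile_truth_correlation(
    inferred_profile: pd.Series,
    true_fc: pd.Series,
    signal_threshold: float = DEFAULT_SIGNAL_THRESHOLD,
) -> float:
    """Spearman correlation between an inferred arm profile and the true
    per-arm fold changes, with the same no-signal exclusion rule as
    :func:`concordance` (arms neutral in either profile are dropped: rank
    correlation over a profile that is mostly exact ties is meaningless)."""
    pair = pd.DataFrame({"inferred": inferred_profile, "truth": true_fc}).dropna()
    rho = concordance(pair.T, signal_threshold=signal_threshold)
    return float(rho.loc["inferred", "truth"])
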