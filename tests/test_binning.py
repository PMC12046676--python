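import numpy as np
import pandas as pd
import pytest

from spotcna.binning import (
    BinningConfig,
    aggregate_bins,
    assign_bins,
    bin_beads,
    cna_scores,
    pseudo_distance,
)
from spotcna.simulate import make_genome
from spotcna.types import IntensityMatrix, ValidationError

from conftest import build_se


def _intensities(arr, beads, genome):
    cols = list(genome.genes)[: arr.shape[1]]
    return IntensityMatrix(
        pd.DataFrame(arr, index=beads, columns=cols), "rescaled", genome.subset(cols)
    )


class TestPseudoDistance:
    def _setup(self):
        gp, _ = make_genome(n_genes=4, n_chromosomes=2)
        beads = ["b0", "b1"]
        coords = pd.DataFrame([[0.0, 0.0], [0.0, 2.0]], index=beads, columns=["x", "y"])
        expr = np.array([[1.0, 1.0, 1.0, 1.0], [1.0, 4.0, 1.0, 1.0]])  # distance 3
        return _intensities(expr, beads, gp), coords

    def test_hand_computed_combination(self):
        im, coords = self._setup()
        d = pseudo_distance(im, coords, BinningConfig(k_spatial=55, k_expression=1))
        assert d.loc["b0", "b1"] == pytest.approx(55 * 2 + 1 * 3)
        assert d.loc["b0", "b0"] == 0.0
        assert np.allclose(d.to_numpy(), d.to_numpy().T)

    def test_expression_weight_zero_is_pure_spatial(self):
        im, coords = self._setup()
        d = pseudo_distance(im, coords, BinningConfig(k_spatial=7, k_expression=0))
        assert d.loc["b0", "b1"] == pytest.approx(14.0)

    def test_non_spatial_mode_drops_spatial_term(self):
        im, coords = self._setup()
        d = pseudo_distance(im, coords, BinningConfig(spatial_mode=False))
        assert d.loc["b0", "b1"] == pytest.approx(3.0)


class TestAssignBins:
    def test_bin_count_from_beads_per_bin(self, rng):
        coords = rng.uniform(0, 100, size=(24, 2))
        from scipy.spatial.distance import pdist, squareform
        beads = [f"b{i}" for i in range(24)]
        pseudo = pd.DataFrame(squareform(pdist(coords)), index=beads, columns=beads)
        membership = assign_bins({"malignant": pseudo}, BinningConfig(beads_per_bin=12))
        assert membership.nunique() == 2

    def test_two_blobs_recovered(self):
        coords = np.array([[0, 0], [1, 0], [0, 1], [100, 100], [101, 100], [100, 101]],
                          dtype=float)
        from scipy.spatial.distance import pdist, squareform
        beads = [f"b{i}" for i in range(6)]
        pseudo = pd.DataFrame(squareform(pdist(coords)), index=beads, columns=beads)
        membership = assign_bins({"g": pseudo}, BinningConfig(beads_per_bin=3))
        assert membership["b0"] == membership["b1"] == membership["b2"]
        assert membership["b3"] == membership["b4"] == membership["b5"]
        assert membership["b0"] != membership["b3"]

    def test_singleton_group(self):
        pseudo = pd.DataFrame([[0.0]], index=["b0"], columns=["b0"])
        membership = assign_bins({"g": pseudo})
        assert membership.tolist() == [1]

    def test_groups_never_share_bins(self, rng):
        from scipy.spatial.distance import pdist, squareform
        groups = {}
        for name, n in (("malignant", 9), ("non_malignant", 7)):
            beads = [f"{name}_{i}" for i in range(n)]
            groups[name] = pd.DataFrame(
                squareform(pdist(rng.uniform(0, 10, size=(n, 2)))),
                index=beads, columns=beads,
            )
        membership = assign_bins(groups, BinningConfig(beads_per_bin=4))
        mal_bins = set(membership[membership.index.str.startswith("malignant")])
        nor_bins = set(membership[membership.index.str.startswith("non_malignant")])
        assert mal_bins.isdisjoint(nor_bins)
        assert len(membership) == 16


class TestAggregateAndScore:
    def _binset(self):
        gp, _ = make_genome(n_genes=2, n_chromosomes=2)
        se = build_se(
            [[8, 2], [6, 4], [5, 5], [100, 100]],
            bead_type=["malignant", "malignant", "non_reference_normal", "reference"],
        )
        im = _intensities(
            np.array([[0.8, 1.0], [1.0, 1.0], [1.2, 1.0], [1.0, 1.0]]),
            se.counts.index, gp,
        )
        membership = pd.Series([1, 1, 1, 2], index=se.counts.index)
        return im, se, membership

    def test_mean_mode_and_umi(self):
        im, se, membership = self._binset()
        binset = aggregate_bins(im, se, membership)
        assert binset.expression.loc[1].tolist() == [pytest.approx(1.0), pytest.approx(1.0)]
        assert binset.info.loc[1, "umi"] == 30
        assert binset.info.loc[1, "type"] == "malignant"  # 2 of 3 beads
        assert binset.info.loc[1, "x"] == pytest.approx(1.0)

    def test_type_tie_resolved_by_sort_order(self):
        gp, _ = make_genome(n_genes=2, n_chromosomes=2)
        se = build_se([[1, 1], [1, 1]], bead_type=["reference", "malignant"])
        im = _intensities(np.ones((2, 2)), se.counts.index, gp)
        binset = aggregate_bins(im, se, pd.Series([1, 1], index=se.counts.index))
        assert binset.info.loc[1, "type"] == "malignant"  # earliest in sort order

    def test_scores_capped(self):
        gp, _ = make_genome(n_genes=2, n_chromosomes=2)
        se = build_se([[10, 10], [10, 10]], bead_type=["malignant", "malignant"])
        im = _intensities(np.array([[1.7, 0.5], [1.7, 0.5]]), se.counts.index, gp)
        binset = aggregate_bins(im, se, pd.Series([1, 1], index=se.counts.index))
        scored = cna_scores(binset, BinningConfig())
        assert scored.cna.iloc[0].tolist() == [1.4, 0.6]

    def test_equal_umi_shrink_is_capping_only(self):
        gp, _ = make_genome(n_genes=2, n_chromosomes=2)
        se = build_se([[10, 10], [10, 10], [10, 10], [10, 10]],
                      bead_type=["malignant"] * 4)
        im = _intensities(np.array([[1.3, 0.8]] * 4), se.counts.index, gp)
        membership = pd.Series([1, 1, 2, 2], index=se.counts.index)
        binset = aggregate_bins(im, se, membership)
        scored = cna_scores(binset, BinningConfig(umi_scaling="shrink"))
        assert np.allclose(scored.cna.to_numpy(), [[1.3, 0.8], [1.3, 0.8]])

    def test_zero_umi_bin_rejected(self):
        gp, _ = make_genome(n_genes=2, n_chromosomes=2)
        se = build_se([[0, 0], [1, 1]], bead_type=["malignant", "malignant"])
        im = _intensities(np.ones((2, 2)), se.counts.index, gp)
        binset = aggregate_bins(im, se, pd.Series([1, 2], index=se.counts.index))
        with pytest.raises(ValidationError, match="zero UMI"):
            cna_scores(binset, BinningConfig())


class TestBinBeads:
    def _sim_se(self, rng, n=60):
        gp, _ = make_genome(n_genes=10, n_chromosomes=2)
        counts = rng.poisson(5, size=(n, 10))
        coords = rng.uniform(0, 1000, size=(n, 2))
        types = ["reference"] * (n // 2) + ["malignant"] * (n - n // 2)
        se = build_se(counts, bead_type=types, coords=coords)
        vals = rng.lognormal(0, 0.05, size=(n, 10))
        im = _intensities(vals, se.counts.index, gp)
        return im, se

    def test_partition_and_type_separation(self, rng):
        im, se = self._sim_se(rng)
        binset = bin_beads(im, se, BinningConfig(beads_per_bin=6))
        assert binset.info["n_beads"].sum() == se.n_beads
        assert set(binset.membership.index) == set(se.counts.index)
        for bin_id in binset.bin_ids:
            members = binset.membership.index[binset.membership == bin_id]
            is_mal = se.is_malignant.loc[members]
            assert is_mal.all() or (~is_mal).all()

    def test_expression_permutation_irrelevant_when_weight_zero(self, rng):
        im, se = self._sim_se(rng)
        cfg = BinningConfig(k_expression=0, beads_per_bin=6)
        binset1 = bin_beads(im, se, cfg)
        perm = rng.permutation(im.values.shape[0])
        im2 = IntensityMatrix(
            pd.DataFrame(im.values.to_numpy()[perm], index=im.values.index,
                         columns=im.values.columns),
            "rescaled", im.gene_order,
        )
        binset2 = bin_beads(im2, se, cfg)
        pd.testing.assert_series_equal(binset1.membership, binset2.membership)

    def test_spatial_spread_non_increasing_in_k_spatial(self, rng):
        im, se = self._sim_se(rng, n=120)
        # strong expression structure orthogonal to space
        vals = im.values.to_numpy()
        vals[::2] *= 3.0
        im = IntensityMatrix(pd.DataFrame(vals, index=im.values.index,
                                          columns=im.values.columns),
                             "rescaled", im.gene_order)
        spreads = []
        for k_spatial in (0, 5, 55, 500):
            binset = bin_beads(im, se, BinningConfig(k_spatial=k_spatial, beads_per_bin=8))
            spread = 0.0
            for bin_id in binset.bin_ids:
                members = binset.membership.index[binset.membership == bin_id]
                xy = se.coords.loc[members]
                spread += float(((xy - xy.mean()) ** 2).sum(axis=1).mean()) * len(members)
            spreads.append(spread / se.n_beads)
        assert all(a >= b - 1e-9 for a, b in zip(spreads, spreads[1:]))
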