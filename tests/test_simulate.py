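import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, spearmanr

from spotcna import simulate as sim
from spotcna.types import ValidationError


@pytest.fixture(scope="module")
def genome():
    gp, cent = sim.make_genome(n_genes=200, n_chromosomes=4)
    return gp


class TestSynthProfiles:
    def test_neutral_spec_indistinguishable_from_normal(self, genome):
        counts, labels, _ = sim.synth_profiles(
            genome, {"normal": 400, "clone1": 400}, {"clone1": {}}, rng=0
        )
        norm = counts[labels == "normal"].mean()
        clone = counts[labels == "clone1"].mean()
        # per-gene means agree within sampling error for ~99% of genes
        se = counts.std() * np.sqrt(2 / 400)
        z = (norm - clone).abs() / se
        assert (z < 3).mean() > 0.95

    def test_amplified_chromosome_doubles_means(self, genome):
        spec = {"clone1": {"1p": 2.0, "1q": 2.0}}
        counts, labels, fc = sim.synth_profiles(
            genome, {"normal": 2000, "clone1": 2000}, spec, rng=0
        )
        chr1 = genome.table.loc[genome.table["chromosome"] == "chr1", "gene"]
        ratio = (
            counts.loc[labels == "clone1", chr1].mean().sum()
            / counts.loc[labels == "normal", chr1].mean().sum()
        )
        assert ratio == pytest.approx(2.0, rel=0.05)
        assert fc.loc["clone1", "1p"] == 2.0 and fc.loc["normal", "1p"] == 1.0

    def test_negative_fold_change_rejected(self, genome):
        with pytest.raises(ValidationError, match="fold change"):
            sim.synth_profiles(genome, {"clone1": 5}, {"clone1": {"1p": -1.0}}, rng=0)

    def test_unknown_arm_rejected(self, genome):
        with pytest.raises(ValidationError, match="unknown arm"):
            sim.synth_profiles(genome, {"clone1": 5}, {"clone1": {"99z": 1.5}}, rng=0)


class TestPlaceCells:
    def _labels(self, n_normal=300, n_clone=300):
        labels = ["normal"] * n_normal + ["clone1"] * n_clone + ["clone2"] * n_clone
        return pd.Series(labels, index=[f"c{i}" for i in range(len(labels))])

    def test_separated_layout(self):
        cfg = sim.SimConfig(scenario="separated", seed=0)
        labels = self._labels()
        pos = sim.place_cells(labels, cfg, rng=0)
        normals = pos[labels == "normal"]
        malig = pos[labels != "normal"]
        assert (normals["y"] > 2700).all()
        assert (malig["y"] <= 2700).all()
        assert pos["x"].between(1, 3000).all() and pos["y"].between(1, 3000).all()

    def test_zone_gradient_endpoints(self):
        cfg = sim.SimConfig(scenario="separated", seed=0)
        labels = self._labels(n_normal=0, n_clone=3000)
        pos = sim.place_cells(labels, cfg, rng=0)
        zone = ((pos["x"] - 1) // 30 + 1).astype(int)
        # clone2 has weight z-1: absent from zone 1; clone1 absent from zone 100
        assert (zone[labels == "clone2"] > 1).all()
        assert (zone[labels == "clone1"] < 100).all()
        # opposing monotone gradients across zone means
        z1 = zone[labels == "clone1"].value_counts().sort_index()
        rho = spearmanr(z1.index, z1.values).statistic
        assert rho < -0.9

    def test_mixed_normals_uniform(self):
        cfg = sim.SimConfig(scenario="mixed", seed=0)
        labels = self._labels(n_normal=2000, n_clone=0)
        pos = sim.place_cells(labels, cfg, rng=1)
        stat = kstest(pos["y"] / 3000.0, "uniform")
        assert stat.pvalue > 0.01


class TestBeadsFromCells:
    def _one_cell_setup(self, genome):
        counts = pd.DataFrame([[5, 10] + [0] * 198], index=["c0"], columns=genome.genes)
        positions = pd.DataFrame({"x": [1500], "y": [1500]}, index=["c0"])
        labels = pd.Series(["clone1"], index=["c0"])
        fc = sim.arm_fold_change_table(genome, {"clone1": {}})
        return counts, positions, labels, fc

    def test_kernel_width_formula(self):
        cfg = sim.SimConfig()  # 6000 + 2*7000 = 20000 cells
        assert cfg.total_cells == 20000
        assert cfg.kernel_width == pytest.approx(10.6066, abs=1e-3)

    def test_single_cell_bead_profile_proportional(self, genome):
        counts, positions, labels, fc = self._one_cell_setup(genome)
        cfg = sim.SimConfig(n_beads=200, n_normal_cells=0, n_malignant_per_clone=0,
                            seed=0)
        se, truth = sim.beads_from_cells(counts, positions, labels, cfg, fc, rng=0)
        assert se.n_beads == 200
        # the only cell defines every bead: genes it lacks stay zero, and the
        # expressed genes keep its 1:2 ratio in aggregate
        assert (se.counts.iloc[:, 2:] == 0).all().all()
        g0, g1 = se.counts.iloc[:, 0].sum(), se.counts.iloc[:, 1].sum()
        assert g1 == pytest.approx(2 * g0, rel=0.15)
        assert (truth.bead_fractions["clone1"] == 1.0).all()
        assert (truth.bead_fractions.sum(axis=1) - 1.0).abs().max() < 1e-9

    def test_equidistant_cells_split_weight(self, genome):
        counts = pd.DataFrame(np.ones((2, 200), dtype=int), index=["c0", "c1"],
                              columns=genome.genes)
        positions = pd.DataFrame({"x": [1495.0, 1505.0], "y": [1500.0, 1500.0]},
                                 index=["c0", "c1"])
        labels = pd.Series(["clone1", "clone2"], index=["c0", "c1"])
        fc = sim.arm_fold_change_table(genome, {"clone1": {}, "clone2": {}})
        cfg = sim.SimConfig(n_beads=1, seed=0)
        rng = np.random.default_rng(0)
        # place the bead exactly between the two cells
        se, truth = sim.beads_from_cells(counts, positions, labels, cfg, fc,
                                         rng=np.random.default_rng(3))
        bead = truth.bead_fractions.index[0]
        x, y = se.coords.loc[bead]
        d0 = np.hypot(x - 1495, y - 1500)
        d1 = np.hypot(x - 1505, y - 1500)
        if abs(d0 - d1) < 1e-9:  # only symmetric placements are informative
            assert truth.bead_fractions.loc[bead, "clone1"] == pytest.approx(0.5)


class TestDownsample:
    def test_fraction_one_identity(self, genome):
        counts, labels, fc = sim.synth_profiles(genome, {"normal": 3}, {}, rng=0)
        se, _ = sim.beads_from_cells(
            counts, pd.DataFrame({"x": [1, 2, 3], "y": [1, 1, 1]}, index=counts.index),
            pd.Series(["normal"] * 3, index=counts.index),
            sim.SimConfig(n_beads=5, seed=0), sim.arm_fold_change_table(genome, {}),
            rng=0,
        )
        assert sim.downsample(se, 1.0, rng=0) is se

    def test_total_preserved_in_expectation(self, rng):
        from conftest import build_se
        counts = rng.poisson(20, size=(30, 40))
        se = build_se(counts)
        total = counts.sum()
        p = 0.1
        for seed in range(20):
            thin = sim.downsample(se, p, rng=seed)
            bound = 3 * np.sqrt(p * (1 - p) * total)
            assert abs(thin.counts.to_numpy().sum() - p * total) < bound
            assert (thin.counts.to_numpy() <= counts).all()

    def test_zero_stays_zero_and_bad_fraction(self):
        from conftest import build_se
        se = build_se(np.zeros((3, 3), dtype=int) + [[0, 1, 2]] * 3)
        thin = sim.downsample(se, 0.5, rng=0)
        assert (thin.counts.iloc[:, 0] == 0).all()
        with pytest.raises(ValidationError):
            sim.downsample(se, 0.0, rng=0)


SMALL_CNA_SPEC = {"clone1": {"1p": 1.5, "2q": 0.5}, "clone2": {"3q": 1.5, "4p": 0.5}}


@pytest.fixture(scope="module")
def bundle():
    cfg = sim.SimConfig(n_beads=600, n_normal_cells=1000, n_malignant_per_clone=1200,
                        scenario="separated", downsample_fraction=0.25, seed=2)
    return sim.simulate_dataset(cfg, n_genes=300, n_chromosomes=5,
                                clone_cna_spec=SMALL_CNA_SPEC)


class TestFullBundle:

    def test_populations_present(self, bundle):
        assert bundle.se.is_reference.sum() > 0
        assert bundle.se.is_malignant.sum() > 0
        assert bundle.se.n_genes == 300

    def test_clone_fractions_sum_to_one(self, bundle):
        sums = bundle.truth.bead_fractions.sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_gradient_monotone_in_x(self, bundle):
        frac = bundle.truth.bead_fractions
        malignant = frac["clone1"] + frac["clone2"] > 0
        share = (frac["clone1"] / (frac["clone1"] + frac["clone2"]))[malignant]
        zones = (bundle.se.coords.loc[share.index, "x"] // 300).astype(int)
        zone_means = share.groupby(zones).mean()
        rho = spearmanr(zone_means.index, zone_means.values).statistic
        assert rho < -0.95

    def test_determinism(self, bundle):
        cfg = sim.SimConfig(n_beads=600, n_normal_cells=1000, n_malignant_per_clone=1200,
                            scenario="separated", downsample_fraction=0.25, seed=2)
        again = sim.simulate_dataset(cfg, n_genes=300, n_chromosomes=5,
                                     clone_cna_spec=SMALL_CNA_SPEC)
        pd.testing.assert_frame_equal(bundle.se.counts, again.se.counts)
        pd.testing.assert_frame_equal(bundle.truth.bead_fractions, again.truth.bead_fractions)
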