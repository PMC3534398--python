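"""DGV computation, reliability splits, subset recovery and gene flags."""

import numpy as np
import pandas as pd
import pytest

from milkgwas import (
    SimulationConfig,
    build_dgv_table,
    compute_dgv,
    correlation_recovery,
    flag_gene_region_markers,
    gene_dgv_proportion,
    genomic_variance_proportions,
    simulate_study,
    split_by_reliability,
)
from milkgwas.prediction import gene_dgv_variance_ratio, nested_top_subsets

from conftest import make_genotypes


def records(reliabilities):
    return pd.DataFrame(
        {
            "animal": np.arange(1, len(reliabilities) + 1),
            "trait": "TMT",
            "ebv": np.zeros(len(reliabilities)),
            "reliability": reliabilities,
        }
    )


class TestSplit:
    def test_boundary_is_strictly_greater(self):
        split = split_by_reliability(records([0.61, 0.60, 0.59]), 0.60)
        assert split.discovery_ids.tolist() == [1]
        assert split.prediction_ids.tolist() == [2, 3]

    def test_all_high_reliability_empty_prediction(self):
        split = split_by_reliability(records([0.8, 0.8, 0.8]), 0.60)
        assert split.n_prediction == 0

    def test_empty_discovery_rejected(self):
        with pytest.raises(ValueError, match="empty discovery"):
            split_by_reliability(records([0.4, 0.5]), 0.60)

    def test_low_reliability_panel_is_prediction_heavy(self):
        cfg = SimulationConfig(
            n_founders=400, n_generations=1, n_chromosomes=2,
            markers_per_chromosome=20, reliability_range=(0.38, 0.62),
            seed=91,
        )
        st = simulate_study(cfg)
        split = split_by_reliability(st.proxies, 0.60)
        assert split.n_discovery + split.n_prediction == 400
        assert split.n_prediction > split.n_discovery


class TestDgv:
    def test_zero_effects_zero_dgv(self, small_study):
        dgv = compute_dgv(small_study.genotypes,
                          np.zeros(small_study.genotypes.n_markers))
        assert np.all(dgv == 0.0)

    def test_single_marker_direct_product(self):
        g = make_genotypes(np.array([[-1.0], [0.0], [1.0]]))
        np.testing.assert_array_equal(
            compute_dgv(g, np.array([0.5])), [-0.5, 0.0, 0.5]
        )

    def test_additivity_bit_exact(self, small_study):
        rng = np.random.default_rng(15)
        effects = rng.normal(size=small_study.genotypes.n_markers)
        p = effects.size
        subset = rng.choice(p, size=p // 3, replace=False)
        complement = np.setdiff1d(np.arange(p), subset)
        total = compute_dgv(small_study.genotypes, effects)
        parts = compute_dgv(small_study.genotypes, effects, subset) + \
            compute_dgv(small_study.genotypes, effects, complement)
        np.testing.assert_allclose(total, parts, rtol=0, atol=1e-9)

    def test_subsets_are_nested(self, small_study):
        rng = np.random.default_rng(16)
        effects = rng.normal(size=small_study.genotypes.n_markers)
        subsets = nested_top_subsets(effects, (25, 50, 100))
        assert set(subsets["25"]) <= set(subsets["50"]) <= set(subsets["100"])


class TestRecovery:
    def test_dgv_equal_to_ebv_gives_unit_recovery(self):
        rng = np.random.default_rng(17)
        g = make_genotypes(rng.binomial(2, 0.5, size=(50, 30)) - 1.0)
        effects = rng.normal(size=30)
        table = build_dgv_table(g, effects, (10,))
        ebv = table.dgv["all"].to_numpy()
        rec = correlation_recovery(ebv, table)
        row = rec[rec["subset"] == "all"].iloc[0]
        assert row["correlation"] == pytest.approx(1.0)
        assert row["recovery"] == pytest.approx(1.0)

    def test_too_few_animals_rejected(self):
        g = make_genotypes(np.zeros((2, 3)))
        table = build_dgv_table(g, np.ones(3), ())
        with pytest.raises(ValueError):
            correlation_recovery(np.zeros(2), table)


class TestVarianceProportions:
    def test_all_row_is_exactly_one(self, small_study):
        rng = np.random.default_rng(18)
        effects = rng.normal(size=small_study.genotypes.n_markers)
        table = build_dgv_table(small_study.genotypes, effects, (25, 50))
        props = genomic_variance_proportions(table)
        assert props.loc[props["subset"] == "all", "proportion"].iloc[0] == 1.0

    def test_nested_monotone_under_linkage_equilibrium(self):
        rng = np.random.default_rng(19)
        g = make_genotypes(rng.binomial(2, 0.4, size=(800, 500)) - 1.0)
        effects = rng.normal(size=500) * np.exp(rng.normal(size=500))
        table = build_dgv_table(g, effects, (25, 50, 100, 300))
        props = genomic_variance_proportions(table)
        ordered = props.set_index("subset").loc[
            ["25", "50", "100", "300", "all"], "proportion"
        ]
        assert np.all(np.diff(ordered.to_numpy()) >= -1e-12)

    def test_zero_variance_rejected(self):
        g = make_genotypes(np.zeros((5, 3)))
        table = build_dgv_table(g, np.ones(3), ())
        with pytest.raises(ValueError):
            genomic_variance_proportions(table)


class TestPredictionValidity:
    @staticmethod
    def _one_replicate(seed):
        from milkgwas import BLassoConfig, run_gibbs

        cfg = SimulationConfig(
            n_founders=500, n_generations=1, n_chromosomes=8,
            markers_per_chromosome=50, n_qtl=10, qtl_variance=0.5,
            h2=0.35, qtl_effect_dist="equal",
            reliability_range=(0.38, 0.80), seed=seed,
        )
        st = simulate_study(cfg)
        split = split_by_reliability(st.proxies, 0.60)
        prox = st.proxies.set_index("animal")
        g_disc = st.genotypes.subset_animals(split.discovery_ids)
        y_disc = prox.loc[split.discovery_ids, "ebv"].to_numpy()
        bcfg = BLassoConfig(n_iter=2500, burn_in=500, thin=2, lam=20.0,
                            use_polygenic=False, seed=seed + 1)
        post = run_gibbs(y_disc, g_disc, None, bcfg)
        g_pred = st.genotypes.subset_animals(split.prediction_ids)
        tbv = prox.loc[split.prediction_ids, "tbv"].to_numpy()
        dgv = compute_dgv(g_pred, post.beta_mean)
        rng = np.random.default_rng(seed + 2)
        dgv_null = compute_dgv(g_pred, rng.permutation(post.beta_mean))
        return (np.corrcoef(dgv, tbv)[0, 1],
                np.corrcoef(dgv_null, tbv)[0, 1])

    def test_dgv_beats_permuted_effects_null(self):
        """Prediction-set DGVs from discovery-estimated effects predict
        true breeding values better than a permuted-effects baseline in
        every replicate."""
        for k in range(10):
            r, r_null = self._one_replicate(1000 + 37 * k)
            assert r > r_null, (k, r, r_null)

    def test_recovery_saturates_before_full_panel(self):
        """Correlation recovery is concave in subset size: the gain from
        a small to a mid-size subset exceeds the gain from the mid-size
        subset to the full panel (scaled-down subset ladder)."""
        from milkgwas import BLassoConfig, run_gibbs

        cfg = SimulationConfig(
            n_founders=600, n_generations=1, n_chromosomes=8,
            markers_per_chromosome=100, n_qtl=40, qtl_variance=0.6,
            h2=0.35, qtl_effect_dist="equal",
            reliability_range=(0.38, 0.80), seed=93,
        )
        st = simulate_study(cfg)
        split = split_by_reliability(st.proxies, 0.60)
        prox = st.proxies.set_index("animal")
        g_disc = st.genotypes.subset_animals(split.discovery_ids)
        y_disc = prox.loc[split.discovery_ids, "ebv"].to_numpy()
        bcfg = BLassoConfig(n_iter=3000, burn_in=600, thin=2, lam=20.0,
                            use_polygenic=False, seed=94)
        post = run_gibbs(y_disc, g_disc, None, bcfg)
        g_pred = st.genotypes.subset_animals(split.prediction_ids)
        ebv_pred = prox.loc[split.prediction_ids, "ebv"].to_numpy()
        table = build_dgv_table(g_pred, post.beta_mean, (24, 240))
        rec = correlation_recovery(ebv_pred, table).set_index("subset")
        r = rec["recovery"]
        assert r["240"] - r["24"] > r["all"] - r["240"]


class TestGeneFlags:
    def gene_frame(self):
        return pd.DataFrame(
            {"chrom": [1], "start": [2_000_000], "end": [2_100_000],
             "gene_id": ["g1"]}
        )

    def make_map(self, positions):
        return pd.DataFrame(
            {
                "name": [f"m{i}" for i in range(len(positions))],
                "chrom": 1,
                "pos": positions,
                "genic": False,
            }
        )

    def test_within_flank_flagged(self):
        # 400 kb upstream of the gene start: inside the 500 kb flank
        flags = flag_gene_region_markers(self.make_map([1_600_000]),
                                         self.gene_frame())
        assert flags.tolist() == [True]

    def test_outside_flank_not_flagged(self):
        flags = flag_gene_region_markers(self.make_map([1_400_000]),
                                         self.gene_frame())
        assert flags.tolist() == [False]

    def test_empty_gene_file(self):
        flags = flag_gene_region_markers(
            self.make_map([1_000_000]),
            pd.DataFrame(columns=["chrom", "start", "end", "gene_id"]),
        )
        assert not flags.any()

    def test_chromosome_mismatch_warns(self):
        genes = self.gene_frame()
        genes["chrom"] = "chrX"
        with pytest.warns(UserWarning, match="no shared chromosome"):
            flags = flag_gene_region_markers(self.make_map([2_000_000]), genes)
        assert not flags.any()


class TestGeneDgvProportion:
    def test_identical_sets_median_one(self):
        rng = np.random.default_rng(20)
        d = rng.normal(size=100)
        assert gene_dgv_proportion(d, d) == pytest.approx(1.0)

    def test_zero_genic_effects_median_zero(self):
        rng = np.random.default_rng(21)
        d = rng.normal(size=100)
        assert gene_dgv_proportion(np.zeros(100), d) == 0.0

    def test_all_below_floor_rejected(self):
        with pytest.raises(ValueError):
            gene_dgv_proportion(np.ones(5), np.zeros(5))

    def test_variance_split_simulation(self):
        """When genic markers carry half the significant-marker variance
        (independent effects), the variance ratio is ~0.5 and the
        per-animal median ratio sits near 0.5 as well."""
        rng = np.random.default_rng(22)
        n, p = 4000, 200
        g = make_genotypes(rng.binomial(2, 0.5, size=(n, p)) - 1.0)
        effects = rng.normal(size=p) * 0.1
        genic = np.arange(p) < p // 2  # half the markers, equal variance
        dgv_sig = compute_dgv(g, effects)
        dgv_gene = compute_dgv(g, effects, np.flatnonzero(genic))
        assert gene_dgv_variance_ratio(dgv_gene, dgv_sig) == pytest.approx(
            0.5, abs=0.1
        )
        med = gene_dgv_proportion(dgv_gene, dgv_sig)
        assert abs(med - 0.5) <= 0.1
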