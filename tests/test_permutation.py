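"""Within-chain permutation: null chain, critical values, declarations."""

import numpy as np
import pytest

from milkgwas import (
    BLassoConfig,
    PermutationConfig,
    SimulationConfig,
    critical_values,
    declare_significant,
    run_gibbs,
    run_permuted_chain,
    select_top_effects,
    simulate_study,
)
from milkgwas.gwas import MarkerEffectPosterior


def posterior_from_beta(beta):
    beta = np.asarray(beta, dtype=float)
    return MarkerEffectPosterior(
        beta_mean=beta, beta_sd=np.zeros_like(beta),
        beta_samples=np.vstack([beta, beta]), mu_samples=np.zeros(2),
        sigma2_e_samples=np.ones(2), sigma2_s_samples=np.ones(2),
        lambda_samples=np.ones(2),
    )


@pytest.fixture(scope="module")
def qtl_study():
    cfg = SimulationConfig(
        n_founders=300, n_generations=1, n_chromosomes=4,
        markers_per_chromosome=50, n_qtl=2, qtl_variance=0.9, h2=0.5,
        qtl_effect_dist="equal", reliability_range=(0.9, 0.9), seed=55,
    )
    return simulate_study(cfg)


class TestPermutedChain:
    def test_h_exceeding_length_rejected(self, qtl_study):
        bcfg = BLassoConfig(n_iter=200, burn_in=50, thin=1, lam=20.0,
                            use_polygenic=False)
        pcfg = PermutationConfig(h=500, n_iter=200, burn_in=50)
        with pytest.raises(ValueError):
            run_permuted_chain(
                qtl_study.proxies["ebv"].to_numpy(), qtl_study.genotypes,
                None, bcfg, pcfg,
            )

    def test_h_equal_length_is_single_permutation(self, qtl_study):
        # one reshuffle for the whole chain = across-chain permutation
        y = qtl_study.proxies["ebv"].to_numpy()
        bcfg = BLassoConfig(n_iter=400, burn_in=100, thin=1, lam=20.0,
                            use_polygenic=False, seed=2)
        pcfg = PermutationConfig(h=400, n_iter=400, burn_in=100, seed=2)
        null = run_permuted_chain(y, qtl_study.genotypes, None, bcfg, pcfg)
        assert null.n_stored == 300

    def test_planted_qtl_null_centers_on_zero(self, qtl_study):
        y = qtl_study.proxies["ebv"].to_numpy()
        bcfg = BLassoConfig(n_iter=3000, burn_in=500, thin=2, lam=20.0,
                            use_polygenic=False, seed=3)
        pcfg = PermutationConfig(h=3, n_iter=3000, burn_in=500, seed=4)
        null = run_permuted_chain(y, qtl_study.genotypes, None, bcfg, pcfg)
        for q in qtl_study.effects.qtl_indices:
            draws = null.beta_samples[:, q]
            se = draws.std() / np.sqrt(draws.size)  # conservative MC error
            assert abs(draws.mean()) < 3 * draws.std() / np.sqrt(
                max(1.0, draws.size / 20)
            ), f"null draws for QTL {q} not centered: {draws.mean():.4f}"
        # while the observed chain shows the QTL clearly
        post = run_gibbs(y, qtl_study.genotypes, None, bcfg)
        q0 = qtl_study.effects.qtl_indices[0]
        assert abs(post.beta_mean[q0]) > np.abs(null.beta_samples[:, q0]).mean()

    def test_seeded_determinism(self, qtl_study):
        y = qtl_study.proxies["ebv"].to_numpy()
        bcfg = BLassoConfig(n_iter=300, burn_in=50, thin=1, lam=20.0,
                            use_polygenic=False, seed=6)
        pcfg = PermutationConfig(h=3, n_iter=300, burn_in=50, seed=6)
        n1 = run_permuted_chain(y, qtl_study.genotypes, None, bcfg, pcfg)
        n2 = run_permuted_chain(y, qtl_study.genotypes, None, bcfg, pcfg)
        np.testing.assert_array_equal(n1.beta_samples, n2.beta_samples)


class TestCriticalValues:
    def test_percentile_ranks_alpha_005(self):
        # 0.25 alpha rule: alpha = 0.05 -> (1.25%, 98.75%)
        draws = np.linspace(0, 1, 10001)[:, None]
        lo, hi = critical_values(draws, alpha=0.05)
        assert lo[0] == pytest.approx(0.0125, abs=1e-4)
        assert hi[0] == pytest.approx(0.9875, abs=1e-4)

    def test_percentile_ranks_alpha_0001(self):
        draws = np.linspace(0, 1, 100001)[:, None]
        lo, hi = critical_values(draws, alpha=0.001)
        assert lo[0] == pytest.approx(0.00025, abs=1e-4)
        assert hi[0] == pytest.approx(0.99975, abs=1e-4)

    def test_symmetric_null_gives_symmetric_bounds(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=20000)
        draws = np.concatenate([z, -z])[:, None]  # exactly symmetric
        lo, hi = critical_values(draws, alpha=0.05)
        assert lo[0] == pytest.approx(-hi[0], abs=1e-10)

    def test_pooled_scope_broadcasts(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(size=(50, 10))
        lo, hi = critical_values(draws, alpha=0.05, scope="pooled")
        assert np.all(lo == lo[0]) and np.all(hi == hi[0])

    def test_small_per_marker_sample_rejected(self):
        with pytest.raises(ValueError):
            critical_values(np.zeros((50, 3)), alpha=0.05)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            critical_values(np.zeros((0, 3)), alpha=0.05)


class TestDeclare:
    def test_inside_bounds_not_significant(self):
        post = posterior_from_beta([0.0])
        res = declare_significant(post, (np.array([-0.1]), np.array([0.1])))
        assert res.n_significant == 0

    def test_outside_bounds_significant(self):
        post = posterior_from_beta([2.5])
        res = declare_significant(post, (np.array([-2.0]), np.array([2.0])))
        assert res.n_significant == 1

    def test_marker_mismatch_rejected(self):
        post = posterior_from_beta([0.0, 1.0])
        with pytest.raises(ValueError):
            declare_significant(post, (np.array([-0.1]), np.array([0.1])))

    def test_alpha_nesting_of_bounds(self, qtl_study):
        y = qtl_study.proxies["ebv"].to_numpy()
        bcfg = BLassoConfig(n_iter=2000, burn_in=500, thin=2, lam=20.0,
                            use_polygenic=False, seed=8)
        pcfg = PermutationConfig(h=3, n_iter=2000, burn_in=500, seed=9)
        null = run_permuted_chain(y, qtl_study.genotypes, None, bcfg, pcfg)
        lo5, hi5 = critical_values(null, 0.05)
        lo1, hi1 = critical_values(null, 0.001)
        assert np.all(lo1 <= lo5) and np.all(hi1 >= hi5)

    def test_null_rejection_rate_conservative(self):
        """The printed percentile rule is conservative for posterior
        means: under a global null the flagged fraction stays below the
        nominal level."""
        cfg = SimulationConfig(
            n_founders=300, n_generations=1, n_chromosomes=4,
            markers_per_chromosome=100, n_qtl=0, h2=0.0, seed=66,
        )
        st = simulate_study(cfg)
        rng = np.random.default_rng(67)
        y = rng.normal(size=300)
        bcfg = BLassoConfig(n_iter=4000, burn_in=800, thin=2, lam=25.0,
                            use_polygenic=False, seed=68)
        post = run_gibbs(y, st.genotypes, None, bcfg)
        pcfg = PermutationConfig(h=3, n_iter=4000, burn_in=800, seed=69)
        null = run_permuted_chain(y, st.genotypes, None, bcfg, pcfg)
        res = declare_significant(post, critical_values(null, 0.05))
        assert res.significant_fraction <= 0.05

    def test_power_monotone_in_effect_size(self):
        """A planted QTL's flagged status is non-decreasing across three
        nested effect sizes."""
        flags = []
        for qv in (0.02, 0.3, 0.9):
            cfg = SimulationConfig(
                n_founders=400, n_generations=1, n_chromosomes=2,
                markers_per_chromosome=50, n_qtl=1, qtl_variance=qv,
                h2=0.5, qtl_effect_dist="equal",
                reliability_range=(0.9, 0.9), seed=70,
            )
            st = simulate_study(cfg)
            y = st.proxies["ebv"].to_numpy()
            bcfg = BLassoConfig(n_iter=3000, burn_in=600, thin=2, lam=15.0,
                                use_polygenic=False, seed=71)
            post = run_gibbs(y, st.genotypes, None, bcfg)
            null = run_permuted_chain(
                y, st.genotypes, None, bcfg,
                PermutationConfig(h=3, n_iter=3000, burn_in=600, seed=72),
            )
            res = declare_significant(post, critical_values(null, 0.05))
            q = st.effects.qtl_indices[0]
            flags.append(bool(res.table["significant"].iloc[q]))
        assert flags == sorted(flags)  # non-decreasing
        assert flags[-1]  # the strong QTL is detected


class TestTopEffects:
    def test_k_at_least_panel_returns_all_sorted(self):
        post = posterior_from_beta([0.5, -0.9, 0.1])
        top = select_top_effects(post, 10)
        assert list(top["panel_index"]) == [1, 0, 2]

    def test_absolute_value_ordering(self):
        post = posterior_from_beta([0.5, -0.9, 0.1])
        top = select_top_effects(post, 2)
        assert list(top["panel_index"]) == [1, 0]

    def test_ties_break_by_panel_order(self):
        post = posterior_from_beta([0.5, -0.5, 0.5])
        top = select_top_effects(post, 3)
        assert list(top["panel_index"]) == [0, 1, 2]

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            select_top_effects(posterior_from_beta([1.0]), 0)
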