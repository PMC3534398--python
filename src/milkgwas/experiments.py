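"""Reference validation experiments for the pipeline.

Each function runs one self-contained simulation experiment that
exercises a pipeline property end to end — sampler correctness against
numerical quadrature, permutation-null behaviour under a global null,
planted-QTL recovery, BayesC-pi mixture recovery and its agreement with
the permutation approach — and returns the measured quantities.  The
experiments are deterministic given their seed.

Problem sizes are desk-scale: chains are far shorter than the reference
long-chain protocol, sized so each experiment completes in minutes on
one CPU; the measured quantities are stable at these lengths.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .cpi import CpiConfig, run_bayescpi
from .gwas import BLassoConfig, estimate_lambda, run_gibbs
from .permutation import (
    PermutationConfig,
    critical_values,
    declare_significant,
    run_permuted_chain,
    select_top_effects,
)
from .sim import SimulationConfig, simulate_study


def _quadrature_beta_mean(y, x, lam, sigma2_e):
    """Grid quadrature of the exact posterior over (beta, tau2) under the
    double-exponential hierarchy."""
    xtx, xty = x @ x, x @ y
    B = np.linspace(-3, 3, 1501)
    T = np.linspace(1e-4, 40, 3001)
    BB, TT = np.meshgrid(B, T, indexing="ij")
    lp = (
        -0.5 * (xtx * BB**2 - 2 * BB * xty) / sigma2_e
        - 0.5 * BB**2 / (TT * sigma2_e)
        - 0.5 * np.log(TT)
        - 0.5 * lam**2 * TT
    )
    w = np.exp(lp - lp.max())
    z = np.trapezoid(np.trapezoid(w, T, axis=1), B)
    return float(np.trapezoid(np.trapezoid(w * BB, T, axis=1), B) / z)


def _toy_panel(x):
    import pandas as pd

    from .types import GenotypeMatrix

    x = np.asarray(x, dtype=float)
    n, p = x.shape
    return GenotypeMatrix(
        animal_ids=np.arange(1, n + 1),
        marker_map=pd.DataFrame(
            {"name": [f"m{j}" for j in range(p)], "chrom": 1,
             "pos": np.arange(1, p + 1) * 1000, "genic": False}
        ),
        geno=x,
    )


def sampler_quadrature_check(seed: int) -> dict:
    """Single-marker model (n=20), residual variance fixed, no polygenic
    term: Gibbs posterior mean of beta vs 2-D quadrature."""
    rng = np.random.default_rng(seed)
    n, lam, s2e = 20, 2.0, 1.0
    x = rng.integers(0, 3, size=n).astype(float) - 1.0
    x -= x.mean()
    y = 0.4 * x + rng.normal(size=n)
    cfg = BLassoConfig(
        n_iter=40_000, burn_in=4_000, thin=4, lam=lam, use_polygenic=False,
        update_mu=False, fixed_sigma2_e=s2e, seed=seed + 1,
    )
    post = run_gibbs(y, _toy_panel(x[:, None]), None, cfg)
    quad = _quadrature_beta_mean(y, x, lam, s2e)
    return {
        "gibbs": float(post.beta_mean[0]),
        "quadrature": quad,
        "abs_error": abs(float(post.beta_mean[0]) - quad),
        "n": n,
    }


def intercept_recovery_check(seed: int) -> dict:
    """Intercept-only model recovers the sample mean."""
    rng = np.random.default_rng(seed)
    y = rng.normal(size=60) + 3.0
    cfg = BLassoConfig(n_iter=6000, burn_in=1000, thin=2, lam=5.0,
                       use_polygenic=False, seed=seed + 1)
    post = run_gibbs(y, _toy_panel(np.zeros((60, 1))), None, cfg)
    mu = float(post.mu_samples.mean()) + y.mean()
    return {"mu": mu, "sample_mean": float(y.mean()),
            "abs_error": abs(mu - y.mean()), "n": 60}


def global_null_config(seed: int) -> SimulationConfig:
    """1,000 unrelated genotyped sires, 2,000 markers, no QTL, no
    polygenic signal."""
    return SimulationConfig(
        n_founders=1000, n_generations=1, n_chromosomes=20,
        markers_per_chromosome=100, n_qtl=0, h2=0.0, seed=seed,
    )


def permutation_calibration(seed: int, n_iter: int = 20_000) -> dict:
    """Global-null calibration of the within-chain permutation test.

    Runs the full protocol (exploratory-chain lambda, observed chain,
    permuted chain with h=3) and measures the fraction of markers whose
    posterior-mean effect falls outside the alpha=0.05 percentile band,
    plus whether the alpha=0.001 band contains the alpha=0.05 band.
    """
    cfg = global_null_config(seed)
    st = simulate_study(cfg)
    rng = np.random.default_rng(seed + 1)
    y = rng.normal(size=cfg.n_founders)
    bcfg = BLassoConfig(
        n_iter=n_iter, burn_in=max(n_iter // 10, 1), thin=3,
        use_polygenic=False, n_exploratory_chains=1,
        exploratory_length=3000, seed=seed + 2,
    )
    lam, _ = estimate_lambda(y, st.genotypes, None, bcfg)
    bcfg = bcfg.with_(lam=lam)
    post = run_gibbs(y, st.genotypes, None, bcfg)
    pcfg = PermutationConfig(h=3, n_iter=n_iter, burn_in=bcfg.burn_in,
                             seed=seed + 3)
    null = run_permuted_chain(y, st.genotypes, None, bcfg, pcfg)
    res = declare_significant(post, critical_values(null, 0.05))
    lo5, hi5 = critical_values(null, 0.05)
    lo1, hi1 = critical_values(null, 0.001)
    return {
        "rejection_rate": res.significant_fraction,
        "lambda": lam,
        "alpha_bands_nested": bool(np.all(lo1 <= lo5) and np.all(hi1 >= hi5)),
        "n": cfg.n_founders,
        "p": st.genotypes.n_markers,
    }


def recovery_config(seed: int) -> SimulationConfig:
    """1,000 unrelated sires, 2,000 markers, 10 equal-variance QTL
    jointly carrying 10% of phenotypic variance (1% each), h2=0.35,
    EBV reliabilities in the default (0.38, 0.60) range."""
    return SimulationConfig(
        n_founders=1000, n_generations=1, n_chromosomes=20,
        markers_per_chromosome=100, n_qtl=10, qtl_variance=0.2857,
        h2=0.35, qtl_effect_dist="equal", seed=seed,
    )


def qtl_recovery_replicate(seed: int, n_iter: int = 6000) -> dict:
    """One recovery replicate: hits = planted QTL with a top-50 |beta|
    marker within 5 panel positions."""
    st = simulate_study(recovery_config(seed))
    y = st.proxies["ebv"].to_numpy()
    bcfg = BLassoConfig(
        n_iter=n_iter, burn_in=n_iter // 5, thin=3, use_polygenic=False,
        n_exploratory_chains=1, exploratory_length=1500, seed=seed + 1,
    )
    lam, _ = estimate_lambda(y, st.genotypes, None, bcfg)
    post = run_gibbs(y, st.genotypes, None, bcfg.with_(lam=lam))
    top50 = set(select_top_effects(post, 50)["panel_index"])
    hits = sum(
        1 for q in st.effects.qtl_indices
        if any(abs(t - q) <= 5 for t in top50)
    )
    return {"hits": hits, "lambda": lam, "n": 1000, "p": 2000}


def qtl_recovery(seed: int, n_replicates: int = 10) -> dict:
    hits = [qtl_recovery_replicate(seed + 97 * k)["hits"]
            for k in range(n_replicates)]
    return {
        "hits": hits,
        "replicates_passing": int(sum(h >= 8 for h in hits)),
        "n_replicates": n_replicates,
    }


def cpi_recovery(seed: int) -> dict:
    """pi_true = 0.95: 100 causal of 2,000 markers, n = 1,000."""
    cfg = SimulationConfig(
        n_founders=1000, n_generations=1, n_chromosomes=20,
        markers_per_chromosome=100, n_qtl=100, qtl_variance=0.8, h2=0.35,
        seed=seed,
    )
    st = simulate_study(cfg)
    res = run_bayescpi(
        st.proxies["ebv"].to_numpy(), st.genotypes, None,
        CpiConfig(n_iter=6000, burn_in=1200, thin=3, use_polygenic=False,
                  seed=seed + 1),
    )
    return {"pi_hat": res.pi_mean, "pi_true": 0.95, "n": 1000, "p": 2000}


#: signal levels spanning null to strong for the agreement experiment
AGREEMENT_SETTINGS = (
    (0, 0.0), (2, 0.3), (5, 0.5), (10, 0.7), (15, 0.9)
)


def cpi_permutation_agreement(seed: int) -> dict:
    """(1 - pi_hat) against the permutation significant-marker fraction
    across signal settings; reports their Spearman rank correlation."""
    fracs, nonnull = [], []
    for k, (n_qtl, qv) in enumerate(AGREEMENT_SETTINGS):
        cfg = SimulationConfig(
            n_founders=500, n_generations=1, n_chromosomes=10,
            markers_per_chromosome=50, n_qtl=n_qtl, qtl_variance=qv,
            h2=0.35, qtl_effect_dist="equal", seed=seed + 11 * k,
        )
        st = simulate_study(cfg)
        y = st.proxies["ebv"].to_numpy()
        bcfg = BLassoConfig(
            n_iter=4000, burn_in=800, thin=2, use_polygenic=False,
            n_exploratory_chains=1, exploratory_length=1000,
            seed=seed + 11 * k + 1,
        )
        lam, _ = estimate_lambda(y, st.genotypes, None, bcfg)
        bcfg = bcfg.with_(lam=lam)
        post = run_gibbs(y, st.genotypes, None, bcfg)
        null = run_permuted_chain(
            y, st.genotypes, None, bcfg,
            PermutationConfig(h=3, n_iter=4000, burn_in=800,
                              seed=seed + 11 * k + 2),
        )
        res = declare_significant(post, critical_values(null, 0.05))
        cres = run_bayescpi(
            y, st.genotypes, None,
            CpiConfig(n_iter=4000, burn_in=800, thin=2,
                      use_polygenic=False, seed=seed + 11 * k + 3),
        )
        fracs.append(res.significant_fraction)
        nonnull.append(1.0 - cres.pi_mean)
    rho = float(stats.spearmanr(fracs, nonnull)[0])
    return {
        "significant_fractions": fracs,
        "one_minus_pi": nonnull,
        "rank_correlation": rho,
        "n_settings": len(AGREEMENT_SETTINGS),
    }
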