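"""Bayesian-LASSO GWAS: relationship matrix, Gibbs sampler front-end,
shrinkage-parameter estimation and posterior summaries.

The model regresses de-regressed proofs y on all SNP genotypes jointly:

    y = mu + s + X beta + e

with s ~ N(0, A sigma2_s) a polygenic sire effect (A the pedigree
numerator relationship matrix, guarding against spurious associations
from population structure), e ~ N(0, I sigma2_e), and the
Park-Casella hierarchy on marker effects:

    beta_j | tau2_j, sigma2_e ~ N(0, tau2_j sigma2_e)
    tau2_j ~ Exponential(lambda^2 / 2)

which marginally places a double-exponential (Laplace) prior on each
beta_j.  lambda is either fixed, or averaged over several short
exploratory chains in which lambda^2 carries a diffuse gamma prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

try:  # pragma: no cover - exercised implicitly
    import arviz as az
except Exception:  # pragma: no cover
    az = None

from . import _kernels
from .types import GenotypeMatrix, Pedigree, RelationshipMatrix


def build_numerator_relationship(
    pedigree: Pedigree, subset: np.ndarray | None = None
) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    A is computed over the full pedigree (recursively from parent rows)
    and then restricted to ``subset`` so ancestral ties between subset
    animals are preserved.  Inbreeding from the pedigree is accounted
    for: diagonal entries are 1 + F.
    """
    n = len(pedigree)
    pos = pedigree.indices()
    sire_idx = np.array(
        [pos[s] if s != 0 else -1 for s in pedigree.sire], dtype=np.int64
    )
    dam_idx = np.array(
        [pos[d] if d != 0 else -1 for d in pedigree.dam], dtype=np.int64
    )
    if np.any(sire_idx >= np.arange(n)) or np.any(dam_idx >= np.arange(n)):
        raise ValueError("pedigree not topologically ordered (possible cycle)")
    A = _tabular(sire_idx, dam_idx)
    full = RelationshipMatrix(animal_ids=pedigree.animal.copy(), values=A)
    if subset is None:
        return full
    return full.align(np.asarray(subset, dtype=np.int64))


def _tabular(sire_idx: np.ndarray, dam_idx: np.ndarray) -> np.ndarray:
    n = sire_idx.size
    A = np.zeros((n, n))
    for i in range(n):
        si, di = sire_idx[i], dam_idx[i]
        f = 0.5 * A[si, di] if (si >= 0 and di >= 0) else 0.0
        A[i, i] = 1.0 + f
        for k in range(i):
            a = 0.0
            if si >= 0:
                a += 0.5 * A[k, si]
            if di >= 0:
                a += 0.5 * A[k, di]
            A[i, k] = A[k, i] = a
    return A


@dataclass(frozen=True)
class BLassoConfig:
    """Chain-control parameters.

    Defaults follow a standard long-chain protocol for this model class:
    a 100,000-iteration chain with 30,000 burn-in, storing every 30th
    sample, lambda fixed from the average of 5 exploratory chains of
    50,000 iterations.  Desk-scale analyses pass shorter values.
    """

    n_iter: int = 100_000
    burn_in: int = 30_000
    thin: int = 30
    lam: float | None = None              # fixed lambda; None = must estimate
    lambda_shape: float = 0.1             # gamma hyperprior on lambda^2
    lambda_rate: float = 0.1
    n_exploratory_chains: int = 5
    exploratory_length: int = 50_000
    nu_e: float = 4.0
    s2_e: float | None = None             # None: set to var(y)/2 at run time
    nu_s: float = 4.0
    s2_s: float | None = None             # None: set to var(y)/4 at run time
    use_polygenic: bool = True
    update_mu: bool = True
    fixed_sigma2_e: float | None = None
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.lam is not None and self.lam <= 0:
            raise ValueError("lambda must be positive when fixed")

    @property
    def n_stored(self) -> int:
        # floor((L - burn_in) / thin): samples land on iterations
        # burn_in + thin, burn_in + 2 thin, ...
        return (self.n_iter - self.burn_in) // self.thin

    def with_(self, **kwargs) -> "BLassoConfig":
        return replace(self, **kwargs)


@dataclass
class MarkerEffectPosterior:
    """Posterior summaries and stored samples of a marker-effect chain."""

    beta_mean: np.ndarray
    beta_sd: np.ndarray
    beta_samples: np.ndarray = field(repr=False)
    mu_samples: np.ndarray = field(repr=False)
    sigma2_e_samples: np.ndarray = field(repr=False)
    sigma2_s_samples: np.ndarray = field(repr=False)
    lambda_samples: np.ndarray = field(repr=False)
    ess: dict = field(default_factory=dict)
    degenerate: bool = False
    config: BLassoConfig | None = None

    @property
    def n_stored(self) -> int:
        return int(self.beta_samples.shape[0])


def _eigendecompose(A: RelationshipMatrix, jitter: float = 1e-8):
    vals, vecs = np.linalg.eigh(A.values)
    if vals.min() < -1e-6 * max(1.0, vals.max()):
        # one jitter attempt before rejecting
        vals, vecs = np.linalg.eigh(A.values + jitter * np.eye(len(vals)))
        if vals.min() < -1e-6 * max(1.0, vals.max()):
            raise ValueError("relationship matrix is not positive semidefinite")
    return vecs, np.clip(vals, jitter, None)


def _prepare(y, genotypes: GenotypeMatrix, A: RelationshipMatrix | None,
             config: BLassoConfig):
    y = np.asarray(y, dtype=np.float64)
    if y.size != genotypes.n_animals:
        raise ValueError("response and genotype panel are misaligned")
    if np.isnan(genotypes.geno).any():
        raise ValueError("genotypes contain missing values; run QC/imputation first")
    X = np.asfortranarray(genotypes.geno - genotypes.geno.mean(axis=0))
    yc = y - y.mean() if config.update_mu else y.copy()
    if config.use_polygenic:
        if A is None:
            raise ValueError("polygenic model requires a relationship matrix")
        if not np.array_equal(A.animal_ids, genotypes.animal_ids):
            A = A.align(genotypes.animal_ids)
        U, d = _eigendecompose(A)
    else:
        U = np.empty((0, 0))
        d = np.empty(0)
    vy = float(np.var(y)) if np.var(y) > 0 else 1.0
    s2_e = config.s2_e if config.s2_e is not None else vy / 2.0
    s2_s = config.s2_s if config.s2_s is not None else vy / 4.0
    return yc, X, U, d, s2_e, s2_s


def run_gibbs(
    y,
    genotypes: GenotypeMatrix,
    A: RelationshipMatrix | None,
    config: BLassoConfig,
    h_perm: int = 0,
) -> MarkerEffectPosterior:
    """Sample the joint posterior; ``h_perm > 0`` turns the chain into a
    within-chain permutation (null) chain that reshuffles the response
    against genotype rows every ``h_perm`` iterations."""
    if config.lam is None:
        raise ValueError("lambda must be fixed before the final chain; "
                         "use estimate_lambda")
    yc, X, U, d, s2_e, s2_s = _prepare(y, genotypes, A, config)
    out = _kernels.blasso_chain(
        yc, X, U, d,
        float(config.lam), False,
        config.lambda_shape, config.lambda_rate,
        config.nu_e, s2_e, config.nu_s, s2_s,
        float(config.fixed_sigma2_e) if config.fixed_sigma2_e else -1.0,
        config.update_mu,
        config.n_iter, config.burn_in, config.thin,
        int(h_perm), int(config.seed) % (2**31),
    )
    return summarize_posterior(out, config)


def estimate_lambda(
    y,
    genotypes: GenotypeMatrix,
    A: RelationshipMatrix | None,
    config: BLassoConfig,
) -> tuple[float, dict]:
    """Fix lambda from the average of several short exploratory chains.

    Each chain samples lambda^2 from its gamma full conditional; the
    returned value is the mean over chains of each chain's post-burn-in
    posterior mean.  A dispersion screen flags chains that disagree
    badly (coefficient of variation above 0.5) — the value is still
    returned, with ``info["converged"] = False``.
    """
    yc, X, U, d, s2_e, s2_s = _prepare(y, genotypes, A, config)
    burn = min(config.exploratory_length // 3, config.exploratory_length - 1)
    means = []
    for c in range(config.n_exploratory_chains):
        out = _kernels.blasso_chain(
            yc, X, U, d,
            1.0, True,
            config.lambda_shape, config.lambda_rate,
            config.nu_e, s2_e, config.nu_s, s2_s,
            -1.0,
            config.update_mu,
            config.exploratory_length, burn, max(1, config.thin // 3),
            0, (int(config.seed) + 7919 * (c + 1)) % (2**31),
        )
        means.append(float(out[4].mean()))
    means_arr = np.array(means)
    lam = float(means_arr.mean())
    cv = float(means_arr.std() / lam) if lam > 0 else np.inf
    return lam, {"chain_means": means, "cv": cv, "converged": cv <= 0.5}


def summarize_posterior(samples, config: BLassoConfig) -> MarkerEffectPosterior:
    """Posterior means/SDs and effective sample sizes for the variances.

    ``samples`` is either a raw kernel output tuple or an existing
    :class:`MarkerEffectPosterior` (whose stored draws are re-summarized).
    """
    if isinstance(samples, MarkerEffectPosterior):
        raw = (samples.beta_samples, samples.mu_samples,
               samples.sigma2_e_samples, samples.sigma2_s_samples,
               samples.lambda_samples)
    else:
        raw = samples
    beta_s, mu_s, s2e_s, s2s_s, lam_s = raw
    if beta_s.shape[0] < 2:
        raise ValueError("need at least 2 stored samples")
    beta_mean = beta_s.mean(axis=0)
    beta_sd = beta_s.std(axis=0, ddof=1)
    degenerate = bool(np.all(beta_sd == 0.0) and np.std(s2e_s) == 0.0)
    ess = {
        "sigma2_e": _ess(s2e_s),
        "sigma2_s": _ess(s2s_s),
    }
    return MarkerEffectPosterior(
        beta_mean=beta_mean,
        beta_sd=beta_sd,
        beta_samples=beta_s,
        mu_samples=mu_s,
        sigma2_e_samples=s2e_s,
        sigma2_s_samples=s2s_s,
        lambda_samples=lam_s,
        ess=ess,
        degenerate=degenerate,
        config=config,
    )


def _ess(chain: np.ndarray) -> float:
    chain = np.asarray(chain, dtype=float)
    if np.std(chain) == 0.0:
        # constant chain: report the sample count (degenerate case)
        return float(chain.size)
    if az is not None:
        return float(az.ess(chain[None, :]))
    # autocorrelation-based fallback (initial positive sequence)
    x = chain - chain.mean()
    acf = np.correlate(x, x, mode="full")[x.size - 1:] / (np.arange(x.size, 0, -1))
    acf /= acf[0]
    rho_sum = 0.0
    for k in range(1, x.size):
        if acf[k] <= 0:
            break
        rho_sum += acf[k]
    return float(x.size / (1.0 + 2.0 * rho_sum))
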