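"""Within-chain permutation significance (Che-Xu).

A second Gibbs chain is run in which the response vector is reshuffled
against the genotype rows every ``h`` iterations (the response keeps its
pedigree linkage, so the polygenic structure is preserved while the
genotype-phenotype linkage is destroyed).  The stored marker-effect
draws of this chain form a null sample; its ``0.25 alpha`` and
``1 - 0.25 alpha`` percentiles are the critical values against which
the observed posterior means are compared.  For ``h`` equal to the
chain length this degenerates to ordinary across-chain permutation;
``h = 1`` reshuffles every iteration.  ``h = 3`` is the recommended
operating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gwas import BLassoConfig, MarkerEffectPosterior, run_gibbs
from .types import GenotypeMatrix, RelationshipMatrix


@dataclass(frozen=True)
class PermutationConfig:
    """Null-chain controls.

    The reference protocol uses ``h = 3`` with a 250,000-iteration
    permuted chain; desk-scale analyses shorten the chain.
    """

    h: int = 3
    n_iter: int = 250_000
    burn_in: int | None = None     # None: reuse the analysis chain's burn-in
    alpha: float = 0.05
    scope: str = "per_marker"      # or "pooled"
    seed: int = 101

    def __post_init__(self) -> None:
        if self.h < 1:
            raise ValueError("h must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.scope not in ("per_marker", "pooled"):
            raise ValueError("scope must be 'per_marker' or 'pooled'")

    def with_(self, **kwargs) -> "PermutationConfig":
        return replace(self, **kwargs)


@dataclass
class SignificanceResult:
    table: pd.DataFrame = field(repr=False)   # per-marker summary
    alpha: float = 0.05
    scope: str = "per_marker"

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def significant_fraction(self) -> float:
        return float(self.table["significant"].mean())


def run_permuted_chain(
    y,
    genotypes: GenotypeMatrix,
    A: RelationshipMatrix | None,
    blasso_config: BLassoConfig,
    perm_config: PermutationConfig,
) -> MarkerEffectPosterior:
    """Null chain: same model, response reshuffled every ``h`` iterations."""
    if perm_config.h > perm_config.n_iter:
        raise ValueError("h cannot exceed the permuted-chain length")
    burn = (perm_config.burn_in if perm_config.burn_in is not None
            else min(blasso_config.burn_in, perm_config.n_iter - 1))
    cfg = blasso_config.with_(
        n_iter=perm_config.n_iter,
        burn_in=burn,
        seed=perm_config.seed,
    )
    return run_gibbs(y, genotypes, A, cfg, h_perm=perm_config.h)


def critical_values(
    null_posterior: MarkerEffectPosterior | np.ndarray,
    alpha: float,
    scope: str = "per_marker",
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile critical values from null marker-effect draws.

    lower = 0.25*alpha quantile, upper = 1 - 0.25*alpha quantile — of
    each marker's own null draws (``per_marker``) or of all draws pooled
    across markers (``pooled``, then broadcast to every marker).
    """
    draws = (null_posterior.beta_samples
             if isinstance(null_posterior, MarkerEffectPosterior)
             else np.asarray(null_posterior))
    if draws.size == 0:
        raise ValueError("empty null sample")
    q_lo, q_hi = 0.25 * alpha, 1.0 - 0.25 * alpha
    p = draws.shape[1]
    if scope == "per_marker":
        if draws.shape[0] < 100:
            raise ValueError(
                "per-marker critical values need >= 100 null draws; "
                "use scope='pooled' or lengthen the permuted chain"
            )
        lower = np.quantile(draws, q_lo, axis=0)
        upper = np.quantile(draws, q_hi, axis=0)
    elif scope == "pooled":
        flat = draws.ravel()
        lo = float(np.quantile(flat, q_lo))
        hi = float(np.quantile(flat, q_hi))
        lower = np.full(p, lo)
        upper = np.full(p, hi)
    else:
        raise ValueError("scope must be 'per_marker' or 'pooled'")
    return lower, upper


def declare_significant(
    posterior: MarkerEffectPosterior,
    critical: tuple[np.ndarray, np.ndarray],
    marker_map: pd.DataFrame | None = None,
    alpha: float = 0.05,
    scope: str = "per_marker",
) -> SignificanceResult:
    """Flag markers whose posterior-mean effect falls outside the null
    percentile band."""
    lower, upper = critical
    beta = posterior.beta_mean
    if beta.size != lower.size or beta.size != upper.size:
        raise ValueError("marker sets of posterior and critical values differ")
    if np.any(lower > upper):
        raise ValueError("lower critical value exceeds upper")
    sig = (beta < lower) | (beta > upper)
    table = pd.DataFrame(
        {
            "beta_mean": beta,
            "lower": lower,
            "upper": upper,
            "significant": sig,
        }
    )
    if marker_map is not None:
        table.insert(0, "name", marker_map["name"].to_numpy())
        table.insert(1, "chrom", marker_map["chrom"].to_numpy())
        table.insert(2, "pos", marker_map["pos"].to_numpy())
    return SignificanceResult(table=table, alpha=alpha, scope=scope)


def select_top_effects(
    posterior: MarkerEffectPosterior,
    k: int,
    marker_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Markers ranked by |posterior mean| descending, top ``k`` returned.

    Ties break by panel (map) order, making the ranking deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    beta = posterior.beta_mean
    order = np.lexsort((np.arange(beta.size), -np.abs(beta)))
    top = order[: min(k, beta.size)]
    out = pd.DataFrame(
        {
            "panel_index": top,
            "beta_mean": beta[top],
            "abs_effect": np.abs(beta[top]),
            "rank": np.arange(1, top.size + 1),
        }
    )
    if marker_map is not None:
        out.insert(1, "name", marker_map["name"].to_numpy()[top])
        out.insert(2, "chrom", marker_map["chrom"].to_numpy()[top])
        out.insert(3, "pos", marker_map["pos"].to_numpy()[top])
    return out
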