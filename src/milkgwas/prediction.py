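"""Direct genomic values (DGV) and marker-subset prediction analytics.

A sire's DGV is the sum of its genotype codes weighted by the estimated
marker effects.  Marker effects are estimated on a discovery set of
high-reliability sires (EBV reliability > 0.60 by default) and
evaluated on the remaining prediction set: Pearson correlation between
DGV and EBV, the proportion of the full-panel correlation recovered by
nested subsets of top markers, the proportion of genomic variance
(variance of the subset-restricted DGV over the all-marker DGV
variance), and gene/regulatory-region analyses with a 500 kb flank
around each gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import GenotypeMatrix

#: default nested subset-size ladder for top-|effect| marker subsets
SUBSET_LADDER = (25, 50, 100, 300, 3000, 10000)


@dataclass
class SplitSpec:
    threshold: float
    discovery_ids: np.ndarray
    prediction_ids: np.ndarray

    @property
    def n_discovery(self) -> int:
        return int(self.discovery_ids.size)

    @property
    def n_prediction(self) -> int:
        return int(self.prediction_ids.size)


def split_by_reliability(
    records: pd.DataFrame, threshold: float = 0.60
) -> SplitSpec:
    """Discovery = reliability strictly greater than ``threshold``; the
    rest form the prediction set."""
    if "reliability" not in records.columns:
        raise ValueError("records need a 'reliability' column")
    rel = records["reliability"].to_numpy(dtype=float)
    ids = records["animal"].to_numpy(dtype=np.int64)
    disc = ids[rel > threshold]
    pred = ids[~(rel > threshold)]
    if disc.size == 0:
        raise ValueError(
            f"empty discovery set: no reliability exceeds {threshold}"
        )
    return SplitSpec(threshold=threshold, discovery_ids=disc,
                     prediction_ids=pred)


def compute_dgv(
    genotypes: GenotypeMatrix,
    effects: np.ndarray,
    subset: np.ndarray | None = None,
) -> np.ndarray:
    """DGV_i = sum over the subset of x_ij * beta_j (post-imputation
    -1/0/1 coding)."""
    effects = np.asarray(effects, dtype=float)
    if effects.size != genotypes.n_markers:
        raise ValueError("effects misaligned with genotype panel")
    if subset is None:
        return genotypes.geno @ effects
    subset = np.asarray(subset, dtype=np.int64)
    return genotypes.geno[:, subset] @ effects[subset]


def nested_top_subsets(
    effects: np.ndarray, ladder: tuple[int, ...] = SUBSET_LADDER
) -> dict[str, np.ndarray]:
    """Nested top-|effect| marker index sets, largest effects first.

    Ladder sizes above the panel size collapse onto "all"; ties break by
    panel order.  Returns a label -> index-array mapping including
    ``"all"``.
    """
    effects = np.asarray(effects, dtype=float)
    p = effects.size
    order = np.lexsort((np.arange(p), -np.abs(effects)))
    out: dict[str, np.ndarray] = {}
    for k in ladder:
        if k < p:
            out[str(k)] = np.sort(order[:k])
    out["all"] = np.arange(p)
    return out


@dataclass
class DGVTable:
    animal_ids: np.ndarray
    dgv: pd.DataFrame = field(repr=False)     # animals x subset labels
    subsets: dict = field(repr=False, default_factory=dict)


def build_dgv_table(
    genotypes: GenotypeMatrix,
    effects: np.ndarray,
    ladder: tuple[int, ...] = SUBSET_LADDER,
) -> DGVTable:
    subsets = nested_top_subsets(effects, ladder)
    cols = {
        label: compute_dgv(genotypes, effects, idx)
        for label, idx in subsets.items()
    }
    return DGVTable(
        animal_ids=genotypes.animal_ids.copy(),
        dgv=pd.DataFrame(cols, index=genotypes.animal_ids),
        subsets=subsets,
    )


def correlation_recovery(
    ebv: np.ndarray, dgv_table: DGVTable
) -> pd.DataFrame:
    """Pearson correlation of each subset DGV with EBV on the
    (prediction-set) animals, plus the fraction of the all-marker
    correlation each subset recovers."""
    ebv = np.asarray(ebv, dtype=float)
    if ebv.size != dgv_table.animal_ids.size:
        raise ValueError("EBV vector misaligned with DGV table")
    if ebv.size < 3:
        raise ValueError("need at least 3 prediction animals")
    rows = []
    r_all = float(np.corrcoef(ebv, dgv_table.dgv["all"])[0, 1])
    for label in dgv_table.dgv.columns:
        r = float(np.corrcoef(ebv, dgv_table.dgv[label])[0, 1])
        rows.append(
            {
                "subset": label,
                "correlation": r,
                "recovery": r / r_all if r_all != 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def genomic_variance_proportions(dgv_table: DGVTable) -> pd.DataFrame:
    """Var(DGV_subset) / Var(DGV_all) across animals, per subset."""
    if dgv_table.animal_ids.size < 2:
        raise ValueError("need at least 2 animals")
    v_all = float(np.var(dgv_table.dgv["all"]))
    if v_all <= 0.0:
        raise ValueError("total DGV variance is zero")
    rows = []
    for label in dgv_table.dgv.columns:
        v = float(np.var(dgv_table.dgv[label]))
        prop = 1.0 if label == "all" else v / v_all
        rows.append({"subset": label, "variance": v, "proportion": prop})
    return pd.DataFrame(rows)


def flag_gene_region_markers(
    marker_map: pd.DataFrame,
    genes: pd.DataFrame,
    flank: int = 500_000,
) -> np.ndarray:
    """Flag markers within ``flank`` bp of any gene (gene body plus
    regulatory flanks).

    ``genes`` needs columns chrom/start/end (as produced by
    :func:`milkgwas.io.read_gene_features`).  A chromosome-name mismatch
    between the two inputs yields zero flags and a warning.
    """
    flags = np.zeros(len(marker_map), dtype=bool)
    if len(genes) == 0:
        return flags
    map_chroms = set(marker_map["chrom"].astype(str))
    gene_chroms = set(genes["chrom"].astype(str))
    if not map_chroms & gene_chroms:
        import warnings

        warnings.warn(
            "no shared chromosome names between marker map and gene file; "
            "no markers flagged",
            stacklevel=2,
        )
        return flags
    for chrom, sub in genes.groupby("chrom"):
        in_chrom = marker_map["chrom"].astype(str) == str(chrom)
        if not in_chrom.any():
            continue
        pos = marker_map.loc[in_chrom, "pos"].to_numpy()
        hit = np.zeros(pos.size, dtype=bool)
        for start, end in zip(sub["start"], sub["end"]):
            hit |= (pos >= start - flank) & (pos <= end + flank)
        flags[np.flatnonzero(in_chrom.to_numpy())] |= hit
    return flags


def gene_dgv_proportion(
    dgv_gene: np.ndarray,
    dgv_sig: np.ndarray,
    floor_factor: float = 1e-8,
) -> float:
    """Median across animals of the per-animal ratio DGV_gene / DGV_sig.

    DGV_gene is built from significant genic markers, DGV_sig from all
    significant markers.  Animals whose |DGV_sig| is below
    ``floor_factor * sd(DGV_sig)`` are excluded to avoid ratio
    blow-ups; if every animal is excluded the result is undefined.
    """
    dgv_gene = np.asarray(dgv_gene, dtype=float)
    dgv_sig = np.asarray(dgv_sig, dtype=float)
    if dgv_gene.shape != dgv_sig.shape:
        raise ValueError("DGV vectors must be computed on the same animals")
    floor = floor_factor * float(np.std(dgv_sig))
    ok = np.abs(dgv_sig) > floor
    if not ok.any():
        raise ValueError("all animals below the |DGV_sig| floor; "
                         "proportion undefined")
    return float(np.median(dgv_gene[ok] / dgv_sig[ok]))


def gene_dgv_variance_ratio(dgv_gene: np.ndarray, dgv_sig: np.ndarray) -> float:
    """Alternative definition: Var(DGV_gene) / Var(DGV_sig)."""
    v = float(np.var(np.asarray(dgv_sig, dtype=float)))
    if v <= 0:
        raise ValueError("DGV_sig variance is zero")
    return float(np.var(np.asarray(dgv_gene, dtype=float)) / v)
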