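"""Marker quality control: call rate, MAF and Hardy-Weinberg filters.

Filters reproduce standard 50k-chip GWAS practice: markers with call
rate < 0.90 or MAF < 0.05, or departing from Hardy-Weinberg equilibrium,
are discarded; remaining missing genotypes are imputed (per-marker mean
by default, preserving allele frequency).

All three statistics are computed on the *unfiltered* panel; a marker
failing several criteria is attributed to the first in the order
call_rate -> maf -> hwe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import GenotypeMatrix, QCReport


def hwe_test(counts: tuple[int, int, int]) -> tuple[float, float]:
    """1-df chi-square goodness-of-fit test of Hardy-Weinberg equilibrium.

    ``counts`` are genotype counts for codes (-1, 0, +1).  Monomorphic
    markers return (0, 1) by convention.

    Returns ``(chi2, p_value)``.
    """
    n_mm, n_het, n_pp = (int(c) for c in counts)
    n = n_mm + n_het + n_pp
    if n < 1:
        raise ValueError("need at least one genotyped animal")
    f = (2 * n_pp + n_het) / (2.0 * n)  # frequency of the +1 allele
    if f == 0.0 or f == 1.0:
        return 0.0, 1.0
    expected = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2]) * n
    observed = np.array([n_mm, n_het, n_pp], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def compute_marker_stats(genotypes: GenotypeMatrix) -> QCReport:
    """Per-marker call rate, MAF and HWE chi-square/p-value.

    Markers with zero calls get call rate 0 and NaN MAF/HWE.
    """
    if genotypes.n_animals < 1:
        raise ValueError("need at least one animal")
    g = genotypes.geno
    call_rate = genotypes.call_rate()
    maf = genotypes.maf()
    chi2 = np.full(genotypes.n_markers, np.nan)
    pval = np.full(genotypes.n_markers, np.nan)
    for j in range(genotypes.n_markers):
        col = g[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        counts = (
            int(np.sum(col == -1.0)),
            int(np.sum(col == 0.0)),
            int(np.sum(col == 1.0)),
        )
        chi2[j], pval[j] = hwe_test(counts)
    table = genotypes.marker_map.copy()
    table["call_rate"] = call_rate
    table["maf"] = maf
    table["hwe_chi2"] = chi2
    table["hwe_p"] = pval
    table["pass"] = True
    table["fail_reason"] = ""
    return QCReport(table=table)


def apply_filters(
    genotypes: GenotypeMatrix,
    call_rate_min: float = 0.90,
    maf_min: float = 0.05,
    hwe_alpha: float = 1e-6,
    impute: str = "mean",
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter markers and impute residual missing genotypes.

    Parameters
    ----------
    call_rate_min, maf_min
        Exclusive lower bounds: a marker fails when its statistic is
        strictly below the threshold.
    hwe_alpha
        A marker fails when its HWE p-value is below ``hwe_alpha``.
    impute
        ``"mean"`` (per-marker mean of observed codes; preserves allele
        frequency) or ``"zero"``.
    """
    for name, v in (("call_rate_min", call_rate_min), ("maf_min", maf_min),
                    ("hwe_alpha", hwe_alpha)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    report = compute_marker_stats(genotypes)
    t = report.table
    reason = np.full(len(t), "", dtype=object)
    fail_cr = (t["call_rate"] < call_rate_min).to_numpy()
    fail_maf = (t["maf"].isna() | (t["maf"] < maf_min)).to_numpy()
    fail_hwe = (t["hwe_p"] < hwe_alpha).fillna(False).to_numpy()
    reason[fail_hwe] = "hwe"
    reason[fail_maf] = "maf"
    reason[fail_cr] = "call_rate"  # first-failing-reason wins
    keep = reason == ""
    t["pass"] = keep
    t["fail_reason"] = reason
    report.thresholds = {
        "call_rate_min": call_rate_min,
        "maf_min": maf_min,
        "hwe_alpha": hwe_alpha,
    }
    if not keep.any():
        raise ValueError("all markers removed by QC filters")
    filtered = genotypes.subset_markers(np.flatnonzero(keep))
    filtered = impute_missing(filtered, method=impute)
    return filtered, report


def impute_missing(genotypes: GenotypeMatrix, method: str = "mean") -> GenotypeMatrix:
    """Replace missing codes; keeps the matrix dense and analysis-ready."""
    g = genotypes.geno.copy()
    nan_mask = np.isnan(g)
    if nan_mask.any():
        if method == "mean":
            col_mean = np.where(
                nan_mask.all(axis=0), 0.0, np.nanmean(genotypes.geno, axis=0)
            )
            g[nan_mask] = np.broadcast_to(col_mean, g.shape)[nan_mask]
        elif method == "zero":
            g[nan_mask] = 0.0
        else:
            raise ValueError(f"unknown imputation method {method!r}")
    return GenotypeMatrix(
        animal_ids=genotypes.animal_ids.copy(),
        marker_map=genotypes.marker_map.copy(),
        geno=g,
    )
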