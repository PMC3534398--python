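"""Region analysis: collapse top markers into regions and annotate them
against literature QTL intervals.

Two selected markers belong to one region when they sit on the same
chromosome and are within a fixed number of panel positions (default
20 markers to the left or right, counted over the full QC-surviving
panel); the relation is chained transitively, so a run of nearby
markers forms a single region.  Each region's share of genomic variance
is the variance of the region-restricted direct genomic value across
animals, divided by the all-marker DGV variance.

QTL intervals are 1-based inclusive base-pair spans with a trait-class
label (milking speed MSPD, udder traits UT, somatic cell score/count
SCS/SCC, clinical mastitis CM, milk yield MY); any base-pair overlap
(closed intervals) tags the region, no-overlap regions are "novel".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .types import GenotypeMatrix

QTL_CLASSES = ("MSPD", "UT", "SCS", "SCC", "CM", "MY")


@dataclass
class Region:
    chrom: int
    start_index: int          # panel order, inclusive
    end_index: int
    start_bp: int
    end_bp: int
    member_indices: np.ndarray = field(repr=False)
    top_marker_index: int = -1
    top_effect: float = 0.0
    variance_share: float = np.nan
    qtl_tags: tuple[str, ...] = ()

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp


def group_regions(
    top_markers: pd.DataFrame,
    marker_map: pd.DataFrame,
    window: int = 20,
) -> list[Region]:
    """Chain selected markers into regions by panel-index gap.

    ``top_markers`` needs ``panel_index`` (position in the QC-surviving
    map) and ``beta_mean`` columns, as produced by
    :func:`milkgwas.permutation.select_top_effects`.  Regions come back
    in genome order.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    idx = np.asarray(top_markers["panel_index"], dtype=np.int64)
    if idx.size == 0:
        return []
    if idx.max() >= len(marker_map) or idx.min() < 0:
        raise ValueError("top marker absent from the marker map")
    beta = np.asarray(top_markers["beta_mean"], dtype=float)
    order = np.argsort(idx)
    idx, beta = idx[order], beta[order]
    chrom = marker_map["chrom"].to_numpy()[idx]
    pos = marker_map["pos"].to_numpy()[idx]

    regions: list[Region] = []
    start = 0
    for k in range(1, idx.size + 1):
        boundary = (
            k == idx.size
            or chrom[k] != chrom[k - 1]
            or idx[k] - idx[k - 1] > window
        )
        if boundary:
            members = idx[start:k]
            b = beta[start:k]
            top = int(members[np.argmax(np.abs(b))])
            regions.append(
                Region(
                    chrom=int(chrom[start]),
                    start_index=int(members[0]),
                    end_index=int(members[-1]),
                    start_bp=int(pos[start]),
                    end_bp=int(pos[k - 1]),
                    member_indices=members.copy(),
                    top_marker_index=top,
                    top_effect=float(b[np.argmax(np.abs(b))]),
                )
            )
            start = k
    return regions


def region_variance_share(
    region: Region,
    genotypes: GenotypeMatrix,
    effects: np.ndarray,
    reference_variance: float | None = None,
) -> float:
    """Variance of the region-restricted DGV over the all-marker DGV
    variance."""
    effects = np.asarray(effects, dtype=float)
    if reference_variance is None:
        reference_variance = float(np.var(genotypes.geno @ effects))
    if reference_variance <= 0.0:
        raise ValueError("reference DGV variance must be positive")
    sub = genotypes.geno[:, region.member_indices] @ effects[region.member_indices]
    return float(np.var(sub) / reference_variance)


def attach_variance_shares(
    regions: list[Region],
    genotypes: GenotypeMatrix,
    effects: np.ndarray,
) -> list[Region]:
    ref = float(np.var(genotypes.geno @ np.asarray(effects, dtype=float)))
    for reg in regions:
        reg.variance_share = region_variance_share(reg, genotypes, effects, ref)
    return regions


def load_qtl_intervals(path=None) -> pd.DataFrame:
    """QTL interval table (chrom, start_bp, end_bp, trait_class, source).

    Without ``path``, loads the bundled literature compilation of bovine
    milking-speed / udder / udder-health / milk-yield QTL intervals.
    Coordinates are 1-based inclusive.
    """
    if path is None:
        ref = resources.files("milkgwas.data").joinpath("qtl_intervals.tsv")
        with resources.as_file(ref) as f:
            qtl = pd.read_csv(f, sep="\t", comment="#")
    else:
        qtl = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "start_bp", "end_bp", "trait_class"}
    if not required <= set(qtl.columns):
        raise ValueError(f"QTL interval file needs columns {sorted(required)}")
    if (qtl["start_bp"] > qtl["end_bp"]).any():
        raise ValueError("malformed QTL interval: start_bp > end_bp")
    return qtl


def annotate_regions(
    regions: list[Region],
    qtl: pd.DataFrame,
) -> list[Region]:
    """Tag each region with every QTL class whose interval overlaps its
    base-pair span (closed-interval overlap); untagged regions get the
    single tag ``novel``."""
    if (qtl["start_bp"] > qtl["end_bp"]).any():
        raise ValueError("malformed QTL interval: start_bp > end_bp")
    for reg in regions:
        hits = qtl[
            (qtl["chrom"] == reg.chrom)
            & (qtl["start_bp"] <= reg.end_bp)
            & (qtl["end_bp"] >= reg.start_bp)
        ]
        classes = tuple(sorted(set(hits["trait_class"])))
        reg.qtl_tags = classes if classes else ("novel",)
    return regions


def regions_to_frame(regions: list[Region], marker_map: pd.DataFrame) -> pd.DataFrame:
    """Tabular report: one row per region in genome order."""
    names = marker_map["name"].to_numpy()
    rows = []
    for reg in regions:
        rows.append(
            {
                "chrom": reg.chrom,
                "start_bp": reg.start_bp,
                "end_bp": reg.end_bp,
                "span_bp": reg.span_bp,
                "n_markers": reg.member_indices.size,
                "top_marker": names[reg.top_marker_index],
                "top_effect": reg.top_effect,
                "variance_share": reg.variance_share,
                "qtl_tags": ",".join(reg.qtl_tags) if reg.qtl_tags else "",
            }
        )
    return pd.DataFrame(rows)
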