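"""Core in-memory containers shared across the pipeline.

The conventions used throughout:

* genotypes are coded ``-1 / 0 / +1`` (allele count minus one) with
  ``NaN`` for missing calls;
* animals are identified by positive integer ids, ``0`` marks an
  unknown parent;
* pedigrees are stored in topological order (parents precede
  offspring).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.nan

#: canonical column order for marker maps
MAP_COLUMNS = ["name", "chrom", "pos", "genic"]


@dataclass
class Pedigree:
    """Ordered pedigree: ``sire``/``dam`` are 0 for unknown founders."""

    animal: np.ndarray          # int ids, topological order
    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray

    def __post_init__(self) -> None:
        self.animal = np.asarray(self.animal, dtype=np.int64)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.generation = np.asarray(self.generation, dtype=np.int64)
        if len(set(self.animal.tolist())) != self.animal.size:
            raise ValueError("pedigree ids must be unique")
        seen: set[int] = set()
        for a, s, d in zip(self.animal, self.sire, self.dam):
            for p in (s, d):
                if p != 0 and p not in seen:
                    raise ValueError(
                        f"pedigree is not topologically ordered: parent {p} "
                        f"of {a} appears later (or never)"
                    )
            seen.add(int(a))

    def __len__(self) -> int:
        return int(self.animal.size)

    @property
    def n_founders(self) -> int:
        return int(np.sum((self.sire == 0) & (self.dam == 0)))

    def indices(self) -> dict[int, int]:
        """Map animal id -> row position."""
        return {int(a): i for i, a in enumerate(self.animal)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal": self.animal,
                "sire": self.sire,
                "dam": self.dam,
                "generation": self.generation,
            }
        )


def check_marker_map(marker_map: pd.DataFrame) -> pd.DataFrame:
    """Validate a marker map frame (name, chrom, pos, genic)."""
    missing = [c for c in MAP_COLUMNS if c not in marker_map.columns]
    if missing:
        raise ValueError(f"marker map lacks columns {missing}")
    if marker_map["name"].duplicated().any():
        raise ValueError("marker names must be unique")
    for chrom, sub in marker_map.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions not strictly increasing on chrom {chrom}")
    return marker_map.reset_index(drop=True)


@dataclass
class GenotypeMatrix:
    """Sires x markers genotype panel with its marker map.

    ``geno`` is float64 with values in {-1, 0, 1, NaN}; rows follow
    ``animal_ids`` and columns follow ``marker_map`` order.
    """

    animal_ids: np.ndarray
    marker_map: pd.DataFrame
    geno: np.ndarray

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids, dtype=np.int64)
        self.geno = np.asarray(self.geno, dtype=np.float64)
        self.marker_map = check_marker_map(self.marker_map)
        n, p = self.geno.shape
        if n != self.animal_ids.size or p != len(self.marker_map):
            raise ValueError(
                f"genotype shape {self.geno.shape} inconsistent with "
                f"{self.animal_ids.size} animals / {len(self.marker_map)} markers"
            )

    @property
    def n_animals(self) -> int:
        return int(self.geno.shape[0])

    @property
    def n_markers(self) -> int:
        return int(self.geno.shape[1])

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.geno), axis=0)

    def allele_freq(self) -> np.ndarray:
        """Frequency of the +1-coded allele among non-missing calls.

        NaN for markers with no calls at all.
        """
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return (np.nanmean(self.geno, axis=0) + 1.0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def subset_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            animal_ids=self.animal_ids.copy(),
            marker_map=self.marker_map.iloc[idx].reset_index(drop=True),
            geno=self.geno[:, idx].copy(),
        )

    def subset_animals(self, ids: np.ndarray) -> "GenotypeMatrix":
        pos = {int(a): i for i, a in enumerate(self.animal_ids)}
        rows = np.array([pos[int(a)] for a in ids], dtype=np.int64)
        return GenotypeMatrix(
            animal_ids=np.asarray(ids, dtype=np.int64),
            marker_map=self.marker_map.copy(),
            geno=self.geno[rows].copy(),
        )


@dataclass
class TrueEffects:
    """Planted additive marker effects; zero except at the QTL subset."""

    beta: np.ndarray
    qtl_indices: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=np.float64)
        self.qtl_indices = np.asarray(self.qtl_indices, dtype=np.int64)
        nz = np.nonzero(self.beta)[0]
        if not set(nz.tolist()) <= set(self.qtl_indices.tolist()):
            raise ValueError("non-zero effects outside the declared QTL subset")


@dataclass
class RelationshipMatrix:
    """Numerator (pedigree-expected additive) relationship matrix."""

    animal_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.animal_ids.size
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")

    def align(self, ids: np.ndarray) -> "RelationshipMatrix":
        pos = {int(a): i for i, a in enumerate(self.animal_ids)}
        rows = np.array([pos[int(a)] for a in ids], dtype=np.int64)
        return RelationshipMatrix(
            animal_ids=np.asarray(ids, dtype=np.int64),
            values=self.values[np.ix_(rows, rows)].copy(),
        )


# Proxy records (one row per animal x trait) travel as a DataFrame with
# these columns; `drp`/`weight` are filled by the deregression module.
PROXY_COLUMNS = [
    "animal",
    "trait",
    "tbv",
    "ebv",
    "reliability",
    "pa_ebv",
    "pa_reliability",
]


@dataclass
class QCReport:
    """Per-marker QC statistics plus the filtering outcome."""

    table: pd.DataFrame = field(repr=False)
    thresholds: dict = field(default_factory=dict)

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def n_surviving(self) -> int:
        return int(self.table["pass"].sum())

    def removals_by_reason(self) -> pd.Series:
        failed = self.table.loc[~self.table["pass"], "fail_reason"]
        return failed.value_counts()

    def per_chromosome_counts(self) -> pd.Series:
        surv = self.table[self.table["pass"]]
        return surv.groupby("chrom").size()
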