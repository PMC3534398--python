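"""Readers and writers for the pipeline's file formats.

Formats handled
---------------
* PLINK-text ``.ped``/``.map`` genotypes (allele letters recoded to
  -1/0/1 by the minor-allele convention; ``0`` = missing allele);
* TSV genotype dialect: rows = animals, columns = markers, cells in
  {-1, 0, 1, NA}, first column ``animal``;
* pedigree TSV (animal, sire, dam[, generation]);
* proxy-record TSV (animal, trait, tbv, ebv, reliability, ...);
* GFF3 gene features (gene rows only, via gffutils);
* QTL-interval TSV (chrom, start_bp, end_bp, trait_class, source) —
  BED-like but 1-based inclusive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, Pedigree, check_marker_map

# ---------------------------------------------------------------- PLINK text


def read_plink_text(ped_path, map_path) -> GenotypeMatrix:
    """Read PLINK-text genotypes and recode alleles to -1/0/1.

    The minor allele (the less frequent letter per marker) counts
    positively: genotype = (#minor alleles) - 1.  Missing alleles
    (``0``) give a missing genotype.
    """
    mmap = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "name", "cm", "pos"],
    )
    ped = pd.read_csv(ped_path, sep=r"\s+", header=None, dtype=str)
    p = len(mmap)
    if ped.shape[1] != 6 + 2 * p:
        raise ValueError(
            f".ped has {ped.shape[1]} columns; expected {6 + 2 * p} "
            f"for {p} markers"
        )
    animal_ids = ped.iloc[:, 1].astype(np.int64).to_numpy()
    alleles = ped.iloc[:, 6:].to_numpy(dtype=object)
    n = alleles.shape[0]
    geno = np.full((n, p), np.nan)
    for j in range(p):
        a1 = alleles[:, 2 * j]
        a2 = alleles[:, 2 * j + 1]
        obs = np.concatenate([a1, a2])
        obs = obs[obs != "0"]
        letters, counts = np.unique(obs, return_counts=True)
        if letters.size == 0:
            continue
        if letters.size > 2:
            raise ValueError(f"marker {mmap['name'][j]} has >2 alleles")
        minor = letters[np.argmin(counts)] if letters.size == 2 else None
        miss = (a1 == "0") | (a2 == "0")
        if minor is None:
            geno[~miss, j] = -1.0  # monomorphic: zero minor-allele copies
        else:
            cnt = (a1 == minor).astype(float) + (a2 == minor).astype(float)
            geno[:, j] = cnt - 1.0
            geno[miss, j] = np.nan
    marker_map = pd.DataFrame(
        {
            "name": mmap["name"],
            "chrom": mmap["chrom"].astype(int),
            "pos": mmap["pos"].astype(int),
            "genic": False,
        }
    )
    return GenotypeMatrix(animal_ids=animal_ids,
                          marker_map=check_marker_map(marker_map),
                          geno=geno)


def write_plink_text(genotypes: GenotypeMatrix, ped_path, map_path) -> None:
    """Write PLINK-text files; codes map to A/B letters (-1 = BB,
    0 = AB, 1 = AA with A the positively-counted allele)."""
    mm = genotypes.marker_map
    with open(map_path, "w") as f:
        for row in mm.itertuples(index=False):
            f.write(f"{row.chrom}\t{row.name}\t0\t{row.pos}\n")
    g = genotypes.geno
    with open(ped_path, "w") as f:
        for i, animal in enumerate(genotypes.animal_ids):
            fields = ["FAM", str(int(animal)), "0", "0", "0", "-9"]
            for j in range(genotypes.n_markers):
                v = g[i, j]
                if np.isnan(v):
                    fields += ["0", "0"]
                elif v == 1.0:
                    fields += ["A", "A"]
                elif v == 0.0:
                    fields += ["A", "B"]
                else:
                    fields += ["B", "B"]
            f.write(" ".join(fields) + "\n")


# --------------------------------------------------------------- TSV dialect


def read_genotype_tsv(path) -> GenotypeMatrix:
    """TSV genotype matrix: column ``animal`` then one column per
    marker named ``name:chrom:pos[:genic]``."""
    frame = pd.read_csv(path, sep="\t")
    if frame.columns[0] != "animal":
        raise ValueError("first column must be 'animal'")
    marker_cols = list(frame.columns[1:])
    names, chroms, poss, genic = [], [], [], []
    for col in marker_cols:
        parts = col.split(":")
        if len(parts) < 3:
            raise ValueError(f"marker column {col!r} not in name:chrom:pos form")
        names.append(parts[0])
        chroms.append(int(parts[1]))
        poss.append(int(parts[2]))
        genic.append(len(parts) > 3 and parts[3] == "1")
    marker_map = pd.DataFrame(
        {"name": names, "chrom": chroms, "pos": poss, "genic": genic}
    )
    geno = frame[marker_cols].to_numpy(dtype=float)
    return GenotypeMatrix(
        animal_ids=frame["animal"].to_numpy(dtype=np.int64),
        marker_map=check_marker_map(marker_map),
        geno=geno,
    )


def write_genotype_tsv(genotypes: GenotypeMatrix, path) -> None:
    cols = {
        "animal": genotypes.animal_ids,
    }
    for j, row in enumerate(genotypes.marker_map.itertuples(index=False)):
        label = f"{row.name}:{row.chrom}:{row.pos}:{int(bool(row.genic))}"
        cols[label] = genotypes.geno[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, na_rep="NA")


# ------------------------------------------------------------------ pedigree


def read_pedigree_tsv(path) -> Pedigree:
    frame = pd.read_csv(path, sep="\t")
    for col in ("animal", "sire", "dam"):
        if col not in frame.columns:
            raise ValueError(f"pedigree TSV needs column {col!r}")
    gen = (frame["generation"].to_numpy(dtype=np.int64)
           if "generation" in frame.columns
           else np.zeros(len(frame), dtype=np.int64))
    return Pedigree(
        animal=frame["animal"].to_numpy(dtype=np.int64),
        sire=frame["sire"].to_numpy(dtype=np.int64),
        dam=frame["dam"].to_numpy(dtype=np.int64),
        generation=gen,
    )


def write_pedigree_tsv(pedigree: Pedigree, path) -> None:
    pedigree.to_frame().to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------- proxy records


def read_proxy_tsv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    for col in ("animal", "trait", "ebv", "reliability"):
        if col not in frame.columns:
            raise ValueError(f"proxy TSV needs column {col!r}")
    return frame


def write_proxy_tsv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------- GFF3


def read_gene_features(path) -> pd.DataFrame:
    """Gene rows of a GFF3 file -> DataFrame(chrom, start, end, gene_id).

    Coordinates stay 1-based inclusive as in GFF3.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for gene in db.features_of_type("gene"):
        rows.append(
            {
                "chrom": gene.seqid,
                "start": gene.start,
                "end": gene.end,
                "gene_id": gene.id,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def write_gene_features_gff3(genes: pd.DataFrame, path) -> None:
    """Write gene rows (chrom, start, end, gene_id) as minimal GFF3."""
    with open(path, "w") as f:
        f.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            f.write(
                f"{row.chrom}\tmilkgwas\tgene\t{row.start}\t{row.end}\t.\t+\t.\t"
                f"ID={row.gene_id}\n"
            )


def genic_blocks_to_genes(marker_map: pd.DataFrame) -> pd.DataFrame:
    """Convert contiguous genic-flagged marker runs into gene features
    (used by the synthetic writers so downstream gene flagging has a
    GFF3 to read)."""
    rows = []
    gid = 0
    for chrom, sub in marker_map.groupby("chrom", sort=False):
        genic = sub["genic"].to_numpy()
        pos = sub["pos"].to_numpy()
        j = 0
        while j < genic.size:
            if genic[j]:
                k = j
                while k + 1 < genic.size and genic[k + 1]:
                    k += 1
                gid += 1
                rows.append(
                    {
                        "chrom": chrom,
                        "start": int(pos[j]),
                        "end": int(pos[k]),
                        "gene_id": f"gene_{gid}",
                    }
                )
                j = k + 1
            else:
                j += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


# ------------------------------------------------------------- QTL intervals


def write_qtl_tsv(qtl: pd.DataFrame, path) -> None:
    qtl.to_csv(path, sep="\t", index=False)
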