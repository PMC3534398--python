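"""Synthetic sire-population generator.

Emulates the data structure of a progeny-tested dairy-bull GWAS: a
multi-generation pedigree, a dense autosomal SNP panel transmitted by
gene dropping, a mostly-polygenic genetic architecture with a minority
of moderate-effect QTL, and EBV proxies whose reliabilities match a
prescribed range.  Defaults are a scaled-down analogue of an Italian
Brown Swiss sire panel: ~29 autosomes, ~50k-chip marker density scaled
down, milk-flow trait heritabilities in 0.02-0.42 and mean EBV
reliabilities in 0.38-0.60.

The simulation deliberately does *not* model linkage disequilibrium,
selection, or genetic correlations among traits; each trait is an
independent run of the generator.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, Pedigree, TrueEffects, check_marker_map

#: heritability and mean EBV reliability typical of milk-flow traits
#: (total milking time, ascending time, time at plateau, descending
#: time, maximum and average milk flow) in Brown Swiss sire evaluations.
MILK_FLOW_TRAITS: dict[str, tuple[float, float]] = {
    "TMT": (0.11, 0.55),
    "AT": (0.02, 0.46),
    "TP": (0.32, 0.59),
    "DT": (0.05, 0.38),
    "MMF": (0.42, 0.60),
    "AVGF": (0.29, 0.58),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic population.

    The defaults produce ~640 sires on 29 chromosomes x 100 markers with
    a 30%-of-genetic-variance QTL component spread over 30 loci — a
    desk-scale analogue of a 1,351-sire, 33,074-SNP panel.
    """

    n_founders: int = 160
    n_generations: int = 4
    offspring_per_mating: int = 2
    n_chromosomes: int = 29
    markers_per_chromosome: int = 100
    chromosome_length: int = 120_000_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int = 30
    qtl_variance: float = 0.30          # fraction of genetic variance
    h2: float = 0.25
    phenotypic_variance: float = 1.0
    reliability_range: tuple[float, float] = (0.38, 0.60)
    gene_fraction: float = 0.30
    qtl_effect_dist: str = "normal"     # or "equal": equal variance shares
    seed: int = 20260101

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if self.n_generations < 1:
            raise ValueError("need at least 1 generation")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0.0 <= self.qtl_variance <= 1.0:
            raise ValueError("qtl_variance must be in [0, 1]")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")
        if self.n_qtl > self.n_chromosomes * self.markers_per_chromosome:
            raise ValueError("n_qtl exceeds total marker count")
        rlo, rhi = self.reliability_range
        if not (0 < rlo <= rhi <= 1.0):
            raise ValueError("reliability_range must be within (0, 1]")
        if self.qtl_effect_dist not in ("normal", "equal"):
            raise ValueError("qtl_effect_dist must be 'normal' or 'equal'")

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.markers_per_chromosome

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Independent deterministic substream per stage."""
    tag = zlib.crc32(stream.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([config.seed, tag]))


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Random-mating pedigree with discrete generations.

    Generation 0 holds ``n_founders`` animals with unknown parents; each
    later generation adds ``n_founders // 2`` matings (a random male and
    female of the previous generation, drawn with replacement) with
    ``offspring_per_mating`` offspring each.
    """
    rng = _rng(config, "pedigree")
    animal, sire, dam, gen, sex = [], [], [], [], []
    next_id = 1
    for i in range(config.n_founders):
        animal.append(next_id)
        sire.append(0)
        dam.append(0)
        gen.append(0)
        sex.append(i % 2)  # alternate male/female so both sexes exist
        next_id += 1
    prev = list(range(config.n_founders))
    n_matings = config.n_founders // 2
    for g in range(1, config.n_generations):
        males = [i for i in prev if sex[i] == 0]
        females = [i for i in prev if sex[i] == 1]
        cur: list[int] = []
        for _ in range(n_matings):
            si = males[rng.integers(len(males))]
            di = females[rng.integers(len(females))]
            for _ in range(config.offspring_per_mating):
                animal.append(next_id)
                sire.append(animal[si])
                dam.append(animal[di])
                gen.append(g)
                sex.append(int(rng.integers(2)))
                cur.append(len(animal) - 1)
                next_id += 1
        # guard against a sex dying out in a tiny population
        if not any(sex[i] == 0 for i in cur):
            sex[cur[0]] = 0
        if not any(sex[i] == 1 for i in cur):
            sex[cur[-1]] = 1
        prev = cur
    return Pedigree(
        animal=np.array(animal),
        sire=np.array(sire),
        dam=np.array(dam),
        generation=np.array(gen),
    )


def simulate_marker_map(config: SimulationConfig) -> pd.DataFrame:
    """Evenly-spread jittered marker positions; genic flags in blocks.

    Genic markers mimic genes plus 500 kb regulatory flanks by flagging
    contiguous blocks of markers totalling ``gene_fraction`` of the
    panel.
    """
    m = config.markers_per_chromosome
    if config.chromosome_length < 2 * m:
        raise ValueError("chromosome_length too small for requested markers")
    rng = _rng(config, "map")
    rows = []
    spacing = config.chromosome_length // (m + 1)
    for c in range(1, config.n_chromosomes + 1):
        base = spacing * np.arange(1, m + 1)
        jitter = rng.integers(0, max(1, spacing // 2), size=m)
        pos = np.sort(base + jitter)
        # enforce strictly increasing
        pos = np.maximum.accumulate(pos + np.arange(m))
        for k in range(m):
            rows.append((f"snp_{c}_{k + 1}", c, int(pos[k]), False))
    frame = pd.DataFrame(rows, columns=["name", "chrom", "pos", "genic"])
    n_genic = int(round(config.gene_fraction * len(frame)))
    block = max(1, m // 20)  # ~5% of a chromosome per gene block
    flagged = 0
    genic = np.zeros(len(frame), dtype=bool)
    order = rng.permutation(config.n_chromosomes)
    while flagged < n_genic:
        c = order[flagged // block % config.n_chromosomes]
        start_in_chrom = int(rng.integers(0, m))
        lo = c * m + start_in_chrom
        hi = min(lo + block, (c + 1) * m)
        take = ~genic[lo:hi]
        room = int(take.sum())
        if room == 0:
            order = rng.permutation(config.n_chromosomes)
            continue
        use = min(room, n_genic - flagged)
        idx = np.flatnonzero(take)[:use] + lo
        genic[idx] = True
        flagged += use
    frame["genic"] = genic
    return check_marker_map(frame)


def simulate_genotypes(
    pedigree: Pedigree, marker_map: pd.DataFrame, config: SimulationConfig
) -> GenotypeMatrix:
    """Gene dropping: founders at Hardy-Weinberg, offspring inherit one
    allele per parent per marker (loci unlinked)."""
    rng = _rng(config, "genotypes")
    p = len(marker_map)
    n = len(pedigree)
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=p)
    pos = pedigree.indices()
    geno = np.zeros((n, p), dtype=np.float64)

    def transmit(parent_geno: np.ndarray) -> np.ndarray:
        # allele transmitted per marker given parent genotype in {-1,0,1}
        allele = np.where(parent_geno == 1.0, 1.0, 0.0)
        het = parent_geno == 0.0
        allele[het] = rng.integers(0, 2, size=int(het.sum()))
        return allele

    for i in range(n):
        s, d = int(pedigree.sire[i]), int(pedigree.dam[i])
        if s == 0 and d == 0:
            geno[i] = rng.binomial(2, freqs) - 1.0
        elif s != 0 and d != 0:
            geno[i] = transmit(geno[pos[s]]) + transmit(geno[pos[d]]) - 1.0
        else:
            raise ValueError(f"animal {pedigree.animal[i]} has a single known parent")
    return GenotypeMatrix(
        animal_ids=pedigree.animal.copy(),
        marker_map=marker_map.copy(),
        geno=geno,
    )


def plant_qtl(
    marker_map: pd.DataFrame,
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
) -> TrueEffects:
    """Choose ``n_qtl`` polymorphic markers and scale their effects so the
    expected QTL variance Σ_j 2 q_j (1 - q_j) β_j² equals
    ``qtl_variance * h2 * phenotypic_variance`` exactly."""
    p = genotypes.n_markers
    beta = np.zeros(p)
    if config.n_qtl == 0:
        return TrueEffects(beta=beta, qtl_indices=np.array([], dtype=np.int64))
    rng = _rng(config, "qtl")
    maf = genotypes.maf()
    poly = np.flatnonzero(maf > 0)
    if poly.size < config.n_qtl:
        raise ValueError("not enough polymorphic markers to plant QTL")
    qtl = np.sort(rng.choice(poly, size=config.n_qtl, replace=False))
    q = genotypes.allele_freq()[qtl]
    het = 2.0 * q * (1.0 - q)
    if config.qtl_effect_dist == "equal":
        # each QTL contributes the same variance share
        raw = rng.choice([-1.0, 1.0], size=config.n_qtl) / np.sqrt(het)
    else:
        raw = rng.normal(size=config.n_qtl)
        raw[raw == 0] = 1.0
    target = config.qtl_variance * config.h2 * config.phenotypic_variance
    current = np.sum(raw**2 * het)
    if current <= 0 and target > 0:
        raise ValueError("requested QTL variance unattainable: chosen markers monomorphic")
    scale = np.sqrt(target / current) if target > 0 else 0.0
    beta[qtl] = raw * scale
    return TrueEffects(beta=beta, qtl_indices=qtl)


def simulate_ebv_proxies(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    effects: TrueEffects,
    config: SimulationConfig,
    trait: str = "TRAIT",
) -> pd.DataFrame:
    """True breeding values plus EBV proxies with prescribed reliability.

    TBV_i = x_i'β + u_i where u is a polygenic deviate bred down the
    pedigree (founders ~ N(0, σ²_poly); offspring = parent mean plus a
    Mendelian-sampling deviate of variance σ²_poly / 2).  The EBV proxy
    mixes standardized TBV with independent noise so that
    cor²(EBV, TBV) ≈ r², with r² drawn per animal from
    ``reliability_range``.  Parent-average columns (mean parental EBV,
    quarter-sum parental reliability) are emitted for de-regression.
    """
    rng = _rng(config, "proxies")
    n = len(pedigree)
    sigma2_g = config.h2 * config.phenotypic_variance
    sigma2_poly = max(0.0, (1.0 - config.qtl_variance) * sigma2_g)
    pos = pedigree.indices()
    u = np.zeros(n)
    for i in range(n):
        s, d = int(pedigree.sire[i]), int(pedigree.dam[i])
        if s == 0 and d == 0:
            u[i] = rng.normal(0.0, np.sqrt(sigma2_poly)) if sigma2_poly > 0 else 0.0
        else:
            ms = rng.normal(0.0, np.sqrt(sigma2_poly / 2.0)) if sigma2_poly > 0 else 0.0
            u[i] = 0.5 * (u[pos[s]] + u[pos[d]]) + ms
    tbv = genotypes.geno @ effects.beta + u

    r2 = rng.uniform(config.reliability_range[0], config.reliability_range[1], size=n)
    sd_tbv = float(np.std(tbv))
    if sd_tbv > 0:
        z = (tbv - tbv.mean()) / sd_tbv
        noise = rng.normal(size=n)
        ebv = (np.sqrt(r2) * z + np.sqrt(1.0 - r2) * noise) * sd_tbv + tbv.mean()
    else:
        ebv = np.zeros(n)

    pa_ebv = np.full(n, np.nan)
    pa_rel = np.full(n, np.nan)
    for i in range(n):
        s, d = int(pedigree.sire[i]), int(pedigree.dam[i])
        if s != 0 and d != 0:
            si, di = pos[s], pos[d]
            pa_ebv[i] = 0.5 * (ebv[si] + ebv[di])
            pa_rel[i] = 0.25 * (r2[si] + r2[di])
    return pd.DataFrame(
        {
            "animal": pedigree.animal,
            "trait": trait,
            "tbv": tbv,
            "ebv": ebv,
            "reliability": r2,
            "pa_ebv": pa_ebv,
            "pa_reliability": pa_rel,
        }
    )


@dataclass
class SyntheticStudy:
    """One full synthetic dataset (single trait)."""

    config: SimulationConfig
    pedigree: Pedigree
    marker_map: pd.DataFrame = field(repr=False)
    genotypes: GenotypeMatrix = field(repr=False)
    effects: TrueEffects = field(repr=False)
    proxies: pd.DataFrame = field(repr=False)


def simulate_study(config: SimulationConfig, trait: str = "TRAIT") -> SyntheticStudy:
    """Run every stage of the generator in order."""
    ped = simulate_pedigree(config)
    mmap = simulate_marker_map(config)
    geno = simulate_genotypes(ped, mmap, config)
    eff = plant_qtl(mmap, geno, config)
    prox = simulate_ebv_proxies(ped, geno, eff, config, trait=trait)
    return SyntheticStudy(config, ped, mmap, geno, eff, prox)
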