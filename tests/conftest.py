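import numpy as np
import pandas as pd
import pytest

from milkgwas import SimulationConfig, simulate_study
from milkgwas.types import GenotypeMatrix


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_founders=80,
        n_generations=3,
        offspring_per_mating=2,
        n_chromosomes=4,
        markers_per_chromosome=50,
        n_qtl=8,
        qtl_variance=0.4,
        h2=0.3,
        seed=2024,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


def make_genotypes(geno, chrom=None, pos=None):
    """Build a GenotypeMatrix from a raw code array for toy tests."""
    geno = np.asarray(geno, dtype=float)
    n, p = geno.shape
    chrom = np.ones(p, dtype=int) if chrom is None else np.asarray(chrom)
    pos = (np.arange(1, p + 1) * 1000 if pos is None else np.asarray(pos))
    marker_map = pd.DataFrame(
        {
            "name": [f"m{j}" for j in range(p)],
            "chrom": chrom,
            "pos": pos,
            "genic": False,
        }
    )
    return GenotypeMatrix(
        animal_ids=np.arange(1, n + 1), marker_map=marker_map, geno=geno
    )
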