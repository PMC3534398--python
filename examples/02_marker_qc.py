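"""Marker quality control on a panel with missing calls.

Damages a clean simulated panel (missing genotypes, a distorted
marker), then filters by call rate < 0.90, MAF < 0.05 and
Hardy-Weinberg disequilibrium.
"""

import numpy as np

from milkgwas import SimulationConfig, apply_filters, simulate_study

study = simulate_study(SimulationConfig(
    n_founders=300, n_generations=1, n_chromosomes=5,
    markers_per_chromosome=60, maf_range=(0.02, 0.5), seed=7,
))
geno = study.genotypes
rng = np.random.default_rng(8)

# knock out 15% of calls for the first 10 markers (call-rate failures)
mask = rng.random((geno.n_animals, 10)) < 0.15
geno.geno[:, :10][mask] = np.nan
# turn marker 20 into a heterozygote-free oddity (HWE failure)
geno.geno[:, 20] = np.where(geno.geno[:, 20] == 0.0, 1.0, geno.geno[:, 20])

filtered, report = apply_filters(geno, call_rate_min=0.90, maf_min=0.05,
                                 hwe_alpha=1e-6)
print(f"markers in:  {report.n_markers}")
print(f"markers out: {report.n_surviving}")
print("removed by reason:")
print(report.removals_by_reason().to_string())
print("surviving markers per chromosome:")
print(report.per_chromosome_counts().to_string())
# Low-MAF markers dominate the removals because the panel was simulated
# with founder frequencies down to 0.02; the remaining missing calls
# are mean-imputed so downstream regression sees a dense matrix.
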