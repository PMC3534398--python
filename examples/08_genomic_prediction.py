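"""Direct genomic values from nested marker subsets.

Splits sires into a discovery set (EBV reliability > 0.60) and a
prediction set, estimates marker effects on discovery DRPs, and asks
how much of the all-marker DGV-EBV correlation and genomic variance
nested subsets of top markers recover.
"""

import numpy as np

from milkgwas import (
    BLassoConfig,
    SimulationConfig,
    build_dgv_table,
    correlation_recovery,
    estimate_lambda,
    genomic_variance_proportions,
    run_gibbs,
    simulate_study,
    split_by_reliability,
)

study = simulate_study(SimulationConfig(
    n_founders=700, n_generations=1, n_chromosomes=10,
    markers_per_chromosome=80, n_qtl=15, qtl_variance=0.5, h2=0.35,
    qtl_effect_dist="equal", reliability_range=(0.38, 0.80), seed=51,
))
split = split_by_reliability(study.proxies, threshold=0.60)
print(f"discovery sires:  {split.n_discovery} (reliability > 0.60)")
print(f"prediction sires: {split.n_prediction}")

g_disc = study.genotypes.subset_animals(split.discovery_ids)
prox = study.proxies.set_index("animal")
y_disc = prox.loc[split.discovery_ids, "ebv"].to_numpy()

cfg = BLassoConfig(n_iter=4000, burn_in=800, thin=2, use_polygenic=False,
                   n_exploratory_chains=1, exploratory_length=1200, seed=52)
lam, _ = estimate_lambda(y_disc, g_disc, None, cfg)
post = run_gibbs(y_disc, g_disc, None, cfg.with_(lam=lam))

g_pred = study.genotypes.subset_animals(split.prediction_ids)
table = build_dgv_table(g_pred, post.beta_mean, (25, 50, 100, 300))
ebv_pred = prox.loc[split.prediction_ids, "ebv"].to_numpy()

rec = correlation_recovery(ebv_pred, table)
var = genomic_variance_proportions(table)
summary = rec.merge(var[["subset", "proportion"]], on="subset")
print("\nsubset  cor(DGV,EBV)  recovery  var.proportion")
for row in summary.itertuples(index=False):
    print(f"{row.subset:>6}  {row.correlation:12.3f}  {row.recovery:8.3f}  "
          f"{row.proportion:14.3f}")
# With a sparse planted architecture a few dozen top markers already
# recover the full-panel correlation (small subsets can even beat the
# full panel, which carries estimation noise from hundreds of null
# markers), while the genomic-variance proportion climbs smoothly
# toward 1 as the nested subsets grow.
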