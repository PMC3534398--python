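# milkgwas

Bayesian LASSO GWAS toolkit for milk-flow (milkability) traits in dairy
sires: marker-effect estimation from de-regressed proofs with a
pedigree polygenic effect, within-chain permutation significance,
a BayesC-π cross-check, QTL-region annotation, and direct-genomic-value
prediction analytics — with a built-in synthetic population generator
so every stage can be exercised and validated without proprietary
breeding-program data.

## Who it is for

Animal geneticists analysing progeny-test data where the response per
sire is an EBV-derived pseudo-phenotype (a de-regressed proof, DRP)
rather than a raw phenotype: milkability traits such as total milking
time (TMT), ascending time (AT), time at plateau (TP), descending time
(DT), and maximum/average milk flow (MMF, AVGF), with heritabilities
from 0.02 to 0.42 and EBV reliabilities around 0.38–0.60.

## The model

All p markers are fitted jointly with a polygenic sire effect:

    y = μ1 + s + Xβ + e,
    s ~ N(0, A σ²_s),        e ~ N(0, I σ²_e),
    β_j | τ²_j, σ²_e ~ N(0, τ²_j σ²_e),   τ²_j ~ Exp(λ²/2)

where y are DRPs, X the −1/0/1 genotype codes, and A the pedigree
numerator relationship matrix (guarding against spurious association
from population structure).  Marginally each β_j carries a
double-exponential (Laplace) prior — the Bayesian LASSO — whose
shrinkage parameter λ is fixed from the average of several short
exploratory chains in which λ² is sampled under a diffuse gamma prior.
The reference long-chain protocol is 100,000 iterations, 30,000
burn-in, storing every 30th sample (2,333 stored draws).

Significance is declared by within-chain permutation: a second chain
reshuffles the response against the genotype rows every h = 3
iterations; the stored null draws per marker supply critical values at
the 0.25α and (1 − 0.25α) percentiles.  A BayesC-π sampler (point mass
at zero, common non-null variance, uniform prior on the null
proportion π) cross-checks the significant fraction.  Top markers are
chained into regions (within 20 panel positions), regions are scored
by their share of genomic variance and annotated against bundled
literature QTL intervals, and direct genomic values
DGV_i = Σ_j x_ij β̂_j drive discovery/prediction evaluation over nested
top-marker subsets.

## Worked example

`examples/` contains one short script per capability.  For instance
`python examples/06_bayescpi.py` simulates 600 sires × 400 markers with
20 causal loci (π_true = 0.95) and estimates the null-marker
proportion:

```
markers: 400, causal: 20 (pi_true = 0.950)
posterior mean pi: 0.917
implied non-null markers: 33
mean inclusion probability - causal markers: 0.999
mean inclusion probability - null markers:   0.033
```

π̂ lands near its true value and planted markers are cleanly separated
from the null background.  `python examples/04_blasso_gwas.py` runs the
full estimation stack (λ from exploratory chains, Gibbs sampling with
the pedigree polygenic term) and prints the top markers by posterior
mean effect, flagging which of them are the planted QTL.

A shell pipeline is also available via the `milkgwas` command
(`simulate`, `qc`, `deregress`, `gwas`, `permute`, `significance`,
`cpi`, `regions`, `dgv`), each a thin wrapper over the library.

## Limitations

The generator mates at random (no selection history), simulates
unlinked loci (no LD tuning) and independent traits; see
`docs/methods.md` for what that does and does not validate, including
the measured conservativeness of the permutation percentile rule.
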