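# Methods

## Model and samplers

The core model is a joint shrinkage regression of de-regressed proofs
(DRPs) on all SNP genotypes with a polygenic sire effect:

    y = μ1 + s + Xβ + e,   s ~ N(0, A σ²_s),   e ~ N(0, I σ²_e).

One record per sire is fitted (the DRP already condenses the sire's
daughter information), genotypes are coded −1/0/1 and column-centred,
and y is mean-centred before sampling; neither centring changes the
posterior of β.

**Bayesian LASSO.**  Marker effects follow the conditional-prior
hierarchy β_j | τ²_j, σ²_e ~ N(0, τ²_j σ²_e), τ²_j ~ Exp(λ²/2), whose
marginal is a double-exponential prior with rate λ/σ_e.  Full
conditionals are standard: normal for μ and each β_j (residuals
maintained incrementally, so each marker update is O(n)),
inverse-Gaussian for 1/τ²_j, scaled-inverse-χ² for the variances, and
gamma for λ² when λ is sampled.  The samplers are numba-compiled, so
chains of tens of thousands of iterations at n ≈ 1,000 × p ≈ 2,000
run in minutes on one CPU.

**Polygenic block.**  With one record per sire the polygenic design is
the identity, so in the eigenbasis of A (A = U diag(d) U′) the full
conditional of the rotated effect is diagonal and the whole block is
drawn exactly in O(n²) per iteration.  A is built by the tabular
method over the full pedigree (diagonal 1 + F) and then restricted to
the genotyped subset, preserving ancestral ties; eigenvalues are
clipped at 1e−8 (one jitter attempt before rejecting a non-PSD
matrix).  When σ²_s and σ²_e are not separately identifiable (A = I)
the chain still mixes on their sum, which is the tested guarantee.

**λ protocol.**  λ is fixed before the final chain as the average of
the posterior means of n short exploratory chains that sample λ² under
a diffuse Gamma(0.1, 0.1) prior (default five chains of 50,000
iterations; desk-scale runs use one or two shorter chains).  A
dispersion screen flags exploratory chains whose means disagree
(CV > 0.5); the value is still returned, flagged.

**Priors.**  Scaled-inverse-χ² with ν = 4 for σ²_e and σ²_s, scales set
from the response variance (var(y)/2 and var(y)/4) unless overridden.
These are weak (4 effective observations) and wash out at the sample
sizes involved.

**BayesC-π.**  β_j = 0 with probability π, else N(0, σ²_β) with a
common σ²_β (scaled-inverse-χ², ν = 4, data-sized scale); π has a
uniform prior and a Beta full conditional; inclusion is sampled from
the marginal-likelihood odds.  Chain defaults mirror the LASSO
protocol.  (1 − π̂) is the model's own estimate of the non-null marker
fraction and is the quantity compared with the permutation method.

## De-regression

EBVs enter the GWAS as proofs de-regressed free of parental averages,
using the Garrick–Taylor–Fernando information-splitting system: from
the animal's reliability r² and its parent-average reliability r²_PA
the information contents Z′Z_PA and Z′Z_i are recovered
(λ = (1 − h²)/h²), the own-information right-hand side is formed, and
DRP = y_i / Z′Z_i.  Weights (1 − h²)/((c + (1 − r²*)/r²*) h²) with
c = 0.5 are computed but the regression defaults to unweighted
residuals (homogeneous e).  Reliabilities are clamped to [0.01, 0.99]
(parent averages to ≤ 0.49, their two-parent ceiling); records whose
own reliability does not exceed the parent average's are flagged and
excluded downstream.  In the r² → 1, no-parent limit the DRP exceeds
the EBV by ≈ 2(1 − r²), i.e. converges to the EBV.

## Marker QC

Call rate, MAF and a 1-df χ² Hardy–Weinberg test are computed on the
unfiltered panel; thresholds are call rate < 0.90, MAF < 0.05 (both
strict) and HWE p < 1e−6 (α configurable; a χ² rather than exact test,
adequate at these sample sizes).  A marker failing several criteria is
attributed to the first in call_rate → maf → hwe order, which makes
the report counts reconcile exactly.  Missing genotypes surviving QC
are mean-imputed per marker (preserves allele frequency; zero-fill
available).  Filtering is idempotent and threshold-monotone.

## Significance by within-chain permutation

A permuted chain reshuffles the response vector against the genotype
rows every h iterations (default h = 3; h = L degenerates to ordinary
across-chain permutation).  The response and its polygenic index move
together, preserving the y↔A linkage while severing the
genotype–phenotype one; in implementation the rows of X are physically
permuted, and the fitted marker contribution is recovered from the
running residual, so the permutation costs one row gather.  The stored
null draws per marker give critical values at the 0.25α and (1 − 0.25α)
percentiles (per-marker by default; a pooled variant broadcasts the
percentiles of all draws).  A marker is significant when its
posterior-mean effect falls outside its band.  "Multiple-comparison
corrected p < 0.001" selection is the same band at α = 0.001.

**Measured operating characteristics.**  The percentile rule is
*conservative* for posterior-mean statistics: null draws mix posterior
spread with across-permutation spread of the conditional mean, so
their variance exceeds that of the null distribution of posterior
means.  The global-null rejection rate at α = 0.05 (measured by the
calibration experiment at n = 1,000, p = 2,000) is far below 0.05.
This is a property of the percentile formula itself, not of chain
length or scope; the package therefore guarantees (and tests) that the
null rejection rate stays *below* α, that bands at smaller α strictly
contain bands at larger α, and that rejection probability is monotone
in planted-QTL size — not exact α-calibration.

## Regions, annotation, prediction

Top-k markers (|β̂| ranked, ties broken by map order) chain into
regions when on one chromosome within 20 panel positions, with
transitive closure.  A region's variance share is
Var(DGV_region)/Var(DGV_all) across animals; under linkage equilibrium
single-marker shares sum to 1 and shares of nested subsets are
monotone.  Regions are tagged with every bundled QTL class (MSPD, UT,
SCS, SCC, CM, MY — 1-based inclusive bp intervals, closed-interval
overlap); no-overlap regions are "novel".

DGVs are Σ_j x_ij β̂_j on the post-imputation coding, exactly additive
over marker-set partitions.  Sires split into discovery (reliability
strictly > 0.60) and prediction sets; effects are estimated on
discovery DRPs and evaluated on the prediction set via Pearson
correlation with EBV over the nested top-|effect| ladder
{25, 50, 100, 300, 3000, 10000, all} (sizes above p collapse onto
"all").  Gene/regulatory flags cover gene bodies ± 500 kb.  The
"proportion of significant-marker DGV explained by genic markers" is
ambiguous as usually stated; the default here is the median across
animals of the per-animal ratio DGV_gene/DGV_sig (animals with
|DGV_sig| under 1e−8 × its SD excluded), with the variance ratio
Var(DGV_gene)/Var(DGV_sig) exposed as an alternative — for two
independent equal-variance halves both definitions give 0.5.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not any particular population's history:

* **Pedigree** — discrete generations, random mating (n_founders/2
  matings per generation, sampled with replacement), alternating
  founder sexes.  No selection; real sire pedigrees descend from heavy
  selection, a documented realism gap.
* **Genotypes** — founders at Hardy–Weinberg with frequencies uniform
  in maf_range; descendants by gene dropping, each parent transmitting
  one allele per marker independently (unlinked loci — no LD, so
  neighbouring markers carry no signal about a QTL between them).
* **QTL** — n_qtl polymorphic markers, effects scaled so
  Σ 2q_j(1−q_j)β_j² equals qtl_variance × h² × phenotypic variance
  exactly; effect sizes drawn normal (default) or set to equal
  variance shares ("equal") when a design needs every QTL at a stated
  size.
* **EBV proxies** — TBV = Xβ + polygenic deviate bred down the
  pedigree (founder variance (1 − qtl_variance) h², Mendelian-sampling
  variance half that); EBV mixes standardized TBV with independent
  noise so cor²(EBV, TBV) ≈ r², r² uniform in reliability_range.  Only
  this marginal reliability structure matters downstream; the
  multi-trait evaluation that produces real EBVs is out of scope.
  Parent-average EBV and reliability columns feed the de-regression.

Defaults are a scaled-down analogue of a Brown Swiss sire panel: 160
founders × 4 generations (640 animals), 29 chromosomes × 100 markers,
30 QTL carrying 30% of genetic variance, h² = 0.25 defaulting with
per-trait values available for the six milk-flow traits (0.02–0.42),
reliabilities 0.38–0.60, 30% genic markers in contiguous blocks
(approximating genes + 500 kb flanks at map scale).  Identical configs
(including seed) give bit-identical outputs; each stage draws from its
own seeded substream.

Because loci are unlinked and mating is random, passing tests validate
the estimation machinery and its calibration, not LD-driven fine
mapping; "within 5 positions" adjacency credit in recovery experiments
is effectively exact-marker recovery here.

## Validation experiment sizes

The reference experiments (tests and `scripts/acceptance.py`) run at
n = 1,000 sires × p = 2,000 markers with chains of 6,000–20,000
iterations — long enough that the measured quantities (quadrature gap
< 0.02, null rejection rate, recovery counts, π̂) are stable — and at
toy sizes for exact algebra.  The QTL-recovery design plants 10
equal-variance QTL at 1% of phenotypic variance each (h² = 0.35) in an
unrelated 1,000-sire panel and uses the EBV proxy at the default
reliability range as the response, matching how this pipeline is
actually driven (EBV-derived proofs, never raw phenotypes).

## Numerical choices

* Gibbs updates guard degenerate cases: monomorphic (zero-variance)
  markers are pinned at β = 0; the inverse-Gaussian mean is capped at
  1e8 (β ≈ 0) and 1/τ² floored at 1e−12.
* Quantiles are NumPy linear-interpolation quantiles; per-marker
  critical values require ≥ 100 null draws (pooled scope relaxes this).
* ESS for the variance chains via arviz (autocorrelation fallback
  included); a constant chain reports ESS = sample count with a
  degeneracy flag.
* Stored samples land on iterations burn_in + thin, burn_in + 2·thin,
  …, giving ⌊(L − burn_in)/thin⌋ draws (2,333 for the reference
  protocol).
* Ties in |β̂| rankings break by marker map order everywhere, making
  region and subset construction deterministic.

## Known limitations

No LD simulation or LD-aware region refinement; single-trait runs only
(no genetic correlations); χ²-based HWE only; the permutation
percentile rule is conservative as measured above; PLINK-text but not
binary PLINK input; the bundled QTL intervals are a convenience
compilation for annotation, not a curated database.
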