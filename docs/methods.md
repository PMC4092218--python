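# Methods

`teatqtl` re-implements, as a tested pipeline, the association workflow
used for counted traits in pedigreed livestock: number of teats (NTE) in a
Large White pig cohort is the motivating setting throughout.  Real cohorts
of this kind are proprietary, so the package ships a first-class synthetic
cohort generator whose defaults encode the study conditions the pipeline
is meant for, and every downstream stage is validated against the
generator's known truth.

## Pipeline model

### 1. Pedigree BLUP (animal model)

Phenotypes are analysed with the single-trait animal model

    y = X b + Z a + e,    a ~ N(0, A sigma2_a),   e ~ N(0, I sigma2_e)

where `A` is the pedigree numerator relationship matrix (tabular method,
inbreeding included) and the fixed effects are sex and farm.  Henderson's
mixed-model equations are solved densely and the coefficient-matrix
inverse gives exact prediction-error variances, so per-animal reliability
is `r2_i = 1 - PEV_i / sigma2_a` with no approximation.  This is feasible
because the cohorts here are desk-scale (thousands of animals); production
evaluations use iterative solvers and approximate reliabilities instead.
Parent-average reliability uses the standard `(r2_sire + r2_dam) / 4`,
with unknown parents contributing zero.

### 2. Deregression and weights

EBVs blend own, progeny and parent information; regressing markers on raw
EBVs double-counts families.  The deregression follows the established
2x2-system recipe (`src/teatqtl/deregress.py` documents the equations):
with `lambda = (1 - h2)/h2`, the parent-average and individual information
contents `Z'Z_PA` and `Z'Z_i` are reconstructed from `(r2_PA, r2_i)`, the
coefficient matrix is applied to `(pa_ebv, ebv)` to recover right-hand
sides, and `dEBV = rhs_i / Z'Z_i` with reliability
`r2* = 1 - lambda/(Z'Z_i + lambda)`.  The residual weight

    w = (1 - h2) / [ (c + (1 - r2*)/r2*) * h2 ]

uses `c`, the fraction of genetic variance not captured by markers,
default 0.5 (exposed in config; the source analyses do not report their
value).  On the default cohort the weights are bimodal around 1: animals
without progeny fall below 1, progeny-tested sires above it.

One caution discovered during testing: the intuitive inequality
`r2* <= r2_i` is *not* implied by this algebra.  When the parent average
is uninformative (`r2_PA -> 0`) the reconstructed `Z'Z_i` exceeds
`lambda r2_i/(1 - r2_i)` and `r2*` slightly exceeds `r2_i` — the parent
equations drag the raw EBV reliability down, and removing them releases
that information.  The implementation keeps the algebra as cited and does
not clamp.

### 3. Genotype QC

Filters and defaults follow dense-Beadchip convention: GenCall < 0.7
(optional per-SNP score column; pass-through when absent, since chip
intensities cannot be simulated meaningfully), no physical position,
call rate < 0.95, MAF < 0.01, applied in that order with first-failure
attribution; animals below 0.90 call rate are removed first.  Residual
missing dosages are mean-imputed.

### 4. Weighted spike-and-slab regression (Bayesian variable selection)

All SNPs are fitted simultaneously:

    y = mu + X beta + e,  e_i ~ N(0, sigma2_e / w_i)
    beta_j ~ (1 - gamma_j) N(0, sigma2_0) + gamma_j N(0, sigma2_1)
    gamma_j ~ Bernoulli(pi1)

with `pi1 = 0.001` fixed (one SNP in a thousand in the large-effect
component) and `sigma2_1 = kappa sigma2_0`, `kappa = 100` fixed.  The
two-Gaussian parameterisation with a fixed variance ratio is the standard
stochastic-search form for "small effects" vs "large effects" components;
the ratio and the priors on `sigma2_0` (scaled-inverse-chi-square, df 4,
scale matched to half the response variance spread over the markers) are
configurable.  Each Gibbs cycle updates `(gamma_j, beta_j)` jointly per
SNP — the component choice integrates `beta_j` out against the current
residuals — then `mu`, then `sigma2_e` and `sigma2_0` from their
conditionals.  A random-walk Metropolis-Hastings step on `log sigma2_0`
is available behind `mh_sigma0` (default off: the Gibbs draw is exact
here; the flag exists because some implementations of this model class
use MH for the variance and it is useful for comparability).

Residuals are maintained incrementally (O(np) per cycle); genotype
columns are stored float32 Fortran-order with float64 accumulators.  Two
oracles guard correctness: the deviance recomputed from scratch at the
final state must match the incrementally maintained value, and on p <= 3
instances the inclusion probabilities must match exhaustive enumeration
of all gamma configurations (exact for fixed variance components).
Convergence is monitored with the Gelman-Rubin PSRF on the per-chain
deviance traces (floored at 1 so identical chains report exactly 1).

Default chain: 500,000 cycles, 5,000 burn-in, 2 chains.  The desk-scale
profile used by the tests and the validation scenarios is 20,000 cycles,
2,000 burn-in, thinning 20 — sized so a full 10-seed recovery study runs
in minutes on one core while leaving the per-SNP inclusion frequencies
with Monte-Carlo error well below the BF > 10 decision boundary.

### 5. Bayes factors, regions, variance partition

Per SNP, `BF = [p_hat/(1 - p_hat)] / [pi1/(1 - pi1)]`; `p_hat = 1` is
capped at `1 - 1/(2 n_samples)` so the odds stay finite.  BF > 10 is
"strong", BF > 100 "decisive".  Significant SNPs are single-linkage
clustered per chromosome with a 2 Mb gap limit; clusters need >= 2
members by default (`min_snps=1` admits singletons — real analyses report
them).  Regions whose top SNPs exceed r2 = 0.7 merge regardless of
distance, transitively via union-find, so the result is order-independent
(`max_pairwise` is available behind a flag; the choice of which SNPs
represent a region for LD purposes is not standardised).

The variance partition works on the retained posterior samples of the
main run: per sample, `Var(X_r beta_r) / Var(X beta)` for each region,
plus a per-chromosome "rest" group, and a null expectation per chromosome
equal to the mean single-SNP variance among null-assigned SNPs times the
chromosome's SNP count (proportional to SNP count — the no-QTL baseline).
A literal second grouped re-estimation run would also be possible; the
grouped-sample estimator was chosen because it needs no second chain and
its identities (zero-effect regions give 0%, LD-free groups add to the
total) are directly testable.

Per-region diagnostics: the allele-substitution effect is the OLS
coefficient of phenotype on minor-allele dosage with sex and farm fixed
effects; gene action is classified from the three genotype-class means by
the dominance ratio `|d/a|` (<= 0.25 additive, > 1 overdominant, within
0.25 of 1 dominant, else partial dominant).

## The synthetic cohort: what it emulates, and what not

Defaults (all in `CohortConfig`):

| parameter | default | meaning |
|---|---|---|
| n_founders / generations | 500 / 2 | ~2,500-animal pedigree |
| sires, dams per generation | 50, 250 | heavy-tailed sire usage (Dirichlet 0.3); top sires reach hundreds of offspring |
| n_farms | 17 | farm fixed effect, ~N(0, 0.1^2) per farm |
| n_snps / chromosomes | 5,250 / 5 | 40 kb spacing, ~5,000 post-QC |
| LD blocks | 400 kb, latent corr 0.995 | median adjacent-SNP r2 ~ 0.8, near zero between blocks — commercial-line LD |
| trait | mean 15.3, SD 0.94, min 14, h2 0.42 | counted, round-then-truncate of a Gaussian latent (reproduces the culling skew) |
| QTL | 5 loci at 15/11/8/6/5 % of additive genetic variance | causal loci off-chip; LD neighbours carry the signal |
| genotyped panel | ~100 sires + 900 final-generation animals | the two reliability classes behind the weight split |

Founder haplotypes come from a Gaussian-copula block model (shared
per-block base MAF drawn U(0.02, 0.5), jitter 0.015); descendants by gene
dropping with Haldane recombination at 1 cM ~ 1 Mb.  The polygenic
background is dropped through the pedigree so that QTL + polygenic
variance meets the requested h2; the environmental variance fills to the
target phenotype SD.

Deliberate simplifications: no selection across generations, no
genotyping-error model, no X/Y chromosomes, no LD decay *within* blocks
(block membership is sharp), and a categorical trait produced by
truncation rather than an explicit threshold liability model.  Passing
tests on this generator therefore demonstrate that the pipeline recovers
a known architecture under realistic LD, family structure and
information heterogeneity — not that it would match any particular real
cohort's power.

Two generator choices deserve emphasis because the validation results
depend on them.  First, causal loci are excluded from the genotyped panel
(`qtl_on_chip=False`): that is the usual situation on a 40k chip and it
is what makes significant *regions* (several LD neighbours each with
BF > 10) rather than lone significant SNPs.  Second, the planted QTL
sizes (15/11/8/6/5 % of additive genetic variance) were set once so that
the architecture is recoverable at the information level of ~1,000
deregressed EBVs: smaller QTL (a few percent) fall below the detection
threshold implied by the pi1 = 0.001 prior at this sample size, which is
a property of the method, not a bug — the scenario is designed to probe
region calling and variance partition, not the power frontier.

## Numerical and degenerate-input policy

* All randomness flows from one root seed; chains derive per-chain seeds;
  the same seed reproduces cohorts and summaries bit-identically.
* Deregression rejects `r2_PA >= 0.5`, `r2_i >= 1`, and records whose
  individual information content is non-positive (EBV less informative
  than its parent average); cohort-level deregression drops such records
  (a per-record domain failure, reported via `drop_invalid=False`).
* `filter_snps` attributes each removed SNP to the first failing filter;
  filtering is idempotent.
* Region calling requires sorted input and breaks top-SNP ties toward the
  smaller position; `ld_r2` refuses constant vectors.
* BLUP raises on singular fixed-effect designs, naming the confounded
  column; with no records it returns the prior mean (EBV 0, reliability 0).

## Validation scenarios

`teatqtl.validate.run_scenario` runs the full stack on the default cohort
and scores it against the simulated truth.  A planted QTL counts as
recovered when its position lies inside a called region extended by one
LD block (400 kb at default spacing is wider than needed; 200 kb is used)
— flanking significant markers can sit on one side of an off-chip causal
locus.  Null calibration uses a smaller zero-QTL genome (~1,600 SNPs,
~560 genotyped animals, 10,000-cycle chains) and counts regions at the
decisive threshold.  Problem sizes for both were chosen so the whole
validation battery (10 recovery seeds + 10 null seeds) completes in
roughly a quarter of an hour on a single core.
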