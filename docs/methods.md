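# Methods

## Overview

`stackprs` builds polygenic scores by stacking: per p-value threshold, a
feed-forward network is trained on the thresholded SNP set; a linear
meta-learner then combines the networks' held-out predictions into one
score.  Everything upstream (QC, splitting, marginal GWAS) and alongside
(linear P+T / threshold-search scores, evaluation metrics) is part of the
package so the whole procedure runs on a laptop against simulated or
PLINK-1 data.

## Quality control

Variant filters run in a fixed order — missing call rate, minor-allele
frequency, Hardy–Weinberg exact test, strand-ambiguous alleles (A/T, C/G),
duplicate positions, imputation INFO — because the per-filter removal
counts depend on the order.  Defaults: rate > 0.05 removed, MAF < 0.01
removed, HWE p < 1e-10 removed, INFO < 0.7 removed; variants without an
INFO score (array data) pass the INFO filter.  Boundary conventions are
"strictly over / strictly under" throughout, so a variant at exactly 5%
missingness survives.

The HWE test is the exact conditional test: given the observed allele
counts, heterozygote counts of the right parity follow
P(h) ∝ n! / (n_AA! h! n_aa!) · 2^h, and the two-sided p-value sums P(h) over
all h with P(h) ≤ P(observed) (no mid-p).  The implementation works in log
space with a 1e-12 relative guard on the ≤ comparison; the test suite checks
it against exact rational enumeration for every table with up to 50
samples.  The test pools cases and controls by default (a controls-only
mask is accepted), and duplicate positions keep the variant with the lower
missing rate, then the lexicographically smaller id — both points are
conventions chosen here, since common practice varies.

## Splitting and GWAS

9:1 test split, then 8:2 validation split of the remainder (72/18/10),
stratified by case status for binary traits; per-stratum counts are rounded,
so partition case fractions match the cohort's within one individual.
Association is marginal, on the training partition only: closed-form simple
linear regression (t test, n−2 df) for quantitative traits, univariate
logistic regression by Newton/IRLS (gradient norm < 1e-8, Wald test) for
binary traits, both vectorised across variants.  Missing dosages are
mean-imputed within the training partition.  Degenerate fits — zero-variance
dosage, perfect separation, non-convergence — are recorded with beta 0,
p 1 and a `flag` column rather than raised, so one pathological variant
cannot abort a scan.  No covariates are included by default.  Threshold
selection is strict (`p < p_t`).

## Linear baselines

The additive score counts the summary-statistics effect allele: a variant
whose alleles are swapped relative to the genotype record contributes
`(2 − x)·b̂` — the count of the effect allele itself — rather than a bare
sign flip, which differs only by a constant per-cohort offset but keeps the
score an actual weighted allele count.  Allele sets that match neither way
raise, naming the variant; ambiguous pairs are already gone after QC.

Clumping is greedy by ascending p (ties: chromosome, position, then id):
the best remaining variant absorbs every unprocessed variant within 250 kb
on the same chromosome with dosage r² ≥ 0.1, computed on the training
partition's genotypes — no external LD panel.  P+T applies `p < 5e-8` to
the clumped set.  The threshold search clumps once, scores the validation
partition at each grid cutoff (default: 25 log-spaced points from 5e-8 to
1; a denser grid is configurable but changes efficiency, not behaviour),
picks the cutoff maximising the validation metric, and reports test scores.

## Base networks

Implemented directly in numpy: forward/backward passes, batch normalisation
(ε = 1e-5, running-stat momentum 0.1), inverted dropout (rate 0.5), Leaky
ReLU (α = 0.01), a logistic or identity output head, binary cross-entropy
or mean-squared-error loss, and Adam (lr 1e-3, β = 0.9/0.999).  Input
dosages are mean-imputed and standardised by training-partition mean/sd;
the constants are stored on the model.  Hidden widths divide the previous
width by an integer 1–4 per layer (depths 1–4); a chain reaching width < 1
marks the architecture invalid and the grid search skips it.  Depth 0 — no
hidden layer, so a plain affine-plus-link model — is also accepted; trained
by the same loop it converges to the logistic/linear-regression fit, which
the test suite verifies against an independent maximum-likelihood oracle
(validation BCE within 5%).

Early stopping: training halts after 10 epochs without a validation-loss
improvement of at least 1e-5 (500-epoch cap), and the best-validation
weights are restored.  These constants, the 256-sample minibatch size and
the full-batch switch below 512 training samples are package choices — the
approach is standard but specific values had to be fixed for
reproducibility; all are fields on `BaseModelSpec`.  One seed drives
initialisation, dropout masks and shuffling, so a spec retrains to
bit-identical weights.  Grid-search ties break toward fewer parameters,
then earlier grid order.

## Stacking

The threshold ladder must be strictly decreasing (default
5e-2 … 5e-8, fully configurable); thresholds selecting no variants are
dropped with a warning, and fewer than two surviving thresholds is an
error.  The meta-learner is unregularised — logistic regression (via
statsmodels) for binary traits, OLS for quantitative — with an intercept,
trained on validation-set base outputs only.  The validation set therefore
does triple duty: early stopping, architecture selection, and meta
training.  That reuse is deliberate (it keeps the test partition
completely untouched) but makes the *validation* metrics optimistic; all
reported comparisons use the test partition.

Stored validation metrics are computed from the meta fit itself — the
logistic fit's log-likelihood pushed through the Nagelkerke formula, or the
R² of the OLS fitted values — because on that scale the stacked model
provably dominates every single base model (each is a restriction of the
meta model class).  Evaluating instead on the sigmoid-transformed output
would break the exact nesting argument, since the Nagelkerke re-fit is
invariant only to affine maps.  The reported PRS for binary traits is
nevertheless the meta probability.  For LD-dense (imputed-style) inputs an
optional pre-clumping of each threshold set is available; it is off by
default.

## Evaluation metrics

ROC AUC uses the rank (Mann–Whitney) form with ties counted ½.  Nagelkerke
R² of a score re-fits a univariate logistic regression of phenotype on
score — the standard PRS-evaluation convention, which makes the metric
well-defined for any scorer — and applies
CS = 1 − exp((2/n)(L0 − L1)), N = CS / (1 − exp((2/n)L0)), capped to [0, 1].
Constant scores return 0; perfect separation approaches and is capped at 1.
Quantitative R² is the squared Pearson correlation, so affine
miscalibration of a score is not penalised.  AUC is reported on the single
held-out test partition; averaging over repeated splits is possible by
rerunning with different split seeds but is not the default.

## The simulator

Genotypes: variants form contiguous blocks; each gamete is a latent AR(1)
Gaussian within a block (parameter `within_block_r`), thresholded at the
normal quantile of the variant's MAF (uniform in [maf_low, maf_high],
defaults 0.05–0.5) to a Bernoulli allele; dosage = two independent gametes.
This is the simplest generator with tunable within-block r², exactly
independent blocks, and valid hard calls.  The induced genotype correlation
is attenuated relative to the latent one; the tests pin it against the
bivariate-normal orthant probability.  Block k starts at 1 + k·10⁶ bp with
1 kb spacing inside, so distinct blocks are farther apart than the 250 kb
clumping window.

Phenotypes: genetic score = Σ β_j (x_j − x̄_j) + Σ c_ab (x_a − x̄_a)(x_b − x̄_b).
Centring makes the interaction terms near-orthogonal to the marginal
effects, which is what lets epistatic architectures hide from marginal GWAS
unless the participating SNPs also carry small additive effects.  Noise is
residualised against the genetic score and rescaled so the realised
variance ratio equals h² exactly; binary traits threshold the liability at
the empirical (1 − prevalence) quantile, so the case fraction equals the
prevalence up to rounding.

What the simulator does *not* emulate: realistic human LD maps and
long-range LD, ancestry structure and admixture, genotyping/imputation
error, covariate confounding, and biobank-scale variant counts.  Passing
tests therefore demonstrate correctness and the qualitative behaviour of
stacking under controlled architectures, not cohort-level effect sizes:
absolute metric values here are far larger than those achievable on real
complex traits, where single-SNP effects are much smaller.

## Simulation-study designs

The two stochastic properties use fixed designs at n = 4000, h² = 0.4,
chosen once as representative desk-scale conditions:

- *Split signal*: 1000 variants in 5-variant blocks; five causal SNPs with
  2% of phenotypic variance each (comfortably past 5e-8 at the 2880-sample
  training partition) plus one hundred weak causals at 0.2% each (typical
  training p between ~1e-4 and ~0.5).  Strict thresholds isolate the strong
  SNPs cleanly; lenient thresholds see the weak signal diluted among nulls,
  so the bases are complementary and the stacked model should match or beat
  the validation-selected single network on test in at least 15 of 20
  seeded replicates.
- *Interaction-dominant*: 400 variants; two strong additive SNPs (4% of
  variance each), twenty interaction-participant SNPs with small additive
  effects (0.4% each, marginally detectable) forming ten centred-product
  pairs carrying 2.4% each.  P+T captures only the additive sliver above
  5e-8; the networks receive the participating SNPs at lenient thresholds
  and can model the products, so the stacked score should exceed the P+T
  score on test in at least 15 of 20 replicates.

## Numerical choices and edge cases

Logistic functions use the two-branch stable form; BCE clips probabilities
at 1e-12.  The per-variant IRLS damps Newton steps larger than 10 and flags
|β| > 30 or non-convergence as separation.  PLINK-1 decoding follows the
2-bit SNP-major encoding (00 = two copies of A1, 01 = missing, 10 = het,
11 = zero copies); the counted allele is always bim A1, recorded in the
summary-statistics dialect (tab-separated, columns
vid/chrom/pos/a1/a2/beta/se/p/freq/n) so effect-allele orientation is never
ambiguous.  Writing sorts variants by (chrom, pos).  Missing dosages use
the sentinel −1 internally, and every consumer states its handling
(training-mean imputation everywhere a design matrix is formed).

## Known limitations

No covariate adjustment in the GWAS (hook provided, off by default); no
mixed models; hard-call genotypes only (no BGEN/VCF dosages); no external
LD reference panels; Bayesian shrinkage scores (mixture-prior or continuous
shrinkage) are out of scope — the linear baselines here are P+T and the
threshold search.  The grid-search space is intentionally small by default;
widening it is a one-line configuration change but scales linearly in
training time.
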