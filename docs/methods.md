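# Methods

This note documents the models implemented in `tissuesig`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions that affect results.

## Synthetic paired data

`datasets.generate_paired` emulates a paired prostatectomy design: each of
`n_patients` patients contributes one normal and one tumour sample, and
carries patient-level binary endpoints (defaults: `gleason`,
`capsular_penetration`), so the two compartments agree on every label.
Expression is Gaussian noise with per-gene standard deviation `noise_sd`
(default 1.0), optionally with equicorrelated blocks of `block_size`
consecutive genes at correlation `block_correlation` (generated by a
shared-factor construction that preserves the marginal variance; blocks
let tests probe collinearity handling in the discriminant).  Each endpoint
receives its own disjoint set of `n_informative` genes whose class-1 mean
is shifted by `effect_size · noise_sd`, in the compartment(s) named by
`signal_tissue` only.  Labels are balanced to `class_balance` (default
0.5) with both classes always represented.

Scale defaults (60 patients, 500 genes, 10 informative genes, effect 1.5)
reflect a filtered microarray study of this design: tens of patients,
hundreds of retained genes, per-gene effects around 1–2 within-class SDs.
The generator emits already-filtered-scale data; probe-level structure,
normalisation artefacts, platform effects and the partial molecular
similarity of adjacent-normal and tumour tissue (shared
micro-environment) are *not* simulated.  Passing tests therefore show the
machinery behaves correctly under the stated statistical model — additive
tissue-restricted shifts in Gaussian noise — not that real tissues behave
this way.

## MLHD classifier and two-level error estimation

The discriminant uses per-class sample means, a pooled within-class
covariance with denominator (n − n_classes), and either empirical
(default) or equal class priors; which priors the original formulation
used is not documented, so both are exposed (`priors=` switch).  Ties in
the discriminant scores resolve to the lowest class label for
reproducibility.  When the pooled covariance is singular (p close to the
training-fold size), a ridge of ε · trace(Σ)/p is added with ε starting at
1e-6 and escalating tenfold until the Cholesky factorisation succeeds; the
ridge actually applied is recorded on the fitted model.

Error estimation is two-level: an inner stratified k-fold CV (k = 5) is
the cheap, reusable subset score that drives search, and an outer average
over 40 random stratified 2/3–1/3 splits is the final accuracy report for
chosen models.  The inner estimate is optimistic for models *selected* by
it (winner's curse); the outer estimate, computed only after selection, is
the honest one, and the test suite checks the bias direction.  Splits are
stratified everywhere because the target designs have ~40–60 samples per
class pair; unstratified folds routinely lose a class.

## GA-MLHD selection

Chromosomes are fixed-size distinct-gene subsets (default size 5, the
size preferred in the reference protocol; 10 and 20 are available for
size comparisons).  Operators: linear-rank parent selection (robust to
fitness scaling), single-point crossover on the ordered gene list followed
by duplicate repair (duplicates replaced by uniform random unused genes),
per-locus replacement mutation (rate 0.01), elitism 2, and optional early
stop at `goal_accuracy`.  Population 30 × 12 generations × `n_runs` are
desk-scale defaults; the reference protocol accumulated ~10,000 evaluated
models, which corresponds to `n_runs ≈ 30` here.  The GA reference the
protocol builds on does not print operator choices or rates, so all of
these are this package's own declared defaults, echoed in the pipeline
manifest rather than treated as inherited values.

Gene ranking from a model population comes in two forms:

- `gene_frequency`: inclusion frequency within the top 1% of models by
  fitness, boundary ties included — the classic model-population ranking
  used for representative-model forward selection and enrichment input.
- `best_per_run_frequency`: frequency across each run's single best
  chromosome.  With ~40 training samples the inner-CV fitness is noisy
  enough that any one converged run carries passenger genes; genes that
  recur in the winners of independent runs are the replicable ones.  On
  synthetic data at the default conditions this ranking roughly doubles
  the number of truly informative genes in a 10-gene signature, so it is
  the default for the specificity test's Step 1 selector.

Forward selection seeds the model with the top-ranked gene, then admits a
candidate only if it improves inner-CV accuracy by more than 0.001, and
stops at `max_size` or after 5 consecutive failures.  The tolerance and
patience are not externally specified; they are config-exposed and logged.

## Bayesian variable selection

Binary probit with latent-variable augmentation: y_i = 1{z_i > 0},
z_i ~ N(w_iᵀβ, 1), where w_i stacks an intercept (always included) and the
currently included genes.  β carries an independence prior N(0, cI) with
c = 10 by default — a g-prior-style data-dependent covariance is singular
whenever p > n, which is routine here, so the independence form is used
and c is config-exposed.  Both endpoints in scope are two-class, so the
binary (rather than multinomial) probit is implemented.

β is integrated out analytically: the marginal likelihood of z under γ is
N(0, I + cWWᵀ), evaluated with the Sylvester determinant identity and the
Woodbury inverse so the cost is cubic in the included-gene count only.
Each iteration (a) Gibbs-samples β | z and then z | β from its truncated
normal full conditionals (signs locked to the labels), and (b) proposes an
add / delete / swap move on γ (probabilities 0.4/0.4/0.2) accepted by the
marginal-likelihood ratio times the Bernoulli prior ratio (inclusion rate
`expected_model_size / n_genes`, so the prior mean model size equals the
configured size) and the proposal-asymmetry correction.  Post-burn-in
subset visits and per-gene inclusion frequencies summarise the chain.

Chain pooling follows the reference protocol: the most-visited subsets
across chains (run at prior sizes 10 and 20) are scored by 5-fold
cross-validated misclassification error using a posterior-mean linear
predictor refit on each training fold, and the minimum-error subset wins,
ties broken by smaller size then higher visit count.

A note on null behaviour: for a *fixed* dataset with no planted signal the
posterior still concentrates on whichever genes are spuriously most
label-correlated — inclusion frequencies are exchangeable across datasets,
not flat within one.  The null tests therefore check that no gene is
systematically preferred across independent null datasets, not that
within-dataset frequencies are uniform.

## Specificity swap test

Patients are co-assigned to train or test in both compartments
(patient-paired splitting), so Step 2 never tests a patient whose other
tissue sample helped train anything — without this the paired design
leaks.  Step 2 retrains from scratch on the other tissue's training
samples restricted to the Step 1 genes; carrying Step 1 coefficients over
would confound signature transfer with coefficient transfer.  Splits are
2/3–1/3, stratified on the endpoint at the patient level; accuracies are
averaged over `n_repeats` independent splits.

## PCA contributions

The matrix restricted to a signature is column-centred (not scaled — the
generator emits comparable-scale genes) and decomposed by SVD.  Loadings
are unit-norm right singular vectors with a deterministic sign convention
(largest-|loading| entry positive); genes with |loading| > 0.3 are flagged
as main contributors.  The first two components are reported by default,
with an override since the class-separating component need not be PC1.
Constant genes are dropped with a warning; fewer than two surviving genes
is an error.

## Enrichment statistics

The network score is the right-tail hypergeometric probability that a
pathway of s genes contains ≥ f of the G focus genes in a universe of N,
reported as −log10 p and computed with log-gamma / log-sum-exp arithmetic
so large-N tails keep full relative precision; score > 5 is exactly the
p < 10⁻⁵ filter.  Pathway membership comes from user-supplied GMT files —
constructing interaction networks from a proprietary knowledge base is
out of scope.  The Fisher canonical-pathway test is the right-tailed exact
test at α = 0.01.  One-way ANOVA and the univariate F-ranking (for a
binary endpoint, identical ordering to the squared pooled t statistic)
carry raw p-values plus a Benjamini–Hochberg FDR column; raw values drive
any threshold filters, matching how such thresholds are conventionally
reported for these analyses.

## Pipeline

`run_pipeline` executes simulate → select-ga → select-bvs → summarize →
specificity → pca → enrich → report from one declarative config; requested
stages pull in their dependencies automatically.  The manifest snapshots
the *complete* effective configuration (every dataclass default, not just
user-set keys), the seed, package version and a SHA-256 digest of every
output, and re-running an identical config reproduces every TSV
byte-for-byte.  All randomness derives from the single manifest seed.  The
default pipeline config is deliberately small (40 patients, 150 genes,
reduced GA/MCMC budgets) so a full run takes well under a minute; study-scale
settings are a config edit away.

## Known limitations

- The generator's additive Gaussian model matches the discriminant's
  assumptions; heavy-tailed noise, batch structure and correlated
  informative genes across compartments are not exercised.
- The GA and MCMC budgets in defaults and tests are sized for a desk run;
  rankings stabilise further with more runs/iterations.
- Redundant planted genes (several strong genes carrying the same label)
  mean minimal representative models legitimately omit some of them; gene
  *recovery* is therefore assessed on rankings, not on representative
  model membership.
- Multi-class endpoints, niching/island GAs and reversible-jump samplers
  beyond add/delete/swap are out of scope.
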