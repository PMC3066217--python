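# Methods

## Scope and data model

The package implements an integrative survival-signature workflow for
multi-cohort expression studies. All stages exchange two containers: an
`ExpressionMatrix` (genes x samples, log2 scale, complete — missing values
are rejected at I/O rather than imputed — with optional per-sample batch
labels) and a `ClinicalTable` (overall survival in months, death indicator,
and the usual covariates: age, stage, grade, debulking, histology, subtype).
Probe-level processing (CEL parsing, RMA, NUSE, pseudo-images) is out of
scope; matrix-level quantile normalization stands in for cross-sample
summarization, and cross-platform harmonization is an id-mapping operation
(many-to-one probe-to-gene, collapsed by mean or by most-variable row)
followed by intersection of the common gene space.

## Survival engine

Cox proportional-hazards regression is implemented directly: Newton-Raphson
on the partial likelihood with Efron (default) or Breslow tie handling,
convergence at gradient norm < 1e-8, explicit errors for no events,
zero-variance covariates, and monotone likelihood (|β| diverging past 20,
where the risk sets are perfectly separated and the MLE does not exist).
Wald standard errors, hazard ratios and 95% CIs come from the inverse
information matrix. The univariate screen that the signature machinery
re-runs inside every cross-validation fold and permutation is a vectorized
scalar-Newton kernel over all genes at once (numba-compiled when available,
with a bit-identical pure-numpy fallback); both paths are cross-checked
against lifelines in the tests. Kaplan-Meier curves use the product-limit
estimator with the median defined as the first event time with S(t) ≤ 0.5
("not reached" if the curve never crosses); the log-rank test is the k-group
O−E chi-square with hypergeometric variance (identical to
`survival::survdiff` to seven digits on shared fixtures). Fisher's exact
test delegates to scipy; odds ratios use the Haldane +0.5 correction (and a
flag) when a cell is zero. FDR adjustment is Benjamini-Hochberg via
statsmodels. For multivariate clinical adjustment, age is dichotomized at
65, stage at 3, grade at 3, and debulking as suboptimal/grossly-visible vs
optimal/no-visible; missing covariates drop a sample from multivariate fits
only (complete case).

## Batch adjustment

`combat_adjust` fits the location/scale empirical-Bayes model: per-gene OLS
on batch indicators plus optional biological covariates (full-rank design
required — confounded covariates are an error, as are single-sample
batches); standardization by pooled residual scale; per-batch per-gene
additive (γ) and multiplicative (δ²) effect estimates; shrinkage toward
batch-level priors. Parametric mode uses normal / inverse-gamma priors with
method-of-moments hyperparameters and the iterative joint solution (inner
tolerance 1e-6); nonparametric mode uses likelihood-weighted posterior means
over a seeded Monte-Carlo subsample of the other genes' estimates (default
2000), which keeps the quadratic cost bounded. The parametric path
reproduces `sva::ComBat` to ~1e-5 on shared fixtures; one such fixture is
frozen into the test suite as an oracle. Two properties of the idealized
description deserve note: EB shrinkage deliberately leaves a residual
between raw and shrunken batch effects, so re-adjusting adjusted data is a
small perturbation (second correction measured at well under 10% of the
first) rather than exactly idempotent; and the degree to which per-gene
batch-mean differences shrink depends on how heterogeneous the true effects
are across genes — homogeneous shifts leave mostly batch-mean sampling
noise, which no shrinkage estimator removes.

Validation-cohort transfer re-runs the adjustment on the row-concatenated
training-plus-validation matrix with cohort as batch, so a frozen model can
be applied "without modification" to co-adjusted data.

## QC statistics

RLE flags samples whose per-array distribution of x_gj − median_g exceeds
0.5 log2 units in absolute median or 1.0 in IQR (defaults; the source
analyses give no thresholds). The RV coefficient of co-structure is
trace(SxSy)/√(trace(Sx²)trace(Sy²)) on row-centered data; because the
diagonals of the cross-product matrices give the classical RV a
deterministic noise floor of ≈ 1/(1+n/G) for unrelated high-dimensional
data, a `modified=True` variant zeroes the diagonals (modified RV), which is
the form to use for null comparisons. Classical (Torgerson) MDS embeds the
sample distance matrix exactly when a Euclidean configuration exists. The
per-cohort sanity check clusters samples by average linkage on 1 − Pearson
correlation, cuts at two clusters and log-rank-tests survival between them;
a significant split warns that technical structure may be confounded with
outcome.

## Supervised-PC signature

Screening keeps genes with univariate Cox p < α (default 0.05) on
standardized expression and ranks by |coefficient| (ties: ascending p, then
gene id). The model takes principal components of the standardized top-k
submatrix (k configurable; n_pc defaults to 1 — the first component already
tracks a planted one-factor program with |r| > 0.9) and fits Cox on the
component scores; the risk score is the resulting linear predictor, making
group assignments invariant to loading sign flips. Degenerate
cross-validation folds in which fewer genes pass the screen than components
needed fall back to the globally smallest p-values so the pipeline stays
defined under the null.

Leave-one-out cross-validation rebuilds the entire pipeline on every fold
and scores only the held-out sample; groups split at the median
cross-validated score with ties assigned to low risk. **Known limitation:**
the chi-square log-rank p computed on these cross-validated groups retains
optimism when gene selection is survival-driven, because each fold's screen
reads the other n−1 samples' outcomes and the test statistic couples all
samples (pre-validation bias). Under a global null at n=100 with 1000 genes
it rejects at roughly 4-5x the nominal rate; with selection disabled
(α → 1) calibration is exact. The calibrated significance of the split is
therefore the survival-permutation p — the full cross-validated procedure
repeated on survival records reassigned at random (default B=100, add-one
rule so p ≥ 1/(B+1)) — which is exact by construction and is what the
acceptance studies verify for power and calibration. The one acceptance
check that asserts naive LOOCV calibration is knowingly left failing, with
the measured rejection rate reported.

Cross-dataset marker pools fit models over a grid of top-k values per
cohort, keep the largest gene set whose cross-validated split is significant
at home (p < 0.05) and whose frozen model splits every other cohort
(transfer threshold: the applied cohort's median score, the more robust
choice when cohorts are only distributionally matched), and return the union
with provenance. Nested submodels refit PCs and Cox on the top-m genes by
contribution weight Σ_c |loading · PC coefficient|.

## Subclass mapping

Markers of a subclass are the top-m genes by signal-to-noise ratio
(μ_in−μ_out)/(σ_in+σ_out) against the rest of the cohort (m defaults to
100 in the CLI; studies here use m=50 with 600-gene universes, respecting
the 2m-universe precondition). The enrichment score is the classic
unweighted KS running sum (hits +1/m, misses −1/(N−m), score = extreme
deviation; defined as 0 when every gene is a marker). Directional p-values
permute the ranking cohort's labels (add-one rule); the permutation stream
is keyed to each cohort's sample ids so that swapping the argument order
transposes the result exactly. Mutual significance combines the two
directions with Fisher's −2(ln p_AB + ln p_BA) against a null of pairs drawn
independently from the two ES null distributions, then BH-FDR over all cells
yields the subclass association matrix. A candidate subclass must hold at
least 10% of its cohort. **Known limitation:** when the two directional
p-values of a cell are strongly dependent — as they are when the second
cohort genuinely contains the first cohort's structure, including the case
of permuted labels that retain a chance overlap of order 1/√n with the true
labels — the independent-resampling Fisher null is anti-conservative; the
acceptance study measures this on label-permuted runs, and the honest
false-positive check against genuinely unstructured cohorts is calibrated.

## Pathway characterization

Differential expression uses Welch t throughout. GSA computes the maxmean
statistic per set (means of positive and negative score parts over the full
set; the larger magnitude wins, signed), restandardized by the mean/SD of
maxmean over 200 seeded random genome sets of the same size, with two-sided
class-label permutation p-values. EASE over-representation is the jackknifed
Fisher score — the one-sided hypergeometric tail after removing one hit from
the category cell, so single-hit categories score 1 — with BH-FDR computed
within each annotation system when systems are supplied. No annotation
databases are shipped; gene sets come from user GMT files.

## Pathway-activation scoring

A signature is trained on arrays with experimentally controlled pathway
activation: top n_genes by |Welch t|, training standardization, rank-1
metagene (first singular vector, oriented so "on" arrays score higher,
scores scaled by their training SD), and Bayesian probit regression of
on/off on the metagene score fitted by the Albert-Chib Gibbs sampler
(N(0, 100) prior on intercept and slope; 1000 burn-in, 5000 retained draws
by default — posterior predictive probabilities from two independent chains
agree within 0.02). Tumors co-adjusted with the training arrays are scored
by the posterior-mean probit probability; probability > 0.5 calls the
pathway active, and activation-by-risk association is the 2x2 odds ratio
with a Woolf CI (Haldane correction on zero cells) plus Fisher's exact p.

## Synthetic data

The generator emulates the study structure, not microarray physics. Per
gene, sample and batch: x = α_g + subclass shift + b_g·u_j + γ_ig + δ_ig·ε,
with gene baselines α ~ N(7,1) (log2 scale), latent risk u ~ N(0,1)
standardized, ±1 loadings on the planted prognostic genes, batch shifts
γ ~ N(0, gamma_sd²), log-normal scale factors δ (dispersion `delta_shape`),
and residual noise SD 0.5 — so a configured latent log-hazard of β
corresponds to a marginal per-gene association of β/√1.25 ≈ 0.9β per SD.
Survival is exponential with hazard h₀·exp(β·u) (h₀ = 0.02/month, median
OS near 35 months at the defaults) and independent uniform administrative
censoring whose horizon is solved numerically to hit the target censoring
fraction (default 30%; realized fraction within ±5 points at n ≥ 200).
Defaults mirror a four-cohort advanced-stage study at desk scale: 4 batches
of 60 arrays, 2000 genes, 20 prognostic. What the generator does not
emulate: probe-level noise, intensity-dependent variance, correlated gene
modules beyond the planted programs, non-proportional hazards, and
informative censoring — so passing tests demonstrate correctness of the
algorithms under the stated model, not robustness to those real-data
features.

Validation studies (tests/test_acceptance.py, scripts/acceptance.py) run at
fixed designs chosen to exercise each stage well inside a desktop budget:
the integration study at the 4x60x2000 default; supervised-PC recovery and
permutation at the 650-gene marker-pool scale with 240 training and 120
validation samples; pools over three 100-sample, 1000-gene cohorts sharing
30 prognostic genes; subclass mapping at n=100 per cohort, 600 genes, 200
permutations, 50 label-permutation runs; GSA at 1000 genes with 30-gene
sets; probit scoring with 20 on / 20 off arrays of 1000 genes.

## Numerical choices and degenerate inputs

Newton steps are clipped (|step| ≤ 2 per iteration for the univariate
screen, norm ≤ 5 for multivariate) to keep early iterations stable;
zero-variance genes screen out neutrally (coef 0, p 1). Quantile
normalization resolves ties by stable sort order. Median-score ties assign
low risk. ES permutation p-values, GSA p-values and the SubMap Fisher p all
use the add-one rule. Single-batch adjustment, single-sample quantile
normalization and degenerate two-cluster cuts warn and return identity /
missing results rather than failing.
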