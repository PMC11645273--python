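# Methods

This note documents the statistical procedures implemented in `pantop`, the
defaults and why they were chosen, what the synthetic generator does and does
not emulate, and the numerical decisions that matter for reproducing results.

## Within-cohort preprocessing

**Microarray intensities** are transformed as log2(x + 1) — tolerant of
zeros, monotone, and standard — and quantile-normalized: each sample's sorted
values are replaced by the mean sorted profile across samples. Tied values
within a sample receive the mean of the profile values their ranks span,
which makes the map deterministic. An optional `already_log` flag skips the
log transform for series distributed on the log scale. After normalization
all samples share one value distribution exactly (a tested invariant).

**RNA-seq counts** are filtered of genes with zero counts in every sample,
normalized with trimmed-mean-of-M-values (TMM) library-size factors, and
transformed to log2-CPM with mean-variance precision weights. TMM uses the
canonical defaults of the method: the reference sample is the one whose
75th-percentile count fraction is closest to the mean of those fractions;
gene-wise log2 relative proportions (M) and average log proportions (A)
against the reference are double-trimmed at 30 % (M) and 5 % (A); the factor
is 2 to the precision-weighted trimmed mean of M with asymptotic binomial
variance weights, and factors are rescaled to geometric mean one. The
transform computes log2((count + 0.5)/(libsize·factor + 1) × 10⁶); the square
root of each gene's residual standard deviation is smoothed against its
average log2 count by lowess (span 0.5, exposed in configuration), and each
observation's weight is the trend prediction at its fitted log2 count raised
to the power −4, with predictions clipped to the trend's range. During
training the residuals use the two-group means; at prediction time only gene
means, so labels never enter normalization. A development cross-check against
the R reference implementations reproduced the empirical-Bayes quantities
below exactly and TMM factors to ~10⁻³ (trim-boundary conventions differ in
the last step).

**Moderated two-group test.** Per gene, the (optionally precision-weighted)
difference of class means and residual variance s_g² with d_g = n − 2 degrees
of freedom. The variance prior (d₀, s₀²) is estimated by moment matching on
log residual variances — mean and variance of log s² matched to a scaled F
distribution via digamma/trigamma identities, with the trigamma inverted by
Newton iteration (tolerance 10⁻⁸, at most 50 iterations). The posterior
variance is s̃_g² = (d₀s₀² + d_g s_g²)/(d₀ + d_g); the moderated t uses
d₀ + d_g degrees of freedom. d₀ = 0 recovers the ordinary pooled t-test
(oracle-tested); infinite d₀ (returned when the spread of log variances does
not exceed chi-square sampling noise) pins every gene to s₀² and a normal
reference. Benjamini–Hochberg adjustment is delegated to statsmodels.

## Cross-cohort meta-analysis

Per-cohort moderated t-statistics are mapped to z-scores through their exact
t distribution, computed through the tail nearest zero so extreme statistics
keep full floating-point precision, and combined per gene with Stouffer's
method z_c = Σz/√k over the genes present in **all** contributing cohorts.
A partial-presence mode (gene in at least m cohorts, per-gene k) exists but
is off by default: the classifier's features are defined on the intersection,
and the meta-analysis follows the same rule.

Differential-expression calls use strict inequality at the chosen p
threshold (deterministic and conservative). The multi-organ intersection
test compares the observed full intersection count O with the chance
expectation E = G·Πp_o (marginal DE fractions p_o over a common universe of
G genes) by a one-degree-of-freedom Pearson chi-square on the two-cell
partition {in the full intersection, not}. The two-cell construction is the
simplest test consistent with a scalar observed/expected comparison; the
marginals can be computed from raw or adjusted combined p at any threshold,
both exposed.

Gene-set enrichment is a two-sided Wilcoxon rank-sum test of in-set versus
out-of-set combined z-scores: exact null distribution on tie-free universes
of ≤ 25 genes (it matches full permutation enumeration, a tested oracle),
normal approximation with tie correction otherwise. Cross-phenotype panels
rank genes by a second-level Stouffer combination of the phenotype-level
combined z-scores (magnitude-ranked, ties broken by symbol); a mean-rank
variant is available by flag. The second-level Stouffer was chosen because
it is symmetric in the phenotypes and consistent with the rest of the stack.

## The transfer-learning classifier

Design choices where the construction was genuinely open:

- **Sign of the feature weight.** The ratio statistic T_j can be negative;
  weights must be nonnegative scale factors, so w_f = √|T_j| and the
  direction is carried by the lasso coefficient.
- **Loss.** The lasso objective is stated in squared-error form on the
  binary outcome, but risks are reported on a logit scale; the default is
  therefore the logistic deviance, with the squared-error objective
  available as `loss="squared"` and matching the written objective term for
  term. Both solvers are tested to within 10⁻⁶ of a generic convex
  optimizer on the same objective (in practice they agree to ~10⁻¹⁴).
- **Solvers.** Squared loss uses scikit-learn's coordinate descent (the
  sample-weighted objective maps onto it with α = λ/(2Σw)). Logistic loss
  uses an in-package penalized IRLS coordinate-descent solver with active-set
  KKT screening, written because a solver matching the exact weighted
  objective (unpenalized intercept, no feature rescaling) at high precision
  was needed on paths of penalties.
- **Penalty selection.** λ = "cv" runs stratified 5-fold cross-validation
  maximizing AUC over a logarithmic grid of 100 points spanning three decades
  down from λ_max, the smallest penalty that zeroes every coefficient; ties
  prefer the sparser model. Grid size, span and folds are configuration.
- **Organ weights** use the organ's cohort count (n_i datasets, as written;
  a sample-count mode is available) and every sample of the organ inherits
  n_i^(−1/4). Sample weights are normalized to mean one before fitting so
  that the penalty scale is comparable across weighting schemes; with equal
  organ representation, balanced and naive weighting then coincide exactly
  (a tested invariant). `organ_weighting="naive"` reproduces the unweighted
  integration baseline.
- **Dataset weights** in the ratio statistics are literally inverse sample
  sizes (not inverse variances); the fudge quantile uses the
  linear-interpolation quantile estimator (exposed in configuration).
- **Single-cohort degeneracy.** With one training cohort all weighted
  variances vanish and the fudge factor is zero; the statistic degenerates
  to the fold change itself (unit denominator). Dataset weights are
  normalized before pooling so this case is numerically exact.
- Ratios are never re-filtered between pairing and the lasso — the lasso is
  the filter.

Self-normalization is exact in exact arithmetic; the test suite verifies
bit-identical predictions under per-sample offsets drawn on a dyadic grid
(so that the floating-point additions themselves are exact) and agreement to
10⁻⁹ through the full raw-intensity pipeline.

## Evaluation

Leave-one-dataset-out: for each cohort, a model is trained on the remaining
trainable cohorts and scores the held-out cohort; the held-out data never
touch gene selection, weights, or penalty selection. Within-cohort
normalization is label-free at prediction time, so it is computed once per
cohort and shared across folds — a pure caching optimization. Cohorts with a
single outcome class are reported as non-evaluable rather than dropped
silently. Paired comparisons reuse identical splits (asserted by fingerprint).
AUC is the Mann–Whitney statistic with half credit for ties. Group contrasts
of logit-scale risks use Welch's unequal-variance two-sided t-test (the
unequal-variance form is the safer default when group variances are not
known to match); two zero-variance groups with equal means return p = 1 by
convention. The clinical covariate baseline is a plain unpenalized logistic
regression, falling back to a ridge-stabilized fit with a warning when the
design is singular or separable.

## Synthetic data

The generator emulates the structure the classifier must survive, not any
particular public series. On a log2 scale: gene baselines N(6, 1.5²),
per-(gene, cohort) batch offsets N(0, 0.5²) — additive in log space, so batch
and organ are perfectly confounded by construction — per-sample scaling
offsets N(0, 0.5²), planted class effects (shared genes with one consistent
random sign per gene across organs; disjoint organ-specific genes), and
N(0, 1) residual noise. Array cohorts exponentiate to intensities as 2^L − 1,
so the array pipeline's log2(x + 1) recovers the log scale exactly. Count
cohorts draw negative-binomial counts with mean = library size × the sample's
softmax-normalized expression, log-normal library sizes (median 10⁶, σ_log
0.3) and log-normal gene-wise dispersions (median 0.1, σ_log 0.5) — standard
bulk RNA-seq emulation. Outcomes are Bernoulli with prevalence 0.4, a
realistic case fraction for dysfunction cohorts. Platforms alternate down the
cohort list so every organ mixes both.

The default specification is the benchmark condition used throughout the
tests: a 2,000-gene universe, 20 shared genes at 1.0 log2 units, three organs
contributing 4/2/2 cohorts of 40 samples, plus 10 organ-specific genes per
organ. The dominant-organ variant (6/2/2 cohorts; 30 dominant-organ-specific
genes at 1.2 against shared signal at 0.8) creates the failure mode that
organ balancing addresses: a model over-learning the dominant organ picks
private features that do not transfer.

What the generator does **not** emulate: probe-level array artifacts,
GC/length biases and count overdispersion trends, correlated gene modules,
label noise, or covariate shift in outcome definitions. Passing recovery and
transfer benchmarks therefore demonstrates correctness of the machinery
under the assumed structure, not clinical performance on real cohorts.

## Benchmark problem sizes

The seeded benchmark suites (`pantop.benchmarks`) run the transfer contrasts
with 20-gene panels (190 ratios), the squared-error objective and a 20-point
penalty grid — the same pipeline structure as the default model at a
fraction of its cost, chosen so each ten-seed suite completes in minutes on
one core. Null calibration uses a 5,000-gene four-cohort collection; the
Kolmogorov–Smirnov distances of moderated and combined p-values from uniform
are ~0.01, and the DE call rate at α = 0.05 sits inside its binomial band.

## Known limitations

- Two-group designs only; no covariate adjustment inside the lasso.
- Gene identity is the symbol string as given; no alias mapping or
  probe-to-gene collapsing.
- The chi-square intersection test's two-cell construction is one of several
  defensible readings of a scalar observed-vs-expected comparison.
- TMM trim boundaries can differ from other implementations by one rank at
  the trim edges (factor differences ~10⁻³).
- Exact rank-sum enrichment requires a tie-free universe; ties always fall
  back to the corrected normal approximation.
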