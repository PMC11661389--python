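# Methods

## Model and assumptions

All association tests are single-variant ordinary least squares with shared
covariates. Writing Z for the N × C covariate matrix (first column the
intercept, full rank), the residual projection P = I − Z(ZᵀZ)⁻¹Zᵀ turns the
model y = Zα + gβ + ε into the univariate regression ỹ = g̃β + ε̃ with
ỹ = Py, g̃ = Pg and residual degrees of freedom d = N − C − 1 (one further
degree for the genotype). The coefficient, standard error and two-sided
t-test follow the closed forms given in the README; they agree with the
joint fit of [Z g] to machine precision, which the unit tests verify against
statsmodels.

The indirect reconstruction assumes:

* the target phenotype is exactly a linear combination y = Xp of the
  features (nonlinear definitions are linearized first, and the fit R² is
  reported as the quality gauge);
* every feature's scan used the same covariates and the same samples
  (complete data) — with per-feature sample sizes the reported n and d use
  the minimum over features with nonzero weight, which is what the
  equivalent direct analysis would have had;
* the partial covariance matrix C was computed on the same covariate
  adjustment. Its divisor is a labelling choice (default N − 1): any common
  divisor cancels in the ratio pᵀCp / Var(g̃), so exactness does not depend
  on it, but the divisor is stored and propagated so inputs can be audited.

Under these assumptions the reconstruction is exact, and the test suite
holds it to 1e−6 relative agreement (it achieves ~1e−13) against the direct
oracle for dense, sparse, negative and single-feature projections.
Logistic and generalized mixed models are out of scope; the only mixed-model
concession is that the covariance input may carry a per-chromosome key, in
which case each variant is scanned against its chromosome's matrix.

## Degrees of freedom and pooling conventions

d = N − C − 1 everywhere, with C counting the intercept. The genotype
partial variance is recovered per feature as Var(x̃ᵢ)/(sᵢ²d + bᵢ²) and
pooled by the arithmetic mean; with exact inputs every per-feature estimate
is identical, and the pooled value equals g̃ᵀg̃/(N−1) to rounding. Pooling
defaults to the projection's nonzero-weight features (pooling over all
features in the block is a flag): restricting to the support keeps the
identity-projection round trip exact and avoids contaminating the estimate
with features the user did not ask about.

## The phenotype language

Ten operators: NOT; AND, OR, XOR; GT, GE, LT, LE, EQ; ADD — plus feature
leaves and numeric constants. Boolean operators use the product forms
(AND = xy, OR = x + y − xy, NOT = 1 − x, XOR = x + y − 2xy). On {0,1} data
these are the exact truth tables; the same formulas extend continuously to
[0,1], which is how definitions are evaluated on microaggregated data whose
rows are cluster centroids. Strict mode (the default) rejects boolean
operators on anything but {0,1} columns — comparisons are the intended
bridge from quantitative values to booleans, with GE/LE inclusive so that
"HbA1c >= 6.5" has its clinical meaning. EQ is exact comparison, intended
for coded/integer fields. The include/exclude list interface lowers onto
the same trees (AND of included codes and NOT of excluded ones).

## Linearization and the quality gauge

Definitions are approximated by OLS on the full supplied feature matrix
with an intercept, no regularization; rank-deficient designs fall back to
the minimum-norm solution with a warning. Restricting the regression to the
definition's own leaves is available as an option but not the default: the
wider basis can only raise R². The gauge bins R² at 0.5 and 0.75
(poor / moderate / good, boundaries inclusive upward). These two cut points
are reporting conventions, not fitted quantities; they bracket the regime
where, in our synthetic experiments, GWAS fidelity transitions from
unusable to near-exact. A useful analytic anchor: for the AND of two
independent Bernoulli(q) codes the population R² is 2q/(1+q) (≈ 0.095 at
q = 0.05 — intrinsically poor), while for OR it is 2(1−q)/(2−q) (≈ 0.974).

## MDAV microaggregation

The generic variant: while ≥ 3k records remain unassigned, take the record
farthest (Euclidean) from the centroid of the unassigned set, cluster it
with its k−1 nearest unassigned neighbours, then do the same around the
record farthest from the first seed; with 2k…3k−1 left, one cluster forms
around the farthest record and the remainder becomes the last cluster; with
fewer than 2k, all remaining records form one cluster. Cluster sizes are
therefore in [k, 2k−1], every released row is a centroid shared by its
whole cluster (k-anonymity), and global column means are preserved exactly
— which is what the downstream least-squares linearization cares about.
Distances are computed on raw columns because the intended input is a
uniformly-coded {0,1} code matrix; a standardization flag exists for
mixed-scale inputs and affects distances only, never the released values.
Ties in farthest/nearest break to the lowest record index, making the
algorithm deterministic for a fixed row order. Binary inputs produce
fractional centroids, which are kept as-is (no rounding): the fractional
evaluation mode of the phenotype language consumes them directly.

## The synthetic cohort

The generator emulates, at desk scale, the structure of a biobank
validation cohort:

* genotypes: per-variant allele frequency uniform on [0.05, 0.5], dosages
  binomial(2, MAF) — unlinked variants in Hardy–Weinberg equilibrium;
* quantitative phenotypes: X = GW + ZA + E with, per phenotype, 10 causal
  variants jointly explaining 30% of variance (default), covariate effects
  drawn N(0, 0.5²), and residuals sharing a single factor giving pairwise
  noise correlation 0.3; total variance ≈ 1;
* binary "diagnosis codes": the same liability model thresholded at the
  empirical (1 − q) quantile, q = 0.05 by default, emulating rare ICD-10
  style indicators with a genetic component;
* covariates: standard normal, plus the always-present intercept;
* all randomness flows from one integer seed through fixed named
  substreams, so sub-simulations are independently reproducible.

Defaults are 2,000 individuals, 500 variants, 10 phenotypes and 5
covariates, with 100 random standard-normal projections in the equivalence
harness; the exactness property does not depend on scale, so these sizes
are chosen as comfortable desk-scale analogues of a biobank run. The
experiments behind the fidelity laws use the same machinery at 400–1,000
variants and 12–20 phenotypes (stated in each test), and the
full-PC-precision experiment strengthens the genetics (50 causal variants
jointly explaining 50% of variance) so that genome-wide-significant hits
exist to score.

What the generator does **not** emulate: linkage disequilibrium, population
structure and relatedness, per-feature missingness, case-control
ascertainment, and the heavy-tailed frequency distribution of real
diagnosis codes. Passing tests therefore demonstrate the mathematics and
the implementation, not robustness to those real-data features; the
linearization R² medians and fidelity correlations observed on synthetic
data are qualitative analogues, not predictions, of what any particular
cohort would show.

## PCA acceleration

PCA is computed on the covariate-residualized phenotype matrix (SVD), so
scores and phenotypes share one covariate adjustment; scores are not
re-standardized, and their covariance — diagonal with the eigenvalues,
divisor N − 1 — is passed to the indirect engine unchanged. Each phenotype's
projection onto the retained components is the corresponding row of the
loading matrix. With 100% of components the reconstruction is exact (the
tests hold it to 1e−6 relative; observed ~1e−13), so the significance
confusion matrix at p < 5 × 10⁻⁸ has precision 1 by construction; with
fewer components fidelity degrades monotonically while the strongest
associations survive longest. The run summary reports direct scans saved,
(1 − f)·m; wall-clock savings are hardware-bound and not asserted.

## Numerical choices

* p-values are carried as −log10 p via the t log-survival function; where
  the double-precision incomplete-beta path underflows (|t| ≳ 35 at large
  d), an arbitrary-precision incomplete-beta evaluation (mpmath, 40 digits)
  takes over, keeping −log10 p accurate beyond 300 without p-space
  underflow. A plain p column is also written, flushed to 0 below the
  double minimum.
* a variant whose residualized dosage has sum of squares ≤ 1e−12 of the
  largest is flagged `constant-genotype` (no estimate, NA in outputs)
  rather than raising;
* a perfect fit (radicand ≤ 1e−14 of the variance ratio, i.e. pure
  cancellation round-off) is reported as se = 0 and flagged
  `se-degenerate`;
* an indirect radicand ≤ 0 signals numerically incompatible inputs and
  flags the variant `inconsistent-inputs` with NA standard error;
* feature alignment is always by id; positional mismatch is impossible by
  construction and unknown ids are hard errors;
* missing features at a variant drop the variant by default; estimating
  from the available subset is opt-in because silently changing the feature
  set changes the estimand;
* complete-case handling: rows with any missing value among y, G, Z are
  dropped before residualization;
* machine outputs serialize floats at 17 significant digits and are read
  back with round-trip float parsing, so write-then-load is bit-exact.

## Known limitations

* Linear models only; for binary phenotypes the scan is the linear
  probability model, a good approximation to logistic results only for
  small or moderate effects.
* The quality gauge is computed on whatever matrix is supplied (original or
  anonymized) and labelled accordingly; it is a proxy for fidelity, not a
  guarantee, and out-of-vocabulary phenotypes that no feature combination
  can express will simply show a poor gauge.
* MDAV is microaggregation-based k-anonymity, not differential privacy; it
  bounds re-identification by row multiplicity only.
* The per-chromosome covariance hook covers leave-one-chromosome-out
  pipelines but no other mixed-model internals.
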