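# indirectgwas

GWAS summary statistics for arbitrary phenotype definitions — without
individual-level data.

Genome-wide association studies regress a phenotype on each genetic variant
in turn. Running one requires access to individual-level genotypes and
phenotypes, which is slow, costly, and privacy-sensitive. Yet for any
phenotype that is a **linear combination of already-scanned phenotypes**, a
new scan is unnecessary: its summary statistics are an exact function of the
per-feature summary statistics and the phenotypic covariance matrix. This
package implements that reconstruction ("indirect GWAS") and the machinery
that makes it useful for real phenotype definitions:

* **`gwas_core`** — covariate residualization, direct single-variant OLS
  scans (the oracle everything is checked against), partial covariance, and
  log-space p-values.
* **`indirect_engine`** — the reconstruction itself, streamed over variants.
* **`phenotype_dsl`** — a small expression language for phenotype
  definitions over diagnosis codes and quantitative measurements
  (`E11 OR (HbA1c >= 6.5)`), with list (include/exclude) and tree
  interfaces.
* **`linearizer`** — OLS approximation of nonlinear definitions plus a
  fit-quality gauge that predicts downstream GWAS fidelity.
* **`mdav`** — MDAV microaggregation, so the feature matrix used for
  linearization can be released with k-anonymity.
* **`pca_accelerator`** — phenome-wide GWAS acceleration: scan a fraction of
  phenotype principal components, reconstruct every phenotype indirectly.
* **`synthesizer`** — synthetic cohorts and the direct-vs-indirect
  validation harness.
* **`io` / `cli`** — tab-delimited formats and the `indirectgwas`
  command-line tool (`simulate`, `gwas`, `indirect`, `linearize`,
  `anonymize`, `define`, `validate`, `pca-gwas`).

## The statistics

For a single variant, residualize the phenotype y, genotype g and features
x_i against the covariates Z (intercept included), giving ỹ, g̃, x̃_i with
d = N − C − 1 degrees of freedom. The direct OLS scan gives per variant

    β̂ = g̃ᵀỹ / g̃ᵀg̃,        SE(β̂)² = (1/d) (Var(ỹ)/Var(g̃) − β̂²).

If y = Σᵢ pᵢ xᵢ, and b, s are the per-feature coefficient and standard-error
vectors at this variant, then with the feature partial covariance matrix C:

    β̂  = bᵀp
    Var(g̃)ᵢ = Var(x̃ᵢ) / (sᵢ² d + bᵢ²),   Var(g̃) = mean over features
    SE(β̂)² = (1/d) ( pᵀCp / Var(g̃) − (bᵀp)² )

which is *exact* — not approximate — for complete data, shared covariates
and a consistent covariance divisor. Nonlinear definitions are first
linearized by OLS; the fit R² ("quality gauge") tells you how much to trust
the result. The reported sample size is the minimum over the features used,
and p-values come from the t distribution, computed in log space.

## Worked example

A privacy-preserving "server" keeps only summary-level artifacts — per-code
GWAS summary statistics, the partial covariance matrix, and a k = 10
anonymized code matrix — and answers a phenotype definition query:

```python
import pandas as pd
from indirectgwas import (
    SimulationConfig, simulate_genotypes, simulate_binary_features,
    feature_stats_from_scan, partial_covariance, mdav_anonymize,
)
from indirectgwas.io import run_definition_pipeline

cfg = SimulationConfig(n_individuals=2000, n_variants=500, n_phenotypes=8,
                       n_covariates=5, seed=1)
G = simulate_genotypes(cfg)
codes, Z, _ = simulate_binary_features(G, cfg, prevalence=0.05)

stats = feature_stats_from_scan(codes.to_numpy(), G, Z, list(codes.columns),
                                cfg.variant_ids)
C = partial_covariance(codes.to_numpy(), Z, list(codes.columns))
anon = pd.DataFrame(mdav_anonymize(codes.to_numpy(), k=10).values,
                    columns=codes.columns)

report, results = run_definition_pipeline("code_1 OR code_2", anon, stats, C)
print(f"fit R2 = {report['r2']:.3f}  gauge = {report['gauge']}")
top = max(results, key=lambda r: r.neg_log10_p)
print(f"top hit: {top.variant_id}  beta = {top.beta:.4f}  se = {top.se:.4f}  "
      f"-log10 p = {top.neg_log10_p:.2f}  n = {top.n}")
```

Output:

```
fit R2 = 0.990  gauge = good
top hit: v213  beta = -0.0585  se = 0.0088  -log10 p = 10.51  n = 2000
```

The OR of two rare codes linearizes almost perfectly (R² = 0.99, gauge
"good"), so the indirect statistics are trustworthy; the top variant shifts
the defined phenotype by −0.059 per allele with two-sided p ≈ 10⁻¹⁰·⁵, from
a scan that never touched individual-level data. The same flow is available
from the shell via `indirectgwas linearize` + `indirectgwas indirect`, and
`indirectgwas validate` runs the direct-vs-indirect equivalence harness.

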