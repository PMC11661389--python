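"""Synthetic genotype/phenotype data and the direct-vs-indirect harness.

The generator emulates, at desk scale, the structure of a biobank validation
cohort: binomial dosage genotypes with per-variant allele frequencies, a set
of correlated quantitative phenotypes with sparse genetic effects and shared
covariates, rare binary diagnosis-code-like features obtained by thresholding
genetically driven latent liabilities, random projection vectors, and random
boolean phenotype definitions.  The harness runs direct OLS GWAS on projected
phenotypes and compares against the indirect reconstruction, reporting
relative errors and chi-squared fidelity.

All randomness flows from a single integer seed through named substreams
(``numpy`` SeedSequence spawn keys), so each sub-simulation is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas_core import CovariateMatrix, InputError, direct_scan, partial_covariance
from .indirect_engine import FeatureStatsBlock, Projection, indirect_scan
from .phenotype_dsl import PhenotypeNode

__all__ = [
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_binary_features",
    "random_projections",
    "random_boolean_definitions",
    "feature_stats_from_scan",
    "boolean_fidelity_experiment",
    "anonymization_fidelity_curve",
    "validate_direct_vs_indirect",
    "gwas_fidelity",
    "inverse_rank_normal",
    "filter_min_observations",
]

# fixed substream keys so sub-simulations are independently reproducible
_STREAMS = {
    "genotypes": 0,
    "phenotypes": 1,
    "covariates": 2,
    "projections": 3,
    "definitions": 4,
    "binary": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults are the desk-scale analogue of a pan-biobank validation run:
    2000 individuals, 500 variants, 10 phenotypes, 5 covariates (plus the
    intercept), allele frequencies uniform on [0.05, 0.5], 10 causal variants
    per phenotype jointly explaining 30% of phenotype variance, and residual
    cross-phenotype correlation 0.3 from a single shared factor.
    """

    n_individuals: int = 2000
    n_variants: int = 500
    n_phenotypes: int = 10
    n_covariates: int = 5          # non-intercept covariates
    maf_range: tuple[float, float] = (0.05, 0.5)
    genetic_variance: float = 0.3  # fraction of phenotype variance from genetics
    causal_per_phenotype: int = 10
    phenotype_correlation: float = 0.3
    seed: int = 0
    variant_ids: list[str] = field(default_factory=list)
    phenotype_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_variants", "n_phenotypes", "causal_per_phenotype"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if self.n_covariates < 0:
            raise InputError("n_covariates must be non-negative")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise InputError("MAF range must lie within (0, 0.5]")
        if not (0 <= self.genetic_variance <= 1):
            raise InputError("genetic_variance must lie in [0, 1]")
        if not (0 <= self.phenotype_correlation < 1):
            raise InputError("phenotype_correlation must lie in [0, 1)")
        if not self.variant_ids:
            self.variant_ids = [f"v{j + 1}" for j in range(self.n_variants)]
        if not self.phenotype_ids:
            self.phenotype_ids = [f"x{j + 1}" for j in range(self.n_phenotypes)]


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def simulate_genotypes(cfg: SimulationConfig) -> np.ndarray:
    """Dosage matrix (N x V): per variant a MAF is drawn uniformly from the
    configured range and dosages are binomial(2, MAF).  Fixed seed gives a
    bit-identical matrix."""
    rng = _rng(cfg.seed, "genotypes")
    mafs = rng.uniform(*cfg.maf_range, size=cfg.n_variants)
    return rng.binomial(2, mafs, size=(cfg.n_individuals, cfg.n_variants)).astype(float)


def _covariates(cfg: SimulationConfig) -> CovariateMatrix:
    rng = _rng(cfg.seed, "covariates")
    if cfg.n_covariates == 0:
        return CovariateMatrix.with_intercept(n=cfg.n_individuals)
    vals = rng.standard_normal((cfg.n_individuals, cfg.n_covariates))
    return CovariateMatrix.with_intercept(vals)


def _latent_traits(
    G: np.ndarray, cfg: SimulationConfig, Z: CovariateMatrix, rng: np.random.Generator,
    n_traits: int,
) -> tuple[np.ndarray, dict]:
    """Latent traits = sparse genetic effects + covariate effects + correlated
    noise, with the genetic component scaled to the configured variance
    fraction and unit total (genetic + noise) variance."""
    n, v = G.shape
    Gc = G - G.mean(axis=0)
    W = np.zeros((v, n_traits))
    for j in range(n_traits):
        causal = rng.choice(v, size=min(cfg.causal_per_phenotype, v), replace=False)
        W[causal, j] = rng.standard_normal(causal.size)
    genetic = Gc @ W
    gsd = genetic.std(axis=0, ddof=0)
    h2 = cfg.genetic_variance
    if h2 > 0:
        nz = gsd > 0
        scale = np.where(nz, np.sqrt(h2) / np.where(nz, gsd, 1.0), 0.0)
        genetic *= scale
        W *= scale
    else:
        genetic[:] = 0.0
        W[:] = 0.0
    rho = cfg.phenotype_correlation
    shared = rng.standard_normal((n, 1))
    eps = rng.standard_normal((n, n_traits))
    noise = np.sqrt(rho) * shared + np.sqrt(1 - rho) * eps
    noise *= np.sqrt(1 - h2)
    A = rng.standard_normal((Z.n_covariates - 1, n_traits)) * 0.5 if Z.n_covariates > 1 else None
    covar_part = Z.values[:, 1:] @ A if A is not None else 0.0
    X = genetic + covar_part + noise
    truth = {"W": W, "A": A, "noise_correlation": rho, "genetic_variance": h2}
    return X, truth


def simulate_phenotypes(
    G: np.ndarray, cfg: SimulationConfig
) -> tuple[np.ndarray, CovariateMatrix, dict]:
    """Quantitative phenotype matrix X (N x m), covariates Z and the ground
    truth (genetic effect matrix W, covariate effects A, noise model)."""
    Z = _covariates(cfg)
    rng = _rng(cfg.seed, "phenotypes")
    X, truth = _latent_traits(G, cfg, Z, rng, cfg.n_phenotypes)
    return X, Z, truth


def simulate_binary_features(
    G: np.ndarray,
    cfg: SimulationConfig,
    prevalence: float = 0.05,
    n_features: int | None = None,
    feature_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, CovariateMatrix, dict]:
    """Rare binary diagnosis-code-like features by liability thresholding.

    Latent liabilities with sparse genetic effects are dichotomized at the
    empirical (1 - prevalence) quantile, emulating rare ICD-10-style codes
    with a genetic component; default prevalence 5%.
    """
    if not (0 < prevalence < 1):
        raise InputError("prevalence must lie in (0, 1)")
    m = n_features if n_features is not None else cfg.n_phenotypes
    Z = _covariates(cfg)
    rng = _rng(cfg.seed, "binary")
    latent, truth = _latent_traits(G, cfg, Z, rng, m)
    cut = np.quantile(latent, 1 - prevalence, axis=0)
    B = (latent > cut).astype(float)
    if feature_ids is None:
        feature_ids = [f"code_{j + 1}" for j in range(m)]
    return pd.DataFrame(B, columns=feature_ids), Z, truth


def random_projections(
    feature_ids: list[str],
    count: int,
    seed: int,
    include_identity: bool = False,
) -> list[Projection]:
    """Dense standard-normal projection vectors; ``include_identity`` prepends
    one single-feature (unit-vector) projection per feature as controls."""
    rng = _rng(seed, "projections")
    out: list[Projection] = []
    if include_identity:
        m = len(feature_ids)
        for j, fid in enumerate(feature_ids):
            w = np.zeros(m)
            w[j] = 1.0
            out.append(Projection(list(feature_ids), w, label=f"identity_{fid}"))
    for i in range(count):
        w = rng.standard_normal(len(feature_ids))
        out.append(Projection(list(feature_ids), w, label=f"proj_{i + 1}"))
    return out


_TEMPLATES = ("x_and_y", "x_or_y", "x_and_not_y", "x_or_y_or_z", "x_and_y_or_z")


def random_boolean_definitions(
    feature_ids: list[str], count: int, seed: int
) -> list[PhenotypeNode]:
    """Random boolean combinations of binary features.

    Templates (drawn uniformly): ``x AND y``, ``x OR y``, ``x AND NOT y``,
    ``x OR y OR z``, ``(x AND y) OR z``; features are sampled without
    replacement within a definition."""
    if len(feature_ids) < 3:
        raise InputError("need at least 3 features for boolean definitions")
    rng = _rng(seed, "definitions")
    leaf = PhenotypeNode.feature
    defs = []
    for _ in range(count):
        template = _TEMPLATES[rng.integers(len(_TEMPLATES))]
        x, y, z = (feature_ids[i] for i in rng.choice(len(feature_ids), 3, replace=False))
        if template == "x_and_y":
            node = PhenotypeNode.apply("AND", leaf(x), leaf(y))
        elif template == "x_or_y":
            node = PhenotypeNode.apply("OR", leaf(x), leaf(y))
        elif template == "x_and_not_y":
            node = PhenotypeNode.apply("AND", leaf(x), PhenotypeNode.apply("NOT", leaf(y)))
        elif template == "x_or_y_or_z":
            node = PhenotypeNode.apply("OR", PhenotypeNode.apply("OR", leaf(x), leaf(y)), leaf(z))
        else:
            node = PhenotypeNode.apply("OR", PhenotypeNode.apply("AND", leaf(x), leaf(y)), leaf(z))
        defs.append(node)
    return defs


# ---------------------------------------------------------------------------
# Utilities emulating cohort preprocessing
# ---------------------------------------------------------------------------

def inverse_rank_normal(x: np.ndarray, offset: float = 0.375) -> np.ndarray:
    """Inverse rank-normal transform (Blom offset): map ranks onto standard
    normal quantiles, yielding an approximately N(0,1) column."""
    from scipy import stats

    x = np.asarray(x, dtype=float)
    ranks = stats.rankdata(x)
    return stats.norm.ppf((ranks - offset) / (x.size - 2 * offset + 1))


def filter_min_observations(X: pd.DataFrame, min_count: int = 100) -> pd.DataFrame:
    """Drop binary feature columns observed (nonzero) fewer than ``min_count``
    times — the standard rare-code exclusion applied before release."""
    counts = (X != 0).sum(axis=0)
    return X.loc[:, counts[counts >= min_count].index]


# ---------------------------------------------------------------------------
# Harness
# ---------------------------------------------------------------------------

def feature_stats_from_scan(
    X: np.ndarray,
    G: np.ndarray,
    Z: CovariateMatrix,
    feature_ids: list[str],
    variant_ids: list[str] | None = None,
) -> FeatureStatsBlock:
    """Run per-feature direct GWAS and pack the results as the summary-stats
    block the indirect engine consumes."""
    beta, se, _, _, _ = direct_scan(X, G, Z)
    n = np.full_like(beta, float(Z.n_samples))
    if variant_ids is None:
        variant_ids = [f"v{j + 1}" for j in range(beta.shape[0])]
    return FeatureStatsBlock(list(variant_ids), list(feature_ids), beta, se, n)


def gwas_fidelity(chi2_a: np.ndarray, chi2_b: np.ndarray) -> float:
    """Pearson correlation between two vectors of per-variant chi-squared
    statistics — the fidelity metric used throughout."""
    a = np.asarray(chi2_a, dtype=float).ravel()
    b = np.asarray(chi2_b, dtype=float).ravel()
    if a.size != b.size:
        raise InputError("chi-squared vectors must have equal length")
    if a.size < 3:
        raise InputError("need at least 3 statistics to correlate")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise InputError("fidelity undefined for constant chi-squared vectors")
    return float(np.corrcoef(a, b)[0, 1])


def _boolean_setup(cfg: SimulationConfig, prevalence: float, n_definitions: int):
    """Shared scaffolding for the boolean-definition fidelity experiments."""
    from .gwas_core import partial_covariance as _pcov

    G = simulate_genotypes(cfg)
    B, Z, _ = simulate_binary_features(G, cfg, prevalence=prevalence)
    fids = list(B.columns)
    defs = random_boolean_definitions(fids, n_definitions, cfg.seed)
    block = feature_stats_from_scan(B.to_numpy(), G, Z, fids, cfg.variant_ids)
    C = _pcov(B.to_numpy(), Z, fids)
    return G, B, Z, fids, defs, block, C


def boolean_fidelity_experiment(
    cfg: SimulationConfig, n_definitions: int = 60, prevalence: float = 0.05
) -> pd.DataFrame:
    """Linearization quality versus GWAS fidelity for random boolean phenotypes.

    For each random definition: evaluate it on the binary feature matrix, run
    a direct GWAS on the evaluated vector, linearize it by OLS on the
    features, run indirect GWAS with the fitted projection, and record the
    fit R^2 and the chi-squared fidelity.  Definitions evaluating to a
    constant vector are skipped.  Returns a DataFrame with columns
    ``definition``, ``r2``, ``fidelity``.
    """
    from .gwas_core import direct_scan as _scan
    from .linearizer import fit_linear_approximation
    from .phenotype_dsl import evaluate

    G, B, Z, fids, defs, block, C = _boolean_setup(cfg, prevalence, n_definitions)
    rows = []
    for node in defs:
        y = evaluate(node, B)
        if np.ptp(y) == 0:
            continue
        _, _, t_d, _, _ = _scan(y, G, Z)
        approx = fit_linear_approximation(y, B.to_numpy(), fids, label=node.to_text())
        res = indirect_scan(block, C, approx.projection)
        t_i = np.array([r.t for r in res])
        ok = np.isfinite(t_d) & np.isfinite(t_i)
        rows.append(
            {"definition": node.to_text(), "r2": approx.r2,
             "fidelity": gwas_fidelity(t_d[ok] ** 2, t_i[ok] ** 2)}
        )
    return pd.DataFrame(rows)


def anonymization_fidelity_curve(
    cfg: SimulationConfig,
    ks: tuple[int, ...] = (2, 5, 10, 20, 50),
    n_definitions: int = 60,
    prevalence: float = 0.05,
) -> pd.DataFrame:
    """GWAS fidelity of anonymize-then-linearize pipelines versus k.

    The baseline is the indirect scan from a linearization fitted on the
    original binary data.  For each anonymity level k, the feature matrix is
    microaggregated with MDAV, each definition is evaluated on the
    (fractional) anonymized data, linearized there, and scanned indirectly
    with the *original* feature summary statistics; fidelity is the Pearson
    correlation of the two indirect chi-squared vectors, isolating the effect
    of anonymization.  Returns one row per k with the median fidelity.
    """
    from .linearizer import fit_linear_approximation
    from .mdav import mdav_anonymize
    from .phenotype_dsl import evaluate

    G, B, Z, fids, defs, block, C = _boolean_setup(cfg, prevalence, n_definitions)

    def indirect_chi2(mat: pd.DataFrame, fractional: bool) -> list[np.ndarray | None]:
        out: list[np.ndarray | None] = []
        for node in defs:
            y = evaluate(node, mat, fractional=fractional)
            if np.ptp(y) == 0:
                out.append(None)
                continue
            approx = fit_linear_approximation(y, mat.to_numpy(), fids)
            res = indirect_scan(block, C, approx.projection)
            out.append(np.array([r.t for r in res]) ** 2)
        return out

    base = indirect_chi2(B, fractional=False)
    rows = []
    for k in ks:
        ds = mdav_anonymize(B.to_numpy(), k)
        anon = indirect_chi2(pd.DataFrame(ds.values, columns=fids), fractional=True)
        fvals = [
            gwas_fidelity(a, b)
            for a, b in zip(base, anon)
            if a is not None and b is not None and np.ptp(a) > 0 and np.ptp(b) > 0
        ]
        rows.append({"k": k, "median_fidelity": float(np.median(fvals)), "n_definitions": len(fvals)})
    return pd.DataFrame(rows)


def validate_direct_vs_indirect(
    cfg: SimulationConfig,
    projections: list[Projection] | None = None,
    n_projections: int = 100,
) -> dict:
    """Simulate a cohort, run direct GWAS on random projected phenotypes, and
    reconstruct the same statistics indirectly from per-feature summary
    statistics plus the partial covariance matrix.

    Returns a report with, per projection, the maximum relative error of beta
    and se and the Pearson R^2 between direct and indirect chi-squared
    statistics, plus worst-case aggregates.
    """
    G = simulate_genotypes(cfg)
    X, Z, _ = simulate_phenotypes(G, cfg)
    fids = cfg.phenotype_ids
    if projections is None:
        projections = random_projections(fids, n_projections, cfg.seed)
    stats_block = feature_stats_from_scan(X, G, Z, fids, cfg.variant_ids)
    C = partial_covariance(X, Z, fids)
    per_proj = []
    for p in projections:
        idx = [fids.index(f) for f in p.feature_ids]
        y = X[:, idx] @ p.weights + p.intercept
        beta_d, se_d, t_d, _, _ = direct_scan(y, G, Z)
        res = indirect_scan(stats_block, C, p)
        beta_i = np.array([r.beta for r in res])
        se_i = np.array([r.se for r in res])
        t_i = np.array([r.t for r in res])
        ok = np.isfinite(beta_d) & np.isfinite(se_d) & np.isfinite(se_i) & (se_d > 0)
        rel_beta = np.abs(beta_i[ok] - beta_d[ok]) / np.maximum(np.abs(beta_d[ok]), 1e-300)
        rel_se = np.abs(se_i[ok] - se_d[ok]) / se_d[ok]
        r = gwas_fidelity(t_d[ok] ** 2, t_i[ok] ** 2)
        per_proj.append(
            {
                "label": p.label,
                "max_rel_beta": float(rel_beta.max()),
                "max_rel_se": float(rel_se.max()),
                "chi2_r2": float(r**2),
                "n_variants": int(ok.sum()),
            }
        )
    return {
        "per_projection": per_proj,
        "max_rel_beta": max(d["max_rel_beta"] for d in per_proj),
        "max_rel_se": max(d["max_rel_se"] for d in per_proj),
        "min_chi2_r2": min(d["chi2_r2"] for d in per_proj),
        "n_projections": len(per_proj),
    }
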