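"""PCA-accelerated many-phenotype GWAS.

Instead of running one direct GWAS per phenotype, the phenotype matrix is
compressed with principal component analysis (after covariate
residualization), direct GWAS is run on a fraction of the component score
vectors, and per-phenotype summary statistics are reconstructed by indirect
GWAS: each original phenotype is exactly a linear combination of the scores
(row of the loading matrix), and the score covariance is diagonal.  With all
components retained the reconstruction is exact; with fewer, fidelity
degrades gracefully while the most significant associations are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gwas_core import (
    CovariateMatrix,
    InputError,
    PartialCovariance,
    direct_scan,
    residualize,
)
from .indirect_engine import AssociationResult, FeatureStatsBlock, Projection, indirect_scan

__all__ = [
    "PcaModel",
    "ConfusionCounts",
    "fit_phenotype_pca",
    "pc_scores",
    "reconstruct_indirect",
    "pca_gwas",
    "fidelity_vs_fraction",
    "significance_confusion",
    "confusion_metrics",
    "GENOME_WIDE_ALPHA",
]

GENOME_WIDE_ALPHA = 5e-8  # conventional genome-wide significance threshold


@dataclass
class PcaModel:
    """PCA of a residualized phenotype matrix.

    ``loadings`` is the m x m orthogonal matrix whose columns are components
    ordered by decreasing explained variance; row j expresses phenotype j in
    score coordinates.  ``component_variances`` are the eigenvalues of the
    residualized covariance (divisor N-1).
    """

    loadings: np.ndarray
    component_variances: np.ndarray
    feature_means: np.ndarray
    feature_ids: list[str]
    n_samples: int
    n_covariates: int

    def __post_init__(self) -> None:
        m = self.loadings.shape[0]
        if self.loadings.shape != (m, m):
            raise InputError("loading matrix must be square")
        if not np.allclose(self.loadings.T @ self.loadings, np.eye(m), atol=1e-8):
            raise InputError("loading columns must be orthonormal")
        if np.any(np.diff(self.component_variances) > 1e-10):
            raise InputError("component variances must be non-increasing")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def components_for_fraction(self, fraction: float) -> int:
        """Number of leading components for a retained fraction in (0, 1]."""
        if not (0 < fraction <= 1):
            raise InputError("retained fraction must lie in (0, 1]")
        return max(1, int(round(fraction * self.n_components)))

    def score_covariance(self, n_retained: int) -> PartialCovariance:
        """Diagonal covariance of the leading scores (components are
        uncorrelated by construction)."""
        ids = [f"PC{i + 1}" for i in range(n_retained)]
        return PartialCovariance(
            np.diag(self.component_variances[:n_retained]), ids, float(self.n_samples - 1),
            self.n_samples, self.n_covariates,
        )


@dataclass
class ConfusionCounts:
    """Significance-call confusion between a direct and a reconstructed scan."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def fit_phenotype_pca(X: np.ndarray, Z: CovariateMatrix, feature_ids: list[str] | None = None) -> PcaModel:
    """PCA on the covariate-residualized (hence centered) phenotype matrix.

    All m components are retained in the model; downstream callers choose the
    fraction to actually scan.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if m > n:
        raise InputError(f"need more samples than phenotypes for PCA: N={n}, m={m}")
    if feature_ids is None:
        feature_ids = [f"x{j + 1}" for j in range(m)]
    R = residualize(X, Z).values
    # SVD of the residualized matrix: columns of V are the components
    _, svals, vt = np.linalg.svd(R, full_matrices=False)
    variances = svals**2 / (n - 1)
    return PcaModel(vt.T, variances, X.mean(axis=0), list(feature_ids), n, Z.n_covariates)


def pc_scores(X: np.ndarray, Z: CovariateMatrix, model: PcaModel, n_retained: int | None = None) -> np.ndarray:
    """Score vectors (N x f): residualized phenotypes projected on the leading
    components."""
    R = residualize(np.asarray(X, dtype=float), Z).values
    f = n_retained if n_retained is not None else model.n_components
    return R @ model.loadings[:, :f]


def reconstruct_indirect(
    pc_stats: FeatureStatsBlock,
    model: PcaModel,
    C_pc: PartialCovariance,
    phenotype_index: int,
) -> list[AssociationResult]:
    """Per-phenotype summary statistics from component-level GWAS.

    The projection for phenotype j is row j of the loading matrix restricted
    to the retained components; statistics follow from the indirect engine
    with the (diagonal) score covariance.
    """
    f = len(pc_stats.feature_ids)
    if f == 0:
        raise InputError("need at least one retained component")
    if list(pc_stats.feature_ids) != list(C_pc.feature_ids):
        raise InputError("component ids of statistics and covariance do not match")
    weights = model.loadings[phenotype_index, :f]
    if not np.any(weights != 0):
        raise InputError(f"phenotype {phenotype_index} has no support on the retained components")
    p = Projection(list(pc_stats.feature_ids), weights,
                   label=model.feature_ids[phenotype_index])
    return indirect_scan(pc_stats, C_pc, p)


def pca_gwas(
    X: np.ndarray,
    G: np.ndarray,
    Z: CovariateMatrix,
    fraction: float,
    feature_ids: list[str] | None = None,
    variant_ids: list[str] | None = None,
) -> dict:
    """Full pipeline: fit PCA, scan the retained score vectors directly, and
    reconstruct every phenotype's statistics indirectly.

    Returns a dict with the model, the retained-component count, the number of
    direct scans saved (m - f), and per-phenotype arrays of reconstructed
    beta / se / t / -log10 p plus dof.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    model = fit_phenotype_pca(X, Z, feature_ids)
    f = model.components_for_fraction(fraction)
    S = pc_scores(X, Z, model, f)
    pc_ids = [f"PC{i + 1}" for i in range(f)]
    beta, se, _, _, _ = direct_scan(S, G, Z)
    nmat = np.full_like(beta, float(n))
    if variant_ids is None:
        variant_ids = [f"v{j + 1}" for j in range(G.shape[1])]
    pc_stats = FeatureStatsBlock(list(variant_ids), pc_ids, beta, se, nmat)
    C_pc = model.score_covariance(f)
    recon = {}
    for j, fid in enumerate(model.feature_ids):
        res = reconstruct_indirect(pc_stats, model, C_pc, j)
        recon[fid] = res
    return {
        "model": model,
        "n_components": f,
        "scans_saved": m - f,
        "results": recon,
        "variant_ids": list(variant_ids),
    }


def fidelity_vs_fraction(
    X: np.ndarray,
    G: np.ndarray,
    Z: CovariateMatrix,
    fractions: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 0.9, 1.0),
    feature_ids: list[str] | None = None,
) -> dict[float, float]:
    """Chi-squared fidelity of PCA-reconstructed scans versus the retained
    component fraction, pooled over all phenotype-variant pairs."""
    from .synthesizer import gwas_fidelity

    X = np.asarray(X, dtype=float)
    if feature_ids is None:
        feature_ids = [f"x{j + 1}" for j in range(X.shape[1])]
    _, _, t_d, _, _ = direct_scan(X, G, Z)
    chi2_d = (t_d**2).ravel()
    out = {}
    for f in fractions:
        run = pca_gwas(X, G, Z, f, feature_ids)
        t_i = np.column_stack(
            [[r.t for r in run["results"][fid]] for fid in feature_ids]
        )
        chi2_i = (t_i**2).ravel()
        ok = np.isfinite(chi2_d) & np.isfinite(chi2_i)
        out[f] = gwas_fidelity(chi2_d[ok], chi2_i[ok])
    return out


def significance_confusion(
    direct_p: np.ndarray, indirect_p: np.ndarray, alpha: float = GENOME_WIDE_ALPHA
) -> ConfusionCounts:
    """Count significance-call agreement at threshold alpha.

    TP: significant in both; FP: reconstructed-only; FN: direct-only; TN:
    neither.  Inputs are p-values (or any aligned statistic where smaller
    means more significant).
    """
    direct_p = np.asarray(direct_p, dtype=float).ravel()
    indirect_p = np.asarray(indirect_p, dtype=float).ravel()
    if direct_p.size != indirect_p.size:
        raise InputError("direct and reconstructed p-value lists differ in length")
    if not (0 < alpha < 1):
        raise InputError("alpha must lie in (0, 1)")
    d = direct_p < alpha
    i = indirect_p < alpha
    return ConfusionCounts(
        tp=int(np.sum(d & i)),
        fp=int(np.sum(~d & i)),
        fn=int(np.sum(d & ~i)),
        tn=int(np.sum(~d & ~i)),
    )


def confusion_metrics(c: ConfusionCounts, decimals: int | None = 3) -> dict:
    """Sensitivity, specificity, precision and F1 from confusion counts.

    Metrics with zero denominators are reported as None (undefined); values
    are rounded to ``decimals`` places for report output (pass None to skip).
    """
    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    sens = ratio(c.tp, c.tp + c.fn)
    spec = ratio(c.tn, c.tn + c.fp)
    prec = ratio(c.tp, c.tp + c.fp)
    if sens is None or prec is None or (sens + prec) == 0:
        f1 = None
    else:
        f1 = 2 * prec * sens / (prec + sens)
    out = {"sensitivity": sens, "specificity": spec, "precision": prec, "f1": f1}
    if decimals is not None:
        out = {k: (None if v is None else round(v, decimals)) for k, v in out.items()}
    return out
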