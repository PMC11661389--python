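"""Indirect GWAS: summary statistics for linear combinations of phenotypes.

Given per-feature GWAS summary statistics (coefficients b, standard errors s,
sample sizes n for every variant) and the covariate-adjusted covariance matrix
C of the feature phenotypes, the statistics of any projected phenotype
``y = X p`` are recovered without individual-level data:

    beta  = b' p
    se^2  = ( p' C p / Var(g~)  -  beta^2 ) / d

where the genotype partial variance ``Var(g~)`` is estimated from each
feature's own statistics, ``Var(g~)_i = Var(x~_i) / (s_i^2 d + b_i^2)``, and
pooled by averaging.  For complete data, shared covariates and a consistent
covariance divisor, this reproduces the direct OLS scan exactly — any common
divisor cancels in the ratio ``p'Cp / Var(g~)``.

Feature alignment is always by id, never by position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .gwas_core import (
    AssociationResult,
    InputError,
    PartialCovariance,
    neg_log10_p_from_t,
)

__all__ = [
    "FeatureStatsBlock",
    "Projection",
    "GVarEstimate",
    "estimate_genotype_variance",
    "indirect_coefficient",
    "indirect_stderr",
    "min_sample_size",
    "indirect_scan",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class FeatureStatsBlock:
    """Per-variant, per-feature summary statistics stacked over variants.

    ``b``, ``s`` and ``n`` all have shape (V variants, m features); NaN marks
    a feature with no statistics at that variant.  Standard errors must be
    strictly positive wherever defined.
    """

    variant_ids: list[str]
    feature_ids: list[str]
    b: np.ndarray
    s: np.ndarray
    n: np.ndarray
    chrom: list[str] = field(default_factory=list)
    pos: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        V, m = len(self.variant_ids), len(self.feature_ids)
        for name, arr in (("b", self.b), ("s", self.s), ("n", self.n)):
            if arr.shape != (V, m):
                raise InputError(f"{name} has shape {arr.shape}, expected {(V, m)}")
        if len(set(self.variant_ids)) != V:
            raise InputError("variant ids must be unique")
        if len(set(self.feature_ids)) != m:
            raise InputError("feature ids must be unique")
        defined = np.isfinite(self.s)
        if np.any(self.s[defined] <= 0):
            raise InputError("standard errors must be strictly positive where defined")
        if not self.chrom:
            self.chrom = ["0"] * V
        if not self.pos:
            self.pos = list(range(1, V + 1))

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def align_features(self, ids: list[str]) -> "FeatureStatsBlock":
        """Column-reorder to the given feature ids; unknown ids are an error."""
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in ids if f not in index]
        if missing:
            raise InputError(f"features absent from summary statistics: {missing}")
        idx = np.array([index[f] for f in ids])
        return FeatureStatsBlock(
            list(self.variant_ids), list(ids),
            self.b[:, idx], self.s[:, idx], self.n[:, idx],
            list(self.chrom), list(self.pos),
        )


@dataclass
class Projection:
    """Coefficient vector expressing a target phenotype as ``y = sum_i p_i x_i``.

    The intercept is carried for provenance only: an additive constant shifts
    the phenotype mean, which covariate residualization removes, so it does
    not enter the association math.
    """

    feature_ids: list[str]
    weights: np.ndarray
    intercept: float = 0.0
    label: str = "projection"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if len(self.feature_ids) != self.weights.size:
            raise InputError("projection weights do not match feature ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise InputError("projection feature ids must be unique")
        if not np.any(self.weights != 0):
            raise InputError("projection must have at least one nonzero weight")

    @property
    def support(self) -> np.ndarray:
        """Boolean mask of features with nonzero weight."""
        return self.weights != 0


@dataclass
class GVarEstimate:
    """Per-feature and pooled estimates of the genotype partial variance."""

    per_feature: np.ndarray
    pooled: float

    def __post_init__(self) -> None:
        finite = self.per_feature[np.isfinite(self.per_feature)]
        if finite.size == 0 or not np.isfinite(self.pooled):
            raise InputError("no features available to estimate genotype variance")
        if np.any(finite <= 0) or self.pooled <= 0:
            raise InputError("genotype variance estimates must be positive")


# ---------------------------------------------------------------------------
# Scalar operations (the per-variant algebra)
# ---------------------------------------------------------------------------

def estimate_genotype_variance(
    b_row: np.ndarray, s_row: np.ndarray, feature_vars: np.ndarray, dof: int
) -> GVarEstimate:
    """Recover Var(g~) from each feature's summary statistics and pool by mean.

    ``Var(g~)_i = Var(x~_i) / (s_i^2 d + b_i^2)``; features with NaN statistics
    are skipped; pooling is the arithmetic mean over available features.
    """
    b_row = np.asarray(b_row, dtype=float)
    s_row = np.asarray(s_row, dtype=float)
    feature_vars = np.asarray(feature_vars, dtype=float)
    if dof < 1:
        raise InputError("degrees of freedom must be >= 1")
    avail = np.isfinite(b_row) & np.isfinite(s_row) & np.isfinite(feature_vars)
    per = np.full(b_row.shape, np.nan)
    per[avail] = feature_vars[avail] / (s_row[avail] ** 2 * dof + b_row[avail] ** 2)
    if not avail.any():
        raise InputError("all features missing at this variant")
    return GVarEstimate(per, float(np.mean(per[avail])))


def indirect_coefficient(
    b_row: np.ndarray, p: Projection, feature_ids: list[str] | None = None
) -> float:
    """Projected coefficient ``beta = b' p``.

    If ``feature_ids`` is given, ``b_row`` is realigned to the projection's
    feature order; ids that do not reconcile are a hard error.
    """
    b_row = np.asarray(b_row, dtype=float)
    if feature_ids is not None:
        index = {f: i for i, f in enumerate(feature_ids)}
        missing = [f for f in p.feature_ids if f not in index]
        if missing:
            raise InputError(f"projection features absent from statistics: {missing}")
        b_row = b_row[np.array([index[f] for f in p.feature_ids])]
    if b_row.size != len(p.feature_ids):
        raise InputError("coefficient row does not match projection features")
    return float(b_row @ p.weights)


def indirect_stderr(
    p: Projection, C: PartialCovariance, gvar: GVarEstimate, beta: float, dof: int
) -> float:
    """Projected standard error ``sqrt((p'Cp / Var(g~) - beta^2) / d)``.

    Returns NaN when the radicand is non-positive, signalling numerically
    incompatible summary statistics (the caller flags the variant).
    """
    Csub = C.subset(list(p.feature_ids))
    pcp = float(p.weights @ Csub.values @ p.weights)
    radicand = pcp / gvar.pooled - beta**2
    if radicand <= 0:
        return float("nan")
    return float(np.sqrt(radicand / dof))


def min_sample_size(n_row: np.ndarray, p: Projection) -> int:
    """Minimum sample size over the projection's nonzero-weight features."""
    n_row = np.asarray(n_row, dtype=float)
    if n_row.size != len(p.feature_ids):
        raise InputError("sample-size row does not match projection features")
    sub = n_row[p.support]
    if not np.all(np.isfinite(sub)):
        raise InputError("sample size undefined for a nonzero-weight feature")
    return int(np.min(sub))


# ---------------------------------------------------------------------------
# Streaming scan
# ---------------------------------------------------------------------------

def indirect_scan(
    stats: FeatureStatsBlock,
    C: PartialCovariance | dict[str, PartialCovariance],
    p: Projection,
    chunk_size: int = 10_000,
    missing_policy: str = "drop",
    pool_all_features: bool = False,
) -> list[AssociationResult]:
    """Indirect GWAS over all variants of a summary-statistics block.

    Parameters
    ----------
    stats
        Per-feature summary statistics; must contain every projection feature.
    C
        Partial covariance of the features, or a mapping from chromosome to
        per-chromosome covariance matrices (used e.g. with
        leave-one-chromosome-out pipelines).  Its metadata must declare the
        covariate count so degrees of freedom can be recovered.
    p
        Projection coefficients; alignment is by feature id.
    chunk_size
        Variants processed per block.  Output is identical for any value >= 1.
    missing_policy
        ``"drop"`` (default) omits variants lacking statistics for any
        projection feature; ``"available"`` estimates from the features
        present, with a warning.
    pool_all_features
        Pool the genotype-variance estimate over every feature in the block
        rather than only the projection's nonzero-weight features.

    Returns results in input variant order; per variant
    ``dof = min(n) - C_covariates - 1`` (the min-N rule).
    """
    if chunk_size < 1:
        raise InputError("chunk_size must be >= 1")
    if missing_policy not in ("drop", "available"):
        raise InputError(f"unknown missing policy: {missing_policy!r}")

    per_chrom = isinstance(C, dict)
    some_C = next(iter(C.values())) if per_chrom else C
    if some_C.n_covariates is None:
        raise InputError("covariance metadata must declare the covariate count")
    c_cov = some_C.n_covariates

    aligned = stats.align_features(list(p.feature_ids))
    support = p.support
    if per_chrom:
        csub = {k: v.subset(list(p.feature_ids)) for k, v in C.items()}
        pcp_by_chrom = {k: float(p.weights @ v.values @ p.weights) for k, v in csub.items()}
        fvar_by_chrom = {k: v.feature_variances for k, v in csub.items()}
    else:
        csub_single = C.subset(list(p.feature_ids))
        pcp_single = float(p.weights @ csub_single.values @ p.weights)
        fvar_single = csub_single.feature_variances

    results: list[AssociationResult] = []
    V = aligned.n_variants
    warned = False
    for start in range(0, V, chunk_size):
        sl = slice(start, min(start + chunk_size, V))
        B, S, Nm = aligned.b[sl], aligned.s[sl], aligned.n[sl]
        chroms = aligned.chrom[sl]
        poss = aligned.pos[sl]
        vids = aligned.variant_ids[sl]
        finite = np.isfinite(B) & np.isfinite(S) & np.isfinite(Nm)
        for i in range(B.shape[0]):
            row_ok = finite[i]
            if not row_ok.any():
                continue
            complete = bool(row_ok.all())
            if not complete:
                if missing_policy == "drop":
                    continue
                if not warned:
                    warnings.warn(
                        "estimating some variants from an incomplete feature subset",
                        stacklevel=2,
                    )
                    warned = True
            if per_chrom:
                key = chroms[i]
                if key not in pcp_by_chrom:
                    raise InputError(f"no covariance matrix for chromosome {key!r}")
                pcp, fvar = pcp_by_chrom[key], fvar_by_chrom[key]
                cmat = csub[key].values
            else:
                pcp, fvar = pcp_single, fvar_single
                cmat = csub_single.values
            use = row_ok if not complete else np.ones_like(row_ok)
            sup = support & use
            if not sup.any():
                continue
            n_min = int(np.min(Nm[i][sup]))
            dof = n_min - c_cov - 1
            if dof < 1:
                continue
            pool = use if pool_all_features else sup
            per = fvar[pool] / (S[i][pool] ** 2 * dof + B[i][pool] ** 2)
            gvar = float(np.mean(per))
            w = np.where(use, p.weights, 0.0)
            beta = float(B[i][use] @ w[use])
            pcp_i = pcp if complete else float(w @ cmat @ w)
            radicand = pcp_i / gvar - beta**2
            if radicand <= 0:
                results.append(
                    AssociationResult(vids[i], beta, np.nan, np.nan, np.nan, n_min, dof,
                                      chroms[i], poss[i], flag="inconsistent-inputs")
                )
                continue
            se = float(np.sqrt(radicand / dof))
            t = beta / se
            nlp = float(neg_log10_p_from_t(np.array(t), dof))
            results.append(
                AssociationResult(vids[i], beta, se, t, nlp, n_min, dof, chroms[i], poss[i])
            )
    return results
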