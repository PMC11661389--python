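"""Core linear-model GWAS machinery.

Residualization against covariates, single-variant ordinary-least-squares
association scans (the direct oracle every other module is checked against),
covariate-adjusted ("partial") phenotypic covariance, and the t-based test
statistics shared by the direct and indirect paths.

Conventions used throughout the package
---------------------------------------
* Covariate matrices always contain an intercept column; with ``C`` covariate
  columns (counting the intercept) the residual degrees of freedom of a
  single-variant regression are ``d = N - C - 1``.
* All partial variances and covariances use divisor ``N - 1``.  Any common
  divisor cancels in the ratio that drives the standard error, so this is a
  labelling choice, not a statistical one; the divisor is recorded on the
  covariance object and checked for consistency downstream.
* p-values are carried as -log10(p), computed in log space so that test
  statistics far beyond double-precision underflow remain finite and accurate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CovariateMatrix",
    "ResidualizedMatrix",
    "AssociationResult",
    "PartialCovariance",
    "residualize",
    "partial_covariance",
    "direct_gwas",
    "direct_scan",
    "chi2_pvalue",
    "neg_log10_p_from_t",
]

_SYM_TOL = 1e-10
_PSD_TOL = 1e-8


class InputError(ValueError):
    """Malformed or inconsistent user input (CLI exit code 2)."""


class NumericalError(ArithmeticError):
    """Numerically impossible request (CLI exit code 3)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CovariateMatrix:
    """An N x C design matrix of covariates whose first column is the intercept.

    Parameters
    ----------
    values
        Covariate values, one row per sample.  Must be full column rank and
        include a constant (all-ones) column.
    labels
        One label per column.
    """

    values: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InputError("covariate matrix must be 2-dimensional")
        n, c = self.values.shape
        if not self.labels:
            self.labels = [f"covar_{i}" for i in range(c)]
        if len(self.labels) != c:
            raise InputError("covariate labels do not match column count")
        has_const = np.any(
            np.all(np.isclose(self.values, self.values[0:1, :]), axis=0)
            & (np.abs(self.values[0, :]) > 0)
        )
        if not has_const:
            raise InputError("covariate matrix must contain an intercept column")
        if n <= c + 1:
            raise InputError(
                f"need more samples than covariates: N={n}, C={c} (require N > C + 1)"
            )
        _check_full_rank(self.values, self.labels)

    @classmethod
    def with_intercept(
        cls, values: np.ndarray | None = None, labels: list[str] | None = None, n: int | None = None
    ) -> "CovariateMatrix":
        """Build a covariate matrix, prepending an intercept column.

        ``values`` holds the non-constant covariates (may be ``None`` for an
        intercept-only design, in which case ``n`` gives the sample count).
        """
        if values is None:
            if n is None:
                raise InputError("need sample count for intercept-only covariates")
            return cls(np.ones((n, 1)), ["intercept"])
        values = np.asarray(values, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        n_rows = values.shape[0]
        full = np.column_stack([np.ones(n_rows), values])
        if labels is None:
            labels = [f"covar_{i + 1}" for i in range(values.shape[1])]
        return cls(full, ["intercept"] + list(labels))

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_covariates(self) -> int:
        """Number of covariate columns, counting the intercept."""
        return self.values.shape[1]


@dataclass
class ResidualizedMatrix:
    """Covariate-residualized data with its residual degrees of freedom.

    ``dof = N - C - 1``: the degrees of freedom left for a single-variant
    regression after removing ``C`` covariates (intercept included) and one
    genotype term.
    """

    values: np.ndarray
    labels: list[str]
    dof: int


@dataclass
class AssociationResult:
    """Per-variant association summary for one phenotype.

    ``flag`` is ``None`` for a clean result; otherwise one of
    ``"constant-genotype"`` (variant constant after residualization, no
    estimate), ``"se-degenerate"`` (residual variance exactly zero, se = 0) or
    ``"inconsistent-inputs"`` (indirect path: negative variance radicand).
    """

    variant_id: str
    beta: float
    se: float
    t: float
    neg_log10_p: float
    n: int
    dof: int
    chrom: str = ""
    pos: int = 0
    flag: str | None = None

    @property
    def valid(self) -> bool:
        return self.flag is None

    @property
    def p(self) -> float:
        """Two-sided p-value; flushed to 0 below double-precision minimum."""
        if not np.isfinite(self.neg_log10_p):
            return 0.0
        with np.errstate(over="ignore"):
            return float(10.0 ** (-self.neg_log10_p))


@dataclass
class PartialCovariance:
    """Covariate-adjusted covariance matrix of feature phenotypes.

    ``divisor`` records the normalization used (default ``N - 1``);
    ``n_samples`` and ``n_covariates`` (intercept included) are carried so the
    indirect engine can recover degrees of freedom.
    """

    values: np.ndarray
    feature_ids: list[str]
    divisor: float
    n_samples: int | None = None
    n_covariates: int | None = None
    chromosome: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m = self.values.shape[0]
        if self.values.shape != (m, m):
            raise InputError("covariance matrix must be square")
        if len(self.feature_ids) != m:
            raise InputError("feature ids do not match covariance dimension")
        if len(set(self.feature_ids)) != m:
            raise InputError("feature ids must be unique")
        if not np.allclose(self.values, self.values.T, atol=_SYM_TOL):
            raise InputError("covariance matrix is not symmetric")
        if np.any(np.diag(self.values) < 0):
            raise InputError("covariance matrix has negative diagonal entries")
        tr = float(np.trace(self.values))
        if m and tr > 0:
            eigmin = float(np.linalg.eigvalsh(self.values)[0])
            if eigmin < -_PSD_TOL * tr:
                raise InputError(
                    f"covariance matrix is not positive semidefinite (min eigenvalue {eigmin:.3g})"
                )

    @property
    def feature_variances(self) -> np.ndarray:
        return np.diag(self.values).copy()

    def subset(self, ids: list[str]) -> "PartialCovariance":
        """Reorder/restrict to the given feature ids (alignment is by id)."""
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in ids if f not in index]
        if missing:
            raise InputError(f"features absent from covariance matrix: {missing}")
        idx = np.array([index[f] for f in ids])
        return PartialCovariance(
            self.values[np.ix_(idx, idx)],
            list(ids),
            self.divisor,
            self.n_samples,
            self.n_covariates,
            self.chromosome,
        )


# ---------------------------------------------------------------------------
# Residualization
# ---------------------------------------------------------------------------

def _check_full_rank(Z: np.ndarray, labels: list[str]) -> None:
    """Raise naming the dependent columns if Z is column-rank deficient."""
    rank = np.linalg.matrix_rank(Z)
    if rank == Z.shape[1]:
        return
    # identify offending columns by greedy rank growth
    dependent = []
    kept: list[int] = []
    for j in range(Z.shape[1]):
        cand = Z[:, kept + [j]]
        if np.linalg.matrix_rank(cand) == len(kept) + 1:
            kept.append(j)
        else:
            dependent.append(labels[j] if j < len(labels) else str(j))
    raise InputError(f"covariate matrix is rank deficient; dependent columns: {dependent}")


def residualize(M: np.ndarray, Z: CovariateMatrix, labels: list[str] | None = None) -> ResidualizedMatrix:
    """Project out covariates: return ``M - Z (Z'Z)^-1 Z' M`` column by column.

    Every output column has zero mean (the intercept is part of ``Z``) and the
    operation is idempotent: residualizing a residualized matrix is a no-op.
    """
    M = np.asarray(M, dtype=float)
    squeeze = M.ndim == 1
    if squeeze:
        M = M[:, None]
    if M.shape[0] != Z.n_samples:
        raise InputError(
            f"row mismatch: data has {M.shape[0]} rows, covariates have {Z.n_samples}"
        )
    coef, *_ = np.linalg.lstsq(Z.values, M, rcond=None)
    resid = M - Z.values @ coef
    if labels is None:
        labels = [f"col_{j}" for j in range(M.shape[1])]
    out = resid[:, 0] if squeeze else resid
    return ResidualizedMatrix(out, labels, Z.n_samples - Z.n_covariates - 1)


# ---------------------------------------------------------------------------
# Partial covariance
# ---------------------------------------------------------------------------

def partial_covariance(
    X: np.ndarray,
    Z: CovariateMatrix,
    feature_ids: list[str] | None = None,
    divisor: float | str = "n-1",
) -> PartialCovariance:
    """Covariance of covariate-residualized features: ``C = X~' X~ / divisor``.

    ``divisor`` may be the string ``"n-1"`` (default) or ``"n"``, or an
    explicit positive number.  Constant residual columns are retained as zero
    rows/columns with a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InputError("feature matrix must be 2-dimensional")
    n, m = X.shape
    if feature_ids is None:
        feature_ids = [f"x{j + 1}" for j in range(m)]
    if divisor == "n-1":
        div = float(n - 1)
    elif divisor == "n":
        div = float(n)
    else:
        div = float(divisor)
        if div <= 0:
            raise InputError("divisor must be positive")
    R = residualize(X, Z).values
    ss = np.einsum("ij,ij->j", R, R)
    const = ss <= 1e-12 * max(1.0, float(np.max(ss, initial=0.0)))
    if np.any(const):
        warnings.warn(
            "features constant after residualization (zero rows retained): "
            f"{[feature_ids[j] for j in np.flatnonzero(const)]}",
            stacklevel=2,
        )
    values = (R.T @ R) / div
    values = (values + values.T) / 2.0  # enforce exact symmetry
    if np.any(const):
        values[const, :] = 0.0
        values[:, const] = 0.0
    return PartialCovariance(values, list(feature_ids), div, n, Z.n_covariates)


# ---------------------------------------------------------------------------
# Test statistics
# ---------------------------------------------------------------------------

def _deep_tail_logsf(t: float, dof: float) -> float:
    """Natural-log t survival function for statistics so extreme that the
    double-precision incomplete-beta path underflows; evaluated with the
    arbitrary-precision regularized incomplete beta (sf = I_x(d/2, 1/2)/2
    with x = d/(d + t^2))."""
    import mpmath

    with mpmath.workdps(40):
        x = mpmath.mpf(dof) / (mpmath.mpf(dof) + mpmath.mpf(t) ** 2)
        sf = mpmath.betainc(mpmath.mpf(dof) / 2, mpmath.mpf("0.5"), 0, x, regularized=True) / 2
        return float(mpmath.log(sf))


def neg_log10_p_from_t(t: np.ndarray, dof: int | np.ndarray) -> np.ndarray:
    """Two-sided -log10 p for t statistics, computed via the log survival
    function so that huge statistics (|t| ~ 40 and beyond) do not underflow."""
    t = np.asarray(t, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        logp = np.log(2.0) + stats.t.logsf(np.abs(t), dof)
    under = np.isneginf(logp) & np.isfinite(t)
    if np.any(under):
        dof_arr = np.broadcast_to(np.asarray(dof, dtype=float), logp.shape)
        t_b = np.broadcast_to(t, logp.shape)
        flat = logp.reshape(-1).copy()
        idx = np.flatnonzero(under.reshape(-1))
        for i in idx:
            flat[i] = np.log(2.0) + _deep_tail_logsf(abs(t_b.reshape(-1)[i]), dof_arr.reshape(-1)[i])
        logp = flat.reshape(logp.shape)
    return -logp / np.log(10.0)


def chi2_pvalue(beta: float, se: float, dof: int) -> tuple[float, float]:
    """Squared t statistic and two-sided -log10 p for one coefficient.

    Raises on ``se <= 0`` or ``dof < 1``; a zero coefficient maps to p = 1.
    """
    if se <= 0:
        raise NumericalError(f"standard error must be positive, got {se}")
    if dof < 1:
        raise NumericalError(f"degrees of freedom must be >= 1, got {dof}")
    t = beta / se
    return float(t * t), float(neg_log10_p_from_t(np.array(t), dof))


# ---------------------------------------------------------------------------
# Direct GWAS (the oracle)
# ---------------------------------------------------------------------------

def _complete_cases(*arrays: np.ndarray) -> np.ndarray:
    mask = np.ones(arrays[0].shape[0], dtype=bool)
    for a in arrays:
        a2 = a if a.ndim == 2 else a[:, None]
        mask &= np.all(np.isfinite(a2), axis=1)
    return mask


def direct_scan(
    Y: np.ndarray, G: np.ndarray, Z: CovariateMatrix
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Vectorized single-variant OLS scans of every column of Y on every column of G.

    Returns ``(beta, se, t, neg_log10_p, dof)``, each array of shape
    (V variants, k phenotypes).  Per variant ``beta = g~'y~ / g~'g~`` and
    ``se^2 = (y~'y~/g~'g~ - beta^2)/d`` with ``d = N - C - 1``; this equals the
    coefficient and standard error on the genotype in a joint fit of
    ``y ~ Z + g``.  Constant residualized variants yield NaN columns;
    zero-residual fits yield se = 0 with t and -log10 p infinite.
    """
    Y = np.asarray(Y, dtype=float)
    G = np.asarray(G, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    Ry = residualize(Y, Z)
    Rg = residualize(G, Z)
    d = Ry.dof
    gss = np.einsum("ij,ij->j", Rg.values, Rg.values)  # (V,)
    yss = np.einsum("ij,ij->j", Ry.values, Ry.values)  # (k,)
    scale = max(1.0, float(np.max(gss, initial=0.0)))
    bad = gss <= 1e-12 * scale
    gss_safe = np.where(bad, 1.0, gss)
    beta = (Rg.values.T @ Ry.values) / gss_safe[:, None]  # (V, k)
    ratio = yss[None, :] / gss_safe[:, None]
    radicand = ratio - beta**2
    # a perfect (noiseless) fit leaves only cancellation round-off behind
    radicand[radicand <= 1e-14 * ratio] = 0.0
    se = np.sqrt(radicand / d)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.sign(beta) * np.inf)
    nlp = np.full_like(beta, np.inf)
    finite = se > 0
    nlp[finite] = neg_log10_p_from_t(t[finite], d)
    beta[bad, :] = np.nan
    se[bad, :] = np.nan
    t[bad, :] = np.nan
    nlp[bad, :] = np.nan
    if squeeze:
        return beta[:, 0], se[:, 0], t[:, 0], nlp[:, 0], d
    return beta, se, t, nlp, d


def direct_gwas(
    y: np.ndarray,
    G: np.ndarray,
    Z: CovariateMatrix,
    variant_ids: list[str] | None = None,
    chrom: list[str] | None = None,
    pos: list[int] | None = None,
) -> list[AssociationResult]:
    """Single-variant OLS GWAS of phenotype ``y`` on each dosage column of ``G``.

    Rows with any missing value among y, G and Z are dropped (complete-case).
    Variants constant after residualization are flagged rather than raised.
    """
    y = np.asarray(y, dtype=float).ravel()
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    if not (y.shape[0] == G.shape[0] == Z.n_samples):
        raise InputError("y, G and Z must have equal row counts")
    mask = _complete_cases(y, G, Z.values)
    if not mask.all():
        y, G = y[mask], G[mask]
        Z = CovariateMatrix(Z.values[mask], Z.labels)
    n = int(mask.sum())
    V = G.shape[1]
    if variant_ids is None:
        variant_ids = [f"v{j + 1}" for j in range(V)]
    chrom = chrom or ["0"] * V
    pos = pos if pos is not None else list(range(1, V + 1))
    beta, se, t, nlp, d = direct_scan(y, G, Z)
    out = []
    for j in range(V):
        if np.isnan(beta[j]):
            out.append(
                AssociationResult(variant_ids[j], np.nan, np.nan, np.nan, np.nan, n, d,
                                  chrom[j], pos[j], flag="constant-genotype")
            )
        elif se[j] == 0.0:
            out.append(
                AssociationResult(variant_ids[j], float(beta[j]), 0.0, float(t[j]),
                                  float(nlp[j]), n, d, chrom[j], pos[j], flag="se-degenerate")
            )
        else:
            out.append(
                AssociationResult(variant_ids[j], float(beta[j]), float(se[j]), float(t[j]),
                                  float(nlp[j]), n, d, chrom[j], pos[j])
            )
    return out
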