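"""Linearization of nonlinear phenotype definitions.

Indirect association math only applies to linear combinations of feature
phenotypes, so an arbitrary (e.g. boolean) phenotype vector is first
approximated by ordinary least squares on the feature matrix.  The R^2 of
that fit is the "quality gauge": it can be computed without any genotype
data yet is a strong predictor of how faithful the downstream association
statistics will be.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .gwas_core import InputError
from .indirect_engine import Projection

__all__ = ["LinearApproximation", "fit_linear_approximation", "quality_gauge"]

_GAUGE_THRESHOLDS = (0.5, 0.75)  # poor < 0.5 <= moderate < 0.75 <= good


@dataclass
class LinearApproximation:
    """An OLS approximation of a phenotype by feature columns.

    ``projection`` holds the fitted weights and intercept; ``r2`` is the
    coefficient of determination of the fit on the supplied data; ``gauge``
    is the thresholded quality category.
    """

    projection: Projection
    r2: float
    n_used: int

    def __post_init__(self) -> None:
        if not (-1e-10 <= self.r2 <= 1 + 1e-10):
            raise InputError(f"R^2 out of range: {self.r2}")
        self.r2 = float(min(max(self.r2, 0.0), 1.0))

    @property
    def gauge(self) -> str:
        return quality_gauge(self.r2)


def quality_gauge(r2: float) -> str:
    """Map a fit R^2 onto the three-level quality category.

    ``poor`` below 0.5, ``moderate`` in [0.5, 0.75), ``good`` at 0.75 and
    above; boundaries are inclusive upward.
    """
    if not (0.0 <= r2 <= 1.0):
        raise InputError(f"R^2 must lie in [0, 1], got {r2}")
    lo, hi = _GAUGE_THRESHOLDS
    if r2 < lo:
        return "poor"
    if r2 < hi:
        return "moderate"
    return "good"


def fit_linear_approximation(
    y: np.ndarray,
    X: np.ndarray,
    feature_ids: list[str] | None = None,
    label: str = "linearized",
) -> LinearApproximation:
    """Least-squares fit of ``y`` on ``[1, X]`` with its R^2.

    An intercept is always included.  Rank-deficient feature matrices are
    solved by the minimum-norm solution with a warning (no regularization).
    A zero-variance target is an error: its gauge would be undefined.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise InputError("y and X must have matching row counts")
    n, m = X.shape
    if feature_ids is None:
        feature_ids = [f"x{j + 1}" for j in range(m)]
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 0:
        raise InputError("target phenotype has zero variance; fit quality is undefined")
    design = np.column_stack([np.ones(n), X])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        warnings.warn(
            "feature matrix is rank deficient; using the minimum-norm solution",
            stacklevel=2,
        )
    rss = float(np.sum((y - design @ coef) ** 2))
    r2 = 1.0 - rss / tss
    proj = Projection(list(feature_ids), coef[1:], intercept=float(coef[0]), label=label)
    return LinearApproximation(proj, r2, n)
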