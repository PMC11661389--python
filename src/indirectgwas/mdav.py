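"""MDAV microaggregation for k-anonymous phenotype release.

Maximum Distance to the AVerage vector (MDAV) partitions records into
clusters of size between k and 2k-1 and replaces each record by its cluster
centroid, so that every released row is identical to at least k-1 others
(k-anonymity).  Centroid replacement preserves the global column means, which
is what downstream least-squares linearization consumes.

This is the "generic" MDAV variant: cluster sizes are exactly k except
possibly the final remainder cluster, which absorbs up to 2k-1 records.
Ties in farthest/nearest selection break to the lowest record index, making
the output deterministic for a fixed input ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gwas_core import InputError

__all__ = ["AnonymizedDataset", "mdav_anonymize", "verify_k_anonymity"]


@dataclass
class AnonymizedDataset:
    """Result of microaggregation: centroid-valued rows plus the clustering."""

    values: np.ndarray          # N x m, each row the centroid of its cluster
    assignments: np.ndarray     # N ints, cluster id per record
    k: int
    cluster_sizes: np.ndarray   # size per cluster id

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)


def _farthest(X: np.ndarray, point: np.ndarray, idx: np.ndarray) -> int:
    """Index (into idx) of the record farthest from point; lowest index on ties."""
    d = np.einsum("ij,ij->i", X[idx] - point, X[idx] - point)
    return int(idx[np.argmax(d)])  # argmax returns the first (lowest) on ties


def _nearest_k(X: np.ndarray, center: int, idx: np.ndarray, k: int) -> np.ndarray:
    """The k records of idx nearest to record `center` (center included),
    ties broken by record index."""
    d = np.einsum("ij,ij->i", X[idx] - X[center], X[idx] - X[center])
    order = np.lexsort((idx, d))
    return idx[order[:k]]


def mdav_anonymize(X: np.ndarray, k: int, standardize: bool = False) -> AnonymizedDataset:
    """Microaggregate ``X`` so every record is at least k-anonymous.

    Distances are Euclidean on the raw columns (all features are assumed to
    share a coding, e.g. {0,1} diagnosis indicators); pass
    ``standardize=True`` to z-score mixed-scale columns first (distance only —
    released centroids are always on the original scale).  Binary inputs
    produce fractional centroids, which are kept as-is.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InputError("input matrix must be 2-dimensional")
    if not np.all(np.isfinite(X)):
        raise InputError("input matrix contains non-finite values")
    n = X.shape[0]
    if k < 2:
        raise InputError(f"anonymity parameter k must be >= 2, got {k}")
    if n < k:
        raise InputError(f"need at least k={k} records, got {n}")

    D = X
    if standardize:
        sd = X.std(axis=0, ddof=0)
        D = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    unassigned = np.arange(n)
    clusters: list[np.ndarray] = []
    while unassigned.size >= 3 * k:
        centroid = D[unassigned].mean(axis=0)
        r = _farthest(D, centroid, unassigned)
        cluster_r = _nearest_k(D, r, unassigned, k)
        unassigned = np.setdiff1d(unassigned, cluster_r, assume_unique=True)
        clusters.append(cluster_r)
        s = _farthest(D, D[r], unassigned)
        cluster_s = _nearest_k(D, s, unassigned, k)
        unassigned = np.setdiff1d(unassigned, cluster_s, assume_unique=True)
        clusters.append(cluster_s)
    if unassigned.size >= 2 * k:
        centroid = D[unassigned].mean(axis=0)
        r = _farthest(D, centroid, unassigned)
        cluster_r = _nearest_k(D, r, unassigned, k)
        unassigned = np.setdiff1d(unassigned, cluster_r, assume_unique=True)
        clusters.append(cluster_r)
        clusters.append(unassigned)
    elif unassigned.size > 0:
        clusters.append(unassigned)

    values = np.empty_like(X)
    assignments = np.empty(n, dtype=int)
    sizes = np.empty(len(clusters), dtype=int)
    for cid, members in enumerate(clusters):
        values[members] = X[members].mean(axis=0)
        assignments[members] = cid
        sizes[cid] = members.size
    return AnonymizedDataset(values, assignments, k, sizes)


def verify_k_anonymity(ds: AnonymizedDataset, original: np.ndarray | None = None) -> dict:
    """Audit an anonymized dataset.

    Reports the minimum multiplicity of identical released rows (must be
    >= k for the guarantee to hold), the cluster-size histogram, the
    within-cluster sum of squares (information loss) and, when the original
    matrix is supplied, the per-column mean drift.
    """
    rows, counts = np.unique(ds.values, axis=0, return_counts=True)
    min_mult = int(counts.min()) if counts.size else 0
    sizes, freq = np.unique(ds.cluster_sizes, return_counts=True)
    report = {
        "k": ds.k,
        "min_multiplicity": min_mult,
        "k_anonymous": bool(min_mult >= ds.k),
        "n_clusters": ds.n_clusters,
        "cluster_size_histogram": {int(s): int(f) for s, f in zip(sizes, freq)},
        "sizes_within_bounds": bool(
            ds.cluster_sizes.min() >= ds.k and ds.cluster_sizes.max() <= 2 * ds.k - 1
        ),
    }
    if original is not None:
        original = np.asarray(original, dtype=float)
        report["max_column_mean_drift"] = float(
            np.max(np.abs(original.mean(axis=0) - ds.values.mean(axis=0)))
        )
        report["within_cluster_ss"] = float(np.sum((original - ds.values) ** 2))
    return report
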