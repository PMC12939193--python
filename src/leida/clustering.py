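"""Clustering of pooled leading eigenvectors into recurrent phase-locking states.

Eigenvectors from all scans and volumes are stacked and partitioned with
k-means under the cosine distance ``d(x, c) = 1 - x.c / (|x||c|)`` for every
K in a range (2..20 by default), 25 random restarts per K.  Because rows and
centroids are kept at unit norm, the update step is the normalized mean of
the assigned rows (spherical k-means).  States within each solution are
sorted by descending occupancy, and the family of solutions over the whole
K range forms the centroid pyramid (209 states for K = 2..20).

Centroids may be spatially matched against user-supplied reference network
vectors (e.g. canonical resting-state networks mapped to the parcellation);
:func:`toy_reference_networks` ships a synthetic 7-network stand-in for
tests and demonstrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (
    ConfigurationError,
    DegenerateClusteringError,
    ValidationError,
)
from .phase import LeadingEigenvectorSeries, _canonicalize_rows
from ._seeds import derive_seed

__all__ = [
    "EigenvectorStack",
    "ClusteringSolution",
    "CentroidPyramid",
    "stack_eigenvectors",
    "kmeans_cosine",
    "fit_pyramid",
    "rsn_overlap",
    "toy_reference_networks",
]

MAX_ITER = 300


@dataclass
class EigenvectorStack:
    """All scans' eigenvectors pooled row-wise, with scan/group bookkeeping."""

    matrix: np.ndarray
    scan_of_row: np.ndarray
    group_of_row: np.ndarray

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2:
            raise ValidationError("stack matrix must be 2-D")
        if len(self.scan_of_row) != len(self.matrix) or len(self.group_of_row) != len(
            self.matrix
        ):
            raise ValidationError("row annotations must match the matrix")
        norms = np.linalg.norm(self.matrix, axis=1)
        if np.abs(norms - 1.0).max() > 1e-8:
            raise ValidationError("stack rows must be unit norm")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def scan_ids(self) -> list[str]:
        """Unique scan ids in first-appearance (cohort) order."""
        _, idx = np.unique(self.scan_of_row, return_index=True)
        return [self.scan_of_row[i] for i in np.sort(idx)]


@dataclass
class ClusteringSolution:
    """One K's partition: occupancy-sorted unit centroids + 1-based labels."""

    K: int
    centroids: np.ndarray
    labels: np.ndarray
    occupancy_order: np.ndarray
    inertia: float
    replicate_seeds: list[int]


@dataclass
class CentroidPyramid:
    """Family of clustering solutions over K = K_min..K_max."""

    solutions: dict[int, ClusteringSolution]

    @property
    def k_values(self) -> list[int]:
        return sorted(self.solutions)

    @property
    def total_states(self) -> int:
        return sum(self.k_values)


def stack_eigenvectors(
    series: list[LeadingEigenvectorSeries], groups: list[str]
) -> EigenvectorStack:
    """Concatenate per-scan eigenvector series into one pooled stack."""
    if len(series) != len(groups):
        raise ValidationError("one group label per scan required")
    if not series:
        raise ValidationError("empty cohort")
    matrix = np.vstack([s.vectors for s in series])
    scan_of_row = np.concatenate(
        [np.full(s.n_vectors, s.scan_id, dtype=object) for s in series]
    )
    group_of_row = np.concatenate(
        [np.full(s.n_vectors, g, dtype=object) for s, g in zip(series, groups)]
    )
    return EigenvectorStack(matrix, scan_of_row, group_of_row)


def _lloyd_cosine(
    X: np.ndarray, init_idx: np.ndarray, max_iter: int = MAX_ITER
) -> tuple[np.ndarray, np.ndarray, float]:
    """One run of Lloyd's algorithm under cosine distance on unit rows.

    Returns (centroids, labels 0-based, inertia).  Empty clusters are
    re-seeded from the row currently farthest from its own centroid.
    """
    K = len(init_idx)
    centroids = X[init_idx].copy()
    labels = np.full(len(X), -1)
    for _ in range(max_iter):
        sim = X @ centroids.T
        new_labels = np.argmax(sim, axis=1)  # ties -> lowest index
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        counts = np.bincount(labels, minlength=K)
        empties = np.flatnonzero(counts == 0)
        if empties.size:
            assigned_sim = sim[np.arange(len(X)), labels]
            order = np.argsort(assigned_sim, kind="stable")  # farthest first
            for k, row in zip(empties, order):
                centroids[k] = X[row]
                labels[row] = k
            counts = np.bincount(labels, minlength=K)
        sums = np.zeros_like(centroids)
        np.add.at(sums, labels, X)
        norms = np.linalg.norm(sums, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        centroids = sums / norms
    inertia = float(np.sum(1.0 - (X @ centroids.T)[np.arange(len(X)), labels]))
    return centroids, labels, inertia


def kmeans_cosine(
    stack: EigenvectorStack, K: int, replicates: int = 25, seed: int = 0
) -> ClusteringSolution:
    """Best-of-``replicates`` cosine k-means on the pooled stack.

    Each replicate draws K distinct rows uniformly at random as initial
    centroids from its own seeded stream, runs Lloyd iterations (centroid =
    normalized mean of assigned rows) until the assignment stabilizes or
    ``MAX_ITER`` iterations, and the replicate with the lowest total cosine
    distance wins.  States are then sorted by descending occupancy (stable
    in the original index on ties), relabelled 1..K, and the centroids
    sign-canonicalized.
    """
    X = stack.matrix
    if replicates < 1:
        raise ConfigurationError("need at least one replicate")
    if K < 1 or K > len(X):
        raise DegenerateClusteringError(f"K={K} infeasible for {len(X)} rows")
    n_distinct = len(np.unique(X, axis=0))
    if K > n_distinct:
        raise DegenerateClusteringError(
            f"K={K} exceeds the {n_distinct} distinct rows"
        )
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    rep_seeds = [derive_seed(seed, "replicate", r) for r in range(replicates)]
    for rep_seed in rep_seeds:
        rng = np.random.default_rng(rep_seed)
        init_idx = rng.choice(len(X), size=K, replace=False)
        centroids, labels, inertia = _lloyd_cosine(X, init_idx)
        if best is None or inertia < best[2]:
            best = (centroids, labels, inertia)
    centroids, labels, inertia = best
    counts = np.bincount(labels, minlength=K)
    order = np.argsort(-counts, kind="stable")
    relabel = np.empty(K, dtype=int)
    relabel[order] = np.arange(K)
    return ClusteringSolution(
        K=K,
        centroids=_canonicalize_rows(centroids[order]),
        labels=relabel[labels] + 1,
        occupancy_order=order,
        inertia=inertia,
        replicate_seeds=rep_seeds,
    )


def fit_pyramid(
    stack: EigenvectorStack,
    k_min: int = 2,
    k_max: int = 20,
    replicates: int = 25,
    seed: int = 0,
) -> CentroidPyramid:
    """Fit one clustering solution per K in ``k_min..k_max``.

    Per-K replicate streams are derived from the master seed, so the whole
    pyramid is reproducible.  For the default K = 2..20 range the pyramid
    holds sum(2..20) = 209 states.
    """
    if k_min < 1 or k_max < k_min:
        raise ConfigurationError("need 1 <= k_min <= k_max")
    solutions = {
        K: kmeans_cosine(stack, K, replicates, derive_seed(seed, "kmeans", K))
        for K in range(k_min, k_max + 1)
    }
    return CentroidPyramid(solutions=solutions)


def rsn_overlap(
    centroid: np.ndarray,
    references: dict[str, np.ndarray],
    threshold: float = 0.3,
) -> tuple[str, float]:
    """Best Pearson match of a centroid against named reference vectors.

    Returns ``(name, r)`` of the highest-correlation reference, or
    ``("none", r_max)`` when no correlation reaches ``threshold``.
    """
    if not references:
        raise ConfigurationError("references must be non-empty")
    centroid = np.asarray(centroid, dtype=float)
    best_name, best_r = "", -np.inf
    for name, ref in references.items():
        ref = np.asarray(ref, dtype=float)
        if ref.shape != centroid.shape:
            raise ValidationError(f"reference {name!r} has mismatched length")
        if np.std(ref) == 0:
            raise ValidationError(f"reference {name!r} has zero variance")
        r = float(np.corrcoef(centroid, ref)[0, 1])
        if r > best_r:
            best_name, best_r = name, r
    if best_r < threshold:
        return "none", best_r
    return best_name, best_r


def toy_reference_networks(n_regions: int = 90) -> dict[str, np.ndarray]:
    """Synthetic 7-network reference set (block patterns, NOT a real atlas).

    Provides named vectors shaped like canonical resting-state network
    maps — contiguous blocks of positive loadings on a negative background —
    purely so the matching machinery can be exercised and demonstrated
    without external atlas data.
    """
    names = [
        "Visual",
        "Somatomotor",
        "DorsalAttention",
        "VentralAttention",
        "Limbic",
        "Frontoparietal",
        "DefaultMode",
    ]
    refs: dict[str, np.ndarray] = {}
    bounds = np.linspace(0, n_regions, len(names) + 1).astype(int)
    for i, name in enumerate(names):
        v = np.full(n_regions, -1.0)
        v[bounds[i] : bounds[i + 1]] = 1.0
        refs[name] = v / np.linalg.norm(v)
    return refs
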