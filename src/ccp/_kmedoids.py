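"""PAM-style k-medoids on a precomputed dissimilarity matrix.

Initialization is the greedy BUILD step of PAM; refinement replaces each
medoid by the point of its own Voronoi cell that minimizes the within-cell
dissimilarity sum (a restricted swap), iterated to convergence.  This keeps
every sweep at O(n^2) which matters when partitioning thousands of genes into
hundreds of clusters.  Ties are broken by lowest index, so the result is
deterministic for a given matrix.
"""

from __future__ import annotations

import numpy as np

__all__ = ["kmedoids"]


def _build(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    medoids = np.empty(k, dtype=np.intp)
    medoids[0] = int(np.argmin(d.sum(axis=0)))
    dmin = d[medoids[0]].copy()
    for t in range(1, k):
        # gain of adding candidate j: sum over points of max(dmin - d[:, j], 0)
        gain = np.maximum(dmin[:, None] - d, 0.0).sum(axis=0)
        gain[medoids[:t]] = -np.inf
        medoids[t] = int(np.argmax(gain))
        np.minimum(dmin, d[medoids[t]], out=dmin)
    return medoids


def kmedoids(
    d: np.ndarray, k: int, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster points given an (n, n) dissimilarity matrix.

    Returns ``(medoids, labels)`` with ``labels[i]`` in ``0..k-1``.
    """
    d = np.asarray(d, dtype=np.float64)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[1] != n:
        raise ValueError("dissimilarity matrix must be square")
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for n={n}")
    medoids = _build(d, k)
    labels = np.argmin(d[medoids], axis=0)
    for _ in range(max_iter):
        changed = False
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                continue
            costs = d[np.ix_(members, members)].sum(axis=0)
            best = members[int(np.argmin(costs))]
            if best != medoids[c]:
                medoids[c] = best
                changed = True
        new_labels = np.argmin(d[medoids], axis=0)
        if not changed and np.array_equal(new_labels, labels):
            break
        labels = new_labels
    # medoids always belong to their own cell (distance 0 to themselves)
    labels[medoids] = np.arange(k)
    return medoids, labels
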