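"""Clustering of reduced representations and agreement metrics.

Cells are clustered with the Leiden algorithm on a k-nearest-neighbor graph
of the representation (super-genes, a 2-D embedding, or raw expression), and
a predicted clustering is scored against reference labels with the adjusted
Rand index (ARI), normalized mutual information (NMI, arithmetic-mean
normalization) and element-centric clustering similarity (ECM).

ARI and NMI delegate to scikit-learn.  ECM is implemented here from the
personalized-PageRank construction it is defined by: for a hard partition the
PageRank affinity of element i has the closed form

    p_ij = alpha / |c_i| + (1 - alpha) * [i == j]   for j in i's cluster,

and the similarity of two partitions is the mean over elements of
1 - (1/2 alpha) * L1(p_i^A, p_i^B), with the conventional alpha = 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

__all__ = [
    "ClusterLabels",
    "MetricsReport",
    "leiden_cluster",
    "ari",
    "nmi",
    "ecm",
    "score_clustering",
    "benchmark_sweep",
    "sweep_summary",
]

ECM_ALPHA = 0.9


@dataclass
class ClusterLabels:
    """Integer cluster assignments 0..n_clusters-1 without gaps."""

    labels: np.ndarray
    n_clusters: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.intp)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        found = np.unique(self.labels).size
        if not self.n_clusters:
            self.n_clusters = found
        used = np.unique(self.labels)
        if not np.array_equal(used, np.arange(self.n_clusters)):
            raise ValueError("labels must cover 0..n_clusters-1 without gaps")

    @classmethod
    def from_raw(cls, raw) -> "ClusterLabels":
        """Canonicalize arbitrary hashable labels to 0..k-1 by first occurrence."""
        raw = list(raw)
        mapping: dict = {}
        out = np.empty(len(raw), dtype=np.intp)
        for i, value in enumerate(raw):
            out[i] = mapping.setdefault(value, len(mapping))
        return cls(out, len(mapping))

    def __len__(self) -> int:
        return self.labels.size


@dataclass
class MetricsReport:
    ari: float
    nmi: float
    ecm: float
    n_cells: int
    n_clusters_pred: int
    n_clusters_true: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.ari <= 1.0:
            raise ValueError("ARI outside [-1, 1]")
        if not 0.0 <= self.nmi <= 1.0 or not 0.0 <= self.ecm <= 1.0:
            raise ValueError("NMI/ECM outside [0, 1]")


def _as_labels(a) -> np.ndarray:
    return np.asarray(a.labels if isinstance(a, ClusterLabels) else a, dtype=np.intp)


def _check_lengths(a: np.ndarray, b: np.ndarray) -> None:
    if a.size != b.size:
        raise ValueError(f"label length mismatch: {a.size} vs {b.size}")


def _knn_graph(values: np.ndarray, n_neighbors: int):
    import igraph as ig
    from sklearn.neighbors import NearestNeighbors

    m = values.shape[0]
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(values)
    _, idx = nn.kneighbors(values)
    edges = set()
    for i in range(m):
        for j in idx[i, 1:]:
            edges.add((i, int(j)) if i < j else (int(j), i))
    return ig.Graph(n=m, edges=sorted(edges))


def _leiden_once(graph, resolution: float, seed: int) -> ClusterLabels:
    import leidenalg

    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=-1,
    )
    return ClusterLabels.from_raw(part.membership)


def leiden_cluster(
    data,
    n_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    target_clusters: int | None = None,
) -> ClusterLabels:
    """Leiden community detection on a kNN graph of the representation.

    The graph joins each cell to its ``n_neighbors`` Euclidean nearest
    neighbors (symmetrized, unweighted); communities are found with the
    RB-configuration objective.  Deterministic for a fixed seed.

    When ``target_clusters`` is given, the resolution is searched
    (geometric bisection, 25 steps) until the community count matches —
    the standard protocol for benchmarking against a known number of cell
    types, since modularity at any fixed resolution over- or under-splits
    depending on cluster geometry.  The labeling closest in cluster count
    is returned if no resolution matches exactly.
    """
    values = np.asarray(data.values if hasattr(data, "values") else data, dtype=np.float64)
    m = values.shape[0]
    if m < 2:
        raise ValueError("need at least 2 cells to cluster")
    if n_neighbors >= m:
        raise ValueError(f"n_neighbors={n_neighbors} must be below the cell count {m}")
    graph = _knn_graph(values, n_neighbors)
    if target_clusters is None:
        return _leiden_once(graph, resolution, seed)
    lo, hi = 1e-3, 10.0
    best: ClusterLabels | None = None
    for _ in range(25):
        mid = float(np.sqrt(lo * hi))
        labels = _leiden_once(graph, mid, seed)
        if best is None or abs(labels.n_clusters - target_clusters) < abs(
            best.n_clusters - target_clusters
        ):
            best = labels
        if labels.n_clusters == target_clusters:
            return labels
        if labels.n_clusters < target_clusters:
            lo = mid
        else:
            hi = mid
    return best


def ari(a, b) -> float:
    """Adjusted Rand index, permutation-invariant and chance-corrected."""
    a, b = _as_labels(a), _as_labels(b)
    _check_lengths(a, b)
    return float(adjusted_rand_score(a, b))


def nmi(a, b) -> float:
    """Normalized mutual information (arithmetic-mean normalization)."""
    a, b = _as_labels(a), _as_labels(b)
    _check_lengths(a, b)
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def ecm(a, b, alpha: float = ECM_ALPHA) -> float:
    """Element-centric clustering similarity in [0, 1].

    Uses the closed-form personalized-PageRank affinities of hard
    partitions; elements sharing clusters in both partitions contribute
    similarity 1, fully disagreeing elements contribute less.
    """
    a, b = _as_labels(a), _as_labels(b)
    _check_lengths(a, b)
    n = a.size
    if n == 0:
        raise ValueError("empty labelings")
    sizes_a = np.bincount(a)
    sizes_b = np.bincount(b)
    # contingency: for element i, the L1 distance between its two affinity
    # vectors depends only on (cluster in A, cluster in B) and the overlap.
    total = 0.0
    for ca in range(sizes_a.size):
        members_a = a == ca
        for cb in np.unique(b[members_a]):
            members_b = b == cb
            overlap = int(np.count_nonzero(members_a & members_b))
            pa, pb = alpha / sizes_a[ca], alpha / sizes_b[cb]
            # shared elements (overlap of the two clusters): |pa - pb|,
            # except the self term where both add (1 - alpha) and it cancels.
            l1 = overlap * abs(pa - pb)
            l1 += (sizes_a[ca] - overlap) * pa  # in A's cluster only
            l1 += (sizes_b[cb] - overlap) * pb  # in B's cluster only
            total += overlap * (1.0 - l1 / (2.0 * alpha))
    return float(total / n)


def score_clustering(pred, true) -> MetricsReport:
    """ARI/NMI/ECM of a predicted clustering against reference labels."""
    p, t = _as_labels(pred), _as_labels(true)
    _check_lengths(p, t)
    return MetricsReport(
        ari=ari(p, t),
        nmi=nmi(p, t),
        ecm=ecm(p, t),
        n_cells=p.size,
        n_clusters_pred=int(np.unique(p).size),
        n_clusters_true=int(np.unique(t).size),
    )


def benchmark_sweep(
    x,
    true_labels,
    n_supergenes_grid=(300,),
    v_c_grid=(0.8,),
    n_seeds: int = 10,
    tau: float = 6.0,
    kappa: float = 2.0,
    leiden_neighbors: int = 15,
) -> pd.DataFrame:
    """Grid sweep over (super-gene count, cutoff ratio) × seeds.

    For every configuration and seed, fits the CCP reduction on ``x``,
    clusters the super-genes with Leiden (resolution matched to the
    reference cluster count), and records ARI/NMI/ECM against the reference
    labels.  Returns one row per (config, seed); aggregate with
    :func:`sweep_summary`.
    """
    from .projection import fit_ccp

    true = _as_labels(true_labels)
    k_true = int(np.unique(true).size)
    rows = []
    for n_sg, v_c in product(n_supergenes_grid, v_c_grid):
        for seed in range(n_seeds):
            _, sg = fit_ccp(
                x, n_clusters=n_sg, v_c=v_c, tau=tau, kappa=kappa, seed=seed
            )
            pred = leiden_cluster(
                sg, n_neighbors=leiden_neighbors, seed=seed, target_clusters=k_true
            )
            report = score_clustering(pred, true)
            rows.append(
                {
                    "n_supergenes": n_sg,
                    "v_c": v_c,
                    "seed": seed,
                    "ari": report.ari,
                    "nmi": report.nmi,
                    "ecm": report.ecm,
                }
            )
    return pd.DataFrame(rows)


def sweep_summary(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-configuration means of a :func:`benchmark_sweep` result."""
    return (
        rows.groupby(["n_supergenes", "v_c"], as_index=False)[["ari", "nmi", "ecm"]]
        .mean()
    )
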