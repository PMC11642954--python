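"""Gene ranking, low-variance consolidation, and gene partitioning.

CCP first ranks genes by expression variance across cells and sets aside the
bottom ``1 - v_c`` fraction as the low-variance (LV) set P; those genes are
later projected into a single LV super-gene instead of being discarded.  The
remaining genes are partitioned into N clusters by gene–gene similarity —
k-medoids on a correlation- or covariance-derived distance matrix by default,
or plain k-means on the raw gene vectors.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._kmedoids import kmedoids
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GenePartition",
    "gene_variances",
    "select_lv_set",
    "gene_distance_matrix",
    "partition_genes",
]


@dataclass
class GenePartition:
    """Disjoint gene clusters S^1..S^N plus the low-variance set P.

    ``clusters`` holds sorted integer gene indices (into the fitted matrix's
    gene axis); ``lv_set`` the indices consolidated into the LV super-gene.
    Together they tile the full gene index set.
    """

    clusters: list[np.ndarray]
    lv_set: np.ndarray
    cutoff_ratio: float
    n_genes: int
    method: str = "kmedoids"
    distance: str = "correlation"

    def __post_init__(self) -> None:
        self.clusters = [np.asarray(sorted(c), dtype=np.intp) for c in self.clusters]
        self.lv_set = np.asarray(sorted(self.lv_set), dtype=np.intp)
        seen: set[int] = set()
        total = 0
        for c in self.clusters:
            if c.size == 0:
                raise ValueError("empty gene cluster")
            total += c.size
            seen.update(c.tolist())
        if len(seen) != total:
            raise ValueError("gene clusters overlap")
        if seen & set(self.lv_set.tolist()):
            raise ValueError("LV set overlaps a gene cluster")
        if total + self.lv_set.size != self.n_genes:
            raise ValueError("clusters + LV set do not tile the gene index set")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def to_json(self, gene_ids: list[str], path: str | Path | None = None) -> str:
        """Serialize as JSON keyed by gene identifiers."""
        payload = {
            "clusters": [[gene_ids[i] for i in c] for c in self.clusters],
            "lv": [gene_ids[i] for i in self.lv_set],
            "params": {
                "cutoff_ratio": self.cutoff_ratio,
                "n_clusters": self.n_clusters,
                "method": self.method,
                "distance": self.distance,
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path, gene_ids: list[str]) -> "GenePartition":
        p = Path(text_or_path) if not str(text_or_path).lstrip().startswith("{") else None
        payload = json.loads(p.read_text() if p else str(text_or_path))
        index = {g: i for i, g in enumerate(gene_ids)}
        return cls(
            clusters=[np.array([index[g] for g in c], dtype=np.intp) for c in payload["clusters"]],
            lv_set=np.array([index[g] for g in payload["lv"]], dtype=np.intp),
            cutoff_ratio=payload["params"]["cutoff_ratio"],
            n_genes=len(gene_ids),
            method=payload["params"]["method"],
            distance=payload["params"]["distance"],
        )


def gene_variances(x: ExpressionMatrix) -> np.ndarray:
    """Population variance of each gene across cells, in gene order."""
    if x.n_cells < 2:
        raise ValueError("variance needs at least 2 cells")
    return x.values.var(axis=0, ddof=0)


def select_lv_set(v: np.ndarray, v_c: float) -> np.ndarray:
    """Indices of the low-variance set P.

    Genes are ranked by descending variance (ties broken by ascending gene
    index); a gene with 1-based rank r belongs to P iff r > v_c * I, so
    exactly ``I - floor(v_c * I)`` genes are consolidated.
    """
    v = np.asarray(v, dtype=np.float64)
    if not 0.0 <= v_c <= 1.0:
        raise ValueError(f"cutoff ratio v_c={v_c} outside [0, 1]")
    i_total = v.size
    order = np.argsort(-v, kind="stable")  # descending variance, index ties ascending
    n_keep = int(np.floor(v_c * i_total))
    return np.sort(order[n_keep:])


def gene_distance_matrix(
    x: ExpressionMatrix, genes: np.ndarray, distance: str = "correlation"
) -> np.ndarray:
    """Symmetric gene–gene dissimilarity on the selected gene columns.

    ``correlation``: d_ij = 1 - Pearson rho (range [0, 2]); a zero-variance
    gene has its correlations defined as 0, i.e. distance 1 to everything,
    with a warning.  ``covariance``: d_ij = c_max - cov_ij with c_max the
    largest off-diagonal covariance, shifted to be a non-negative
    dissimilarity; the diagonal is set to 0.
    """
    genes = np.asarray(genes, dtype=np.intp)
    if genes.size < 2:
        raise ValueError("need at least 2 genes for a distance matrix")
    if x.n_cells < 2:
        raise ValueError("need at least 2 cells for gene similarity")
    sub = x.values[:, genes]
    if distance == "correlation":
        sd = sub.std(axis=0, ddof=0)
        flat = np.flatnonzero(sd == 0)
        if flat.size:
            warnings.warn(
                f"{flat.size} zero-variance gene(s) in distance matrix; "
                "their correlations are set to 0"
            )
        safe = np.where(sd == 0, 1.0, sd)
        z = (sub - sub.mean(axis=0)) / safe
        rho = (z.T @ z) / x.n_cells
        rho[flat, :] = 0.0
        rho[:, flat] = 0.0
        np.fill_diagonal(rho, 1.0)
        d = 1.0 - rho
    elif distance == "covariance":
        cov = np.cov(sub, rowvar=False, ddof=0)
        off = cov[~np.eye(cov.shape[0], dtype=bool)]
        d = off.max() - cov
    else:
        raise ValueError(f"unknown gene distance {distance!r}")
    d = np.maximum(d, 0.0)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def _repair_empty(labels: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Ensure every cluster label 0..k-1 is used by splitting the largest."""
    labels = labels.copy()
    for c in range(k):
        if not (labels == c).any():
            sizes = np.bincount(labels, minlength=k)
            big = int(np.argmax(sizes))
            members = np.flatnonzero(labels == big)
            take = rng.choice(members, size=members.size // 2, replace=False)
            labels[take] = c
            logger.warning("repaired empty cluster %d by splitting cluster %d", c, big)
    return labels


def partition_genes(
    x: ExpressionMatrix,
    n_clusters: int,
    method: str = "kmedoids",
    distance: str = "correlation",
    seed: int = 0,
    v_c: float = 0.8,
) -> GenePartition:
    """Select the LV set, then partition the remaining genes into N clusters.

    The LV set is removed first and clustering operates only on the genes
    that survive the variance cutoff.  Deterministic given ``seed``.
    """
    v = gene_variances(x)
    lv = select_lv_set(v, v_c)
    active = np.setdiff1d(np.arange(x.n_genes), lv, assume_unique=True)
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > active.size:
        raise ValueError(
            f"n_clusters={n_clusters} exceeds the {active.size} genes outside the LV set"
        )
    rng = np.random.default_rng(seed)
    if active.size == n_clusters:
        labels = np.arange(n_clusters)
    elif method == "kmedoids":
        d = gene_distance_matrix(x, active, distance)
        _, labels = kmedoids(d, n_clusters)
    elif method == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
        labels = km.fit_predict(x.values[:, active].T)
    else:
        raise ValueError(f"unknown partition method {method!r}")
    labels = _repair_empty(np.asarray(labels), n_clusters, rng)
    clusters = [active[labels == c] for c in range(n_clusters)]
    return GenePartition(
        clusters=clusters,
        lv_set=lv,
        cutoff_ratio=v_c,
        n_genes=x.n_genes,
        method=method,
        distance=distance,
    )
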