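"""FRI kernel projection of gene clusters into non-negative super-genes.

For a gene cluster S^n, the super-gene value of cell i is the kernel sum

    x_i^n = sum_m  Phi(|| z_i^{S_n} - z_m^{S_n} ||; eta, tau, kappa)

over the reference cells m, where Phi is the generalized exponential kernel

    Phi(d) = exp(-(d / (eta * tau))**kappa)   for d < r_c,   0 otherwise,

a flexibility-rigidity-index (FRI) construction: each super-gene measures the
accumulated correlation of a cell with all reference cells, restricted to one
cluster's genes.  Two scale parameters are estimated per cluster from the
reference data: eta, the average over cells of the minimal distance to
another cell, and the cutoff r_c, three (population) standard deviations of
the pairwise cell distances.  The same machinery projects the low-variance
set P into one extra "LV" super-gene, and supports out-of-sample embedding
of new cells against the stored reference without re-estimating any scale.
"""

from __future__ import annotations

import io as _stdio
import json
import logging
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse
from scipy.spatial.distance import cdist, pdist, squareform

from .io import ExpressionMatrix, write_matrix_csv
from .partition import GenePartition, partition_genes

logger = logging.getLogger(__name__)

DEGENERATE_ETA = 1e-8

__all__ = [
    "ClusterScale",
    "CCPModel",
    "SuperGeneMatrix",
    "pairwise_cell_distances",
    "compute_eta",
    "compute_rc",
    "kernel",
    "project_cluster",
    "fit_ccp",
    "embed_new",
    "save_model",
    "load_model",
]


@dataclass
class ClusterScale:
    """Per-cluster kernel scales: eta (data units), cutoff r_c, and the
    global kernel parameters tau (scale multiplier) and kappa (power)."""

    eta: float
    r_c: float
    tau: float = 6.0
    kappa: float = 2.0
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.eta < 0 or self.r_c < 0:
            raise ValueError("eta and r_c must be non-negative")
        if self.tau <= 0 or self.kappa <= 0:
            raise ValueError("tau and kappa must be positive")
        if self.metric not in ("euclidean", "manhattan", "wasserstein"):
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass
class SuperGeneMatrix:
    """Cells × super-genes non-negative matrix (one column per gene cluster,
    plus a final "LV" column when a low-variance set exists)."""

    values: np.ndarray
    cell_ids: list[str]
    column_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("super-gene values must be 2-D")
        if self.values.shape != (len(self.cell_ids), len(self.column_labels)):
            raise ValueError("super-gene shape does not match identifiers")
        if (self.values < 0).any():
            raise ValueError("negative super-gene value")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path: str | Path) -> Path:
        return write_matrix_csv(self.values, self.cell_ids, self.column_labels, path)


@dataclass
class CCPModel:
    """A fitted CCP reduction: the gene partition, per-cluster kernel scales,
    and the reference (training) cells needed to embed new data."""

    partition: GenePartition
    scales: list[ClusterScale]
    lv_scale: ClusterScale | None
    reference: np.ndarray  # training cells x genes (log-normalized)
    gene_ids: list[str]
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.scales) != self.partition.n_clusters:
            raise ValueError("one ClusterScale required per gene cluster")
        if (self.partition.lv_set.size > 0) != (self.lv_scale is not None):
            raise ValueError("LV scale must be present iff the LV set is non-empty")
        if self.reference.shape[1] != len(self.gene_ids):
            raise ValueError("reference matrix width does not match gene_ids")

    @property
    def n_reference(self) -> int:
        return self.reference.shape[0]

    @property
    def column_labels(self) -> list[str]:
        labels = [f"SG{n + 1:03d}" for n in range(self.partition.n_clusters)]
        if self.lv_scale is not None:
            labels.append("LV")
        return labels


def pairwise_cell_distances(
    values: np.ndarray | ExpressionMatrix, genes: np.ndarray, metric: str = "euclidean"
) -> np.ndarray:
    """Symmetric M × M cell–cell distances restricted to one cluster's genes.

    ``wasserstein`` treats each cell's within-cluster gene values as an
    empirical distribution and computes the 1-D Wasserstein-1 distance
    (mean absolute difference of sorted values).
    """
    if isinstance(values, ExpressionMatrix):
        values = values.values
    genes = np.asarray(genes, dtype=np.intp)
    if genes.size == 0:
        raise ValueError("empty gene set")
    sub = np.ascontiguousarray(values[:, genes])
    if metric == "euclidean":
        return squareform(pdist(sub, "euclidean"))
    if metric == "manhattan":
        return squareform(pdist(sub, "cityblock"))
    if metric == "wasserstein":
        return squareform(pdist(np.sort(sub, axis=1), "cityblock")) / genes.size
    raise ValueError(f"unknown metric {metric!r}")


def _cross_distances(
    a: np.ndarray, b: np.ndarray, genes: np.ndarray, metric: str
) -> np.ndarray:
    genes = np.asarray(genes, dtype=np.intp)
    sa, sb = a[:, genes], b[:, genes]
    if metric == "euclidean":
        return cdist(sa, sb, "euclidean")
    if metric == "manhattan":
        return cdist(sa, sb, "cityblock")
    if metric == "wasserstein":
        return cdist(np.sort(sa, axis=1), np.sort(sb, axis=1), "cityblock") / genes.size
    raise ValueError(f"unknown metric {metric!r}")


def compute_eta(d: np.ndarray) -> float:
    """Average minimal distance: eta = (1/M) sum_m min_{j != m} d_mj.

    The self term is excluded from each minimum — otherwise every minimum is
    zero and the kernel scale collapses.
    """
    d = np.asarray(d, dtype=np.float64)
    m = d.shape[0]
    if m < 2:
        raise ValueError("eta needs at least 2 cells")
    masked = d + np.diag(np.full(m, np.inf))
    return float(masked.min(axis=1).mean())


def compute_rc(d: np.ndarray) -> float:
    """Cutoff distance: 3 × population standard deviation of the pairwise
    (upper-triangle) distances."""
    d = np.asarray(d, dtype=np.float64)
    m = d.shape[0]
    if m < 2:
        raise ValueError("r_c needs at least 2 cells")
    pairs = d[np.triu_indices(m, k=1)]
    return float(3.0 * pairs.std(ddof=0))


def kernel(dist: float | np.ndarray, scale: ClusterScale) -> float | np.ndarray:
    """Generalized exponential kernel Phi(d) in [0, 1].

    Phi(0) = 1 always (the zero-distance limit takes precedence even when
    r_c = 0, so identical cells stay maximally correlated); Phi(d) = 0 for
    d >= r_c; in between Phi(d) = exp(-(d / (eta * tau))**kappa).
    """
    d = np.asarray(dist, dtype=np.float64)
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    eta = scale.eta
    if eta * scale.tau == 0:
        raise ValueError(
            "degenerate scale eta*tau = 0 (all reference cells identical); "
            f"substitute eta = {DEGENERATE_ETA}"
        )
    with np.errstate(over="ignore"):
        phi = np.exp(-((d / (eta * scale.tau)) ** scale.kappa))
    phi = np.where(d < scale.r_c, phi, 0.0)
    phi = np.where(d == 0, 1.0, phi)
    if np.isscalar(dist):
        return float(phi)
    return phi


def estimate_scale(
    reference: np.ndarray,
    genes: np.ndarray,
    tau: float,
    kappa: float,
    metric: str = "euclidean",
) -> ClusterScale:
    """Estimate (eta, r_c) for one gene cluster from the reference cells."""
    d = pairwise_cell_distances(reference, genes, metric)
    eta = compute_eta(d)
    if eta == 0.0:
        warnings.warn(
            "all reference cells coincide on a gene cluster; "
            f"substituting eta = {DEGENERATE_ETA}"
        )
        eta = DEGENERATE_ETA
    return ClusterScale(eta=eta, r_c=compute_rc(d), tau=tau, kappa=kappa, metric=metric)


def project_cluster(
    x: np.ndarray | ExpressionMatrix,
    genes: np.ndarray,
    scale: ClusterScale,
    reference: np.ndarray | None = None,
) -> np.ndarray:
    """Super-gene values for one cluster: per-cell kernel sum over the
    reference cells (weights 1).  When ``reference`` is omitted the input is
    its own reference, so each cell's self term contributes Phi(0) = 1."""
    if isinstance(x, ExpressionMatrix):
        x = x.values
    genes = np.asarray(genes, dtype=np.intp)
    if genes.size == 0:
        raise ValueError("empty gene set")
    ref = x if reference is None else reference
    if genes.max() >= ref.shape[1]:
        raise ValueError("gene index outside the reference matrix")
    d = _cross_distances(x, ref, genes, scale.metric)
    return kernel(d, scale).sum(axis=1)


def fit_ccp(
    x: ExpressionMatrix,
    n_clusters: int = 300,
    v_c: float = 0.8,
    tau: float = 6.0,
    kappa: float = 2.0,
    metric: str = "euclidean",
    method: str = "kmedoids",
    distance: str = "correlation",
    seed: int = 0,
    require_log_stage: bool = True,
) -> tuple[CCPModel, SuperGeneMatrix]:
    """Fit the full CCP reduction on a log-normalized matrix.

    Selects the LV set, partitions the remaining genes, estimates per-cluster
    kernel scales from ``x`` itself, and computes all super-genes with ``x``
    as its own reference.  Column order is cluster 1..N then "LV".
    Deterministic given ``seed``.
    """
    if require_log_stage and x.stage != "log_normalized":
        raise ValueError(
            f"fit_ccp expects a log-normalized matrix, got stage {x.stage!r}; "
            "pass require_log_stage=False to override"
        )
    part = partition_genes(
        x, n_clusters=n_clusters, method=method, distance=distance, seed=seed, v_c=v_c
    )
    scales = [estimate_scale(x.values, c, tau, kappa, metric) for c in part.clusters]
    lv_scale = (
        estimate_scale(x.values, part.lv_set, tau, kappa, metric)
        if part.lv_set.size
        else None
    )
    model = CCPModel(
        partition=part,
        scales=scales,
        lv_scale=lv_scale,
        reference=x.values.copy(),
        gene_ids=list(x.gene_ids),
        cell_ids=list(x.cell_ids),
    )
    return model, embed_new(model, x)


def embed_new(model: CCPModel, y: ExpressionMatrix) -> SuperGeneMatrix:
    """Embed cells into a fitted model's super-gene space.

    Kernel sums run against the model's stored reference cells with the
    stored eta, r_c, tau, kappa — no scale is re-estimated, so embedding the
    training matrix itself reproduces the fit output exactly.  ``y`` must
    carry every gene the model uses (matched by gene id, any column order).
    """
    index = {g: i for i, g in enumerate(y.gene_ids)}
    missing = [g for g in model.gene_ids if g not in index]
    if missing:
        raise ValueError(
            f"{len(missing)} gene(s) required by the model are missing: {missing[:10]}"
        )
    cols = np.array([index[g] for g in model.gene_ids], dtype=np.intp)
    yv = np.ascontiguousarray(y.values[:, cols])
    out = np.empty((y.n_cells, len(model.column_labels)), dtype=np.float64)
    for n, (genes, scale) in enumerate(zip(model.partition.clusters, model.scales)):
        out[:, n] = project_cluster(yv, genes, scale, reference=model.reference)
    if model.lv_scale is not None:
        out[:, -1] = project_cluster(
            yv, model.partition.lv_set, model.lv_scale, reference=model.reference
        )
    return SuperGeneMatrix(out, list(y.cell_ids), model.column_labels)


def save_model(model: CCPModel, path: str | Path) -> Path:
    """Serialize a fitted model to a single zip archive (partition JSON,
    scales JSON, reference matrix in Matrix Market)."""
    path = Path(path)
    scales_payload = {
        "scales": [vars(s) for s in model.scales],
        "lv_scale": vars(model.lv_scale) if model.lv_scale else None,
        "cell_ids": model.cell_ids,
        "gene_ids": model.gene_ids,
    }
    buf = _stdio.BytesIO()
    scipy.io.mmwrite(buf, scipy.sparse.coo_matrix(model.reference))
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as z:
        z.writestr("partition.json", model.partition.to_json(model.gene_ids))
        z.writestr("scales.json", json.dumps(scales_payload, indent=1))
        z.writestr("reference.mtx", buf.getvalue())
    return path


def load_model(path: str | Path) -> CCPModel:
    with zipfile.ZipFile(path) as z:
        scales_payload = json.loads(z.read("scales.json"))
        gene_ids = scales_payload["gene_ids"]
        part = GenePartition.from_json(z.read("partition.json").decode(), gene_ids)
        ref = scipy.io.mmread(_stdio.BytesIO(z.read("reference.mtx")))
    if scipy.sparse.issparse(ref):
        ref = np.asarray(ref.todense())
    return CCPModel(
        partition=part,
        scales=[ClusterScale(**s) for s in scales_payload["scales"]],
        lv_scale=(
            ClusterScale(**scales_payload["lv_scale"])
            if scales_payload["lv_scale"]
            else None
        ),
        reference=np.asarray(ref, dtype=np.float64),
        gene_ids=gene_ids,
        cell_ids=scales_payload["cell_ids"],
    )
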