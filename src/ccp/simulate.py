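"""Seeded synthetic scRNA-seq counts with known cell-type structure.

The generator emulates the structure the CCP reduction relies on, at desk
scale: ``k`` cell populations of unequal size, a minority of informative
genes organized into disjoint correlated modules with cluster-specific mean
shifts (so there is gene–gene correlation for the partitioning step to find),
a large majority of near-constant noise genes sharing one low global mean
(the low-variance set), negative-binomial counts, and multiplicative
dropout.  Everything is reproducible from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import ClusterLabels
from .io import ExpressionMatrix

__all__ = ["SyntheticDataset", "generate_synthetic", "worked_example_fixture"]


@dataclass
class SyntheticDataset:
    """A generated raw-count matrix with its ground-truth cell labels and the
    generator parameters that produced it."""

    x: ExpressionMatrix
    labels: ClusterLabels
    params: dict = field(default_factory=dict)


def _cluster_sizes(m: int, proportions: np.ndarray) -> np.ndarray:
    # largest-remainder rounding so sizes sum exactly to m
    raw = proportions * m
    sizes = np.floor(raw).astype(int)
    remainder = m - sizes.sum()
    order = np.argsort(-(raw - sizes), kind="stable")
    sizes[order[:remainder]] += 1
    if (sizes == 0).any():
        raise ValueError("a cluster proportion is too small for the cell count")
    return sizes


def generate_synthetic(
    M: int = 500,
    I: int = 2000,
    k: int = 3,
    fraction_informative: float = 0.1,
    dropout_rate: float = 0.3,
    cluster_proportions=None,
    module_count: int = 10,
    nb_mean: float = 8.0,
    nb_dispersion: float = 2.0,
    noise_mean: float = 1.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a cells × genes raw-count matrix with planted populations.

    Parameters
    ----------
    M, I, k
        Cells, genes, and cell populations.
    fraction_informative
        Fraction of genes carrying population signal; the informative genes
        are split into ``module_count`` disjoint co-expressed modules, each
        strongly expressed in one population (4× the base mean) and damped
        (0.25×) elsewhere, with a shared per-cell activity factor that makes
        genes of one module correlated beyond the population structure.
    dropout_rate
        Probability that an entry is zeroed (multiplicative dropout).
    cluster_proportions
        Population proportions summing to 1; defaults to an unequal
        0.6/0.3/0.1-style split to mimic real cell-type imbalance.
    nb_mean, nb_dispersion
        Base negative-binomial mean of informative genes and the NB shape
        parameter theta (variance = mu + mu^2/theta).
    noise_mean
        Shared low mean of all non-informative genes.  Kept at a realistic
        background level (about one count) rather than near zero: background
        genes must carry genuine technical variance for the full gene space
        to behave like real data, where the accumulated noise of thousands
        of uninformative genes degrades distance-based embeddings.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 <= dropout_rate < 1.0:
        raise ValueError("dropout_rate must be in [0, 1)")
    if not 0.0 < fraction_informative <= 1.0:
        raise ValueError("fraction_informative must be in (0, 1]")
    if cluster_proportions is None:
        props = np.array([2.0 ** (-c) for c in range(k)])
        proportions = props / props.sum()
    else:
        proportions = np.asarray(cluster_proportions, dtype=np.float64)
        if proportions.size != k:
            raise ValueError(f"{proportions.size} proportions for k={k} clusters")
        if (proportions <= 0).any() or abs(proportions.sum() - 1.0) > 1e-8:
            raise ValueError("cluster proportions must be positive and sum to 1")
    rng = np.random.default_rng(seed)
    sizes = _cluster_sizes(M, proportions)
    labels = rng.permutation(np.repeat(np.arange(k), sizes))

    n_inf = max(int(round(I * fraction_informative)), 1)
    module_count = min(module_count, n_inf)
    module_of_gene = np.sort(np.arange(n_inf) % module_count)
    active_cluster = np.arange(module_count) % k  # every population owns modules

    mu = np.empty((M, I), dtype=np.float64)
    # module activity: one gamma factor per (cell, module) shared by the
    # module's genes -> within-module gene-gene correlation
    activity = rng.gamma(shape=4.0, scale=0.25, size=(M, module_count))
    fold = np.where(
        active_cluster[None, :] == labels[:, None], 4.0, 0.25
    )  # (M, module_count)
    cell_module_mean = nb_mean * fold * activity
    mu[:, :n_inf] = cell_module_mean[:, module_of_gene]
    mu[:, n_inf:] = noise_mean

    p = nb_dispersion / (nb_dispersion + mu)
    counts = rng.negative_binomial(nb_dispersion, p).astype(np.float64)
    if dropout_rate > 0:
        counts *= rng.random(counts.shape) >= dropout_rate

    gene_perm = rng.permutation(I)  # informative genes not identifiable by index
    counts = counts[:, gene_perm]
    informative = np.flatnonzero(np.isin(gene_perm, np.arange(n_inf)))

    x = ExpressionMatrix(counts, stage="raw")
    params = {
        "M": M,
        "I": I,
        "k": k,
        "fraction_informative": fraction_informative,
        "module_count": module_count,
        "dropout_rate": dropout_rate,
        "cluster_proportions": proportions.tolist(),
        "nb_mean": nb_mean,
        "nb_dispersion": nb_dispersion,
        "noise_mean": noise_mean,
        "seed": seed,
        "informative_gene_indices": informative.tolist(),
    }
    return SyntheticDataset(x=x, labels=ClusterLabels.from_raw(labels), params=params)


def worked_example_fixture() -> ExpressionMatrix:
    """The tiny hand-checkable fixture: 3 cells whose single informative gene
    takes values 0, 1, 3, padded with two constant genes.

    With a one-gene cluster the cell distances are {1, 2, 3}, giving
    eta = 4/3 (average nearest-neighbor distance) and r_c = 3 * sqrt(2/3);
    under tau = 1, kappa = 2 the super-gene is approximately
    (1.5698, 1.6752, 1.1054).  Returned at stage ``log_normalized`` so it can
    feed the projection directly.
    """
    values = np.array(
        [
            [0.0, 1.0, 1.0],
            [1.0, 1.0, 1.0],
            [3.0, 1.0, 1.0],
        ]
    )
    return ExpressionMatrix(
        values,
        cell_ids=["cell_a", "cell_b", "cell_c"],
        gene_ids=["gene_signal", "gene_pad1", "gene_pad2"],
        stage="log_normalized",
    )
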