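"""End-to-end orchestration: preprocess → reduce → visualize → evaluate.

Each run writes its artifacts (model archive, super-gene CSV, coordinate
CSVs, figures, metrics) plus a ``manifest.json`` recording every parameter
and seed, so a run can be re-executed bit-for-bit.  Large inputs can be
fitted on a random subsample of cells, with the remaining cells embedded
out-of-sample against the fitted reference.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, visualize
from .evaluation import ClusterLabels, leiden_cluster, score_clustering
from .io import (
    ExpressionMatrix,
    drop_zero_cells,
    drop_zero_genes,
    log1p_transform,
    normalize_counts,
    read_expression,
    write_matrix_csv,
)
from .projection import CCPModel, SuperGeneMatrix, embed_new, fit_ccp, load_model, save_model

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_fit", "run_visualize", "run_evaluate", "preprocess"]


@dataclass
class RunConfig:
    """Parameters of one pipeline run.  Defaults are the benchmark settings:
    300 super-genes, cutoff ratio 0.8, tau = 6, kappa = 2, Leiden clustering,
    10 seeds."""

    input: str = ""
    format: str = "auto"
    outdir: str = "ccp_run"
    n_supergenes: int = 300
    v_c: float = 0.8
    tau: float = 6.0
    kappa: float = 2.0
    metric: str = "euclidean"
    method: str = "kmedoids"
    distance: str = "correlation"
    subsample_size: int | None = None
    seeds: list[int] = field(default_factory=lambda: list(range(10)))
    embedders: list[str] = field(default_factory=lambda: ["umap", "tsne"])
    labels: str | None = None
    leiden_resolution: float = 1.0
    leiden_neighbors: int = 15
    umap_neighbors: int = 15
    umap_min_dist: float = 0.5
    tsne_perplexity: float = 30.0
    drop_zero_genes: bool = False

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ValueError("at least one seed is required")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            payload = yaml.safe_load(path.read_text())
        elif path.suffix == ".toml":
            import tomllib

            payload = tomllib.loads(path.read_text())
        else:
            raise ValueError(f"config must be YAML or TOML, got {path.suffix!r}")
        return cls(**payload)


def _setup_run(config: RunConfig) -> Path:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("ccp")
    if not any(isinstance(h, logging.FileHandler) for h in root.handlers):
        root.addHandler(handler)
    return outdir


def _write_manifest(outdir: Path, config: RunConfig, extra: dict) -> None:
    payload = {"config": dataclasses.asdict(config), **extra}
    (outdir / "manifest.json").write_text(json.dumps(payload, indent=1))


def preprocess(x: ExpressionMatrix, drop_genes: bool = False) -> ExpressionMatrix:
    """Raw counts → depth-normalized → log1p, dropping all-zero cells."""
    x = drop_zero_cells(x)
    if drop_genes:
        x = drop_zero_genes(x)
    return log1p_transform(normalize_counts(x))


def run_fit(config: RunConfig, x: ExpressionMatrix | None = None):
    """Fit the CCP reduction and write model + super-gene artifacts.

    When ``subsample_size`` is set and the data exceed it, the model is
    fitted on a seeded uniform subsample (without replacement) and every
    remaining cell is embedded out-of-sample; the super-gene matrix always
    covers all cells in input order.
    """
    outdir = _setup_run(config)
    t0 = time.time()
    if x is None:
        x = read_expression(config.input, config.format)
    logger.info("loaded %d cells x %d genes (stage=%s)", x.n_cells, x.n_genes, x.stage)
    if x.stage == "raw":
        x = preprocess(x, drop_genes=config.drop_zero_genes)
    seed = config.seeds[0]
    subsampled = bool(config.subsample_size) and x.n_cells > int(config.subsample_size)
    if subsampled:
        rng = np.random.default_rng(seed)
        train_idx = np.sort(
            rng.choice(x.n_cells, size=int(config.subsample_size), replace=False)
        )
        train = ExpressionMatrix(
            x.values[train_idx],
            [x.cell_ids[i] for i in train_idx],
            list(x.gene_ids),
            x.stage,
        )
        logger.info("fitting on subsample of %d / %d cells", train.n_cells, x.n_cells)
    else:
        train = x
    model, _ = fit_ccp(
        train,
        n_clusters=config.n_supergenes,
        v_c=config.v_c,
        tau=config.tau,
        kappa=config.kappa,
        metric=config.metric,
        method=config.method,
        distance=config.distance,
        seed=seed,
    )
    sg = embed_new(model, x)  # all cells, training ones included, input order
    save_model(model, outdir / "model.zip")
    sg.to_csv(outdir / "supergenes.csv")
    _write_manifest(
        outdir,
        config,
        {
            "stage": "fit",
            "n_cells": x.n_cells,
            "n_genes": x.n_genes,
            "n_supergene_columns": len(sg.column_labels),
            "subsampled": subsampled,
            "fit_seed": seed,
            "elapsed_s": round(time.time() - t0, 2),
        },
    )
    logger.info("fit complete: %d super-gene columns", len(sg.column_labels))
    return model, sg


def _load_labels(path: str | Path) -> ClusterLabels:
    df = pd.read_csv(path)
    col = df.columns[-1]  # single column, or (cell_id, label)
    return ClusterLabels.from_raw(df[col].tolist())


def _embed(kind: str, data, config: RunConfig, seed: int) -> visualize.Embedding2D:
    if kind == "umap":
        return visualize.assist_umap(
            data, n_neighbors=config.umap_neighbors, min_dist=config.umap_min_dist, seed=seed
        )
    if kind == "tsne":
        values = data.values if hasattr(data, "values") else data
        perplexity = min(config.tsne_perplexity, max((values.shape[0] - 2) / 3.0, 2.0))
        return visualize.assist_tsne(data, perplexity=perplexity, seed=seed)
    raise ValueError(f"unknown embedder {kind!r}")


def run_visualize(config: RunConfig, x: ExpressionMatrix | None = None):
    """Produce CCP-assisted and raw 2-D embeddings, coordinates, figures."""
    outdir = _setup_run(config)
    model_path = outdir / "model.zip"
    sg_path = outdir / "supergenes.csv"
    if not (model_path.exists() and sg_path.exists()):
        raise FileNotFoundError(
            f"no fitted artifacts in {outdir}; run the fit step first"
        )
    sg_df = pd.read_csv(sg_path, index_col=0)
    sg = SuperGeneMatrix(
        sg_df.to_numpy(), sg_df.index.astype(str).tolist(), list(sg_df.columns)
    )
    if x is None:
        x = read_expression(config.input, config.format)
    if x.stage == "raw":
        x = preprocess(x, drop_genes=config.drop_zero_genes)
    labels = _load_labels(config.labels) if config.labels else None
    seed = config.seeds[0]
    outputs = {}
    for kind in config.embedders:
        for name, data in (("ccp", sg), ("raw", x)):
            e = _embed(kind, data, config, seed)
            stem = f"{name}-{kind}"
            write_matrix_csv(e.coords, sg.cell_ids, ["dim1", "dim2"], outdir / f"{stem}.csv")
            visualize.plot_embedding(e, labels, outdir / f"{stem}.png")
            outputs[stem] = e
    logger.info("wrote %d embeddings to %s", len(outputs), outdir)
    return outputs


def run_evaluate(config: RunConfig, x: ExpressionMatrix | None = None,
                 true_labels: ClusterLabels | None = None) -> pd.DataFrame:
    """Score every representation against reference labels over all seeds.

    For each seed: fit CCP, then Leiden-cluster the super-genes and each
    requested 2-D embedding (CCP-assisted and raw) and record ARI/NMI/ECM.
    Writes per-seed rows and per-representation means.
    """
    outdir = _setup_run(config)
    if x is None:
        x = read_expression(config.input, config.format)
    if x.stage == "raw":
        x = preprocess(x, drop_genes=config.drop_zero_genes)
    if true_labels is None:
        if not config.labels:
            raise ValueError("evaluation requires reference labels")
        true_labels = _load_labels(config.labels)
    if len(true_labels) != x.n_cells:
        raise ValueError(
            f"{len(true_labels)} labels for {x.n_cells} cells"
        )
    rows = []
    for seed in config.seeds:
        _, sg = fit_ccp(
            x,
            n_clusters=config.n_supergenes,
            v_c=config.v_c,
            tau=config.tau,
            kappa=config.kappa,
            metric=config.metric,
            method=config.method,
            distance=config.distance,
            seed=seed,
        )
        representations: dict[str, object] = {"supergenes": sg}
        for kind in config.embedders:
            representations[f"ccp-{kind}"] = _embed(kind, sg, config, seed).coords
            representations[f"raw-{kind}"] = _embed(kind, x, config, seed).coords
        for name, rep in representations.items():
            pred = leiden_cluster(
                rep,
                n_neighbors=config.leiden_neighbors,
                seed=seed,
                target_clusters=true_labels.n_clusters,
            )
            report = score_clustering(pred, true_labels)
            rows.append(
                {
                    "representation": name,
                    "seed": seed,
                    "ari": report.ari,
                    "nmi": report.nmi,
                    "ecm": report.ecm,
                    "n_clusters_pred": report.n_clusters_pred,
                }
            )
        logger.info("evaluated seed %d", seed)
    df = pd.DataFrame(rows)
    means = df.groupby("representation", as_index=False)[["ari", "nmi", "ecm"]].mean()
    df.to_csv(outdir / "metrics_per_seed.csv", index=False)
    means.to_csv(outdir / "metrics_mean.csv", index=False)
    (outdir / "metrics.json").write_text(
        json.dumps(
            {
                "per_seed": df.to_dict(orient="records"),
                "means": means.to_dict(orient="records"),
            },
            indent=1,
        )
    )
    _write_manifest(outdir, config, {"stage": "evaluate", "n_cells": x.n_cells})
    return df
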