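"""Matrix pre-processing, 2D embeddings and graph clustering via scanpy.

The pre-processing pipeline filters cells with fewer than
``min_genes_per_cell`` detected genes and genes detected in fewer than
``min_cells_per_gene`` cells, then applies -- each gated by its flag, in
this order -- total-count normalization (target = median cell total),
log(1+x), restriction to the most variable genes, and unit-variance
scaling.

Embeddings (UMAP, t-SNE) and clusterings (Leiden, Louvain) expose the
handful of parameters that matter: UMAP's number of neighbors and minimum
distance; t-SNE's perplexity, initial dimensions (-1 triggers PCA
pre-reduction), early exaggeration and learning rate; and, for Leiden and
Louvain, the number of neighbors of the kNN graph.  Every stochastic step
takes a seed and is reproducible under it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp

from .errors import ParameterError
from .matrix_io import CategoryRow, ExpressionExperiment

__all__ = [
    "PreprocessConfig",
    "PreprocessReport",
    "EmbedClusterParams",
    "CellEmbedding",
    "preprocess",
    "embed",
    "cluster",
    "clustering_to_category_row",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Pre-processing stage flags and filter thresholds (defaults on)."""

    normalize: bool = True
    log_transform: bool = True
    restrict_hvg: bool = True
    scale: bool = True
    min_genes_per_cell: int = 100
    min_cells_per_gene: int = 1
    n_top_genes: int = 2000  # HVG count; the restriction method's one knob


@dataclass
class PreprocessReport:
    """What the pipeline removed and which stages ran."""

    removed_cells: list[str]
    removed_genes: list[str]
    stages: list[str]


@dataclass(frozen=True)
class EmbedClusterParams:
    """Exposed embedding/clustering parameters.

    ``tsne_init_dims=-1`` requests PCA pre-reduction before t-SNE.
    """

    umap_n_neighbors: int = 15
    umap_min_dist: float = 0.5
    tsne_perplexity: float = 30.0
    tsne_init_dims: int = -1
    tsne_early_exaggeration: float = 12.0
    tsne_learning_rate: float = 1000.0
    cluster_n_neighbors: int = 15
    seed: int = 0


@dataclass
class CellEmbedding:
    """2D coordinates per retained cell, with provenance."""

    coords: pd.DataFrame  # columns: cell_id, x, y
    method: str  # "UMAP" or "tSNE"
    params: EmbedClusterParams
    stages: list[str] = field(default_factory=list)


def to_anndata(exp: ExpressionExperiment) -> ad.AnnData:
    """Cells x genes AnnData view of an experiment (AnnData convention)."""
    adata = ad.AnnData(X=sp.csr_matrix(exp.matrix.T))
    adata.obs_names = list(exp.cell_ids)
    adata.var_names = list(exp.gene_ids)
    return adata


def preprocess(
    exp: ExpressionExperiment, config: PreprocessConfig | None = None
) -> tuple[ExpressionExperiment, PreprocessReport]:
    """Filter and transform an experiment; returns (experiment, report).

    Filtering is cells-then-genes; a cell "detects" a gene when its value
    is > 0.  Raises :class:`ParameterError` when every cell is filtered
    out.  The returned experiment is marked ``transformed`` once any
    transform stage has run (scaled data contains negatives).
    """
    config = config or PreprocessConfig()
    if exp.matrix.nnz == 0 and config.min_genes_per_cell > 0:
        raise ParameterError("matrix is all-zero; every cell would be removed")
    adata = to_anndata(exp)
    stages: list[str] = []

    detected = np.asarray((adata.X > 0).sum(axis=1)).ravel()
    keep_cells = detected >= config.min_genes_per_cell
    removed_cells = [c for c, k in zip(exp.cell_ids, keep_cells) if not k]
    if not keep_cells.any():
        raise ParameterError(
            f"all {exp.n_cells} cells have fewer than "
            f"{config.min_genes_per_cell} detected genes"
        )
    adata = adata[keep_cells].copy()
    stages.append("filter_cells")

    expressing = np.asarray((adata.X > 0).sum(axis=0)).ravel()
    keep_genes = expressing >= config.min_cells_per_gene
    removed_genes = [g for g, k in zip(exp.gene_ids, keep_genes) if not k]
    adata = adata[:, keep_genes].copy()
    stages.append("filter_genes")

    if config.normalize:
        sc.pp.normalize_total(adata)  # scanpy default target: median total
        stages.append("normalize")
    if config.log_transform:
        sc.pp.log1p(adata)
        stages.append("log1p")
    if config.restrict_hvg and adata.n_vars > config.n_top_genes:
        sc.pp.highly_variable_genes(adata, n_top_genes=config.n_top_genes)
        adata = adata[:, adata.var["highly_variable"]].copy()
        stages.append("hvg")
    if config.scale:
        sc.pp.scale(adata)
        stages.append("scale")

    transformed = any(s in stages for s in ("normalize", "log1p", "scale"))
    matrix = adata.X
    if not sp.issparse(matrix):
        matrix = sp.csr_matrix(matrix)
    out = ExpressionExperiment(
        matrix=matrix.T.tocsr(),
        gene_ids=list(adata.var_names),
        cell_ids=list(adata.obs_names),
        species=exp.species,
        accession=exp.accession,
        source=exp.source,
        transformed=transformed,
    )
    out.categories = dict(exp.categories)
    return out, PreprocessReport(removed_cells, removed_genes, stages)


def _check_cells(n_cells: int, needed: float, what: str) -> None:
    if n_cells <= needed:
        raise ParameterError(
            f"{what} requires more cells than available "
            f"({n_cells} cells, needs > {needed}); lower the parameter"
        )


def embed(
    exp: ExpressionExperiment,
    method: str,
    params: EmbedClusterParams | None = None,
) -> CellEmbedding:
    """UMAP or t-SNE embedding of a (preprocessed) experiment.

    Deterministic under ``params.seed``.  Raises
    :class:`ParameterError` when the cell count cannot support the
    requested perplexity / neighbor count.
    """
    params = params or EmbedClusterParams()
    method = method.upper().replace("-", "")
    if method not in {"UMAP", "TSNE"}:
        raise ValueError(f"unknown embedding method {method!r}")
    if exp.n_cells < 3:
        raise ParameterError("embedding needs at least 3 cells")
    adata = to_anndata(exp)
    stages: list[str] = []

    if method == "UMAP":
        _check_cells(exp.n_cells, params.umap_n_neighbors, "UMAP n_neighbors")
        sc.pp.neighbors(adata, n_neighbors=params.umap_n_neighbors,
                        random_state=params.seed)
        sc.tl.umap(adata, min_dist=params.umap_min_dist,
                   random_state=params.seed)
        coords = adata.obsm["X_umap"]
        stages += ["neighbors", "umap"]
        label = "UMAP"
    else:
        _check_cells(exp.n_cells, params.tsne_perplexity, "t-SNE perplexity")
        if params.tsne_init_dims == -1:
            n_pcs = int(min(50, adata.n_obs - 1, adata.n_vars - 1))
            stages.append("pca")
        elif params.tsne_init_dims > 0:
            n_pcs = int(min(params.tsne_init_dims, adata.n_obs - 1,
                            adata.n_vars - 1))
            stages.append("pca")
        else:
            n_pcs = 0
        sc.tl.tsne(
            adata,
            n_pcs=n_pcs,
            perplexity=params.tsne_perplexity,
            early_exaggeration=params.tsne_early_exaggeration,
            learning_rate=params.tsne_learning_rate,
            random_state=params.seed,
        )
        coords = adata.obsm["X_tsne"]
        stages.append("tsne")
        label = "tSNE"

    df = pd.DataFrame({
        "cell_id": list(adata.obs_names),
        "x": np.asarray(coords)[:, 0].astype(float),
        "y": np.asarray(coords)[:, 1].astype(float),
    })
    return CellEmbedding(coords=df, method=label, params=params, stages=stages)


def cluster(
    exp: ExpressionExperiment,
    algorithm: str,
    params: EmbedClusterParams | None = None,
) -> CategoryRow:
    """Leiden or Louvain community detection on the kNN graph.

    Builds the neighborhood graph on ``cluster_n_neighbors`` neighbors and
    packages the labels as a :class:`CategoryRow` (row_label = number of
    communities) attachable to the experiment.
    """
    params = params or EmbedClusterParams()
    algorithm = algorithm.lower()
    if algorithm not in {"leiden", "louvain"}:
        raise ValueError(f"unknown clustering algorithm {algorithm!r}")
    if exp.matrix.nnz == 0:
        raise ParameterError("cannot cluster an all-zero matrix")
    _check_cells(exp.n_cells, params.cluster_n_neighbors,
                 f"{algorithm} n_neighbors")
    adata = to_anndata(exp)
    sc.pp.neighbors(adata, n_neighbors=params.cluster_n_neighbors,
                    random_state=params.seed)
    if algorithm == "leiden":
        sc.tl.leiden(adata, random_state=params.seed, flavor="igraph",
                     n_iterations=2, directed=False)
        labels = adata.obs["leiden"]
    else:
        # scanpy's default Louvain backend (vtraag) is optional; the igraph
        # multilevel implementation is the supported backend here
        sc.tl.louvain(adata, random_state=params.seed, flavor="igraph")
        labels = adata.obs["louvain"]
    assignments = {c: str(l) for c, l in zip(adata.obs_names, labels)}
    k = len(set(assignments.values()))
    return CategoryRow(row_label=str(k), is_default=True, assignments=assignments)


def clustering_to_category_row(labels: dict[str, str]) -> CategoryRow:
    """Package an arbitrary cell -> label mapping as a CategoryRow."""
    k = len({v for v in labels.values() if v != "NA"})
    return CategoryRow(row_label=str(k), is_default=False, assignments=dict(labels))
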