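"""Synthetic single-cell experiments with planted structure.

The generator emulates the inputs the pipeline consumes -- a normalized
genes x cells matrix, a clusters-style category, and a STRING-style
interaction table -- with known ground truth: which genes are markers of
which group, and which interaction edges form planted modules.

Counts are drawn from a negative binomial (mean ``baseline_mean``,
dispersion ``dispersion``); each group's marker genes have their mean
multiplied by ``2**marker_log2fc`` in that group only.  Dropout zeroes
entries independently with probability ``dropout_rate``.  Counts are then
scaled per cell to the median cell total, mimicking library-size
normalization.  Everything is deterministic under ``seed``.

Interaction fixtures plant high-scoring edges (score ~ U(0.7, 1.0)) among
same-group markers and low-scoring background edges (score ~ U(0.15,
0.45)) elsewhere, so planted modules survive the default 0.4 combined-
score cutoff while background mostly does not.
"""

from __future__ import annotations

import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrix_io import (
    Category,
    CategoryRow,
    ExpressionExperiment,
    write_clusters_csv,
    write_mtx_triple,
)

__all__ = [
    "SyntheticSpec",
    "generate_experiment",
    "generate_interactions",
    "write_experiment",
    "write_interactions",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-marker experiment.

    Defaults describe a small but realistic study: 3 groups of 50 cells,
    300 genes of which 5 per group are markers at log2FC 2, negative
    binomial baseline mean 8 (normalized units) with dispersion 10, and
    30% dropout.
    """

    n_groups: int = 3
    cells_per_group: int = 50
    n_genes: int = 300
    markers_per_group: int = 5
    marker_log2fc: float = 2.0
    baseline_mean: float = 8.0
    dispersion: float = 10.0
    dropout_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ValueError("need at least 2 groups")
        if self.cells_per_group < 5:
            raise ValueError("need at least 5 cells per group")
        if self.markers_per_group * self.n_groups > self.n_genes:
            raise ValueError(
                "markers_per_group * n_groups must not exceed n_genes"
            )
        if self.marker_log2fc < 0:
            raise ValueError("marker_log2fc must be >= 0")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be > 0")


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i:04d}" for i in range(n)]


def generate_experiment(
    spec: SyntheticSpec, accession: str = "SYN-0001", species: str = "Homo sapiens"
) -> tuple[ExpressionExperiment, Category, pd.DataFrame]:
    """Generate (experiment, ground-truth category, marker ground truth).

    Marker gene g of group k occupies gene index ``k * markers_per_group +
    j``; the returned truth table has one (gene, group) row per planted
    marker.  Group labels are "1" .. str(n_groups), and the category's
    single row is flagged default with row_label = K.
    """
    rng = np.random.default_rng(spec.seed)
    n_cells = spec.n_groups * spec.cells_per_group
    labels = np.repeat(np.arange(spec.n_groups), spec.cells_per_group)

    mean = np.full((spec.n_genes, n_cells), float(spec.baseline_mean))
    truth_rows = []
    gene_ids = _gene_ids(spec.n_genes)
    for k in range(spec.n_groups):
        for j in range(spec.markers_per_group):
            gi = k * spec.markers_per_group + j
            mean[gi, labels == k] *= 2.0 ** spec.marker_log2fc
            truth_rows.append({"gene": gene_ids[gi], "group": str(k + 1)})
    truth = pd.DataFrame(truth_rows, columns=["gene", "group"])

    r = spec.dispersion
    p = r / (r + mean)
    counts = rng.negative_binomial(r, p).astype(float)
    if spec.dropout_rate > 0:
        counts[rng.random(counts.shape) < spec.dropout_rate] = 0.0

    totals = counts.sum(axis=0)
    target = np.median(totals[totals > 0]) if np.any(totals > 0) else 1.0
    scale = np.divide(target, totals, out=np.ones_like(totals), where=totals > 0)
    matrix = sp.csr_matrix(counts * scale)

    cell_ids = [f"CELL{i:04d}" for i in range(n_cells)]
    assignments = {cell_ids[i]: str(labels[i] + 1) for i in range(n_cells)}
    category = Category(
        name="Cluster",
        rows=[CategoryRow(row_label=str(spec.n_groups), is_default=True,
                          assignments=assignments)],
        selected_row=0,
    )
    exp = ExpressionExperiment(
        matrix=matrix,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        species=species,
        accession=accession,
        source="file",
    )
    exp.categories[category.name] = category
    return exp, category, truth


def generate_interactions(
    truth: pd.DataFrame,
    within_module_prob: float = 0.9,
    background_prob: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """STRING-style edge fixture with planted same-group modules.

    Returns (edges, alias, planted_edges): ``edges`` has columns protein1/
    protein2/score in [0, 1]; ``alias`` maps each marker gene to protein id
    ``P_<gene>``; ``planted_edges`` lists the high-confidence module edges
    for ground-truth bookkeeping.  Same-group marker pairs get an edge with
    probability ``within_module_prob`` and score ~ U(0.7, 1.0); all other
    marker pairs with probability ``background_prob`` and score ~ U(0.15,
    0.45), below the default 0.4 cutoff most of the time.
    """
    if not 0 <= within_module_prob <= 1 or not 0 <= background_prob <= 1:
        raise ValueError("edge probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = list(truth["gene"])
    group_of = dict(zip(truth["gene"], truth["group"]))
    alias = pd.DataFrame({"gene": genes, "protein": [f"P_{g}" for g in genes]})

    edge_rows, planted_rows = [], []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a, b = genes[i], genes[j]
            same = group_of[a] == group_of[b]
            if same and rng.random() < within_module_prob:
                score = rng.uniform(0.7, 1.0)
                edge_rows.append((f"P_{a}", f"P_{b}", score))
                planted_rows.append((f"P_{a}", f"P_{b}", score))
            elif not same and rng.random() < background_prob:
                edge_rows.append((f"P_{a}", f"P_{b}", rng.uniform(0.15, 0.45)))
    cols = ["protein1", "protein2", "score"]
    return (
        pd.DataFrame(edge_rows, columns=cols),
        alias,
        pd.DataFrame(planted_rows, columns=cols),
    )


def write_experiment(
    exp: ExpressionExperiment,
    category: Category,
    directory: str | Path,
    archive: bool = True,
) -> dict[str, Path]:
    """Emit the experiment in the GXA on-disk layout.

    Writes the MatrixMarket triple (zipped when ``archive``) plus the
    clusters CSV in the GXA dialect; the result reads back identically via
    :func:`scnetkit.matrix_io.read_mtx_triple` / ``read_category_csv``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = exp.accession or "experiment"
    triple = write_mtx_triple(exp, directory, stem=stem)
    paths: dict[str, Path] = {}
    if archive:
        zip_path = directory / f"{stem}.zip"
        with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as zf:
            for p in triple:
                zf.write(p, arcname=p.name)
        for p in triple:
            p.unlink()
        paths["matrix"] = zip_path
    else:
        paths["matrix"] = directory
    clusters = directory / f"{stem}.clusters.csv"
    write_clusters_csv(category, clusters, cell_ids=exp.cell_ids)
    paths["clusters"] = clusters
    return paths


def write_interactions(
    edges: pd.DataFrame, alias: pd.DataFrame, directory: str | Path,
    stem: str = "interactions",
) -> dict[str, Path]:
    """Write the edge and alias fixtures as STRING-style TSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    edge_path = directory / f"{stem}.links.tsv"
    edges.rename(columns={"score": "combined_score"}).to_csv(
        edge_path, sep="\t", index=False
    )
    alias_path = directory / f"{stem}.aliases.tsv"
    alias.to_csv(alias_path, sep="\t", index=False, header=False)
    return {"edges": edge_path, "alias": alias_path}
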