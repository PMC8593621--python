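"""Plot-ready tables (and optional static rendering) for the three plot
families: cell plots (embedding colored by group), per-gene violin data
across groups, and the top-marker-genes heatmap.

The tested surface is the tables -- pure, deterministic views of their
inputs; PNG rendering is a thin matplotlib layer for convenience.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexp import DiffExpTable
from .errors import ParameterError
from .marker_network import MarkerSelection
from .matrix_io import CategoryRow, ExpressionExperiment
from .preprocess_embed import CellEmbedding

__all__ = [
    "PlotTable",
    "cell_plot_table",
    "violin_table",
    "heatmap_matrix",
    "volcano_table",
    "render_cell_plot",
    "render_violin",
    "render_heatmap",
]


@dataclass
class PlotTable:
    """Long-format plot data plus axis labels and provenance."""

    data: pd.DataFrame
    x_label: str
    y_label: str
    title: str
    accession: str = ""
    meta: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.data.to_csv(path, index=False)
        return path


def cell_plot_table(embedding: CellEmbedding, row: CategoryRow,
                    accession: str = "") -> PlotTable:
    """One record per cell: x, y, group label.

    Cells present in only one of embedding/row are dropped; the dropped
    count is recorded in ``meta["n_dropped"]``.  An empty intersection is
    an error.
    """
    records = []
    dropped = 0
    for cell, x, y in embedding.coords.itertuples(index=False):
        label = row.assignments.get(cell)
        if label is None:
            dropped += 1
            continue
        records.append({"cell_id": cell, "x": x, "y": y, "group": label})
    dropped += sum(1 for c in row.assignments if c not in set(embedding.coords["cell_id"]))
    if not records:
        raise ParameterError("embedding and category row share no cells")
    return PlotTable(
        data=pd.DataFrame(records),
        x_label=f"{embedding.method} 1",
        y_label=f"{embedding.method} 2",
        title=f"{embedding.method} cell plot",
        accession=accession,
        meta={"n_dropped": dropped, "method": embedding.method},
    )


def violin_table(exp: ExpressionExperiment, gene: str, row: CategoryRow,
                 jitter: float = 0.0) -> PlotTable:
    """Expression of one gene per cell, labeled by group.

    ``jitter`` is recorded as rendering metadata only.  Unknown genes
    raise with the closest matching identifiers listed.
    """
    if not 0 <= jitter <= 1:
        raise ValueError("jitter must lie in [0, 1]")
    index = exp.gene_index()
    if gene not in index:
        by_lower = {g.lower(): g for g in exp.gene_ids}
        close = [by_lower[m] for m in difflib.get_close_matches(
            gene.lower(), list(by_lower), n=3)]
        hint = f"; did you mean {', '.join(close)}?" if close else ""
        raise KeyError(f"gene {gene!r} not in experiment{hint}")
    values = np.asarray(exp.matrix[index[gene], :].todense()).ravel()
    records = [
        {"cell_id": c, "value": float(v), "group": row.assignments.get(c, "NA")}
        for c, v in zip(exp.cell_ids, values)
    ]
    return PlotTable(
        data=pd.DataFrame(records),
        x_label="group",
        y_label="expression",
        title=f"{gene} expression by group",
        accession=exp.accession,
        meta={"gene": gene, "jitter": jitter},
    )


def heatmap_matrix(table: DiffExpTable, markers: MarkerSelection,
                   exp: ExpressionExperiment | None = None) -> pd.DataFrame:
    """Mean in-group expression of the selected genes, genes x groups.

    Rows are the union of all groups' markers in group-blocked order
    (deduplicated at first appearance); values are the DE table's
    ``mean_in``.  ``exp`` is accepted for interface symmetry with the
    other plot builders; the means come from the table.
    """
    genes = markers.all_genes()
    if not genes:
        raise ParameterError("no marker genes selected for any group")
    mean_in = table.data.pivot_table(index="gene", columns="group",
                                     values="mean_in", aggfunc="first")
    out = mean_in.reindex(index=genes, columns=table.groups)
    out.index.name = "gene"
    out.columns.name = "group"
    return out


def volcano_table(table: DiffExpTable, group: str) -> PlotTable:
    """Volcano view of one group's DE records: x=log2FC, y=-log10 FDR."""
    df = table.for_group(group)
    if df.empty:
        raise ParameterError(f"group {group!r} not present in the DE table")
    data = pd.DataFrame({
        "gene": df["gene"],
        "log2fc": df["log2fc"],
        "neg_log10_fdr": -np.log10(df["fdr"]),
        "passed_filters": df["passed_filters"],
    })
    return PlotTable(
        data=data.reset_index(drop=True),
        x_label="log2 fold change",
        y_label="-log10 FDR",
        title=f"Volcano: group {group}",
        accession=table.accession,
        meta={"group": group},
    )


# ---------------------------------------------------------------------------
# Optional static rendering
# ---------------------------------------------------------------------------


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def render_cell_plot(table: PlotTable, path: str | Path) -> Path:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 5))
    for group, sub in table.data.groupby("group"):
        ax.scatter(sub["x"], sub["y"], s=12, label=str(group))
    ax.set_xlabel(table.x_label)
    ax.set_ylabel(table.y_label)
    ax.set_title(table.title)
    ax.legend(markerscale=1.5, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def render_violin(table: PlotTable, path: str | Path) -> Path:
    plt = _plt()
    groups = sorted(table.data["group"].unique())
    data = [table.data.loc[table.data["group"] == g, "value"] for g in groups]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(groups) + 1), groups)
    ax.set_xlabel(table.x_label)
    ax.set_ylabel(table.y_label)
    ax.set_title(table.title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def render_heatmap(matrix: pd.DataFrame, path: str | Path) -> Path:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, max(3, 0.25 * len(matrix))))
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=6)
    ax.set_xlabel("group")
    fig.colorbar(im, ax=ax, label="mean expression")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
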