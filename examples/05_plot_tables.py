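"""Plot-ready tables: cell plot, violin, heatmap and volcano views.

Each table is a pure, deterministic view of its inputs; rendering to PNG
is a thin optional layer on top.
"""

import tempfile
from pathlib import Path

import scnetkit as sk
from scnetkit import plots
from scnetkit import preprocess_embed as pe

exp, category, truth = sk.generate_experiment(sk.SyntheticSpec(seed=0))
table = sk.compute_diffexp(exp, category)
markers = sk.select_markers(table)
outdir = Path(tempfile.mkdtemp(prefix="scnetkit-example-"))

prepped, _ = pe.preprocess(exp, pe.PreprocessConfig(min_genes_per_cell=10))
embedding = pe.embed(prepped, "umap", pe.EmbedClusterParams(seed=0))
cells = plots.cell_plot_table(embedding, category.rows[0])
plots.render_cell_plot(cells, outdir / "cells.png")
print(f"cell plot: {len(cells.data)} cells across "
      f"{cells.data['group'].nunique()} groups -> {outdir / 'cells.png'}")

gene = truth.iloc[0]["gene"]
violin = plots.violin_table(exp, gene, category.rows[0])
medians = violin.data.groupby("group")["value"].median()
print(f"violin for planted marker {gene}: per-group medians\n"
      f"{medians.round(2).to_string()}")

heat = plots.heatmap_matrix(table, markers)
plots.render_heatmap(heat, outdir / "heatmap.png")
print(f"heatmap: {heat.shape[0]} selected genes x {heat.shape[1]} groups "
      f"of mean in-group expression -> {outdir / 'heatmap.png'}")

volcano = plots.volcano_table(table, table.groups[0])
n_sig = int((volcano.data["neg_log10_fdr"] > 2).sum())
print(f"volcano of group {table.groups[0]!r}: {n_sig} genes above "
      f"FDR < 0.01")
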