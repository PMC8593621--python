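"""Read a MatrixMarket triple and its clusters category.

Builds a small archived experiment (the GXA on-disk layout: a zip of
.mtx/.mtx_rows/.mtx_cols plus a clusters CSV), reads it back, and shows
which clustering resolution is flagged as the default.
"""

import tempfile
from pathlib import Path

import scnetkit as sk

workdir = Path(tempfile.mkdtemp(prefix="scnetkit-example-"))
exp, category, truth = sk.generate_experiment(
    sk.SyntheticSpec(n_groups=3, cells_per_group=10, n_genes=50,
                     markers_per_group=3, seed=0),
    accession="E-DEMO-1",
)
paths = sk.write_experiment(exp, category, workdir)
print(f"wrote {paths['matrix'].name} and {paths['clusters'].name}")

back = sk.read_mtx_triple(paths["matrix"], species="Homo sapiens",
                          accession="E-DEMO-1")
print(f"matrix: {back.n_genes} genes x {back.n_cells} cells, "
      f"{back.matrix.nnz} nonzeros (kept sparse)")

clusters = sk.read_category_csv(paths["clusters"], transpose=False,
                                name="Cluster")
row = sk.select_default_row(clusters)
print(f"clusters file has {len(clusters.rows)} resolution row(s); "
      f"row {row} (K={clusters.rows[row].row_label}) is flagged default")
# The default row is the grouping every downstream step (DE, networks,
# plots) uses unless another row is chosen explicitly.
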