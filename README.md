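# scnetkit

From single-cell expression matrices to cluster-specific
functional-interaction networks.

`scnetkit` is a headless Python library (plus a thin CLI) for a common
workflow in single-cell transcriptomics: given a normalized genes × cells
expression matrix and a cell annotation (a clustering, a cell type, a
disease state), find the genes that mark each group of cells, and examine
the functional interactions among the proteins those genes encode. It is
aimed at computational biologists who want the whole chain — atlas or
local-file input, differential expression, marker selection, network
extraction, plot tables — scriptable and reproducible offline.

## The method

For a chosen annotation row with groups $g_1, \dots, g_K$, every gene is
tested **one-vs-rest**: the cells of group $g$ against all other labeled
cells. Per (gene, group) the table records

- the **Mann–Whitney U test** (U of the in-group sample, midrank ties,
  two-sided p; exact permutation enumeration at small sample sizes,
  tie-corrected normal approximation with continuity correction
  otherwise),
- $\log_2 \mathrm{FC} = \log_2\frac{\bar{x}_{\text{in}} + c}{\bar{x}_{\text{out}} + c}$
  with pseudocount $c = 0.01$,
- the percentage of cells expressing the gene (value > 0) in the group
  and in the rest,
- the **Benjamini–Hochberg FDR**, computed within each group's gene list.

Two noise filters gate network input (defaults: expressed in ≥ 10% of the
group *or* the rest; $|\log_2 \mathrm{FC}| \ge 0.5$). Marker selection
then applies the network-analysis cutoffs (FDR ≤ 0.5,
$|\log_2 \mathrm{FC}| \ge 1$, ≤ 200 genes per group), and one STRING-style
interaction network is built over the union of all groups' markers, with
one induced subnetwork per group — always $K + 1$ networks. Pre-processing,
UMAP/t-SNE embeddings and Leiden/Louvain clustering are provided through
scanpy with a deliberately small exposed parameter set.

## Worked example

```python
import scnetkit as sk

exp, category, truth = sk.generate_experiment(sk.SyntheticSpec(seed=0))
table = sk.compute_diffexp(exp, category)
markers = sk.select_markers(table)
edges, alias, _ = sk.generate_interactions(truth, seed=0)
source = sk.InteractionTable(edges=edges,
                             alias=dict(zip(alias["gene"], alias["protein"])))
union = sk.build_union_network(markers, source)
subnets = sk.extract_group_subnetworks(union, markers)
print(len(subnets) + 1, union.n_nodes, union.n_edges)
```

prints `4 15 28`: three per-group subnetworks plus the union network over
the 15 selected marker proteins, connected by the 28 interaction edges
that clear the 0.4 combined-score cutoff. On the same synthetic run the
top of group 1's table looks like

```
    gene   log2fc      p_value      fdr  passed_filters
GENE0003 2.132792 8.375015e-08 0.000025            True
GENE0000 2.117638 2.494548e-07 0.000036            True
GENE0002 2.043904 3.643403e-07 0.000036            True
GENE0001 2.558377 8.122633e-07 0.000061            True
GENE0004 1.679500 5.701368e-06 0.000342            True
```

— exactly the five genes planted as group-1 markers, with estimated
log2 fold changes scattered around the planted value of 2.

The `examples/` directory holds one short narrative script per
capability (matrix/category I/O, differential expression, networks,
embedding/clustering, plot tables, the CLI workflow); each prints what it
computes and what the numbers mean. The same steps run from a shell:

```bash
scnetkit load gxa --accession E-CURD-3
scnetkit calculate diffexp --accession E-CURD-3
scnetkit create network --accession E-CURD-3 --interactions links.tsv
```

## Data sources

- **Local files**: MatrixMarket triples (`.mtx`, `.mtx_rows`,
  `.mtx_cols`) as a directory or zip/tar.gz/tgz archive; category tables
  as CSV/TSV in either orientation (clusters-in-rows or cells-in-rows,
  with transposition).
- **Single Cell Expression Atlas (GXA)**: listing, normalized matrix,
  clusters and experiment-design endpoints.
- **Human Cell Atlas (DCP1)**: project listing filtered to matrix files;
  projects with one matrix per tissue are split into separate entries.

All client behavior is reproducible offline via recorded-payload
transports; no test touches the network.

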