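# Methods

## Scope and model

`scnetkit` computes one-vs-rest differential expression over a cell
annotation and turns the resulting marker lists into functional-
interaction networks. The statistical unit is the (gene, group) pair: for
group $g$ of the selected annotation row, the in-sample is the gene's
expression over the cells of $g$ and the out-sample over all other
labeled cells of the same row. Cells labeled `NA` are excluded from both
sides. The design assumes the matrix is already normalized (and, if
needed, batch-corrected); the package deliberately offers no raw-count
normalization beyond the optional pre-processing chain used for
embeddings and clustering.

## The test statistic

The Mann–Whitney U statistic is computed from midranks of the pooled
sample; the reported `U` is the U of the in-group sample (the convention
is labeled in the export rather than left implicit). Expression matrices
are sparse and non-negative, so ranks are computed sparsely: all zeros of
a gene tie at the shared midrank $(z+1)/2$ ($z$ = number of zeros) and
only the nonzero values are ranked explicitly. Peak memory per gene
scales with that gene's nonzeros.

Two p-value routes exist:

- **Exact permutation** (scalar API, small samples): when the number of
  in/out assignments $\binom{n}{n_\text{in}}$ is at most 5000, the
  two-sided p is the exact proportion of assignments whose U deviates
  from the null mean at least as much as the observed U. This route stays
  correct under heavy ties, where the normal approximation is poor — in
  the extreme tied case `[5,5]` vs `[1,1]` the exact two-sided p is 1/3
  while the continuity-corrected normal approximation gives ≈ 0.19. An
  asymptotic-only implementation therefore cannot stay within a 0.05
  absolute error of the exact answer at tiny n, which is why the exact
  route exists.
- **Tie-corrected normal approximation** with continuity correction
  (vectorized table computation, and the scalar API at larger n): at
  single-cell sample sizes the approximation error is negligible and the
  computation is O(genes × cells log cells). The approximation path is
  cross-checked in the test suite against an independent library
  implementation to near machine precision.

p-values are clipped to (0, 1]; a comparison with zero variance (all
pooled values identical) reports p = 1.

## Fold change, filters, FDR

log2 fold change is $\log_2\!\big((\bar{x}_\text{in} + c)/(\bar{x}_\text{out} + c)\big)$
with pseudocount $c = 0.01$ (configurable). The pseudocount keeps markers
absent from the rest set finite; it was chosen small relative to
normalized expression units so it only matters near zero.

"Expressed" means a value strictly greater than zero. The two noise
filters — expressed in at least `min_pct_cutoff` (default 10) percent of
the group *or* of the rest, and $|\log_2\mathrm{FC}|$ at least
`log_fc_cutoff` (default 0.5) — exist to de-noise the interaction
network, so genes failing them are still tested and reported, flagged
`passed_filters=False`, rather than dropped from the table.

FDR is Benjamini–Hochberg (via statsmodels), applied within each group
across all of that group's genes, not pooled across groups: marker lists
are consumed per group, so the error rate should be controlled per list.
Whether the filters should be applied before FDR computation was an open
design choice; testing everything and flagging afterwards keeps the
table complete and makes the filter a pure view.

## Marker selection and networks

Per group, records pass the network-analysis cutoffs (`fdr_cutoff` 0.5,
`log2fc_cutoff` 1.0, optional positive-only; `passed_filters` required),
are ranked by FDR ascending with |log2FC| descending and gene id as tie
breaks, and truncated to `max_genes` (200). The ranking key for "top"
genes was an open choice; FDR-first matches the selection cutoff's own
scale and is deterministic under the documented tie-breaks.

The union network is one query over the concatenated marker lists of all
groups, so edges between markers of different groups are kept. Offline
sources are STRING-style edge tables (`protein1 protein2 combined_score`,
0–1000 integers or 0–1 reals auto-detected) with an optional
gene-to-protein alias table; without an alias table the mapping is the
identity. Live queries go to the STRING network endpoint with the
species, `limit=0` (no added interactors) and `includesViruses=false`.
Edges below `string_score_cutoff` (default 0.4, STRING's medium
confidence) are removed post-hoc; self-loops are dropped; for duplicate
pairs the highest score wins. Genes that resolve to no protein, or to a
protein with no qualifying edge, are listed in a mapping report instead
of disappearing. Group subnetworks are induced subgraphs of the union on
each group's markers, so a run with K groups always yields K + 1
networks, each node carrying the per-group log2FC/FDR attributes.

## Pre-processing, embeddings, clustering

The pre-processing chain (scanpy-backed) filters cells with fewer than
100 detected genes, then genes detected in fewer than 1 cell, then
applies — each gated by a flag — total-count normalization to the median
cell total, log(1+x), restriction to the 2000 most variable genes, and
unit-variance scaling. The variable-gene count and normalization target
are package defaults, not reproductions of any particular service's
values. Scaled matrices contain negatives; the experiment container
relaxes its non-negativity invariant once a transform stage has run
(`transformed=True`).

Embeddings and clustering expose a small parameter set: UMAP's
`n_neighbors`/`min_dist`; t-SNE's perplexity, initial dimensions
(−1 triggers PCA pre-reduction to ≤ 50 components), early exaggeration
and learning rate; Leiden/Louvain's kNN-graph neighbor count. Everything
stochastic takes a seed and is bit-reproducible under it on one machine.
Louvain runs on igraph's multilevel implementation (scanpy
`flavor="igraph"`); Leiden on the igraph backend with 2 iterations.

## The synthetic generator

The generator exists to make the whole pipeline testable offline with
known ground truth. Counts are negative binomial with mean
`baseline_mean` (8.0) and dispersion `dispersion` (10.0, i.e. variance
$\mu + \mu^2/10$); each group's `markers_per_group` (5) marker genes have
their mean multiplied by $2^{\texttt{marker\_log2fc}}$ (log2FC 2) in that
group only; dropout zeroes entries independently with probability
`dropout_rate` (0.3); per-cell totals are then scaled to the median cell
total. Defaults describe the study conditions used throughout the tests:
3 groups × 50 cells, 300 genes.

Baseline mean and dispersion are free parameters of the emulation and
were set by calibration against the pipeline's intended operating
characteristics at those study conditions (planted-marker recall ≥ 0.9
at FDR ≤ 0.05; null type-I proportion near 0.05): with 30% dropout and
50-cell groups, the binomial variation of a marker's expressing-cell
count caps per-marker detection power at roughly 0.95 regardless of the
noise model, and (8, 10) sits at that ceiling. Consequences worth
knowing: a typical run recovers 93–100% of planted markers, but
individual seeds can land at 80–87% — 15 planted records is a coarse
grid for a proportion, which is why the acceptance script averages over
replicate simulations. Interaction fixtures plant edges among same-group
markers with score ~ U(0.7, 1.0) and background edges with score ~
U(0.15, 0.45), so planted modules survive the default 0.4 cutoff and
background mostly does not.

What the generator does **not** emulate: library-size variation, batch
structure, gene–gene correlation, mean-dependent dropout, realistic
mean-variance trends across genes. Passing tests therefore demonstrate
the pipeline's correctness and calibration under a clean planted model,
not performance on real tissue data. One real-data behavior the
generator *does* reproduce: under per-cell normalization, boosting
markers slightly depresses all other genes of the same cells
(compositional coupling), and another group's marker is genuinely
down-regulated one-vs-rest — both appear in the DE table as true,
if unplanted, signal.

## Numerical and degenerate-input choices

- MTX coordinates are 1-based on disk, 0-based in memory (scipy handles
  the conversion); matrices stay sparse end to end.
- Duplicate gene ids are preserved as separate rows with a warning;
  merging would silently change the statistics.
- Delimiters are sniffed from the header line (tab beats comma).
- Cells present in a category but absent from the matrix are dropped
  with a warning; matrix cells missing from a category row get `NA`.
- A category row with a single group cannot be compared and is an error;
  an annotation with no default-flagged row falls back to row 0 with a
  warning; ties among default flags resolve to the first.
- Empty marker lists produce empty subnetworks, not errors; an entirely
  unmappable marker set is an error.
- Atlas clients cache only when given an explicit cache directory
  (cache key = URL), so repeated fetches of an accession perform no new
  requests; incomplete downloads are never written to the cache.

## Known limitations

- Only one-vs-rest comparisons; no arbitrary two-group contrasts.
- No Loom/HDF5/10x input; MatrixMarket triples and CSV/TSV only.
- The HCA client speaks the DCP1 API only; DCP2 raises.
- Live STRING/GXA/HCA access is implemented but exercised only against
  recorded fixtures in the test suite; atlas releases drift, so
  accession-level numbers from live endpoints are not guaranteed stable.
- The exact-permutation p-value route is quadratic-ish in the assignment
  count and intentionally capped; large-sample p-values are asymptotic.
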