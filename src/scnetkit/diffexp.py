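"""One-vs-rest differential expression with the Mann-Whitney U test.

For a selected category row, every group of cells is compared against the
union of all other labeled cells.  Per (gene, group) the table records the
group and rest means, the percentage of cells expressing the gene (value
strictly greater than zero), the log2 fold change of the mean ratio, the
Mann-Whitney U statistic (U of the in-group sample), a two-sided p-value
and the Benjamini-Hochberg FDR computed within each group's gene list.

Two noise filters gate which genes feed network construction: a gene must
be expressed in at least ``min_pct_cutoff`` percent of the in-group cells
or of the rest cells, and |log2FC| must reach ``log_fc_cutoff``.  Filtered
genes remain in the table with ``passed_filters=False`` -- the cutoffs
exist to de-noise the interaction network, not to censor the statistics.

The rank computation is sparse-aware: for normalized non-negative data all
zeros of a gene tie at a shared midrank, so ranks are computed on the
nonzero values only and the zero block is handled in closed form.  Peak
memory per gene scales with that gene's nonzeros, not with the number of
cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientCellsError, ParameterError
from .matrix_io import Category, CategoryRow, ExpressionExperiment

__all__ = [
    "DiffExpConfig",
    "DiffExpTable",
    "log2_fold_change",
    "mann_whitney_one_vs_rest",
    "benjamini_hochberg",
    "compute_diffexp",
]

#: assignments with at most this many distinct in/out splits are enumerated
#: exactly; beyond it the tie-corrected normal approximation is used.
EXACT_ENUMERATION_LIMIT = 5000


@dataclass(frozen=True)
class DiffExpConfig:
    """Cutoffs for the differential-expression noise filters.

    log_fc_cutoff
        minimum |log2 fold change| (the ``logGERCutoff``), default 0.5.
    min_pct_cutoff
        minimum percentage of expressing cells in the group OR the rest
        (the ``minPctCutoff``), default 10.
    pseudocount
        added to both means before the fold-change ratio so that markers
        absent from the rest set stay defined; default 0.01.
    """

    log_fc_cutoff: float = 0.5
    min_pct_cutoff: float = 10.0
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        if self.log_fc_cutoff < 0:
            raise ValueError("log_fc_cutoff must be >= 0")
        if not 0 <= self.min_pct_cutoff <= 100:
            raise ValueError("min_pct_cutoff must be in [0, 100]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


@dataclass
class DiffExpTable:
    """Per (gene, group) differential-expression records.

    ``data`` is a DataFrame with columns gene, group, mean_in, mean_out,
    pct_in, pct_out, log2fc, u_stat, p_value, fdr, passed_filters: one row
    per (gene, group-of-the-selected-row) pair.
    """

    data: pd.DataFrame
    config: DiffExpConfig
    groups: list[str]
    group_sizes: dict[str, int]
    accession: str = ""
    category_name: str = ""
    row_label: str = ""

    def for_group(self, group: str) -> pd.DataFrame:
        return self.data[self.data["group"] == group]

    def to_csv(self, path: str | Path) -> Path:
        """Export with the documented column layout (U is U of the in-group)."""
        path = Path(path)
        out = self.data.rename(
            columns={"log2fc": "log2FC", "u_stat": "U", "fdr": "FDR"}
        )
        out.to_csv(path, index=False)
        return path


def log2_fold_change(mean_in: float, mean_out: float, pseudocount: float = 0.01) -> float:
    """log2 of the ratio of group mean to rest mean, pseudocount-stabilized.

    Returns ``log2((mean_in + c) / (mean_out + c))``.
    """
    if mean_in < 0 or mean_out < 0:
        raise ValueError("means must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return math.log2((mean_in + pseudocount) / (mean_out + pseudocount))


def _tie_term(values: np.ndarray) -> float:
    """sum(t^3 - t) over tie groups of the pooled sample."""
    _, counts = np.unique(values, return_counts=True)
    counts = counts.astype(float)
    return float(np.sum(counts**3 - counts))


def _normal_p(u: float, n_in: int, n_out: int, tie_term: float) -> float:
    """Two-sided p from the tie-corrected normal approximation with
    continuity correction."""
    n = n_in + n_out
    mu = n_in * n_out / 2.0
    var = n_in * n_out / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    diff = abs(u - mu)
    z = max(diff - 0.5, 0.0) / math.sqrt(var)
    p = 2.0 * norm.sf(z)
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


def _exact_p(pooled: np.ndarray, ranks: np.ndarray, n_in: int, u_obs: float) -> float:
    """Exact two-sided permutation p: the proportion of in/out assignments
    whose U deviates from its null mean at least as much as the observed U."""
    n = len(pooled)
    mu = n_in * (n - n_in) / 2.0
    threshold = abs(u_obs - mu) - 1e-9
    offset = n_in * (n_in + 1) / 2.0
    hits = 0
    total = 0
    for idx in combinations(range(n), n_in):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mu) >= threshold:
            hits += 1
        total += 1
    return hits / total


def mann_whitney_one_vs_rest(
    values_in: np.ndarray, values_out: np.ndarray
) -> tuple[float, float]:
    """Mann-Whitney U (of the in-group) and two-sided p-value.

    Small samples -- at most :data:`EXACT_ENUMERATION_LIMIT` distinct
    in/out assignments -- are handled by exact permutation enumeration,
    which stays correct under heavy ties where the normal approximation
    degrades.  Larger samples use the midrank tie correction and
    continuity-corrected normal approximation.  p is clipped to (0, 1].
    """
    values_in = np.asarray(values_in, dtype=float)
    values_out = np.asarray(values_out, dtype=float)
    if values_in.size == 0 or values_out.size == 0:
        raise InsufficientCellsError(
            "both the group and the comparison set need at least one cell"
        )
    n_in, n_out = values_in.size, values_out.size
    pooled = np.concatenate([values_in, values_out])
    ranks = rankdata(pooled)
    u = float(ranks[:n_in].sum() - n_in * (n_in + 1) / 2.0)

    if math.comb(n_in + n_out, n_in) <= EXACT_ENUMERATION_LIMIT:
        p = _exact_p(pooled, ranks, n_in, u)
    else:
        p = _normal_p(u, n_in, n_out, _tie_term(pooled))
    return u, float(min(max(p, np.nextafter(0, 1)), 1.0))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Order-preserving (permutation equivariant); each output is >= its
    input and <= 1.  Empty input yields an empty array.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Full table computation
# ---------------------------------------------------------------------------


def _group_rank_sums(
    X: sp.csr_matrix, group_codes: np.ndarray, n_groups: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per gene: rank sum of each group's cells, plus the pooled tie term.

    Exploits sparsity: all zeros of a gene share the midrank (z+1)/2 where
    z is the zero count, and nonzero values are ranked among themselves
    with an offset of z.
    """
    n_genes, n_cells = X.shape
    group_counts = np.bincount(group_codes, minlength=n_groups).astype(float)
    rank_sums = np.zeros((n_genes, n_groups))
    tie_terms = np.zeros(n_genes)
    indptr, indices, data = X.indptr, X.indices, X.data
    for i in range(n_genes):
        lo, hi = indptr[i], indptr[i + 1]
        vals = data[lo:hi]
        cols = indices[lo:hi]
        nnz = hi - lo
        z = n_cells - nnz
        zero_rank = (z + 1) / 2.0
        # zeros: every group gets (its zero count) * shared midrank
        nz_per_group = np.bincount(group_codes[cols], minlength=n_groups).astype(float)
        rank_sums[i] = (group_counts - nz_per_group) * zero_rank
        if nnz:
            nz_ranks = rankdata(vals) + z
            sums = np.zeros(n_groups)
            np.add.at(sums, group_codes[cols], nz_ranks)
            rank_sums[i] += sums
            _, counts = np.unique(vals, return_counts=True)
            counts = counts.astype(float)
            tie_terms[i] = np.sum(counts**3 - counts)
        tie_terms[i] += z**3 - z
    return rank_sums, tie_terms


def compute_diffexp(
    exp: ExpressionExperiment,
    category: Category,
    row: int | None = None,
    config: DiffExpConfig | None = None,
) -> DiffExpTable:
    """One-vs-rest differential expression over the selected category row.

    For each group G and gene g the in-sample is g's expression over cells
    of G and the out-sample over all other labeled cells; cells labeled
    "NA" are excluded from both sides.  FDR is Benjamini-Hochberg within
    each group across all genes.  Raises :class:`ParameterError` when the
    row has fewer than two groups (no comparison set exists).
    """
    config = config or DiffExpConfig()
    if row is None:
        row = category.selected_row
    if not 0 <= row < len(category.rows):
        raise ParameterError(f"category row {row} out of range")
    cat_row: CategoryRow = category.rows[row]

    labels = np.array([cat_row.assignments.get(c, "NA") for c in exp.cell_ids])
    labeled = labels != "NA"
    if labeled.sum() == 0:
        raise ParameterError("no labeled cells in the selected category row")
    groups = sorted({str(g) for g in labels[labeled]})
    if len(groups) < 2:
        raise ParameterError(
            f"category row has a single group ({groups}); one-vs-rest needs >= 2"
        )
    group_to_code = {g: k for k, g in enumerate(groups)}
    codes = np.array([group_to_code[g] for g in labels[labeled]])
    X = sp.csr_matrix(exp.matrix)[:, np.flatnonzero(labeled)]
    n_cells = X.shape[1]
    n_groups = len(groups)
    group_counts = np.bincount(codes, minlength=n_groups).astype(float)

    # means and expressing-cell percentages via one-hot group indicators
    onehot = sp.csr_matrix(
        (np.ones(n_cells), (np.arange(n_cells), codes)), shape=(n_cells, n_groups)
    )
    sums = np.asarray((X @ onehot).todense())  # genes x groups
    total = sums.sum(axis=1, keepdims=True)
    pos = X.copy()
    pos.data = (pos.data > 0).astype(float)
    counts_pos = np.asarray((pos @ onehot).todense())
    total_pos = counts_pos.sum(axis=1, keepdims=True)

    mean_in = sums / group_counts
    mean_out = (total - sums) / (n_cells - group_counts)
    pct_in = 100.0 * counts_pos / group_counts
    pct_out = 100.0 * (total_pos - counts_pos) / (n_cells - group_counts)
    c = config.pseudocount
    log2fc = np.log2((mean_in + c) / (mean_out + c))

    rank_sums, tie_terms = _group_rank_sums(X, codes, n_groups)
    n_in = group_counts[np.newaxis, :]
    n_out = n_cells - n_in
    u = rank_sums - n_in * (n_in + 1) / 2.0
    mu = n_in * n_out / 2.0
    var = n_in * n_out / 12.0 * (
        (n_cells + 1) - tie_terms[:, np.newaxis] / (n_cells * (n_cells - 1))
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.maximum(np.abs(u - mu) - 0.5, 0.0) / np.sqrt(var)
    p = 2.0 * norm.sf(z)
    p = np.where(var <= 0, 1.0, p)
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    records = []
    tiny = np.nextafter(0, 1)
    for k, g in enumerate(groups):
        fdr = benjamini_hochberg(p[:, k])
        fdr = np.clip(fdr, tiny, 1.0)
        passed = (
            ((pct_in[:, k] >= config.min_pct_cutoff)
             | (pct_out[:, k] >= config.min_pct_cutoff))
            & (np.abs(log2fc[:, k]) >= config.log_fc_cutoff)
        )
        records.append(pd.DataFrame({
            "gene": exp.gene_ids,
            "group": g,
            "mean_in": mean_in[:, k],
            "mean_out": mean_out[:, k],
            "pct_in": pct_in[:, k],
            "pct_out": pct_out[:, k],
            "log2fc": log2fc[:, k],
            "u_stat": u[:, k],
            "p_value": p[:, k],
            "fdr": fdr,
            "passed_filters": passed,
        }))
    data = pd.concat(records, ignore_index=True)
    return DiffExpTable(
        data=data,
        config=config,
        groups=groups,
        group_sizes={g: int(group_counts[group_to_code[g]]) for g in groups},
        accession=exp.accession,
        category_name=category.name,
        row_label=cat_row.row_label,
    )
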