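"""The one-vs-rest Mann-Whitney DE core, fold changes and BH FDR."""

import itertools
import math

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.stats import mannwhitneyu

import scnetkit as sk
from scnetkit.diffexp import DiffExpConfig
from scnetkit.errors import InsufficientCellsError, ParameterError


def exact_two_sided_p(values_in, values_out):
    """Independent oracle: enumerate every in/out assignment of the pooled
    values and count those whose U deviates from the null mean at least as
    much as the observed one.  U is computed from pairwise comparisons,
    not ranks."""

    def u_of(ins, outs):
        return sum(
            1.0 if a > b else (0.5 if a == b else 0.0)
            for a in ins for b in outs
        )

    pooled = list(values_in) + list(values_out)
    n_in = len(values_in)
    mu = n_in * len(values_out) / 2.0
    u_obs = u_of(values_in, values_out)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_in):
        ins = [pooled[i] for i in idx]
        outs = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(u_of(ins, outs) - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
        total += 1
    return hits / total


class TestLog2FoldChange:
    def test_equal_means_are_zero(self):
        assert sk.log2_fold_change(3.7, 3.7) == 0.0

    def test_ratio_in_small_pseudocount_limit(self):
        assert sk.log2_fold_change(4, 1, pseudocount=1e-12) == pytest.approx(2.0)

    def test_zero_rest_mean_is_stabilized(self):
        # log2(1.01 / 0.01) with the default pseudocount
        assert sk.log2_fold_change(1, 0) == pytest.approx(math.log2(101), abs=1e-9)

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            sk.log2_fold_change(-1, 2)


class TestMannWhitney:
    def test_printed_tie_case_is_exact(self):
        u, p = sk.mann_whitney_one_vs_rest([5, 5], [1, 1])
        assert u == 4.0
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_are_null(self):
        u, p = sk.mann_whitney_one_vs_rest([1, 2, 3], [1, 2, 3])
        assert u == pytest.approx(9 / 2)  # n^2 / 2
        assert p >= 0.99

    def test_empty_side_raises(self):
        with pytest.raises(InsufficientCellsError):
            sk.mann_whitney_one_vs_rest([], [1.0])

    @pytest.mark.parametrize("n_in,n_out", [(2, 2), (3, 3), (4, 4), (3, 7), (5, 5)])
    def test_small_samples_match_exhaustive_oracle(self, n_in, n_out):
        rng = np.random.default_rng(42)
        for _ in range(20):
            vin = rng.integers(0, 4, n_in).astype(float)
            vout = rng.integers(0, 4, n_out).astype(float)
            _, p = sk.mann_whitney_one_vs_rest(vin, vout)
            assert p == pytest.approx(exact_two_sided_p(vin, vout), abs=0.05)

    def test_large_sample_path_matches_scipy_asymptotic(self):
        # independent route for the tie-corrected normal approximation
        rng = np.random.default_rng(7)
        for _ in range(20):
            vin = rng.poisson(3, 25).astype(float)
            vout = rng.poisson(4, 40).astype(float)
            u, p = sk.mann_whitney_one_vs_rest(vin, vout)
            u_ref, p_ref = mannwhitneyu(vin, vout, alternative="two-sided",
                                        method="asymptotic")
            assert u == pytest.approx(float(u_ref))
            assert p == pytest.approx(float(p_ref), rel=1e-9)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(123)
        hits = 0
        n_draws = 500
        for _ in range(n_draws):
            vin = rng.normal(size=8)
            vout = rng.normal(size=12)
            _, p = sk.mann_whitney_one_vs_rest(vin, vout)
            hits += p < 0.05
        assert 0.02 <= hits / n_draws <= 0.09


class TestBenjaminiHochberg:
    def test_step_up_hand_example(self):
        out = sk.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_value_identity(self):
        assert sk.benjamini_hochberg([0.5]) == pytest.approx([0.5])

    def test_empty_input(self):
        assert sk.benjamini_hochberg([]).size == 0

    def test_permutation_equivariance_and_bounds(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            p = rng.uniform(1e-6, 1.0, rng.integers(1, 30))
            adj = sk.benjamini_hochberg(p)
            assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)
            perm = rng.permutation(len(p))
            assert np.allclose(sk.benjamini_hochberg(p[perm]), adj[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sk.benjamini_hochberg([0.0, 0.5])


def _toy_experiment(matrix, labels):
    matrix = np.asarray(matrix, dtype=float)
    n_genes, n_cells = matrix.shape
    gene_ids = [f"g{i}" for i in range(n_genes)]
    cell_ids = [f"c{i}" for i in range(n_cells)]
    exp = sk.ExpressionExperiment(matrix=sp.csr_matrix(matrix),
                                  gene_ids=gene_ids, cell_ids=cell_ids)
    cat = sk.Category(name="Cluster", rows=[sk.CategoryRow(
        row_label=str(len(set(labels))), is_default=True,
        assignments=dict(zip(cell_ids, labels)))])
    return exp, cat


class TestComputeDiffexp:
    def test_planted_markers_recovered(self, planted_run):
        _, _, truth, table = planted_run
        indexed = table.data.set_index(["gene", "group"])
        planted = indexed.loc[list(map(tuple, truth.values))]
        assert planted["passed_filters"].all()
        assert (planted["fdr"] <= 0.05).mean() >= 0.9
        # planted records sit at the bottom of their groups' FDR ranking
        for group in table.groups:
            grp = table.for_group(group).sort_values("fdr")
            top = set(grp.head(20)["gene"])
            mine = set(truth.loc[truth["group"] == group, "gene"])
            assert mine <= top

    def test_low_pct_gene_fails_filters_regardless_of_p(self):
        # expressed in 5% of each side (1 of 20 cells in, 1 of 20 out)
        row = np.zeros(40)
        row[0] = 50.0
        row[20] = 1.0
        base = np.ones(40)
        exp, cat = _toy_experiment([row, base], ["a"] * 20 + ["b"] * 20)
        table = sk.compute_diffexp(exp, cat)
        rec = table.data[(table.data.gene == "g0") & (table.data.group == "a")].iloc[0]
        assert rec["pct_in"] == 5.0 and rec["pct_out"] == 5.0
        assert not rec["passed_filters"]

    def test_small_fold_change_fails_filters(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 2, 40)
        boosted = base.copy()
        boosted[:20] *= 2 ** 0.3  # |log2FC| ~ 0.3 < 0.5 default cutoff
        exp, cat = _toy_experiment([boosted, base], ["a"] * 20 + ["b"] * 20)
        table = sk.compute_diffexp(exp, cat)
        rec = table.data[(table.data.gene == "g0") & (table.data.group == "a")].iloc[0]
        assert abs(rec["log2fc"]) < 0.5
        assert not rec["passed_filters"]

    def test_swapping_groups_negates_log2fc_keeps_p(self):
        rng = np.random.default_rng(3)
        matrix = rng.poisson(4, size=(5, 30)).astype(float)
        labels = ["a"] * 12 + ["b"] * 18
        exp, cat = _toy_experiment(matrix, labels)
        table = sk.compute_diffexp(exp, cat)
        a = table.for_group("a").set_index("gene")
        b = table.for_group("b").set_index("gene")
        assert np.allclose(a["log2fc"], -b["log2fc"], atol=1e-9)
        assert np.allclose(a["p_value"], b["p_value"])

    def test_group_sizes_partition_labeled_cells(self, planted_run):
        exp, _, _, table = planted_run
        assert sum(table.group_sizes.values()) == exp.n_cells

    def test_na_cells_excluded(self):
        matrix = np.arange(30, dtype=float).reshape(3, 10)
        labels = ["a"] * 4 + ["b"] * 4 + ["NA"] * 2
        exp, cat = _toy_experiment(matrix, labels)
        table = sk.compute_diffexp(exp, cat)
        assert sum(table.group_sizes.values()) == 8

    def test_single_group_rejected(self):
        matrix = np.ones((2, 6))
        exp, cat = _toy_experiment(matrix, ["a"] * 6)
        with pytest.raises(ParameterError, match="single group"):
            sk.compute_diffexp(exp, cat)

    def test_fdr_never_below_p(self, planted_run):
        _, _, _, table = planted_run
        assert (table.data["fdr"] >= table.data["p_value"] - 1e-12).all()

    def test_export_column_layout(self, planted_run, tmp_path):
        _, _, _, table = planted_run
        out = table.to_csv(tmp_path / "de.csv")
        header = out.read_text().splitlines()[0].split(",")
        assert header == ["gene", "group", "mean_in", "mean_out", "pct_in",
                          "pct_out", "log2FC", "U", "p_value", "FDR",
                          "passed_filters"]
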