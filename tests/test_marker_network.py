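"""Marker selection, union-network construction and subnetwork extraction."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import scnetkit as sk
from scnetkit.diffexp import DiffExpConfig, DiffExpTable
from scnetkit.errors import EmptyNetworkError


def _table(records, groups):
    df = pd.DataFrame(records, columns=["gene", "group", "log2fc", "fdr",
                                        "passed_filters"])
    for col in ("mean_in", "mean_out", "pct_in", "pct_out", "u_stat", "p_value"):
        df[col] = 1.0
    return DiffExpTable(data=df, config=DiffExpConfig(), groups=groups,
                        group_sizes={g: 10 for g in groups})


def brute_force_selection(table, config):
    """Independent filter-sort-truncate over the raw records."""
    out = {}
    for group in table.groups:
        recs = [
            r for _, r in table.data.iterrows()
            if r["group"] == group and r["passed_filters"]
            and r["fdr"] <= config.fdr_cutoff
            and abs(r["log2fc"]) >= config.log2fc_cutoff
            and (r["log2fc"] > 0 or not config.positive_only)
        ]
        recs.sort(key=lambda r: (r["fdr"], -abs(r["log2fc"]), r["gene"]))
        out[group] = [r["gene"] for r in recs[: config.max_genes]]
    return out


class TestSelectMarkers:
    def test_toy_table_matches_brute_force(self):
        rng = np.random.default_rng(11)
        records = [
            (f"g{i}", grp, float(rng.normal(0, 2)), float(rng.uniform(0.001, 1)),
             bool(rng.random() < 0.8))
            for i in range(6) for grp in ("a", "b")
        ]
        table = _table(records, ["a", "b"])
        for config in (sk.NetworkConfig(),
                       sk.NetworkConfig(fdr_cutoff=0.3, log2fc_cutoff=0.5),
                       sk.NetworkConfig(positive_only=True, max_genes=2)):
            sel = sk.select_markers(table, config)
            expected = brute_force_selection(table, config)
            assert {g: sel.genes(g) for g in table.groups} == expected

    def test_truncation_keeps_smallest_fdrs(self):
        rng = np.random.default_rng(0)
        fdrs = rng.uniform(0.0001, 0.4, 300)
        records = [(f"g{i:03d}", "a", 2.0, float(fdrs[i]), True)
                   for i in range(300)]
        sel = sk.select_markers(_table(records, ["a"]),
                                sk.NetworkConfig(max_genes=200))
        chosen = sel.per_group["a"]
        assert len(chosen) == 200
        cutoff = np.sort(fdrs)[199]
        assert (chosen["fdr"] <= cutoff + 1e-12).all()

    def test_positive_only_drops_downregulated(self):
        records = [("up", "a", 1.5, 0.01, True), ("down", "a", -1.5, 0.01, True)]
        sel = sk.select_markers(_table(records, ["a"]),
                                sk.NetworkConfig(positive_only=True))
        assert sel.genes("a") == ["up"]

    def test_empty_group_warns(self):
        records = [("g0", "a", 0.1, 0.9, False)]
        with pytest.warns(UserWarning, match="no gene passes"):
            sel = sk.select_markers(_table(records, ["a"]))
        assert sel.genes("a") == []

    def test_raising_fdr_cutoff_never_removes_markers(self, planted_run):
        _, _, _, table = planted_run
        loose = sk.select_markers(table, sk.NetworkConfig(fdr_cutoff=0.5))
        tight = sk.select_markers(table, sk.NetworkConfig(fdr_cutoff=0.05))
        for g in table.groups:
            assert set(tight.genes(g)) <= set(loose.genes(g))


def _selection(per_group):
    config = sk.NetworkConfig()
    frames = {
        g: pd.DataFrame({"gene": genes, "log2fc": 2.0,
                         "fdr": [0.01 * (i + 1) for i in range(len(genes))]})
        for g, genes in per_group.items()
    }
    return sk.MarkerSelection(per_group=frames, config=config)


class TestUnionNetwork:
    def test_score_filter_on_toy_graph(self):
        edges = pd.DataFrame(
            [("A", "B", 0.9), ("B", "C", 0.3), ("C", "D", 0.8)],
            columns=["protein1", "protein2", "score"],
        )
        markers = _selection({"g1": ["A", "B"], "g2": ["C", "D"]})
        net = sk.build_union_network(markers, sk.InteractionTable(edges=edges))
        assert set(net.graph.nodes) == {"A", "B", "C", "D"}
        assert {frozenset(e) for e in net.graph.edges} == \
            {frozenset("AB"), frozenset("CD")}

    def test_marker_without_edges_stays_as_isolated_node(self):
        edges = pd.DataFrame([("A", "B", 0.9)],
                             columns=["protein1", "protein2", "score"])
        markers = _selection({"g1": ["A", "B", "LONER"]})
        net = sk.build_union_network(markers, sk.InteractionTable(edges=edges))
        assert "LONER" in net.graph.nodes
        assert "LONER" in net.mapping_report["unmapped_to_edges"]

    def test_planted_modules_recovered(self, marker_network_inputs):
        markers, source, planted = marker_network_inputs
        net = sk.build_union_network(markers, source)
        planted_set = {frozenset((a, b)) for a, b, _ in planted.itertuples(index=False)}
        got = {frozenset(e) for e in net.graph.edges}
        assert planted_set <= got
        # non-planted edges can only come from background scores >= 0.4
        extra = got - planted_set
        for e in extra:
            assert net.graph.edges[tuple(e)]["score"] >= 0.4

    def test_self_loops_dropped_and_scores_cut(self, marker_network_inputs):
        markers, source, _ = marker_network_inputs
        net = sk.build_union_network(markers, source)
        assert all(u != v for u, v in net.graph.edges)
        assert all(d["score"] >= 0.4 for _, _, d in net.graph.edges(data=True))

    def test_raising_score_cutoff_never_adds_edges(self, marker_network_inputs):
        markers, source, _ = marker_network_inputs
        prev = None
        for cut in (0.2, 0.4, 0.7, 0.9):
            net = sk.build_union_network(
                markers, source, sk.NetworkConfig(string_score_cutoff=cut))
            edges = {frozenset(e) for e in net.graph.edges}
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_nodes_carry_group_de_attributes(self, marker_network_inputs):
        markers, source, _ = marker_network_inputs
        net = sk.build_union_network(markers, source)
        for group, df in markers.per_group.items():
            for gene in df["gene"]:
                prot = source.protein_for(gene)
                attrs = net.graph.nodes[prot]
                assert f"log2fc_{group}" in attrs and f"fdr_{group}" in attrs

    def test_empty_selection_is_an_error(self):
        markers = sk.MarkerSelection(per_group={}, config=sk.NetworkConfig())
        edges = pd.DataFrame(columns=["protein1", "protein2", "score"])
        with pytest.raises(EmptyNetworkError):
            sk.build_union_network(markers, sk.InteractionTable(edges=edges))


class TestSubnetworks:
    def test_network_count_is_groups_plus_one(self, marker_network_inputs):
        markers, source, _ = marker_network_inputs
        net = sk.build_union_network(markers, source)
        subs = sk.extract_group_subnetworks(net, markers)
        assert len(subs) + 1 == len(markers.per_group) + 1
        assert len(subs) == len(markers.per_group)

    def test_induced_subgraph_matches_edge_scan(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            n = int(rng.integers(4, 12))
            proteins = [f"P{i}" for i in range(n)]
            edges = pd.DataFrame(
                [(a, b, float(rng.uniform(0.5, 1)))
                 for a, b in itertools.combinations(proteins, 2)
                 if rng.random() < 0.4],
                columns=["protein1", "protein2", "score"],
            )
            k = int(rng.integers(1, n))
            member = list(rng.choice(proteins, size=k, replace=False))
            markers = _selection({"grp": member, "other": proteins})
            union = sk.build_union_network(markers, sk.InteractionTable(edges=edges))
            sub = sk.extract_group_subnetworks(union, markers)[0]
            expected = {
                frozenset((a, b))
                for a, b, _ in edges.itertuples(index=False)
                if a in member and b in member
            }
            assert {frozenset(e) for e in sub.graph.edges} == expected
            assert set(sub.graph.nodes) == set(member)

    def test_subnetwork_is_subset_of_union(self, marker_network_inputs):
        markers, source, _ = marker_network_inputs
        union = sk.build_union_network(markers, source)
        for sub in sk.extract_group_subnetworks(union, markers):
            assert set(sub.graph.nodes) <= set(union.graph.nodes)
            assert {frozenset(e) for e in sub.graph.edges} <= \
                {frozenset(e) for e in union.graph.edges}
            for n in sub.graph.nodes:
                assert f"log2fc_{sub.group}" in sub.graph.nodes[n]


class TestIO:
    def test_string_edge_table_score_autodetection(self, tmp_path):
        milli = tmp_path / "milli.tsv"
        milli.write_text("protein1\tprotein2\tcombined_score\nA\tB\t900\nB\tC\t150\n")
        table = sk.read_string_edges(milli)
        assert table.edges["score"].tolist() == [0.9, 0.15]
        unit = tmp_path / "unit.tsv"
        unit.write_text("protein1\tprotein2\tcombined_score\nA\tB\t0.9\n")
        assert sk.read_string_edges(unit).edges["score"].tolist() == [0.9]

    def test_alias_table_controls_mapping(self, tmp_path):
        edge_path = tmp_path / "e.tsv"
        edge_path.write_text("protein1\tprotein2\tcombined_score\nP1\tP2\t0.9\n")
        alias_path = tmp_path / "a.tsv"
        alias_path.write_text("geneA\tP1\ngeneB\tP2\n")
        source = sk.read_string_edges(edge_path, alias_path)
        markers = _selection({"g": ["geneA", "geneB", "unknown"]})
        net = sk.build_union_network(markers, source)
        assert set(net.graph.nodes) == {"P1", "P2"}
        assert net.mapping_report["unresolved_genes"] == ["unknown"]

    def test_graphml_and_sif_round_trip(self, marker_network_inputs, tmp_path):
        markers, source, _ = marker_network_inputs
        net = sk.build_union_network(markers, source)
        gml = net.write_graphml(tmp_path / "union.graphml")
        back = nx.read_graphml(gml)
        assert back.number_of_nodes() == net.n_nodes
        assert back.number_of_edges() == net.n_edges
        sif = net.write_sif(tmp_path / "union.sif")
        n_lines = len(sif.read_text().splitlines())
        isolated = sum(1 for n in net.graph.nodes if net.graph.degree(n) == 0)
        assert n_lines == net.n_edges + isolated
        nodes = net.node_table()
        assert set(nodes.columns) == {"protein", "gene", "group", "log2FC",
                                      "FDR", "selected"}
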