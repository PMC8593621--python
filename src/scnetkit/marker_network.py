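"""Marker selection and functional-interaction network construction.

From the differential-expression table, each group contributes its top
marker genes (FDR ascending, ties broken by |log2FC| descending, then by
gene id) under the network-analysis cutoffs.  One interaction network is
built for the union of all groups' markers -- a single query over the
concatenated gene list, so cross-group edges are kept -- and per-group
subnetworks are the induced subgraphs on each group's markers.  A run with
K groups therefore always yields K + 1 networks.

Interactions come either from an offline STRING-style edge table
(``protein1  protein2  combined_score``, scores as 0-1000 integers or 0-1
reals, auto-detected) with an optional gene-to-protein alias table, or
from the live STRING API (species-scoped protein query with ``limit=0``,
i.e. no added interactors, and ``includesViruses=false``).  Edges below
``string_score_cutoff`` are dropped post-hoc; unmapped genes are reported,
never silently discarded.
"""

from __future__ import annotations

import csv
import json
import urllib.parse
import urllib.request
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .diffexp import DiffExpTable
from .errors import EmptyNetworkError, FormatError, TransportError

__all__ = [
    "NetworkConfig",
    "MarkerSelection",
    "GeneNetwork",
    "InteractionTable",
    "select_markers",
    "read_string_edges",
    "build_union_network",
    "extract_group_subnetworks",
    "StringApiClient",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Cutoffs controlling marker selection and network construction.

    Defaults mirror the automation defaults: ``fdrCutoff=0.5``,
    ``log2FCCutoff=1.0``, ``maxgenes=200``, ``positiveOnly=false``.  The
    STRING combined-score cutoff defaults to 0.4 (medium confidence).
    """

    fdr_cutoff: float = 0.5
    log2fc_cutoff: float = 1.0
    max_genes: int = 200
    positive_only: bool = False
    string_score_cutoff: float = 0.4
    species: str = "Homo sapiens"

    def __post_init__(self) -> None:
        if not 0 < self.fdr_cutoff <= 1:
            raise ValueError("fdr_cutoff must be in (0, 1]")
        if self.log2fc_cutoff < 0:
            raise ValueError("log2fc_cutoff must be >= 0")
        if self.max_genes < 1:
            raise ValueError("max_genes must be >= 1")
        if not 0 <= self.string_score_cutoff <= 1:
            raise ValueError("string_score_cutoff must be in [0, 1]")


@dataclass
class MarkerSelection:
    """Per group, the ordered marker genes passing the network cutoffs.

    ``per_group[g]`` is a DataFrame (gene, log2fc, fdr) in rank order.
    """

    per_group: dict[str, pd.DataFrame]
    config: NetworkConfig

    def genes(self, group: str) -> list[str]:
        return list(self.per_group[group]["gene"])

    def all_genes(self) -> list[str]:
        """Union of all groups' markers, first-seen order, deduplicated."""
        seen: dict[str, None] = {}
        for g in self.per_group:
            for gene in self.per_group[g]["gene"]:
                seen.setdefault(gene, None)
        return list(seen)


@dataclass
class GeneNetwork:
    """An undirected scored interaction network over marker proteins.

    Nodes carry ``gene``, ``display_name`` and per-group DE attributes
    (``log2fc_<group>``, ``fdr_<group>``, ``selected_<group>``); edges
    carry ``score`` (STRING combined score in [0, 1]).  ``kind`` is
    "category_union" for the all-groups network or "group_subnetwork" for
    a single group's induced subgraph.
    """

    graph: nx.Graph
    name: str
    kind: str
    group: str | None = None
    mapping_report: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def write_graphml(self, path: str | Path) -> Path:
        path = Path(path)
        g = self.graph.copy()
        for _, attrs in g.nodes(data=True):  # GraphML cannot hold None
            for k, v in list(attrs.items()):
                if v is None:
                    del attrs[k]
        nx.write_graphml(g, path)
        return path

    def write_sif(self, path: str | Path) -> Path:
        path = Path(path)
        lines = [f"{u}\tinteracts\t{v}" for u, v in sorted(self.graph.edges())]
        lines += [f"{n}" for n in sorted(self.graph.nodes()) if self.graph.degree(n) == 0]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        return path

    def node_table(self) -> pd.DataFrame:
        """Long-format node attributes: one row per (node, group) with DE stats."""
        rows = []
        for n, attrs in self.graph.nodes(data=True):
            for key, val in attrs.items():
                if key.startswith("log2fc_"):
                    grp = key[len("log2fc_"):]
                    rows.append({
                        "protein": n,
                        "gene": attrs.get("gene", n),
                        "group": grp,
                        "log2FC": val,
                        "FDR": attrs.get(f"fdr_{grp}"),
                        "selected": bool(attrs.get(f"selected_{grp}", False)),
                    })
        return pd.DataFrame(rows, columns=["protein", "gene", "group",
                                           "log2FC", "FDR", "selected"])

    def edge_table(self) -> pd.DataFrame:
        rows = [{"source": u, "target": v, "score": d["score"]}
                for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["source", "target", "score"])


# ---------------------------------------------------------------------------
# Marker selection
# ---------------------------------------------------------------------------


def select_markers(table: DiffExpTable, config: NetworkConfig | None = None) -> MarkerSelection:
    """Filter-sort-truncate the DE table into per-group marker lists.

    Keeps records with ``passed_filters``, FDR <= ``fdr_cutoff`` and
    |log2FC| >= ``log2fc_cutoff`` (log2FC > 0 only when ``positive_only``),
    ranks by (FDR ascending, |log2FC| descending, gene id) and truncates to
    ``max_genes`` per group.  A group with no qualifying gene yields an
    empty list and a warning -- its subnetwork will be empty.
    """
    config = config or NetworkConfig()
    per_group: dict[str, pd.DataFrame] = {}
    for group in table.groups:
        df = table.for_group(group)
        mask = (
            df["passed_filters"]
            & (df["fdr"] <= config.fdr_cutoff)
            & (df["log2fc"].abs() >= config.log2fc_cutoff)
        )
        if config.positive_only:
            mask &= df["log2fc"] > 0
        sel = df[mask].copy()
        sel["_abs_fc"] = sel["log2fc"].abs()
        sel = sel.sort_values(
            ["fdr", "_abs_fc", "gene"], ascending=[True, False, True]
        ).head(config.max_genes)
        if sel.empty:
            warnings.warn(
                f"group {group!r}: no gene passes the network-analysis cutoffs",
                stacklevel=2,
            )
        per_group[group] = sel[["gene", "log2fc", "fdr"]].reset_index(drop=True)
    return MarkerSelection(per_group=per_group, config=config)


# ---------------------------------------------------------------------------
# Interaction sources
# ---------------------------------------------------------------------------


@dataclass
class InteractionTable:
    """Offline STRING-style interaction source.

    ``edges`` has columns protein1, protein2, score (combined score scaled
    to [0, 1]); ``alias`` maps gene id to protein id (identity when no
    alias table accompanies the edge file).
    """

    edges: pd.DataFrame
    alias: dict[str, str] | None = None

    def protein_for(self, gene: str) -> str | None:
        if self.alias is None:
            return gene
        return self.alias.get(gene)


def read_string_edges(path: str | Path, alias_path: str | Path | None = None) -> InteractionTable:
    """Read a STRING protein.links-style table (TSV or whitespace-separated).

    Scores given as 0-1000 integers are rescaled to [0, 1]; 0-1 reals pass
    through.  The optional alias table is two columns: gene id, protein id.
    """
    path = Path(path)
    rows = []
    with path.open() as fh:
        header = fh.readline()
        delim = "\t" if "\t" in header else None  # None = any whitespace
        cols = header.split(delim)
        if len(cols) < 3:
            raise FormatError(f"{path}: expected >= 3 columns, got {len(cols)}")
        for line in fh:
            parts = line.split(delim)
            if len(parts) < 3 or not line.strip():
                continue
            rows.append((parts[0].strip(), parts[1].strip(), float(parts[2])))
    edges = pd.DataFrame(rows, columns=["protein1", "protein2", "score"])
    if not edges.empty and edges["score"].max() > 1.0:
        edges["score"] /= 1000.0
    alias = None
    if alias_path is not None:
        alias = {}
        with Path(alias_path).open() as fh:
            reader = csv.reader(fh, delimiter="\t")
            for row in reader:
                if len(row) >= 2:
                    alias[row[0].strip()] = row[1].strip()
    return InteractionTable(edges=edges, alias=alias)


class StringApiClient:
    """Thin live client for the STRING network endpoint.

    Queries carry the species, the concatenated gene list, ``limit=0`` (no
    added interactors) and ``includesViruses=false``; STRING's own resolver
    maps gene identifiers to proteins.  Returns an
    :class:`InteractionTable`; intended for interactive use, not the test
    suite (which runs offline).
    """

    BASE = "https://string-db.org/api/json/network"

    def __init__(self, species: int | str, timeout: float = 60.0, opener=None):
        self.species = species
        self.timeout = timeout
        self._opener = opener or urllib.request.urlopen

    def fetch_interactions(self, genes: list[str]) -> InteractionTable:
        params = {
            "identifiers": "\r".join(genes),
            "species": str(self.species),
            "limit": "0",
            "includesViruses": "false",
            "caller_identity": "scnetkit",
        }
        url = self.BASE + "?" + urllib.parse.urlencode(params)
        try:
            with self._opener(url, timeout=self.timeout) as resp:
                payload = json.loads(resp.read().decode("utf-8"))
        except Exception as exc:  # noqa: BLE001 - rewrap with endpoint context
            raise TransportError(f"STRING query failed at {self.BASE}: {exc}") from exc
        rows = [
            (e["preferredName_A"], e["preferredName_B"], float(e["score"]))
            for e in payload
        ]
        edges = pd.DataFrame(rows, columns=["protein1", "protein2", "score"])
        return InteractionTable(edges=edges, alias=None)


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------


def build_union_network(
    markers: MarkerSelection,
    interactions: InteractionTable,
    config: NetworkConfig | None = None,
    name: str = "category union",
) -> GeneNetwork:
    """The interaction network over the union of all groups' markers.

    Nodes are marker genes mapped to proteins; edges are interactions among
    mapped nodes with combined score >= ``string_score_cutoff`` (self-loops
    dropped).  Node attributes carry every group's log2FC/FDR for the gene.
    Genes that fail identifier mapping or have no qualifying edge are
    listed in ``mapping_report``.
    """
    config = config or markers.config
    genes = markers.all_genes()
    if not genes:
        raise EmptyNetworkError("no marker gene was selected for any group")

    protein_of: dict[str, str] = {}
    unresolved: list[str] = []
    for gene in genes:
        prot = interactions.protein_for(gene)
        if prot is None:
            unresolved.append(gene)
        else:
            protein_of[gene] = prot
    if not protein_of:
        raise EmptyNetworkError(
            f"none of the {len(genes)} marker genes mapped to a protein"
        )

    graph = nx.Graph(name=name)
    for gene, prot in protein_of.items():
        graph.add_node(prot, gene=gene, display_name=prot)
    for group, df in markers.per_group.items():
        sel = dict(zip(df["gene"], zip(df["log2fc"], df["fdr"])))
        for gene, prot in protein_of.items():
            if gene in sel:
                lfc, fdr = sel[gene]
                graph.nodes[prot][f"log2fc_{group}"] = float(lfc)
                graph.nodes[prot][f"fdr_{group}"] = float(fdr)
                graph.nodes[prot][f"selected_{group}"] = True

    node_set = set(graph.nodes)
    for p1, p2, score in interactions.edges.itertuples(index=False):
        if p1 == p2:
            continue
        if p1 in node_set and p2 in node_set and score >= config.string_score_cutoff:
            prev = graph.get_edge_data(p1, p2)
            if prev is None or prev["score"] < score:
                graph.add_edge(p1, p2, score=float(score))

    isolated = sorted(n for n in graph.nodes if graph.degree(n) == 0)
    report = {
        "unresolved_genes": unresolved,
        "unmapped_to_edges": isolated,
        "n_genes_queried": len(genes),
        "n_nodes": graph.number_of_nodes(),
    }
    return GeneNetwork(graph=graph, name=name, kind="category_union",
                       mapping_report=report)


def extract_group_subnetworks(
    union: GeneNetwork, markers: MarkerSelection
) -> list[GeneNetwork]:
    """Induced subgraph of the union network per group's marker list.

    Returns one subnetwork per group (possibly empty); together with the
    union this yields number-of-groups + 1 networks.
    """
    subnets = []
    gene_to_node = {d["gene"]: n for n, d in union.graph.nodes(data=True)}
    for group, df in markers.per_group.items():
        nodes = [gene_to_node[g] for g in df["gene"] if g in gene_to_node]
        sub = union.graph.subgraph(nodes).copy()
        subnets.append(GeneNetwork(
            graph=sub,
            name=f"{union.name} - group {group}",
            kind="group_subnetwork",
            group=group,
        ))
    return subnets
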