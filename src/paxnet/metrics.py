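"""Evaluation metrics for reconstructed networks.

The headline metric is input *coverage*: the percentage of input genes
present as nodes in the output graph, S = |ON| / |IG| x 100 with
ON ⊆ IG.  The remaining functions characterize graph topology the way
network-analysis reports for signed signaling graphs usually do
(components, diameter, characteristic path length, 2-cycles, clique
census, betweenness ranking), plus a raw local triad census — a simple
count of connected 3-node subgraph types, *not* a motif-significance
analysis against randomized ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

from .errors import UsageError
from .expansion import SynonymTable
from .graphs import InfluenceGraph


@dataclass
class CoverageReport:
    """Coverage of the input gene set by the output graph."""

    IG: frozenset[str]            # input genes
    ON: frozenset[str]            # input genes present in the output graph
    S: float                      # coverage percentage

    @property
    def S_rounded(self) -> int:
        """Coverage rounded to the nearest integer percent."""
        return int(round(self.S))


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    connected_components: int
    diameter: int
    characteristic_path_length: float
    avg_neighbors: float
    self_loops: int
    multi_edge_pairs: int
    two_cycle_fraction: float
    percent_shortest_paths: float
    clique_counts: dict[int, int] = field(default_factory=dict)
    max_clique_size: int = 0


def coverage(input_genes: set[str], graph: InfluenceGraph,
             synonyms: SynonymTable | None = None) -> CoverageReport:
    """Compute S = |ON| / |IG| x 100.

    With a synonym table, an input gene counts as present if any name of
    any gene it matches (canonical symbol or registered synonym) names a
    graph node — otherwise alias spelling would deflate ON arbitrarily.
    """
    if not input_genes:
        raise UsageError("input gene set must be non-empty")
    node_names = graph.node_names()
    on = set()
    for gene in input_genes:
        candidates = {gene}
        if synonyms is not None:
            for gid in synonyms.gene_ids(gene):
                candidates |= synonyms.names_for(gid)
        if candidates & node_names:
            on.add(gene)
    s = len(on) / len(input_genes) * 100.0
    return CoverageReport(IG=frozenset(input_genes), ON=frozenset(on), S=s)


def _influence_edges(graph: InfluenceGraph):
    """Non-membership (i.e. signed/unknown influence) edges."""
    return [e for e in graph.edges() if e.kind != "membership"]


def two_cycle_fraction(graph: InfluenceGraph) -> float:
    """Fraction of non-membership edges on a 2-cycle (A->B with B->A).

    Self-loops are not 2-cycles.  Returns 0.0 on an edgeless graph.
    """
    edges = _influence_edges(graph)
    if not edges:
        return 0.0
    pairs = {(e.source, e.target) for e in edges}
    in_cycle = sum(
        1 for e in edges
        if e.source != e.target and (e.target, e.source) in pairs
    )
    return in_cycle / len(edges)


def _undirected_simple(graph: InfluenceGraph) -> nx.Graph:
    """Undirected simple projection: signs/directions/multiedges collapsed."""
    g = nx.Graph()
    g.add_nodes_from(graph.node_names())
    for e in graph.edges():
        if e.source != e.target:
            g.add_edge(e.source, e.target)
    return g


def _directed_simple(graph: InfluenceGraph) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(graph.node_names())
    for e in graph.edges():
        g.add_edge(e.source, e.target)
    return g


def clique_census(graph: InfluenceGraph, max_size: int = 5) -> tuple[dict[int, int], int]:
    """Count all cliques (complete subgraphs) of sizes 3..max_size.

    Computed on the undirected simple projection.  Returns the per-size
    counts and the maximal clique size found anywhere in the graph.
    """
    if max_size < 3:
        raise UsageError("max_size must be >= 3")
    g = _undirected_simple(graph)
    counts = {size: 0 for size in range(3, max_size + 1)}
    max_clique = min(2, g.number_of_nodes())
    for clique in nx.enumerate_all_cliques(g):
        size = len(clique)
        max_clique = max(max_clique, size)
        if 3 <= size <= max_size:
            counts[size] += 1
    return counts, max_clique


def topology_summary(graph: InfluenceGraph, clique_max_size: int = 5) -> TopologySummary:
    """Standard topology report for a signed directed multigraph.

    Path statistics (diameter, characteristic path length, percentage of
    shortest paths) use directed shortest paths over the simple
    projection and consider only finite distances between distinct
    nodes; on a disconnected graph this amounts to computing the
    diameter within components (effectively the largest one).
    Connected components are counted on the undirected projection.
    """
    und = _undirected_simple(graph)
    dirg = _directed_simple(graph)
    n_nodes = graph.n_nodes
    n_edges = graph.n_edges

    components = nx.number_connected_components(und) if n_nodes else 0

    finite = []
    for source, lengths in nx.all_pairs_shortest_path_length(dirg):
        for target, dist in lengths.items():
            if source != target:
                finite.append(dist)
    diameter = max(finite) if finite else 0
    cpl = sum(finite) / len(finite) if finite else 0.0
    ordered_pairs = n_nodes * (n_nodes - 1)
    pct_paths = len(finite) / ordered_pairs if ordered_pairs else 0.0

    avg_neighbors = (
        sum(d for _, d in und.degree()) / n_nodes if n_nodes else 0.0
    )

    self_loops = sum(1 for e in graph.edges() if e.source == e.target)
    pair_counts: dict[frozenset, int] = {}
    for e in graph.edges():
        if e.source != e.target:
            key = frozenset((e.source, e.target))
            pair_counts[key] = pair_counts.get(key, 0) + 1
    multi_pairs = sum(1 for c in pair_counts.values() if c > 1)

    counts, max_clique = clique_census(graph, clique_max_size)

    return TopologySummary(
        n_nodes=n_nodes,
        n_edges=n_edges,
        connected_components=components,
        diameter=diameter,
        characteristic_path_length=cpl,
        avg_neighbors=avg_neighbors,
        self_loops=self_loops,
        multi_edge_pairs=multi_pairs,
        two_cycle_fraction=two_cycle_fraction(graph),
        percent_shortest_paths=pct_paths,
        clique_counts=counts,
        max_clique_size=max_clique,
    )


def betweenness_top_k(graph: InfluenceGraph, k: int = 10) -> list[tuple[str, float, int]]:
    """Top-k nodes by shortest-path betweenness centrality.

    Computed on the largest (weakly) connected component of the directed
    simple projection; ties are broken lexicographically.  Each entry
    carries the node's neighbor count (distinct neighbors, either
    direction) for centrality-vs-degree scatter plots.
    """
    if k < 1:
        raise UsageError("k must be >= 1")
    dirg = _directed_simple(graph)
    if dirg.number_of_nodes() == 0:
        return []
    largest = max(nx.weakly_connected_components(dirg), key=len)
    sub = dirg.subgraph(largest)
    scores = nx.betweenness_centrality(sub, normalized=True)
    neighbor_counts = {
        n: len((set(sub.predecessors(n)) | set(sub.successors(n))) - {n})
        for n in sub
    }
    ranked = sorted(scores.items(), key=lambda item: (-item[1], item[0]))
    return [(name, score, neighbor_counts[name]) for name, score in ranked[:k]]


def local_triad_census(graph: InfluenceGraph) -> dict[str, int]:
    """Raw census of connected 3-node subgraph types (triad codes).

    A plain local count over the directed simple projection using the
    standard 16-type triad classification, reported only for the
    connected types.  This is a descriptive census, not a motif
    z-score analysis against randomized networks.
    """
    dirg = _directed_simple(graph)
    dirg.remove_edges_from(nx.selfloop_edges(dirg))
    census = nx.triadic_census(dirg)
    # drop the types in which the three nodes do not form one connected piece
    not_connected = {"003", "012", "102"}
    return {code: n for code, n in census.items()
            if code not in not_connected and n > 0}


def write_topology_report(summary: TopologySummary, path: str) -> None:
    """Write a two-column TSV topology report."""
    rows = [
        ("N. Nodes", summary.n_nodes),
        ("N. Edges", summary.n_edges),
        ("Connected components", summary.connected_components),
        ("Network diameter", summary.diameter),
        ("Percentage of shortest paths", f"{summary.percent_shortest_paths:.2%}"),
        ("Characteristic path length", f"{summary.characteristic_path_length:.4g}"),
        ("Avg. number of neighbors", f"{summary.avg_neighbors:.4g}"),
        ("Self-loops", summary.self_loops),
        ("Multi-edge node pairs", summary.multi_edge_pairs),
        ("Two-cycle edge fraction", f"{summary.two_cycle_fraction:.4g}"),
        ("Maximal clique size", summary.max_clique_size),
    ]
    for size, count in sorted(summary.clique_counts.items()):
        rows.append((f"Cliques of size {size}", count))
    with open(path, "w") as fh:
        fh.write("property\tvalue\n")
        for name, value in rows:
            fh.write(f"{name}\t{value}\n")
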