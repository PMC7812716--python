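"""Network unification and output formats.

*Unification* merges graph nodes that are synonyms of the same gene into
a single node carrying the canonical symbol, as registered in an NCBI
gene_info-style table.  It is a post-processing on the finished graph;
a run always keeps both forms, unified and non-unified.

Exports:

* SIF (``source<TAB>RELATION<TAB>target``), the Cytoscape simple
  interaction format, plus a TSV edge-attribute table with kind and
  provenance;
* a three-column signed-network table (``source  sign  target`` with
  signs ``+``/``-``) for sign-consistency tools, where PART_OF complex
  membership maps to ``+`` (complex formation treated as a positive
  influence) or is dropped;
* GraphML for the reaction hypergraph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .errors import ExportError
from .expansion import SynonymTable
from .graphs import HyperGraph, InfluenceGraph

logger = logging.getLogger(__name__)


@dataclass
class UnificationReport:
    """What :func:`unify_graph` merged, skipped, and why."""

    merges: dict[str, str] = field(default_factory=dict)   # alias -> canonical
    ambiguous: set[str] = field(default_factory=set)
    node_count_before: int = 0
    node_count_after: int = 0


def unify_graph(graph: InfluenceGraph,
                table: SynonymTable) -> tuple[InfluenceGraph, UnificationReport]:
    """Merge synonym nodes into canonical-symbol nodes.

    A node is renamed to a canonical symbol when its name matches exactly
    one gene in the table.  Names matching several genes are left alone
    and reported as ambiguous.  A merge that would fuse entities of
    conflicting classes (e.g. a complex with a protein) is refused and
    logged.  The input graph is not modified.
    """
    report = UnificationReport(node_count_before=graph.n_nodes)
    rename: dict[str, str] = {}
    classes = {name: graph.entity(name).entity_class for name in graph.node_names()}
    for name in sorted(graph.node_names()):
        gene_ids = table.gene_ids(name)
        if len(gene_ids) > 1:
            report.ambiguous.add(name)
            continue
        if not gene_ids:
            continue
        canonical = table.canonical_symbol(next(iter(gene_ids)))
        if canonical == name:
            continue
        existing = classes.get(canonical)
        mine = classes[name]
        if (existing is not None and existing != "unknown"
                and mine != "unknown" and existing != mine):
            logger.warning("refusing to merge %r into %r: class %s vs %s",
                           name, canonical, mine, existing)
            continue
        rename[name] = canonical
        report.merges[name] = canonical

    unified = InfluenceGraph()
    for name in sorted(graph.node_names()):
        ent = graph.entity(name)
        new_name = rename.get(name, name)
        aliases = set(ent.aliases)
        if new_name != name:
            aliases.add(name)
        unified.add_entity(new_name, ent.entity_class, aliases)
    for edge in graph.edges():
        unified.add_edge(rename.get(edge.source, edge.source),
                         rename.get(edge.target, edge.target),
                         edge.sign, edge.kind, set(edge.provenance))
    report.node_count_after = unified.n_nodes
    return unified, report


def to_influence_graph(h: HyperGraph) -> InfluenceGraph:
    """Compile a reaction hypergraph down to a signed influence graph.

    Every controller of a reaction gets one signed edge (its control
    sign) to every product / right-hand participant; member-of links on
    complex-assembly nodes become PART_OF edges onto the assembled
    complex; reaction nodes disappear.
    """
    graph = InfluenceGraph()
    g = h.nx
    for name in sorted(h.entity_nodes()):
        graph.add_entity(name, g.nodes[name].get("entity_class", "unknown"))
    for reaction in sorted(h.reaction_nodes()):
        kind = g.nodes[reaction]["kind"]
        products = ([n for n, _ in h.participations(reaction, "product-of")]
                    + [n for n, _ in h.participations(reaction, "right-of")])
        if kind == "complex_assembly":
            for member, _ in h.participations(reaction, "member-of"):
                for complex_name in products:
                    graph.add_edge(member, complex_name, "PART_OF", "membership")
            continue
        for controller, sign in h.participations(reaction, "controller-of"):
            for product in products:
                graph.add_edge(controller, product, sign or "UNKNOWN", kind)
    return graph


# ----------------------------------------------------------------------
def _sif_lines(graph: InfluenceGraph) -> list[str]:
    return sorted(
        f"{e.source}\t{e.sign}\t{e.target}" for e in graph.edges()
    )


def export_sif(graph: InfluenceGraph, path: str) -> None:
    """Write the graph as SIF plus a ``<path>.attrs.tsv`` attribute table."""
    try:
        with open(path, "w") as fh:
            for line in _sif_lines(graph):
                fh.write(line + "\n")
        with open(str(path) + ".attrs.tsv", "w") as fh:
            fh.write("source\trelation\ttarget\tkind\tprovenance\n")
            for edge in sorted(graph.edges()):
                provenance = ",".join(sorted(edge.provenance))
                fh.write(f"{edge.source}\t{edge.sign}\t{edge.target}"
                         f"\t{edge.kind}\t{provenance}\n")
    except OSError as exc:
        raise ExportError(f"cannot write SIF to {path}: {exc}") from exc


def parse_sif(path: str) -> InfluenceGraph:
    """Re-read a SIF file written by :func:`export_sif` (attrs included
    when the companion table is present)."""
    graph = InfluenceGraph()
    try:
        with open(str(path) + ".attrs.tsv") as fh:
            header = fh.readline()
            for line in fh:
                source, sign, target, kind, provenance = line.rstrip("\n").split("\t")
                prov = set(provenance.split(",")) if provenance else set()
                graph.add_edge(source, target, sign, kind, prov)
        return graph
    except FileNotFoundError:
        pass
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            source, sign, target = line.rstrip("\n").split("\t")
            kind = "membership" if sign == "PART_OF" else "unknown"
            graph.add_edge(source, target, sign, kind)
    return graph


_SIGN_MAP = {"ACTIVATION": "+", "INHIBITION": "-"}


def export_signed_network(graph: InfluenceGraph, path: str,
                          part_of_sign: str = "plus",
                          drop_unknown: bool = True) -> None:
    """Write a 3-column (source, sign, target) table for modeling tools.

    ACTIVATION -> ``+``, INHIBITION -> ``-``.  PART_OF membership maps to
    ``+`` when ``part_of_sign="plus"`` (complex formation as positive
    influence), and is omitted when ``part_of_sign="drop"`` for tools
    that cannot handle complexes.  UNKNOWN edges are omitted when
    ``drop_unknown``; otherwise their presence is an error, since an
    unsigned edge has no representation in this format.
    """
    if part_of_sign not in ("plus", "drop"):
        raise ExportError(f"part_of_sign must be 'plus' or 'drop', got {part_of_sign!r}")
    rows = []
    for edge in sorted(graph.edges()):
        if edge.sign == "PART_OF":
            if part_of_sign == "plus":
                rows.append((edge.source, "+", edge.target))
            continue
        if edge.sign == "UNKNOWN":
            if drop_unknown:
                continue
            raise ExportError(
                "graph contains UNKNOWN-signed edges; filter them "
                "(filter_unsigned / drop_unknown) before export"
            )
        rows.append((edge.source, _SIGN_MAP[edge.sign], edge.target))
    try:
        with open(path, "w") as fh:
            fh.write("source\tsign\ttarget\n")
            for source, sign, target in rows:
                fh.write(f"{source}\t{sign}\t{target}\n")
    except OSError as exc:
        raise ExportError(f"cannot write signed network to {path}: {exc}") from exc


def export_hypergraph_graphml(h: HyperGraph, path: str) -> None:
    """Write the bipartite entity/reaction hypergraph as GraphML."""
    g = nx.MultiDiGraph()
    for node, data in h.nx.nodes(data=True):
        g.add_node(node, **{k: str(v) for k, v in data.items()})
    for u, v, data in h.nx.edges(data=True):
        g.add_edge(u, v, **{k: str(v2) for k, v2 in data.items() if v2 is not None})
    try:
        nx.write_graphml(g, path)
    except OSError as exc:
        raise ExportError(f"cannot write GraphML to {path}: {exc}") from exc
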