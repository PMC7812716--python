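"""Recursive upstream network assembly.

Starting from a list of gene or protein names (level 0), each round
queries the knowledge base for interactions whose *target* is on the
current frontier, adds the hits as signed edges, and promotes the newly
seen upstream entities (controllers, reaction substrates, complex
members) to the next frontier.  Exploration stops when no new
controllers can be found or the maximum depth is reached.

Names are expanded (synonyms, decorated labels) *before* querying and
normalized (decorations stripped) *before* node creation, so the graph
carries canonical names while the queries cast a wide net.  An entity is
queried at most once ever — a global visited set guarantees termination
even on cyclic knowledge bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import UsageError
from .expansion import (
    ExpansionConfig,
    SynonymTable,
    decompose_complex_label,
    expand_labels,
    expand_synonyms,
    strip_decorations,
)
from .graphs import HyperGraph, InfluenceGraph, SignedEdge
from .kb_access import BP, KnowledgeBase
from .metrics import CoverageReport, coverage
from .query_patterns import (
    PART_OF,
    UNKNOWN,
    QueryBatch,
    RawInteraction,
    build_regulation_query,
    build_signaling_query,
    chunk_names,
    parse_bindings,
)

logger = logging.getLogger(__name__)

_COMPONENT_QUERY = (
    f"PREFIX bp: <{BP}>\n"
    "SELECT ?memberName ?memberClass WHERE {{\n"
    "  <{iri}> bp:component ?member .\n"
    "  ?member bp:displayName ?memberName .\n"
    "  OPTIONAL {{ ?member a ?memberClass .\n"
    "             VALUES ?memberClass {{ bp:Protein bp:SmallMolecule bp:Complex }} }}\n"
    "}}"
)


@dataclass
class AssemblyState:
    """Mutable exploration state between frontier steps."""

    frontier: list[str]
    explored: set[str] = field(default_factory=set)
    depth: int = 0
    edges: dict[tuple[str, str, str, str], set[str]] = field(default_factory=dict)
    entities: dict[str, str] = field(default_factory=dict)   # name -> entity class
    hypergraph: HyperGraph = field(default_factory=HyperGraph)
    log: list[dict] = field(default_factory=list)


@dataclass
class AssemblyResult:
    """Everything one reconstruction run produces."""

    influence_graph: InfluenceGraph
    hypergraph: HyperGraph
    coverage: CoverageReport
    provenance_histogram: dict[str, int]
    levels_run: int
    log: list[dict] = field(default_factory=list)


def _record_entity(state: AssemblyState, name: str, entity_class: str) -> None:
    current = state.entities.get(name)
    if current is None or current == "unknown":
        state.entities[name] = entity_class
    elif entity_class not in ("unknown", current):
        logger.warning("entity %r: class conflict %s vs %s; keeping first",
                       name, current, entity_class)


def _record_edge(state: AssemblyState, source: str, target: str, sign: str,
                 kind: str, provenance: set[str]) -> None:
    state.edges.setdefault((source, target, sign, kind), set()).update(provenance)


def _complex_members(kb: KnowledgeBase, interaction: RawInteraction,
                     config: ExpansionConfig) -> tuple[list[str], list[str]]:
    """Member names of a complex controller and their classes.

    Explicit BioPAX component links are preferred; the delimiter-joined
    label is the syntactic fallback.
    """
    if interaction.controller_iri:
        rows = kb.query(_COMPONENT_QUERY.format(iri=interaction.controller_iri))
        members, classes = [], []
        for row in rows:
            if row.get("memberName"):
                members.append(row["memberName"])
                classes.append(row.get("memberClass") or "")
        if members:
            order = sorted(range(len(members)), key=lambda i: members[i])
            return ([members[i] for i in order], [classes[i] for i in order])
    label_members = decompose_complex_label(interaction.controller_name,
                                            config.complex_delimiters)
    if label_members == [interaction.controller_name]:
        logger.warning("complex %r has neither component links nor a "
                       "decomposable label; no membership edges emitted",
                       interaction.controller_name)
        return [], []
    return label_members, [""] * len(label_members)


def add_complex_membership_edges(
    edges: set[SignedEdge],
    complex_name: str,
    member_names: list[str],
) -> tuple[set[SignedEdge], list[str]]:
    """PART_OF edges member -> complex for every member name.

    Returns the augmented edge set and the members, for frontier
    enqueueing.  Pure-set variant used directly in tests; the assembler
    applies the same rule through its accumulator.
    """
    out = set(edges)
    for member in member_names:
        out.add(SignedEdge(source=member, target=complex_name, sign=PART_OF,
                           kind="membership"))
    return out, list(member_names)


def step_frontier(
    state: AssemblyState,
    kb: KnowledgeBase,
    network_kind: str,
    config: ExpansionConfig,
    excluded_sources: set[str] = frozenset(),
    synonyms: SynonymTable | None = None,
    drop_unknown: bool = False,
    chunk_size: int = 20,
) -> AssemblyState:
    """Run one exploration level: query the frontier, absorb the hits.

    The frontier names are expanded (synonyms, decorated labels) into the
    query batch; hit names are decoration-stripped before node creation.
    Complex controllers contribute PART_OF membership edges and enqueue
    their members when decomposition is on.
    """
    if not state.frontier:
        raise UsageError("frontier is empty")
    names = list(state.frontier)
    query_names = names
    if config.use_synonyms and synonyms is not None:
        query_names = expand_synonyms(query_names, synonyms)
    if config.use_label_expansion:
        query_names = expand_labels(query_names, config)

    build = (build_regulation_query if network_kind == "regulation"
             else build_signaling_query)
    parse_kind = "regulation" if network_kind == "regulation" else "signaling"

    interactions: set[RawInteraction] = set()
    for chunk in chunk_names(QueryBatch(names=query_names, chunk_size=chunk_size)):
        rows = kb.query(build(chunk, excluded_sources))
        interactions.update(parse_bindings(rows, parse_kind))

    new_names: list[str] = []
    n_edges_before = len(state.edges)
    for inter in sorted(interactions):
        if drop_unknown and inter.sign_token == UNKNOWN:
            continue
        source = strip_decorations(inter.controller_name, config)
        target = strip_decorations(inter.target_name, config)
        class_map = {
            "protein": "protein_or_gene",
            "complex": "complex",
            "small_molecule": "small_molecule",
        }
        source_class = class_map.get(inter.controller_class, "unknown")
        _record_entity(state, target, class_map.get(inter.target_class, "unknown"))
        _record_entity(state, source, source_class)
        _record_edge(state, source, target, inter.sign_token, inter.kind,
                     {inter.source_db})
        new_names.append(source)

        hg = state.hypergraph
        hg.add_reaction(inter.reaction_id, kind=inter.kind)
        hg.add_participation(source, inter.reaction_id, "controller-of",
                             sign=inter.sign_token)
        hg.add_participation(target, inter.reaction_id, "product-of")

        if source_class == "complex" and config.use_complex_decomposition:
            members, member_classes = _complex_members(kb, inter, config)
            if members:
                assembly_id = f"complex-assembly:{source}"
                hg.add_reaction(assembly_id, kind="complex_assembly")
                hg.add_participation(source, assembly_id, "product-of")
                if any("SmallMolecule" in c for c in member_classes):
                    state.entities[source] = "small_molecule_complex"
                for member, mclass in zip(members, member_classes):
                    member = strip_decorations(member, config)
                    cls = ("small_molecule" if "SmallMolecule" in mclass
                           else "protein_or_gene" if "Protein" in mclass
                           else "unknown")
                    _record_entity(state, member, cls)
                    _record_edge(state, member, source, PART_OF, "membership", set())
                    hg.add_participation(member, assembly_id, "member-of")
                    new_names.append(member)

    state.explored.update(names)
    frontier_next = sorted({n for n in new_names if n not in state.explored})
    state.frontier = frontier_next
    state.depth += 1
    state.log.append({
        "level": state.depth,
        "queried_names": len(names),
        "new_edges": len(state.edges) - n_edges_before,
        "frontier_next": len(frontier_next),
    })
    logger.info("level %d: queried %d names, %d new edges, next frontier %d",
                state.depth, len(names), len(state.edges) - n_edges_before,
                len(frontier_next))
    return state


def filter_unsigned(edges: set[SignedEdge]) -> set[SignedEdge]:
    """Drop UNKNOWN-signed edges; signed and PART_OF edges are kept."""
    return {e for e in edges if e.sign != UNKNOWN}


def reconstruct(
    kb: KnowledgeBase,
    genes: list[str],
    network_kind: str = "regulation",
    max_depth: int = 10,
    config: ExpansionConfig | None = None,
    excluded_sources: set[str] = frozenset(),
    drop_unknown: bool = False,
    synonyms: SynonymTable | None = None,
    chunk_size: int = 20,
) -> AssemblyResult:
    """Assemble the upstream network of ``genes``.

    Parameters
    ----------
    kb:
        Knowledge base (local file or remote endpoint).
    genes:
        Input gene/protein names; they form exploration level 0.
    network_kind:
        ``"regulation"`` (transcriptional pattern) or ``"signaling"``.
    max_depth:
        Maximum number of query rounds (levels).
    config:
        Expansion configuration; defaults to all augmentations off.
    excluded_sources:
        Data-source names filtered out inside the queries.
    drop_unknown:
        Recover only signed interactions: UNKNOWN-signed hits are
        discarded as they arrive and do not extend the frontier.
    synonyms:
        Synonym table backing synonym expansion and coverage matching.

    Returns an :class:`AssemblyResult` with both graph forms, the input
    coverage, the per-source edge histogram and the number of levels run.
    """
    if not genes:
        raise UsageError("gene list must be non-empty")
    if network_kind not in ("regulation", "signaling"):
        raise UsageError(f"unknown network kind {network_kind!r}")
    if max_depth < 1:
        raise UsageError("max_depth must be >= 1")
    config = config or ExpansionConfig()

    state = AssemblyState(frontier=list(dict.fromkeys(genes)))
    while state.frontier and state.depth < max_depth:
        state = step_frontier(state, kb, network_kind, config,
                              excluded_sources=excluded_sources,
                              synonyms=synonyms, drop_unknown=drop_unknown,
                              chunk_size=chunk_size)

    graph = InfluenceGraph()
    for name in sorted(state.entities):
        graph.add_entity(name, state.entities[name])
    histogram: dict[str, int] = {}
    for (source, target, sign, kind), provenance in sorted(state.edges.items()):
        graph.add_edge(source, target, sign, kind, provenance)
        if kind != "membership":
            for db in provenance:
                histogram[db] = histogram.get(db, 0) + 1

    report = coverage(set(genes), graph, synonyms)
    return AssemblyResult(
        influence_graph=graph,
        hypergraph=state.hypergraph,
        coverage=report,
        provenance_histogram=histogram,
        levels_run=state.depth,
        log=state.log,
    )
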