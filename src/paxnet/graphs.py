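"""In-memory graph containers: signed influence graphs and reaction
hypergraphs.

Both wrap :class:`networkx.MultiDiGraph`.  The influence graph is the
entity-level view (signed, provenance-annotated edges between biological
entities); the hypergraph keeps the reaction nodes, as a bipartite graph
of entities and reactions joined by typed participation links.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

import networkx as nx

logger = logging.getLogger(__name__)

SIGN_TOKENS = ("ACTIVATION", "INHIBITION", "UNKNOWN", "PART_OF")

#: entity classes an influence-graph node may carry
ENTITY_CLASSES = (
    "protein_or_gene", "complex", "small_molecule_complex",
    "small_molecule", "unknown",
)

#: participation roles in the hypergraph (entity->reaction unless noted)
PARTICIPATION_ROLES = (
    "controller-of",   # entity -> reaction
    "left-of",         # entity -> reaction
    "member-of",       # entity -> reaction (complex-assembly pseudo-reaction)
    "product-of",      # reaction -> entity
    "right-of",        # reaction -> entity
)


@dataclass
class BioEntity:
    """A typed biological entity node."""

    name: str
    entity_class: str = "unknown"
    aliases: set[str] = field(default_factory=set)


@dataclass(frozen=True, order=True)
class SignedEdge:
    """A signed, provenance-annotated influence between two entities."""

    source: str
    target: str
    sign: str                                   # one of SIGN_TOKENS
    kind: str                                   # transcriptional|signaling|membership
    provenance: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.sign not in SIGN_TOKENS:
            raise ValueError(f"bad sign {self.sign!r}")


class InfluenceGraph:
    """Directed multigraph of entities with signed edges.

    Parallel edges with different signs are kept (contradictory reports
    from different databases are data, not noise); edges that coincide on
    (source, target, sign, kind) are merged with their provenance sets
    unioned.
    """

    def __init__(self):
        self._g = nx.MultiDiGraph()

    # -- construction ---------------------------------------------------
    def add_entity(self, name: str, entity_class: str = "unknown",
                   aliases: set[str] | None = None) -> BioEntity:
        if not name:
            raise ValueError("entity name must be non-empty")
        if name in self._g:
            ent: BioEntity = self._g.nodes[name]["entity"]
            if (entity_class != "unknown" and ent.entity_class == "unknown"):
                ent.entity_class = entity_class
            elif (entity_class not in ("unknown", ent.entity_class)):
                logger.warning("entity %r: class conflict %s vs %s; keeping first",
                               name, ent.entity_class, entity_class)
            if aliases:
                ent.aliases |= aliases
            return ent
        ent = BioEntity(name=name, entity_class=entity_class,
                        aliases=set(aliases or ()))
        self._g.add_node(name, entity=ent)
        return ent

    def add_edge(self, source: str, target: str, sign: str, kind: str,
                 provenance: set[str] | frozenset[str] = frozenset()) -> None:
        self.add_entity(source)
        self.add_entity(target)
        key = (sign, kind)
        if self._g.has_edge(source, target, key=key):
            self._g[source][target][key]["provenance"] |= set(provenance)
        else:
            self._g.add_edge(source, target, key=key, sign=sign, kind=kind,
                             provenance=set(provenance))

    # -- access ---------------------------------------------------------
    @property
    def nx(self) -> nx.MultiDiGraph:
        return self._g

    def entity(self, name: str) -> BioEntity:
        return self._g.nodes[name]["entity"]

    def node_names(self) -> set[str]:
        return set(self._g.nodes)

    def edges(self) -> Iterator[SignedEdge]:
        for u, v, data in self._g.edges(data=True):
            yield SignedEdge(source=u, target=v, sign=data["sign"],
                             kind=data["kind"],
                             provenance=frozenset(data["provenance"]))

    def edge_set(self) -> set[SignedEdge]:
        return set(self.edges())

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def copy(self) -> "InfluenceGraph":
        out = InfluenceGraph()
        for name in self._g.nodes:
            ent = self.entity(name)
            out.add_entity(name, ent.entity_class, set(ent.aliases))
        for edge in self.edges():
            out.add_edge(edge.source, edge.target, edge.sign, edge.kind,
                         set(edge.provenance))
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, InfluenceGraph):
            return NotImplemented
        return (self.node_names() == other.node_names()
                and self.edge_set() == other.edge_set())


class HyperGraph:
    """Bipartite entity/reaction graph preserving reaction nodes.

    Reaction nodes carry their BioPAX kind (template regulation,
    biochemical reaction control, or a complex-assembly pseudo-reaction
    standing for complex membership).  Participation edges are typed by
    role; entity-entity and reaction-reaction links never occur.
    """

    def __init__(self):
        self._g = nx.MultiDiGraph()

    def add_entity(self, name: str, entity_class: str = "unknown") -> None:
        if name not in self._g:
            self._g.add_node(name, bipartite="entity", entity_class=entity_class)

    def add_reaction(self, reaction_id: str, kind: str) -> None:
        if reaction_id not in self._g:
            self._g.add_node(reaction_id, bipartite="reaction", kind=kind)

    def add_participation(self, entity: str, reaction_id: str, role: str,
                          sign: str | None = None) -> None:
        if role not in PARTICIPATION_ROLES:
            raise ValueError(f"unknown participation role {role!r}")
        self.add_entity(entity)
        if reaction_id not in self._g:
            raise ValueError(f"unknown reaction {reaction_id!r}")
        if role in ("controller-of", "left-of", "member-of"):
            u, v = entity, reaction_id
        else:
            u, v = reaction_id, entity
        if not self._g.has_edge(u, v, key=role):
            self._g.add_edge(u, v, key=role, role=role, sign=sign)

    # -- access ---------------------------------------------------------
    @property
    def nx(self) -> nx.MultiDiGraph:
        return self._g

    def entity_nodes(self) -> set[str]:
        return {n for n, d in self._g.nodes(data=True) if d["bipartite"] == "entity"}

    def reaction_nodes(self) -> set[str]:
        return {n for n, d in self._g.nodes(data=True) if d["bipartite"] == "reaction"}

    def participations(self, reaction_id: str, role: str) -> list[tuple[str, str | None]]:
        """Entities joined to ``reaction_id`` with ``role`` (name, sign)."""
        out = []
        if role in ("controller-of", "left-of", "member-of"):
            for u, _, k, d in self._g.in_edges(reaction_id, keys=True, data=True):
                if d["role"] == role:
                    out.append((u, d.get("sign")))
        else:
            for _, v, k, d in self._g.out_edges(reaction_id, keys=True, data=True):
                if d["role"] == role:
                    out.append((v, d.get("sign")))
        return sorted(out)
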