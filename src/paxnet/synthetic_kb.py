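"""Synthetic BioPAX knowledge bases with planted ground truth.

The generator builds layered upstream-regulation networks and emits them
as BioPAX Level 3 RDF (Turtle-serializable): regulation fixtures use the
``TemplateReactionRegulation -> TemplateReaction -> product`` idiom,
signaling fixtures use ``Catalysis/Control -> BiochemicalReaction``.
Complexes carry *both* explicit ``component`` links and a
delimiter-joined label, so both decomposition code paths are exercised.
Aliases are planted as additional ``name`` literals (the display name
stays canonical) and recorded in a companion gene_info-format synonym
file; decorated entities carry a display name like ``expression of X``.

All randomness flows from ``KbSpec.seed`` through one named RNG
(:class:`random.Random`, a Mersenne Twister), so a spec generates the
same knowledge base and ground truth every time.

:func:`ground_truth_upstream` is an independent brute-force oracle: a
breadth-first upstream closure over the planted edge table, used to
check the assembler's output exactly.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import rdflib
from rdflib import Literal, Namespace, RDF, URIRef

from .errors import UsageError
from .kb_access import BP, KnowledgeBase

BPNS = Namespace(BP)
EX = Namespace("http://example.org/kb/")

ACTIVATION = "ACTIVATION"
INHIBITION = "INHIBITION"
UNKNOWN = "UNKNOWN"
PART_OF = "PART_OF"


@dataclass
class KbSpec:
    """Parameters of a planted upstream network.

    ``branching`` is the mean number of upstream regulators added per
    node and level (at least one, so every non-leaf level grows);
    ``p_inhibition``/``p_unknown`` are per-edge sign probabilities, the
    remainder being activations.
    """

    n_genes: int = 5
    n_levels: int = 3
    branching: float = 1.0
    p_inhibition: float = 0.2
    p_unknown: float = 0.0
    n_complexes: int = 0
    complex_size: tuple[int, int] = (2, 3)
    n_aliases: int = 0
    n_decorated: int = 0
    source_names: tuple[str, ...] = ("ctd", "pid", "panther")
    seed: int = 0
    kind: str = "regulation"      # regulation | signaling
    reuse_probability: float = 0.0   # chance a regulator reuses an existing node

    def __post_init__(self):
        if self.n_genes < 1 or self.n_levels < 0:
            raise UsageError("n_genes >= 1 and n_levels >= 0 required")
        if not (0 <= self.p_inhibition <= 1 and 0 <= self.p_unknown <= 1
                and self.p_inhibition + self.p_unknown <= 1):
            raise UsageError("sign probabilities must be in [0,1] and sum <= 1")
        if self.branching < 1:
            raise UsageError("branching must be >= 1")
        if min(self.n_complexes, self.n_aliases, self.n_decorated) < 0:
            raise UsageError("counts must be >= 0")
        if self.complex_size[0] < 2 or self.complex_size[1] < self.complex_size[0]:
            raise UsageError("complex_size must be a range with lower bound >= 2")
        if self.kind not in ("regulation", "signaling"):
            raise UsageError(f"unknown kind {self.kind!r}")
        if not self.source_names:
            raise UsageError("at least one source name required")


@dataclass
class GroundTruth:
    """Exactly what was planted, independent of the RDF emission."""

    input_genes: list[str] = field(default_factory=list)
    upstream_edges: set[tuple[str, str, str, str, str]] = field(default_factory=set)
    # (source, target, sign, kind, source_db); kind is transcriptional|signaling
    complexes: dict[str, list[str]] = field(default_factory=dict)
    aliases: dict[str, str] = field(default_factory=dict)       # alias -> canonical
    decorated: dict[str, str] = field(default_factory=dict)     # decorated -> canonical
    depth_of: dict[str, int] = field(default_factory=dict)

    def all_names(self) -> set[str]:
        names = set(self.depth_of)
        for members in self.complexes.values():
            names |= set(members)
        return names


def _poisson(rng: random.Random, lam: float) -> int:
    """Knuth's poisson sampler (small lambda only)."""
    if lam <= 0:
        return 0
    threshold = pow(2.718281828459045, -lam)
    k, product = 0, 1.0
    while True:
        product *= rng.random()
        if product <= threshold:
            return k
        k += 1


def _draw_sign(rng: random.Random, spec: KbSpec) -> str:
    u = rng.random()
    if u < spec.p_inhibition:
        return INHIBITION
    if u < spec.p_inhibition + spec.p_unknown:
        return UNKNOWN
    return ACTIVATION


def generate_kb(spec: KbSpec) -> tuple[KnowledgeBase, GroundTruth]:
    """Generate a planted knowledge base and its ground truth.

    Returns ``(kb, truth)`` where ``kb`` is a local-mode KnowledgeBase
    whose triples realize exactly the interactions in ``truth``.
    """
    rng = random.Random(spec.seed)
    truth = GroundTruth()

    inputs = [f"G{index:03d}" for index in range(spec.n_genes)]
    truth.input_genes = list(inputs)
    for name in inputs:
        truth.depth_of[name] = 0

    kind_token = "transcriptional" if spec.kind == "regulation" else "signaling"
    node_counter = 0
    complexes_left = spec.n_complexes
    levels: list[list[str]] = [list(inputs)]

    for level in range(1, spec.n_levels + 1):
        new_level: list[str] = []
        for target in levels[level - 1]:
            n_regulators = 1 + _poisson(rng, spec.branching - 1.0)
            for _ in range(n_regulators):
                reuse_pool = [n for n in truth.depth_of
                              if n != target and n not in truth.complexes]
                if reuse_pool and rng.random() < spec.reuse_probability:
                    source = rng.choice(sorted(reuse_pool))
                elif complexes_left > 0:
                    size = rng.randint(*spec.complex_size)
                    members = []
                    for _ in range(size):
                        node_counter += 1
                        members.append(f"M{node_counter:03d}")
                    source = "/".join(members)
                    truth.complexes[source] = members
                    truth.depth_of[source] = level
                    complexes_left -= 1
                    new_level.append(source)
                else:
                    node_counter += 1
                    source = f"N{node_counter:03d}"
                    truth.depth_of[source] = level
                    new_level.append(source)
                truth.upstream_edges.add((
                    source, target, _draw_sign(rng, spec), kind_token,
                    rng.choice(sorted(spec.source_names)),
                ))
        levels.append(new_level)

    # decorate / alias plain upstream (non-input, non-complex) proteins
    plain = sorted(n for n, d in truth.depth_of.items()
                   if d > 0 and n not in truth.complexes)
    rng.shuffle(plain)
    for name in plain[:spec.n_decorated]:
        truth.decorated[f"expression of {name}"] = name
    remaining = plain[spec.n_decorated:]
    for name in remaining[:spec.n_aliases]:
        truth.aliases[f"{name}ALT"] = name

    graph = _emit_rdf(spec, truth)
    return KnowledgeBase(graph=graph), truth


def _entity_iri(name: str, registry: dict[str, URIRef]) -> URIRef:
    if name not in registry:
        registry[name] = EX[f"entity{len(registry):04d}"]
    return registry[name]


def _emit_rdf(spec: KbSpec, truth: GroundTruth) -> rdflib.Graph:
    g = rdflib.Graph()
    g.bind("bp", BPNS)
    g.bind("ex", EX)
    registry: dict[str, URIRef] = {}
    decorated_of = {v: k for k, v in truth.decorated.items()}
    aliases_of: dict[str, list[str]] = {}
    for alias, canonical in truth.aliases.items():
        aliases_of.setdefault(canonical, []).append(alias)

    def declare_entity(name: str) -> URIRef:
        iri = _entity_iri(name, registry)
        if (iri, RDF.type, None) in g:
            return iri
        if name in truth.complexes:
            g.add((iri, RDF.type, BPNS.Complex))
            g.add((iri, BPNS.displayName, Literal(name)))
            for member in truth.complexes[name]:
                g.add((iri, BPNS.component, declare_entity(member)))
        else:
            g.add((iri, RDF.type, BPNS.Protein))
            display = decorated_of.get(name, name)
            g.add((iri, BPNS.displayName, Literal(display)))
            for alias in aliases_of.get(name, []):
                g.add((iri, BPNS.name, Literal(alias)))
        return iri

    sources: dict[str, URIRef] = {}

    def source_iri(db: str) -> URIRef:
        if db not in sources:
            iri = EX[f"source-{db}"]
            g.add((iri, RDF.type, BPNS.Provenance))
            g.add((iri, BPNS.displayName, Literal(db)))
            sources[db] = iri
        return sources[db]

    for index, (source, target, sign, kind, db) in enumerate(
            sorted(truth.upstream_edges)):
        source_ent = declare_entity(source)
        target_ent = declare_entity(target)
        if spec.kind == "regulation":
            regulation = EX[f"regulation{index:05d}"]
            template = EX[f"template{index:05d}"]
            g.add((regulation, RDF.type, BPNS.TemplateReactionRegulation))
            g.add((regulation, BPNS.controlled, template))
            g.add((regulation, BPNS.controller, source_ent))
            g.add((template, RDF.type, BPNS.TemplateReaction))
            g.add((template, BPNS.product, target_ent))
            interaction = regulation
        else:
            control = EX[f"catalysis{index:05d}"]
            conversion = EX[f"reaction{index:05d}"]
            g.add((control, RDF.type, BPNS.Catalysis))
            g.add((control, BPNS.controlled, conversion))
            g.add((control, BPNS.controller, source_ent))
            g.add((conversion, RDF.type, BPNS.BiochemicalReaction))
            g.add((conversion, BPNS.right, target_ent))
            interaction = control
        if sign != UNKNOWN:
            g.add((interaction, BPNS.controlType, Literal(sign)))
        g.add((interaction, BPNS.dataSource, source_iri(db)))
    return g


def ground_truth_upstream(
    truth: GroundTruth,
    genes: set[str],
    depth: int,
    drop_unknown: bool = False,
) -> set[tuple[str, str, str, str, str | None]]:
    """Brute-force BFS upstream closure over the planted edge table.

    Expected edge tuples are ``(source, target, sign, kind, source_db)``
    with canonical names; complex members contribute
    ``(member, complex, PART_OF, membership, None)`` edges and join the
    next frontier.  Aliases and decorations in ``genes`` are resolved to
    canonical names first.  With ``drop_unknown``, UNKNOWN-signed edges
    are skipped and do not extend the frontier.
    """
    resolve = {}
    resolve.update(truth.aliases)
    resolve.update(truth.decorated)
    frontier = {resolve.get(g, g) for g in genes}
    explored: set[str] = set()
    expected: set[tuple[str, str, str, str, str | None]] = set()
    for _ in range(depth):
        if not frontier:
            break
        explored |= frontier
        upstream: set[str] = set()
        for source, target, sign, kind, db in truth.upstream_edges:
            if target not in frontier:
                continue
            if drop_unknown and sign == UNKNOWN:
                continue
            expected.add((source, target, sign, kind, db))
            upstream.add(source)
            if source in truth.complexes:
                for member in truth.complexes[source]:
                    expected.add((member, source, PART_OF, "membership", None))
                    upstream.add(member)
        frontier = upstream - explored
    return expected


def influence_edge_tuples(graph) -> set[tuple[str, str, str, str, str | None]]:
    """Flatten an InfluenceGraph into per-provenance edge tuples.

    The shape matches :func:`ground_truth_upstream` output: one tuple per
    (edge, data source), with ``None`` for provenance-free membership
    edges — the form in which assembled graphs are compared against the
    planted ground truth.
    """
    out: set[tuple[str, str, str, str, str | None]] = set()
    for edge in graph.edges():
        if edge.provenance:
            for db in edge.provenance:
                out.add((edge.source, edge.target, edge.sign, edge.kind, db))
        else:
            out.add((edge.source, edge.target, edge.sign, edge.kind, None))
    return out


def generate_gene_list(n: int, seed: int = 0) -> list[str]:
    """``n`` distinct synthetic gene symbols, deterministic per seed."""
    if n < 1:
        raise UsageError("n must be >= 1")
    rng = random.Random(seed)
    names = [f"SYM{index:04d}" for index in range(n)]
    rng.shuffle(names)
    return names


def write_gene_list(names: list[str], path: str) -> None:
    """Write a single-column CSV gene list (one name per line)."""
    with open(path, "w") as fh:
        for name in names:
            fh.write(name + "\n")


def write_gene_info(truth: GroundTruth, path: str) -> None:
    """Write a gene_info-format synonym table covering the planted aliases."""
    aliases_of: dict[str, list[str]] = {}
    for alias, canonical in truth.aliases.items():
        aliases_of.setdefault(canonical, []).append(alias)
    with open(path, "w") as fh:
        fh.write("#tax_id\tGeneID\tSymbol\tSynonyms\n")
        for index, name in enumerate(sorted(truth.depth_of), start=1):
            if name in truth.complexes:
                continue
            synonyms = "|".join(sorted(aliases_of.get(name, []))) or "-"
            fh.write(f"9606\t{index}\t{name}\t{synonyms}\n")


def generate_drug_kb(
    drugs: list[tuple[str, str, str, list[str]]],
) -> KnowledgeBase:
    """Build a DrugBank-like RDF fixture.

    ``drugs`` rows are ``(drug_id, drug_name, status, target_gene_symbols)``;
    the emitted pattern is drug --target--> target-entity --gene-name-->
    symbol, with the drug's status on a group literal, mirroring the
    linked-data DrugBank layout.
    """
    dv = Namespace("http://bio2rdf.org/drugbank_vocabulary:")
    dcterms = Namespace("http://purl.org/dc/terms/")
    g = rdflib.Graph()
    for drug_id, drug_name, status, symbols in drugs:
        drug = URIRef(f"http://example.org/drug/{drug_id}")
        g.add((drug, RDF.type, dv.Drug))
        g.add((drug, dcterms.title, Literal(drug_name)))
        g.add((drug, dv.group, Literal(status)))
        for symbol in symbols:
            target = URIRef(f"http://example.org/drugtarget/{drug_id}-{symbol}")
            g.add((drug, dv.target, target))
            g.add((target, dv["gene-name"], Literal(symbol)))
    return KnowledgeBase(graph=g)
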