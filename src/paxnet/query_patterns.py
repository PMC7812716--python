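"""SPARQL pattern generation and result parsing.

Two BioPAX Level 3 idioms drive the whole reconstruction:

* **regulation** — a ``TemplateReactionRegulation`` whose controlled
  ``TemplateReaction`` produces an entity named in the query batch.  The
  controller is the transcription factor; ``controlType`` carries the
  sign.  This is the pattern behind gene-regulatory networks.
* **signaling** — a ``Control`` or ``Catalysis`` whose controlled
  ``BiochemicalReaction`` has a named entity among its right-hand
  (product) participants.  Upstream entities are the controllers plus
  the reaction's left-hand participants.

Both patterns match an entity through *either* its ``displayName`` or
any additional ``name`` literal, so synonym/label-expanded batches reach
as many entities as possible, and both filter out excluded data sources
(e.g. miRTarBase, MSigDB) directly in the query.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .errors import MalformedResultsError, UsageError
from .kb_access import BP, BindingsTable

ACTIVATION = "ACTIVATION"
INHIBITION = "INHIBITION"
UNKNOWN = "UNKNOWN"
PART_OF = "PART_OF"

#: rdf:type IRIs accepted for controllers, mapped to entity-class tokens.
_CONTROLLER_CLASSES = {
    BP + "Protein": "protein",
    BP + "Complex": "complex",
    BP + "SmallMolecule": "small_molecule",
}


@dataclass(frozen=True, order=True)
class RawInteraction:
    """One parsed query hit: an upstream influence on a named target."""

    controller_name: str
    target_name: str
    sign_token: str                 # ACTIVATION | INHIBITION | UNKNOWN
    kind: str                       # transcriptional | signaling
    source_db: str
    reaction_id: str
    controller_class: str = "unknown"   # protein|complex|small_molecule|unknown
    controller_iri: str | None = None
    target_class: str = "unknown"


@dataclass
class QueryBatch:
    """An ordered batch of entity names to query, split into chunks."""

    names: list[str]
    chunk_size: int = 20

    def __post_init__(self):
        if self.chunk_size < 1:
            raise UsageError("chunk_size must be >= 1")
        if len(set(self.names)) != len(self.names):
            raise UsageError("duplicate names within a QueryBatch")


def _escape(value: str) -> str:
    return value.replace("\\", "\\\\").replace('"', '\\"')


def _name_filter(var: str, names: Iterable[str], case_insensitive: bool) -> str:
    if case_insensitive:
        quoted = ", ".join(f'"{_escape(n.lower())}"' for n in names)
        return f"  FILTER ( LCASE(STR({var})) IN ({quoted}) )"
    quoted = ", ".join(f'"{_escape(n)}"' for n in names)
    return f"  FILTER ( STR({var}) IN ({quoted}) )"


def _exclusion_filter(excluded_sources: Iterable[str]) -> str:
    excluded = sorted({s.lower() for s in excluded_sources})
    if not excluded:
        return ""
    quoted = ", ".join(f'"{_escape(s)}"' for s in excluded)
    return f"  FILTER ( !BOUND(?source) || LCASE(STR(?source)) NOT IN ({quoted}) )\n"


_COMMON_TAIL = """\
  OPTIONAL {{ ?reaction bp:controlType ?controlType . }}
  OPTIONAL {{ ?reaction bp:dataSource ?prov .
             ?prov bp:displayName|bp:name ?source . }}
  OPTIONAL {{ ?controller a ?controllerClass .
             VALUES ?controllerClass {{ bp:Protein bp:Complex bp:SmallMolecule }} }}
  OPTIONAL {{ ?product a ?targetClass .
             VALUES ?targetClass {{ bp:Protein bp:Complex bp:SmallMolecule }} }}
{name_filter}
{exclusion_filter}}}"""


def build_regulation_query(
    names: list[str],
    excluded_sources: Iterable[str] = (),
    case_insensitive: bool = False,
) -> str:
    """SPARQL for the transcriptional-regulation pattern over ``names``."""
    if not names:
        raise UsageError("names must be non-empty")
    head = (
        f"PREFIX bp: <{BP}>\n"
        "SELECT DISTINCT ?controller ?controllerName ?controllerClass "
        "?targetName ?targetClass ?controlType ?source ?reaction\n"
        "WHERE {{\n"
        "  ?reaction a bp:TemplateReactionRegulation ;\n"
        "            bp:controlled ?template ;\n"
        "            bp:controller ?controller .\n"
        "  ?template a bp:TemplateReaction ;\n"
        "            bp:product ?product .\n"
        "  ?product bp:displayName|bp:name ?matchName .\n"
        "  ?product bp:displayName ?targetName .\n"
        "  ?controller bp:displayName ?controllerName .\n"
    )
    return (head + _COMMON_TAIL).format(
        name_filter=_name_filter("?matchName", names, case_insensitive),
        exclusion_filter=_exclusion_filter(excluded_sources),
    )


def build_signaling_query(
    names: list[str],
    excluded_sources: Iterable[str] = (),
    case_insensitive: bool = False,
) -> str:
    """SPARQL for the signaling pattern (controlled conversions) over ``names``."""
    if not names:
        raise UsageError("names must be non-empty")
    head = (
        f"PREFIX bp: <{BP}>\n"
        "SELECT DISTINCT ?controller ?controllerName ?controllerClass "
        "?targetName ?targetClass ?leftName ?controlType ?source ?reaction\n"
        "WHERE {{\n"
        "  VALUES ?ctrlKind {{ bp:Control bp:Catalysis }}\n"
        "  ?reaction a ?ctrlKind ;\n"
        "            bp:controlled ?conversion ;\n"
        "            bp:controller ?controller .\n"
        "  ?conversion a bp:BiochemicalReaction ;\n"
        "              bp:right ?product .\n"
        "  ?product bp:displayName|bp:name ?matchName .\n"
        "  ?product bp:displayName ?targetName .\n"
        "  ?controller bp:displayName ?controllerName .\n"
        "  OPTIONAL {{ ?conversion bp:left ?left . ?left bp:displayName ?leftName . }}\n"
    )
    return (head + _COMMON_TAIL).format(
        name_filter=_name_filter("?matchName", names, case_insensitive),
        exclusion_filter=_exclusion_filter(excluded_sources),
    )


def chunk_names(batch: QueryBatch) -> list[list[str]]:
    """Split a batch into consecutive chunks of at most ``chunk_size`` names."""
    size = batch.chunk_size
    return [batch.names[i:i + size] for i in range(0, len(batch.names), size)]


def normalize_control_type(literal: str | None) -> str:
    """Collapse BioPAX controlType subtypes onto the three sign tokens.

    BioPAX enumerates subtypes such as ``ACTIVATION-ALLOSTERIC``; any
    literal containing ``ACTIVATION`` or ``INHIBITION`` maps onto the
    corresponding sign, everything else (including absence) is UNKNOWN.
    """
    if literal is None:
        return UNKNOWN
    upper = literal.upper()
    if "ACTIVATION" in upper:
        return ACTIVATION
    if "INHIBITION" in upper:
        return INHIBITION
    return UNKNOWN


def parse_bindings(rows: BindingsTable, kind: str) -> list[RawInteraction]:
    """Turn query bindings into deduplicated :class:`RawInteraction` records.

    A signaling row carrying a left participant yields a second
    interaction (left participant -> product) with sign UNKNOWN, since a
    conversion's substrates influence its products without a stated
    control sign.
    """
    if kind == "regulation":
        kind_token = "transcriptional"
    elif kind == "signaling":
        kind_token = "signaling"
    else:
        raise UsageError(f"unknown interaction kind {kind!r}")

    mandatory = {"controllerName", "targetName", "reaction"}
    missing = mandatory - set(rows.columns)
    if missing:
        raise MalformedResultsError(
            f"query results lack mandatory variable(s): {sorted(missing)}"
        )

    seen: set[RawInteraction] = set()
    for row in rows:
        controller = row.get("controllerName")
        target = row.get("targetName")
        reaction = row.get("reaction")
        if not controller or not target or not reaction:
            raise MalformedResultsError("row with unbound mandatory variable")
        source = row.get("source") or "unspecified"
        cls = _CONTROLLER_CLASSES.get(row.get("controllerClass") or "", "unknown")
        seen.add(RawInteraction(
            controller_name=controller,
            target_name=target,
            sign_token=normalize_control_type(row.get("controlType")),
            kind=kind_token,
            source_db=source,
            reaction_id=reaction,
            controller_class=cls,
            controller_iri=row.get("controller"),
            target_class=_CONTROLLER_CLASSES.get(row.get("targetClass") or "",
                                                 "unknown"),
        ))
        left = row.get("leftName")
        if left and left != controller:
            seen.add(RawInteraction(
                controller_name=left,
                target_name=target,
                sign_token=UNKNOWN,
                kind=kind_token,
                source_db=source,
                reaction_id=reaction,
                controller_class="unknown",
            ))
    return sorted(seen)
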