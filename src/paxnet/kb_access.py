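"""Uniform access to BioPAX-typed RDF knowledge bases.

A :class:`KnowledgeBase` is either *local* (an in-memory :mod:`rdflib`
graph parsed from a Turtle / RDF-XML / N-Triples file) or *remote* (a
SPARQL-protocol HTTP endpoint).  Both modes answer SPARQL SELECT queries
with the same :class:`BindingsTable` structure, so the rest of the
package never needs to know where the triples live.

Remote access speaks the standard SPARQL protocol (HTTP POST, JSON
results) through the standard library, with bounded retries and a
configurable timeout — public pathway endpoints are slow and flaky, so
every failure carries the endpoint URL and the attempt count.
"""

from __future__ import annotations

import json
import logging
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field

import rdflib

from .errors import InputFormatError, TransportError, UsageError

logger = logging.getLogger(__name__)

#: BioPAX Level 3 vocabulary namespace.
BP = "http://www.biopax.org/release/biopax-level3.owl#"

#: RDF serializations accepted by :func:`load_rdf_graph`, mapped to the
#: parser names rdflib uses.
_SERIALIZATIONS = {
    "turtle": "turtle",
    "rdfxml": "xml",
    "ntriples": "nt",
}

_SPARQL_PREAMBLE = f"PREFIX bp: <{BP}>\n"


@dataclass
class BindingsTable:
    """SELECT-query results: ordered variable names and one row per match.

    Values are plain strings (IRIs or literal lexical forms); an unbound
    variable is ``None``.
    """

    columns: list[str]
    rows: list[dict[str, str | None]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)


class KnowledgeBase:
    """A queryable BioPAX triple collection, local or remote."""

    def __init__(
        self,
        graph: rdflib.Graph | None = None,
        endpoint: str | None = None,
        timeout: float = 60.0,
        retries: int = 3,
    ):
        if (graph is None) == (endpoint is None):
            raise UsageError("provide exactly one of graph / endpoint")
        self.graph = graph
        self.endpoint = endpoint
        self.timeout = timeout
        self.retries = retries

    # ------------------------------------------------------------------
    @property
    def mode(self) -> str:
        return "local" if self.graph is not None else "remote"

    def __len__(self) -> int:
        """Number of statements (local mode only; remote raises)."""
        if self.graph is None:
            raise UsageError("statement count is undefined for remote endpoints")
        return len(self.graph)

    # ------------------------------------------------------------------
    def query(self, sparql: str) -> BindingsTable:
        """Run a SPARQL SELECT query and return its bindings.

        Local graphs evaluate in memory; remote endpoints are queried over
        HTTP with ``retries`` attempts.  Both paths return an identical
        :class:`BindingsTable` for identical data.
        """
        if self.graph is not None:
            return self._query_local(sparql)
        return self._query_remote(sparql)

    def _query_local(self, sparql: str) -> BindingsTable:
        try:
            result = self.graph.query(sparql)
        except Exception as exc:  # rdflib raises parser-specific classes
            raise UsageError(f"invalid SPARQL query: {exc}") from exc
        columns = [str(v) for v in result.vars or []]
        rows = []
        for binding in result:
            row = {}
            for col in columns:
                val = binding[col] if col in binding.labels else None
                row[col] = None if val is None else str(val)
            rows.append(row)
        return BindingsTable(columns=columns, rows=rows)

    def _query_remote(self, sparql: str) -> BindingsTable:
        assert self.endpoint is not None
        data = urllib.parse.urlencode({"query": sparql}).encode()
        request = urllib.request.Request(
            self.endpoint,
            data=data,
            headers={
                "Accept": "application/sparql-results+json",
                "Content-Type": "application/x-www-form-urlencoded",
            },
            method="POST",
        )
        last_error: Exception | None = None
        attempts = max(1, self.retries)
        for attempt in range(attempts):
            try:
                with urllib.request.urlopen(request, timeout=self.timeout) as resp:
                    payload = json.loads(resp.read().decode("utf-8"))
                return _bindings_from_json(payload)
            except (urllib.error.URLError, OSError, ValueError) as exc:
                last_error = exc
                logger.warning(
                    "SPARQL request to %s failed (attempt %d/%d): %s",
                    self.endpoint, attempt + 1, attempts, exc,
                )
        raise TransportError(
            f"endpoint {self.endpoint} unreachable after {attempts} attempts: "
            f"{last_error}",
            endpoint=self.endpoint,
            attempts=attempts,
        )


def _bindings_from_json(payload: dict) -> BindingsTable:
    """Convert a SPARQL JSON results document into a BindingsTable."""
    try:
        columns = list(payload["head"]["vars"])
        raw_rows = payload["results"]["bindings"]
    except (KeyError, TypeError) as exc:
        raise TransportError(f"malformed SPARQL JSON results: {exc}") from exc
    rows = []
    for raw in raw_rows:
        rows.append({
            col: (raw[col]["value"] if col in raw else None) for col in columns
        })
    return BindingsTable(columns=columns, rows=rows)


# ----------------------------------------------------------------------
def load_rdf_graph(path: str, serialization: str = "turtle") -> KnowledgeBase:
    """Parse a local RDF file into a local-mode :class:`KnowledgeBase`.

    Parameters
    ----------
    path:
        File to parse.
    serialization:
        One of ``turtle``, ``rdfxml``, ``ntriples``.
    """
    fmt = _SERIALIZATIONS.get(serialization)
    if fmt is None:
        raise UsageError(
            f"unknown serialization {serialization!r}; "
            f"expected one of {sorted(_SERIALIZATIONS)}"
        )
    graph = rdflib.Graph()
    try:
        graph.parse(path, format=fmt)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise InputFormatError(f"failed to parse {path} as {serialization}: {exc}") from exc
    return KnowledgeBase(graph=graph)


def from_endpoint(url: str, timeout: float = 60.0, retries: int = 3) -> KnowledgeBase:
    """Wrap a remote SPARQL endpoint as a KnowledgeBase."""
    return KnowledgeBase(endpoint=url, timeout=timeout, retries=retries)


def list_data_sources(kb: KnowledgeBase) -> set[str]:
    """Distinct data-source names attached to any statement.

    Sources are read from the BioPAX statement-level provenance pattern
    ``?x bp:dataSource ?prov . ?prov bp:displayName|bp:name ?name``.
    Interactions lacking a dataSource link are not represented here (a
    warning is logged); the parser later assigns them the source
    ``"unspecified"``.
    """
    table = kb.query(
        _SPARQL_PREAMBLE
        + "SELECT DISTINCT ?name WHERE { ?s bp:dataSource ?prov . "
        "?prov bp:displayName|bp:name ?name . }"
    )
    sources = {row["name"] for row in table if row["name"]}
    untagged = kb.query(
        _SPARQL_PREAMBLE
        + "SELECT (COUNT(?i) AS ?n) WHERE { ?i a ?cls . "
        "VALUES ?cls { bp:TemplateReactionRegulation bp:Control bp:Catalysis } "
        "FILTER NOT EXISTS { ?i bp:dataSource ?prov } }"
    )
    n_untagged = int(untagged.rows[0]["n"]) if untagged.rows else 0
    if n_untagged:
        logger.warning(
            "%d interaction(s) carry no data-source annotation; they will be "
            "attributed to 'unspecified'", n_untagged,
        )
    return sources
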