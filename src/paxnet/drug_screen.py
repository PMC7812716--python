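"""Drug-screening workflow over a DrugBank-like RDF source.

Three steps: (1) query approved drugs targeting the input gene symbols,
(2) assemble a one-level upstream regulation network to collect new
candidate target genes (the regulators of the input genes), (3) re-run
the drug query on those regulators.  The point is that regulators with a
putative indirect effect widen an otherwise tiny candidate-drug list.

The drug pattern links drugs to gene symbols through *target* and
*gene-name* edges; predicate IRIs are configurable because linked-data
DrugBank deployments drift in their vocabularies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .assembler import reconstruct
from .errors import UsageError
from .expansion import ExpansionConfig, SynonymTable
from .kb_access import KnowledgeBase

#: Default predicate/class IRIs for a linked-data DrugBank deployment.
DEFAULT_DRUG_VOCAB = {
    "drug_class": "http://bio2rdf.org/drugbank_vocabulary:Drug",
    "target": "http://bio2rdf.org/drugbank_vocabulary:target",
    "gene_name": "http://bio2rdf.org/drugbank_vocabulary:gene-name",
    "group": "http://bio2rdf.org/drugbank_vocabulary:group",
    "title": "http://purl.org/dc/terms/title",
}


@dataclass
class DrugScreenReport:
    initial_targets: frozenset[str]
    initial_drugs: frozenset[tuple[str, str, str]]   # (drug id, name, status)
    new_targets: frozenset[str]
    new_drugs: frozenset[tuple[str, str, str]]
    provenance: dict[str, frozenset[str]] = field(default_factory=dict)
    # new target -> data sources of the regulation edges that introduced it

    def to_json(self) -> str:
        return json.dumps({
            "initial_targets": sorted(self.initial_targets),
            "initial_drugs": sorted(self.initial_drugs),
            "new_targets": sorted(self.new_targets),
            "new_drugs": sorted(self.new_drugs),
            "provenance": {k: sorted(v) for k, v in sorted(self.provenance.items())},
        }, indent=2)


def _escape(value: str) -> str:
    return value.replace("\\", "\\\\").replace('"', '\\"')


def build_drug_query(symbols: set[str], approved_only: bool = True,
                     vocab: dict[str, str] = DEFAULT_DRUG_VOCAB) -> str:
    """SPARQL matching drug --target--> entity --gene-name--> symbol paths."""
    if not symbols:
        raise UsageError("symbols must be non-empty")
    quoted = ", ".join(f'"{_escape(s)}"' for s in sorted(symbols))
    status_filter = (
        '  FILTER ( LCASE(STR(?status)) = "approved" )\n' if approved_only else ""
    )
    return (
        "SELECT DISTINCT ?drug ?name ?status ?symbol WHERE {\n"
        f"  ?drug a <{vocab['drug_class']}> ;\n"
        f"        <{vocab['target']}> ?target ;\n"
        f"        <{vocab['title']}> ?name ;\n"
        f"        <{vocab['group']}> ?status .\n"
        f"  ?target <{vocab['gene_name']}> ?symbol .\n"
        f"  FILTER ( STR(?symbol) IN ({quoted}) )\n"
        f"{status_filter}"
        "}"
    )


def _query_drugs(drug_kb: KnowledgeBase, symbols: set[str], approved_only: bool,
                 vocab: dict[str, str]) -> set[tuple[str, str, str]]:
    rows = drug_kb.query(build_drug_query(symbols, approved_only, vocab))
    return {
        (row["drug"], row.get("name") or "", row.get("status") or "")
        for row in rows if row.get("drug")
    }


def screen(
    drug_kb: KnowledgeBase,
    pathway_kb: KnowledgeBase,
    genes: set[str],
    config: ExpansionConfig | None = None,
    excluded_sources: set[str] = frozenset(),
    synonyms: SynonymTable | None = None,
    approved_only: bool = True,
    vocab: dict[str, str] = DEFAULT_DRUG_VOCAB,
) -> DrugScreenReport:
    """Run the three-step target-augmentation drug screen.

    ``genes`` are the initial targets; the upstream exploration runs one
    recursion level with the supplied expansion config (all expansions
    on by default), and the new targets are the regulators — sources of
    non-membership edges onto the initial genes — that are not
    themselves initial genes.
    """
    if not genes:
        raise UsageError("gene set must be non-empty")
    if config is None:
        config = ExpansionConfig(use_synonyms=synonyms is not None,
                                 use_complex_decomposition=True,
                                 use_label_expansion=True)

    try:
        initial_drugs = _query_drugs(drug_kb, genes, approved_only, vocab)
    except Exception as exc:
        raise type(exc)(f"[drug query, initial targets] {exc}") from exc

    try:
        result = reconstruct(pathway_kb, sorted(genes),
                             network_kind="regulation", max_depth=1,
                             config=config, excluded_sources=excluded_sources,
                             synonyms=synonyms)
    except Exception as exc:
        raise type(exc)(f"[upstream augmentation] {exc}") from exc

    new_targets: set[str] = set()
    provenance: dict[str, set[str]] = {}
    for edge in result.influence_graph.edges():
        if edge.kind == "membership":
            continue
        if edge.target in genes and edge.source not in genes:
            new_targets.add(edge.source)
            provenance.setdefault(edge.source, set()).update(edge.provenance)

    new_drugs: set[tuple[str, str, str]] = set()
    if new_targets:
        try:
            new_drugs = _query_drugs(drug_kb, new_targets, approved_only, vocab)
        except Exception as exc:
            raise type(exc)(f"[drug query, new targets] {exc}") from exc

    return DrugScreenReport(
        initial_targets=frozenset(genes),
        initial_drugs=frozenset(initial_drugs),
        new_targets=frozenset(new_targets),
        new_drugs=frozenset(new_drugs),
        provenance={k: frozenset(v) for k, v in provenance.items()},
    )


def write_report_tsv(report: DrugScreenReport, path: str) -> None:
    """Summary TSV: stage, targets, distinct drugs."""
    with open(path, "w") as fh:
        fh.write("stage\tn_targets\tn_drugs\tdrugs\n")
        initial_ids = sorted({d[0] for d in report.initial_drugs})
        new_ids = sorted({d[0] for d in report.new_drugs})
        fh.write(f"initial\t{len(report.initial_targets)}\t{len(initial_ids)}\t"
                 + ",".join(initial_ids) + "\n")
        fh.write(f"augmented\t{len(report.new_targets)}\t{len(new_ids)}\t"
                 + ",".join(new_ids) + "\n")
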