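"""Input-augmentation procedures: complex decomposition, label expansion
and synonym expansion.

Pathway databases name the same molecule in many ways: complexes appear
as delimiter-joined member lists (``CDK4/CCND1``), entity states are
encoded as decorated labels (``expression of MYC``, ``FOO mutant
form``), and gene symbols have registered synonyms.  Each procedure here
widens a name batch before querying (recall), and `strip_decorations`
undoes label decoration when entities enter the graph (precision).

Synonyms come from an NCBI gene_info-format table
(tab-delimited, columns including GeneID / Symbol / Synonyms with
pipe-separated values, ``-`` meaning none), as distributed for
``Homo_sapiens.gene_info``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .errors import InputFormatError

logger = logging.getLogger(__name__)

DEFAULT_COMPLEX_DELIMITERS = ("/", ":")
# "-" is deliberately not a delimiter: it occurs inside gene symbols (HLA-A).
DEFAULT_PREFIXES = ("expression of",)
DEFAULT_SUFFIXES = ("mutant form", "phosphorylated", "protein", "gene")


@dataclass
class ExpansionConfig:
    """Which augmentations to apply, and their vocabulary."""

    use_synonyms: bool = False
    use_complex_decomposition: bool = False
    use_label_expansion: bool = False
    complex_delimiters: tuple[str, ...] = DEFAULT_COMPLEX_DELIMITERS
    prefixes: tuple[str, ...] = DEFAULT_PREFIXES
    suffixes: tuple[str, ...] = DEFAULT_SUFFIXES

    def __post_init__(self):
        if any(not d for d in self.complex_delimiters):
            raise ValueError("complex delimiters must be non-empty strings")
        if any(not p for p in self.prefixes) or any(not s for s in self.suffixes):
            raise ValueError("prefixes/suffixes must not contain empty strings")

    @classmethod
    def from_yaml(cls, path: str, **flags) -> "ExpansionConfig":
        """Load delimiters/prefixes/suffixes from a YAML config file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(
            complex_delimiters=tuple(data.get("complex_delimiters",
                                              DEFAULT_COMPLEX_DELIMITERS)),
            prefixes=tuple(data.get("prefixes", DEFAULT_PREFIXES)),
            suffixes=tuple(data.get("suffixes", DEFAULT_SUFFIXES)),
            **flags,
        )


@dataclass
class SynonymTable:
    """Gene-symbol synonym records with a name -> gene_id index.

    A name may map to several gene ids; that ambiguity is preserved in
    the index and handled by the callers (expansion takes all matches,
    unification refuses ambiguous merges).
    """

    records: list[tuple[int, str, frozenset[str]]] = field(default_factory=list)
    index: dict[str, set[int]] = field(default_factory=dict)
    _canonical: dict[int, str] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records) -> "SynonymTable":
        table = cls()
        for gene_id, symbol, synonyms in records:
            syns = frozenset(synonyms)
            table.records.append((gene_id, symbol, syns))
            table._canonical[gene_id] = symbol
            for name in {symbol, *syns}:
                table.index.setdefault(name, set()).add(gene_id)
        return table

    def canonical_symbol(self, gene_id: int) -> str:
        return self._canonical[gene_id]

    def gene_ids(self, name: str) -> set[int]:
        return self.index.get(name, set())

    def names_for(self, gene_id: int) -> set[str]:
        for gid, symbol, syns in self.records:
            if gid == gene_id:
                return {symbol, *syns}
        return set()


def decompose_complex_label(label: str, delimiters=DEFAULT_COMPLEX_DELIMITERS) -> list[str]:
    """Split a complex label into trimmed member names.

    Delimiters are applied in order; a label containing none of them is
    returned whole.
    """
    parts = [label]
    for delim in delimiters:
        parts = [piece for part in parts for piece in part.split(delim)]
    members = [p.strip() for p in parts if p.strip()]
    return members or [label.strip()]


def expand_labels(names: list[str], config: ExpansionConfig) -> list[str]:
    """Each name plus its prefix- and suffix-decorated variants.

    Input order is preserved first; decorated variants follow, deduplicated.
    """
    out: list[str] = []
    seen: set[str] = set()
    for name in names:
        if name not in seen:
            out.append(name)
            seen.add(name)
    for name in names:
        for prefix in config.prefixes:
            decorated = f"{prefix} {name}"
            if decorated not in seen:
                out.append(decorated)
                seen.add(decorated)
        for suffix in config.suffixes:
            decorated = f"{name} {suffix}"
            if decorated not in seen:
                out.append(decorated)
                seen.add(decorated)
    return out


def strip_decorations(label: str, config: ExpansionConfig) -> str:
    """Remove at most one known prefix and one known suffix from a label.

    Idempotent for labels whose core is not itself decorated.
    """
    stripped = label
    for prefix in config.prefixes:
        if stripped.startswith(prefix + " "):
            stripped = stripped[len(prefix) + 1:]
            break
    for suffix in config.suffixes:
        if stripped.endswith(" " + suffix):
            stripped = stripped[: -(len(suffix) + 1)]
            break
    stripped = stripped.strip()
    return stripped or label


def load_synonym_table(path: str) -> SynonymTable:
    """Parse an NCBI gene_info-format file into a :class:`SynonymTable`."""
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    except Exception as exc:
        raise InputFormatError(f"failed to read synonym table {path}: {exc}") from exc
    # NCBI ships the header as "#tax_id\tGeneID\t..."; normalize the first column.
    frame.columns = [c.lstrip("#") for c in frame.columns]
    missing = {"GeneID", "Symbol", "Synonyms"} - set(frame.columns)
    if missing:
        raise InputFormatError(
            f"synonym table {path} lacks column(s): {sorted(missing)}"
        )
    records = []
    for _, row in frame.iterrows():
        raw_syn = row["Synonyms"]
        if pd.isna(raw_syn) or raw_syn == "-":
            synonyms: set[str] = set()
        else:
            synonyms = {s for s in str(raw_syn).split("|") if s}
        records.append((int(row["GeneID"]), str(row["Symbol"]), synonyms))
    return SynonymTable.from_records(records)


def expand_synonyms(names: list[str], table: SynonymTable) -> list[str]:
    """Input names plus every name of every gene any of them matches.

    Ambiguous names (matching several gene ids) expand over all matches;
    a warning is logged.  Output keeps input order first, then the added
    names sorted, deduplicated.
    """
    out = list(dict.fromkeys(names))
    seen = set(out)
    additions: set[str] = set()
    for name in names:
        gene_ids = table.gene_ids(name)
        if len(gene_ids) > 1:
            logger.warning("name %r matches %d genes; expanding over all",
                           name, len(gene_ids))
        for gid in gene_ids:
            additions |= table.names_for(gid)
    for name in sorted(additions - seen):
        out.append(name)
    return out
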