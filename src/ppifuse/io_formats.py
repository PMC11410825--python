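"""Readers and writers for the external formats the pipeline touches.

All parsers validate strictly by default and are order-deterministic: the
same input file always yields the same in-memory structure, and writers emit
sorted, byte-reproducible output so round-trips are exact.

Formats
-------
- FASTA (multi-record) for protein sequences.
- An OBO 1.2 subset for the ontology: ``[Term]`` stanzas with ``id``,
  ``name``, ``namespace``, ``is_a``, ``relationship: part_of`` and
  ``is_obsolete``; only ``is_a``/``part_of`` edges are retained.
- Plain TSV for annotations (``protein_id<TAB>go_id``) and labeled pairs
  (``id_u<TAB>id_v<TAB>label``). A GAF-subset reader (columns 2 and 5) is
  provided as a convenience.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ppifuse.go_features import GoDag

log = logging.getLogger(__name__)

#: The 20 canonical amino-acid one-letter codes.
CANONICAL_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ontology relations kept when loading an OBO graph.
KEPT_RELATIONS = ("is_a", "part_of")


class FormatError(ValueError):
    """Raised when an input file violates the expected format or invariants."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 20 canonical amino-acid letters."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"protein {self.id!r}: empty sequence")
        bad = [(i, c) for i, c in enumerate(self.sequence) if c not in CANONICAL_ALPHABET]
        if bad:
            pos, char = bad[0]
            raise FormatError(
                f"protein {self.id!r}: non-canonical residue {char!r} at position {pos + 1}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Pair:
    """A labeled, canonically ordered protein pair (lexicographically smaller id first)."""

    u: str
    v: str
    label: int

    @classmethod
    def canonical(cls, u: str, v: str, label: int) -> "Pair":
        if v < u:
            u, v = v, u
        return cls(u, v, int(label))

    @property
    def key(self) -> tuple[str, str]:
        return (self.u, self.v)


@dataclass
class PairList:
    """An ordered list of unique unordered pairs with 0/1 labels."""

    rows: list[Pair]

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def __getitem__(self, i):
        return self.rows[i]

    def labels(self) -> list[int]:
        return [p.label for p in self.rows]


class AnnotationTable:
    """Map from protein id to its set of GO term ids, namespace-aware.

    ``namespaces`` maps each GO id to its namespace so per-namespace views
    can be taken without holding on to the full ontology.
    """

    def __init__(self, terms: Mapping[str, Iterable[str]], namespaces: Mapping[str, str]):
        self._terms: dict[str, frozenset[str]] = {
            p: frozenset(ts) for p, ts in terms.items() if ts
        }
        self._namespaces = dict(namespaces)

    @property
    def proteins(self) -> list[str]:
        return sorted(self._terms)

    def terms_for(self, protein: str, namespace: str | None = None) -> frozenset[str]:
        terms = self._terms.get(protein, frozenset())
        if namespace is None:
            return terms
        return frozenset(t for t in terms if self._namespaces.get(t) == namespace)

    def namespace_of(self, term: str) -> str | None:
        return self._namespaces.get(term)

    def __len__(self) -> int:
        return len(self._terms)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnnotationTable):
            return NotImplemented
        return self._terms == other._terms

    def items(self):
        return self._terms.items()


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, on_invalid: str = "error") -> list[ProteinRecord]:
    """Read a multi-record FASTA file into validated :class:`ProteinRecord` objects.

    Sequences are uppercased; order is preserved. ``on_invalid`` controls
    what happens on a non-canonical residue: ``"error"`` (default) raises,
    ``"skip"`` drops the record with a logged warning. Duplicate ids always
    raise.
    """
    if on_invalid not in ("error", "skip"):
        raise ValueError("on_invalid must be 'error' or 'skip'")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate protein id {rec.id!r} in {path}")
        seen.add(rec.id)
        try:
            records.append(ProteinRecord(rec.id, str(rec.seq).upper()))
        except FormatError:
            if on_invalid == "skip":
                log.warning("skipping protein %r: non-canonical sequence", rec.id)
                continue
            raise
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    seq_records = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# OBO ontology


def read_go_obo(path: str | Path) -> GoDag:
    """Load an OBO file into a :class:`~ppifuse.go_features.GoDag`.

    Only ``is_a`` and ``part_of`` edges are retained, obsolete terms are
    dropped (obonet's default), and one root per namespace is required.
    Raises :class:`FormatError` on cycles (listing one cycle) or on edges to
    terms that have no ``[Term]`` stanza.
    """
    graph = obonet.read_obo(str(path))
    edges: list[tuple[str, str]] = []
    namespaces: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        if "name" not in data and "namespace" not in data:
            # obonet materializes referenced-but-undefined parents as bare nodes
            raise FormatError(f"term {node!r} is referenced as a parent but never defined")
        namespaces[node] = data.get("namespace", "default")
    for child, parent, key in graph.edges(keys=True):
        if key in KEPT_RELATIONS:
            edges.append((child, parent))
    dg = nx.DiGraph(edges)
    try:
        cycle = nx.find_cycle(dg)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        raise FormatError(f"ontology contains a cycle: {cycle}")
    return GoDag(edges, namespaces)


# ---------------------------------------------------------------------------
# Annotations


def read_annotations(
    path: str | Path, dag: GoDag, on_unknown: str = "error"
) -> AnnotationTable:
    """Read a ``protein_id<TAB>go_id`` TSV, validating term ids against ``dag``.

    Duplicate rows collapse into sets. ``on_unknown="drop"`` discards rows
    whose term is absent from the ontology (count logged) instead of raising.
    """
    if on_unknown not in ("error", "drop"):
        raise ValueError("on_unknown must be 'error' or 'drop'")
    terms: dict[str, set[str]] = {}
    dropped = 0
    for lineno, line in enumerate(_read_lines(path), start=1):
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
        protein, go_id = fields
        if go_id not in dag:
            if on_unknown == "drop":
                dropped += 1
                continue
            raise FormatError(f"{path}:{lineno}: unknown GO id {go_id!r}")
        terms.setdefault(protein, set()).add(go_id)
    if dropped:
        log.warning("dropped %d annotation rows with unknown GO ids", dropped)
    return AnnotationTable(terms, {t: dag.namespace(t) for ts in terms.values() for t in ts})


def read_gaf_subset(path: str | Path, dag: GoDag, on_unknown: str = "error") -> AnnotationTable:
    """Convenience reader for GAF-like files: takes columns 2 (id) and 5 (GO id)."""
    if on_unknown not in ("error", "drop"):
        raise ValueError("on_unknown must be 'error' or 'drop'")
    terms: dict[str, set[str]] = {}
    dropped = 0
    for lineno, line in enumerate(_read_lines(path, skip_comments="!"), start=1):
        fields = line.split("\t")
        if len(fields) < 5:
            raise FormatError(f"{path}:{lineno}: expected at least 5 GAF columns")
        protein, go_id = fields[1], fields[4]
        if go_id not in dag:
            if on_unknown == "drop":
                dropped += 1
                continue
            raise FormatError(f"{path}:{lineno}: unknown GO id {go_id!r}")
        terms.setdefault(protein, set()).add(go_id)
    if dropped:
        log.warning("dropped %d GAF rows with unknown GO ids", dropped)
    return AnnotationTable(terms, {t: dag.namespace(t) for ts in terms.values() for t in ts})


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for protein in table.proteins:
            for term in sorted(table.terms_for(protein)):
                fh.write(f"{protein}\t{term}\n")


# ---------------------------------------------------------------------------
# Pair lists


def read_pairs(path: str | Path, proteins: Sequence[ProteinRecord]) -> PairList:
    """Read a 3-column pair TSV and validate it against the loaded proteins.

    Pairs are stored canonically (lexicographically smaller id first);
    duplicate unordered pairs and unresolvable ids raise.
    """
    known = {p.id for p in proteins}
    rows: list[Pair] = []
    seen: set[tuple[str, str]] = set()
    for lineno, line in enumerate(_read_lines(path), start=1):
        fields = line.split("\t")
        if len(fields) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 tab-separated columns")
        u, v, raw_label = fields
        for pid in (u, v):
            if pid not in known:
                raise FormatError(f"{path}:{lineno}: unknown protein id {pid!r}")
        if raw_label not in ("0", "1"):
            raise FormatError(f"{path}:{lineno}: label must be 0 or 1, got {raw_label!r}")
        pair = Pair.canonical(u, v, int(raw_label))
        if pair.key in seen:
            raise FormatError(f"{path}:{lineno}: duplicate unordered pair {pair.key}")
        seen.add(pair.key)
        rows.append(pair)
    return PairList(rows)


def write_pairs(pairs: PairList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.u}\t{p.v}\t{p.label}\n")


def _read_lines(path: str | Path, skip_comments: str | None = None):
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if skip_comments and line.startswith(skip_comments):
                continue
            yield line
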