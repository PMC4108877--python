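"""Assay annotation tables → ABox triples → reasoning-backed retrieval.

Assay metadata is captured in spreadsheet-style tables whose column headers
correspond to ontology relations and whose cells name ontology classes
(design method, detection method, format, endpoint, …).  This module reads
such tables (CSV/TSV), maps headers through a declared header mapping and
emits one assay individual per row plus one assertion per non-empty cell:
class-term cells become object-property links to deterministic skolem
filler individuals typed by the named class; literal cells become inert
data assertions with a unit tag.

Cell values resolve to ontology terms by exact label match after
whitespace normalization and case folding (rdfs:label or local-name
spelling); an ambiguous surface form is an error, never a guess.

The payoff of the formalization is mechanism-based retrieval: an assay
annotated only with its design method can be retrieved by a molecular
participant (luciferase, ATP) that appears nowhere in the annotations,
because the participant is entailed through the design method's
definition.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import rdflib

from .dl import (
    And, AnnotationAssertion, Atomic, Axiom, ClassAssertion, ConceptExpr,
    DataAssertion, Declaration, Exists, Ontology, OntoAssayError, RoleRef,
    ObjectPropertyAssertion, RDFS_LABEL, _local_name, _norm_name,
    signature_of,
)
from .reasoner import retrieve_instances

DEFAULT_INDIVIDUAL_NS = "http://example.org/bao-mini/abox#"


class TableError(OntoAssayError):
    pass


class RaggedRowError(TableError):
    def __init__(self, row_number: int, expected: int, found: int):
        super().__init__(
            f"row {row_number} has {found} cells, expected {expected}")
        self.row_number = row_number


class UnmappedHeaderError(OntoAssayError):
    def __init__(self, header: str):
        super().__init__(f"no mapping for column header {header!r}")
        self.header = header


class UnresolvableTermError(OntoAssayError):
    def __init__(self, text: str, row: int, column: str, reason: str):
        super().__init__(
            f"cannot resolve {text!r} (row {row}, column {column!r}): "
            f"{reason}")
        self.text = text
        self.row = row
        self.column = column


@dataclass
class Dialect:
    delimiter: str = ","
    quotechar: str = '"'


TSV = Dialect(delimiter="\t")


@dataclass
class AnnotationTable:
    """An in-memory annotation table; all rows share the column arity.

    The first column is the designated assay-identifier column unless
    ``id_column`` names another header.
    """

    columns: List[str]
    rows: List[Dict[str, str]]
    dialect: Dialect = field(default_factory=Dialect)
    id_column: Optional[str] = None

    def __post_init__(self):
        if not self.columns:
            raise TableError("a table needs at least one column")
        if self.id_column is None:
            self.id_column = self.columns[0]
        if self.id_column not in self.columns:
            raise TableError(
                f"identifier column {self.id_column!r} is not a header")


def read_annotation_table(path, dialect: Optional[Dialect] = None,
                          id_column: Optional[str] = None) -> AnnotationTable:
    """Read a CSV/TSV annotation table with verbatim cell text.

    Empty cells are preserved as absent values (empty string in the row
    dict); a row whose arity differs from the header's raises a ragged-row
    error naming the 1-based data row.
    """
    dialect = dialect or Dialect()
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter,
                            quotechar=dialect.quotechar)
        try:
            columns = next(reader)
        except StopIteration:
            raise TableError(f"{path} is empty")
        rows = []
        for i, raw in enumerate(reader, start=1):
            if not raw:
                continue
            if len(raw) != len(columns):
                raise RaggedRowError(i, len(columns), len(raw))
            rows.append(dict(zip(columns, raw)))
    return AnnotationTable(columns=columns, rows=rows, dialect=dialect,
                           id_column=id_column)


# ---------------------------------------------------------------------------
# Header mapping
# ---------------------------------------------------------------------------

OBJECT_KINDS = ("class", "individual", "literal")


@dataclass
class HeaderMapping:
    """header name → (predicate IRI, object kind[, unit IRI])."""

    entries: Dict[str, Tuple]

    def __post_init__(self):
        for header, entry in self.entries.items():
            if entry[1] not in OBJECT_KINDS:
                raise ValueError(
                    f"unknown object kind {entry[1]!r} for {header!r}")

    @classmethod
    def load(cls, path) -> "HeaderMapping":
        import yaml
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        entries = {}
        for header, spec in data.items():
            entries[header] = (spec["predicate"], spec.get("kind", "class"),
                               spec.get("unit"))
        return cls(entries)

    def get(self, header: str) -> Tuple:
        if header not in self.entries:
            raise UnmappedHeaderError(header)
        return self.entries[header]

    def validate_against(self, kb: Ontology) -> None:
        sig = signature_of(kb.all_axioms())
        known = sig.roles | sig.data_properties
        for header, entry in self.entries.items():
            if entry[0] not in known:
                raise UnmappedHeaderError(
                    f"{header} (predicate <{entry[0]}> not in the "
                    f"ontology signature)")


class TermResolver:
    """Resolve cell text to class IRIs by normalized label / local name."""

    def __init__(self, kb: Ontology):
        sig = signature_of(kb.all_axioms())
        self.table: Dict[str, Set[str]] = {}
        for iri in sig.classes:
            local = _local_name(iri)
            self._put(_norm_name(local), iri)
            self._put(_norm_name(local.replace("_", " ")), iri)
        for label, iris in kb.label_map().items():
            for iri in iris:
                self._put(label, iri)

    def _put(self, name: str, iri: str) -> None:
        self.table.setdefault(name, set()).add(iri)

    def resolve(self, text: str, row: int, column: str) -> str:
        hits = self.table.get(_norm_name(text), set())
        if not hits:
            raise UnresolvableTermError(text, row, column,
                                        "no class with this label")
        if len(hits) > 1:
            raise UnresolvableTermError(
                text, row, column,
                f"ambiguous label, matches {sorted(hits)}")
        return next(iter(hits))


def _skolem(ns: str, *parts: str) -> str:
    safe = [re.sub(r"[^A-Za-z0-9_-]+", "_", p.strip()) for p in parts]
    return ns + "__".join(safe)


def table_to_triples(table: AnnotationTable, mapping: HeaderMapping,
                     kb: Ontology,
                     individual_ns: str = DEFAULT_INDIVIDUAL_NS,
                     bioassay_class: Optional[str] = None) -> Set[Axiom]:
    """Translate table rows into ABox assertions.

    Per row: one assay individual (from the identifier column) typed as
    bioassay, plus per non-empty cell either an object-property link to a
    skolem individual typed by the cell's class, or a data assertion.
    Skolems are deterministic functions of (assay id, header), so repeated
    runs emit identical triples.
    """
    resolver = TermResolver(kb)
    if bioassay_class is None:
        bioassay_class = resolver.resolve("bioassay", 0, "<bioassay type>")
    out: Set[Axiom] = set()
    for rownum, row in enumerate(table.rows, start=1):
        assay_id = row[table.id_column].strip()
        if not assay_id:
            raise UnresolvableTermError("", rownum, table.id_column,
                                        "empty assay identifier")
        assay = _skolem(individual_ns, assay_id)
        out.add(Declaration("NamedIndividual", assay))
        out.add(ClassAssertion(Atomic(bioassay_class), assay))
        for header in table.columns:
            if header == table.id_column:
                continue
            cell = row.get(header, "").strip()
            if not cell:
                continue
            predicate, kind, *rest = mapping.get(header)
            if kind == "class":
                cls = resolver.resolve(cell, rownum, header)
                filler = _skolem(individual_ns, assay_id, header)
                out.add(Declaration("NamedIndividual", filler))
                out.add(ClassAssertion(Atomic(cls), filler))
                out.add(ObjectPropertyAssertion(RoleRef(predicate),
                                                assay, filler))
            elif kind == "individual":
                target = _skolem(individual_ns, cell)
                out.add(Declaration("NamedIndividual", target))
                out.add(ObjectPropertyAssertion(RoleRef(predicate),
                                                assay, target))
            else:  # literal (+ optional unit tag from the mapping)
                unit = rest[0] if rest else None
                try:
                    value: object = float(cell)
                except ValueError:
                    value = cell
                out.add(DataAssertion(predicate, assay, value, unit))
    return out


# ---------------------------------------------------------------------------
# Reasoning-backed retrieval
# ---------------------------------------------------------------------------

def query_assays_by_participant(kb, participant: str) -> Set[str]:
    """Assays whose design method involves the given molecular participant.

    Retrieval over bioassay ⊓ ∃'has assay method'.('assay design method' ⊓
    ∃'has participant'.participant) — the participant need not appear in
    any annotation; entailment through design-method definitions suffices.
    ``kb`` must be an Ontology (term names are resolved in its signature).
    """
    resolver = TermResolver(kb)
    sig = signature_of(kb.all_axioms())
    if participant not in sig.classes:
        raise UnresolvableTermError(participant, 0, "<participant>",
                                    "not a declared class")
    expr = And(
        Atomic(resolver.resolve("bioassay", 0, "<query>")),
        Exists(RoleRef(_resolve_role(sig, kb, "has assay method")),
               And(Atomic(resolver.resolve("assay design method", 0,
                                           "<query>")),
                   Exists(RoleRef(_resolve_role(sig, kb, "has participant")),
                          Atomic(participant)))))
    return retrieve_instances(kb, expr)


def _resolve_role(sig, kb: Ontology, name: str) -> str:
    norm = _norm_name(name)
    hits = {iri for iri in sig.roles
            if _norm_name(_local_name(iri).replace("_", " ")) == norm}
    for ann in kb.annotations:
        if ann.property == RDFS_LABEL and _norm_name(ann.text) == norm \
                and ann.subject in sig.roles:
            hits.add(ann.subject)
    if len(hits) > 1:
        # same surface form is acceptable when the roles are told-equivalent
        # (combinator bridges); any member then has the same extension
        import networkx as nx
        from .dl import SubObjectPropertyOf
        g = nx.DiGraph()
        g.add_nodes_from(hits)
        for ax in kb.rbox:
            if isinstance(ax, SubObjectPropertyOf):
                g.add_edge(ax.sub.name, ax.sup.name)
        closure = nx.transitive_closure(g)
        if all(closure.has_edge(a, b) and closure.has_edge(b, a)
               for a in hits for b in hits if a != b):
            return sorted(hits)[0]
    if len(hits) != 1:
        raise UnresolvableTermError(name, 0, "<role>",
                                    f"matches {sorted(hits)}")
    return next(iter(hits))


# ---------------------------------------------------------------------------
# Turtle output
# ---------------------------------------------------------------------------

RDF_TYPE = "http://www.w3.org/1999/02/22-rdf-syntax-ns#type"
OWL_NAMED_INDIVIDUAL = "http://www.w3.org/2002/07/owl#NamedIndividual"
XSD_STRING = "http://www.w3.org/2001/XMLSchema#string"


def _turtle_triples(assertions: Iterable[Axiom]) -> List[Tuple[str, str, str]]:
    triples: List[Tuple[str, str, str]] = []
    for ax in assertions:
        if isinstance(ax, Declaration):
            if ax.kind != "NamedIndividual":
                raise OntoAssayError(
                    f"only individual declarations serialize to Turtle: {ax}")
            triples.append((f"<{ax.iri}>", f"<{RDF_TYPE}>",
                            f"<{OWL_NAMED_INDIVIDUAL}>"))
        elif isinstance(ax, ClassAssertion):
            if not isinstance(ax.expr, Atomic):
                raise OntoAssayError(
                    f"complex class assertions have no Turtle form: {ax}")
            triples.append((f"<{ax.individual}>", f"<{RDF_TYPE}>",
                            f"<{ax.expr.iri}>"))
        elif isinstance(ax, ObjectPropertyAssertion):
            triples.append((f"<{ax.subject}>", f"<{ax.role.name}>",
                            f"<{ax.object}>"))
        elif isinstance(ax, DataAssertion):
            if isinstance(ax.value, (int, float)):
                text = repr(float(ax.value))
            else:
                text = str(ax.value)
            lit = '"%s"' % text.replace("\\", "\\\\").replace('"', '\\"')
            if ax.unit:
                lit += f"^^<{ax.unit}>"
            triples.append((f"<{ax.subject}>", f"<{ax.property}>", lit))
        elif isinstance(ax, AnnotationAssertion):
            lit = '"%s"' % ax.text.replace("\\", "\\\\").replace('"', '\\"')
            triples.append((f"<{ax.subject}>", f"<{ax.property}>", lit))
        else:
            raise OntoAssayError(f"not an ABox assertion: {ax}")
    return sorted(set(triples))


def write_turtle(assertions: Iterable[Axiom], path) -> Path:
    """Serialize assertions to Turtle with fully deterministic bytes.

    Triples are sorted by (subject, predicate, object); two serializations
    of the same assertion set are byte-identical.  ``parse_turtle`` (backed
    by rdflib) inverts this exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["@prefix owl: <http://www.w3.org/2002/07/owl#> .", ""]
    for s, p, o in _turtle_triples(assertions):
        lines.append(f"{s} {p} {o} .")
    path.write_bytes(("\n".join(lines) + "\n").encode("utf-8"))
    return path


def parse_turtle(path) -> Set[Axiom]:
    """Read a Turtle file back into an assertion set (via rdflib)."""
    g = rdflib.Graph()
    g.parse(str(path), format="turtle")
    out: Set[Axiom] = set()
    for s, p, o in g:
        s_iri, p_iri = str(s), str(p)
        if isinstance(o, rdflib.Literal):
            dt = str(o.datatype) if o.datatype else None
            if dt in (None, XSD_STRING):
                out.add(AnnotationAssertion(s_iri, p_iri, str(o)))
            else:
                try:
                    value: object = float(str(o))
                except ValueError:
                    value = str(o)
                out.add(DataAssertion(p_iri, s_iri, value, dt))
        elif p_iri == RDF_TYPE:
            if str(o) == OWL_NAMED_INDIVIDUAL:
                out.add(Declaration("NamedIndividual", s_iri))
            else:
                out.add(ClassAssertion(Atomic(str(o)), s_iri))
        else:
            out.add(ObjectPropertyAssertion(RoleRef(p_iri), s_iri, str(o)))
    return out
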