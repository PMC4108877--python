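"""Reading and writing the ontology file dialect.

The on-disk dialect is a subset of OWL 2 Functional-Style Syntax: Prefix,
Ontology, Import, Declaration, SubClassOf, EquivalentClasses,
DisjointClasses, SubObjectPropertyOf, ClassAssertion,
ObjectPropertyAssertion, DataPropertyAssertion and AnnotationAssertion,
with ObjectIntersectionOf / ObjectUnionOf / ObjectComplementOf /
ObjectSomeValuesFrom / ObjectAllValuesFrom / ObjectMinCardinality /
ObjectMaxCardinality / ObjectOneOf / ObjectHasSelf class expressions.
It is line-oriented and diff-friendly; serialization is canonical (sorted
prefixes, axioms ordered by kind then canonical string, UTF-8, LF), so the
same ontology always produces identical bytes.  Data values carry their
unit tag in the literal's datatype position: ``"3.5"^^unit:micromolar``.

Known OWL constructs outside the subset (property chains, inverse roles,
role characteristics, datatype expressions, HasValue) raise an
unsupported-construct error naming the construct — nothing is dropped
silently.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from .dl import (
    TOP, BOTTOM, And, AnnotationAssertion, Atomic, Axiom, ClassAssertion,
    ConceptExpr, DataAssertion, Declaration, DisjointClasses,
    EquivalentClasses, Exists, Forall, MaxCard, MinCard, Nominal, Not,
    ObjectPropertyAssertion, Ontology, OntoAssayError, Or, RoleRef,
    SelfRestriction, SubClassOf, SubObjectPropertyOf, _And, _Or,
    UnsupportedConstructError,
)

OWL_THING = "http://www.w3.org/2002/07/owl#Thing"
OWL_NOTHING = "http://www.w3.org/2002/07/owl#Nothing"

BUILTIN_PREFIXES = {
    "owl": "http://www.w3.org/2002/07/owl#",
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "xsd": "http://www.w3.org/2001/XMLSchema#",
}


class OntologySyntaxError(OntoAssayError):
    def __init__(self, message: str, line: int, col: int):
        super().__init__(f"{message} (line {line}, column {col})")
        self.line = line
        self.col = col


# Recognized-but-rejected construct heads, for loud errors.
_KNOWN_UNSUPPORTED = {
    "SubObjectPropertyChain", "ObjectPropertyChain", "ObjectInverseOf",
    "TransitiveObjectProperty", "SymmetricObjectProperty",
    "AsymmetricObjectProperty", "ReflexiveObjectProperty",
    "IrreflexiveObjectProperty", "FunctionalObjectProperty",
    "InverseFunctionalObjectProperty", "DisjointObjectProperties",
    "ObjectHasValue", "DataSomeValuesFrom", "DataAllValuesFrom",
    "DataHasValue", "ObjectExactCardinality", "DataExactCardinality",
    "EquivalentObjectProperties", "InverseObjectProperties",
    "DatatypeDefinition", "HasKey", "SameIndividual",
    "DifferentIndividuals", "NegativeObjectPropertyAssertion",
}


@dataclass
class SerializationPolicy:
    """Canonical serialization conventions: prefixes and ordering."""

    prefixes: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        merged = dict(BUILTIN_PREFIXES)
        merged.update(self.prefixes)
        self.prefixes = merged
        # longest-namespace-first for abbreviation
        self._by_len = sorted(self.prefixes.items(),
                              key=lambda kv: -len(kv[1]))

    def abbreviate(self, iri: str) -> str:
        for prefix, ns in self._by_len:
            if iri.startswith(ns):
                local = iri[len(ns):]
                if re.fullmatch(r"[A-Za-z0-9_.-]+", local):
                    return f"{prefix}:{local}"
        return f"<{iri}>"


DEFAULT_POLICY = SerializationPolicy()


@dataclass
class OntologyFile:
    """A physical ontology file plus its declared modular layer kind."""

    path: Optional[Path]
    iri: str
    ontology: Ontology
    kind: Optional[str] = None


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _render_expr(e: ConceptExpr, pol: SerializationPolicy) -> str:
    if isinstance(e, Atomic):
        return pol.abbreviate(e.iri)
    if e is TOP:
        return "owl:Thing"
    if e is BOTTOM:
        return "owl:Nothing"
    if isinstance(e, Not):
        return f"ObjectComplementOf({_render_expr(e.arg, pol)})"
    if isinstance(e, _And):
        return "ObjectIntersectionOf(%s)" % " ".join(
            _render_expr(a, pol) for a in e.args)
    if isinstance(e, _Or):
        return "ObjectUnionOf(%s)" % " ".join(
            _render_expr(a, pol) for a in e.args)
    if isinstance(e, Exists):
        return (f"ObjectSomeValuesFrom({pol.abbreviate(e.role.name)} "
                f"{_render_expr(e.filler, pol)})")
    if isinstance(e, Forall):
        return (f"ObjectAllValuesFrom({pol.abbreviate(e.role.name)} "
                f"{_render_expr(e.filler, pol)})")
    if isinstance(e, MinCard):
        return (f"ObjectMinCardinality({e.n} {pol.abbreviate(e.role.name)} "
                f"{_render_expr(e.filler, pol)})")
    if isinstance(e, MaxCard):
        return (f"ObjectMaxCardinality({e.n} {pol.abbreviate(e.role.name)} "
                f"{_render_expr(e.filler, pol)})")
    if isinstance(e, Nominal):
        return f"ObjectOneOf({pol.abbreviate(e.individual)})"
    if isinstance(e, SelfRestriction):
        return f"ObjectHasSelf({pol.abbreviate(e.role.name)})"
    raise UnsupportedConstructError(type(e).__name__, e.key)


def _quote(text: str) -> str:
    return '"%s"' % text.replace("\\", "\\\\").replace('"', '\\"')


def _render_axiom(ax: Axiom, pol: SerializationPolicy) -> str:
    if isinstance(ax, Declaration):
        return f"Declaration({ax.kind}({pol.abbreviate(ax.iri)}))"
    if isinstance(ax, SubClassOf):
        return (f"SubClassOf({_render_expr(ax.sub, pol)} "
                f"{_render_expr(ax.sup, pol)})")
    if isinstance(ax, EquivalentClasses):
        return "EquivalentClasses(%s)" % " ".join(
            _render_expr(e, pol) for e in ax.exprs)
    if isinstance(ax, DisjointClasses):
        return "DisjointClasses(%s)" % " ".join(
            _render_expr(e, pol) for e in ax.exprs)
    if isinstance(ax, SubObjectPropertyOf):
        return (f"SubObjectPropertyOf({pol.abbreviate(ax.sub.name)} "
                f"{pol.abbreviate(ax.sup.name)})")
    if isinstance(ax, ClassAssertion):
        return (f"ClassAssertion({_render_expr(ax.expr, pol)} "
                f"{pol.abbreviate(ax.individual)})")
    if isinstance(ax, ObjectPropertyAssertion):
        return (f"ObjectPropertyAssertion({pol.abbreviate(ax.role.name)} "
                f"{pol.abbreviate(ax.subject)} {pol.abbreviate(ax.object)})")
    if isinstance(ax, DataAssertion):
        if isinstance(ax.value, (int, float)):
            lit = _quote(repr(float(ax.value)))
        else:
            lit = _quote(str(ax.value))
        if ax.unit:
            lit += f"^^{pol.abbreviate(ax.unit)}"
        return (f"DataPropertyAssertion({pol.abbreviate(ax.property)} "
                f"{pol.abbreviate(ax.subject)} {lit})")
    if isinstance(ax, AnnotationAssertion):
        return (f"AnnotationAssertion({pol.abbreviate(ax.property)} "
                f"{pol.abbreviate(ax.subject)} {_quote(ax.text)})")
    raise UnsupportedConstructError(type(ax).__name__)


_AXIOM_RANK = {
    Declaration: 0, SubClassOf: 1, EquivalentClasses: 2, DisjointClasses: 3,
    SubObjectPropertyOf: 4, ClassAssertion: 5, ObjectPropertyAssertion: 6,
    DataAssertion: 7, AnnotationAssertion: 8,
}


def serialize(onto: Ontology,
              policy: SerializationPolicy = DEFAULT_POLICY) -> str:
    """Canonical text of an ontology (deterministic bytes)."""
    lines = []
    for prefix in sorted(policy.prefixes):
        lines.append(f"Prefix({prefix}:=<{policy.prefixes[prefix]}>)")
    lines.append(f"Ontology(<{onto.iri}>")
    for imp in sorted(set(onto.direct_imports)):
        lines.append(f"Import(<{imp}>)")
    rendered = [( _AXIOM_RANK[type(ax)], _render_axiom(ax, policy))
                for ax in onto.all_axioms()]
    for _, line in sorted(rendered):
        lines.append(line)
    lines.append(")")
    return "\n".join(lines) + "\n"


def write_ontology_file(onto: Ontology, path,
                        policy: SerializationPolicy = DEFAULT_POLICY) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_bytes(serialize(onto, policy).encode("utf-8"))
    return path


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_OFN_TOKEN = re.compile(
    r"""
      (?P<ws>\s+|\#[^\n]*)
    | (?P<iriref><[^<>\s]*>)
    | (?P<string>"(?:[^"\\]|\\.)*")
    | (?P<caret>\^\^)
    | (?P<eq>=)
    | (?P<lparen>\()
    | (?P<rparen>\))
    | (?P<int>\d+(?![\w.-]))
    | (?P<pname>[A-Za-z_][A-Za-z0-9_.-]*:?[A-Za-z0-9_.-]*|:[A-Za-z0-9_.-]+)
    """,
    re.VERBOSE,
)


class _OfnTokens:
    def __init__(self, text: str):
        self.toks: List[Tuple[str, str, int, int]] = []
        line, line_start, pos = 1, 0, 0
        while pos < len(text):
            m = _OFN_TOKEN.match(text, pos)
            if not m:
                raise OntologySyntaxError(
                    f"cannot tokenize {text[pos:pos+10]!r}",
                    line, pos - line_start + 1)
            kind = m.lastgroup
            val = m.group(kind)
            if kind != "ws":
                self.toks.append((kind, val, line, m.start() - line_start + 1))
            line += val.count("\n")
            if "\n" in val:
                line_start = m.start() + val.rfind("\n") + 1
            pos = m.end()
        self.i = 0

    def peek(self):
        if self.i < len(self.toks):
            return self.toks[self.i]
        return ("eof", "", -1, -1)

    def next(self):
        t = self.peek()
        self.i += 1
        return t

    def expect(self, kind: str, value: Optional[str] = None) -> str:
        k, v, ln, col = self.next()
        if k != kind or (value is not None and v != value):
            raise OntologySyntaxError(
                f"expected {value or kind}, found {v!r}", ln, col)
        return v


class _OfnParser:
    def __init__(self, text: str):
        self.t = _OfnTokens(text)
        self.prefixes: Dict[str, str] = dict(BUILTIN_PREFIXES)

    def _iri(self) -> str:
        k, v, ln, col = self.t.next()
        if k == "iriref":
            return v[1:-1]
        if k == "pname":
            if ":" not in v:
                raise OntologySyntaxError(f"expected an IRI, found {v!r}",
                                          ln, col)
            prefix, local = v.split(":", 1)
            ns = self.prefixes.get(prefix)
            if ns is None:
                raise OntologySyntaxError(f"undeclared prefix {prefix!r}",
                                          ln, col)
            return ns + local
        raise OntologySyntaxError(f"expected an IRI, found {v!r}", ln, col)

    def parse(self) -> Ontology:
        while self.t.peek()[1] == "Prefix":
            self.t.next()
            self.t.expect("lparen")
            k, v, ln, col = self.t.next()
            if k != "pname" or not v.endswith(":"):
                raise OntologySyntaxError(
                    f"malformed prefix name {v!r}", ln, col)
            name = v[:-1]
            self.t.expect("eq")
            k2, iriref, ln2, col2 = self.t.next()
            if k2 != "iriref":
                raise OntologySyntaxError("expected an IRI reference",
                                          ln2, col2)
            self.prefixes[name] = iriref[1:-1]
            self.t.expect("rparen")
        self.t.expect("pname", "Ontology")
        self.t.expect("lparen")
        onto = Ontology(iri=self._iri())
        while self.t.peek()[1] == "Import":
            self.t.next()
            self.t.expect("lparen")
            onto.direct_imports.append(self._iri())
            self.t.expect("rparen")
        while self.t.peek()[0] != "rparen":
            onto.add(self._axiom())
        self.t.expect("rparen")
        if self.t.peek()[0] != "eof":
            k, v, ln, col = self.t.peek()
            raise OntologySyntaxError(f"trailing content {v!r}", ln, col)
        return onto

    def _axiom(self) -> Axiom:
        k, head, ln, col = self.t.next()
        if k != "pname":
            raise OntologySyntaxError(f"expected an axiom, found {head!r}",
                                      ln, col)
        if head in _KNOWN_UNSUPPORTED:
            raise UnsupportedConstructError(head)
        self.t.expect("lparen")
        try:
            if head == "Declaration":
                kind = self.t.expect("pname")
                self.t.expect("lparen")
                iri = self._iri()
                self.t.expect("rparen")
                ax: Axiom = Declaration(kind, iri)
            elif head == "SubClassOf":
                ax = SubClassOf(self._expr(), self._expr())
            elif head == "EquivalentClasses":
                ax = EquivalentClasses(*self._expr_list())
            elif head == "DisjointClasses":
                ax = DisjointClasses(*self._expr_list())
            elif head == "SubObjectPropertyOf":
                if self.t.peek()[1] in _KNOWN_UNSUPPORTED:
                    raise UnsupportedConstructError(self.t.peek()[1])
                ax = SubObjectPropertyOf(RoleRef(self._iri()),
                                         RoleRef(self._iri()))
            elif head == "ClassAssertion":
                ax = ClassAssertion(self._expr(), self._iri())
            elif head == "ObjectPropertyAssertion":
                ax = ObjectPropertyAssertion(
                    RoleRef(self._iri()), self._iri(), self._iri())
            elif head == "DataPropertyAssertion":
                prop = self._iri()
                subj = self._iri()
                value, unit = self._literal()
                ax = DataAssertion(prop, subj, value, unit)
            elif head == "AnnotationAssertion":
                prop = self._iri()
                subj = self._iri()
                k2, raw, ln2, col2 = self.t.next()
                if k2 != "string":
                    raise OntologySyntaxError("expected a string literal",
                                              ln2, col2)
                ax = AnnotationAssertion(subj, prop, _unquote(raw))
            else:
                raise OntologySyntaxError(f"unknown axiom kind {head!r}",
                                          ln, col)
        except ValueError as exc:
            raise OntologySyntaxError(str(exc), ln, col)
        self.t.expect("rparen")
        return ax

    def _literal(self) -> Tuple[object, Optional[str]]:
        k, raw, ln, col = self.t.next()
        if k != "string":
            raise OntologySyntaxError("expected a literal", ln, col)
        text = _unquote(raw)
        unit = None
        if self.t.peek()[0] == "caret":
            self.t.next()
            unit = self._iri()
        try:
            value: object = float(text)
        except ValueError:
            value = text
        return value, unit

    def _expr_list(self) -> List[ConceptExpr]:
        out = []
        while self.t.peek()[0] != "rparen":
            out.append(self._expr())
        return out

    def _expr(self) -> ConceptExpr:
        k, v, ln, col = self.t.peek()
        nxt = (self.t.toks[self.t.i + 1][0]
               if self.t.i + 1 < len(self.t.toks) else "eof")
        if k == "pname" and nxt == "lparen":
            head = v
            if head in _KNOWN_UNSUPPORTED:
                raise UnsupportedConstructError(head)
            if head in {"ObjectIntersectionOf", "ObjectUnionOf",
                        "ObjectComplementOf", "ObjectSomeValuesFrom",
                        "ObjectAllValuesFrom", "ObjectMinCardinality",
                        "ObjectMaxCardinality", "ObjectOneOf",
                        "ObjectHasSelf"}:
                self.t.next()
                self.t.expect("lparen")
                expr = self._complex(head, ln, col)
                self.t.expect("rparen")
                return expr
        iri = self._iri()
        if iri == OWL_THING:
            return TOP
        if iri == OWL_NOTHING:
            return BOTTOM
        return Atomic(iri)

    def _complex(self, head: str, ln: int, col: int) -> ConceptExpr:
        if head == "ObjectIntersectionOf":
            return And(*self._expr_list())
        if head == "ObjectUnionOf":
            return Or(*self._expr_list())
        if head == "ObjectComplementOf":
            return Not(self._expr())
        if head == "ObjectSomeValuesFrom":
            return Exists(RoleRef(self._iri()), self._expr())
        if head == "ObjectAllValuesFrom":
            return Forall(RoleRef(self._iri()), self._expr())
        if head in {"ObjectMinCardinality", "ObjectMaxCardinality"}:
            k, n, ln2, col2 = self.t.next()
            if k != "int":
                raise OntologySyntaxError("expected a cardinality", ln2, col2)
            role = RoleRef(self._iri())
            filler = TOP if self.t.peek()[0] == "rparen" else self._expr()
            cls = MinCard if head == "ObjectMinCardinality" else MaxCard
            return cls(int(n), role, filler)
        if head == "ObjectOneOf":
            inds = []
            while self.t.peek()[0] != "rparen":
                inds.append(self._iri())
            if len(inds) != 1:
                raise UnsupportedConstructError(
                    "ObjectOneOf", "only singleton nominals are representable")
            return Nominal(inds[0])
        if head == "ObjectHasSelf":
            return SelfRestriction(RoleRef(self._iri()))
        raise OntologySyntaxError(f"unknown expression {head!r}", ln, col)


def _unquote(raw: str) -> str:
    return raw[1:-1].replace('\\"', '"').replace("\\\\", "\\")


def parse_ontology(text: str) -> Ontology:
    return _OfnParser(text).parse()


def read_ontology_file(path, kind: Optional[str] = None) -> OntologyFile:
    """Parse one file of the dialect; imports stay unresolved."""
    path = Path(path)
    onto = parse_ontology(path.read_text(encoding="utf-8"))
    return OntologyFile(path=path, iri=onto.iri, ontology=onto, kind=kind)
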