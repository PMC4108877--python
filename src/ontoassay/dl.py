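"""Core description-logic data model.

Implements the ALC class-expression grammar (atomic classes, top, bottom,
complement, intersection, union, existential and universal restrictions)
extended with the representable-but-not-reasoned constructs of SROIQ(D):
nominals, Self restrictions and unqualified/qualified number restrictions.
Knowledge bases are split the standard way into a TBox (class axioms), an
RBox (role axioms) and an ABox (assertions about individuals).

Expressions are immutable and canonicalized at construction time:
intersections and unions are flattened, deduplicated and sorted by their
canonical serialization, so structural equality is independent of argument
order.  Syntactic transformations provided here: a Manchester-style surface
parser, negation normal form, signature extraction and TBox internalization
(all GCIs folded into one global concept constraint for the tableau).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class OntoAssayError(Exception):
    """Base class for all package errors."""


class ExpressionSyntaxError(OntoAssayError):
    """Malformed surface syntax; carries a character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class UnknownNameError(OntoAssayError):
    """A name in a surface expression does not resolve in the signature."""

    def __init__(self, name: str):
        super().__init__(f"unknown name: {name!r}")
        self.name = name


class AmbiguousNameError(OntoAssayError):
    def __init__(self, name: str, candidates: Sequence[str]):
        super().__init__(
            f"ambiguous name {name!r}: matches {sorted(candidates)}")
        self.name = name
        self.candidates = tuple(sorted(candidates))


class UnsupportedConstructError(OntoAssayError):
    """A construct is representable but outside the supported fragment."""

    def __init__(self, construct: str, detail: str = ""):
        msg = f"unsupported construct: {construct}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)
        self.construct = construct


# ---------------------------------------------------------------------------
# Roles
# ---------------------------------------------------------------------------

#: Role characteristics that can be *parsed*.  None of them is interpreted by
#: the tableau; a knowledge base whose axioms use a characterized role is
#: rejected loudly by the reasoner.
ROLE_CHARACTERISTICS = frozenset({
    "transitive", "symmetric", "asymmetric", "reflexive", "irreflexive",
    "functional", "inverse-functional",
})


@dataclass(frozen=True, order=True)
class RoleRef:
    """An object property (abstract role), by IRI.

    ``characteristics`` is parsed metadata only; the reasoner supports plain
    roles plus an atomic role hierarchy and refuses anything more.
    """

    name: str
    characteristics: frozenset = field(default_factory=frozenset, compare=False)

    def __post_init__(self):
        bad = set(self.characteristics) - ROLE_CHARACTERISTICS
        if bad:
            raise ValueError(f"unknown role characteristics: {sorted(bad)}")

    @property
    def key(self) -> str:
        return self.name


# ---------------------------------------------------------------------------
# Class expressions
# ---------------------------------------------------------------------------

class ConceptExpr:
    """Base class of the class-expression tree.

    Every node carries a canonical string ``key``; equality, hashing and
    ordering all delegate to it, which makes And/Or argument order
    irrelevant after the construction-time sort.
    """

    __slots__ = ("key",)

    def __init__(self, key: str):
        object.__setattr__(self, "key", key)

    def __eq__(self, other):
        return isinstance(other, ConceptExpr) and self.key == other.key

    def __hash__(self):
        return hash(self.key)

    def __lt__(self, other: "ConceptExpr"):
        return self.key < other.key

    def __repr__(self):
        return self.key

    def __setattr__(self, *_):  # immutability guard
        raise AttributeError("ConceptExpr instances are immutable")


class Atomic(ConceptExpr):
    __slots__ = ("iri",)

    def __init__(self, iri: str):
        object.__setattr__(self, "iri", iri)
        super().__init__(f"<{iri}>")


class _Top(ConceptExpr):
    __slots__ = ()

    def __init__(self):
        super().__init__("Top")


class _Bottom(ConceptExpr):
    __slots__ = ()

    def __init__(self):
        super().__init__("Bottom")


TOP = _Top()
BOTTOM = _Bottom()


class Not(ConceptExpr):
    __slots__ = ("arg",)

    def __init__(self, arg: ConceptExpr):
        object.__setattr__(self, "arg", arg)
        super().__init__(f"Not({arg.key})")


class _NaryBool(ConceptExpr):
    __slots__ = ("args",)

    def __init__(self, tag: str, args: Sequence[ConceptExpr]):
        object.__setattr__(self, "args", tuple(args))
        super().__init__(f"{tag}({' '.join(a.key for a in args)})")


class _And(_NaryBool):
    __slots__ = ()

    def __init__(self, args):
        super().__init__("And", args)


class _Or(_NaryBool):
    __slots__ = ()

    def __init__(self, args):
        super().__init__("Or", args)


def _flatten(kind, args: Iterable[ConceptExpr]) -> list:
    out = []
    for a in args:
        if not isinstance(a, ConceptExpr):
            raise TypeError(f"not a ConceptExpr: {a!r}")
        if isinstance(a, kind):
            out.extend(a.args)
        else:
            out.append(a)
    # dedupe preserving canonical order
    return sorted(set(out))


def And(*args: ConceptExpr) -> ConceptExpr:
    """Intersection; flattens nested intersections, dedupes and sorts.

    Collapses to the single remaining argument (or Top) when fewer than two
    distinct conjuncts survive normalization.
    """
    flat = _flatten(_And, args)
    flat = [a for a in flat if a is not TOP]
    if BOTTOM in flat:
        return BOTTOM
    if not flat:
        return TOP
    if len(flat) == 1:
        return flat[0]
    return _And(flat)


def Or(*args: ConceptExpr) -> ConceptExpr:
    """Union; dual of :func:`And`."""
    flat = _flatten(_Or, args)
    flat = [a for a in flat if a is not BOTTOM]
    if TOP in flat:
        return TOP
    if not flat:
        return BOTTOM
    if len(flat) == 1:
        return flat[0]
    return _Or(flat)


class Exists(ConceptExpr):
    """Existential restriction ∃R.C."""

    __slots__ = ("role", "filler")

    def __init__(self, role: RoleRef, filler: ConceptExpr):
        if isinstance(role, str):
            role = RoleRef(role)
        object.__setattr__(self, "role", role)
        object.__setattr__(self, "filler", filler)
        super().__init__(f"Exists(<{role.name}> {filler.key})")


class Forall(ConceptExpr):
    """Universal restriction ∀R.C."""

    __slots__ = ("role", "filler")

    def __init__(self, role: RoleRef, filler: ConceptExpr):
        if isinstance(role, str):
            role = RoleRef(role)
        object.__setattr__(self, "role", role)
        object.__setattr__(self, "filler", filler)
        super().__init__(f"Forall(<{role.name}> {filler.key})")


class MinCard(ConceptExpr):
    __slots__ = ("n", "role", "filler")

    def __init__(self, n: int, role: RoleRef, filler: ConceptExpr = TOP):
        if n < 1:
            raise ValueError("MinCard requires n >= 1")
        if isinstance(role, str):
            role = RoleRef(role)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "role", role)
        object.__setattr__(self, "filler", filler)
        super().__init__(f"MinCard({n} <{role.name}> {filler.key})")


class MaxCard(ConceptExpr):
    __slots__ = ("n", "role", "filler")

    def __init__(self, n: int, role: RoleRef, filler: ConceptExpr = TOP):
        if n < 0:
            raise ValueError("MaxCard requires n >= 0")
        if isinstance(role, str):
            role = RoleRef(role)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "role", role)
        object.__setattr__(self, "filler", filler)
        super().__init__(f"MaxCard({n} <{role.name}> {filler.key})")


class Nominal(ConceptExpr):
    """Singleton class {a}."""

    __slots__ = ("individual",)

    def __init__(self, individual: str):
        object.__setattr__(self, "individual", individual)
        super().__init__(f"Nominal(<{individual}>)")


class SelfRestriction(ConceptExpr):
    __slots__ = ("role",)

    def __init__(self, role: RoleRef):
        if isinstance(role, str):
            role = RoleRef(role)
        object.__setattr__(self, "role", role)
        super().__init__(f"Self(<{role.name}>)")


def subexpressions(expr: ConceptExpr) -> Iterator[ConceptExpr]:
    """Yield expr and every subexpression (pre-order)."""
    yield expr
    if isinstance(expr, Not):
        yield from subexpressions(expr.arg)
    elif isinstance(expr, _NaryBool):
        for a in expr.args:
            yield from subexpressions(a)
    elif isinstance(expr, (Exists, Forall, MinCard, MaxCard)):
        yield from subexpressions(expr.filler)


# ---------------------------------------------------------------------------
# Axioms
# ---------------------------------------------------------------------------

class Axiom:
    """Base class; canonical-string equality like ConceptExpr."""

    __slots__ = ("key",)

    def __init__(self, key: str):
        object.__setattr__(self, "key", key)

    def __eq__(self, other):
        return isinstance(other, Axiom) and self.key == other.key

    def __hash__(self):
        return hash(self.key)

    def __lt__(self, other: "Axiom"):
        return self.key < other.key

    def __repr__(self):
        return self.key

    def __setattr__(self, *_):
        raise AttributeError("Axiom instances are immutable")


class SubClassOf(Axiom):
    __slots__ = ("sub", "sup")

    def __init__(self, sub: ConceptExpr, sup: ConceptExpr):
        object.__setattr__(self, "sub", sub)
        object.__setattr__(self, "sup", sup)
        super().__init__(f"SubClassOf({sub.key} {sup.key})")


class EquivalentClasses(Axiom):
    __slots__ = ("exprs",)

    def __init__(self, *exprs: ConceptExpr):
        if len(exprs) < 2:
            raise ValueError("EquivalentClasses needs >= 2 expressions")
        exprs = tuple(sorted(set(exprs)))
        object.__setattr__(self, "exprs", exprs)
        super().__init__(
            f"EquivalentClasses({' '.join(e.key for e in exprs)})")


class DisjointClasses(Axiom):
    __slots__ = ("exprs",)

    def __init__(self, *exprs: ConceptExpr):
        if len(exprs) < 2:
            raise ValueError("DisjointClasses needs >= 2 expressions")
        exprs = tuple(sorted(set(exprs)))
        object.__setattr__(self, "exprs", exprs)
        super().__init__(
            f"DisjointClasses({' '.join(e.key for e in exprs)})")


class SubObjectPropertyOf(Axiom):
    __slots__ = ("sub", "sup")

    def __init__(self, sub: RoleRef, sup: RoleRef):
        if isinstance(sub, str):
            sub = RoleRef(sub)
        if isinstance(sup, str):
            sup = RoleRef(sup)
        object.__setattr__(self, "sub", sub)
        object.__setattr__(self, "sup", sup)
        super().__init__(f"SubObjectPropertyOf(<{sub.name}> <{sup.name}>)")


class ClassAssertion(Axiom):
    __slots__ = ("expr", "individual")

    def __init__(self, expr: ConceptExpr, individual: str):
        object.__setattr__(self, "expr", expr)
        object.__setattr__(self, "individual", individual)
        super().__init__(f"ClassAssertion({expr.key} <{individual}>)")


class ObjectPropertyAssertion(Axiom):
    __slots__ = ("role", "subject", "object")

    def __init__(self, role: RoleRef, subject: str, obj: str):
        if isinstance(role, str):
            role = RoleRef(role)
        object.__setattr__(self, "role", role)
        object.__setattr__(self, "subject", subject)
        object.__setattr__(self, "object", obj)
        super().__init__(
            f"ObjectPropertyAssertion(<{role.name}> <{subject}> <{obj}>)")


class DataAssertion(Axiom):
    """A data-property value with an optional unit tag.

    Endpoint results ("there exists a unit and a value") are carried as inert
    data: they are queryable but take no part in satisfiability.
    """

    __slots__ = ("property", "subject", "value", "unit")

    def __init__(self, prop: str, subject: str,
                 value: Union[float, str], unit: Optional[str] = None):
        object.__setattr__(self, "property", prop)
        object.__setattr__(self, "subject", subject)
        object.__setattr__(self, "value", value)
        object.__setattr__(self, "unit", unit)
        vkey = repr(float(value)) if isinstance(value, (int, float)) else repr(value)
        super().__init__(
            f"DataAssertion(<{prop}> <{subject}> {vkey} <{unit or ''}>)")


ENTITY_KINDS = ("Class", "ObjectProperty", "DataProperty",
                "NamedIndividual", "AnnotationProperty")


class Declaration(Axiom):
    __slots__ = ("kind", "iri")

    def __init__(self, kind: str, iri: str):
        if kind not in ENTITY_KINDS:
            raise ValueError(f"unknown entity kind: {kind}")
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "iri", iri)
        super().__init__(f"Declaration({kind} <{iri}>)")


class AnnotationAssertion(Axiom):
    __slots__ = ("subject", "property", "text")

    def __init__(self, subject: str, prop: str, text: str):
        object.__setattr__(self, "subject", subject)
        object.__setattr__(self, "property", prop)
        object.__setattr__(self, "text", text)
        super().__init__(
            f"AnnotationAssertion(<{prop}> <{subject}> {text!r})")


RDFS_LABEL = "http://www.w3.org/2000/01/rdf-schema#label"

_TBOX_KINDS = (SubClassOf, EquivalentClasses, DisjointClasses)
_RBOX_KINDS = (SubObjectPropertyOf,)
_ABOX_KINDS = (ClassAssertion, ObjectPropertyAssertion, DataAssertion)


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------

class Ontology:
    """A TBox + RBox + ABox with declarations, annotations and imports.

    Axiom sets are plain Python sets of canonical axioms, so the union of the
    five sets is duplicate-free by construction.
    """

    def __init__(self, iri: str = "", axioms: Iterable[Axiom] = (),
                 direct_imports: Iterable[str] = ()):
        self.iri = iri
        self.tbox: set = set()
        self.rbox: set = set()
        self.abox: set = set()
        self.declarations: set = set()
        self.annotations: set = set()
        self.direct_imports: list = list(direct_imports)
        for ax in axioms:
            self.add(ax)

    def add(self, axiom: Axiom) -> None:
        if isinstance(axiom, _TBOX_KINDS):
            self.tbox.add(axiom)
        elif isinstance(axiom, _RBOX_KINDS):
            self.rbox.add(axiom)
        elif isinstance(axiom, _ABOX_KINDS):
            self.abox.add(axiom)
        elif isinstance(axiom, Declaration):
            self.declarations.add(axiom)
        elif isinstance(axiom, AnnotationAssertion):
            self.annotations.add(axiom)
        else:
            raise TypeError(f"not an axiom: {axiom!r}")

    def all_axioms(self) -> set:
        return (self.tbox | self.rbox | self.abox
                | self.declarations | self.annotations)

    def logical_axioms(self) -> set:
        """TBox + RBox + ABox (no declarations or annotations)."""
        return self.tbox | self.rbox | self.abox

    def merge(self, other: "Ontology") -> None:
        for ax in other.all_axioms():
            self.add(ax)

    def label_map(self) -> dict:
        """Map normalized rdfs:label text -> IRI (for surface-name lookup)."""
        out: dict = {}
        for ann in self.annotations:
            if ann.property == RDFS_LABEL:
                out.setdefault(_norm_name(ann.text), set()).add(ann.subject)
        return out

    def __eq__(self, other):
        return (isinstance(other, Ontology) and self.iri == other.iri
                and self.all_axioms() == other.all_axioms()
                and sorted(self.direct_imports) == sorted(other.direct_imports))

    def __repr__(self):
        return (f"Ontology(<{self.iri}>, {len(self.all_axioms())} axioms, "
                f"{len(self.direct_imports)} imports)")


# ---------------------------------------------------------------------------
# Signature
# ---------------------------------------------------------------------------

@dataclass
class Signature:
    """IRIs occurring in a set of axioms, partitioned by entity kind."""

    classes: set = field(default_factory=set)
    roles: set = field(default_factory=set)
    individuals: set = field(default_factory=set)
    data_properties: set = field(default_factory=set)

    def update(self, other: "Signature") -> None:
        self.classes |= other.classes
        self.roles |= other.roles
        self.individuals |= other.individuals
        self.data_properties |= other.data_properties

    def all_iris(self) -> set:
        return (self.classes | self.roles | self.individuals
                | self.data_properties)


def _expr_signature(expr: ConceptExpr, sig: Signature) -> None:
    for e in subexpressions(expr):
        if isinstance(e, Atomic):
            sig.classes.add(e.iri)
        elif isinstance(e, (Exists, Forall, MinCard, MaxCard, SelfRestriction)):
            sig.roles.add(e.role.name)
        elif isinstance(e, Nominal):
            sig.individuals.add(e.individual)


_DECL_FIELD = {"Class": "classes", "ObjectProperty": "roles",
               "NamedIndividual": "individuals", "DataProperty": "data_properties"}


def signature_of(axioms: Iterable[Axiom]) -> Signature:
    """Exact set of IRIs occurring in the axioms, partitioned by kind.

    Annotation assertions are non-logical and contribute nothing; entity
    declarations place their IRI in the matching partition.
    """
    sig = Signature()
    for ax in axioms:
        if isinstance(ax, SubClassOf):
            _expr_signature(ax.sub, sig)
            _expr_signature(ax.sup, sig)
        elif isinstance(ax, (EquivalentClasses, DisjointClasses)):
            for e in ax.exprs:
                _expr_signature(e, sig)
        elif isinstance(ax, SubObjectPropertyOf):
            sig.roles.add(ax.sub.name)
            sig.roles.add(ax.sup.name)
        elif isinstance(ax, ClassAssertion):
            _expr_signature(ax.expr, sig)
            sig.individuals.add(ax.individual)
        elif isinstance(ax, ObjectPropertyAssertion):
            sig.roles.add(ax.role.name)
            sig.individuals.add(ax.subject)
            sig.individuals.add(ax.object)
        elif isinstance(ax, DataAssertion):
            sig.data_properties.add(ax.property)
            sig.individuals.add(ax.subject)
        elif isinstance(ax, Declaration):
            f = _DECL_FIELD.get(ax.kind)
            if f is not None:
                getattr(sig, f).add(ax.iri)
        # AnnotationAssertion: skipped on purpose
    return sig


# ---------------------------------------------------------------------------
# Negation normal form
# ---------------------------------------------------------------------------

def _require_supported(expr: ConceptExpr) -> None:
    for e in subexpressions(expr):
        if isinstance(e, (MinCard, MaxCard)):
            raise UnsupportedConstructError(
                "cardinality restriction", e.key)
        if isinstance(e, Nominal):
            raise UnsupportedConstructError("nominal", e.key)
        if isinstance(e, SelfRestriction):
            raise UnsupportedConstructError("self restriction", e.key)


def to_nnf(expr: ConceptExpr) -> ConceptExpr:
    """Push negations down to atomic classes (supported fragment only)."""
    _require_supported(expr)
    return _nnf(expr)


def _nnf(e: ConceptExpr) -> ConceptExpr:
    if isinstance(e, Not):
        return _nnf_neg(e.arg)
    if isinstance(e, _And):
        return And(*[_nnf(a) for a in e.args])
    if isinstance(e, _Or):
        return Or(*[_nnf(a) for a in e.args])
    if isinstance(e, Exists):
        return Exists(e.role, _nnf(e.filler))
    if isinstance(e, Forall):
        return Forall(e.role, _nnf(e.filler))
    return e


def _nnf_neg(e: ConceptExpr) -> ConceptExpr:
    if isinstance(e, Not):
        return _nnf(e.arg)
    if e is TOP:
        return BOTTOM
    if e is BOTTOM:
        return TOP
    if isinstance(e, _And):
        return Or(*[_nnf_neg(a) for a in e.args])
    if isinstance(e, _Or):
        return And(*[_nnf_neg(a) for a in e.args])
    if isinstance(e, Exists):
        return Forall(e.role, _nnf_neg(e.filler))
    if isinstance(e, Forall):
        return Exists(e.role, _nnf_neg(e.filler))
    if isinstance(e, Atomic):
        return Not(e)
    raise UnsupportedConstructError(type(e).__name__, e.key)


# ---------------------------------------------------------------------------
# Internalization
# ---------------------------------------------------------------------------

def gcis_of(axiom: Axiom) -> list:
    """Expand a class axiom into its list of (sub, sup) GCIs."""
    if isinstance(axiom, SubClassOf):
        return [(axiom.sub, axiom.sup)]
    if isinstance(axiom, EquivalentClasses):
        out = []
        es = axiom.exprs
        for a, b in zip(es, es[1:]):
            out.append((a, b))
            out.append((b, a))
        return out
    if isinstance(axiom, DisjointClasses):
        out = []
        es = axiom.exprs
        for i in range(len(es)):
            for j in range(i + 1, len(es)):
                out.append((And(es[i], es[j]), BOTTOM))
        return out
    raise UnsupportedConstructError(type(axiom).__name__, axiom.key)


def internalize(tbox: Iterable[Axiom]) -> ConceptExpr:
    """Fold all GCIs into one global NNF constraint ⨅ (¬C ⊔ D).

    An empty TBox internalizes to Top.
    """
    parts = []
    for ax in sorted(tbox):
        for sub, sup in gcis_of(ax):
            parts.append(to_nnf(Or(Not(sub), sup)))
    return And(*parts) if parts else TOP


# ---------------------------------------------------------------------------
# Manchester-style surface parser
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<quoted>'(?:[^'\\]|\\.)*')
      | (?P<lparen>\()
      | (?P<rparen>\))
      | (?P<lbrace>\{)
      | (?P<rbrace>\})
      | (?P<int>\d+)
      | (?P<word>[^\s(){}']+)
    )""",
    re.VERBOSE,
)

_KEYWORDS = {"and", "or", "not", "some", "only", "min", "max", "self"}


def _norm_name(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip()).casefold()


def _local_name(iri: str) -> str:
    for sep in ("#", "/", ":"):
        if sep in iri:
            iri = iri.rsplit(sep, 1)[1]
    return iri


class NameResolver:
    """Resolve surface names to IRIs of one entity category.

    A name matches an IRI if it equals the IRI itself, the IRI's local name,
    the local name with underscores read as spaces, or a supplied rdfs:label
    (all after whitespace normalization and case folding).  Two IRIs sharing
    a surface form make that form an error, never a guess.
    """

    def __init__(self, iris: Iterable[str],
                 labels: Optional[Mapping[str, set]] = None):
        self.table: dict = {}
        for iri in iris:
            self._put(iri, iri)
            local = _local_name(iri)
            self._put(_norm_name(local), iri)
            spaced = local.replace("_", " ")
            self._put(_norm_name(spaced), iri)
            # printed names may hyphenate what the IRI underscores
            self._put(_norm_name(spaced.replace("-", " ")), iri)
        if labels:
            for label, iri_set in labels.items():
                for iri in iri_set:
                    self._put(_norm_name(label), iri)

    def _put(self, name: str, iri: str):
        self.table.setdefault(name, set()).add(iri)

    def resolve(self, name: str) -> str:
        hits = (self.table.get(name) or self.table.get(_norm_name(name))
                or self.table.get(_norm_name(name.replace("-", " "))))
        if not hits:
            raise UnknownNameError(name)
        if len(hits) > 1:
            raise AmbiguousNameError(name, hits)
        return next(iter(hits))


class _Parser:
    def __init__(self, text: str, sig: Signature,
                 labels: Optional[Mapping[str, set]] = None):
        self.text = text
        self.tokens: list = []  # (kind, value, pos)
        pos = 0
        while pos < len(text):
            m = _TOKEN_RE.match(text, pos)
            if not m or m.end() == pos:
                raise ExpressionSyntaxError("cannot tokenize", pos)
            kind = m.lastgroup
            val = m.group(kind)
            tok_pos = m.start(kind)
            if kind == "quoted":
                val = val[1:-1].replace("\\'", "'")
                kind = "name"
            elif kind == "word":
                low = val.casefold()
                if low in _KEYWORDS:
                    kind, val = "kw", low
                else:
                    kind = "name"
            self.tokens.append((kind, val, tok_pos))
            pos = m.end()
        self.i = 0
        label_subset = None
        if labels:
            label_subset = {k: v for k, v in labels.items()}
        self.classes = NameResolver(sig.classes, label_subset)
        self.roles = NameResolver(sig.roles, label_subset)
        self.individuals = NameResolver(sig.individuals, label_subset)

    # -- token helpers
    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None, len(self.text))

    def next(self):
        tok = self.peek()
        self.i += 1
        return tok

    def expect(self, kind, value=None):
        k, v, p = self.next()
        if k != kind or (value is not None and v != value):
            raise ExpressionSyntaxError(
                f"expected {value or kind}, found {v!r}", p)
        return v

    # -- grammar: or_expr > and_expr > unary > primary
    def parse(self) -> ConceptExpr:
        e = self.or_expr()
        k, v, p = self.peek()
        if k is not None:
            raise ExpressionSyntaxError(f"unexpected trailing token {v!r}", p)
        return e

    def or_expr(self) -> ConceptExpr:
        parts = [self.and_expr()]
        while self.peek()[:2] == ("kw", "or"):
            self.next()
            parts.append(self.and_expr())
        return Or(*parts) if len(parts) > 1 else parts[0]

    def and_expr(self) -> ConceptExpr:
        parts = [self.unary()]
        while self.peek()[:2] == ("kw", "and"):
            self.next()
            parts.append(self.unary())
        return And(*parts) if len(parts) > 1 else parts[0]

    def unary(self) -> ConceptExpr:
        k, v, p = self.peek()
        if (k, v) == ("kw", "not"):
            self.next()
            return Not(self.unary())
        if k == "name":
            # look ahead: a restriction is "<role> some|only|min|max|self ..."
            nk, nv, _ = self.tokens[self.i + 1][:3] if self.i + 1 < len(self.tokens) else (None, None, None)
            if nk == "kw" and nv in {"some", "only", "min", "max", "self"}:
                return self.restriction()
        return self.primary()

    def restriction(self) -> ConceptExpr:
        _, rname, p = self.next()
        try:
            role = RoleRef(self.roles.resolve(rname))
        except UnknownNameError:
            raise UnknownNameError(rname)
        _, quant, _ = self.next()
        if quant == "some":
            return Exists(role, self.unary())
        if quant == "only":
            return Forall(role, self.unary())
        if quant == "self":
            return SelfRestriction(role)
        k, n, p2 = self.next()
        if k != "int":
            raise ExpressionSyntaxError(
                f"expected a cardinality after {quant!r}", p2)
        filler = TOP
        nk = self.peek()[0]
        if nk in {"name", "lparen", "kw"} and self.peek()[:2] != ("kw", "and") \
                and self.peek()[:2] != ("kw", "or"):
            filler = self.unary()
        if quant == "min":
            return MinCard(int(n), role, filler)
        return MaxCard(int(n), role, filler)

    def primary(self) -> ConceptExpr:
        k, v, p = self.next()
        if k == "lparen":
            e = self.or_expr()
            self.expect("rparen")
            return e
        if k == "lbrace":
            _, name, _ = self.next()
            self.expect("rbrace")
            return Nominal(self.individuals.resolve(name))
        if k == "name":
            if v in {"owl:Thing", "Thing"}:
                return TOP
            if v in {"owl:Nothing", "Nothing"}:
                return BOTTOM
            return Atomic(self.classes.resolve(v))
        raise ExpressionSyntaxError(f"unexpected token {v!r}", p)


def parse_class_expression(text: str, sig: Signature,
                           labels: Optional[Mapping[str, set]] = None
                           ) -> ConceptExpr:
    """Parse a Manchester-style class expression against a signature.

    Keywords: ``and``, ``or``, ``not``, ``some``, ``only``, ``min``, ``max``,
    ``self``; multi-word names are single-quoted; ``{a}`` is a nominal.
    Names must resolve in ``sig`` (optionally helped by an rdfs:label map,
    e.g. :meth:`Ontology.label_map`); unknown names raise, nothing is
    silently created.  The parser preserves structure apart from the
    canonical And/Or normalization — in particular it never rewrites
    negations.
    """
    return _Parser(text, sig, labels).parse()
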