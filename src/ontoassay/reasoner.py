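"""Tableau reasoning for ALC plus an atomic role hierarchy.

The decision procedure is a standard completion-graph tableau: absorbable
axioms (atomic left-hand sides) are handled by lazy unfolding, the remaining
general class inclusions are internalized into one global constraint added
to every node, and termination under GCIs is guaranteed by subset blocking
against tree ancestors.  Disjunctions are explored depth-first in canonical
order, so every run is fully deterministic.

Each satisfiable verdict is accompanied by a finite model exported from the
completion graph (blocked leaves borrow the witnesses of their blockers);
``verify_model`` evaluates the direct model-theoretic semantics over such a
structure and is the package's independent testing oracle, together with
``exhaustive_model_search`` which enumerates all interpretations up to a
bounded domain size.

Everything beyond the supported fragment — nominals, Self, cardinality
restrictions, role characteristics, role chains — errors loudly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import (Dict, FrozenSet, Iterable, List, Optional, Sequence, Set,
                    Tuple, Union)

import networkx as nx

from .dl import (
    TOP, BOTTOM, And, Atomic, Axiom, ClassAssertion, ConceptExpr, DataAssertion,
    Declaration, DisjointClasses, EquivalentClasses, Exists, Forall, Not,
    ObjectPropertyAssertion, Ontology, OntoAssayError, Or, RoleRef, SubClassOf,
    SubObjectPropertyOf, UnsupportedConstructError, _And, _Or, gcis_of,
    signature_of, to_nnf,
)

TOP_IRI = "http://www.w3.org/2002/07/owl#Thing"
BOTTOM_IRI = "http://www.w3.org/2002/07/owl#Nothing"

DEFAULT_NODE_CAP = 50_000


class ResourceLimitError(OntoAssayError):
    def __init__(self, cap: int):
        super().__init__(f"tableau exceeded the node cap ({cap})")
        self.cap = cap


class InconsistentOntologyError(OntoAssayError):
    def __init__(self, detail: str = "the knowledge base is inconsistent"):
        super().__init__(detail)


class NotEntailedError(OntoAssayError):
    def __init__(self, axiom: Axiom):
        super().__init__(f"not entailed: {axiom!r}")
        self.axiom = axiom


class UnknownIndividualError(OntoAssayError):
    def __init__(self, iri: str):
        super().__init__(f"unknown individual: <{iri}>")
        self.iri = iri


# ---------------------------------------------------------------------------
# Interpretations (finite structures)
# ---------------------------------------------------------------------------

@dataclass
class Interpretation:
    """A finite structure: domain Δ, class/role extensions, individual map."""

    domain: frozenset
    class_ext: Dict[str, frozenset]
    role_ext: Dict[str, frozenset]
    individual_map: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if not self.domain:
            raise ValueError("interpretation domain must be nonempty")
        for ext in self.class_ext.values():
            if not ext <= self.domain:
                raise ValueError("class extension outside domain")
        for pairs in self.role_ext.values():
            for a, b in pairs:
                if a not in self.domain or b not in self.domain:
                    raise ValueError("role extension outside domain")
        for el in self.individual_map.values():
            if el not in self.domain:
                raise ValueError("individual mapped outside domain")


def concept_extension(expr: ConceptExpr, interp: Interpretation) -> frozenset:
    """Evaluate the extended interpretation function on a class expression."""
    if isinstance(expr, Atomic):
        return interp.class_ext.get(expr.iri, frozenset())
    if expr is TOP:
        return frozenset(interp.domain)
    if expr is BOTTOM:
        return frozenset()
    if isinstance(expr, Not):
        return frozenset(interp.domain) - concept_extension(expr.arg, interp)
    if isinstance(expr, _And):
        exts = [concept_extension(a, interp) for a in expr.args]
        return frozenset(set.intersection(*map(set, exts)))
    if isinstance(expr, _Or):
        out: set = set()
        for a in expr.args:
            out |= concept_extension(a, interp)
        return frozenset(out)
    if isinstance(expr, Exists):
        pairs = interp.role_ext.get(expr.role.name, frozenset())
        filler = concept_extension(expr.filler, interp)
        return frozenset(a for a, b in pairs if b in filler)
    if isinstance(expr, Forall):
        pairs = interp.role_ext.get(expr.role.name, frozenset())
        filler = concept_extension(expr.filler, interp)
        bad = frozenset(a for a, b in pairs if b not in filler)
        return frozenset(interp.domain) - bad
    raise UnsupportedConstructError(type(expr).__name__, expr.key)


def verify_model(interp: Interpretation, kb) -> bool:
    """True iff every logical axiom of ``kb`` holds in ``interp``.

    Declarations and annotations are non-logical; data assertions are inert.
    A class or role assertion about an individual missing from the
    individual map counts as unsatisfied.
    """
    for ax in sorted(_logical_axioms(kb)):
        if isinstance(ax, SubClassOf):
            if not concept_extension(ax.sub, interp) <= \
                    concept_extension(ax.sup, interp):
                return False
        elif isinstance(ax, EquivalentClasses):
            exts = [concept_extension(e, interp) for e in ax.exprs]
            if any(e != exts[0] for e in exts[1:]):
                return False
        elif isinstance(ax, DisjointClasses):
            exts = [concept_extension(e, interp) for e in ax.exprs]
            for i in range(len(exts)):
                for j in range(i + 1, len(exts)):
                    if exts[i] & exts[j]:
                        return False
        elif isinstance(ax, SubObjectPropertyOf):
            if not interp.role_ext.get(ax.sub.name, frozenset()) <= \
                    interp.role_ext.get(ax.sup.name, frozenset()):
                return False
        elif isinstance(ax, ClassAssertion):
            el = interp.individual_map.get(ax.individual)
            if el is None or el not in concept_extension(ax.expr, interp):
                return False
        elif isinstance(ax, ObjectPropertyAssertion):
            a = interp.individual_map.get(ax.subject)
            b = interp.individual_map.get(ax.object)
            if a is None or b is None or \
                    (a, b) not in interp.role_ext.get(ax.role.name, frozenset()):
                return False
        elif isinstance(ax, DataAssertion):
            continue
        else:  # pragma: no cover - routed out by _logical_axioms
            raise UnsupportedConstructError(type(ax).__name__)
    return True


def _logical_axioms(kb) -> Set[Axiom]:
    if isinstance(kb, KnowledgeBase):
        return set(kb.axioms)
    if isinstance(kb, Ontology):
        return kb.logical_axioms()
    return {ax for ax in kb
            if not isinstance(ax, Declaration)
            and not ax.key.startswith("AnnotationAssertion")}


# ---------------------------------------------------------------------------
# Knowledge base preprocessing (absorption + internalization)
# ---------------------------------------------------------------------------

class KnowledgeBase:
    """Preprocessed axioms ready for the tableau.

    Atomic-LHS GCIs become lazy unfoldings (A in a node label pulls in its
    told constraints); everything else is internalized into the global
    constraint list applied at every node.  The role hierarchy is closed
    reflexively and transitively once.
    """

    def __init__(self, source: Union[Ontology, Iterable[Axiom]],
                 node_cap: int = DEFAULT_NODE_CAP):
        if isinstance(source, Ontology):
            axioms = source.logical_axioms()
            self.declarations = set(source.declarations)
        else:
            axioms = set()
            self.declarations = set()
            for ax in source:
                if isinstance(ax, Declaration):
                    self.declarations.add(ax)
                elif not ax.key.startswith("AnnotationAssertion"):
                    axioms.add(ax)
        self.axioms: FrozenSet[Axiom] = frozenset(axioms)
        self.node_cap = node_cap
        self.signature = signature_of(self.axioms | self.declarations)
        self._check_roles()

        # role hierarchy: reflexive-transitive closure of told sub-properties
        g = nx.DiGraph()
        g.add_nodes_from(self.signature.roles)
        for ax in self.axioms:
            if isinstance(ax, SubObjectPropertyOf):
                g.add_edge(ax.sub.name, ax.sup.name)
        self.role_supers: Dict[str, frozenset] = {
            r: frozenset(nx.descendants(g, r) | {r}) for r in g.nodes}

        # absorption
        self.unfoldings: Dict[str, List[ConceptExpr]] = {}
        g_parts: List[ConceptExpr] = []
        for ax in sorted(self.axioms):
            if isinstance(ax, (SubClassOf, EquivalentClasses, DisjointClasses)):
                for sub, sup in gcis_of(ax):
                    if isinstance(sub, Atomic):
                        self.unfoldings.setdefault(sub.iri, []).append(
                            to_nnf(sup))
                    elif isinstance(sub, _And) and any(
                            isinstance(c, Atomic) for c in sub.args):
                        # absorb A ⊓ rest ⊑ D as A → ¬rest ⊔ D
                        a = next(c for c in sorted(sub.args)
                                 if isinstance(c, Atomic))
                        rest = And(*[c for c in sub.args if c is not a])
                        self.unfoldings.setdefault(a.iri, []).append(
                            to_nnf(Or(Not(rest), sup)))
                    else:
                        g_parts.append(to_nnf(Or(Not(sub), sup)))
        for v in self.unfoldings.values():
            v.sort()
        self.globals: Tuple[ConceptExpr, ...] = tuple(sorted(set(g_parts)))

        # ABox
        self.individuals = sorted(self.signature.individuals)
        self.abox_labels: Dict[str, Set[ConceptExpr]] = {
            i: set() for i in self.individuals}
        self.abox_edges: List[Tuple[str, str, str]] = []
        for ax in sorted(self.axioms):
            if isinstance(ax, ClassAssertion):
                self.abox_labels[ax.individual].add(to_nnf(ax.expr))
            elif isinstance(ax, ObjectPropertyAssertion):
                self.abox_edges.append((ax.subject, ax.role.name, ax.object))

        self._consistent: Optional[bool] = None
        self._sat_cache: Dict[str, bool] = {}

    def _check_roles(self) -> None:
        for ax in self.axioms:
            roles = []
            if isinstance(ax, SubObjectPropertyOf):
                roles = [ax.sub, ax.sup]
            elif isinstance(ax, ObjectPropertyAssertion):
                roles = [ax.role]
            elif isinstance(ax, (SubClassOf, EquivalentClasses,
                                 DisjointClasses, ClassAssertion)):
                exprs = ([ax.sub, ax.sup] if isinstance(ax, SubClassOf)
                         else [ax.expr] if isinstance(ax, ClassAssertion)
                         else list(ax.exprs))
                from .dl import subexpressions
                for e in exprs:
                    for s in subexpressions(e):
                        if hasattr(s, "role") and isinstance(
                                getattr(s, "role"), RoleRef):
                            roles.append(s.role)
            for r in roles:
                if r.characteristics:
                    raise UnsupportedConstructError(
                        "role characteristics",
                        f"<{r.name}>: {sorted(r.characteristics)}")

    def super_roles(self, role: str) -> frozenset:
        return self.role_supers.get(role, frozenset({role}))


def _as_kb(kb) -> KnowledgeBase:
    return kb if isinstance(kb, KnowledgeBase) else KnowledgeBase(kb)


# ---------------------------------------------------------------------------
# The tableau
# ---------------------------------------------------------------------------

@dataclass
class SatResult:
    satisfiable: bool
    model: Optional[Interpretation] = None


_EMPTY_DEP: FrozenSet[int] = frozenset()


class _State:
    """A completion graph with dependency-tracked labels.

    Every label entry and edge carries the set of branch points it depends
    on, enabling dependency-directed backjumping: when a clash does not
    involve a choice point, its remaining alternatives are skipped.
    """

    __slots__ = ("labels", "deps", "edges", "parent", "order", "next_id")

    def __init__(self):
        self.labels: Dict[int, Set[ConceptExpr]] = {}
        self.deps: Dict[Tuple[int, str], FrozenSet[int]] = {}
        self.edges: Dict[int, List[Tuple[str, int, FrozenSet[int]]]] = {}
        self.parent: Dict[int, Optional[int]] = {}
        self.order: List[int] = []
        self.next_id = 0

    def new_node(self, parent: Optional[int]) -> int:
        n = self.next_id
        self.next_id += 1
        self.labels[n] = set()
        self.edges[n] = []
        self.parent[n] = parent
        self.order.append(n)
        return n

    def add(self, n: int, c: ConceptExpr, dep: FrozenSet[int]) -> bool:
        if c in self.labels[n]:
            return False
        self.labels[n].add(c)
        self.deps[(n, c.key)] = dep
        return True

    def dep(self, n: int, c: ConceptExpr) -> FrozenSet[int]:
        return self.deps.get((n, c.key), _EMPTY_DEP)

    def clone(self) -> "_State":
        s = _State.__new__(_State)
        s.labels = {k: set(v) for k, v in self.labels.items()}
        s.deps = dict(self.deps)
        s.edges = {k: list(v) for k, v in self.edges.items()}
        s.parent = dict(self.parent)
        s.order = list(self.order)
        s.next_id = self.next_id
        return s


def _branch_key(d: ConceptExpr) -> Tuple[int, str]:
    """Branch-order heuristic: cheap (non-generating) disjuncts first."""
    rank = 0 if isinstance(d, (Not, Forall)) else 1
    return (rank, d.key)


_NEG_CACHE: Dict[str, ConceptExpr] = {}


def _negation_of(expr: ConceptExpr) -> ConceptExpr:
    """NNF complement, cached (used for disjunct pruning)."""
    neg = _NEG_CACHE.get(expr.key)
    if neg is None:
        neg = to_nnf(Not(expr))
        _NEG_CACHE[expr.key] = neg
    return neg


class _Tableau:
    def __init__(self, kb: KnowledgeBase):
        self.kb = kb
        self._next_branch = 0

    # -- public entry ------------------------------------------------------
    def run(self, init_roots: List[Tuple[Optional[str], Set[ConceptExpr]]]
            ) -> Optional[Interpretation]:
        """Saturate from the given roots; return a model or None.

        ``init_roots`` is a list of (individual-IRI-or-None, extra label)
        pairs; ABox role edges are added between individual roots.
        """
        import sys
        if sys.getrecursionlimit() < 30_000:
            sys.setrecursionlimit(30_000)
        state = _State()
        node_of: Dict[str, int] = {}
        for ind, extra in init_roots:
            n = state.new_node(None)
            for c in self.kb.globals:
                state.add(n, c, _EMPTY_DEP)
            for c in extra:
                state.add(n, c, _EMPTY_DEP)
            if ind is not None:
                node_of[ind] = n
        for s, r, o in self.kb.abox_edges:
            if s in node_of and o in node_of:
                state.edges[node_of[s]].append((r, node_of[o], _EMPTY_DEP))
        self._ind_nodes = dict(node_of)
        result = self._expand(state)
        return result if isinstance(result, Interpretation) else None

    # -- rules -------------------------------------------------------------
    def _saturate(self, state: _State) -> Optional[FrozenSet[int]]:
        """Apply deterministic rules to fixpoint.

        Returns None when saturated without clash, else the union of branch
        points the clash depends on.
        """
        changed = True
        while changed:
            changed = False
            for n in list(state.order):
                label = state.labels[n]
                for c in list(label):
                    cdep = state.dep(n, c)
                    if isinstance(c, _And):
                        for a in c.args:
                            changed |= state.add(n, a, cdep)
                    elif isinstance(c, _Or):
                        # unit propagation: drop contradicted disjuncts
                        if any(d in label for d in c.args):
                            continue
                        open_d, pdep = [], set(cdep)
                        for d in c.args:
                            nd = _negation_of(d)
                            if nd in label:
                                pdep |= state.dep(n, nd)
                            else:
                                open_d.append(d)
                        if not open_d:
                            return frozenset(pdep)
                        if len(open_d) == 1:
                            changed |= state.add(n, open_d[0],
                                                 frozenset(pdep))
                    elif isinstance(c, Atomic):
                        for u in self.kb.unfoldings.get(c.iri, ()):
                            changed |= state.add(n, u, cdep)
                    elif isinstance(c, Forall):
                        for r, dst, edep in state.edges[n]:
                            if c.role.name in self.kb.super_roles(r):
                                changed |= state.add(dst, c.filler,
                                                     cdep | edep)
                clash = self._clash_dep(state, n)
                if clash is not None:
                    return clash
            if changed:
                continue
            # generating rule last, gated by blocking
            blocked = self._blocked(state)
            for n in list(state.order):
                if blocked[n]:
                    continue
                for c in sorted(state.labels[n]):
                    if isinstance(c, Exists):
                        if self._has_witness(state, n, c):
                            continue
                        if state.next_id >= self.kb.node_cap:
                            raise ResourceLimitError(self.kb.node_cap)
                        cdep = state.dep(n, c)
                        child = state.new_node(n)
                        state.add(child, c.filler, cdep)
                        for g in self.kb.globals:
                            state.add(child, g, cdep)
                        state.edges[n].append((c.role.name, child, cdep))
                        changed = True
                if changed:
                    break  # re-run cheap rules before generating more
        return None

    def _has_witness(self, state: _State, n: int, c: Exists) -> bool:
        for r, dst, _dep in state.edges[n]:
            if c.role.name in self.kb.super_roles(r) and \
                    c.filler in state.labels[dst]:
                return True
        return False

    @staticmethod
    def _clash_dep(state: _State, n: int) -> Optional[FrozenSet[int]]:
        label = state.labels[n]
        if BOTTOM in label:
            return state.dep(n, BOTTOM)
        for c in label:
            if isinstance(c, Not) and c.arg in label:
                return state.dep(n, c) | state.dep(n, c.arg)
        return None

    def _blocked(self, state: _State) -> Dict[int, bool]:
        """Anywhere subset blocking.

        A non-root node is blocked when some earlier unblocked node's label
        contains its own (the blocker's witnesses then serve for both in
        the exported model); descendants of blocked nodes are blocked too.
        Computed in creation order, so the relation is deterministic.
        """
        blocked: Dict[int, bool] = {}
        unblocked: List[int] = []
        for n in state.order:
            p = state.parent[n]
            if p is None:
                blocked[n] = False
                unblocked.append(n)
                continue
            if blocked[p]:
                blocked[n] = True
                continue
            label = state.labels[n]
            b = any(label <= state.labels[m] for m in unblocked)
            blocked[n] = b
            if not b:
                unblocked.append(n)
        return blocked

    # -- search ------------------------------------------------------------
    def _expand(self, state: _State
                ) -> Union[Interpretation, FrozenSet[int]]:
        """Depth-first search over Or-choices with backjumping.

        Returns a model, or the set of branch points the failure depends
        on; a choice point absent from that set is skipped entirely
        (dependency-directed backtracking).  Branch order is deterministic:
        non-generating disjuncts first, then canonical order; each branch
        additionally asserts the literal complements of the disjuncts
        already refuted (semantic branching).
        """
        clash = self._saturate(state)
        if clash is not None:
            return clash
        pick = self._pick_disjunction(state)
        if pick is None:
            return self._build_model(state)
        n, or_c, open_d, prune_dep = pick
        k = self._next_branch
        self._next_branch += 1
        base = state.dep(n, or_c) | prune_dep
        union: Set[int] = set()
        negs: List[ConceptExpr] = []
        for d in sorted(open_d, key=_branch_key):
            child = state.clone()
            bdep = base | {k}
            child.add(n, d, bdep)
            for nc in negs:
                child.add(n, nc, bdep)
            res = self._expand(child)
            if isinstance(res, Interpretation):
                return res
            if k not in res:
                return res  # clash independent of this choice: backjump
            union |= res
            if isinstance(d, Atomic) or \
                    (isinstance(d, Not) and isinstance(d.arg, Atomic)):
                negs.append(_negation_of(d))
        union.discard(k)
        return frozenset(union)

    @staticmethod
    def _pick_disjunction(state: _State):
        """First undecided disjunction in creation/canonical order."""
        for n in state.order:
            label = state.labels[n]
            for c in sorted(label):
                if isinstance(c, _Or) and not any(d in label
                                                  for d in c.args):
                    open_d, pdep = [], set()
                    for d in c.args:
                        nd = _negation_of(d)
                        if nd in label:
                            pdep |= state.dep(n, nd)
                        else:
                            open_d.append(d)
                    return n, c, open_d, frozenset(pdep)
        return None

    # -- model export ------------------------------------------------------
    def _build_model(self, state: _State) -> Interpretation:
        blocked = self._blocked(state)

        def blocker(n: int) -> int:
            for m in state.order:
                if m != n and not blocked[m] \
                        and state.labels[n] <= state.labels[m]:
                    return m
            raise AssertionError("blocked node without blocker")

        live = [n for n in state.order if not blocked[n]]
        live_set = set(live)
        class_ext: Dict[str, set] = {}
        role_ext: Dict[str, set] = {}
        for n in live:
            for c in state.labels[n]:
                if isinstance(c, Atomic):
                    class_ext.setdefault(c.iri, set()).add(n)
            for r, dst, _dep in state.edges[n]:
                target = dst if dst in live_set else blocker(dst)
                for sup in self.kb.super_roles(r):
                    role_ext.setdefault(sup, set()).add((n, target))
        ind_map = {i: n for i, n in getattr(self, "_ind_nodes", {}).items()}
        return Interpretation(
            domain=frozenset(live),
            class_ext={k: frozenset(v) for k, v in class_ext.items()},
            role_ext={k: frozenset(v) for k, v in role_ext.items()},
            individual_map=ind_map,
        )


# ---------------------------------------------------------------------------
# Reasoning services
# ---------------------------------------------------------------------------

def is_consistent(kb) -> bool:
    """Global (ABox + TBox) consistency."""
    kb = _as_kb(kb)
    if kb._consistent is None:
        tableau = _Tableau(kb)
        if kb.individuals:
            roots = [(i, set(kb.abox_labels[i])) for i in kb.individuals]
        else:
            roots = [(None, set())]
        kb._consistent = tableau.run(roots) is not None
    return kb._consistent


def is_satisfiable(kb, expr: ConceptExpr) -> SatResult:
    """Concept satisfiability with respect to the knowledge base.

    A positive verdict always carries a witness model exported from the
    completion graph; the model verifies under :func:`verify_model` for the
    TBox/RBox part of the KB.
    """
    kb = _as_kb(kb)
    nnf = to_nnf(expr)
    roots = [(i, set(kb.abox_labels[i])) for i in kb.individuals]
    roots.append((None, {nnf}))
    model = _Tableau(kb).run(roots)
    if model is None:
        return SatResult(False)
    return SatResult(True, model)


def _tbox_satisfiable(kb: KnowledgeBase, expr: ConceptExpr) -> bool:
    """Concept satisfiability from a single fresh root.

    Without nominals the ABox influences class satisfiability only through
    global inconsistency, which callers check once (cached); leaving the
    ABox roots out keeps classification linear in the TBox.
    """
    key = expr.key
    if key not in kb._sat_cache:
        nnf = to_nnf(expr)
        kb._sat_cache[key] = \
            _Tableau(kb).run([(None, {nnf})]) is not None
    return kb._sat_cache[key]


def check_subsumption(kb, sub: ConceptExpr, sup: ConceptExpr) -> bool:
    """kb ⊨ sub ⊑ sup, by refutation: sub ⊓ ¬sup must be unsatisfiable."""
    kb = _as_kb(kb)
    if not is_consistent(kb):
        return True
    return not _tbox_satisfiable(kb, And(sub, Not(sup)))


def check_instance(kb, individual: str, expr: ConceptExpr) -> bool:
    """kb ⊨ expr(individual), by refutation against the ABox."""
    kb = _as_kb(kb)
    if individual not in kb.abox_labels:
        raise UnknownIndividualError(individual)
    neg = to_nnf(Not(expr))
    roots = [(i, set(kb.abox_labels[i])
              | ({neg} if i == individual else set()))
             for i in kb.individuals]
    return _Tableau(kb).run(roots) is None


def retrieve_instances(kb, expr: ConceptExpr) -> Set[str]:
    """All declared individuals entailed to be instances of ``expr``."""
    kb = _as_kb(kb)
    return {i for i in kb.individuals if check_instance(kb, i, expr)}


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass
class InferredHierarchy:
    """The entailed named-class hierarchy, transitively reduced.

    ``direct_supers`` maps each named class (plus owl:Thing/owl:Nothing) to
    its direct superclasses; ``equivalents`` partitions classes into
    equivalence groups (unsatisfiable classes share the owl:Nothing group);
    ``ancestors_map`` keeps the full entailed preorder for queries.
    """

    direct_supers: Dict[str, FrozenSet[str]]
    equivalents: List[FrozenSet[str]]
    satisfiable_flags: Dict[str, bool]
    ancestors_map: Dict[str, FrozenSet[str]] = field(default_factory=dict)

    def direct_subclasses(self, iri: str) -> Set[str]:
        return {c for c, sups in self.direct_supers.items() if iri in sups}

    def ancestors(self, iri: str) -> FrozenSet[str]:
        return self.ancestors_map.get(iri, frozenset())

    def is_subsumed(self, sub: str, sup: str) -> bool:
        return sup == sub or sup in self.ancestors_map.get(sub, frozenset())

    def equivalence_group(self, iri: str) -> FrozenSet[str]:
        for grp in self.equivalents:
            if iri in grp:
                return grp
        return frozenset({iri})


def _positive_toplevel_atoms(expr: ConceptExpr, out: Set[str]) -> None:
    """Positive atoms reachable through And/Or only (not under quantifiers)."""
    if isinstance(expr, Atomic):
        out.add(expr.iri)
    elif isinstance(expr, (_And, _Or)):
        for a in expr.args:
            _positive_toplevel_atoms(a, out)


def _candidate_supers(kb: KnowledgeBase) -> Set[str]:
    """Named classes that can possibly subsume non-told.

    During a subsumption test sub ⊑ D the tableau root label grows only by
    And/Or decomposition, lazy unfolding and the global constraints —
    quantified fillers land on successor nodes.  The clash refuting ¬D
    therefore needs a positive, quantifier-free occurrence of D in some
    unfolding or global conjunct; classes without one gain no entailed
    subsumers beyond told ones (unsatisfiable subs are handled separately).
    """
    cands: Set[str] = set()
    for rhss in kb.unfoldings.values():
        for rhs in rhss:
            _positive_toplevel_atoms(rhs, cands)
    for g in kb.globals:
        _positive_toplevel_atoms(g, cands)
    return cands


def classify(kb) -> InferredHierarchy:
    """Compute the entailed subsumption hierarchy over named classes.

    Told subsumers are seeded without tableau calls; remaining pairs are
    decided by subsumption tests restricted to candidate superclasses, and
    the resulting preorder is condensed (equivalence groups) and transitively
    reduced.  Classes are processed in lexicographic IRI order.
    """
    kb = _as_kb(kb)
    if not is_consistent(kb):
        raise InconsistentOntologyError()
    named = sorted(kb.signature.classes - {TOP_IRI, BOTTOM_IRI})

    sat: Dict[str, bool] = {}
    for c in named:
        sat[c] = _tbox_satisfiable(kb, Atomic(c))

    # told subsumption closure (atomic subclass + atomic equivalences)
    told = nx.DiGraph()
    told.add_nodes_from(named)
    for ax in kb.axioms:
        if isinstance(ax, SubClassOf) and isinstance(ax.sub, Atomic) \
                and isinstance(ax.sup, Atomic):
            told.add_edge(ax.sub.iri, ax.sup.iri)
        elif isinstance(ax, EquivalentClasses):
            atoms = [e.iri for e in ax.exprs if isinstance(e, Atomic)]
            for a, b in itertools.combinations(atoms, 2):
                told.add_edge(a, b)
                told.add_edge(b, a)
    told_closure = {c: nx.descendants(told, c) | {c} for c in named}

    cands = _candidate_supers(kb) & set(named)
    cache: Dict[Tuple[str, str], bool] = {}

    def subsumed(c: str, d: str) -> bool:
        if c == d or not sat[c]:
            return True
        if d in told_closure[c]:
            return True
        if not sat[d] or d not in cands:
            return False
        key = (c, d)
        if key not in cache:
            cache[key] = check_subsumption(kb, Atomic(c), Atomic(d))
        return cache[key]

    g = nx.DiGraph()
    g.add_nodes_from(named + [TOP_IRI, BOTTOM_IRI])
    g.add_edge(BOTTOM_IRI, TOP_IRI)
    for c in named:
        g.add_edge(c, TOP_IRI)
        g.add_edge(BOTTOM_IRI, c)
        if not sat[c]:
            g.add_edge(c, BOTTOM_IRI)
        for d in named:
            if c != d and subsumed(c, d):
                g.add_edge(c, d)
        # C equivalent to Top?
        if sat[c] and c in cands and check_subsumption(kb, TOP, Atomic(c)):
            g.add_edge(TOP_IRI, c)

    condensed = nx.condensation(g)
    groups = {n: frozenset(condensed.nodes[n]["members"])
              for n in condensed.nodes}
    reduced = nx.transitive_reduction(condensed)

    direct_supers: Dict[str, FrozenSet[str]] = {}
    for n in condensed.nodes:
        sups: Set[str] = set()
        for m in reduced.successors(n):
            sups |= groups[m]
        for c in groups[n]:
            direct_supers[c] = frozenset(sups)
    ancestors_map = {}
    full = nx.transitive_closure(condensed)
    for n in condensed.nodes:
        anc: Set[str] = set()
        for m in full.successors(n):
            anc |= groups[m]
        for c in groups[n]:
            anc_c = (anc | groups[n]) - {c}
            ancestors_map[c] = frozenset(anc_c)
    equivalents = sorted((grp for grp in groups.values()), key=sorted)
    sat[TOP_IRI] = True
    sat[BOTTOM_IRI] = False
    return InferredHierarchy(
        direct_supers=direct_supers,
        equivalents=[g_ for g_ in equivalents],
        satisfiable_flags=sat,
        ancestors_map=ancestors_map,
    )


# ---------------------------------------------------------------------------
# Justification
# ---------------------------------------------------------------------------

def _entails(axioms: Iterable[Axiom], entailment: Axiom,
             node_cap: int = DEFAULT_NODE_CAP) -> bool:
    kb = KnowledgeBase(set(axioms), node_cap=node_cap)
    if isinstance(entailment, SubClassOf):
        return check_subsumption(kb, entailment.sub, entailment.sup)
    if isinstance(entailment, EquivalentClasses):
        es = entailment.exprs
        return all(check_subsumption(kb, a, b) and check_subsumption(kb, b, a)
                   for a, b in zip(es, es[1:]))
    if isinstance(entailment, DisjointClasses):
        return all(
            not is_satisfiable(kb, And(a, b)).satisfiable
            for a, b in itertools.combinations(entailment.exprs, 2))
    if isinstance(entailment, ClassAssertion):
        if entailment.individual not in kb.abox_labels:
            return False
        return check_instance(kb, entailment.individual, entailment.expr)
    raise UnsupportedConstructError(
        type(entailment).__name__, "not a justifiable entailment kind")


def justify(kb, entailment: Axiom) -> Set[Axiom]:
    """A minimal axiom subset entailing ``entailment``.

    Deletion-based shrinking: walk the logical axioms in canonical order and
    drop every axiom whose removal preserves the entailment.  The result J
    satisfies J ⊨ entailment and J∖{x} ⊭ entailment for every x ∈ J.
    """
    kb = _as_kb(kb)
    axioms = sorted(kb.axioms)
    if not _entails(axioms, entailment, kb.node_cap):
        raise NotEntailedError(entailment)
    just = list(axioms)
    for ax in axioms:
        trial = [a for a in just if a != ax]
        if _entails(trial, entailment, kb.node_cap):
            just = trial
    return set(just)


# ---------------------------------------------------------------------------
# Bounded exhaustive model search (testing oracle)
# ---------------------------------------------------------------------------

_TRUE = ("T",)
_FALSE = ("F",)


def _ground_concept(expr: ConceptExpr, d: int, size: int,
                    positive: bool, cvar, rvar):
    """Ground a class expression at element ``d`` into an and/or/literal
    tree over membership bits (negations pushed onto the literals)."""
    if isinstance(expr, Atomic):
        lit = cvar(expr.iri, d)
        return ("L", lit if positive else -lit)
    if expr is TOP:
        return _TRUE if positive else _FALSE
    if expr is BOTTOM:
        return _FALSE if positive else _TRUE
    if isinstance(expr, Not):
        return _ground_concept(expr.arg, d, size, not positive, cvar, rvar)
    if isinstance(expr, (_And, _Or)):
        conj = isinstance(expr, _And) == positive
        parts = [_ground_concept(a, d, size, positive, cvar, rvar)
                 for a in expr.args]
        return _gate(conj, parts)
    if isinstance(expr, (Exists, Forall)):
        conj = isinstance(expr, Forall) == positive
        parts = []
        for e in range(size):
            rlit = rvar(expr.role.name, d, e)
            filler = _ground_concept(expr.filler, e, size, positive,
                                     cvar, rvar)
            if conj:   # ¬edge ∨ filler, for every successor candidate
                parts.append(_gate(False, [("L", -rlit), filler]))
            else:      # edge ∧ filler, for some successor candidate
                parts.append(_gate(True, [("L", rlit), filler]))
        return _gate(conj, parts)
    raise UnsupportedConstructError(type(expr).__name__, expr.key)


def _gate(conj: bool, parts):
    """Build an AND (conj) or OR node with constant folding."""
    kept = []
    for part in parts:
        if part is (_FALSE if conj else _TRUE) or \
                part == (_FALSE if conj else _TRUE):
            return _FALSE if conj else _TRUE
        if part == (_TRUE if conj else _FALSE):
            continue
        kept.append(part)
    if not kept:
        return _TRUE if conj else _FALSE
    if len(kept) == 1:
        return kept[0]
    return ("A" if conj else "O", kept)


def _ground_axioms(logical, classes, roles, size, ind_map):
    """Ground all axioms for the given domain size into formula trees."""
    cindex = {c: i for i, c in enumerate(classes)}
    rindex = {r: i for i, r in enumerate(roles)}
    n_cls = len(classes) * size

    def cvar(iri: str, d: int) -> int:
        return 1 + cindex[iri] * size + d

    def rvar(role: str, d: int, e: int) -> int:
        return 1 + n_cls + rindex[role] * size * size + d * size + e

    n_base = n_cls + len(roles) * size * size
    formulas = []
    for ax in logical:
        if isinstance(ax, (SubClassOf, EquivalentClasses, DisjointClasses)):
            for sub, sup in gcis_of(ax):
                parts = []
                for d in range(size):
                    parts.append(_gate(False, [
                        _ground_concept(sub, d, size, False, cvar, rvar),
                        _ground_concept(sup, d, size, True, cvar, rvar)]))
                formulas.append(_gate(True, parts))
        elif isinstance(ax, SubObjectPropertyOf):
            parts = []
            for d in range(size):
                for e in range(size):
                    parts.append(_gate(False, [
                        ("L", -rvar(ax.sub.name, d, e)),
                        ("L", rvar(ax.sup.name, d, e))]))
            formulas.append(_gate(True, parts))
        elif isinstance(ax, ClassAssertion):
            formulas.append(_ground_concept(
                ax.expr, ind_map[ax.individual], size, True, cvar, rvar))
        elif isinstance(ax, ObjectPropertyAssertion):
            formulas.append(("L", rvar(ax.role.name, ind_map[ax.subject],
                                       ind_map[ax.object])))
        elif isinstance(ax, DataAssertion):
            continue
        else:
            raise UnsupportedConstructError(type(ax).__name__)
    return formulas, n_base


def _tseitin(formulas, n_base):
    """Single-polarity (Plaisted–Greenbaum) CNF of ⋀ formulas."""
    clauses: List[List[int]] = []
    next_var = [n_base]

    def lit_of(node) -> int:
        kind = node[0]
        if kind == "L":
            return node[1]
        next_var[0] += 1
        aux = next_var[0]
        if kind == "A":
            for child in node[1]:
                clauses.append([-aux, lit_of(child)])
        else:  # "O"
            clauses.append([-aux] + [lit_of(c) for c in node[1]])
        return aux

    for f in formulas:
        if f == _FALSE:
            return None, 0
        if f == _TRUE:
            continue
        clauses.append([lit_of(f)])
    return clauses, next_var[0]


def _dpll(clauses: List[List[int]], n_vars: int) -> Optional[List[int]]:
    """Small DPLL with two watched literals; returns an assignment or None.

    Deterministic: branch variables in index order, false before true.
    """
    assign = [0] * (n_vars + 1)
    watches: Dict[int, List[int]] = {}
    for ci, cl in enumerate(clauses):
        if not cl:
            return None
        for lit in cl[: 2]:
            watches.setdefault(lit, []).append(ci)

    def value(lit: int) -> int:
        v = assign[abs(lit)]
        return 0 if v == 0 else (1 if (v > 0) == (lit > 0) else -1)

    trail: List[int] = []

    def enqueue(lit: int) -> None:
        assign[abs(lit)] = 1 if lit > 0 else -1
        trail.append(lit)

    def propagate(start: int) -> bool:
        i = start
        while i < len(trail):
            false_lit = -trail[i]
            i += 1
            occurrences = watches.get(false_lit, [])
            kept: List[int] = []
            j = 0
            while j < len(occurrences):
                ci = occurrences[j]
                j += 1
                cl = clauses[ci]
                # normalize: put the other watch first
                if cl[0] == false_lit and len(cl) > 1:
                    cl[0], cl[1] = cl[1], cl[0]
                if value(cl[0]) == 1:
                    kept.append(ci)
                    continue
                moved = False
                for k in range(2, len(cl)):
                    if value(cl[k]) != -1:
                        cl[1], cl[k] = cl[k], cl[1]
                        watches.setdefault(cl[1], []).append(ci)
                        moved = True
                        break
                if moved:
                    continue
                kept.append(ci)
                v0 = value(cl[0])
                if v0 == -1 or (len(cl) == 1 and v0 != 1):
                    kept.extend(occurrences[j:])
                    watches[false_lit] = kept
                    return False
                if v0 == 0:
                    enqueue(cl[0])
            watches[false_lit] = kept
        return True

    # top-level units
    for cl in clauses:
        if len(cl) == 1:
            if value(cl[0]) == -1:
                return None
            if value(cl[0]) == 0:
                enqueue(cl[0])
    if not propagate(0):
        return None

    decisions: List[Tuple[int, int, bool]] = []  # (trail mark, var, flipped)
    var = 1
    while True:
        while var <= n_vars and assign[var] != 0:
            var += 1
        if var > n_vars:
            return assign
        decisions.append((len(trail), var, False))
        enqueue(-var)  # try false first
        while not propagate(decisions[-1][0] if decisions else 0):
            # conflict: undo to the most recent unflipped decision
            while decisions:
                mark, dvar, flipped = decisions.pop()
                for lit in trail[mark:]:
                    assign[abs(lit)] = 0
                del trail[mark:]
                if not flipped:
                    decisions.append((mark, dvar, True))
                    enqueue(dvar)
                    break
            else:
                return None
        var = 1


def _add_lex_symmetry(clauses: List[List[int]], n_vars: int,
                      n_classes: int, size: int) -> int:
    """Force classvec(d) ≥lex classvec(d+1) for adjacent elements.

    Any model can be element-permuted into this form, so the constraint
    preserves satisfiability while pruning permuted duplicates.  The
    prefix-equality auxiliaries are only forced true when the prefix really
    is equal, so no spurious ordering constraint can fire.
    """
    def cvar(i: int, d: int) -> int:
        return 1 + i * size + d

    for d in range(size - 1):
        prev_eq = 0  # 0 means "no premise" (prefix trivially equal)
        for k in range(n_classes):
            u, v = cvar(k, d), cvar(k, d + 1)
            prem = [-prev_eq] if prev_eq else []
            clauses.append(prem + [u, -v])
            if k < n_classes - 1:
                n_vars += 1
                eq = n_vars
                clauses.append(prem + [-u, -v, eq])
                clauses.append(prem + [u, v, eq])
                prev_eq = eq
    return n_vars


def exhaustive_model_search(axioms: Iterable[Axiom],
                            max_domain: int = 3) -> Optional[Interpretation]:
    """Complete search for a model over domains of size ≤ ``max_domain``.

    The bounded-model problem is grounded to propositional clauses (one
    boolean per class membership and per role pair, plus definitional
    auxiliaries) and decided by a small DPLL procedure — an exhaustive
    search over all interpretations up to the bound, organized as
    backtracking with unit propagation.  Domain sizes are tried in
    ascending order; the first model found (deterministic) is returned,
    or None when no interpretation within the bound satisfies the axioms.
    """
    logical = sorted(_logical_axioms(set(axioms)))
    sig = signature_of(logical)
    classes = sorted(sig.classes - {TOP_IRI, BOTTOM_IRI})
    roles = sorted(sig.roles)
    individuals = sorted(sig.individuals)

    for size in range(1, max_domain + 1):
        for combo in itertools.product(range(size), repeat=len(individuals)):
            ind_map = dict(zip(individuals, combo))
            try:
                formulas, n_base = _ground_axioms(
                    logical, classes, roles, size, ind_map)
            except KeyError:
                raise UnsupportedConstructError("grounding", "unknown symbol")
            clauses, n_vars = _tseitin(formulas, n_base)
            if clauses is None:
                continue
            if not individuals:
                # domain elements are interchangeable: break the permutation
                # symmetry by sorting elements on their class-bit vectors
                clauses = list(clauses)
                n_vars = _add_lex_symmetry(clauses, n_vars, len(classes),
                                           size)
            assignment = _dpll([list(c) for c in clauses], n_vars)
            if assignment is None:
                continue
            class_ext = {}
            for i, c in enumerate(classes):
                class_ext[c] = frozenset(
                    d for d in range(size)
                    if assignment[1 + i * size + d] > 0)
            role_ext = {}
            n_cls = len(classes) * size
            for i, r in enumerate(roles):
                role_ext[r] = frozenset(
                    (d, e) for d in range(size) for e in range(size)
                    if assignment[1 + n_cls + i * size * size
                                  + d * size + e] > 0)
            return Interpretation(frozenset(range(size)), class_ext,
                                  role_ext, dict(ind_map))
    return None
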