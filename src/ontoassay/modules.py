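"""Layered ontology modularization.

The framework distinguishes file kinds in a layered architecture:

* ``vocabulary`` — terms only: entity declarations, atomic subsumptions,
  atomic sub-property axioms, labels.  No complex axioms, no assertions.
* ``module`` — a gluing file combining vocabularies through imports.
* ``axiomfile`` — logical axioms over imported terms; it declares no
  classes or properties of its own (named individuals for ABox files are
  allowed).
* ``combinator`` — bridging axioms mapping internal terms to external ones
  (equivalence or subsumption between atomic terms of different
  namespaces).
* ``external_stub`` — a vocabulary excerpted from an external source.
* ``perspective`` — a view on the knowledge base: a file that selects
  imports (direct and indirect) and from which a merged, import-free
  ontology is built.

Files are wired by imports into a directed acyclic graph; validators check
acyclicity, the kind-specific purity rules and self-containedness (every
IRI used in a closure is declared in that closure).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import yaml

from .dl import (
    AnnotationAssertion, Atomic, Axiom, ClassAssertion, DataAssertion,
    Declaration, DisjointClasses, EquivalentClasses, ObjectPropertyAssertion,
    Ontology, OntoAssayError, RoleRef, SubClassOf, SubObjectPropertyOf,
    signature_of,
)
from .ofn import BUILTIN_PREFIXES, OntologyFile, read_ontology_file

FILE_KINDS = ("vocabulary", "module", "axiomfile", "combinator",
              "perspective", "external_stub")

#: IRIs exempt from self-containedness (built-in vocabulary).
_BUILTIN_NAMESPACES = tuple(BUILTIN_PREFIXES.values())


class CatalogError(OntoAssayError):
    pass


class UnresolvedImportError(OntoAssayError):
    def __init__(self, importer: str, target: str):
        super().__init__(
            f"<{importer}> imports <{target}>, which is not in the catalog")
        self.importer = importer
        self.target = target


class ValidationFailure(OntoAssayError):
    """Raised when a build aborts on a failing validation report."""

    def __init__(self, report: "ValidationReport"):
        lines = "; ".join(f"[{r}] {m}" for r, _, m in report.violations)
        super().__init__(f"validation failed for <{report.file_iri}>: {lines}")
        self.report = report


class UnknownSeedError(OntoAssayError):
    def __init__(self, iri: str):
        super().__init__(f"seed IRI not in the external signature: <{iri}>")


class ConflictingMappingError(OntoAssayError):
    def __init__(self, internal: str, external: str):
        super().__init__(
            f"conflicting combinator mappings for <{internal}> / <{external}>")


# ---------------------------------------------------------------------------
# Catalog and import graph
# ---------------------------------------------------------------------------

@dataclass
class CatalogEntry:
    iri: str
    path: Path
    kind: str

    def __post_init__(self):
        if self.kind not in FILE_KINDS:
            raise CatalogError(f"unknown file kind {self.kind!r} "
                               f"for <{self.iri}>")
        self.path = Path(self.path)


@dataclass
class ImportCatalog:
    """Maps ontology IRIs to local files; no network resolution ever."""

    entries: Dict[str, CatalogEntry]
    roots: List[str] = field(default_factory=list)
    base_dir: Path = Path(".")

    def resolve_path(self, iri: str) -> Path:
        entry = self.entries[iri]
        p = entry.path
        return p if p.is_absolute() else self.base_dir / p

    @classmethod
    def load(cls, path) -> "ImportCatalog":
        path = Path(path)
        data = yaml.safe_load(path.read_text(encoding="utf-8"))
        entries = {}
        for item in data.get("files", []):
            entry = CatalogEntry(iri=item["iri"], path=Path(item["path"]),
                                 kind=item["kind"])
            if entry.iri in entries:
                raise CatalogError(f"duplicate catalog entry <{entry.iri}>")
            entries[entry.iri] = entry
        return cls(entries=entries,
                   roots=list(data.get("perspectives", [])),
                   base_dir=path.parent)

    def dump(self, path) -> Path:
        path = Path(path)
        data = {
            "files": [
                {"iri": e.iri, "path": str(e.path), "kind": e.kind}
                for e in sorted(self.entries.values(), key=lambda e: e.iri)
            ],
            "perspectives": list(self.roots),
        }
        path.write_text(yaml.safe_dump(data, sort_keys=False),
                        encoding="utf-8")
        return path


@dataclass
class ImportGraph:
    """Nodes are file IRIs, edges point importer -> imported."""

    graph: nx.DiGraph
    files: Dict[str, OntologyFile]

    @property
    def nodes(self) -> Set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> Set[Tuple[str, str]]:
        return set(self.graph.edges)

    def closure(self, iri: str) -> Set[str]:
        """The import closure of a node (itself included)."""
        return nx.descendants(self.graph, iri) | {iri}

    def closure_axioms(self, iri: str) -> Set[Axiom]:
        out: Set[Axiom] = set()
        for member in self.closure(iri):
            out |= self.files[member].ontology.all_axioms()
        return out


@dataclass
class ValidationReport:
    file_iri: str
    violations: List[Tuple[str, str, str]] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations

    def add(self, rule: str, subject, message: str) -> None:
        self.violations.append((rule, str(subject), message))

    def __repr__(self):
        status = "passed" if self.passed else "FAILED"
        return f"ValidationReport(<{self.file_iri}>, {status}, " \
               f"{len(self.violations)} violations)"


def build_import_graph(catalog: ImportCatalog) -> ImportGraph:
    """Parse every catalogued file and wire the import edges.

    An import whose target IRI is not in the catalog is an error (there is
    no network fallback); closure queries reduce to graph reachability.
    """
    g = nx.DiGraph()
    files: Dict[str, OntologyFile] = {}
    for iri, entry in sorted(catalog.entries.items()):
        f = read_ontology_file(catalog.resolve_path(iri), kind=entry.kind)
        if f.iri != iri:
            raise CatalogError(
                f"catalog lists <{iri}> but {entry.path} declares <{f.iri}>")
        files[iri] = f
        g.add_node(iri)
    for iri, f in sorted(files.items()):
        for target in f.ontology.direct_imports:
            if target not in files:
                raise UnresolvedImportError(iri, target)
            g.add_edge(iri, target)
    return ImportGraph(graph=g, files=files)


def assert_acyclic(graph: ImportGraph) -> ValidationReport:
    """Report one witness cycle per strongly connected component."""
    report = ValidationReport(file_iri="<import-graph>")
    for scc in nx.strongly_connected_components(graph.graph):
        sub = graph.graph.subgraph(scc)
        if len(scc) > 1 or any(sub.has_edge(n, n) for n in scc):
            cycle = [a for a, _ in nx.find_cycle(sub)]
            report.add("acyclic-imports", "->".join(cycle),
                       f"import cycle: {' -> '.join(cycle)}")
    return report


# ---------------------------------------------------------------------------
# Purity rules per file kind
# ---------------------------------------------------------------------------

def namespace_of(iri: str) -> str:
    if "#" in iri:
        return iri.rsplit("#", 1)[0] + "#"
    return iri.rsplit("/", 1)[0] + "/"


def _is_atomic_pair(ax: Axiom) -> bool:
    if isinstance(ax, SubClassOf):
        return isinstance(ax.sub, Atomic) and isinstance(ax.sup, Atomic)
    if isinstance(ax, EquivalentClasses):
        return len(ax.exprs) == 2 and all(
            isinstance(e, Atomic) for e in ax.exprs)
    return False


def validate_artifact(file: OntologyFile) -> ValidationReport:
    """Check the kind-specific purity rules of one file.

    vocabulary / external_stub: declarations, atomic subsumptions (class
    and property) and annotations only.  axiomfile: no class/property
    declarations, no imports of terms it then declares; named individuals
    are allowed (ABox files).  combinator: only atomic cross-namespace
    bridges.  module / perspective: unrestricted here (self-containedness
    is a separate check).
    """
    report = ValidationReport(file_iri=file.iri)
    kind = file.kind
    onto = file.ontology
    if kind in {"vocabulary", "external_stub"}:
        for ax in sorted(onto.tbox):
            if not (isinstance(ax, SubClassOf) and
                    isinstance(ax.sub, Atomic) and
                    isinstance(ax.sup, Atomic)):
                report.add("vocabulary-subsumption-only", ax,
                           "vocabularies contain terms with atomic "
                           "subsumption only")
        for ax in sorted(onto.abox):
            report.add("vocabulary-no-assertions", ax,
                       "vocabularies contain no individual assertions")
    elif kind == "axiomfile":
        for ax in sorted(onto.declarations):
            if ax.kind in {"Class", "ObjectProperty", "DataProperty"}:
                report.add("axiomfile-no-declarations", ax,
                           "axiom files do not declare classes or "
                           "properties")
    elif kind == "combinator":
        for ax in sorted(onto.tbox | onto.rbox):
            if isinstance(ax, SubObjectPropertyOf):
                sides: Sequence[str] = (ax.sub.name, ax.sup.name)
            elif _is_atomic_pair(ax):
                if isinstance(ax, SubClassOf):
                    sides = (ax.sub.iri, ax.sup.iri)
                else:
                    sides = tuple(e.iri for e in ax.exprs)
            else:
                report.add("combinator-atomic-bridges-only", ax,
                           "combinators contain only atomic equivalence or "
                           "subsumption bridges")
                continue
            if namespace_of(sides[0]) == namespace_of(sides[1]):
                report.add("combinator-cross-namespace", ax,
                           "combinator bridges map terms of different "
                           "namespaces")
        for ax in sorted(onto.declarations):
            report.add("combinator-no-declarations", ax,
                       "combinators declare nothing; both sides are "
                       "imported terms")
        for ax in sorted(onto.abox):
            report.add("combinator-no-assertions", ax,
                       "combinators contain no individual assertions")
    elif kind in {"module", "perspective"}:
        pass
    else:
        report.add("unknown-kind", kind or "<none>",
                   f"file kind {kind!r} is not a known layer kind")
    return report


def check_self_contained(file: OntologyFile,
                         catalog_or_graph) -> ValidationReport:
    """Every IRI used in the file's import closure is declared in it.

    Built-in OWL/RDFS/XSD names are exempt.  Requires an acyclic import
    graph (closure is reachability).
    """
    graph = (catalog_or_graph if isinstance(catalog_or_graph, ImportGraph)
             else build_import_graph(catalog_or_graph))
    report = ValidationReport(file_iri=file.iri)
    axioms = graph.closure_axioms(file.iri)
    sig = signature_of(axioms)
    declared = {ax.iri for ax in axioms if isinstance(ax, Declaration)}
    for iri in sorted(sig.all_iris()):
        if iri in declared:
            continue
        if any(iri.startswith(ns) for ns in _BUILTIN_NAMESPACES):
            continue
        report.add("self-contained", iri,
                   f"<{iri}> is used but not declared in the import closure")
    return report


# ---------------------------------------------------------------------------
# Perspective building
# ---------------------------------------------------------------------------

def build_perspective(root: str, catalog: ImportCatalog,
                      graph: Optional[ImportGraph] = None) -> Ontology:
    """Merge the import closure of ``root`` into one import-free ontology.

    All closure files must pass their purity rules and the graph must be
    acyclic, otherwise the build aborts with the offending report.  Merging
    is a deduplicated set union under canonical structural equality, so the
    result is independent of catalog order.
    """
    if graph is None:
        graph = build_import_graph(catalog)
    cyc = assert_acyclic(graph)
    if not cyc.passed:
        raise ValidationFailure(cyc)
    closure = sorted(graph.closure(root))
    for iri in closure:
        rep = validate_artifact(graph.files[iri])
        if not rep.passed:
            raise ValidationFailure(rep)
    merged = Ontology(iri=root)
    for iri in closure:
        merged.merge(graph.files[iri].ontology)
    merged.direct_imports = []
    return merged


# ---------------------------------------------------------------------------
# External module extraction
# ---------------------------------------------------------------------------

@dataclass
class ExtractOptions:
    annotations: bool = True


def extract_module(external: Ontology, seeds: Iterable[str],
                   opts: Optional[ExtractOptions] = None) -> Ontology:
    """Upward-closure extraction from an external taxonomy.

    The module keeps each seed, all its ancestors along asserted atomic
    subsumptions up to the external root, the connecting subsumption
    axioms, their declarations and (optionally) label annotations —
    nothing else.  Output is monotone in the seed set.
    """
    opts = opts or ExtractOptions()
    seeds = set(seeds)
    sig = signature_of(external.all_axioms())
    for s in seeds:
        if s not in sig.all_iris():
            raise UnknownSeedError(s)
    parents: Dict[str, Set[str]] = {}
    for ax in external.tbox:
        if isinstance(ax, SubClassOf) and isinstance(ax.sub, Atomic) \
                and isinstance(ax.sup, Atomic):
            parents.setdefault(ax.sub.iri, set()).add(ax.sup.iri)
    keep: Set[str] = set()
    frontier = list(seeds)
    while frontier:
        cur = frontier.pop()
        if cur in keep:
            continue
        keep.add(cur)
        frontier.extend(parents.get(cur, ()))
    module = Ontology(iri=external.iri + "/module" if external.iri else "")
    decl_kind = {d.iri: d.kind for d in external.declarations}
    for iri in sorted(keep):
        module.add(Declaration(decl_kind.get(iri, "Class"), iri))
    for ax in sorted(external.tbox):
        if isinstance(ax, SubClassOf) and isinstance(ax.sub, Atomic) \
                and isinstance(ax.sup, Atomic) \
                and ax.sub.iri in keep and ax.sup.iri in keep:
            module.add(ax)
    if opts.annotations:
        for ann in sorted(external.annotations):
            if ann.subject in keep:
                module.add(ann)
    return module


# ---------------------------------------------------------------------------
# Combinators
# ---------------------------------------------------------------------------

def make_combinator(mappings: Iterable[Tuple], iri: str = "") -> Ontology:
    """Build a bridging ontology from (internal, external, relation) rows.

    ``relation`` is ``equivalent``, ``subclass`` (internal ⊑ external) or
    ``superclass`` (external ⊑ internal).  A fourth element ``"property"``
    switches to object-property bridges (sub-property axioms).  Conflicting
    duplicate mappings for the same pair are an error.
    """
    seen: Dict[Tuple[str, str], str] = {}
    onto = Ontology(iri=iri)
    for row in mappings:
        internal, external, relation = row[0], row[1], row[2]
        entity = row[3] if len(row) > 3 else "class"
        key = (internal, external)
        if key in seen and seen[key] != relation:
            raise ConflictingMappingError(internal, external)
        seen[key] = relation
        if relation not in {"equivalent", "subclass", "superclass"}:
            raise ValueError(f"unknown mapping relation {relation!r}")
        if entity == "class":
            if relation == "equivalent":
                onto.add(EquivalentClasses(Atomic(internal), Atomic(external)))
            elif relation == "subclass":
                onto.add(SubClassOf(Atomic(internal), Atomic(external)))
            else:
                onto.add(SubClassOf(Atomic(external), Atomic(internal)))
        elif entity == "property":
            if relation == "equivalent":
                onto.add(SubObjectPropertyOf(RoleRef(internal),
                                             RoleRef(external)))
                onto.add(SubObjectPropertyOf(RoleRef(external),
                                             RoleRef(internal)))
            elif relation == "subclass":
                onto.add(SubObjectPropertyOf(RoleRef(internal),
                                             RoleRef(external)))
            else:
                onto.add(SubObjectPropertyOf(RoleRef(external),
                                             RoleRef(internal)))
        else:
            raise ValueError(f"unknown entity kind {entity!r}")
    return onto
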