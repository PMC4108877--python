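# Methods

## The model

The package works in the ALC fragment of OWL 2 DL, extended with an
atomic object-property hierarchy.  A knowledge base is the usual triple
of TBox (SubClassOf, EquivalentClasses, DisjointClasses over class
expressions), RBox (atomic SubObjectPropertyOf) and ABox (class,
object-property and data-property assertions).  Interpretations are the
standard model-theoretic structures: a nonempty domain Δ with functions
mapping classes to subsets of Δ, roles to binary relations and
individuals to elements; complex expressions are evaluated by the
extended interpretation function.  Entailment tasks reduce to
(un)satisfiability: C ⊑ D holds iff C ⊓ ¬D has no model; an individual
is an instance of C iff adding ¬C(a) makes the ABox inconsistent.

Constructs beyond the fragment — nominals, Self restrictions, qualified
number restrictions, role characteristics (transitivity, functionality,
…), role chains, inverse roles, datatype expressions — are representable
in the data model and in the file dialect where the grammar admits them,
but every reasoning entry point rejects them with an explicit
unsupported-construct error.  This fragment is the smallest in which all
of the bioassay inferences the fixture encodes (defined-class
classification, measure-group subsumption, participant-based retrieval)
are derivable; anything larger would buy expressivity the test bed never
exercises, at a steep cost in procedure complexity.

Data assertions (endpoint value plus unit tag) are deliberately inert:
they are carried, serialized and queryable, but take no part in
satisfiability.  Endpoints in this domain are numeric readouts (IC50 in
micromolar, percent inhibition); nothing in the classification workflow
conditions on their values, so datatype reasoning is out of scope.

## The tableau procedure

Satisfiability is decided by a completion-graph tableau:

* **Absorption and lazy unfolding.**  GCIs whose left side is atomic —
  or an intersection containing an atom — are turned into unfoldings
  triggered only when the atom enters a node label.  The remaining GCIs
  are internalized (⨅ ¬C ⊔ D) into a global constraint added to every
  node.  In the fixture, all heavy axioms (the defined classes) absorb,
  so the global constraint stays small.
* **Blocking.**  Anywhere subset blocking: a non-root node is blocked
  when an earlier unblocked node's label contains its own; descendants
  of blocked nodes are blocked.  With no inverse roles this is sound,
  and it terminates expansion far earlier than ancestor-only blocking on
  internalized GCIs.
* **Disjunctions.**  Unit propagation drops disjuncts whose complement
  is in the label and propagates forced singletons deterministically.
  Branching is depth-first in a fixed order (non-generating disjuncts
  first, then canonical order), with semantic branching on literal
  disjuncts (later branches assert the complements of refuted ones) and
  dependency-directed backjumping: every label entry carries the set of
  choice points it depends on, and a clash that does not involve a
  choice point skips its remaining alternatives.  The procedure is fully
  deterministic; no randomness is involved anywhere in reasoning.
* **Model export.**  A clash-free completed graph is converted to a
  finite interpretation: unblocked nodes form the domain, edges into
  blocked nodes are redirected to their blockers, role extensions are
  closed upward along the told role hierarchy, and ABox individuals map
  to their root nodes.  Every satisfiable verdict therefore carries a
  model, and the test suite re-checks each one with the direct-semantics
  evaluator.
* **Resource cap.**  Node creation stops at a configurable cap (default
  50,000) with a resource-limit error, so a runaway input fails loudly
  rather than silently.

Classification first checks global consistency (cached), computes
per-class satisfiability, seeds told subsumptions (atomic SubClassOf and
atomic equivalence members, transitively closed), and then tests only
candidate superclasses.  A class is a candidate only if it occurs
positively outside all quantifiers in some unfolding or global conjunct:
during a subsumption test the root label grows only by And/Or
decomposition, unfolding and the global constraint — quantified fillers
land on successors — so a class without such an occurrence can never be
forced into the root label and gains no non-told subsumers (unsatisfiable
subclasses are handled separately).  The entailed preorder is condensed
into equivalence groups (unsatisfiable classes join the owl:Nothing
group) and transitively reduced; classes are processed in lexicographic
IRI order, making hierarchies reproducible.

Justifications are computed by deletion: walk the logical axioms in
canonical order, drop any axiom whose removal preserves the entailment.
The result is a minimal subset (every single deletion breaks the
entailment), re-verified independently in the tests.

## The testing oracles

Two independent routes check the tableau.  `verify_model` evaluates the
direct semantics of every axiom over a finite interpretation; it accepts
the exported model of every satisfiable verdict.  For unsatisfiable
verdicts, `exhaustive_model_search` performs a complete search over all
interpretations with at most three domain elements: the bounded-model
problem is grounded to propositional clauses (one boolean per class
membership and per role pair, with single-polarity definitional
auxiliaries) and decided by a small DPLL procedure with two watched
literals.  When no named individuals are present, a lexicographic
ordering constraint over the class-bit vectors of adjacent elements
removes domain-permutation symmetry; any model can be permuted into that
form, so satisfiability is preserved.  The soundness suite runs 500
seeded random TBoxes (at most 6 axioms, 4 atomic classes, 2 roles,
expression depth 3 — small enough that a three-element bound is usually
decisive, large enough to exercise every rule, including pathological
∀-left GCIs): whenever the bounded search finds a model, the tableau
must report satisfiable, and every satisfiable verdict's model must pass
the checker.  The whole sweep completes in well under a minute.

## The modularization framework

Files carry one of six layer kinds with machine-checked purity rules:
vocabularies (and external stubs) contain declarations, atomic
subsumptions, atomic sub-property axioms and labels only; axiom files
contain logical axioms over imported terms and may declare only named
individuals (ABox files); combinators contain only atomic
equivalence/subsumption bridges between terms of different namespaces
(sub-property bridges are allowed for property mappings, since relation
vocabularies contain no classes); modules and perspectives glue by
imports.  Imports form a DAG validated for acyclicity (one witness cycle
per strongly connected component) and resolved exclusively through a
local catalog — never the network.  Self-containedness requires every
IRI used anywhere in a closure to be declared in that closure, with the
built-in OWL/RDFS/XSD names exempt.

A perspective is built by merging the deduplicated union of all axioms
in the root's import closure, under canonical structural equality
(And/Or arguments flattened, deduplicated and sorted; every axiom keyed
by its canonical string).  Merging is therefore commutative and
associative, and the canonical serializer (sorted prefixes, axioms
ordered by kind then canonical string, UTF-8, LF) makes rebuilt
perspectives byte-identical regardless of catalog order.  Module
extraction from external taxonomies is upward closure along asserted
atomic subsumptions — seeds, their ancestors, the connecting axioms,
declarations and optionally labels — which is monotone in the seed set.

## What the generated fixture emulates

The fixture is a deliberately small, fully self-contained image of a
production assay ontology's *structure*: six component vocabularies
(bioassay, assay biology, assay method, assay format, assay endpoint,
screened entity) plus a property vocabulary, a core gluing module, axiom
files, eleven external stubs (GO, CLO, UO, NCBITaxon, DOID, ChEBI,
UBERON, PATO, IAO, RO, BFO) bridged by combinators, and core/complete
perspectives.  Its axioms are reconstructions chosen so that every
documented inference holds and every documented non-assertion stays
unasserted:

* `bioassay uses luciferase` is defined exactly as the printed
  equivalence over assay method and luciferase participation; the five
  assays reach it through five distinct design methods (the ATP-coupled
  method only via its inferred superclass).
* `ATP quantitation using luciferase` carries a full definition
  (design method ⊓ ∃participant.ATP ⊓ ∃participant.luciferase); the
  ATP-coupled measurement method asserts the same conditions piecemeal,
  so the subsumption is derivable but never told.
* `bioassay` is defined by its assay-method and endpoint restrictions
  and `measure group` asserts exactly those conditions, so measure
  group ⊑ bioassay is inference-only.  Asserting the equivalence
  directly would be wrong — an assay can own many measure groups — which
  is why the overlap is axiomatized instead.
* The m×n panel encodes two-stage aggregation: m·n base measure groups
  (concentration × target), n derived groups each carrying an IC50
  endpoint (the per-target concentration-response aggregation), and one
  profile group carrying the profile endpoint — m·n + n + 1 classes in a
  two-level derived-from DAG.  Endpoint individuals carry synthetic
  values from the fixed formula IC50(target j) = 0.5·(j+1) µM, inert for
  reasoning.

The fixture does **not** emulate the scale of a real release (hundreds
of classes per component, thousands of annotated assays), real external
ontology content (stubs carry two to four classes each), OWL/XML or
RDF/XML syntax, or corpus-level annotation statistics; green tests
demonstrate that the machinery draws the right inferences on faithful
miniature axiomatizations, not that it scales to full ontologies or that
real release files obey these layer rules.  The annotation table keeps
the printed design-method names (which contain the word "luciferase");
what matters for the retrieval demonstration is that no participant is
annotated anywhere — the link to luciferase and ATP is entailed, never
asserted.

## Numerical and design choices

* And/Or canonicalization at construction (flatten, dedupe, sort by
  canonical string; ⊤/⊥ absorbed; singleton collapse) gives
  order-independent structural equality and bit-stable serialization.
* Surface syntax is Manchester-style (`and`, `or`, `not`, `some`,
  `only`, `min`, `max`, quoted multi-word names); names resolve against
  a signature by exact IRI, local name (underscores read as spaces,
  hyphens tolerated) or rdfs:label, after whitespace normalization and
  case folding; ambiguity is an error, never a guess.  One exception:
  when an ambiguous *role* name denotes told-equivalent properties
  (combinator bridges make the internal and external participant
  relations mutual sub-properties), the canonical member is taken, since
  the extension is provably identical.
* The file dialect is a functional-syntax subset rather than OWL/XML:
  line-oriented, diff-friendly, and canonically serializable to
  identical bytes.  Unit tags ride in the literal's datatype position.
* Annotation skolems are deterministic functions of (assay id, header),
  so repeated runs emit identical triples; Turtle output is sorted by
  subject, predicate, object.
* Fixture generation involves no randomness at all.  The only seeded
  randomness in the package is the random-TBox generator for the
  soundness suite.
* Degenerate inputs: empty TBoxes internalize to ⊤; empty tables yield
  empty assertion sets; empty seed sets yield empty modules; an
  inconsistent knowledge base makes classification fail with an explicit
  error rather than returning a degenerate hierarchy.

## Known limitations

* The reasoner is sound and complete only for ALC plus atomic role
  hierarchies; everything else is rejected, not approximated.
* Performance targets are desk-scale ontologies (hundreds of axioms);
  there is no caching between knowledge bases, no told-subsumer
  enhanced-traversal classification, and no ABox summarization.
* The bounded model search certifies the absence of models only up to
  the domain bound; it is an oracle for the test conditions, not a
  decision procedure.
* Turtle output covers ABox assertions and annotations only; TBox
  exchange goes through the functional-syntax dialect.
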