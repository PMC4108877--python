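# ontoassay

Layered ontology modularization and description-logic reasoning for
bioassay classification.

High-throughput screening campaigns describe their assays with free-text
protocols, which makes it nearly impossible to ask mechanistic questions
across repositories — for example, *which assays rely on the
luciferase-catalyzed reaction and are therefore vulnerable to the same
compound artifacts?*  Formal assay ontologies answer such questions by
axiomatizing each assay's design method, detection technology, format,
endpoint and molecular participants in OWL DL, and letting a reasoner
compute the classification.  This package provides, for that workflow:

* a **description-logic core** — the ALC class-expression grammar
  (C, D ← A | ⊤ | ⊥ | ¬C | C⊓D | C⊔D | ∃R.C | ∀R.C, plus representable
  nominal/Self/cardinality forms), axioms (TBox / RBox / ABox),
  Manchester-style expression parsing, negation normal form and TBox
  internalization;
* a **tableau reasoner** for ALC with an atomic role hierarchy:
  satisfiability with lazy unfolding, anywhere subset blocking, semantic
  branching and dependency-directed backjumping; subsumption (C ⊑ D iff
  C ⊓ ¬D is unsatisfiable), classification into a transitively reduced
  inferred hierarchy, instance checking and retrieval, and deletion-based
  minimal justifications;
* a **direct-semantics model checker** and a bounded exhaustive model
  search (grounding to propositional clauses, solved by a small DPLL
  procedure) that serve as independent oracles for the tableau;
* a **modularization framework**: vocabulary / module / axiom-file /
  combinator / perspective layer kinds with purity validators, an import
  DAG with acyclicity and self-containedness checks, deterministic
  perspective builds, upward-closure module extraction and combinator
  generation;
* a deterministic **fixture generator** that emits a miniature layered
  bioassay ontology — six component vocabularies, a core module, axiom
  files, eleven external stub ontologies with bridging combinators, two
  perspectives, an m×n kinase concentration-response panel and a
  spreadsheet-style annotation table;
* an **annotation pipeline** that turns such tables into ABox triples
  (deterministic skolem individuals, Turtle output) and answers
  reasoning-backed retrieval queries.

## Worked example

Five luciferase assays (reporter gene, cell-viability ATP quantitation,
cytochrome P450, kinase activity, luciferase enzyme activity) each carry a
*different* assay design method, so no asserted annotation links them.
All five designs, however, involve the enzyme Luciferin 4-monooxygenase,
and the defined class

```
'bioassay uses luciferase' ≡ bioassay ⊓ ∃'has assay method'.
    ('assay design method' ⊓ ∃'has participant'.'Luciferin 4-monooxygenase')
```

collects them by inference alone:

```python
from ontoassay import KnowledgeBase, classify, fixtures

suite = fixtures.generate_luciferase_suite()
hierarchy = classify(KnowledgeBase(suite))
for iri in sorted(hierarchy.direct_subclasses(
        fixtures.b("bioassay_uses_luciferase"))):
    print(iri.rsplit("#", 1)[1])
```

prints

```
cell_viability_atp_quantitation_assay
cytochrome_p450_enzyme_activity_assay
kinase_activity_assay
luciferase_enzyme_activity_assay
luciferase_reporter_gene_assay
```

— exactly the five assay classes, none of which is asserted below the
defined class.  The same machinery explains *why*: a minimal
justification for the inferred design-method subsumption

```sh
ontoassay generate-fixture --out fixture
ontoassay build fixture/catalog.yaml \
    --perspective http://example.org/bao-mini/perspectives/core --out core.ofn
ontoassay justify core.ofn \
    "'ATP coupled enzyme activity measurement method'" \
    "'ATP quantitation using luciferase'"
```

prints the four axioms that force the entailment (the full definition of
ATP quantitation using luciferase and the three asserted conditions of
the ATP-coupled method) and nothing about the other four assays.
Retrieval works the same way from annotations: the bundled five-row
annotation table never names luciferase in any participant column, yet
`ontoassay query --kb <complete perspective> --participant
'Luciferin 4-monooxygenase'` returns all five assay individuals, because
the participant is entailed through each design method's definition.

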