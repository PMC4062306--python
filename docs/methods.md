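# Methods

This note documents the model implemented by `akb`, the design choices
made where the design was genuinely open, the synthetic-data generator,
and the numerical/algorithmic conventions. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## State representation and interoperability

An abnormal state is one record (`StateDescriptor`) in one of five forms:
property forms `OP` / `OPVd` / `OSoP` (object + property + presence or
degree) and attribute forms `OAV` / `OSoAV` (object [+ sub-object] +
attribute + value). Exactly one of `property_id` / `attribute` is
populated; `validate()` returns the full list of violated invariants
rather than failing on the first.

**Decomposition rules** are a bijective table: `property_id` is unique,
and so is the `(object, sub-object, attribute, token)` tuple, which makes
`compose` a function and gives the exact round-trip
`compose(decompose(x)) = x` for every decomposable property. Properties
without a rule are returned unchanged with a `nondecomposable` flag — an
expected outcome (nausea has no accepted mechanism), not an error.
Ratio-like properties carry one of three `ratio_kind` tags
(whole-vs-focused, m-of-same-object, ratio-of-same-object) on the rule
rather than separate types, keeping composition a single table lookup.

**Quantization.** A `ThresholdSpec` holds a neutral band `[lower, upper]`,
a three-token ordered scale, and optional degree bands. Conventions:

- a value exactly on a threshold belongs to the **neutral** band by
  default (`boundary="abnormal"` flips it outward); thresholds are
  institutional inputs that change over time, so they are data, never
  constants of the model;
- degree bands are `(cutoff, degree)` pairs read as "this degree applies
  at or beyond this cutoff in the abnormal direction"; the degree chosen
  is the strongest cutoff crossed, which makes `grade` monotone in the
  magnitude by construction;
- the degree vocabulary is fixed to `mild/moderate/severe` (a minimal
  ordinal scale; anything else is rejected at load time), and a degree may
  only attach to a *present* property;
- a magnitude that does not reach the graded side yields the property
  with `presence=False` (e.g. `<hyperglycemia, false>` in latent
  diabetes);
- units must match exactly — no unit conversion in v1, because silent
  conversion is a correctness hazard and none of the worked examples
  needs it.

**Canonical identity.** `canonical_key` maps a descriptor to
`(object, sub-object, attribute-or-property, token)`, with property forms
routed through their rule so that `<hyperglycemia,true>` and
`<blood, glucose, concentration, high>` get the same key. Open metadata
(e.g. `age="neonatal"`) is excluded by default and can be opted in. A
degree is allowed only on property forms; whether a degree can attach to
a decomposed attribute form is left out of v1 (it is carried as metadata
across conversions instead).

Categorical values (viviparous/oviparous) name kinds rather than
deviations; they are excluded from `compose`.

## Taxonomy

The taxonomy is a `networkx` DiGraph with child→parent edges, so
subsumption is literally reachability. Levels are **stored**, not derived
from bindings, because level 2 spans several strata (generic structures
down to organ-specific classes) that bindings alone cannot order.
Level-2 classes must bind an object; level-3 classes must bind a disease
context and have a level-2 parent; parents may never sit at a higher
level than their children.

Single asserted parent is the default (multiple inheritance is the main
source of tangled clinical hierarchies); a multi-parent mode exists, and
all queries specify deterministic tie-breaks so both modes are
reproducible:

- **depth** = longest root path;
- **lcs** = common ancestor of maximal depth, ties broken by smallest id.
  Longest-path depth prefers the most specific shared concept, which is
  what makes the stenosis ladder come out as arterial stenosis /
  vascular stenosis / narrowing tube for the three organ pairs;
- **abstract_to_level** defaults to the *nearest* (deepest) ancestor at
  the requested level — a disease-bound stenosis abstracts to its
  organ-level class, which is what cross-department unification needs
  (two departments both talk about "coronary artery stenosis", not about
  "narrowing tube"). The *generic* strategy (shallowest, e.g. up to
  "narrowing tube") is available for coarse commonality studies. The
  operation is idempotent and returns an explicit `None` when no ancestor
  has the level.

Labels are display-only; identity is by id. This is what keeps the two
"cardiac hypertrophy" contexts (hypertensive heart disease vs. Pompe
disease) distinct level-3 classes under one level-2 parent.

## Causal chains and disease is-a

A disease's chain is a DAG over taxonomy class ids; "the causal chains of
a disease" are its maximal directed paths (source to sink). Inclusion of
the whole graph is tested path-by-path, which is order-insensitive and
cheaper than whole-graph matching, and the per-path matcher is the
backtracking embedder `chain_included`:

- node direction: a node of the **more general** disease must be a
  superclass-or-equal of its image in the more specific one;
- link semantics default to **path mode** — a causal link may be realized
  by a multi-edge directed path, because specialized diseases interpose
  intermediate states (myocardial infarction realizes
  stenosis → ischemia through decreased blood flow). Edge-strict mode is
  kept for exactness studies;
- the matcher is backtracking over candidate images, most-constrained
  node first, with incremental edge checking; it is cross-checked against
  brute-force enumeration of all injective maps
  (`chain_included_bruteforce`) on instances of ≤ 8 nodes, where
  enumeration is exact and fast. The brute-force routine is the oracle in
  tests and in the acceptance script; it is never the implementation.

`disease_is_a(A, B)` requires every maximal chain of A's **core** (scope
default) to embed in B's full chain. Whether derived chains should also
participate is genuinely open — the worked families are consistent with
both readings — so both scopes are implemented and `scope="full"` is one
argument away. `infer_hierarchy` reports the transitive reduction of the
strict relation; mutually-including diseases are reported as equivalence
groups, never as edges (disease equality is otherwise undefined).

Core chains are both **asserted** (authors mark core edges) and
**computed** (`compute_core_chain`: drop edges that fail embedding into
some subclass, then iterate path-level pruning until stable — per-edge
checks alone do not guarantee whole-path embeddability because
injectivity can bind). `validate_core` compares the two instead of
overwriting either. An empty computed core is an explicit "no common
core" outcome.

`merge_generic` unions chains across diseases, unifying nodes by id or by
nearest level-2 abstraction, tagging every edge with
(disease, department) provenance. Unions of DAGs need not be acyclic, so
merged graphs allow cycles and expose `has_cycles`; an edge whose two
endpoints collapse onto one node under abstraction is dropped.

## Commonality

Between two states, commonality is their LCS plus its level; it counts as
"shared" only when the LCS lies below the top categories
(structural/functional/other) and the root. Between departments, the
state sets of all their diseases are abstracted to a chosen level and
compared by **Jaccard index**, with raw shared counts always reported
alongside (the metric choice is non-binding) and states that fail to
abstract counted in a coverage diagnostic — a department with an empty
abstracted set gets NaN (undefined), not zero. Jaccard is *not*
guaranteed monotone under arbitrary coarsening (merging two intersection
elements while singletons survive can lower it); on the shipped fixture,
where level 1 is very coarse, level-1 commonality does dominate level-2
commonality, and the tests assert exactly that plus the universally valid
binary form (nonempty intersections stay nonempty). The specificity
report lists abstracted states confined to a single department, ranked by
the number of that department's diseases carrying them — a per-state
prevalence reading of "no commonality with other departments".

## Worked-example fixture

`build_worked_examples()` encodes the worked examples as data: the
decomposition table (six rules + atomic nausea), glucose thresholds
(70/126 mg/dL with degree bands at 126/160/200 — the 126 diagnostic
cutoff is the only published number; the band edges are illustrative
institutional choices), the arterial-area band (30/80 mm²), the taxonomy
skeleton with the stenosis and hyperglycemia lineages, and ten diseases
in three departments. The ischemic-heart-disease family is modeled so
that each specialization exercises one mechanism: myocardial infarction
interposes decreased blood flow (path-mode matching) and appends
necrosis; Prinzmetal angina prepends coronary spasm with smoking as a
*derived* upstream cause; organic angina pectoris routes through arterial
sclerosis with cholesterol accumulation derived. Hyperlipidemia
(metabolic) shares the stenosis node, which is what produces the four-node
generic merged chain and the positive cardiology–metabolic commonality
entry; the gastroenterology diseases carry the intestinal/esophageal
stenoses for the ladder and specificity examples.

## Synthetic generator

`generate_synthetic(SynthConfig)` builds a random taxonomy tree (root,
level-1 categories, then object-bound level-2 tiers) and plants disease
families by **refinement**: a family root gets a random 2–3-node core
chain; each subclass disease applies 1–2 inclusion-preserving operations
to its parent's chain — insert an intermediate node on a link, append an
upstream cause, or specialize a node to a taxonomy child. Because each
operation preserves chain inclusion by construction, the planted
refinement forest *is* the ground-truth hierarchy, independent of the
matcher being tested.

Two constraints make recovery exact rather than merely likely:

- fresh classes come from a designated taxonomy tier whose members are
  mutually incomparable (and each op only ever uses classes incomparable
  to everything already used in the family, except the deliberate
  parent/child pair of a specialization), so sibling branches can never
  accidentally include one another;
- families draw from disjoint level-2 subtrees, so cross-family inclusion
  is impossible; and synthetic chains are all-core, because derived-only
  additions would be invisible to the core-scope is-a test and collapse
  siblings into spurious equivalence groups.

Defaults (depth 5, branching 4, 15 diseases, 3 departments,
op probabilities 0.6/0.4/0.5) keep every family comfortably inside its
subtree's capacity; `SynthConfig.validate` rejects infeasible
combinations with an explicit capacity calculation. Node labels are
opaque ids; no medical plausibility is attempted — the generator emulates
the *structure* of authored disease families (refinement with shared
cores), not their content, so passing recovery tests speaks to the
reasoning machinery, not to the fidelity of any real clinical resource.

`random_inclusion_instances` generates matcher stress tests: half
unconstrained random DAG pairs, half with a planted embedding (descendant
images, links realized as edges or two-edge paths) plus structural noise,
giving a healthy mix of positive and negative instances of ≤ 8 nodes.

## Serialization

The native format is canonical JSON (sorted keys, ids only; YAML accepted
on input), so `save∘load` is byte-stable and diffs are meaningful.
Schema violations are reported with JSON-pointer-style paths. The Turtle
export uses a minimal self-defined vocabulary (`https://w3id.org/akb/…`);
causal assertions get deterministic provenance URIs (no blank nodes), so
the emitted triple set is reproducible. The OBO writer emits one `[Term]`
stanza per class with `is_a` lines (round-trip checked against an
independent OBO parser in the tests); DOT output is sorted and styles
core edges distinctly.

## Problem sizes in the acceptance script

The script reproduces every worked example symbolically (sub-second), and
sizes the two property checks as: 500 random chain pairs × 2 modes for
matcher-vs-oracle agreement, and 20 generator seeds × 40 diseases × 5
departments for hierarchy recovery (the whole script runs in well under a
minute on one CPU). Seeds derive from `--seed`, so runs are reproducible;
the worked-example quantities are seed-independent by construction.

## Known limitations

- No unit conversion, term-string parsing, or mapping to external
  terminologies (SNOMED-CT, LOINC, PATO); compound clinical terms enter
  only via decomposition-rule entries.
- Syndrome-type diseases (defined by diagnostic criteria rather than a
  mechanism) and time-indexed states are out of scope.
- Deciding *whether* a state is abnormal is a medical judgement; the
  package only represents and reasons over states already asserted
  abnormal.
- The chain matcher is exponential in the worst case; it is intended for
  authored disease chains (tens of nodes), not arbitrary large graphs.
- Merged generic graphs may contain cycles; downstream consumers must
  check `has_cycles` rather than assume a DAG.
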