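# akb — abnormality knowledge base

`akb` is a library and command-line tool for representing **clinical
abnormal states** in a unified, computable form and for reasoning over
**diseases modeled as causal chains** of those states.

It addresses a concrete interoperability gap in medical informatics:
disease definitions speak in *properties* ("hyperglycemia", "arterial
stenosis"), clinical test data speak in *quantities* (260 mg/dL,
24 mm²), and findings speak in *qualities* ("glucose is high"). These
vocabularies describe the same states but do not interconvert in most
terminologies, which makes computing across definitions, records and raw
data hard. `akb` is aimed at medical-ontology engineers and informatics
researchers who need these layers to be mutually convertible and who want
subsumption-based reasoning over disease definitions.

## The model

**Unified state representation.** An abnormal state is written in any of
several interoperable forms:

- `<O, P, Vp>` — object, property, presence (`<blood, hyperglycemia, true>`),
  optionally refined by an ordinal degree `Vd ∈ {mild, moderate, severe}`;
- `<O, A, V>` — object, attribute, value (`<stomach, volume, large>`);
- `<O, SO, A, V>` — with a focused *sub-object* for ratios and
  meta-attributes (`<blood, glucose, concentration, high>`;
  `<stomach, polyp, number, many>`).

A table of **decomposition rules** makes the property form and the
attribute form interconvertible (`decompose` / `compose`); **threshold
specifications** map quantitative values into qualitative tokens
(`quantize`) or straight into graded properties (`grade`). Properties
with no known decomposition (e.g. nausea) are first-class and simply
flagged atomic.

**Three-level taxonomy.** Abnormal-state classes live in an is-a DAG with
three levels: generic object-independent states (level 1, e.g. "small in
area"), object-dependent states (level 2, from "narrowing tube" on tubular
structures down to "coronary artery stenosis"), and disease-context-bound
states (level 3). The taxonomy answers subsumption, least-common-subsumer
and level-abstraction queries.

**Diseases as causal chains.** A disease is a DAG of abnormal states with
cause→effect links, split into a **core** chain (its identifying
mechanism) and **derived** chains (optional causes such as smoking).
Disease A subsumes disease B when every maximal causal chain of A embeds
into B's chain graph — node-wise up to taxonomy subsumption, link-wise as
an edge or a directed path. On top of this the package infers disease
hierarchies, computes core chains by intersection over subclasses, merges
chains across departments into generic causal chains, and quantifies
cross-department commonality of abnormal states (Jaccard overlap of
abstracted state sets, plus specificity reports).

## Worked example

```python
import akb

bundle = akb.build_worked_examples()          # rules, thresholds, taxonomy, diseases

# quantitative -> qualitative -> property
glucose = akb.StateDescriptor.attribute_state(
    object=bundle.entities["blood"], sub_object=bundle.entities["glucose"],
    attribute=akb.Attribute("concentration"),
    value=akb.AttributeValue.quantitative(260, "mg/dL"))
spec = akb.find_spec(bundle.thresholds, glucose)
print(akb.quantize(glucose, spec).value.token)            # high
print(akb.compose(akb.quantize(glucose, spec), bundle.rules).property_id)
                                                          # hyperglycemia
print(akb.grade(glucose, spec, bundle.rules).property_value.degree)
                                                          # severe

# disease hierarchy from chain inclusion
fam = [bundle.diseases[i] for i in
       ("ihd", "myocardial_infarction", "prinzmetal_angina",
        "organic_angina_pectoris")]
print(sorted(akb.infer_hierarchy(fam, bundle.taxonomy).edges))
# [('ihd', 'myocardial_infarction'), ('ihd', 'organic_angina_pectoris'),
#  ('ihd', 'prinzmetal_angina')]

# commonality of stenoses across organs
print(bundle.taxonomy.lcs("coronary_artery_stenosis", "intestinal_stenosis"))
# narrowing_tube
```

The quantize output says the measured 260 mg/dL exceeds the institutional
126 mg/dL cutoff ("high"), which composes into the named property
*hyperglycemia* and grades as *severe* under the fixture's degree bands.
The hierarchy output is the inferred is-a relation: ischemic heart disease
subsumes its three specializations because its core chain
(stenosis → ischemia) embeds in each of their chains.

The same operations are available from the shell:

```bash
akb grade --value 260 --unit mg/dL --object blood --sub glucose --attr concentration
akb hierarchy
akb commonality --level 2 --out matrix.csv
akb export turtle --out bundle.ttl
```

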