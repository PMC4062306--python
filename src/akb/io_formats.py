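"""Model-bundle serialization and standard exports.

The native interchange format is canonical JSON (YAML is accepted on
input): one bundle file carries the entity registry, the taxonomy, the
decomposition rules, the threshold tables and the disease definitions,
with every cross-reference by id.  Exports:

* **Turtle** — one RDF resource per state class and disease, is-a as
  ``rdfs:subClassOf``, causal links as an ``akb:causes`` predicate with a
  per-assertion provenance resource (disease + department).  The
  vocabulary is a minimal self-defined namespace (``AKB``).
* **OBO** — one ``[Term]`` stanza per taxonomy class with ``is_a`` lines.
* **DOT** — graphviz rendering of chain graphs or the is-a DAG, with core
  edges styled distinctly.

All writers emit ids in sorted order, so output is deterministic for a
given bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml
from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef

from .chains import CausalChainGraph, DiseaseDefinition, build_disease
from .errors import BundleError
from .model import (
    Attribute,
    AttributeValue,
    DecompositionRule,
    DecompositionRuleSet,
    EntityRef,
    ThresholdSpec,
)
from .ontology import AbnormalStateClass, Binding, StateTemplate, Taxonomy

AKB = Namespace("https://w3id.org/akb/vocab#")
AKB_STATE = Namespace("https://w3id.org/akb/state/")
AKB_DISEASE = Namespace("https://w3id.org/akb/disease/")
AKB_ASSERT = Namespace("https://w3id.org/akb/assertion/")

FORMAT_VERSION = "1.0"


@dataclass
class ModelBundle:
    """Everything one analysis needs, cross-referenced and validated."""

    taxonomy: Taxonomy
    entities: dict[str, EntityRef] = field(default_factory=dict)
    rules: DecompositionRuleSet = field(default_factory=DecompositionRuleSet)
    thresholds: list[ThresholdSpec] = field(default_factory=list)
    diseases: dict[str, DiseaseDefinition] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def register_entities(self, *refs: EntityRef) -> None:
        for r in refs:
            self.entities.setdefault(r.id, r)

    def disease_list(self) -> list[DiseaseDefinition]:
        return [self.diseases[k] for k in sorted(self.diseases)]


# ---------------------------------------------------------------------
# dict <-> object codecs
# ---------------------------------------------------------------------

def _entity_to_dict(e: EntityRef) -> dict:
    return {"id": e.id, "label": e.label, "kind": e.kind}


def _attr_to_dict(a: Attribute) -> dict:
    d = {"name": a.name}
    if a.dimension:
        d["dimension"] = a.dimension
    if a.ratio_spec:
        d["ratio_spec"] = list(a.ratio_spec)
    return d


def _attr_from_dict(d: dict) -> Attribute:
    return Attribute(
        name=d["name"],
        dimension=d.get("dimension"),
        ratio_spec=tuple(d["ratio_spec"]) if d.get("ratio_spec") else None,
    )


def _class_to_dict(c: AbnormalStateClass) -> dict:
    d = {"id": c.id, "label": c.label, "level": c.level, "parents": sorted(c.parents)}
    if c.category:
        d["category"] = c.category
    if c.binding.object is not None:
        d["object"] = c.binding.object.id
    if c.binding.disease_context is not None:
        d["disease_context"] = c.binding.disease_context
    if c.definition is not None:
        d["definition"] = {"attribute": c.definition.attribute,
                           "token": c.definition.token}
    return d


def bundle_to_dict(b: ModelBundle) -> dict:
    """Canonical plain-dict form (sorted keys, ids only)."""
    classes = [_class_to_dict(b.taxonomy[i]) for i in sorted(b.taxonomy.classes)]
    rules = []
    for r in sorted(b.rules, key=lambda r: r.property_id):
        rd = {
            "property_id": r.property_id,
            "object": r.object.id,
            "attribute": _attr_to_dict(r.attribute),
            "qualitative_token": r.qualitative_token,
        }
        if r.sub_object:
            rd["sub_object"] = r.sub_object.id
        if r.scale:
            rd["scale"] = list(r.scale)
        if r.ratio_kind:
            rd["ratio_kind"] = r.ratio_kind
        rules.append(rd)
    thresholds = []
    for t in sorted(b.thresholds, key=lambda t: (t.object.id,
                                                 t.sub_object.id if t.sub_object else "",
                                                 t.attribute.name)):
        td = {
            "object": t.object.id,
            "attribute": _attr_to_dict(t.attribute),
            "unit": t.unit,
            "lower": t.lower,
            "upper": t.upper,
            "boundary": t.boundary,
            "scale": list(t.scale),
        }
        if t.sub_object:
            td["sub_object"] = t.sub_object.id
        if t.degree_bands:
            td["degree_bands"] = [[c, d] for c, d in t.degree_bands]
        thresholds.append(td)
    diseases = []
    for d in b.disease_list():
        diseases.append({
            "id": d.id,
            "label": d.label,
            "department": d.department,
            "states": sorted(d.chain.nodes),
            "causal_links": sorted([list(e) for e in d.chain.edges]),
            "core_edges": sorted([list(e) for e in d.core_edges]),
        })
    return {
        "format_version": FORMAT_VERSION,
        "metadata": dict(sorted(b.metadata.items())),
        "entities": [_entity_to_dict(b.entities[k]) for k in sorted(b.entities)],
        "taxonomy": {"classes": classes},
        "rules": rules,
        "thresholds": thresholds,
        "diseases": diseases,
    }


def bundle_from_dict(data: dict) -> ModelBundle:
    def fail(path, msg):
        raise BundleError(f"{path}: {msg}")

    entities: dict[str, EntityRef] = {}
    for i, ed in enumerate(data.get("entities", [])):
        if "id" not in ed:
            fail(f"/entities/{i}", "missing id")
        entities[ed["id"]] = EntityRef(
            id=ed["id"], label=ed.get("label", ""), kind=ed.get("kind", "anatomical")
        )

    def entity(ref: Optional[str], path: str) -> Optional[EntityRef]:
        if ref is None:
            return None
        if ref not in entities:
            fail(path, f"dangling entity reference {ref!r}")
        return entities[ref]

    tax = Taxonomy()
    classes = data.get("taxonomy", {}).get("classes", [])
    # classes may be listed in any order; insert parents first
    pending = {c["id"]: c for c in classes}
    order: list[str] = []
    seen: set[str] = set()

    def visit(cid, trail):
        if cid in seen:
            return
        if cid in trail:
            fail(f"/taxonomy/classes/{cid}", "parent cycle")
        c = pending.get(cid)
        if c is None:
            fail(f"/taxonomy/classes/{cid}", "dangling parent id")
        for p in c.get("parents", []):
            visit(p, trail + [cid])
        seen.add(cid)
        order.append(cid)

    for cid in sorted(pending):
        visit(cid, [])
    for cid in order:
        cd = pending[cid]
        defn = cd.get("definition")
        try:
            tax.add_class(AbnormalStateClass(
                id=cd["id"],
                label=cd.get("label", ""),
                level=cd.get("level", 1),
                parents=tuple(cd.get("parents", [])),
                category=cd.get("category"),
                binding=Binding(
                    object=entity(cd.get("object"), f"/taxonomy/classes/{cid}/object"),
                    disease_context=cd.get("disease_context"),
                ),
                definition=StateTemplate(defn["attribute"], defn["token"])
                if defn else None,
            ))
        except BundleError:
            raise
        except Exception as e:
            fail(f"/taxonomy/classes/{cid}", str(e))

    rules = DecompositionRuleSet()
    for i, rd in enumerate(data.get("rules", [])):
        path = f"/rules/{i}"
        try:
            rules.add(DecompositionRule(
                property_id=rd["property_id"],
                object=entity(rd["object"], f"{path}/object"),
                sub_object=entity(rd.get("sub_object"), f"{path}/sub_object"),
                attribute=_attr_from_dict(rd["attribute"]),
                qualitative_token=rd["qualitative_token"],
                scale=tuple(rd.get("scale", ())),
                ratio_kind=rd.get("ratio_kind"),
            ))
        except BundleError:
            raise
        except Exception as e:
            fail(path, str(e))

    thresholds = []
    for i, td in enumerate(data.get("thresholds", [])):
        path = f"/thresholds/{i}"
        try:
            thresholds.append(ThresholdSpec(
                object=entity(td["object"], f"{path}/object"),
                sub_object=entity(td.get("sub_object"), f"{path}/sub_object"),
                attribute=_attr_from_dict(td["attribute"]),
                unit=td["unit"],
                lower=float(td["lower"]),
                upper=float(td["upper"]),
                boundary=td.get("boundary", "neutral"),
                degree_bands=tuple(
                    (float(c), d) for c, d in td.get("degree_bands", ())
                ),
                scale=tuple(td.get("scale", ("low", "normal", "high"))),
            ))
        except BundleError:
            raise
        except Exception as e:
            fail(path, str(e))

    diseases: dict[str, DiseaseDefinition] = {}
    for i, dd in enumerate(data.get("diseases", [])):
        path = f"/diseases/{i}"
        try:
            d = build_disease(
                id=dd["id"],
                label=dd.get("label", dd["id"]),
                department=dd.get("department", ""),
                states=dd.get("states", []),
                causal_links=[tuple(e) for e in dd.get("causal_links", [])],
                core_flags=[tuple(e) for e in dd.get("core_edges", [])],
                tax=tax,
            )
        except BundleError:
            raise
        except Exception as e:
            fail(path, str(e))
        diseases[d.id] = d

    return ModelBundle(
        taxonomy=tax,
        entities=entities,
        rules=rules,
        thresholds=thresholds,
        diseases=diseases,
        metadata=data.get("metadata", {}),
    )


def save_bundle(bundle: ModelBundle, path) -> None:
    """Write the canonical JSON form (byte-stable for a given bundle)."""
    Path(path).write_text(
        json.dumps(bundle_to_dict(bundle), indent=2, sort_keys=True) + "\n"
    )


def load_bundle(path) -> ModelBundle:
    """Read a bundle from JSON or YAML (by extension)."""
    p = Path(path)
    text = p.read_text()
    if p.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise BundleError("/: bundle document must be a mapping")
    return bundle_from_dict(data)


# ---------------------------------------------------------------------
# Turtle export
# ---------------------------------------------------------------------

def export_turtle(
    source: Union[ModelBundle, CausalChainGraph], path=None
) -> str:
    """Serialize a bundle (or a merged chain graph) as Turtle.

    Every causal assertion gets a deterministic provenance resource, so the
    emitted triple set is identical run to run.  Returns the Turtle text;
    writes it to ``path`` when given.
    """
    g = Graph()
    g.bind("akb", AKB)
    g.bind("state", AKB_STATE)
    g.bind("disease", AKB_DISEASE)
    g.bind("assertion", AKB_ASSERT)

    def state_uri(i):
        return AKB_STATE[i]

    def add_chain(chain: CausalChainGraph, disease_id: str, department: str):
        for n in sorted(chain.nodes):
            g.add((state_uri(n), RDF.type, AKB.AbnormalState))
        for (a, b) in sorted(chain.edges):
            g.add((state_uri(a), AKB.causes, state_uri(b)))
            prov = chain.provenance(a, b) or [(disease_id, department)]
            for (did, dept) in sorted(prov):
                assertion = AKB_ASSERT[f"{did}/{a}--{b}"]
                g.add((assertion, RDF.type, AKB.CausalAssertion))
                g.add((assertion, AKB.cause, state_uri(a)))
                g.add((assertion, AKB.effect, state_uri(b)))
                if did:
                    g.add((assertion, AKB.assertedBy, AKB_DISEASE[did]))
                if dept:
                    g.add((assertion, AKB.department, Literal(dept)))

    if isinstance(source, ModelBundle):
        for cid in sorted(source.taxonomy.classes):
            c = source.taxonomy[cid]
            uri = state_uri(cid)
            g.add((uri, RDF.type, AKB.AbnormalState))
            g.add((uri, RDFS.label, Literal(c.label)))
            g.add((uri, AKB.level, Literal(c.level)))
            for p in sorted(c.parents):
                g.add((uri, RDFS.subClassOf, state_uri(p)))
        for d in source.disease_list():
            duri = AKB_DISEASE[d.id]
            g.add((duri, RDF.type, AKB.Disease))
            g.add((duri, RDFS.label, Literal(d.label)))
            if d.department:
                g.add((duri, AKB.department, Literal(d.department)))
            add_chain(d.chain, d.id, d.department)
            for (a, b) in sorted(d.core_edges):
                g.add((AKB_ASSERT[f"{d.id}/{a}--{b}"], AKB.core, Literal(True)))
    else:
        add_chain(source, "", "")

    text = g.serialize(format="turtle")
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------
# OBO export
# ---------------------------------------------------------------------

def export_obo(tax: Taxonomy, path=None, ontology_name: str = "akb") -> str:
    """One ``[Term]`` stanza per class, ``is_a`` lines to each parent."""
    lines = [
        "format-version: 1.2",
        f"ontology: {ontology_name}",
        "",
    ]
    for cid in sorted(tax.classes):
        c = tax[cid]
        lines.append("[Term]")
        lines.append(f"id: {c.id}")
        lines.append(f"name: {c.label}")
        for p in sorted(c.parents):
            lines.append(f"is_a: {p} ! {tax[p].label}")
        lines.append("")
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------
# DOT export
# ---------------------------------------------------------------------

def _dot_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def export_dot(
    graph,
    path=None,
    core_edges=(),
    labels: Optional[dict[str, str]] = None,
    name: str = "G",
) -> str:
    """Deterministic DOT text for a chain graph or an is-a DiGraph.

    ``core_edges`` are drawn bold/colored, mirroring the convention of
    highlighting a disease's core chain in a different color.
    """
    nxg = graph.graph if isinstance(graph, CausalChainGraph) else graph
    core = {tuple(e) for e in core_edges}
    labels = labels or {}
    out = [f'digraph "{_dot_escape(name)}" {{']
    for n in sorted(nxg.nodes):
        label = _dot_escape(labels.get(n, str(n)))
        out.append(f'  "{_dot_escape(str(n))}" [label="{label}"];')
    for (a, b) in sorted(nxg.edges):
        style = ' [color="orange", penwidth=2.0]' if (a, b) in core else ""
        out.append(f'  "{_dot_escape(str(a))}" -> "{_dot_escape(str(b))}"{style};')
    out.append("}")
    text = "\n".join(out) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
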