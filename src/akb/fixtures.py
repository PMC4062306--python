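"""The worked clinical examples as an executable model bundle.

Ships, in code, everything needed to exercise every operation end to end:

* the decomposition rules for the canonical property examples
  (gastrectasia, hyperglycemia, gastric polyposis, the three ratio
  flavours, arterial stenosis) — nausea deliberately has *no* rule, since
  it is an atomic clinical property;
* threshold tables for blood glucose (diagnostic cutoff 126 mg/dL, with
  degree bands) and arterial cross-sectional area;
* the abnormality taxonomy: published skeleton + stenosis/hyperglycemia
  lineages + the two distinct cardiac-hypertrophy contexts (hypertensive
  heart disease vs. Pompe disease) as separate level-3 classes;
* the ischemic-heart-disease family (IHD, myocardial infarction,
  Prinzmetal angina with a smoking-derived upstream chain, organic angina
  pectoris with cholesterol accumulation) and supporting diseases across
  three departments (cardiovascular, metabolic, gastroenterology), sized
  for the cross-department merging and commonality analyses.
"""

from __future__ import annotations

from .chains import build_disease
from .io_formats import ModelBundle
from .model import (
    Attribute,
    DecompositionRule,
    DecompositionRuleSet,
    EntityRef,
    ThresholdSpec,
)
from .ontology import AbnormalStateClass, StateTemplate, build_seed_taxonomy

DEPT_CARDIO = "cardiovascular"
DEPT_METABOLIC = "metabolic"
DEPT_GASTRO = "gastroenterology"


def _entities() -> dict[str, EntityRef]:
    refs = [
        EntityRef("stomach"),
        EntityRef("patient", kind="organism"),
        EntityRef("blood", kind="substance"),
        EntityRef("glucose", kind="substance"),
        EntityRef("polyp"),
        EntityRef("urine", kind="substance"),
        EntityRef("albumin", kind="substance"),
        EntityRef("ag_ratio", label="A/G", kind="substance"),
        EntityRef("artery"),
        EntityRef("tubular_structure", kind="generic-structure"),
        EntityRef("valve_structure", kind="generic-structure"),
        EntityRef("blood_vessel"),
        EntityRef("coronary_artery"),
        EntityRef("pulmonary_artery"),
        EntityRef("cerebral_vessel"),
        EntityRef("intestine"),
        EntityRef("esophagus"),
        EntityRef("trachea"),
        EntityRef("rectum"),
        EntityRef("heart"),
        EntityRef("heart_muscle"),
        EntityRef("myocardium"),
        EntityRef("pancreas"),
        EntityRef("artery_wall"),
    ]
    return {r.id: r for r in refs}


def canonical_rules(entities=None) -> DecompositionRuleSet:
    """The canonical decomposition table.

    Basic triples, extended quadruples with a sub-object, and the three
    ratio flavours; plus the stenosis decomposition used by the
    quantitative interoperability example.
    """
    e = entities or _entities()
    size_scale = ("small", "normal", "large")
    amount_scale = ("low", "normal", "high")
    count_scale = ("few", "normal", "many")
    return DecompositionRuleSet([
        DecompositionRule(
            property_id="gastrectasia",
            object=e["stomach"],
            attribute=Attribute("volume"),
            qualitative_token="large",
            scale=size_scale,
        ),
        DecompositionRule(
            property_id="hyperglycemia",
            object=e["blood"],
            sub_object=e["glucose"],
            attribute=Attribute("concentration"),
            qualitative_token="high",
            scale=amount_scale,
            ratio_kind="whole-vs-focused",
        ),
        DecompositionRule(
            property_id="gastric_polyposis",
            object=e["stomach"],
            sub_object=e["polyp"],
            attribute=Attribute("number"),  # a meta-attribute of the polyps
            qualitative_token="many",
            scale=count_scale,
        ),
        DecompositionRule(
            property_id="high_albumin_ratio",
            object=e["urine"],
            sub_object=e["albumin"],
            attribute=Attribute("concentration",
                                ratio_spec=("albumin", "creatinine")),
            qualitative_token="high",
            scale=amount_scale,
            ratio_kind="m-of-same-object",
        ),
        DecompositionRule(
            property_id="increased_ag_ratio",
            object=e["blood"],
            sub_object=e["ag_ratio"],
            attribute=Attribute("ratio", ratio_spec=("albumin", "globulin")),
            qualitative_token="high",
            scale=amount_scale,
            ratio_kind="ratio-of-same-object",
        ),
        DecompositionRule(
            property_id="arterial_stenosis",
            object=e["artery"],
            attribute=Attribute("cross-sectional-area"),
            qualitative_token="small",
            scale=size_scale,
        ),
    ])


def thresholds(entities=None) -> list[ThresholdSpec]:
    """Institutional threshold tables for the quantitative examples.

    The glucose upper bound is the 126 mg/dL fasting-glucose diagnostic
    cutoff; the degree-band edges (126/160/200) and the arterial-area band
    are illustrative institutional choices — thresholds are inputs, not
    model constants.
    """
    e = entities or _entities()
    return [
        ThresholdSpec(
            object=e["blood"],
            sub_object=e["glucose"],
            attribute=Attribute("concentration"),
            unit="mg/dL",
            lower=70.0,
            upper=126.0,
            scale=("low", "normal", "high"),
            degree_bands=((126.0, "mild"), (160.0, "moderate"), (200.0, "severe")),
        ),
        ThresholdSpec(
            object=e["artery"],
            attribute=Attribute("cross-sectional-area"),
            unit="mm^2",
            lower=30.0,
            upper=80.0,
            scale=("small", "normal", "large"),
        ),
    ]


def _extend_taxonomy(tax, e):
    """Add the chain-node classes used by the fixture diseases."""
    C = AbnormalStateClass

    def l2(cid, parent, obj, label=None, definition=None):
        tax.specialize(parent, object=e[obj], id=cid,
                       label=label or cid.replace("_", " "),
                       definition=definition)

    # cardiovascular chain nodes
    l2("myocardial_ischemia", "decreased_parameter", "myocardium",
       definition=StateTemplate("blood-supply", "low"))
    l2("myocardial_hypoxia", "decreased_parameter", "myocardium",
       definition=StateTemplate("oxygen-level", "low"))
    l2("decreased_blood_flow", "decreased_parameter", "coronary_artery",
       definition=StateTemplate("blood-flow", "low"))
    l2("myocardial_necrosis", "material_abnormality", "myocardium")
    l2("coronary_spasm", "hyperfunction", "coronary_artery")
    l2("smoking", "other_abnormality", "patient",
       label="smoking (nicotine absorption)")
    l2("accumulation_of_cholesterol", "increased_parameter", "artery_wall")
    l2("arterial_sclerosis", "material_abnormality", "artery")
    l2("hypertension", "increased_parameter", "blood",
       definition=StateTemplate("pressure", "high"))
    l2("pressure_overload", "increased_parameter", "heart")
    l2("cardiac_hypertrophy", "size_abnormality", "heart")
    # metabolic
    l2("metabolic_dysfunction", "dysfunction", "patient")
    l2("glycogen_accumulation", "increased_parameter", "heart_muscle")
    l2("insulin_deficiency", "decreased_parameter", "pancreas")
    # gastroenterology
    l2("dysphagia", "dysfunction", "esophagus")
    l2("intestinal_obstruction", "function_arrest", "intestine")

    # level-3 contexts: the two distinct cardiac-hypertrophy uses, and the
    # context-bound hyperglycemia of diabetes
    tax.specialize("cardiac_hypertrophy",
                   disease_context="hypertensive_heart_disease",
                   id="cardiac_hypertrophy_in_hhd",
                   label="cardiac hypertrophy in hypertensive heart disease")
    tax.specialize("cardiac_hypertrophy",
                   disease_context="glycogenosis_ii",
                   id="cardiac_hypertrophy_in_pompe",
                   label="cardiac hypertrophy in glycogenosis II")
    tax.specialize("hyperglycemia", disease_context="diabetes_mellitus",
                   id="hyperglycemia_in_diabetes",
                   label="hyperglycemia in diabetes mellitus")
    return tax


def _diseases(tax):
    D = []
    # --- the ischemic heart disease family ---
    D.append(build_disease(
        "ihd", "ischemic heart disease", DEPT_CARDIO,
        states=["coronary_artery_stenosis", "myocardial_ischemia",
                "myocardial_hypoxia"],
        causal_links=[("coronary_artery_stenosis", "myocardial_ischemia"),
                      ("myocardial_ischemia", "myocardial_hypoxia")],
        core_flags=[("coronary_artery_stenosis", "myocardial_ischemia")],
        tax=tax,
    ))
    D.append(build_disease(
        "myocardial_infarction", "myocardial infarction", DEPT_CARDIO,
        states=["coronary_artery_stenosis", "decreased_blood_flow",
                "myocardial_ischemia", "myocardial_necrosis"],
        causal_links=[("coronary_artery_stenosis", "decreased_blood_flow"),
                      ("decreased_blood_flow", "myocardial_ischemia"),
                      ("myocardial_ischemia", "myocardial_necrosis")],
        core_flags=[("coronary_artery_stenosis", "decreased_blood_flow"),
                    ("decreased_blood_flow", "myocardial_ischemia"),
                    ("myocardial_ischemia", "myocardial_necrosis")],
        tax=tax,
    ))
    D.append(build_disease(
        "prinzmetal_angina", "Prinzmetal angina", DEPT_CARDIO,
        states=["smoking", "coronary_spasm", "coronary_artery_stenosis",
                "myocardial_ischemia"],
        causal_links=[("smoking", "coronary_spasm"),
                      ("coronary_spasm", "coronary_artery_stenosis"),
                      ("coronary_artery_stenosis", "myocardial_ischemia")],
        core_flags=[("coronary_spasm", "coronary_artery_stenosis"),
                    ("coronary_artery_stenosis", "myocardial_ischemia")],
        tax=tax,
    ))
    D.append(build_disease(
        "organic_angina_pectoris", "organic angina pectoris", DEPT_CARDIO,
        states=["accumulation_of_cholesterol", "arterial_sclerosis",
                "coronary_artery_stenosis", "myocardial_ischemia"],
        causal_links=[("accumulation_of_cholesterol", "arterial_sclerosis"),
                      ("arterial_sclerosis", "coronary_artery_stenosis"),
                      ("coronary_artery_stenosis", "myocardial_ischemia")],
        core_flags=[("arterial_sclerosis", "coronary_artery_stenosis"),
                    ("coronary_artery_stenosis", "myocardial_ischemia")],
        tax=tax,
    ))
    # --- hypertrophy contexts (term disambiguation example) ---
    D.append(build_disease(
        "hypertensive_heart_disease", "hypertensive heart disease", DEPT_CARDIO,
        states=["hypertension", "pressure_overload", "cardiac_hypertrophy_in_hhd"],
        causal_links=[("hypertension", "pressure_overload"),
                      ("pressure_overload", "cardiac_hypertrophy_in_hhd")],
        core_flags=[("hypertension", "pressure_overload"),
                    ("pressure_overload", "cardiac_hypertrophy_in_hhd")],
        tax=tax,
    ))
    D.append(build_disease(
        "glycogenosis_ii", "glycogenosis II (Pompe disease)", DEPT_METABOLIC,
        states=["metabolic_dysfunction", "glycogen_accumulation",
                "cardiac_hypertrophy_in_pompe"],
        causal_links=[("metabolic_dysfunction", "glycogen_accumulation"),
                      ("glycogen_accumulation", "cardiac_hypertrophy_in_pompe")],
        core_flags=[("metabolic_dysfunction", "glycogen_accumulation"),
                    ("glycogen_accumulation", "cardiac_hypertrophy_in_pompe")],
        tax=tax,
    ))
    # --- metabolic diseases feeding the cross-department merge ---
    D.append(build_disease(
        "hyperlipidemia", "hyperlipidemia", DEPT_METABOLIC,
        states=["accumulation_of_cholesterol", "coronary_artery_stenosis"],
        causal_links=[("accumulation_of_cholesterol", "coronary_artery_stenosis")],
        core_flags=[("accumulation_of_cholesterol", "coronary_artery_stenosis")],
        tax=tax,
    ))
    D.append(build_disease(
        "diabetes_mellitus", "diabetes mellitus", DEPT_METABOLIC,
        states=["insulin_deficiency", "hyperglycemia_in_diabetes"],
        causal_links=[("insulin_deficiency", "hyperglycemia_in_diabetes")],
        core_flags=[("insulin_deficiency", "hyperglycemia_in_diabetes")],
        tax=tax,
    ))
    # --- gastroenterology ---
    D.append(build_disease(
        "ileus", "ileus", DEPT_GASTRO,
        states=["intestinal_stenosis", "intestinal_obstruction"],
        causal_links=[("intestinal_stenosis", "intestinal_obstruction")],
        core_flags=[("intestinal_stenosis", "intestinal_obstruction")],
        tax=tax,
    ))
    D.append(build_disease(
        "esophageal_stricture", "esophageal stricture", DEPT_GASTRO,
        states=["esophagostenosis", "dysphagia"],
        causal_links=[("esophagostenosis", "dysphagia")],
        core_flags=[("esophagostenosis", "dysphagia")],
        tax=tax,
    ))
    return {d.id: d for d in D}


def build_worked_examples() -> ModelBundle:
    """Assemble the complete worked-example bundle."""
    entities = _entities()
    tax = build_seed_taxonomy()
    _extend_taxonomy(tax, entities)
    bundle = ModelBundle(
        taxonomy=tax,
        entities=entities,
        rules=canonical_rules(entities),
        thresholds=thresholds(entities),
        diseases=_diseases(tax),
        metadata={"name": "worked-examples", "version": "1"},
    )
    return bundle
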