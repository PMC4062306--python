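"""Causal chains: inclusion matching, disease is-a, cores, merging."""

import pytest

from akb import (
    CausalChainGraph,
    build_disease,
    chain_included,
    chain_included_bruteforce,
    classify_chain_parts,
    compute_core_chain,
    disease_is_a,
    infer_hierarchy,
    merge_generic,
    validate_core,
)
from akb.errors import CycleError, UnknownClassError, ValidationError
from akb.synthetic import random_inclusion_instances


# ---------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------

def test_build_disease_validates(tax):
    d = build_disease(
        "toy", "toy", "cardiovascular",
        states=["coronary_artery_stenosis", "myocardial_ischemia"],
        causal_links=[("coronary_artery_stenosis", "myocardial_ischemia")],
        core_flags=[("coronary_artery_stenosis", "myocardial_ischemia")],
        tax=tax,
    )
    assert d.derived_edges == frozenset()

    with pytest.raises(UnknownClassError):
        build_disease("bad", "bad", "x", ["not_a_state"], [], [], tax)
    with pytest.raises(CycleError):
        build_disease(
            "loop", "loop", "x", ["myocardial_ischemia"],
            [("myocardial_ischemia", "myocardial_ischemia")], [], tax)
    with pytest.raises(CycleError):
        build_disease(
            "cyc", "cyc", "x",
            ["coronary_artery_stenosis", "myocardial_ischemia"],
            [("coronary_artery_stenosis", "myocardial_ischemia"),
             ("myocardial_ischemia", "coronary_artery_stenosis")], [], tax)
    with pytest.raises(ValidationError, match="core edges"):
        build_disease(
            "core_bad", "x", "x", ["myocardial_ischemia"], [],
            [("a", "b")], tax)


# ---------------------------------------------------------------------
# chain inclusion
# ---------------------------------------------------------------------

def test_core_chain_embeds_into_specialized_chain(bundle, tax):
    ihd = bundle.diseases["ihd"].core_chain()
    mi = bundle.diseases["myocardial_infarction"].chain
    m = chain_included(ihd, mi, tax, mode="path")
    assert m is not None and m.is_valid(ihd, mi, tax)
    # the stenosis -> ischemia link is realized as a 2-edge path through
    # decreased blood flow, so edge-strict matching must fail
    assert chain_included(ihd, mi, tax, mode="edge") is None


def test_empty_chain_trivially_included(bundle, tax):
    empty = CausalChainGraph()
    m = chain_included(empty, bundle.diseases["ihd"].chain, tax)
    assert m is not None and m.node_map == {}


def test_reversed_chain_not_included(tax):
    fwd = CausalChainGraph.from_path(
        ["coronary_artery_stenosis", "myocardial_ischemia",
         "myocardial_necrosis"])
    rev = CausalChainGraph.from_path(
        ["myocardial_ischemia", "coronary_artery_stenosis"])
    assert chain_included(rev, fwd, tax) is None
    assert chain_included_bruteforce(rev, fwd, tax) is None


def test_node_subsumption_in_matching(tax):
    """A chain over a general state embeds into one over its subclass,
    never the other way around."""
    general = CausalChainGraph.from_path(
        ["vascular_stenosis", "myocardial_ischemia"])
    specific = CausalChainGraph.from_path(
        ["coronary_artery_stenosis", "myocardial_ischemia"])
    m = chain_included(general, specific, tax)
    assert m is not None
    assert m.node_map["vascular_stenosis"] == "coronary_artery_stenosis"
    assert chain_included(specific, general, tax) is None


def test_matcher_agrees_with_bruteforce_oracle():
    tax, pairs = random_inclusion_instances(seed=11, n_pairs=120)
    for small, large in pairs:
        for mode in ("path", "edge"):
            fast = chain_included(small, large, tax, mode)
            slow = chain_included_bruteforce(small, large, tax, mode)
            assert (fast is None) == (slow is None)
            if fast is not None:
                assert fast.is_valid(small, large, tax)


def test_chain_inclusion_reflexive_and_transitive():
    tax, pairs = random_inclusion_instances(seed=5, n_pairs=40)
    graphs = [g for pair in pairs for g in pair if g.nodes]
    for g in graphs[:10]:
        assert chain_included(g, g, tax) is not None
    # transitivity: witness composition on observed inclusions
    hits = 0
    for a in graphs[:8]:
        for b in graphs[:8]:
            if chain_included(a, b, tax) is None:
                continue
            for c in graphs[:8]:
                if chain_included(b, c, tax) is not None:
                    assert chain_included(a, c, tax) is not None
                    hits += 1
    assert hits > 0


def test_cyclic_input_rejected(tax):
    cyclic = CausalChainGraph(
        nodes=["coronary_artery_stenosis", "myocardial_ischemia"],
        edges=[("coronary_artery_stenosis", "myocardial_ischemia"),
               ("myocardial_ischemia", "coronary_artery_stenosis")],
        allow_cycles=True,
    )
    with pytest.raises(CycleError):
        chain_included(cyclic, cyclic, tax)


# ---------------------------------------------------------------------
# disease is-a and hierarchy
# ---------------------------------------------------------------------

def test_ihd_family_is_a(bundle, tax, ihd_family):
    ihd, mi, prinz, organic = ihd_family
    assert disease_is_a(ihd, mi, tax)
    assert disease_is_a(ihd, prinz, tax)
    assert disease_is_a(ihd, organic, tax)
    assert disease_is_a(ihd, ihd, tax)
    assert not disease_is_a(mi, ihd, tax)
    assert not disease_is_a(prinz, ihd, tax)
    assert not disease_is_a(organic, ihd, tax)
    assert not disease_is_a(mi, prinz, tax)
    assert not disease_is_a(prinz, mi, tax)


def test_infer_hierarchy_reproduces_family(tax, ihd_family):
    result = infer_hierarchy(ihd_family, tax)
    assert result.edges == {
        ("ihd", "myocardial_infarction"),
        ("ihd", "prinzmetal_angina"),
        ("ihd", "organic_angina_pectoris"),
    }
    assert result.equivalence_groups == []


def test_single_disease_hierarchy(tax, ihd_family):
    result = infer_hierarchy(ihd_family[:1], tax)
    assert set(result.graph.nodes) == {"ihd"}
    assert result.edges == set()


def test_mutually_including_diseases_form_group(tax):
    a = build_disease("a", "a", "x",
                      ["coronary_artery_stenosis", "myocardial_ischemia"],
                      [("coronary_artery_stenosis", "myocardial_ischemia")],
                      [("coronary_artery_stenosis", "myocardial_ischemia")],
                      tax)
    b = build_disease("b", "b", "y",
                      ["coronary_artery_stenosis", "myocardial_ischemia"],
                      [("coronary_artery_stenosis", "myocardial_ischemia")],
                      [("coronary_artery_stenosis", "myocardial_ischemia")],
                      tax)
    result = infer_hierarchy([a, b], tax)
    assert result.equivalence_groups == [frozenset({"a", "b"})]
    assert result.edges == set()


# ---------------------------------------------------------------------
# core chains
# ---------------------------------------------------------------------

def test_computed_core_matches_asserted(bundle, tax, ihd_family):
    ihd, mi, prinz, organic = ihd_family
    core = compute_core_chain(ihd, [mi, prinz, organic], tax)
    assert core.edges == {("coronary_artery_stenosis", "myocardial_ischemia")}
    assert core.edges == set(ihd.core_edges)


def test_core_chain_no_subclasses_returns_asserted(bundle, tax):
    d = bundle.diseases["hyperlipidemia"]
    assert compute_core_chain(d, [], tax).edges == set(d.core_edges)


def test_computed_core_embeds_everywhere_and_is_maximal(tax, ihd_family):
    ihd, *subs = ihd_family
    core = compute_core_chain(ihd, subs, tax)
    for p in core.maximal_paths():
        for s in subs:
            assert chain_included(CausalChainGraph.from_path(p), s.chain,
                                  tax) is not None
    # adding back any removed edge breaks embedding in some subclass
    for extra in ihd.chain.edges - core.edges:
        for s in subs:
            bigger = ihd.chain.subgraph_from_edges(core.edges | {extra})
            ok = all(
                chain_included(CausalChainGraph.from_path(p), s.chain, tax)
                is not None
                for p in bigger.maximal_paths()
            )
            if not ok:
                break
        else:
            pytest.fail(f"edge {extra} should not be core")


def test_no_common_core_outcome(tax):
    a = build_disease("a", "a", "x",
                      ["hypertension", "pressure_overload"],
                      [("hypertension", "pressure_overload")],
                      [("hypertension", "pressure_overload")], tax)
    b = build_disease("b", "b", "y",
                      ["esophagostenosis", "dysphagia"],
                      [("esophagostenosis", "dysphagia")],
                      [("esophagostenosis", "dysphagia")], tax)
    assert compute_core_chain(a, [b], tax).is_empty()


def test_asserted_cores_validate_on_family(tax, ihd_family):
    ihd, *subs = ihd_family
    assert validate_core(ihd, subs, tax)


def test_classify_chain_parts(bundle):
    prinz = bundle.diseases["prinzmetal_angina"]
    core, derived = classify_chain_parts(prinz)
    assert ("smoking", "coronary_spasm") in derived.edges
    assert ("smoking", "coronary_spasm") not in core.edges

    organic = bundle.diseases["organic_angina_pectoris"]
    _, derived_o = classify_chain_parts(organic)
    assert ("accumulation_of_cholesterol", "arterial_sclerosis") in \
        derived_o.edges

    mi = bundle.diseases["myocardial_infarction"]
    core_mi, derived_mi = classify_chain_parts(mi)
    assert derived_mi.is_empty()
    assert core_mi.edges == mi.chain.edges


# ---------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------

def test_merge_produces_generic_chain(bundle, tax):
    merged = merge_generic(
        [bundle.diseases["ihd"], bundle.diseases["hyperlipidemia"]], tax)
    want = [
        ("accumulation_of_cholesterol", "coronary_artery_stenosis"),
        ("coronary_artery_stenosis", "myocardial_ischemia"),
        ("myocardial_ischemia", "myocardial_hypoxia"),
    ]
    assert set(want) <= merged.edges
    prov = merged.provenance("accumulation_of_cholesterol",
                             "coronary_artery_stenosis")
    assert ("hyperlipidemia", "metabolic") in prov


def test_merge_single_disease_is_identity(bundle, tax):
    d = bundle.diseases["ihd"]
    merged = merge_generic([d], tax)
    assert merged.nodes == d.chain.nodes
    assert merged.edges == d.chain.edges


def test_merge_idempotent_and_order_invariant(bundle, tax):
    ds = bundle.disease_list()
    once = merge_generic(ds, tax)
    twice = merge_generic(ds + ds, tax)
    rev = merge_generic(list(reversed(ds)), tax)
    assert once.nodes == twice.nodes == rev.nodes
    assert once.edges == twice.edges == rev.edges
    assert len(once.nodes) <= sum(len(d.chain.nodes) for d in ds)


def test_merge_unify_level2_collapses_contexts(bundle, tax):
    """The two level-3 cardiac-hypertrophy contexts become one node."""
    ds = [bundle.diseases["hypertensive_heart_disease"],
          bundle.diseases["glycogenosis_ii"]]
    plain = merge_generic(ds, tax)
    assert {"cardiac_hypertrophy_in_hhd", "cardiac_hypertrophy_in_pompe"} <= \
        plain.nodes
    unified = merge_generic(ds, tax, unify_level=2)
    assert "cardiac_hypertrophy" in unified.nodes
    assert not {"cardiac_hypertrophy_in_hhd",
                "cardiac_hypertrophy_in_pompe"} & unified.nodes


def test_merged_edges_keep_provenance(bundle, tax):
    merged = merge_generic(bundle.disease_list(), tax)
    for d in bundle.disease_list():
        for (a, b) in d.chain.edges:
            assert (d.id, d.department) in merged.provenance(a, b)
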