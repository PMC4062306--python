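"""Unit and property tests for the state-representation core."""

import pytest
from hypothesis import given, settings, strategies as st

from akb import (
    Attribute,
    AttributeValue,
    EntityRef,
    StateDescriptor,
    ThresholdSpec,
    canonical_key,
    compose,
    decompose,
    find_spec,
    grade,
    quantize,
    validate,
)
from akb.errors import (
    DegreeBandError,
    NoThresholdError,
    UnitMismatchError,
    ValidationError,
)
from akb.fixtures import canonical_rules, thresholds


@pytest.fixture(scope="module")
def rules():
    return canonical_rules()


@pytest.fixture(scope="module")
def glucose_spec():
    return next(t for t in thresholds() if t.object.id == "blood")


@pytest.fixture(scope="module")
def artery_spec():
    return next(t for t in thresholds() if t.object.id == "artery")


def _prop(rules, pid, degree=None, presence=True):
    rule = rules.by_property(pid)
    obj = rule.object if rule else EntityRef("patient", kind="organism")
    return StateDescriptor.property_state(pid, obj, presence=presence,
                                          degree=degree)


def _glucose_state(magnitude):
    return StateDescriptor.attribute_state(
        object=EntityRef("blood", kind="substance"),
        sub_object=EntityRef("glucose", kind="substance"),
        attribute=Attribute("concentration"),
        value=AttributeValue.quantitative(magnitude, "mg/dL"),
    )


# ---------------------------------------------------------------------
# decompose / compose
# ---------------------------------------------------------------------

@pytest.mark.parametrize(
    "pid, object_id, sub_id, attr, token",
    [
        ("gastrectasia", "stomach", None, "volume", "large"),
        ("hyperglycemia", "blood", "glucose", "concentration", "high"),
        ("gastric_polyposis", "stomach", "polyp", "number", "many"),
        ("high_albumin_ratio", "urine", "albumin", "concentration", "high"),
        ("increased_ag_ratio", "blood", "ag_ratio", "ratio", "high"),
        ("arterial_stenosis", "artery", None, "cross-sectional-area", "small"),
    ],
)
def test_decompose_reproduces_printed_tuples(rules, pid, object_id, sub_id,
                                             attr, token):
    out = decompose(_prop(rules, pid), rules)
    assert out.form == ("OSoAV" if sub_id else "OAV")
    assert out.object.id == object_id
    assert (out.sub_object.id if out.sub_object else None) == sub_id
    assert out.attribute.name == attr
    assert out.value.token == token
    assert not out.nondecomposable


def test_nausea_is_atomic(rules):
    """A property with no known mechanism stays in property form, flagged."""
    out = decompose(_prop(rules, "nausea"), rules)
    assert out.form == "OP"
    assert out.property_id == "nausea"
    assert out.nondecomposable


def test_compose_names_the_property(rules):
    state = StateDescriptor.attribute_state(
        object=EntityRef("artery"),
        attribute=Attribute("cross-sectional-area"),
        value=AttributeValue.qualitative("small"),
    )
    out = compose(state, rules)
    assert out.property_id == "arterial_stenosis"
    assert out.property_value.presence is True


def test_compose_unknown_tuple_returns_none(rules):
    state = StateDescriptor.attribute_state(
        object=EntityRef("artery"),
        attribute=Attribute("cross-sectional-area"),
        value=AttributeValue.qualitative("large", ("small", "normal", "large")),
    )
    assert compose(state, rules) is None


def test_compose_requires_qualitative(rules):
    with pytest.raises(ValidationError):
        compose(_glucose_state(260), rules)


def test_round_trip_all_rules(rules):
    """compose(decompose(x)) == x and decompose(compose(y)) == y per rule."""
    for rule in rules:
        op = _prop(rules, rule.property_id)
        oav = decompose(op, rules)
        assert compose(oav, rules) == op
        assert decompose(compose(oav, rules), rules) == oav


def test_degree_survives_the_round_trip(rules):
    op = _prop(rules, "hyperglycemia", degree="severe")
    oav = decompose(op, rules)
    assert oav.metadata["degree"] == "severe"
    back = compose(oav, rules)
    assert back.property_value.degree == "severe"
    assert back.form == "OPVd"


# ---------------------------------------------------------------------
# quantize
# ---------------------------------------------------------------------

def test_quantize_glucose_260_is_high(rules, glucose_spec):
    out = quantize(_glucose_state(260), glucose_spec)
    assert out.value.token == "high"
    assert compose(out, rules).property_id == "hyperglycemia"


def test_quantize_artery_24mm2_is_small(rules, artery_spec):
    state = StateDescriptor.attribute_state(
        object=EntityRef("artery"),
        attribute=Attribute("cross-sectional-area"),
        value=AttributeValue.quantitative(24, "mm^2"),
    )
    out = quantize(state, artery_spec)
    assert out.value.token == "small"
    assert compose(out, rules).property_id == "arterial_stenosis"


def test_quantize_boundary_belongs_to_neutral_band(glucose_spec):
    assert quantize(_glucose_state(126.0), glucose_spec).value.token == "normal"
    assert quantize(_glucose_state(70.0), glucose_spec).value.token == "normal"


def test_quantize_abnormal_boundary_convention(glucose_spec):
    import dataclasses

    spec = dataclasses.replace(glucose_spec, boundary="abnormal",
                               degree_bands=())
    assert quantize(_glucose_state(126.0), spec).value.token == "high"


def test_quantize_unit_mismatch(glucose_spec):
    state = StateDescriptor.attribute_state(
        object=EntityRef("blood", kind="substance"),
        sub_object=EntityRef("glucose", kind="substance"),
        attribute=Attribute("concentration"),
        value=AttributeValue.quantitative(14.4, "mmol/L"),
    )
    with pytest.raises(UnitMismatchError, match="mmol/L"):
        quantize(state, glucose_spec)


def test_find_spec_missing_target():
    state = StateDescriptor.attribute_state(
        object=EntityRef("liver"),
        attribute=Attribute("volume"),
        value=AttributeValue.quantitative(1, "L"),
    )
    with pytest.raises(NoThresholdError):
        find_spec(thresholds(), state)


@settings(max_examples=200, derandomize=True)
@given(m1=st.floats(0, 500, allow_nan=False),
       m2=st.floats(0, 500, allow_nan=False))
def test_quantize_monotone(m1, m2):
    """Larger magnitudes never map to a lower rank on the qualitative scale."""
    spec = next(t for t in thresholds() if t.object.id == "blood")
    if m1 > m2:
        m1, m2 = m2, m1
    r = {t: i for i, t in enumerate(spec.scale)}
    t1 = quantize(_glucose_state(m1), spec).value.token
    t2 = quantize(_glucose_state(m2), spec).value.token
    assert r[t1] <= r[t2]


# ---------------------------------------------------------------------
# grade
# ---------------------------------------------------------------------

@pytest.mark.parametrize("magnitude, degree", [
    (130, "mild"), (160, "moderate"), (199.9, "moderate"), (260, "severe"),
])
def test_grade_band_lookup(rules, glucose_spec, magnitude, degree):
    out = grade(_glucose_state(magnitude), glucose_spec, rules)
    assert out.form == "OPVd"
    assert out.property_id == "hyperglycemia"
    assert out.property_value.degree == degree


def test_grade_neutral_is_absent_property(rules, glucose_spec):
    """A normal value grades to <hyperglycemia, false> (latent diabetes)."""
    out = grade(_glucose_state(100), glucose_spec, rules)
    assert out.property_id == "hyperglycemia"
    assert out.property_value.presence is False
    assert out.property_value.degree is None


def test_grade_without_bands_rejected(rules, artery_spec):
    state = StateDescriptor.attribute_state(
        object=EntityRef("artery"),
        attribute=Attribute("cross-sectional-area"),
        value=AttributeValue.quantitative(24, "mm^2"),
    )
    with pytest.raises(DegreeBandError, match="quantize"):
        grade(state, artery_spec, rules)


@settings(max_examples=200, derandomize=True)
@given(m1=st.floats(126.5, 500, allow_nan=False),
       m2=st.floats(126.5, 500, allow_nan=False))
def test_grade_monotone_in_magnitude(m1, m2):
    """A larger abnormal magnitude never receives a lower degree."""
    spec = next(t for t in thresholds() if t.object.id == "blood")
    rules = canonical_rules()
    if m1 > m2:
        m1, m2 = m2, m1
    rank = {d: i for i, d in enumerate(("mild", "moderate", "severe"))}
    d1 = grade(_glucose_state(m1), spec, rules).property_value.degree
    d2 = grade(_glucose_state(m2), spec, rules).property_value.degree
    assert rank[d1] <= rank[d2]


def test_interoperability_chain_consistency(rules, glucose_spec):
    """compose(quantize(x)) agrees with grade(x) up to the degree."""
    for magnitude in (90, 130, 170, 260):
        q = _glucose_state(magnitude)
        composed = compose(quantize(q, glucose_spec), rules)
        graded = grade(q, glucose_spec, rules)
        if magnitude > glucose_spec.upper:
            assert composed.property_id == graded.property_id
            assert graded.property_value.presence is True
        else:
            assert composed is None  # 'normal' names no property
            assert graded.property_value.presence is False


# ---------------------------------------------------------------------
# canonical_key / validate
# ---------------------------------------------------------------------

def test_canonical_key_invariant_under_form_conversion(rules):
    for rule in rules:
        op = _prop(rules, rule.property_id)
        oav = decompose(op, rules)
        assert canonical_key(op, rules) == canonical_key(oav, rules)


def test_canonical_key_value_sensitive(rules):
    high = StateDescriptor.attribute_state(
        object=EntityRef("blood"), sub_object=EntityRef("glucose"),
        attribute=Attribute("concentration"),
        value=AttributeValue.qualitative("high", ("low", "normal", "high")))
    low = StateDescriptor.attribute_state(
        object=EntityRef("blood"), sub_object=EntityRef("glucose"),
        attribute=Attribute("concentration"),
        value=AttributeValue.qualitative("low", ("low", "normal", "high")))
    assert canonical_key(high, rules) != canonical_key(low, rules)


def test_canonical_key_ignores_open_metadata_by_default(rules):
    a = _prop(rules, "gastrectasia")
    b = StateDescriptor.property_state("gastrectasia", EntityRef("stomach"),
                                       age="neonatal")
    assert canonical_key(a, rules) == canonical_key(b, rules)
    assert canonical_key(a, rules, include_metadata=True) != \
        canonical_key(b, rules, include_metadata=True)


def test_validate_well_formed_oav_is_clean():
    state = StateDescriptor.attribute_state(
        object=EntityRef("stomach"), attribute=Attribute("volume"),
        value=AttributeValue.qualitative("large"))
    assert validate(state) == []


def test_validate_flags_exclusivity_and_form_violations():
    both = StateDescriptor(
        form="OP", object=EntityRef("stomach"), property_id="gastrectasia",
        attribute=Attribute("volume"),
        property_value=None,
    )
    v = validate(both)
    assert any("exactly one" in x for x in v)
    assert any("property_value" in x for x in v)

    no_sub = StateDescriptor(
        form="OSoAV", object=EntityRef("blood"),
        attribute=Attribute("concentration"),
        value=AttributeValue.qualitative("high"),
    )
    assert any("sub_object" in x for x in validate(no_sub))


def test_degree_requires_presence():
    from akb import PropertyValue

    assert PropertyValue(presence=False, degree="severe").violations()
    assert not PropertyValue(presence=True, degree="severe").violations()


def test_threshold_spec_rejects_inverted_bounds():
    with pytest.raises(ValidationError):
        ThresholdSpec(object=EntityRef("blood"),
                      attribute=Attribute("concentration"),
                      unit="mg/dL", lower=126, upper=70)
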