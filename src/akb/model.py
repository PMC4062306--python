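"""Unified representation of clinical abnormal states.

An abnormal state can be written in several interoperable forms:

* property form ``<Object, Property, true/false>`` (``OP``), optionally with
  an ordinal degree (``OPVd``), e.g. ``<blood, hyperglycemia, severe>``;
* attribute form ``<Object, Attribute, Value>`` (``OAV``), e.g.
  ``<stomach, volume, large>``;
* extended attribute form with a focused sub-object,
  ``<Object, Sub-Object, Attribute, Value>`` (``OSoAV``), e.g.
  ``<blood, glucose, concentration, high>``.

The attribute value may be qualitative (``high``/``small``/``many``),
quantitative (``260 mg/dL``) or categorical.  This module implements the
conversions between the forms:

``decompose``
    property -> attribute form, via a table of decomposition rules
    (a property is a lexicalized attribute/value pair; some clinical
    properties, like nausea, are legitimately atomic and stay undecomposed);
``compose``
    qualitative attribute form -> property form (the inverse lookup);
``quantize``
    quantitative -> qualitative value against a per-hospital threshold band;
``grade``
    quantitative -> property-with-degree (mild/moderate/severe), the form
    clinicians use in case reports.

Together these make raw clinical test data, qualitative findings and the
conceptual vocabulary of disease definitions mutually convertible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Optional

from .errors import (
    DegreeBandError,
    NoThresholdError,
    RuleConfigError,
    UnitMismatchError,
    ValidationError,
)

# Descriptor forms
OP = "OP"          # <Object, Property, presence>
OPVD = "OPVd"      # <Object, Property, degree>
OAV = "OAV"        # <Object, Attribute, Value>
OSOAV = "OSoAV"    # <Object, Sub-Object, Attribute, Value>
OSOP = "OSoP"      # property form that keeps an explicit sub-object
FORMS = (OP, OPVD, OAV, OSOAV, OSOP)

PROPERTY_FORMS = (OP, OPVD, OSOP)
ATTRIBUTE_FORMS = (OAV, OSOAV)

ENTITY_KINDS = ("anatomical", "generic-structure", "substance", "organism")
VALUE_KINDS = ("quantitative", "qualitative", "categorical")

#: The only degree vocabulary accepted at load time.  A fixed, minimal
#: ordinal scale keeps degree values exchangeable between institutions.
DEGREES = ("mild", "moderate", "severe")

#: Ratio flavours: the whole object vs. a focused constituent
#: (glucose/blood), a constituent ratio within one object
#: (albumin/creatinine in urine), and a named ratio of one object (A/G).
RATIO_KINDS = ("whole-vs-focused", "m-of-same-object", "ratio-of-same-object")


@dataclass(frozen=True)
class EntityRef:
    """A reference to an independent entity (object or sub-object)."""

    id: str
    label: str = ""
    kind: str = "anatomical"

    def __post_init__(self):
        if not self.label:
            object.__setattr__(self, "label", self.id)

    def violations(self) -> list[str]:
        out = []
        if not self.id:
            out.append("EntityRef.id must be non-empty")
        if self.kind not in ENTITY_KINDS:
            out.append(f"EntityRef.kind {self.kind!r} not in {ENTITY_KINDS}")
        return out


@dataclass(frozen=True)
class Attribute:
    """A generic quality dimension (volume, concentration, number, ...).

    ``ratio_spec`` names the numerator/denominator pair for ratio-like
    attributes, e.g. ``("albumin", "creatinine")``.
    """

    name: str
    dimension: Optional[str] = None
    ratio_spec: Optional[tuple[str, str]] = None

    def violations(self) -> list[str]:
        out = []
        if not self.name:
            out.append("Attribute.name must be non-empty")
        if self.name == "ratio" and self.ratio_spec is None:
            out.append("Attribute 'ratio' requires ratio_spec (m, n)")
        return out


@dataclass(frozen=True)
class AttributeValue:
    """A categorical, quantitative or qualitative attribute value."""

    kind: str
    magnitude: Optional[float] = None
    unit: Optional[str] = None
    token: Optional[str] = None
    scale: tuple[str, ...] = ()

    @staticmethod
    def quantitative(magnitude: float, unit: str) -> "AttributeValue":
        return AttributeValue(kind="quantitative", magnitude=float(magnitude), unit=unit)

    @staticmethod
    def qualitative(token: str, scale: tuple[str, ...] = ()) -> "AttributeValue":
        return AttributeValue(kind="qualitative", token=token, scale=scale or (token,))

    @staticmethod
    def categorical(token: str) -> "AttributeValue":
        return AttributeValue(kind="categorical", token=token, scale=(token,))

    def violations(self) -> list[str]:
        out = []
        if self.kind not in VALUE_KINDS:
            out.append(f"AttributeValue.kind {self.kind!r} not in {VALUE_KINDS}")
            return out
        if self.kind == "quantitative":
            if self.magnitude is None:
                out.append("quantitative value requires magnitude")
            if self.token is not None:
                out.append("quantitative value must not carry a token")
        else:
            if self.token is None:
                out.append(f"{self.kind} value requires token")
            elif self.kind == "qualitative" and self.scale and self.token not in self.scale:
                out.append(f"qualitative token {self.token!r} not in scale {self.scale}")
        return out


@dataclass(frozen=True)
class PropertyValue:
    """Presence (true/false) of a property, optionally refined by a degree.

    The degree is treated as a specialization of the present state, so a
    degree may only be given for a present property.
    """

    presence: bool
    degree: Optional[str] = None

    def violations(self) -> list[str]:
        out = []
        if self.degree is not None:
            if self.degree not in DEGREES:
                out.append(f"degree {self.degree!r} not in {DEGREES}")
            if not self.presence:
                out.append("degree requires presence=True")
        return out


@dataclass(frozen=True)
class StateDescriptor:
    """One abnormal state in any of the interoperable forms.

    Exactly one of ``property_id`` (property forms) and ``attribute``
    (attribute forms) is populated.  ``metadata`` is an open key->token map
    for additional parameters (e.g. ``age="neonatal"``); it also carries the
    ``nondecomposable`` flag and a preserved ``degree`` across form
    conversions.
    """

    form: str
    object: EntityRef
    sub_object: Optional[EntityRef] = None
    property_id: Optional[str] = None
    attribute: Optional[Attribute] = None
    value: Optional[AttributeValue] = None
    property_value: Optional[PropertyValue] = None
    metadata: dict = field(default_factory=dict)

    # -- convenience constructors -------------------------------------
    @staticmethod
    def property_state(
        property_id: str,
        object: EntityRef,
        presence: bool = True,
        degree: Optional[str] = None,
        sub_object: Optional[EntityRef] = None,
        **metadata,
    ) -> "StateDescriptor":
        form = OPVD if degree is not None else (OSOP if sub_object else OP)
        return StateDescriptor(
            form=form,
            object=object,
            sub_object=sub_object,
            property_id=property_id,
            property_value=PropertyValue(presence=presence, degree=degree),
            metadata=dict(metadata),
        )

    @staticmethod
    def attribute_state(
        object: EntityRef,
        attribute: Attribute,
        value: AttributeValue,
        sub_object: Optional[EntityRef] = None,
        **metadata,
    ) -> "StateDescriptor":
        form = OSOAV if sub_object is not None else OAV
        return StateDescriptor(
            form=form,
            object=object,
            sub_object=sub_object,
            attribute=attribute,
            value=value,
            metadata=dict(metadata),
        )

    @property
    def is_property_form(self) -> bool:
        return self.form in PROPERTY_FORMS

    @property
    def is_attribute_form(self) -> bool:
        return self.form in ATTRIBUTE_FORMS

    @property
    def nondecomposable(self) -> bool:
        return bool(self.metadata.get("nondecomposable"))


def validate(state: StateDescriptor) -> list[str]:
    """Return the list of violated invariants (empty iff well-formed)."""
    out: list[str] = []
    if state.form not in FORMS:
        out.append(f"form {state.form!r} not in {FORMS}")
        return out
    out.extend(state.object.violations())
    if state.sub_object is not None:
        out.extend(state.sub_object.violations())

    populated = [x for x in (state.property_id, state.attribute) if x is not None]
    if len(populated) != 1:
        out.append("exactly one of property_id / attribute must be populated")

    if state.form in PROPERTY_FORMS:
        if state.property_id is None:
            out.append(f"{state.form} form requires property_id")
        if state.property_value is None:
            out.append(f"{state.form} form requires property_value")
        else:
            out.extend(state.property_value.violations())
            if state.form == OPVD and state.property_value.degree is None:
                out.append("OPVd form requires a degree")
        if state.attribute is not None:
            out.append(f"{state.form} form must not carry an attribute")
        if state.form == OSOP and state.sub_object is None:
            out.append("OSoP form requires sub_object")
    else:
        if state.attribute is None:
            out.append(f"{state.form} form requires attribute")
        else:
            out.extend(state.attribute.violations())
        if state.value is None:
            out.append(f"{state.form} form requires value")
        else:
            out.extend(state.value.violations())
        if state.form == OSOAV and state.sub_object is None:
            out.append("OSoAV form requires sub_object")
        if state.form == OAV and state.sub_object is not None:
            out.append("OAV form must not carry sub_object (use OSoAV)")
    return out


def _check(state: StateDescriptor) -> None:
    v = validate(state)
    if v:
        raise ValidationError(v)


# ---------------------------------------------------------------------
# Decomposition rules
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class DecompositionRule:
    """Links one property to its attribute/value decomposition.

    E.g. *gastrectasia* |-> ``<stomach, volume, large>`` or *hyperglycemia*
    |-> ``<blood, glucose, concentration, high>``.
    """

    property_id: str
    object: EntityRef
    attribute: Attribute
    qualitative_token: str
    sub_object: Optional[EntityRef] = None
    scale: tuple[str, ...] = ()
    ratio_kind: Optional[str] = None

    def __post_init__(self):
        if self.ratio_kind is not None and self.ratio_kind not in RATIO_KINDS:
            raise RuleConfigError(
                f"ratio_kind {self.ratio_kind!r} not in {RATIO_KINDS}"
            )

    @property
    def key(self) -> tuple:
        return (
            self.object.id,
            self.sub_object.id if self.sub_object else None,
            self.attribute.name,
            self.qualitative_token,
        )

    def value_scale(self) -> tuple[str, ...]:
        return self.scale or (self.qualitative_token,)


class DecompositionRuleSet:
    """An indexed, bidirectional table of decomposition rules.

    Composition must be a function: both the property id and the
    (object, sub-object, attribute, token) tuple are unique per rule set.
    """

    def __init__(self, rules=()):
        self._by_property: dict[str, DecompositionRule] = {}
        self._by_tuple: dict[tuple, DecompositionRule] = {}
        for r in rules:
            self.add(r)

    def add(self, rule: DecompositionRule) -> None:
        if rule.property_id in self._by_property:
            raise RuleConfigError(f"duplicate rule for property {rule.property_id!r}")
        if rule.key in self._by_tuple:
            raise RuleConfigError(f"ambiguous rule set: duplicate tuple {rule.key}")
        self._by_property[rule.property_id] = rule
        self._by_tuple[rule.key] = rule

    def __len__(self):
        return len(self._by_property)

    def __iter__(self):
        return iter(self._by_property.values())

    def by_property(self, property_id: str) -> Optional[DecompositionRule]:
        return self._by_property.get(property_id)

    def by_tuple(self, object_id, sub_object_id, attribute_name, token):
        return self._by_tuple.get((object_id, sub_object_id, attribute_name, token))


# ---------------------------------------------------------------------
# Threshold specifications
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdSpec:
    """Quantization bands for one (object, sub-object, attribute) target.

    ``[lower, upper]`` is the neutral (normal) band; the ``scale`` is the
    ordered qualitative vocabulary ``(low token, neutral token, high token)``.
    ``degree_bands`` is an ordered list of ``(cutoff, degree)`` pairs, read
    as "this degree applies at or beyond this cutoff in the abnormal
    direction"; cutoffs are strictly increasing and sit entirely above
    ``upper`` (high-side bands) or at/below ``lower`` (low-side bands).

    Thresholds are institution- and era-specific inputs, never constants of
    the model (the diabetic fasting-glucose cutoff itself moved from
    140 mg/dL to 126 mg/dL in 1999).
    """

    object: EntityRef
    attribute: Attribute
    unit: str
    lower: float
    upper: float
    sub_object: Optional[EntityRef] = None
    boundary: str = "neutral"  # a value exactly at a threshold is normal
    degree_bands: tuple[tuple[float, str], ...] = ()
    scale: tuple[str, str, str] = ("low", "normal", "high")

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValidationError([f"lower {self.lower} > upper {self.upper}"])
        if self.boundary not in ("neutral", "abnormal"):
            raise ValidationError([f"boundary {self.boundary!r} unknown"])
        if len(self.scale) != 3:
            raise ValidationError(["scale must have exactly 3 ordered tokens"])
        if self.degree_bands:
            cutoffs = [c for c, _ in self.degree_bands]
            if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
                raise ValidationError(["degree_bands cutoffs must strictly increase"])
            if not (cutoffs[0] >= self.upper or cutoffs[-1] <= self.lower):
                raise ValidationError(
                    ["degree_bands must lie above upper or at/below lower"]
                )
            for _, d in self.degree_bands:
                if d not in DEGREES:
                    raise ValidationError([f"degree {d!r} not in {DEGREES}"])

    @property
    def high_side(self) -> bool:
        """True when the degree bands grade the high-abnormal direction."""
        return bool(self.degree_bands) and self.degree_bands[0][0] >= self.upper

    def matches(self, state: StateDescriptor) -> bool:
        return (
            state.object.id == self.object.id
            and (state.sub_object.id if state.sub_object else None)
            == (self.sub_object.id if self.sub_object else None)
            and state.attribute is not None
            and state.attribute.name == self.attribute.name
        )


def find_spec(specs, state: StateDescriptor) -> ThresholdSpec:
    """Select the threshold spec targeting this state's object/attribute."""
    for spec in specs:
        if spec.matches(state):
            return spec
    sub = state.sub_object.id if state.sub_object else None
    raise NoThresholdError(
        f"no threshold spec for ({state.object.id}, {sub}, "
        f"{state.attribute.name if state.attribute else None})"
    )


# ---------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------

def decompose(state: StateDescriptor, rules: DecompositionRuleSet) -> StateDescriptor:
    """Rewrite a property-form state into its attribute form.

    Returns an ``OAV`` (or ``OSoAV`` when the rule names a sub-object)
    descriptor.  A property with no rule — an atomic clinical property such
    as nausea — is returned unchanged with the ``nondecomposable`` metadata
    flag set; this is a legitimate outcome, not an error.  A degree on the
    input is preserved in the output's metadata.
    """
    _check(state)
    if not state.is_property_form:
        raise ValidationError([f"decompose expects a property form, got {state.form}"])
    rule = rules.by_property(state.property_id)
    if rule is None or not state.property_value.presence:
        return replace(state, metadata={**state.metadata, "nondecomposable": True})
    meta = dict(state.metadata)
    if state.property_value.degree is not None:
        meta["degree"] = state.property_value.degree
    return StateDescriptor.attribute_state(
        object=rule.object,
        sub_object=rule.sub_object,
        attribute=rule.attribute,
        value=AttributeValue.qualitative(rule.qualitative_token, rule.value_scale()),
        **meta,
    )


def compose(
    state: StateDescriptor, rules: DecompositionRuleSet
) -> Optional[StateDescriptor]:
    """Rewrite a qualitative attribute-form state into its property form.

    Returns ``None`` when no rule names this tuple (there simply is no
    property word for it — distinct from an error).  Quantitative inputs
    must be quantized first.
    """
    _check(state)
    if not state.is_attribute_form:
        raise ValidationError([f"compose expects an attribute form, got {state.form}"])
    if state.value.kind == "quantitative":
        raise ValidationError(
            ["compose requires a qualitative value; quantize(state, spec) first"]
        )
    if state.value.kind == "categorical":
        # categorical values (viviparous/oviparous) name kinds, not
        # deviations; they do not participate in property composition
        return None
    rule = rules.by_tuple(
        state.object.id,
        state.sub_object.id if state.sub_object else None,
        state.attribute.name,
        state.value.token,
    )
    if rule is None:
        return None
    meta = {k: v for k, v in state.metadata.items() if k != "degree"}
    return StateDescriptor.property_state(
        property_id=rule.property_id,
        object=rule.object,
        presence=True,
        degree=state.metadata.get("degree"),
        **meta,
    )


def quantize(state: StateDescriptor, spec: ThresholdSpec) -> StateDescriptor:
    """Convert a quantitative attribute value to its qualitative token.

    ``magnitude > upper`` maps to the high token, ``magnitude < lower`` to
    the low token, anything else to the neutral token.  A value exactly on
    a threshold belongs to the neutral band under the default boundary
    convention (``spec.boundary == "abnormal"`` flips it outward).
    """
    _check(state)
    if not state.is_attribute_form or state.value.kind != "quantitative":
        raise ValidationError(["quantize expects a quantitative attribute form"])
    if not spec.matches(state):
        sub = state.sub_object.id if state.sub_object else None
        raise NoThresholdError(
            f"spec targets ({spec.object.id}, "
            f"{spec.sub_object.id if spec.sub_object else None}, "
            f"{spec.attribute.name}), state is ({state.object.id}, {sub}, "
            f"{state.attribute.name})"
        )
    if state.value.unit != spec.unit:
        raise UnitMismatchError(
            f"state unit {state.value.unit!r} != spec unit {spec.unit!r}"
        )
    m = state.value.magnitude
    low_tok, neutral_tok, high_tok = spec.scale
    if spec.boundary == "neutral":
        token = high_tok if m > spec.upper else low_tok if m < spec.lower else neutral_tok
    else:
        token = high_tok if m >= spec.upper else low_tok if m <= spec.lower else neutral_tok
    return replace(
        state,
        value=AttributeValue.qualitative(token, tuple(spec.scale)),
    )


def grade(
    state: StateDescriptor,
    spec: ThresholdSpec,
    rules: DecompositionRuleSet,
) -> StateDescriptor:
    """Convert a quantitative state straight to a graded property form.

    Returns the ``OPVd`` descriptor ``<object, property, degree>`` whose
    degree band contains the magnitude (the degree is the strongest cutoff
    crossed in the abnormal direction).  A magnitude that does not reach the
    graded side returns the plain property with ``presence=False`` (e.g.
    ``<hyperglycemia, false>`` in latent diabetes).
    """
    if not spec.degree_bands:
        raise DegreeBandError(
            "threshold spec has no degree_bands; use quantize() + compose()"
        )
    qual = quantize(state, spec)
    low_tok, _, high_tok = spec.scale
    abnormal_tok = high_tok if spec.high_side else low_tok
    rule = rules.by_tuple(
        state.object.id,
        state.sub_object.id if state.sub_object else None,
        state.attribute.name,
        abnormal_tok,
    )
    if rule is None:
        raise RuleConfigError(
            f"no composition rule for ({state.object.id}, {state.attribute.name}, "
            f"{abnormal_tok}); cannot name the graded property"
        )
    m = state.value.magnitude
    if qual.value.token != abnormal_tok:
        return StateDescriptor.property_state(
            property_id=rule.property_id, object=rule.object, presence=False
        )
    if spec.high_side:
        # strongest cutoff at or below the magnitude
        degree = spec.degree_bands[0][1]
        for cutoff, d in spec.degree_bands:
            if m >= cutoff:
                degree = d
    else:
        # strongest cutoff at or above the magnitude
        degree = spec.degree_bands[0][1]
        for cutoff, d in reversed(spec.degree_bands):
            if m <= cutoff:
                degree = d
    return StateDescriptor.property_state(
        property_id=rule.property_id, object=rule.object, presence=True, degree=degree
    )


def canonical_key(
    state: StateDescriptor,
    rules: DecompositionRuleSet,
    include_metadata: bool = False,
) -> tuple:
    """A normalized identity tuple, stable across form conversions.

    A property form and its rule-decomposed attribute form share the same
    key, which is what lets causal chains authored in different vocabularies
    be unified.  Open metadata is ignored unless ``include_metadata``.
    """
    _check(state)
    if state.is_property_form:
        rule = rules.by_property(state.property_id)
        if rule is not None:
            key = rule.key
        else:
            key = (state.object.id,
                   state.sub_object.id if state.sub_object else None,
                   state.property_id,
                   None)
    else:
        key = (
            state.object.id,
            state.sub_object.id if state.sub_object else None,
            state.attribute.name,
            state.value.token if state.value else None,
        )
    if include_metadata:
        extra = tuple(sorted(
            (k, v) for k, v in state.metadata.items()
            if k not in ("nondecomposable", "degree")
        ))
        key = key + (extra,)
    return key


def descriptor_to_dict(state: StateDescriptor) -> dict:
    """Plain-dict serialization (JSON-ready) of a descriptor."""
    d = dataclasses.asdict(state)
    return {k: v for k, v in d.items() if v not in (None, {}, ())}
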