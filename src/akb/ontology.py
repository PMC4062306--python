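"""Three-level is-a taxonomy of abnormal-state classes.

Level 1 holds generic, object-independent states ("small in area",
"hypofunction") under three top categories: structural, functional and
other (parametric) abnormalities.  Level 2 binds a state to an object —
first to generic structures ("narrowing tube" on tubular structures), then
to specific anatomy ("coronary artery stenosis").  Level 3 binds a level-2
state to a disease context ("coronary artery stenosis in angina pectoris").

The taxonomy answers subsumption (:meth:`Taxonomy.is_subclass`),
least-common-subsumer (:meth:`Taxonomy.lcs`) and level-abstraction
(:meth:`Taxonomy.abstract_to_level`) queries; these underpin both the
causal-chain is-a inference and the cross-department commonality analysis.

By default each class asserts a single is-a parent (multiple inheritance
invites tangled hierarchies; the tie-breaks below make the multi-parent
mode deterministic anyway).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .errors import CycleError, UnknownClassError, ValidationError
from .model import EntityRef

CATEGORIES = ("structural", "functional", "other")

ROOT_ID = "abnormal_state"


@dataclass(frozen=True)
class Binding:
    """What a class is bound to: an object (level 2) or a disease (level 3)."""

    object: Optional[EntityRef] = None
    disease_context: Optional[str] = None


@dataclass(frozen=True)
class StateTemplate:
    """The defining attribute/token of a class, e.g. (area, small)."""

    attribute: str
    token: str


@dataclass(frozen=True)
class AbnormalStateClass:
    id: str
    label: str = ""
    level: int = 1
    parents: tuple[str, ...] = ()
    category: Optional[str] = None
    binding: Binding = field(default_factory=Binding)
    definition: Optional[StateTemplate] = None

    def __post_init__(self):
        if not self.label:
            object.__setattr__(self, "label", self.id.replace("_", " "))

    def violations(self) -> list[str]:
        out = []
        if not self.id:
            out.append("class id must be non-empty")
        if self.level not in (1, 2, 3):
            out.append(f"level must be 1, 2 or 3, got {self.level}")
        if self.category is not None and self.category not in CATEGORIES:
            out.append(f"category {self.category!r} not in {CATEGORIES}")
        if self.level == 2 and self.binding.object is None:
            out.append(f"level-2 class {self.id!r} requires binding.object")
        if self.level == 3 and self.binding.disease_context is None:
            out.append(f"level-3 class {self.id!r} requires binding.disease_context")
        return out


class Taxonomy:
    """The is-a DAG over :class:`AbnormalStateClass` nodes.

    Internally a :class:`networkx.DiGraph` with child -> parent edges, so
    reachability *is* subsumption.
    """

    def __init__(self, allow_multiple_parents: bool = False):
        self.allow_multiple_parents = allow_multiple_parents
        self.classes: dict[str, AbnormalStateClass] = {}
        self._g = nx.DiGraph()  # edges: child -> parent
        self._depth: dict[str, int] = {}

    # -- basic container protocol -------------------------------------
    def __contains__(self, class_id: str) -> bool:
        return class_id in self.classes

    def __len__(self) -> int:
        return len(self.classes)

    def __iter__(self):
        return iter(self.classes.values())

    def __getitem__(self, class_id: str) -> AbnormalStateClass:
        try:
            return self.classes[class_id]
        except KeyError:
            raise UnknownClassError(class_id) from None

    def _require(self, class_id: str) -> AbnormalStateClass:
        return self[class_id]

    # -- construction --------------------------------------------------
    def add_class(self, cls: AbnormalStateClass) -> "Taxonomy":
        """Insert a class, enforcing all taxonomy invariants."""
        v = cls.violations()
        if cls.id in self.classes:
            v.append(f"duplicate class id {cls.id!r}")
        if not self.allow_multiple_parents and len(cls.parents) > 1:
            v.append(
                f"class {cls.id!r} asserts {len(cls.parents)} parents; "
                "single-parent mode is in force"
            )
        for p in cls.parents:
            if p == cls.id:
                raise CycleError(f"class {cls.id!r} is its own parent", [cls.id, cls.id])
            if p not in self.classes:
                v.append(f"unknown parent {p!r} of {cls.id!r}")
            elif self.classes[p].level > cls.level:
                v.append(
                    f"parent {p!r} (level {self.classes[p].level}) above "
                    f"child {cls.id!r} (level {cls.level}) violates level ordering"
                )
        if not v and cls.level == 3:
            if not any(self.classes[p].level == 2 for p in cls.parents):
                v.append(
                    f"level-3 class {cls.id!r} must refer to a level-2 parent"
                )
        if v:
            raise ValidationError(v)
        # parents already exist and the new node has no children yet, so a
        # cycle through cls is impossible; assert anyway for multi-parent mode
        self.classes[cls.id] = cls
        self._g.add_node(cls.id)
        for p in cls.parents:
            self._g.add_edge(cls.id, p)
        if not nx.is_directed_acyclic_graph(self._g):
            cyc = nx.find_cycle(self._g)
            del self.classes[cls.id]
            self._g.remove_node(cls.id)
            raise CycleError(f"inserting {cls.id!r} creates a cycle", [a for a, _ in cyc])
        self._depth.clear()  # invalidate closure caches
        return self

    def specialize(
        self,
        parent_id: str,
        *,
        object: Optional[EntityRef] = None,
        disease_context: Optional[str] = None,
        id: Optional[str] = None,
        label: Optional[str] = None,
        definition: Optional[StateTemplate] = None,
    ) -> AbnormalStateClass:
        """Create and insert a child by binding the parent to a context.

        Binding an object yields a (lower-)level-2 class; binding a disease
        context yields a level-3 class and requires a level-2 parent (a
        generic level-1 state cannot jump straight into a disease context).
        The child inherits the parent's defining attribute/token template.
        """
        parent = self._require(parent_id)
        if (object is None) == (disease_context is None):
            raise ValidationError(
                ["specialize requires exactly one of object / disease_context"]
            )
        if disease_context is not None:
            if parent.level < 2:
                raise ValidationError(
                    [
                        f"disease-context binding on level-{parent.level} parent "
                        f"{parent_id!r}: specialize through level 2 first"
                    ]
                )
            level = 3
            binding = Binding(disease_context=disease_context)
            default_label = f"{parent.label} in {disease_context.replace('_', ' ')}"
            default_id = f"{parent.id}_in_{disease_context}"
        else:
            level = 2
            binding = Binding(object=object)
            default_label = f"{parent.label} of {object.label}"
            default_id = f"{parent.id}_of_{object.id}"
        cls = AbnormalStateClass(
            id=id or default_id,
            label=label or default_label,
            level=level,
            parents=(parent_id,),
            category=parent.category,
            binding=binding,
            definition=definition or parent.definition,
        )
        self.add_class(cls)
        return cls

    # -- queries --------------------------------------------------------
    def is_subclass(self, a_id: str, b_id: str) -> bool:
        """True iff ``a`` is-a ``b`` (reflexive-transitive closure)."""
        self._require(a_id)
        self._require(b_id)
        return a_id == b_id or nx.has_path(self._g, a_id, b_id)

    def ancestors(self, class_id: str, include_self: bool = True) -> set[str]:
        self._require(class_id)
        anc = nx.descendants(self._g, class_id)  # child->parent edges
        if include_self:
            anc = anc | {class_id}
        return anc

    def descendants(self, class_id: str, include_self: bool = True) -> set[str]:
        self._require(class_id)
        des = nx.ancestors(self._g, class_id)
        if include_self:
            des = des | {class_id}
        return des

    def depth(self, class_id: str) -> int:
        """Longest root path; roots have depth 0."""
        if not self._depth:
            for node in nx.topological_sort(self._g.reverse(copy=False)):
                parents = list(self._g.successors(node))
                self._depth[node] = (
                    0 if not parents else 1 + max(self._depth[p] for p in parents)
                )
        self._require(class_id)
        return self._depth[class_id]

    def roots(self) -> list[str]:
        return sorted(n for n in self._g if self._g.out_degree(n) == 0)

    def top_categories(self) -> set[str]:
        """Direct children of the root(s): the coarse category classes."""
        roots = set(self.roots())
        return {c.id for c in self if set(c.parents) & roots}

    def lcs(self, a_id: str, b_id: str) -> str:
        """Least common subsumer: the deepest shared ancestor.

        Depth is the longest root path (prefers the most specific shared
        concept); ties break on the smallest id for determinism.  With a
        single root the answer always exists.
        """
        common = self.ancestors(a_id) & self.ancestors(b_id)
        if not common:
            raise UnknownClassError(f"no common ancestor of {a_id!r} and {b_id!r}")
        return min(common, key=lambda c: (-self.depth(c), c))

    def abstract_to_level(
        self, class_id: str, level: int, strategy: str = "nearest"
    ) -> Optional[str]:
        """The ancestor of ``class_id`` at the requested level (1 or 2).

        ``strategy="nearest"`` (default) returns the deepest such ancestor —
        e.g. a disease-bound "coronary artery stenosis in IHD" abstracts to
        the organ-level "coronary artery stenosis".  ``strategy="generic"``
        returns the shallowest one — the same class abstracts to the
        generic-structure "narrowing tube".  Identity if the class is
        already at the level; ``None`` when no ancestor has it ("no
        abstraction" outcome).
        """
        if level not in (1, 2):
            raise ValidationError([f"abstraction level must be 1 or 2, got {level}"])
        if strategy not in ("nearest", "generic"):
            raise ValidationError([f"unknown abstraction strategy {strategy!r}"])
        cls = self._require(class_id)
        if cls.level == level:
            return class_id
        candidates = [
            a for a in self.ancestors(class_id, include_self=False)
            if self.classes[a].level == level
        ]
        if not candidates:
            return None
        if strategy == "nearest":
            return min(candidates, key=lambda c: (-self.depth(c), c))
        return min(candidates, key=lambda c: (self.depth(c), c))

    # -- views -----------------------------------------------------------
    def isa_graph(self) -> nx.DiGraph:
        """A copy of the is-a DAG with parent -> child edge direction."""
        return self._g.reverse(copy=True)

    def add_classes(self, classes: Iterable[AbnormalStateClass]) -> "Taxonomy":
        for c in classes:
            self.add_class(c)
        return self


# ---------------------------------------------------------------------
# Published skeleton
# ---------------------------------------------------------------------

def build_seed_taxonomy() -> Taxonomy:
    """The published top-level skeleton plus the worked lineages.

    Level 1: root; structural (material / shape / size / conformational,
    the last covering topological abnormalities and structural defects);
    functional (hyperfunction; malfunction subdivided into dysfunction,
    function arrest and hypofunction); other (parametric increase /
    decrease).  On top of it, the stenosis lineage ("small in area" ->
    "narrowing tube" -> vascular/arterial/organ-specific stenoses) and the
    hyperglycemia lineage used throughout the worked examples.
    """
    t = Taxonomy()
    C = AbnormalStateClass

    t.add_class(C(id=ROOT_ID, label="abnormal state", level=1))
    for cid, cat in (
        ("structural_abnormality", "structural"),
        ("functional_abnormality", "functional"),
        ("other_abnormality", "other"),
    ):
        t.add_class(C(id=cid, level=1, parents=(ROOT_ID,), category=cat))

    structural = dict(level=1, category="structural")
    t.add_classes([
        C(id="material_abnormality", parents=("structural_abnormality",), **structural),
        C(id="shape_abnormality", parents=("structural_abnormality",), **structural),
        C(id="size_abnormality", parents=("structural_abnormality",), **structural),
        C(id="conformational_abnormality", parents=("structural_abnormality",), **structural),
        C(id="topological_abnormality", parents=("conformational_abnormality",), **structural),
        C(id="structural_defect", parents=("conformational_abnormality",), **structural),
        C(id="small_in_area", parents=("size_abnormality",),
          definition=StateTemplate("area", "small"), **structural),
    ])

    functional = dict(level=1, category="functional")
    t.add_classes([
        C(id="hyperfunction", parents=("functional_abnormality",), **functional),
        C(id="malfunction", parents=("functional_abnormality",), **functional),
        C(id="dysfunction", parents=("malfunction",), **functional),
        C(id="function_arrest", parents=("malfunction",), **functional),
        C(id="hypofunction", parents=("malfunction",), **functional),
    ])

    other = dict(level=1, category="other")
    t.add_classes([
        C(id="parametric_abnormality", parents=("other_abnormality",), **other),
        C(id="increased_parameter", parents=("parametric_abnormality",), **other),
        C(id="decreased_parameter", parents=("parametric_abnormality",), **other),
    ])

    # --- stenosis lineage (levels 1 -> 2) ---
    tube = EntityRef("tubular_structure", kind="generic-structure")
    valve = EntityRef("valve_structure", kind="generic-structure")
    t.specialize("small_in_area", object=tube, id="narrowing_tube",
                 label="narrowing tube",
                 definition=StateTemplate("cross-sectional-area", "small"))
    t.specialize("small_in_area", object=valve, id="narrowing_valve",
                 label="narrowing valve")
    # within a level-2 lineage the template re-targets to the tube section
    for cid, parent, obj, label in [
        ("vascular_stenosis", "narrowing_tube",
         EntityRef("blood_vessel"), "vascular stenosis"),
        ("arterial_stenosis", "vascular_stenosis",
         EntityRef("artery"), "arterial stenosis"),
        ("coronary_artery_stenosis", "arterial_stenosis",
         EntityRef("coronary_artery"), "coronary artery stenosis"),
        ("pulmonary_artery_stenosis", "arterial_stenosis",
         EntityRef("pulmonary_artery"), "pulmonary artery stenosis"),
        ("cerebrovascular_stenosis", "vascular_stenosis",
         EntityRef("cerebral_vessel"), "cerebrovascular stenosis"),
        ("intestinal_stenosis", "narrowing_tube",
         EntityRef("intestine"), "intestinal stenosis"),
        ("esophagostenosis", "narrowing_tube",
         EntityRef("esophagus"), "esophagostenosis"),
        ("tracheal_stenosis", "narrowing_tube",
         EntityRef("trachea"), "tracheal stenosis"),
        ("rectal_stenosis", "narrowing_tube",
         EntityRef("rectum"), "rectal stenosis"),
    ]:
        t.specialize(parent, object=obj, id=cid, label=label)

    # --- hyperglycemia lineage ---
    t.specialize("increased_parameter", object=EntityRef("blood", kind="substance"),
                 id="hyperglycemia", label="hyperglycemia")

    # --- disease-context example (level 3) ---
    t.specialize("coronary_artery_stenosis", disease_context="angina_pectoris",
                 id="coronary_artery_stenosis_in_angina_pectoris",
                 label="coronary artery stenosis in angina pectoris")
    return t
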