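"""Quantifying commonality of abnormal states across departments.

Clinicians treat abnormal states disease-by-disease inside one medical
division, which hides the fact that "coronary artery stenosis" (cardiology),
"pulmonary artery stenosis" (tetralogy of Fallot) and "intestinal stenosis"
(ileus) are all specializations of the same narrowing-tube state.  The
taxonomy makes this computable: the least common subsumer of two states
says *what* they share, and abstracting each department's state set to a
chosen level lets the overlap between departments be measured.

The degree of commonality between two departments is reported as the
Jaccard index of their abstracted state sets; raw shared counts are always
reported alongside, so the metric choice is non-binding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .chains import DiseaseDefinition
from .ontology import Taxonomy


@dataclass(frozen=True)
class CommonalityRecord:
    """The shared ancestry of two abnormal states."""

    state_a: str
    state_b: str
    lcs_class: str
    lcs_level: int
    shared: bool


def state_commonality(tax: Taxonomy, a: str, b: str) -> CommonalityRecord:
    """LCS of two states, with ``shared=False`` when the only thing they
    have in common is a top category (structural/functional/other) or the
    root itself — i.e. no substantive commonality."""
    lcs = tax.lcs(a, b)
    trivial = set(tax.roots()) | tax.top_categories()
    return CommonalityRecord(
        state_a=a,
        state_b=b,
        lcs_class=lcs,
        lcs_level=tax[lcs].level,
        shared=lcs not in trivial,
    )


def department_states(diseases: list[DiseaseDefinition]) -> dict[str, set[str]]:
    """All abnormal-state classes appearing in each department's chains."""
    out: dict[str, set[str]] = {}
    for d in diseases:
        out.setdefault(d.department, set()).update(d.chain.nodes)
    return out


def _abstract_sets(
    diseases: list[DiseaseDefinition],
    tax: Taxonomy,
    level: int,
    strategy: str,
) -> tuple[dict[str, set[str]], dict[str, int]]:
    """Per-department abstracted state sets plus a count of states that
    failed to abstract (coverage diagnostic)."""
    abstracted: dict[str, set[str]] = {}
    dropped: dict[str, int] = {}
    for dept, states in sorted(department_states(diseases).items()):
        img = set()
        miss = 0
        for s in sorted(states):
            a = tax.abstract_to_level(s, level, strategy=strategy)
            if a is None:
                miss += 1
            else:
                img.add(a)
        abstracted[dept] = img
        dropped[dept] = miss
    return abstracted, dropped


@dataclass
class CommonalityMatrix:
    """Department x department commonality at one abstraction level."""

    level: int
    jaccard: pd.DataFrame
    shared_counts: pd.DataFrame
    dropped: dict[str, int]

    def to_csv(self, path) -> None:
        self.jaccard.to_csv(path)


def commonality_matrix(
    diseases: list[DiseaseDefinition],
    tax: Taxonomy,
    level: int,
    strategy: str = "nearest",
) -> CommonalityMatrix:
    """Pairwise Jaccard overlap of abstracted state sets per department.

    A department whose abstracted set is empty yields NaN entries
    (undefined, deliberately distinct from 0).  The diagonal is 1.
    """
    abstracted, dropped = _abstract_sets(diseases, tax, level, strategy)
    depts = sorted(abstracted)
    jac = pd.DataFrame(index=depts, columns=depts, dtype=float)
    cnt = pd.DataFrame(0, index=depts, columns=depts, dtype=int)
    for a in depts:
        for b in depts:
            sa, sb = abstracted[a], abstracted[b]
            inter = len(sa & sb)
            union = len(sa | sb)
            cnt.loc[a, b] = inter
            if not sa or not sb:
                jac.loc[a, b] = float("nan")
            elif a == b:
                jac.loc[a, b] = 1.0
            else:
                jac.loc[a, b] = inter / union
    return CommonalityMatrix(level=level, jaccard=jac, shared_counts=cnt,
                             dropped=dropped)


@dataclass(frozen=True)
class SpecificityRecord:
    """A state (abstracted) confined to a single department."""

    state: str
    department: str
    n_diseases: int


def specificity_report(
    diseases: list[DiseaseDefinition],
    tax: Taxonomy,
    level: int,
    strategy: str = "nearest",
) -> list[SpecificityRecord]:
    """States whose abstraction occurs in exactly one department.

    E.g. esophagostenosis shows no commonality outside gastroenterology,
    flagging it as specific to esophageal disease.  Ranked by how many
    diseases of that department carry the state (a per-state prevalence),
    then by state id.
    """
    occupancy: dict[str, set[str]] = {}       # abstracted state -> departments
    prevalence: dict[str, set[str]] = {}      # abstracted state -> diseases
    for d in diseases:
        for s in d.chain.nodes:
            a = tax.abstract_to_level(s, level, strategy=strategy)
            if a is None:
                continue
            occupancy.setdefault(a, set()).add(d.department)
            prevalence.setdefault(a, set()).add(d.id)
    out = [
        SpecificityRecord(state=s, department=next(iter(depts)),
                          n_diseases=len(prevalence[s]))
        for s, depts in occupancy.items()
        if len(depts) == 1
    ]
    return sorted(out, key=lambda r: (-r.n_diseases, r.state))


def specificity_frame(records: list[SpecificityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.state, r.department, r.n_diseases) for r in records],
        columns=["state", "department", "n_diseases"],
    )
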