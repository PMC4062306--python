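"""Diseases as causal chains of abnormal states.

A (mechanistically understood) disease is defined by a directed acyclic
graph whose nodes are abnormal-state classes and whose edges are causal
links, e.g. ``coronary artery stenosis -> myocardial ischemia`` for
ischemic heart disease.  On top of that representation this module
implements:

* **chain inclusion** — an injective embedding of one chain into another in
  which each node maps to a subclass-or-equal state and each causal link
  maps to a single edge (``mode="edge"``) or to a directed path
  (``mode="path"``, the default: a specialized disease may interpose
  intermediate states on a causal link);
* **disease is-a** — disease A subsumes disease B when every maximal causal
  chain of A embeds into B's chain graph;
* **core vs. derived chains** — the core chain is the part shared by (i.e.
  embeddable into) all subclass diseases; derived chains are additional
  possible causes/effects such as smoking upstream of a coronary spasm.
  Cores are both *asserted* by authors and *computed* by intersection, and
  the two can be compared;
* **cross-department merging** — the union of many diseases' chains with
  states unified by identity or by level-2 abstraction, yielding generic
  causal chains that span departments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .errors import CycleError, UnknownClassError, ValidationError
from .ontology import Taxonomy

Edge = tuple[str, str]


class CausalChainGraph:
    """A DAG of abnormal-state class ids with cause -> effect edges.

    Merged cross-department graphs are unions of DAGs and may legitimately
    contain cycles; such graphs are constructed with ``allow_cycles=True``
    and flagged via :attr:`has_cycles`.
    """

    def __init__(self, nodes=(), edges=(), allow_cycles: bool = False):
        self._g = nx.DiGraph()
        self.allow_cycles = allow_cycles
        for n in nodes:
            self._g.add_node(n)
        for e in edges:
            self.add_edge(*e)
        self._assert_acyclic()

    def _assert_acyclic(self):
        if not self.allow_cycles and not nx.is_directed_acyclic_graph(self._g):
            cyc = [a for a, _ in nx.find_cycle(self._g)]
            raise CycleError(f"causal chain contains a cycle: {cyc}", cyc)

    # -- construction ---------------------------------------------------
    def add_node(self, node: str) -> None:
        self._g.add_node(node)

    def add_edge(self, cause: str, effect: str, **provenance) -> None:
        if cause == effect:
            raise CycleError(f"self-loop causal link on {cause!r}", [cause, cause])
        if self._g.has_edge(cause, effect):
            prov = self._g.edges[cause, effect].setdefault("provenance", [])
            prov.extend(
                p for p in provenance.pop("provenance", []) if p not in prov
            )
        else:
            self._g.add_edge(cause, effect, provenance=provenance.pop("provenance", []))
        if provenance:
            self._g.edges[cause, effect].update(provenance)
        self._assert_acyclic()

    # -- views ------------------------------------------------------------
    @property
    def graph(self) -> nx.DiGraph:
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> set[Edge]:
        return set(self._g.edges)

    @property
    def has_cycles(self) -> bool:
        return not nx.is_directed_acyclic_graph(self._g)

    def provenance(self, cause: str, effect: str) -> list:
        return list(self._g.edges[cause, effect].get("provenance", []))

    def is_empty(self) -> bool:
        return self._g.number_of_nodes() == 0

    def __eq__(self, other):
        return (
            isinstance(other, CausalChainGraph)
            and self.nodes == other.nodes
            and self.edges == other.edges
        )

    def __repr__(self):
        return f"CausalChainGraph({sorted(self.nodes)}, {sorted(self.edges)})"

    def subgraph_from_edges(self, edges: Iterable[Edge]) -> "CausalChainGraph":
        """The subgraph spanned by ``edges`` (isolated nodes pruned)."""
        edges = list(edges)
        nodes = {n for e in edges for n in e}
        return CausalChainGraph(nodes=nodes, edges=edges)

    def maximal_paths(self) -> list[tuple[str, ...]]:
        """All maximal directed paths (source to sink; isolated nodes as
        singleton paths).  These are "the causal chains" of the disease."""
        if self.has_cycles:
            raise CycleError("maximal paths undefined on a cyclic graph")
        sources = [n for n in sorted(self._g) if self._g.in_degree(n) == 0]
        out: list[tuple[str, ...]] = []
        for s in sources:
            if self._g.out_degree(s) == 0:
                out.append((s,))
                continue
            sinks = [n for n in sorted(self._g) if self._g.out_degree(n) == 0]
            for t in sinks:
                for p in nx.all_simple_paths(self._g, s, t):
                    out.append(tuple(p))
        return sorted(out)

    @staticmethod
    def from_path(path: Iterable[str]) -> "CausalChainGraph":
        path = list(path)
        return CausalChainGraph(nodes=path, edges=list(zip(path, path[1:])))


@dataclass
class DiseaseDefinition:
    """A disease: its causal-chain DAG plus the asserted core edges."""

    id: str
    label: str
    department: str
    chain: CausalChainGraph
    core_edges: frozenset[Edge] = frozenset()

    @property
    def derived_edges(self) -> frozenset[Edge]:
        return frozenset(self.chain.edges - self.core_edges)

    def core_chain(self) -> CausalChainGraph:
        return self.chain.subgraph_from_edges(self.core_edges)

    def derived_chain(self) -> CausalChainGraph:
        return self.chain.subgraph_from_edges(self.derived_edges)


@dataclass(frozen=True)
class ChainMapping:
    """A witness that one chain embeds into another.

    ``node_map`` is injective; ``edge_map`` sends every causal link of the
    smaller chain to the directed path realizing it in the larger chain.
    """

    node_map: dict[str, str] = field(default_factory=dict)
    edge_map: dict[Edge, tuple[str, ...]] = field(default_factory=dict)

    def is_valid(self, small: CausalChainGraph, large: CausalChainGraph,
                 tax: Taxonomy) -> bool:
        """Check the witness against the two chains and the taxonomy."""
        if set(self.node_map) != small.nodes:
            return False
        images = list(self.node_map.values())
        if len(set(images)) != len(images):
            return False
        if not set(images) <= large.nodes:
            return False
        for n, m in self.node_map.items():
            if not tax.is_subclass(m, n):  # image specializes the general node
                return False
        for (a, b) in small.edges:
            path = self.edge_map.get((a, b))
            if not path or path[0] != self.node_map[a] or path[-1] != self.node_map[b]:
                return False
            if len(path) < 2:
                return False
            if any(not large.graph.has_edge(u, v) for u, v in zip(path, path[1:])):
                return False
        return True


def build_disease(
    id: str,
    label: str,
    department: str,
    states: Iterable[str],
    causal_links: Iterable[Edge],
    core_flags: Iterable[Edge],
    tax: Taxonomy,
) -> DiseaseDefinition:
    """Construct and validate a disease definition against the taxonomy."""
    states = list(states)
    causal_links = [tuple(e) for e in causal_links]
    core = frozenset(tuple(e) for e in core_flags)
    unknown = [s for s in states if s not in tax]
    if unknown:
        raise UnknownClassError(f"states not in taxonomy: {sorted(unknown)}")
    bad_links = [e for e in causal_links if e[0] not in states or e[1] not in states]
    if bad_links:
        raise ValidationError(
            [f"causal link {e} references a state not listed for {id!r}"
             for e in bad_links]
        )
    if not core <= set(causal_links):
        extra = sorted(core - set(causal_links))
        raise ValidationError([f"core edges not in chain: {extra}"])
    chain = CausalChainGraph(nodes=states, edges=causal_links)
    return DiseaseDefinition(
        id=id, label=label, department=department, chain=chain, core_edges=core
    )


# ---------------------------------------------------------------------
# Chain inclusion
# ---------------------------------------------------------------------

def _candidates(node: str, large: CausalChainGraph, tax: Taxonomy) -> list[str]:
    return sorted(m for m in large.nodes if tax.is_subclass(m, node))


def _edges_ok(small, large, assignment, mode):
    for (a, b) in small.edges:
        fa, fb = assignment.get(a), assignment.get(b)
        if fa is None or fb is None:
            continue  # not yet assigned
        if mode == "edge":
            if not large.graph.has_edge(fa, fb):
                return False
        else:
            if fa == fb or not nx.has_path(large.graph, fa, fb):
                return False
    return True


def chain_included(
    small: CausalChainGraph,
    large: CausalChainGraph,
    tax: Taxonomy,
    mode: str = "path",
) -> Optional[ChainMapping]:
    """Search for an embedding of ``small`` into ``large``.

    Backtracking over candidate node images, most-constrained node first.
    Returns a :class:`ChainMapping` witness, or ``None`` when no embedding
    exists.  The empty chain embeds trivially into anything.
    """
    if mode not in ("edge", "path"):
        raise ValidationError([f"unknown inclusion mode {mode!r}"])
    if small.has_cycles or large.has_cycles:
        raise CycleError("chain inclusion requires acyclic inputs")
    cand = {n: _candidates(n, large, tax) for n in small.nodes}
    order = sorted(small.nodes, key=lambda n: (len(cand[n]), n))
    assignment: dict[str, str] = {}
    used: set[str] = set()

    def backtrack(i: int) -> bool:
        if i == len(order):
            return True
        n = order[i]
        for m in cand[n]:
            if m in used:
                continue
            assignment[n] = m
            used.add(m)
            if _edges_ok(small, large, assignment, mode):
                if backtrack(i + 1):
                    return True
            del assignment[n]
            used.discard(m)
        return False

    if not backtrack(0):
        return None
    edge_map = {}
    for (a, b) in small.edges:
        fa, fb = assignment[a], assignment[b]
        if mode == "edge":
            edge_map[(a, b)] = (fa, fb)
        else:
            edge_map[(a, b)] = tuple(nx.shortest_path(large.graph, fa, fb))
    return ChainMapping(node_map=dict(assignment), edge_map=edge_map)


def chain_included_bruteforce(
    small: CausalChainGraph,
    large: CausalChainGraph,
    tax: Taxonomy,
    mode: str = "path",
) -> Optional[ChainMapping]:
    """Oracle: enumerate every injective node map.  Exponential; only for
    cross-checking the backtracking matcher on small instances."""
    if small.has_cycles or large.has_cycles:
        raise CycleError("chain inclusion requires acyclic inputs")
    small_nodes = sorted(small.nodes)
    if not small_nodes:
        return ChainMapping()
    for images in itertools.permutations(sorted(large.nodes), len(small_nodes)):
        assignment = dict(zip(small_nodes, images))
        if any(not tax.is_subclass(m, n) for n, m in assignment.items()):
            continue
        if not _edges_ok(small, large, assignment, mode):
            continue
        edge_map = {
            (a, b): (
                (assignment[a], assignment[b]) if mode == "edge"
                else tuple(nx.shortest_path(large.graph, assignment[a], assignment[b]))
            )
            for (a, b) in small.edges
        }
        return ChainMapping(node_map=assignment, edge_map=edge_map)
    return None


# ---------------------------------------------------------------------
# Disease is-a and hierarchy
# ---------------------------------------------------------------------

def _scope_graph(d: DiseaseDefinition, scope: str) -> CausalChainGraph:
    if scope == "core":
        return d.core_chain() if d.core_edges else d.chain
    if scope == "full":
        return d.chain
    raise ValidationError([f"unknown scope {scope!r}"])


def disease_is_a(
    A: DiseaseDefinition,
    B: DiseaseDefinition,
    tax: Taxonomy,
    scope: str = "core",
    mode: str = "path",
) -> bool:
    """True iff A is a superclass of B: every maximal causal chain of A
    (its core chain by default) embeds into B's chain graph."""
    g = _scope_graph(A, scope)
    for path in g.maximal_paths():
        if chain_included(CausalChainGraph.from_path(path), B.chain, tax, mode) is None:
            return False
    return True


@dataclass
class HierarchyResult:
    """Inferred disease hierarchy: a transitively reduced is-a DAG
    (edges point superclass -> subclass, between equivalence-group
    representatives) plus any groups of mutually-including diseases."""

    graph: nx.DiGraph
    equivalence_groups: list[frozenset[str]]

    @property
    def edges(self) -> set[Edge]:
        return set(self.graph.edges)


def infer_hierarchy(
    diseases: list[DiseaseDefinition],
    tax: Taxonomy,
    scope: str = "core",
    mode: str = "path",
) -> HierarchyResult:
    ids = [d.id for d in diseases]
    rel = {
        (a.id, b.id)
        for a in diseases for b in diseases
        if a.id != b.id and disease_is_a(a, b, tax, scope, mode)
    }
    mutual = {frozenset((a, b)) for (a, b) in rel if (b, a) in rel}
    # union-find over mutual pairs -> equivalence groups
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for pair in mutual:
        a, b = sorted(pair)
        parent[find(b)] = find(a)
    groups: dict[str, set[str]] = {}
    for i in ids:
        groups.setdefault(find(i), set()).add(i)
    rep = {i: min(groups[find(i)]) for i in ids}
    eq_groups = sorted(
        (frozenset(g) for g in groups.values() if len(g) > 1), key=sorted
    )

    quotient = nx.DiGraph()
    quotient.add_nodes_from(sorted(set(rep.values())))
    for (a, b) in rel:
        ra, rb = rep[a], rep[b]
        if ra != rb:
            quotient.add_edge(ra, rb)
    reduced = nx.transitive_reduction(quotient)
    graph = nx.DiGraph()
    graph.add_nodes_from(ids)
    graph.add_edges_from(reduced.edges)
    return HierarchyResult(graph=graph, equivalence_groups=eq_groups)


# ---------------------------------------------------------------------
# Core chains
# ---------------------------------------------------------------------

def compute_core_chain(
    disease: DiseaseDefinition,
    subclasses: list[DiseaseDefinition],
    tax: Taxonomy,
    mode: str = "path",
) -> CausalChainGraph:
    """The maximal part of ``disease``'s chain shared with every subclass.

    With no subclasses the intersection is vacuous and the asserted core is
    returned.  Otherwise edges whose single-link chain fails to embed into
    some subclass are removed (then isolated nodes pruned), and removal is
    iterated until every remaining maximal path embeds everywhere.  An
    empty result is the explicit "no common core" outcome
    (:meth:`CausalChainGraph.is_empty`).
    """
    if not subclasses:
        return disease.core_chain()
    edges = set(disease.chain.edges)
    edges = {
        e for e in edges
        if all(
            chain_included(CausalChainGraph.from_path(e), s.chain, tax, mode)
            is not None
            for s in subclasses
        )
    }
    # per-edge embeddability does not guarantee whole-path embeddability
    # (injectivity can bind); prune until stable
    while True:
        g = disease.chain.subgraph_from_edges(edges)
        bad = set()
        for path in g.maximal_paths():
            for s in subclasses:
                if chain_included(CausalChainGraph.from_path(path), s.chain,
                                  tax, mode) is None:
                    bad.update(zip(path, path[1:]))
                    break
        if not bad:
            return g
        edges -= bad


def validate_core(
    disease: DiseaseDefinition,
    subclasses: list[DiseaseDefinition],
    tax: Taxonomy,
    mode: str = "path",
) -> bool:
    """Does the asserted core embed into every subclass's chain?"""
    core = disease.core_chain()
    return all(
        chain_included(CausalChainGraph.from_path(p), s.chain, tax, mode) is not None
        for p in core.maximal_paths()
        for s in subclasses
    )


def classify_chain_parts(
    disease: DiseaseDefinition,
) -> tuple[CausalChainGraph, CausalChainGraph]:
    """Partition a disease's chain into (core, derived) subgraphs."""
    return disease.core_chain(), disease.derived_chain()


# ---------------------------------------------------------------------
# Cross-department merging
# ---------------------------------------------------------------------

def merge_generic(
    diseases: list[DiseaseDefinition],
    tax: Taxonomy,
    unify_level: Optional[int] = None,
) -> CausalChainGraph:
    """Union of many diseases' chains into one generic causal-chain graph.

    Nodes are unified by class id, or — when ``unify_level=2`` — by their
    nearest level-2 ancestor, so that e.g. "coronary artery stenosis in
    IHD" (cardiology) and the same stenosis in hyperlipidemia (metabolic
    medicine) become one node.  States with no ancestor at the requested
    level keep their own id.  Edges carry ``(disease id, department)``
    provenance.  The union of DAGs need not be acyclic; the result is
    flagged via :attr:`CausalChainGraph.has_cycles`.
    """

    def unify(node: str) -> str:
        if unify_level is None:
            return node
        return tax.abstract_to_level(node, unify_level) or node

    merged = CausalChainGraph(allow_cycles=True)
    for d in diseases:
        for n in sorted(d.chain.nodes):
            merged.add_node(unify(n))
        for (a, b) in sorted(d.chain.edges):
            ua, ub = unify(a), unify(b)
            if ua == ub:
                continue  # unification collapsed a link onto one node
            merged.add_edge(ua, ub, provenance=[(d.id, d.department)])
    return merged
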