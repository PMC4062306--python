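"""Seeded synthetic taxonomies and disease families with planted ground truth.

The generator builds a random taxonomy tree (level 1 at the top, object-
bound level 2 below) and plants disease families by *refinement*: each
family starts from a root disease with a random core chain, and every
subclass disease applies inclusion-preserving refinement operations to its
parent's chain:

* insert an intermediate state on a causal link (edge -> path),
* append a fresh upstream cause,
* specialize a state to one of its taxonomy subclasses.

Each operation preserves chain inclusion *by construction*, so the planted
refinement forest is the ground-truth disease hierarchy without ever
running the matcher — which is exactly what makes it a fair recovery test
for the matcher.

Two design constraints keep the ground truth exact rather than merely
expected:

* every subclass applies at least one refinement, and refinements only use
  classes *incomparable* to everything already used in the family (fresh
  draws) or strict subclasses of the node being specialized — so no two
  sibling branches can accidentally include one another;
* families draw from disjoint subtrees of the taxonomy, so diseases in
  different families share no subsumption-compatible states at all.

Synthetic chains are all-core: upstream extensions are planted as core
edges, because derived (optional) edges are invisible to the core-scope
is-a test and would collapse siblings into spurious equivalence groups.
Node labels are opaque ids; no medical plausibility is attempted.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from .chains import DiseaseDefinition, build_disease
from .errors import InfeasibleConfigError
from .io_formats import ModelBundle
from .model import EntityRef
from .ontology import AbnormalStateClass, Taxonomy, ROOT_ID

_MAX_FAMILY = 5          # diseases per planted family (root + refinements)
_OPS = ("insert", "upstream", "specialize")


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters; the seed fully determines the output."""

    seed: int = 0
    taxonomy_depth: int = 5
    branching: int = 4
    n_departments: int = 3
    n_diseases: int = 15
    p_insert: float = 0.6
    p_upstream: float = 0.4
    p_specialize: float = 0.5

    def validate(self) -> None:
        if self.taxonomy_depth < 3:
            raise InfeasibleConfigError(
                f"taxonomy_depth must be >= 3, got {self.taxonomy_depth}"
            )
        if self.branching < 2:
            raise InfeasibleConfigError("branching must be >= 2")
        if self.n_diseases < 1 or self.n_departments < 1:
            raise InfeasibleConfigError("need at least one disease and department")
        for name in ("p_insert", "p_upstream", "p_specialize"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise InfeasibleConfigError(f"{name}={p} outside [0, 1]")
        if self.n_families > self.branching ** 2:
            raise InfeasibleConfigError(
                f"{self.n_families} families need {self.n_families} disjoint "
                f"level-2 subtrees but the taxonomy only has {self.branching ** 2}"
            )
        capacity = self.branching ** (self.taxonomy_depth - 3)
        family_size = math.ceil(self.n_diseases / self.n_families)
        needed = 3 + 2 * (family_size - 1)  # root chain + 2 draws per subclass
        if capacity < needed:
            raise InfeasibleConfigError(
                f"draw-tier capacity {capacity} cannot host families of "
                f"{family_size} diseases (need {needed}); increase "
                "taxonomy_depth or branching"
            )

    @property
    def n_families(self) -> int:
        return max(1, math.ceil(self.n_diseases / _MAX_FAMILY))


@dataclass
class GroundTruth:
    """What the generator planted: the refinement forest."""

    planted_edges: set[tuple[str, str]] = field(default_factory=set)
    families: list[list[str]] = field(default_factory=list)

    @property
    def partial_order(self) -> set[tuple[str, str]]:
        """Transitive closure of the planted forest (strict pairs)."""
        children: dict[str, list[str]] = {}
        for (p, c) in self.planted_edges:
            children.setdefault(p, []).append(c)
        closure = set()

        def walk(root, node):
            for c in children.get(node, []):
                closure.add((root, c))
                walk(root, c)

        nodes = {n for e in self.planted_edges for n in e}
        for n in nodes:
            walk(n, n)
        return closure


def _build_taxonomy(cfg: SynthConfig, rng: random.Random) -> tuple[Taxonomy, list[list[str]]]:
    """Random tree: root + level-1 tier, then object-bound level-2 tiers.

    Returns the taxonomy and one class pool per level-2 subtree (rooted at
    depth 2), listed in deterministic order.
    """
    tax = Taxonomy()
    tax.add_class(AbnormalStateClass(id=ROOT_ID, label="abnormal state", level=1))
    counter = 0

    def new_id():
        nonlocal counter
        counter += 1
        return f"s{counter:04d}"

    categories = ("structural", "functional", "other")
    tier1 = []
    for i in range(cfg.branching):
        cid = new_id()
        tax.add_class(AbnormalStateClass(
            id=cid, level=1, parents=(ROOT_ID,),
            category=categories[i % len(categories)],
        ))
        tier1.append(cid)

    pools: list[list[str]] = []
    frontier_obj = 0
    for t1 in tier1:
        for _ in range(cfg.branching):
            frontier_obj += 1
            sub_root = new_id()
            tax.specialize(
                t1, object=EntityRef(f"obj{frontier_obj:04d}"), id=sub_root
            )
            pool = [sub_root]
            frontier = [sub_root]
            for _depth in range(3, cfg.taxonomy_depth + 1):
                nxt = []
                for parent in frontier:
                    for _ in range(cfg.branching):
                        frontier_obj += 1
                        cid = new_id()
                        tax.specialize(
                            parent, object=EntityRef(f"obj{frontier_obj:04d}"),
                            id=cid,
                        )
                        nxt.append(cid)
                pool.extend(nxt)
                frontier = nxt
            pools.append(pool)
    return tax, pools


class _FamilyState:
    """Bookkeeping for one planted family: its class pool and usage.

    Fresh draws come from the *draw tier* — the second-to-last tier of the
    family's subtree — whose classes are mutually incomparable (so the
    capacity for fresh draws is the full tier) while each still has
    taxonomy children left for the specialize op.
    """

    def __init__(self, pool: list[str], tax: Taxonomy, rng: random.Random,
                 draw_depth: int):
        self.pool = list(pool)
        self.draw_pool = [c for c in pool if tax.depth(c) == draw_depth]
        self.tax = tax
        self.rng = rng
        self.used: set[str] = set()

    def _incomparable_to_used(self, cand: str, exempt: set[str]) -> bool:
        for u in self.used - exempt:
            if self.tax.is_subclass(cand, u) or self.tax.is_subclass(u, cand):
                return False
        return True

    def draw_fresh(self) -> str | None:
        cands = [c for c in self.draw_pool
                 if c not in self.used and self._incomparable_to_used(c, set())]
        if not cands:
            return None
        pick = self.rng.choice(sorted(cands))
        self.used.add(pick)
        return pick

    def draw_child_of(self, node: str) -> str | None:
        """An unused taxonomy child of ``node``, incomparable to everything
        used except ``node``'s own ancestor line."""
        exempt = self.tax.ancestors(node)
        kids = [c for c in sorted(self.tax.descendants(node, include_self=False))
                if node in self.tax[c].parents]
        cands = [c for c in kids
                 if c not in self.used and self._incomparable_to_used(c, exempt)]
        if not cands:
            return None
        pick = self.rng.choice(cands)
        self.used.add(pick)
        return pick


def _refine(chain_edges, fam: _FamilyState, rng: random.Random, cfg: SynthConfig):
    """Apply 1–2 inclusion-preserving ops to a parent chain's edge list.

    Returns the new edge list, or ``None`` when no op is applicable (pool
    exhausted)."""
    edges = [tuple(e) for e in chain_edges]
    wanted = [op for op, p in zip(_OPS, (cfg.p_insert, cfg.p_upstream,
                                         cfg.p_specialize))
              if rng.random() < p][:2]
    if not wanted:
        wanted = [rng.choice(_OPS)]
    applied = 0
    for op in wanted:
        if op == "insert":
            x = fam.draw_fresh()
            if x is None:
                continue
            a, b = edges[rng.randrange(len(edges))]
            edges.remove((a, b))
            edges.extend([(a, x), (x, b)])
        elif op == "upstream":
            u = fam.draw_fresh()
            if u is None:
                continue
            nodes = {n for e in edges for n in e}
            sources = sorted(n for n in nodes
                             if all(b != n for _, b in edges))
            edges.append((u, rng.choice(sources)))
        else:  # specialize
            nodes = sorted({n for e in edges for n in e})
            rng.shuffle(nodes)
            done = False
            for c in nodes:
                c2 = fam.draw_child_of(c)
                if c2 is not None:
                    edges = [(c2 if a == c else a, c2 if b == c else b)
                             for (a, b) in edges]
                    done = True
                    break
            if not done:
                continue
        applied += 1
    if applied == 0:
        # fall back: force any applicable op so the child differs strictly
        for op in _OPS:
            if op == "insert":
                x = fam.draw_fresh()
                if x is not None:
                    a, b = edges[0]
                    edges.remove((a, b))
                    edges.extend([(a, x), (x, b)])
                    return edges
            elif op == "upstream":
                u = fam.draw_fresh()
                if u is not None:
                    nodes = {n for e in edges for n in e}
                    src = sorted(n for n in nodes
                                 if all(b != n for _, b in edges))[0]
                    edges.append((u, src))
                    return edges
            else:
                for c in sorted({n for e in edges for n in e}):
                    c2 = fam.draw_child_of(c)
                    if c2 is not None:
                        return [(c2 if a == c else a, c2 if b == c else b)
                                for (a, b) in edges]
        return None
    return edges


# ---------------------------------------------------------------------
# Random instances for matcher cross-checks
# ---------------------------------------------------------------------

def _random_dag(rng: random.Random, classes: list[str], n_nodes: int,
                p_edge: float = 0.4) -> "CausalChainGraph":
    from .chains import CausalChainGraph

    nodes = rng.sample(classes, min(n_nodes, len(classes)))
    edges = [
        (nodes[i], nodes[j])
        for i in range(len(nodes))
        for j in range(i + 1, len(nodes))
        if rng.random() < p_edge
    ]
    return CausalChainGraph(nodes=nodes, edges=edges)


def random_inclusion_instances(seed: int, n_pairs: int):
    """Random (small, large) chain pairs over a random taxonomy.

    Half the pairs are unconstrained random DAGs (mostly negative
    instances); the other half plant an embedding — each small node mapped
    to a taxonomy descendant, each link realized as an edge or a two-edge
    path — and then add noise, so positives are well represented.  Used to
    cross-check the backtracking matcher against brute-force enumeration.
    """
    from .chains import CausalChainGraph
    import networkx as nx

    rng = random.Random(seed)
    tax, _pools = _build_taxonomy(
        SynthConfig(seed=seed, taxonomy_depth=4, branching=3), rng
    )
    classes = sorted(tax.classes)
    out = []
    for k in range(n_pairs):
        small = _random_dag(rng, classes, rng.randint(0, 3))
        if k % 2 == 0 or not small.nodes:
            large = _random_dag(rng, classes, rng.randint(1, 8))
        else:
            image = {
                n: rng.choice(sorted(tax.descendants(n))) for n in small.nodes
            }
            nodes = set(image.values())
            edges = set()
            for (a, b) in small.edges:
                fa, fb = image[a], image[b]
                if fa == fb:
                    continue  # collided image; instance may come out negative
                x = rng.choice(classes)
                if rng.random() < 0.4 and x not in (fa, fb) and len(nodes) < 7:
                    nodes.add(x)
                    edges.update([(fa, x), (x, fb)])
                else:
                    edges.add((fa, fb))
            while len(nodes) < 8 and rng.random() < 0.4:  # structural noise
                nodes.add(rng.choice(classes))
            g = nx.DiGraph()
            g.add_nodes_from(nodes)
            g.add_edges_from(edges)
            if not nx.is_directed_acyclic_graph(g):
                large = _random_dag(rng, classes, rng.randint(1, 8))
            else:
                large = CausalChainGraph(nodes=nodes, edges=edges)
        out.append((small, large))
    return tax, out


def generate_synthetic(cfg: SynthConfig) -> tuple[ModelBundle, GroundTruth]:
    """Build a seeded random bundle plus its planted hierarchy."""
    cfg.validate()
    rng = random.Random(cfg.seed)
    tax, pools = _build_taxonomy(cfg, rng)
    rng.shuffle(pools)

    truth = GroundTruth()
    diseases: dict[str, DiseaseDefinition] = {}
    family_states: list[_FamilyState] = []
    family_members: list[list[str]] = []
    chains: dict[str, list[tuple[str, str]]] = {}

    n_fam = cfg.n_families
    for d_index in range(cfg.n_diseases):
        fam_idx = d_index % n_fam
        did = f"d{d_index:03d}"
        dept = f"dept{d_index % cfg.n_departments}"
        if d_index < n_fam:
            fam = _FamilyState(pools[fam_idx], tax, rng,
                               draw_depth=cfg.taxonomy_depth - 1)
            family_states.append(fam)
            family_members.append([])
            # root core chain: a short path of pairwise-incomparable states
            length = rng.randint(2, 3)
            nodes = []
            for _ in range(length):
                n = fam.draw_fresh()
                if n is None:
                    raise InfeasibleConfigError(
                        "taxonomy too small for the requested root chain"
                    )
                nodes.append(n)
            edges = list(zip(nodes, nodes[1:]))
        else:
            fam = family_states[fam_idx]
            parent_id = rng.choice(family_members[fam_idx])
            edges = _refine(chains[parent_id], fam, rng, cfg)
            if edges is None:
                raise InfeasibleConfigError(
                    "family class pool exhausted; enlarge the taxonomy or "
                    "reduce n_diseases"
                )
            truth.planted_edges.add((parent_id, did))
        states = sorted({n for e in edges for n in e})
        diseases[did] = build_disease(
            did, did, dept, states=states, causal_links=edges,
            core_flags=edges, tax=tax,
        )
        chains[did] = edges
        family_members[fam_idx].append(did)

    truth.families = family_members
    bundle = ModelBundle(
        taxonomy=tax,
        entities={},
        diseases=diseases,
        metadata={"name": "synthetic", "seed": cfg.seed},
    )
    return bundle, truth
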