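"""Synthetic gene families: duplication-loss histories on a ranked species
tree with protein sequence evolution.

The generator emulates the evolutionary scenario the classification targets:
a single ancestral gene at the root of the green lineage evolves along a
dated species tree

    (green_algae, (bryophyte, (lycophyte, (monocot, eudicot))))

with the named divergences at fixed epoch ages (viridiplantae 1.0,
embryophyte 0.8, vascular 0.6, angiosperm 0.4; ages are abstract units —
only their order matters to truth labels). Along every species-tree branch
each gene lineage duplicates at rate ``dup_rate`` and dies at rate
``loss_rate`` (independent Poisson processes); at speciation nodes every
surviving lineage is copied into both daughter species. Surviving leaves
receive protein sequences evolved site-independently under the JTT model
(or a 20-state equal-rates model) at ``subst_rate`` expected substitutions
per site per unit time, with no indel process: the simulated homologous
sites are already an alignment.

Truth labels are read directly off the event history: a surviving angiosperm
leaf's *true group* is the identity of its ancestral gene lineage at the
monocot/eudicot split, and its *true supergroup* the lineage at the
bryophyte/vascular (embryophyte) split — the exact quantities the classifier
is meant to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from . import _jtt
from .io_formats import Node, SequenceRecord, TaxonomyTable, Tree

__all__ = [
    "DEFAULT_SPECIES",
    "DEFAULT_EPOCH_TIMES",
    "SimConfig",
    "GeneEventHistory",
    "TruthLabels",
    "FamilySimulation",
    "species_tree",
    "simulate_family",
    "truth_from_history",
    "evolve_pair",
    "sim_taxonomy",
]

#: Minimal species set exercising every rank boundary:
#: 3 eudicots, 2 monocots, 1 lycophyte, 1 bryophyte, 1 green alga.
DEFAULT_SPECIES: tuple[tuple[str, str], ...] = (
    ("Ed1", "eudicot"),
    ("Ed2", "eudicot"),
    ("Ed3", "eudicot"),
    ("Mo1", "monocot"),
    ("Mo2", "monocot"),
    ("Ly1", "lycophyte"),
    ("Br1", "bryophyte"),
    ("Ga1", "green_algae"),
)

DEFAULT_EPOCH_TIMES: dict[str, float] = {
    "viridiplantae": 1.0,
    "embryophyte": 0.8,
    "vascular": 0.6,
    "angiosperm": 0.4,
}

_RANK_ATTACH = {
    "green_algae": "viridiplantae",
    "bryophyte": "embryophyte",
    "lycophyte": "vascular",
    "monocot": "angiosperm",
    "eudicot": "angiosperm",
}


@dataclass
class SimConfig:
    """Parameters of one simulated gene family.

    Rates are per gene lineage per unit time; ``subst_rate`` is expected
    substitutions per site per unit time. Defaults give a moderately
    duplicating family (about one expected duplication per root-to-tip
    lineage) with mild loss and alignments long enough for distance
    estimation.
    """

    species: tuple[tuple[str, str], ...] = DEFAULT_SPECIES
    epoch_times: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EPOCH_TIMES)
    )
    within_rank_split_times: dict[str, list[float]] | None = None
    dup_rate: float = 0.3
    loss_rate: float = 0.1
    seq_length: int = 1000
    subst_rate: float = 0.5
    model: str = "jtt"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.dup_rate, self.loss_rate, self.subst_rate) < 0:
            raise ValueError("rates must be >= 0")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        e = self.epoch_times
        if not (
            e["viridiplantae"] > e["embryophyte"] > e["vascular"] > e["angiosperm"] > 0
        ):
            raise ValueError("epoch times must strictly decrease root -> tips")
        ranks_used = {rank for _, rank in self.species}
        missing = set(_RANK_ATTACH) - ranks_used
        if missing:
            raise ValueError(f"need >= 1 species per rank; missing {sorted(missing)}")
        if self.model not in ("jtt", "equal_rates_20state"):
            raise ValueError(f"unknown model {self.model!r}")


def sim_taxonomy(cfg: SimConfig) -> TaxonomyTable:
    """Taxonomy table for the configured species set."""
    return TaxonomyTable({ab: (ab, rank) for ab, rank in cfg.species})


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------


class _SpNode:
    __slots__ = ("name", "age", "children")

    def __init__(self, name: str, age: float, children: list["_SpNode"] | None = None):
        self.name = name
        self.age = age
        self.children = children or []

    @property
    def is_leaf(self) -> bool:
        return not self.children


def _rank_subtree(cfg: SimConfig, rank: str) -> _SpNode:
    """Caterpillar subtree of the species of one rank.

    Split ages default to even spacing within the rank's crown window
    (between 0 and the age at which the rank's stem attaches)."""
    members = [ab for ab, r in cfg.species if r == rank]
    k = len(members)
    if k == 1:
        return _SpNode(members[0], 0.0)
    attach = cfg.epoch_times[_RANK_ATTACH[rank]]
    if cfg.within_rank_split_times and rank in cfg.within_rank_split_times:
        times = sorted(cfg.within_rank_split_times[rank])
        if len(times) != k - 1 or not all(0 < t < attach for t in times):
            raise ValueError(
                f"{rank}: need {k - 1} split times strictly inside (0, {attach})"
            )
    else:
        times = [attach * j / k for j in range(1, k)]
    node = _SpNode(members[0], 0.0)
    for j, member in enumerate(members[1:], start=1):
        node = _SpNode(
            f"{rank}_{j}", times[j - 1], [node, _SpNode(member, 0.0)]
        )
    return node


def _build_species_tree(cfg: SimConfig) -> _SpNode:
    e = cfg.epoch_times
    angiosperm = _SpNode(
        "angiosperm",
        e["angiosperm"],
        [_rank_subtree(cfg, "monocot"), _rank_subtree(cfg, "eudicot")],
    )
    vascular = _SpNode(
        "vascular", e["vascular"], [_rank_subtree(cfg, "lycophyte"), angiosperm]
    )
    embryophyte = _SpNode(
        "embryophyte", e["embryophyte"], [_rank_subtree(cfg, "bryophyte"), vascular]
    )
    return _SpNode(
        "viridiplantae",
        e["viridiplantae"],
        [_rank_subtree(cfg, "green_algae"), embryophyte],
    )


def species_tree(cfg: SimConfig | None = None) -> Tree:
    """The configured dated species tree as a :class:`Tree` (branch lengths
    in time units)."""
    cfg = cfg or SimConfig()

    def _convert(sp: _SpNode, parent_age: float | None) -> Node:
        length = None if parent_age is None else parent_age - sp.age
        node = Node(label=sp.name if sp.is_leaf else None, length=length)
        for c in sp.children:
            node.add_child(_convert(c, sp.age))
        return node

    return Tree(_convert(_build_species_tree(cfg), None), rooted=True)


# ---------------------------------------------------------------------------
# Gene tree simulation
# ---------------------------------------------------------------------------


class _GeneNode:
    __slots__ = ("id", "time", "kind", "species", "children", "parent")

    def __init__(self, id: int, time: float, kind: str, species: str):
        self.id = id
        self.time = time
        self.kind = kind  # root | speciation | duplication | loss | leaf
        self.species = species
        self.children: list["_GeneNode"] = []
        self.parent: "_GeneNode | None" = None

    def add(self, child: "_GeneNode") -> "_GeneNode":
        child.parent = self
        self.children.append(child)
        return child


@dataclass(frozen=True)
class GeneEvent:
    time: float
    branch: str  # species node naming the branch (its lower end) or the node itself
    kind: str  # duplication | loss | speciation


@dataclass
class GeneEventHistory:
    """The complete simulated history: the full gene tree including lost
    lineages, and the chronological event list."""

    root: _GeneNode
    events: list[GeneEvent]
    epoch_times: dict[str, float]


@dataclass
class TruthLabels:
    """Per surviving angiosperm leaf: ancestral lineage identities at the
    group and supergroup epoch boundaries. ``true_group`` refines
    ``true_supergroup``."""

    true_group: dict[str, int]
    true_supergroup: dict[str, int]


class FamilySimulation(NamedTuple):
    records: list[SequenceRecord]
    true_tree: Tree
    history: GeneEventHistory
    truth: TruthLabels


def _simulate_gene_tree(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[_GeneNode, list[GeneEvent]]:
    sp_root = _build_species_tree(cfg)
    counter = [0]
    events: list[GeneEvent] = []
    total_rate = cfg.dup_rate + cfg.loss_rate

    def _new(time: float, kind: str, species: str) -> _GeneNode:
        counter[0] += 1
        return _GeneNode(counter[0], time, kind, species)

    def _speciate(gnode: _GeneNode, sp: _SpNode) -> None:
        events.append(GeneEvent(sp.age, sp.name, "speciation"))
        for child_sp in sp.children:
            _along_branch(gnode, sp.age, child_sp)

    def _along_branch(parent: _GeneNode, t_from: float, sp_child: _SpNode) -> None:
        t = t_from
        while True:
            wait = rng.exponential(1.0 / total_rate) if total_rate > 0 else np.inf
            t_next = t - wait
            if t_next <= sp_child.age:
                break
            if rng.random() < cfg.dup_rate / total_rate:
                dup = parent.add(_new(t_next, "duplication", sp_child.name))
                events.append(GeneEvent(t_next, sp_child.name, "duplication"))
                # first copy continues down this branch, second recurses
                _along_branch(dup, t_next, sp_child)
                parent = dup
                t = t_next
            else:
                parent.add(_new(t_next, "loss", sp_child.name))
                events.append(GeneEvent(t_next, sp_child.name, "loss"))
                return
        if sp_child.is_leaf:
            parent.add(_new(0.0, "leaf", sp_child.name))
        else:
            spec = parent.add(_new(sp_child.age, "speciation", sp_child.name))
            _speciate(spec, sp_child)

    root = _new(cfg.epoch_times["viridiplantae"], "root", sp_root.name)
    _speciate(root, sp_root)
    events.sort(key=lambda e: (-e.time, e.branch, e.kind))
    return root, events


def _surviving_leaves(root: _GeneNode) -> list[_GeneNode]:
    out = []
    stack = [root]
    while stack:
        n = stack.pop()
        if n.kind == "leaf":
            out.append(n)
        stack.extend(reversed(n.children))
    return out


def _prune_to_survivors(root: _GeneNode) -> tuple[Node, dict[int, _GeneNode]] | None:
    """Pruned gene tree of surviving lineages as a :class:`Node` structure
    (branch lengths in time units, leaves labelled ``<species>_g<k>``).

    Returns ``(root_node, leaf_origin)`` mapping leaf node ids back to their
    history nodes, or None if nothing survives."""
    per_species_count: dict[str, int] = {}
    leaf_origin: dict[int, _GeneNode] = {}

    def _convert(g: _GeneNode) -> tuple[Node, _GeneNode] | None:
        if g.kind == "loss":
            return None
        if g.kind == "leaf":
            k = per_species_count.get(g.species, 0) + 1
            per_species_count[g.species] = k
            node = Node(label=f"{g.species}_g{k}")
            leaf_origin[id(node)] = g
            return node, g
        kept = []
        for c in g.children:
            sub = _convert(c)
            if sub is not None:
                kept.append((c, sub))
        if not kept:
            return None
        if len(kept) == 1:
            # unary: splice this node out, child's branch reaches further up
            return kept[0][1]
        node = Node()
        for child_g, (child_node, _origin) in kept:
            child_node.length = g.time - _branch_top_time(child_node, _origin)
            node.add_child(child_node)
        return node, g

    res = _convert(root)
    if res is None:
        return None
    node, _ = res
    return node, leaf_origin


def _branch_top_time(node: Node, origin: _GeneNode) -> float:
    # the time of the history node this pruned node corresponds to
    return origin.time


def truth_from_history(history: GeneEventHistory) -> TruthLabels:
    """Trace each surviving angiosperm leaf to its ancestral lineage at the
    angiosperm and embryophyte splits."""
    t_angio = history.epoch_times["angiosperm"]
    t_embryo = history.epoch_times["embryophyte"]
    # label surviving leaves exactly as _prune_to_survivors does
    per_species_count: dict[str, int] = {}
    true_group: dict[str, int] = {}
    true_supergroup: dict[str, int] = {}
    for leaf in _surviving_leaves(history.root):
        k = per_species_count.get(leaf.species, 0) + 1
        per_species_count[leaf.species] = k
        label = f"{leaf.species}_g{k}"
        group_id = None
        supergroup_id = None
        cur = leaf
        while cur is not None:
            if cur.kind == "speciation":
                if cur.species == "angiosperm" and cur.time == t_angio:
                    group_id = cur.id
                if cur.species == "embryophyte" and cur.time == t_embryo:
                    supergroup_id = cur.id
            cur = cur.parent
        if group_id is not None:  # angiosperm leaf
            true_group[label] = group_id
            true_supergroup[label] = supergroup_id
    return TruthLabels(true_group=true_group, true_supergroup=true_supergroup)


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------


def _equal_rates_transition(d: float) -> np.ndarray:
    """20-state equal-rates transition matrix normalized to one expected
    substitution per site per unit distance."""
    decay = np.exp(-20.0 / 19.0 * d)
    p = np.full((20, 20), (1.0 - decay) / 20.0)
    np.fill_diagonal(p, (1.0 + 19.0 * decay) / 20.0)
    return p


def _model_funcs(model: str):
    if model == "jtt":
        return _jtt.JTT_FREQS, _jtt.transition_matrix
    return np.full(20, 0.05), _equal_rates_transition


def _evolve_states(
    parent_states: np.ndarray, d: float, transition, rng: np.random.Generator
) -> np.ndarray:
    p = transition(d)
    out = np.empty_like(parent_states)
    for state in range(20):
        mask = parent_states == state
        k = int(mask.sum())
        if k:
            out[mask] = rng.choice(20, size=k, p=p[state])
    return out


def _states_to_seq(states: np.ndarray) -> str:
    return "".join(_jtt.AA_ORDER[s] for s in states)


def _evolve_along_tree(
    tree: Tree, cfg: SimConfig, rng: np.random.Generator
) -> list[SequenceRecord]:
    freqs, transition = _model_funcs(cfg.model)
    root_states = rng.choice(20, size=cfg.seq_length, p=freqs)
    records: list[SequenceRecord] = []

    def _walk(node: Node, states: np.ndarray) -> None:
        if node.is_leaf:
            records.append(SequenceRecord(node.label, _states_to_seq(states)))
            return
        for c in node.children:
            d = cfg.subst_rate * (c.length or 0.0)
            child_states = _evolve_states(states, d, transition, rng) if d > 0 else states
            _walk(c, child_states)

    _walk(tree.root, root_states)
    return records


def evolve_pair(
    d: float, length: int, seed: int, model: str = "jtt"
) -> tuple[SequenceRecord, SequenceRecord]:
    """Two sequences separated by *d* expected substitutions per site: one
    drawn from the model equilibrium, the other evolved from it."""
    rng = np.random.default_rng(seed)
    freqs, transition = _model_funcs(model)
    a = rng.choice(20, size=length, p=freqs)
    b = _evolve_states(a, d, transition, rng)
    return (
        SequenceRecord("pair_a", _states_to_seq(a)),
        SequenceRecord("pair_b", _states_to_seq(b)),
    )


# ---------------------------------------------------------------------------
# Top-level simulation
# ---------------------------------------------------------------------------

_MAX_ATTEMPTS = 1000


def simulate_family(cfg: SimConfig | None = None) -> FamilySimulation:
    """Simulate one gene family: returns sequences, the true (pruned,
    rooted) gene tree, the complete event history, and truth labels.

    Conditions on at least one surviving leaf by resampling from seed
    substreams ``(seed, attempt)``; deterministic given ``seed``.
    """
    cfg = cfg or SimConfig()
    for attempt in range(_MAX_ATTEMPTS):
        rng = np.random.default_rng([cfg.seed, attempt])
        root, events = _simulate_gene_tree(cfg, rng)
        pruned = _prune_to_survivors(root)
        if pruned is not None:
            break
    else:
        raise RuntimeError(
            f"family extinct in {_MAX_ATTEMPTS} attempts; lower loss_rate"
        )
    node, _leaf_origin = pruned
    node.length = None
    true_tree = Tree(node, rooted=True)
    history = GeneEventHistory(root=root, events=events, epoch_times=dict(cfg.epoch_times))
    truth = truth_from_history(history)
    records = _evolve_along_tree(true_tree, cfg, rng)
    return FamilySimulation(records, true_tree, history, truth)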