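"""Rank-level reconciliation and group/supergroup classification.

The central algorithm of the package. A rooted gene tree is mapped onto the
fixed land-plant *rank ladder*

    (green_algae, (bryophyte, (lycophyte, (monocot, eudicot))))

whose internal nodes are named viridiplantae, embryophyte, vascular and
angiosperm. Each gene-tree node ``v`` receives ``M(v)``, the lowest ladder
node containing the ranks of all its descendant leaves; ``v`` is a
*duplication* when some child maps to the same ladder node, a *speciation*
otherwise. From this annotation:

* a **group** is a maximal clade descended from a single gene present in the
  last common ancestor of monocots and eudicots — found by descending from
  the root while the mapping is strictly above ``angiosperm`` or the node is
  a duplication mapping to ``angiosperm``;
* a **supergroup** bundles groups whose separating duplications predate the
  bryophyte/vascular-plant split — the same traversal with ``embryophyte``
  in place of ``angiosperm``.

Supergroups are lettered A, B, C, ... and the groups inside each are
numbered with Roman numerals, both in deterministic order (descending leaf
count, ties by smallest contained leaf id). Each angiosperm leaf carries an
E (eudicot) or M (monocot) half marker, yielding labels such as ``A-I E``.

Mapping is at rank granularity on purpose: duplications *within* a rank
never move a group or supergroup boundary, so species-level reconciliation
is unnecessary for this classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import Node, TaxonomyTable, Tree
from .phylo_core import collapse_low_support

__all__ = [
    "RANK_LADDER_PARENT",
    "ladder_lca",
    "NodeAnnotation",
    "LeafClassification",
    "ClassificationResult",
    "lca_map",
    "find_group_roots",
    "find_supergroup_roots",
    "classify",
    "compare_partitions",
    "roman",
]

#: Parent relation of the rank ladder. Leaves are the five ranks; internal
#: nodes are the named ancestors.
RANK_LADDER_PARENT: dict[str, str | None] = {
    "green_algae": "viridiplantae",
    "bryophyte": "embryophyte",
    "lycophyte": "vascular",
    "monocot": "angiosperm",
    "eudicot": "angiosperm",
    "angiosperm": "vascular",
    "vascular": "embryophyte",
    "embryophyte": "viridiplantae",
    "viridiplantae": None,
}

_LADDER_DEPTH = {
    "viridiplantae": 0,
    "green_algae": 1,
    "embryophyte": 1,
    "bryophyte": 2,
    "vascular": 2,
    "lycophyte": 3,
    "angiosperm": 3,
    "monocot": 4,
    "eudicot": 4,
}


def _ancestors(rank: str) -> list[str]:
    out = [rank]
    while RANK_LADDER_PARENT[out[-1]] is not None:
        out.append(RANK_LADDER_PARENT[out[-1]])
    return out


def ladder_lca(a: str, b: str) -> str:
    """Lowest common ancestor of two rank-ladder nodes."""
    anc_a = _ancestors(a)
    set_a = set(anc_a)
    for x in _ancestors(b):
        if x in set_a:
            return x
    raise ValueError(f"no common ancestor for {a!r}, {b!r}")  # unreachable


def ladder_is_strictly_above(a: str, b: str) -> bool:
    """True iff ladder node *a* is a strict ancestor of *b*."""
    return a != b and a in _ancestors(b)


@dataclass(frozen=True)
class NodeAnnotation:
    """Reconciliation annotation of one gene-tree node."""

    mapping: str  # rank-ladder node
    event: str  # "speciation" | "duplication" | "leaf"


def lca_map(tree: Tree, taxonomy: TaxonomyTable) -> dict[int, NodeAnnotation]:
    """Post-order LCA mapping of the gene tree onto the rank ladder.

    Returns ``id(node) -> NodeAnnotation``. A node is a duplication iff a
    child maps to the same ladder node (the rule applies unchanged at
    polytomies). Non-plant leaves are rejected: prune the outgroup first.
    """
    annotations: dict[int, NodeAnnotation] = {}
    for node in tree.postorder():
        if node.is_leaf:
            rank = taxonomy.rank_of_sequence(node.label)
            if rank == "nonplant":
                raise ValueError(
                    f"leaf {node.label!r} has rank nonplant: "
                    "prune outgroup before classification"
                )
            annotations[id(node)] = NodeAnnotation(rank, "leaf")
        else:
            mapping = annotations[id(node.children[0])].mapping
            for c in node.children[1:]:
                mapping = ladder_lca(mapping, annotations[id(c)].mapping)
            event = (
                "duplication"
                if any(annotations[id(c)].mapping == mapping for c in node.children)
                else "speciation"
            )
            annotations[id(node)] = NodeAnnotation(mapping, event)
    return annotations


def _emit_roots(
    tree: Tree, annotations: dict[int, NodeAnnotation], boundary: str
) -> list[Node]:
    """Pre-order traversal emitting maximal clades at the given ladder
    boundary: descend while the mapping is strictly above *boundary* or the
    node is a duplication mapping exactly to *boundary*; emit otherwise."""
    emitted: list[Node] = []
    stack = [tree.root]
    while stack:
        v = stack.pop()
        ann = annotations[id(v)]
        above = ladder_is_strictly_above(ann.mapping, boundary)
        dup_at_boundary = ann.event == "duplication" and ann.mapping == boundary
        if (above or dup_at_boundary) and not v.is_leaf:
            stack.extend(reversed(v.children))
        else:
            emitted.append(v)
    return emitted


_ANGIOSPERM_RANKS = {"monocot", "eudicot", "angiosperm"}


def _contains_angiosperm(node: Node, annotations: dict[int, NodeAnnotation]) -> bool:
    m = annotations[id(node)].mapping
    return m in _ANGIOSPERM_RANKS


def find_group_roots(
    tree: Tree, annotations: dict[int, NodeAnnotation]
) -> tuple[list[Node], list[Node]]:
    """Roots of groups: maximal clades below a single ancestral
    monocot/eudicot-LCA gene. Returns ``(group_roots, unplaced)`` where
    *unplaced* holds emitted clades with no angiosperm leaves (e.g. a
    bryophyte-only clade basal in a supergroup)."""
    emitted = _emit_roots(tree, annotations, "angiosperm")
    groups = [v for v in emitted if _contains_angiosperm(v, annotations)]
    unplaced = [v for v in emitted if not _contains_angiosperm(v, annotations)]
    return groups, unplaced


def find_supergroup_roots(
    tree: Tree, annotations: dict[int, NodeAnnotation]
) -> tuple[list[Node], list[Node]]:
    """Roots of supergroups: maximal clades whose separating duplications
    predate the bryophyte/vascular split. Returns ``(roots, unplaced)``;
    duplications mapping to ``vascular`` or ``angiosperm`` stay inside one
    supergroup, duplications at ``embryophyte`` or ``viridiplantae`` split
    supergroups apart."""
    emitted = _emit_roots(tree, annotations, "embryophyte")
    roots = [v for v in emitted if _contains_angiosperm_below(v, annotations)]
    unplaced = [v for v in emitted if not _contains_angiosperm_below(v, annotations)]
    return roots, unplaced


def _subtree_leaves(node: Node) -> list[Node]:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        else:
            stack.extend(reversed(n.children))
    return out


def _contains_angiosperm_below(
    node: Node, annotations: dict[int, NodeAnnotation]
) -> bool:
    return any(
        annotations[id(l)].mapping in ("monocot", "eudicot")
        for l in _subtree_leaves(node)
    )


def roman(n: int) -> str:
    """Roman numeral for a positive integer (group numbering)."""
    if not 1 <= n <= 3999:
        raise ValueError("roman() supports 1..3999")
    pairs = [
        (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
        (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
        (5, "V"), (4, "IV"), (1, "I"),
    ]
    out = []
    for value, sym in pairs:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


def _letters(i: int) -> str:
    """A, B, ..., Z, AA, AB, ... (supergroup lettering)."""
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = chr(ord("A") + rem) + out
    return out


@dataclass(frozen=True)
class LeafClassification:
    leaf_id: str
    supergroup: str | None
    group: str | None
    half: str | None  # "E" | "M" | None

    @property
    def label(self) -> str:
        if self.supergroup is None:
            return "unplaced"
        if self.group is None:
            return self.supergroup
        base = f"{self.supergroup}-{self.group}"
        return f"{base} {self.half}" if self.half else base


@dataclass
class ClassificationResult:
    """Full output of :func:`classify`."""

    leaves: dict[str, LeafClassification]
    annotations: dict[int, NodeAnnotation]
    supergroup_roots: dict[str, Node]
    group_roots: dict[str, dict[str, Node]]  # letter -> numeral -> node
    unplaced: list[Node] = field(default_factory=list)
    tree: Tree | None = None

    def group_partition(self) -> dict[str, tuple[str, str]]:
        """Angiosperm leaf id -> (supergroup letter, group numeral)."""
        return {
            lid: (lc.supergroup, lc.group)
            for lid, lc in self.leaves.items()
            if lc.half in ("E", "M") and lc.group is not None
        }


def _order_key(node: Node) -> tuple[int, str]:
    leaves = _subtree_leaves(node)
    return (-len(leaves), min(l.label for l in leaves))


def classify(
    tree: Tree,
    taxonomy: TaxonomyTable,
    collapse_threshold: float | None = None,
    anchors: dict[str, str] | None = None,
) -> ClassificationResult:
    """Classify a rooted gene tree into named supergroups and groups.

    Steps: optionally contract internal edges with support <=
    ``collapse_threshold``; prune non-plant leaves; LCA-map onto the rank
    ladder; detect supergroups, then groups within each supergroup subtree;
    assign deterministic names. ``anchors`` optionally pins supergroup
    letters by a contained leaf id (e.g. force the clade containing a known
    published member to keep its published letter).
    """
    work = tree
    if collapse_threshold is not None:
        work = collapse_low_support(work, collapse_threshold)
    nonplant = [
        l for l in work.leaf_labels() if taxonomy.rank_of_sequence(l) == "nonplant"
    ]
    if nonplant:
        work = work.prune_leaves(nonplant)
    annotations = lca_map(work, taxonomy)

    sg_roots, sg_unplaced = find_supergroup_roots(work, annotations)
    sg_roots = sorted(sg_roots, key=_order_key)

    # Letter assignment, honoring anchors first.
    letters: dict[int, str] = {}
    used: set[str] = set()
    if anchors:
        for node in sg_roots:
            labels = {l.label for l in _subtree_leaves(node)}
            for leaf_id, letter in anchors.items():
                if leaf_id in labels:
                    if letter in used:
                        raise ValueError(f"anchor letter {letter!r} used twice")
                    letters[id(node)] = letter
                    used.add(letter)
                    break
    next_i = 0
    for node in sg_roots:
        if id(node) not in letters:
            while _letters(next_i) in used:
                next_i += 1
            letters[id(node)] = _letters(next_i)
            used.add(_letters(next_i))
            next_i += 1

    leaves: dict[str, LeafClassification] = {}
    supergroup_roots: dict[str, Node] = {}
    group_roots: dict[str, dict[str, Node]] = {}
    all_unplaced: list[Node] = list(sg_unplaced)

    for sg_node in sg_roots:
        letter = letters[id(sg_node)]
        supergroup_roots[letter] = sg_node
        sub = Tree.__new__(Tree)  # light subtree view rooted at sg_node
        sub.root = sg_node
        sub.rooted = True
        g_roots, g_unplaced = find_group_roots(sub, annotations)
        all_unplaced.extend(g_unplaced)
        g_roots = sorted(g_roots, key=_order_key)
        group_roots[letter] = {}
        grouped: set[str] = set()
        for gi, g_node in enumerate(g_roots):
            numeral = roman(gi + 1)
            group_roots[letter][numeral] = g_node
            for leaf in _subtree_leaves(g_node):
                rank = annotations[id(leaf)].mapping
                half = {"eudicot": "E", "monocot": "M"}.get(rank)
                leaves[leaf.label] = LeafClassification(
                    leaf.label, letter, numeral, half
                )
                grouped.add(leaf.label)
        for leaf in _subtree_leaves(sg_node):
            if leaf.label not in grouped:
                leaves[leaf.label] = LeafClassification(leaf.label, letter, None, None)

    for node in all_unplaced:
        for leaf in _subtree_leaves(node):
            if leaf.label not in leaves:
                leaves[leaf.label] = LeafClassification(leaf.label, None, None, None)

    return ClassificationResult(
        leaves=leaves,
        annotations=annotations,
        supergroup_roots=supergroup_roots,
        group_roots=group_roots,
        unplaced=all_unplaced,
        tree=work,
    )


def compare_partitions(
    inferred: "ClassificationResult", truth
) -> tuple[bool, int, int]:
    """Compare the inferred angiosperm group partition with truth labels.

    *truth* is a :class:`famclade.simulate.TruthLabels` (or any object with a
    ``true_group`` mapping from angiosperm leaf id to lineage id). Returns
    ``(exact_match, merges, splits)`` where *merges* counts inferred groups
    spanning >= 2 truth groups and *splits* counts truth groups broken
    across >= 2 inferred groups.
    """
    inferred_map = inferred.group_partition()
    truth_map = dict(truth.true_group)
    if set(inferred_map) != set(truth_map):
        raise ValueError(
            "angiosperm leaf sets differ between inferred and truth: "
            f"{sorted(set(inferred_map) ^ set(truth_map))}"
        )
    inferred_groups: dict[tuple[str, str], set[str]] = {}
    for leaf, key in inferred_map.items():
        inferred_groups.setdefault(key, set()).add(leaf)
    truth_groups: dict[object, set[str]] = {}
    for leaf, key in truth_map.items():
        truth_groups.setdefault(key, set()).add(leaf)

    merges = 0
    for members in inferred_groups.values():
        if len({truth_map[m] for m in members}) >= 2:
            merges += 1
    splits = 0
    for members in truth_groups.values():
        if len({inferred_map[m] for m in members}) >= 2:
            splits += 1
    exact = set(frozenset(g) for g in inferred_groups.values()) == set(
        frozenset(g) for g in truth_groups.values()
    )
    return exact, merges, splits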