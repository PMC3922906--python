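"""Clan detection on unrooted trees, and outgroup rooting.

A *clan* is the unrooted analogue of a clade: a set of leaves that can be
separated from all remaining leaves by cutting a single edge. Testing
whether the putative outgroup (e.g. all non-plant homologs) forms a single
clan is the package's monophyly check: if homologs from outside the lineage
of interest all fall on one side of one edge, the in-lineage sequences are
consistent with vertical inheritance from a single ancestral gene.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import Node, PLANT_RANKS, TaxonomyTable, Tree

__all__ = ["is_clan", "monophyly_report", "root_by_outgroup", "MonophylyReport"]


def _side_sets(tree: Tree) -> dict[int, frozenset[str]]:
    return tree.leaf_sets()


def is_clan(tree: Tree, labels: frozenset[str] | set[str]) -> bool:
    """True iff *labels* can be split off the (unrooted) tree by one edge.

    Singletons and the full leaf set are clans by convention. Unknown labels
    raise ``KeyError``.
    """
    s = frozenset(labels)
    if not s:
        raise ValueError("empty leaf set")
    all_leaves = frozenset(tree.leaf_labels())
    unknown = s - all_leaves
    if unknown:
        raise KeyError(f"labels not in tree: {sorted(unknown)}")
    if len(s) == 1 or s == all_leaves:
        return True
    complement = all_leaves - s
    for node, side in _iter_edge_sides(tree):
        if side == s or side == complement:
            return True
    return False


def _iter_edge_sides(tree: Tree):
    leaf_sets = tree.leaf_sets()
    for node in tree.postorder():
        if node is tree.root:
            continue
        yield node, leaf_sets[id(node)]


@dataclass
class MonophylyReport:
    """Per-rank clan status, plus the merged all-plant class."""

    by_rank: dict[str, tuple[int, bool]]  # rank -> (n leaves, is clan)
    plant: tuple[int, bool]

    @property
    def nonplant_is_clan(self) -> bool | None:
        """The monophyly verdict: whether the non-plant leaves form one clan
        (None when the tree has no non-plant leaves)."""
        if "nonplant" not in self.by_rank:
            return None
        return self.by_rank["nonplant"][1]


def monophyly_report(tree: Tree, taxonomy: TaxonomyTable) -> MonophylyReport:
    """Clan status of every rank class present in the tree, and of the
    merged plant class. The vertical-inheritance test passes when the
    non-plant class is a single clan."""
    by_class: dict[str, set[str]] = {}
    for label in tree.leaf_labels():
        rank = taxonomy.rank_of_sequence(label)
        by_class.setdefault(rank, set()).add(label)
    by_rank = {
        rank: (len(members), is_clan(tree, members))
        for rank, members in sorted(by_class.items())
    }
    plant_members = set().union(
        *(m for r, m in by_class.items() if r in PLANT_RANKS), set()
    )
    if plant_members:
        plant = (len(plant_members), is_clan(tree, plant_members))
    else:
        plant = (0, False)
    return MonophylyReport(by_rank=by_rank, plant=plant)


def root_by_outgroup(
    tree: Tree, outgroup: frozenset[str] | set[str], position: float = 0.5
) -> Tree:
    """Root the tree on the edge separating *outgroup* from everything else.

    The outgroup must be a clan and a proper subset of the leaves. The new
    root is placed at fraction *position* of the separating edge's length,
    measured from the outgroup side; total branch length is conserved.
    """
    s = frozenset(outgroup)
    all_leaves = frozenset(tree.leaf_labels())
    if not s or s == all_leaves:
        raise ValueError("outgroup must be a non-empty proper subset of the leaves")
    unknown = s - all_leaves
    if unknown:
        raise KeyError(f"labels not in tree: {sorted(unknown)}")
    if not is_clan(tree, s):
        raise ValueError("outgroup is not a clan; cannot root")
    if not 0.0 <= position <= 1.0:
        raise ValueError("position must be in [0,1]")

    work = tree.copy()
    complement = all_leaves - s

    # n == 2: the tree is a single edge; rooting it is immediate.
    if len(all_leaves) == 2:
        edge = work.total_branch_length()
        have_lengths = any(
            n.length is not None for n in work.postorder() if n is not work.root
        )
        og_label = next(iter(s))
        in_label = next(iter(complement))
        og = Node(label=og_label, length=position * edge if have_lengths else None)
        ig = Node(label=in_label, length=(1 - position) * edge if have_lengths else None)
        return Tree(Node(children=[og, ig]), rooted=True)

    _deroot(work)

    leaf_sets = work.leaf_sets()
    # Find the edge whose lower side is the outgroup or its complement.
    target: Node | None = None
    outgroup_below = True
    for node in work.postorder():
        if node is work.root:
            continue
        side = leaf_sets[id(node)]
        if side == s:
            target = node
            outgroup_below = True
            break
        if side == complement:
            target = node
            outgroup_below = False
            break
    if target is None:  # unreachable once is_clan has passed
        raise ValueError("outgroup is not a clan; cannot root")

    edge_length = target.length
    edge_support = target.support
    old_parent = target.parent
    assert old_parent is not None
    old_parent.remove_child(target)

    upper = _reverse_path(old_parent)  # subtree on the parent side of the edge

    root = Node()
    if outgroup_below:
        og_side, in_side = target, upper
    else:
        og_side, in_side = upper, target
    if edge_length is None:
        og_side.length = None
        in_side.length = None
    else:
        og_side.length = position * edge_length
        in_side.length = (1.0 - position) * edge_length
    # both halves of the split edge carry its support
    for half in (og_side, in_side):
        if not half.is_leaf:
            half.support = edge_support
    root.add_child(og_side)
    root.add_child(in_side)
    return Tree(root, rooted=True)


def _deroot(tree: Tree) -> None:
    """Collapse a two-child root in place so the stored root is a true
    multifurcation: the two root edges of such a representation are one
    unrooted edge, whose length/support is merged onto a single child."""
    root = tree.root
    if len(root.children) != 2:
        return
    c1, c2 = root.children
    if c1.is_leaf and c2.is_leaf:
        return  # n == 2, handled by the caller
    if c1.is_leaf:
        c1, c2 = c2, c1
    # c1 is internal: promote its children to the root, fold c1's edge into c2.
    if c1.length is not None or c2.length is not None:
        c2.length = (c1.length or 0.0) + (c2.length or 0.0)
    if c2.support is None:
        c2.support = c1.support
    root.children = []
    for child in c1.children + [c2]:
        root.add_child(child)
    c1.children = []


def _reverse_path(node: Node) -> Node:
    """Reorient the tree so *node* becomes the root of its remaining part.

    Walks from *node* to the old root flipping parent edges into child
    edges; degree-2 nodes left by the flip are spliced out with branch
    lengths summed.
    """
    # Collect the path node -> old root, saving original edge attributes.
    path: list[Node] = []
    cur: Node | None = node
    while cur is not None:
        path.append(cur)
        cur = cur.parent
    orig = [(n.length, n.support) for n in path]
    # Flip each edge along the path; the flipped edge keeps its attributes.
    for i in range(len(path) - 1):
        child, parent = path[i], path[i + 1]
        parent.remove_child(child)
        child.add_child(parent)
        parent.length, parent.support = orig[i]
    node.parent = None
    node.length = None
    node.support = None
    # Splice out any unary node created by the flip (the old root, typically).
    _splice_unary(node)
    return node


def _splice_unary(root: Node) -> None:
    stack = [root]
    while stack:
        n = stack.pop()
        for c in list(n.children):
            while len(c.children) == 1:
                gc = c.children[0]
                c.children = []
                gc.parent = None
                if gc.length is not None or c.length is not None:
                    gc.length = (gc.length or 0.0) + (c.length or 0.0)
                if gc.support is None:
                    gc.support = c.support
                n.children[n.children.index(c)] = gc
                gc.parent = n
                c = gc
            stack.append(c)
    while len(root.children) == 1:
        only = root.children[0]
        root.children = only.children
        for c in root.children:
            c.parent = root
        root.label = only.label
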