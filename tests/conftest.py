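"""Shared fixtures and small tree utilities for the test suite."""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from famclade.io_formats import Node, TaxonomyTable, Tree
from famclade.phylo_core import DistanceMatrix


@pytest.fixture
def mini_taxonomy() -> TaxonomyTable:
    """One species per rank plus extras, ids resolved by prefix (e1, m2, ...)."""
    return TaxonomyTable(
        {
            "e1": ("Eudicot one", "eudicot"),
            "e2": ("Eudicot two", "eudicot"),
            "e3": ("Eudicot three", "eudicot"),
            "m1": ("Monocot one", "monocot"),
            "m2": ("Monocot two", "monocot"),
            "l1": ("Lycophyte one", "lycophyte"),
            "b1": ("Bryophyte one", "bryophyte"),
            "b2": ("Bryophyte two", "bryophyte"),
            "a1": ("Alga one", "green_algae"),
            "n1": ("Nonplant one", "nonplant"),
            "n2": ("Nonplant two", "nonplant"),
        }
    )


def random_binary_tree(
    labels: list[str],
    rng: np.random.Generator,
    min_len: float = 0.1,
    max_len: float = 1.0,
) -> Tree:
    """A random unrooted binary tree (3-way basal node) with positive
    branch lengths."""
    nodes = [
        Node(label=l, length=float(rng.uniform(min_len, max_len))) for l in labels
    ]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = Node(length=float(rng.uniform(min_len, max_len)))
        parent.add_child(a)
        parent.add_child(b)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = Node()
    for n in nodes:
        root.add_child(n)
    return Tree(root, rooted=False)


def path_distance_matrix(tree: Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances of a tree with branch lengths."""
    adj: dict[int, list[tuple[int, float]]] = {}
    leaves: dict[int, str] = {}

    def _walk(n: Node) -> None:
        if n.is_leaf:
            leaves[id(n)] = n.label
        for c in n.children:
            w = c.length or 0.0
            adj.setdefault(id(n), []).append((id(c), w))
            adj.setdefault(id(c), []).append((id(n), w))
            _walk(c)

    _walk(tree.root)
    labels = sorted(leaves.values())
    index = {}
    for nid, lab in leaves.items():
        index[lab] = nid
    n = len(labels)
    d = np.zeros((n, n))
    for i, lab in enumerate(labels):
        dist = {index[lab]: 0.0}
        queue = deque([index[lab]])
        while queue:
            cur = queue.popleft()
            for nxt, w in adj.get(cur, []):
                if nxt not in dist:
                    dist[nxt] = dist[cur] + w
                    queue.append(nxt)
        for j, lab2 in enumerate(labels):
            d[i, j] = dist[index[lab2]]
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(labels, d)
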