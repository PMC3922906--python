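"""Protein distances, neighbor joining, bootstrap support, collapse.

The inference engine is distance-based: pairwise distances under either a
Poisson correction or the maximum-likelihood Jones-Taylor-Thornton (JTT)
model, neighbor-joining agglomeration, nonparametric bootstrap over alignment
columns with bipartition (split) counting, and contraction of weakly
supported internal edges into polytomies.

Determinism: neighbor joining breaks Q-criterion ties by the
lexicographically smallest pair of cluster tags (a cluster's tag is its
smallest contained leaf label), and each bootstrap replicate draws from an
independent RNG stream keyed by ``(seed, replicate index)``, so identical
inputs always give identical trees and supports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from . import _jtt
from .io_formats import GAP, Alignment, Node, SequenceRecord, Tree

__all__ = [
    "DistanceMatrix",
    "Bipartition",
    "BootstrapConfig",
    "NoSharedColumnsError",
    "p_distance",
    "model_distance",
    "alignment_distances",
    "neighbor_joining",
    "bipartitions",
    "support_from_trees",
    "bootstrap_support",
    "collapse_low_support",
]

#: Distances are capped here when saturation makes the estimate undefined.
MAX_DISTANCE = 10.0

#: Mismatch proportions at or above this are treated as saturated.
SATURATION_P = 0.95


class NoSharedColumnsError(ValueError):
    """Two aligned rows share no column in which both carry a residue."""


@dataclass
class DistanceMatrix:
    """A labelled symmetric matrix of pairwise distances."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} != ({n}, {n})")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if np.any(self.d < 0):
            raise ValueError("negative distances")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix has nonzero diagonal")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.d[i, j])


@dataclass(frozen=True)
class Bipartition:
    """A non-trivial split of the leaf set, canonicalized so that ``side``
    never contains the lexicographically smallest leaf label."""

    side: frozenset[str]


@dataclass
class BootstrapConfig:
    replicates: int = 1000
    seed: int = 0
    method: str = "nj"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.method != "nj":
            raise ValueError(f"unknown bootstrap method {self.method!r}")


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def p_distance(a: SequenceRecord, b: SequenceRecord) -> tuple[float, int]:
    """Mismatch proportion over columns where both rows carry a residue.

    Returns ``(p, n_shared)``. Raises :class:`NoSharedColumnsError` when the
    rows share no residue-bearing column.
    """
    if len(a.seq) != len(b.seq):
        raise ValueError("sequences must be aligned to equal length")
    n_shared = 0
    mismatches = 0
    for x, y in zip(a.seq, b.seq):
        if x == GAP or y == GAP:
            continue
        n_shared += 1
        if x != y:
            mismatches += 1
    if n_shared == 0:
        raise NoSharedColumnsError(f"no shared columns between {a.id!r} and {b.id!r}")
    return mismatches / n_shared, n_shared


def _pair_count_matrix(a: SequenceRecord, b: SequenceRecord) -> np.ndarray:
    """20x20 matrix of residue-pair counts (gaps and X excluded)."""
    xa = _encode_seq(a.seq)
    xb = _encode_seq(b.seq)
    mask = (xa >= 0) & (xb >= 0)
    if not mask.any():
        raise NoSharedColumnsError(f"no shared columns between {a.id!r} and {b.id!r}")
    flat = xa[mask] * 20 + xb[mask]
    return np.bincount(flat, minlength=400).reshape(20, 20).astype(float)


def _encode_seq(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(raw.shape, -1, dtype=np.int64)
    for aa, i in _jtt.AA_INDEX.items():
        out[raw == ord(aa)] = i
    return out


def _jtt_neg_loglik(d: float, counts: np.ndarray) -> float:
    p = _jtt.transition_matrix(d)
    joint = _jtt.JTT_FREQS[:, np.newaxis] * p
    with np.errstate(divide="ignore"):
        log_joint = np.log(joint)
    log_joint[np.isneginf(log_joint)] = -1e10
    return -float((counts * log_joint).sum())


def model_distance(
    p: float | None,
    model: str = "poisson",
    pair: tuple[SequenceRecord, SequenceRecord] | None = None,
) -> float:
    """Evolutionary distance (expected substitutions per site) from aligned
    sequences.

    ``model="poisson"`` applies the Poisson correction ``d = -ln(1 - p)`` to
    the mismatch proportion *p*. ``model="jtt_ml"`` maximizes the pairwise
    likelihood of the residue-pair counts under the JTT rate matrix by scalar
    optimization on ``[0, 10]`` (tolerance 1e-6); it requires ``pair``.

    Saturated comparisons (``p >= 0.95`` or an estimate at the bracket
    ceiling) are capped at 10.0 with a warning.
    """
    if model == "poisson":
        if p is None:
            raise ValueError("poisson model requires p")
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p out of [0,1]: {p}")
        if p >= SATURATION_P:
            warnings.warn(f"saturated pair (p={p:.3f}); distance capped at {MAX_DISTANCE}")
            return MAX_DISTANCE
        return -float(np.log1p(-p))
    if model == "jtt_ml":
        if pair is None:
            raise ValueError("jtt_ml model requires the aligned pair")
        a, b = pair
        counts = _pair_count_matrix(a, b)
        total = counts.sum()
        p_obs = (total - np.trace(counts)) / total
        if p_obs >= SATURATION_P:
            warnings.warn(
                f"saturated pair (p={p_obs:.3f}); distance capped at {MAX_DISTANCE}"
            )
            return MAX_DISTANCE
        res = minimize_scalar(
            _jtt_neg_loglik,
            bounds=(0.0, MAX_DISTANCE),
            args=(counts,),
            method="bounded",
            options={"xatol": 1e-6},
        )
        d = float(res.x)
        if d >= MAX_DISTANCE - 1e-3:
            warnings.warn(f"distance optimizer at ceiling; capped at {MAX_DISTANCE}")
            return MAX_DISTANCE
        return d
    raise ValueError(f"unknown distance model {model!r}")


def alignment_distances(aln: Alignment, model: str = "poisson") -> DistanceMatrix:
    """All pairwise distances of an alignment under the chosen model."""
    n = len(aln)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if model == "poisson":
                p, _ = p_distance(aln[i], aln[j])
                dij = model_distance(p, "poisson")
            else:
                dij = model_distance(None, model, pair=(aln[i], aln[j]))
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(aln.ids(), d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Neighbor-joining agglomeration of a distance matrix.

    At each step the pair minimizing ``Q(i,j) = (m-2) d(i,j) - r_i - r_j``
    is joined (ties broken by the lexicographically smallest pair of cluster
    tags); limb lengths follow the standard formulas, with negative limbs
    clamped to 0 and the deficit moved to the sibling limb. The result is an
    unrooted tree anchored at a final 3-way (2-way for n=2) multifurcation.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("neighbor joining requires at least 2 taxa")
    d = dm.d.copy()
    nodes: list[Node] = [Node(label=l) for l in dm.labels]
    tags: list[str] = list(dm.labels)
    active = list(range(n))

    def _pick_pair() -> tuple[int, int]:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, np.newaxis] - r[np.newaxis, :]
        # q[a,b] and q[b,a] can differ by one ulp (summation order); use the
        # upper triangle only so the minimum and the scan below agree exactly
        iu = np.triu_indices(m, k=1)
        qmin = q[iu].min()
        best: tuple[str, str] | None = None
        best_pair = (0, 1)
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] == qmin:
                    ta, tb = tags[active[a]], tags[active[b]]
                    key = (min(ta, tb), max(ta, tb))
                    if best is None or key < best:
                        best = key
                        best_pair = (a, b)
        return best_pair

    while len(active) > 3:
        m = len(active)
        a, b = _pick_pair()
        i, j = active[a], active[b]
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        dij = d[i, j]
        limb_i = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        limb_j = dij - limb_i
        if limb_i < 0:
            limb_j += -limb_i
            limb_i = 0.0
        if limb_j < 0:
            limb_i += -limb_j
            limb_j = 0.0
        parent = Node()
        ci, cj = nodes[i], nodes[j]
        ci.length, cj.length = limb_i, limb_j
        parent.add_child(ci)
        parent.add_child(cj)
        # distances from the new cluster to every other active cluster
        k = len(nodes)
        newrow = np.zeros(k + 1)
        for idx in active:
            if idx in (i, j):
                continue
            newrow[idx] = 0.5 * (d[i, idx] + d[j, idx] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[k, : k + 1] = newrow
        d[: k + 1, k] = newrow
        nodes.append(parent)
        tags.append(min(tags[i], tags[j]))
        active = [x for x in active if x not in (i, j)] + [k]

    root = Node()
    if len(active) == 2:
        i, j = active
        half = d[i, j] / 2.0
        nodes[i].length = half
        nodes[j].length = half
        root.add_child(nodes[i])
        root.add_child(nodes[j])
    else:
        i, j, k = active
        li = max(0.0, 0.5 * (d[i, j] + d[i, k] - d[j, k]))
        lj = max(0.0, 0.5 * (d[i, j] + d[j, k] - d[i, k]))
        lk = max(0.0, 0.5 * (d[i, k] + d[j, k] - d[i, j]))
        for idx, limb in zip((i, j, k), (li, lj, lk)):
            nodes[idx].length = limb
            root.add_child(nodes[idx])
    return Tree(root, rooted=False)


# ---------------------------------------------------------------------------
# Bipartitions and bootstrap
# ---------------------------------------------------------------------------


def bipartitions(tree: Tree) -> set[Bipartition]:
    """Canonical non-trivial bipartitions, one per internal edge of the tree
    viewed as unrooted. Invariant under re-rooting."""
    all_leaves = frozenset(tree.leaf_labels())
    n = len(all_leaves)
    if n < 4:
        return set()
    ref = min(all_leaves)
    out: set[Bipartition] = set()
    leaf_sets = tree.leaf_sets()
    for node in tree.postorder():
        if node is tree.root:
            continue
        side = leaf_sets[id(node)]
        if not 2 <= len(side) <= n - 2:
            continue
        if ref in side:
            side = all_leaves - side
        out.add(Bipartition(side))
    return out


def support_from_trees(reference: Tree, replicate_trees: list[Tree]) -> Tree:
    """Map split frequencies from replicate trees onto the reference.

    The support of each internal edge of the reference is the fraction of
    replicates whose bipartition set contains that edge's canonical
    bipartition (exact matches only).
    """
    if not replicate_trees:
        raise ValueError("no replicate trees")
    ref_leaves = frozenset(reference.leaf_labels())
    counts: dict[Bipartition, int] = {}
    for t in replicate_trees:
        if frozenset(t.leaf_labels()) != ref_leaves:
            raise ValueError("replicate leaf set differs from reference")
        for bp in bipartitions(t):
            counts[bp] = counts.get(bp, 0) + 1
    denom = len(replicate_trees)
    n = len(ref_leaves)
    ref = min(ref_leaves) if ref_leaves else ""
    annotated = reference.copy()
    leaf_sets = annotated.leaf_sets()
    for node in annotated.postorder():
        if node is annotated.root or node.is_leaf:
            continue
        side = leaf_sets[id(node)]
        if not 2 <= len(side) <= n - 2:
            continue
        if ref in side:
            side = frozenset(ref_leaves) - side
        node.support = counts.get(Bipartition(side), 0) / denom
    return annotated


def bootstrap_support(
    aln: Alignment,
    reference: Tree,
    cfg: BootstrapConfig | None = None,
    dist_model: str = "poisson",
) -> Tree:
    """Column-resampling bootstrap with split mapping onto the reference.

    Each replicate resamples ``length`` columns with replacement from an RNG
    stream keyed by ``(seed, replicate index)``, recomputes distances and a
    neighbor-joining tree, and the reference's internal edges receive the
    fraction of replicates containing their split. Replicates in which some
    pair of rows shares no residue-bearing column are dropped (with a
    warning) and the denominator reduced accordingly.
    """
    cfg = cfg or BootstrapConfig()
    if frozenset(aln.ids()) != frozenset(reference.leaf_labels()):
        raise ValueError("alignment ids and reference leaf labels differ")
    replicate_trees: list[Tree] = []
    for rep in range(cfg.replicates):
        rng = np.random.default_rng([cfg.seed, rep])
        cols = rng.integers(0, aln.length, size=aln.length)
        resampled = aln.select_columns(cols.tolist())
        try:
            dm = alignment_distances(resampled, model=dist_model)
        except NoSharedColumnsError:
            warnings.warn(f"replicate {rep} dropped: a pair shares no columns")
            continue
        replicate_trees.append(neighbor_joining(dm))
    if not replicate_trees:
        raise ValueError("every bootstrap replicate was dropped")
    return support_from_trees(reference, replicate_trees)


def collapse_low_support(tree: Tree, threshold: float = 0.75) -> Tree:
    """Contract internal edges whose support is <= *threshold* (strictly
    greater survives), producing polytomies.

    The contracted edge's length is discarded; retained edges keep their
    lengths, so leaf-to-leaf paths through surviving edges are unchanged.
    Internal edges without a support value are kept.
    """
    out = tree.copy()
    if not out.rooted and len(out.root.children) == 2:
        # the two root edges are one unrooted edge; unify their support
        c1, c2 = out.root.children
        sup = c1.support if c1.support is not None else c2.support
        c1.support = c2.support = sup
    for node in list(out.postorder()):
        if node is out.root or node.is_leaf:
            continue
        if node.support is not None and node.support <= threshold:
            parent = node.parent
            pos = parent.children.index(node)
            for c in node.children:
                c.parent = parent
            parent.children[pos : pos + 1] = node.children
            node.children = []
            node.parent = None
    return out
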