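"""Readers, writers and shared domain types.

Formats handled here: FASTA / aligned FASTA (protein), Newick trees with
support values in the internal-label position, 12-column tabular similarity
search hit files (the standard tabular BLAST-style output), and TSV taxonomy
tables mapping species abbreviations to taxonomic ranks.

Conventions
-----------
* Support values are stored as fractions in ``[0, 1]``; Newick inputs carrying
  percent supports (values > 1) are divided by 100 on read.
* Gap characters ``-`` and ``.`` are both accepted and normalized to ``-``.
  ``X`` counts as a residue, not a gap.
* Alignment columns are 0-based half-open programmatically; reports use
  1-based inclusive coordinates.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "RANKS",
    "PLANT_RANKS",
    "GAP",
    "FormatError",
    "SequenceRecord",
    "Alignment",
    "HitRecord",
    "TaxonomyTable",
    "Node",
    "Tree",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "read_hits",
    "write_hits",
    "read_newick",
    "write_newick",
    "parse_newick",
    "newick_string",
    "read_taxonomy",
    "write_taxonomy",
]

#: Closed vocabulary of taxonomic ranks used throughout the package.
RANKS = ("green_algae", "bryophyte", "lycophyte", "monocot", "eudicot", "nonplant")

#: The plant ranks (everything but the non-plant outgroup class).
PLANT_RANKS = frozenset(RANKS) - {"nonplant"}

GAP = "-"
_AA = set("ACDEFGHIKLMNPQRSTVWY")
_VALID_CHARS = _AA | {"X", GAP}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Sequences and alignments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceRecord:
    """A named protein sequence, possibly gapped when part of an alignment."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - _VALID_CHARS
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters: {sorted(bad)!r}"
            )

    def ungapped(self) -> str:
        return self.seq.replace(GAP, "")


class Alignment:
    """An ordered collection of equal-length gapped sequences."""

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if not records:
            raise ValueError("alignment must contain at least one sequence")
        length = len(records[0].seq)
        if length < 1:
            raise ValueError("alignment length must be >= 1")
        for r in records:
            if len(r.seq) != length:
                raise ValueError(
                    f"unequal sequence lengths: {r.id!r} has {len(r.seq)}, "
                    f"expected {length}"
                )
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids in alignment: {dup}")
        self.records: list[SequenceRecord] = records
        self.length: int = length

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def column(self, i: int) -> str:
        """Residues of 0-based column *i*, top to bottom."""
        return "".join(r.seq[i] for r in self.records)

    def select_columns(self, indices: Sequence[int]) -> "Alignment":
        """A new alignment restricted to the given 0-based columns, in order."""
        idx = list(indices)
        return Alignment(
            [SequenceRecord(r.id, "".join(r.seq[i] for i in idx)) for r in self.records]
        )

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Alignment) and self.records == other.records

    def __repr__(self) -> str:
        return f"<Alignment: {len(self)} sequences x {self.length} columns>"


def _normalize_seq(raw: str) -> str:
    return raw.upper().replace(".", GAP)


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    The id is the header token up to the first whitespace; sequences are
    uppercased and ``.`` gaps normalized to ``-``. Duplicate ids and empty
    sequences are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _normalize_seq(str(rec.seq))
        if not seq:
            raise FormatError(f"empty sequence for id {rec.id!r} in {path}")
        records.append(SequenceRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, os.fspath(path), "fasta")


def read_alignment(path: str | os.PathLike) -> Alignment:
    """Read an aligned FASTA file; all sequences must share one length."""
    return Alignment(read_fasta(path))


# ---------------------------------------------------------------------------
# Tabular hit files
# ---------------------------------------------------------------------------


@dataclass
class HitRecord:
    """One row of a 12-column tabular similarity-search output.

    ``pct_identity`` (percent, 0-100), ``aln_length`` and ``evalue`` are
    parsed; the remaining six columns are carried verbatim as strings so a
    read/write cycle reproduces the input bytes.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: str
    gap_opens: str
    q_start: str
    q_end: str
    s_start: str
    s_end: str
    evalue: float
    bitscore: str
    # original text of the parsed numeric columns, for verbatim round-trips
    _texts: tuple[str, str, str] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity out of range: {self.pct_identity}")
        if self.evalue < 0:
            raise ValueError(f"negative evalue: {self.evalue}")
        if self.aln_length < 1:
            raise ValueError(f"aln_length must be >= 1: {self.aln_length}")

    def to_fields(self) -> list[str]:
        if self._texts is not None:
            pid, alen, ev = self._texts
        else:
            pid = f"{self.pct_identity:g}"
            alen = str(self.aln_length)
            ev = f"{self.evalue:g}"
        return [
            self.query_id,
            self.subject_id,
            pid,
            alen,
            self.mismatches,
            self.gap_opens,
            self.q_start,
            self.q_end,
            self.s_start,
            self.s_end,
            ev,
            self.bitscore,
        ]


def read_hits(path: str | os.PathLike) -> list[HitRecord]:
    """Parse a 12-column tab-separated hit file; ``#`` comment lines allowed."""
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip() or stripped.lstrip().startswith("#"):
                continue
            fields = stripped.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                pid = float(fields[2])
                alen = int(fields[3])
                ev = float(fields[10])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable number: {exc}") from exc
            hits.append(
                HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=pid,
                    aln_length=alen,
                    mismatches=fields[4],
                    gap_opens=fields[5],
                    q_start=fields[6],
                    q_end=fields[7],
                    s_start=fields[8],
                    s_end=fields[9],
                    evalue=ev,
                    bitscore=fields[11],
                    _texts=(fields[2], fields[3], fields[10]),
                )
            )
    return hits


def write_hits(hits: Iterable[HitRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join(h.to_fields()) + "\n")


# ---------------------------------------------------------------------------
# Taxonomy tables
# ---------------------------------------------------------------------------


class TaxonomyTable:
    """Species abbreviation -> (species name, taxonomic rank).

    Sequence/leaf identifiers are mapped to species by the longest matching
    abbreviation prefix (ids follow the ``<abbrev><family>-<letter>`` or
    ``<abbrev>_g<n>`` conventions), so e.g. ``PrpNRT2-A`` resolves to ``Prp``
    even though ``P``-initial abbreviations overlap.
    """

    def __init__(self, entries: dict[str, tuple[str, str]]):
        for abbrev, (name, rank) in entries.items():
            if rank not in RANKS:
                raise ValueError(
                    f"unknown rank {rank!r} for {abbrev!r}; expected one of {RANKS}"
                )
        self._entries = dict(entries)
        # longest first so prefix matching is unambiguous
        self._by_length = sorted(self._entries, key=len, reverse=True)

    @property
    def abbreviations(self) -> list[str]:
        return list(self._entries)

    def __contains__(self, abbrev: str) -> bool:
        return abbrev in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def species_name(self, abbrev: str) -> str:
        return self._entries[abbrev][0]

    def rank(self, abbrev: str) -> str:
        if abbrev not in self._entries:
            raise KeyError(f"unknown species abbreviation {abbrev!r}")
        return self._entries[abbrev][1]

    def species_of_sequence(self, seq_id: str) -> str:
        """Resolve a sequence/leaf id to its species abbreviation."""
        for abbrev in self._by_length:
            if seq_id.startswith(abbrev):
                return abbrev
        raise KeyError(f"no species abbreviation matches sequence id {seq_id!r}")

    def rank_of_sequence(self, seq_id: str) -> str:
        return self.rank(self.species_of_sequence(seq_id))

    def items(self):
        return self._entries.items()


def read_taxonomy(path: str | os.PathLike) -> TaxonomyTable:
    """Read a TSV taxonomy table with header ``abbrev\\tspecies\\trank``."""
    entries: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.strip().lower() for h in header] != ["abbrev", "species", "rank"]:
            raise FormatError(
                f"{path}: expected header 'abbrev\\tspecies\\trank', got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            abbrev, species, rank = (f.strip() for f in fields)
            if abbrev in entries:
                raise FormatError(f"{path}:{lineno}: duplicate abbreviation {abbrev!r}")
            if rank not in RANKS:
                raise FormatError(
                    f"{path}:{lineno}: unknown rank {rank!r}; expected one of {RANKS}"
                )
            entries[abbrev] = (species, rank)
    return TaxonomyTable(entries)


def write_taxonomy(taxonomy: TaxonomyTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("abbrev\tspecies\trank\n")
        for abbrev, (species, rank) in taxonomy.items():
            fh.write(f"{abbrev}\t{species}\t{rank}\n")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


class Node:
    """A tree node: leaves carry a label, internal edges may carry support.

    ``length`` and ``support`` describe the edge above this node (toward the
    parent); both may be absent (``None``).
    """

    __slots__ = ("children", "parent", "length", "support", "label")

    def __init__(
        self,
        label: str | None = None,
        length: float | None = None,
        support: float | None = None,
        children: list["Node"] | None = None,
    ):
        if length is not None and length < 0:
            raise ValueError(f"negative branch length: {length}")
        if support is not None and not 0.0 <= support <= 1.0:
            raise ValueError(f"support out of [0,1]: {support}")
        self.label = label
        self.length = length
        self.support = support
        self.parent: Node | None = None
        self.children: list[Node] = []
        for c in children or []:
            self.add_child(c)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    def __repr__(self) -> str:
        kind = f"leaf {self.label!r}" if self.is_leaf else f"internal ({len(self.children)} children)"
        return f"<Node: {kind}>"


class Tree:
    """A rooted node structure; with ``rooted=False`` the root is semantically
    an arbitrary anchoring of an unrooted tree."""

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        labels = self.leaf_labels()
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate leaf labels: {dup}")

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    # -- utilities ---------------------------------------------------------

    def total_branch_length(self) -> float:
        return sum(
            n.length or 0.0 for n in self.postorder() if n is not self.root
        )

    def copy(self) -> "Tree":
        def _copy(node: Node) -> Node:
            new = Node(label=node.label, length=node.length, support=node.support)
            for c in node.children:
                new.add_child(_copy(c))
            return new

        return Tree(_copy(self.root), rooted=self.rooted)

    def leaf_sets(self) -> dict[int, frozenset[str]]:
        """Map ``id(node)`` -> set of leaf labels at or below each node."""
        out: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                out[id(node)] = frozenset([node.label])
            else:
                s: set[str] = set()
                for c in node.children:
                    s |= out[id(c)]
                out[id(node)] = frozenset(s)
        return out

    def prune_leaves(self, labels: Iterable[str]) -> "Tree":
        """A new tree with the given leaves removed and unary nodes spliced
        out (branch lengths summed). Raises if nothing would remain."""
        drop = set(labels)
        keep = [x for x in self.leaf_labels() if x not in drop]
        if not keep:
            raise ValueError("pruning would remove every leaf")
        tree = self.copy()

        def _prune(node: Node) -> Node | None:
            if node.is_leaf:
                return None if node.label in drop else node
            new_children = []
            for c in list(node.children):
                kept = _prune(c)
                if kept is not None:
                    new_children.append(kept)
            node.children = []
            for c in new_children:
                node.add_child(c)
            if not node.children:
                return None
            if len(node.children) == 1:
                child = node.children[0]
                if node.length is not None or child.length is not None:
                    child.length = (node.length or 0.0) + (child.length or 0.0)
                child.parent = None
                return child
            return node

        new_root = _prune(tree.root)
        assert new_root is not None
        new_root.parent = None
        new_root.length = None
        new_root.support = None
        return Tree(new_root, rooted=self.rooted)

    def __repr__(self) -> str:
        return f"<Tree: {len(self.leaf_labels())} leaves, rooted={self.rooted}>"


# -- Newick ---------------------------------------------------------------


def _from_dendropy(dnode: "dendropy.Node") -> Node:
    if dnode.is_leaf():
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        if label is None:
            raise FormatError("leaf without a label in Newick input")
        node = Node(label=label, length=dnode.edge.length)
    else:
        support = None
        raw = dnode.label
        if raw is not None:
            try:
                support = float(raw)
            except ValueError:
                raise FormatError(
                    f"internal node label {raw!r} is not a numeric support value"
                ) from None
            if support > 1.0:  # percent convention
                support /= 100.0
            if not 0.0 <= support <= 1.0:
                raise FormatError(f"support value out of range: {raw!r}")
        node = Node(length=dnode.edge.length, support=support)
        for child in dnode.child_nodes():
            node.add_child(_from_dendropy(child))
    return node


def parse_newick(text: str, rooted: bool = True) -> Tree:
    """Parse one Newick string. Internal-node labels are read as support
    values (percent inputs > 1 are converted to fractions)."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise FormatError(f"invalid Newick: {exc}") from exc
    root = _from_dendropy(dtree.seed_node)
    root.length = None
    root.support = None
    return Tree(root, rooted=rooted)


def read_newick(path: str | os.PathLike, rooted: bool = True) -> Tree:
    with open(path) as fh:
        return parse_newick(fh.read(), rooted=rooted)


_NEEDS_QUOTE = set("()[]{}:;,'\" \t\n")


def _format_label(label: str) -> str:
    if set(label) & _NEEDS_QUOTE:
        return "'" + label.replace("'", "''") + "'"
    return label


def _format_float(x: float) -> str:
    return format(x, ".12g")


def newick_string(tree: Tree) -> str:
    def _fmt(node: Node) -> str:
        if node.is_leaf:
            out = _format_label(node.label)
        else:
            out = "(" + ",".join(_fmt(c) for c in node.children) + ")"
            if node.support is not None and node.parent is not None:
                out += _format_float(node.support)
        if node.length is not None and node.parent is not None:
            out += ":" + _format_float(node.length)
        return out

    return _fmt(tree.root) + ";"


def write_newick(tree: Tree, path: str | os.PathLike | io.TextIOBase) -> None:
    text = newick_string(tree) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)
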