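"""Sequence- and column-level filtering.

Three screening stages precede tree building:

1. **Hit filtering** — candidate family members from a similarity search are
   accepted only if they share at least ``min_identity_pct`` percent identity
   with the query, have an E-value strictly below ``max_evalue``, and align
   over at least ``min_hit_coverage`` of the query length (the fragment rule).
2. **Gap filtering** — aligned sequences whose gap fraction strictly exceeds
   ``max_gap_fraction`` of the alignment length are excluded.
3. **Column trimming** — alignment columns whose reliability score falls
   below ``min_column_score`` are removed before distances are computed.

The column score is the fraction of residue pairs in a column with a positive
entry in a standard amino-acid log-odds matrix (BLOSUM62 by default): a
transparent, matrix-parameterized measure of local column similarity.
Columns with fewer than two residues score 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from .io_formats import GAP, Alignment, HitRecord

__all__ = ["FilterConfig", "filter_hits", "gap_filter", "column_scores", "trim_columns"]


@dataclass
class FilterConfig:
    """Thresholds for the three filtering stages.

    Defaults follow the screening regime the package implements: >= 30 %
    identity, E-value < 1e-50, hit coverage >= 50 % of the query, gap
    fraction <= 30 % of the alignment length, column score >= 0.40.
    """

    min_identity_pct: float = 30.0
    max_evalue: float = 1e-50
    min_hit_coverage: float = 0.5
    max_gap_fraction: float = 0.30
    min_column_score: float = 0.40
    similarity_matrix: str = "BLOSUM62"

    def __post_init__(self) -> None:
        for name in ("min_hit_coverage", "max_gap_fraction", "min_column_score"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 0.0 <= self.min_identity_pct <= 100.0:
            raise ValueError(f"min_identity_pct must be in [0,100]")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be > 0")


def filter_hits(
    hits: list[HitRecord],
    query_lengths: dict[str, int],
    cfg: FilterConfig | None = None,
) -> tuple[list[HitRecord], list[tuple[HitRecord, str]]]:
    """Partition hits into accepted and rejected-with-reason.

    A hit is accepted iff ``pct_identity >= min_identity_pct`` and
    ``evalue < max_evalue`` (strict) and
    ``aln_length >= min_hit_coverage * query_length``. Rejections carry the
    first failing criterion, tested in the order identity, evalue, coverage.
    """
    cfg = cfg or FilterConfig()
    accepted: list[HitRecord] = []
    rejected: list[tuple[HitRecord, str]] = []
    for hit in hits:
        if hit.query_id not in query_lengths:
            raise KeyError(f"no query length for {hit.query_id!r}")
        if hit.pct_identity < cfg.min_identity_pct:
            rejected.append((hit, "identity"))
        elif not hit.evalue < cfg.max_evalue:
            rejected.append((hit, "evalue"))
        elif hit.aln_length < cfg.min_hit_coverage * query_lengths[hit.query_id]:
            rejected.append((hit, "coverage"))
        else:
            accepted.append(hit)
    return accepted, rejected


def gap_filter(
    aln: Alignment, cfg: FilterConfig | None = None
) -> tuple[Alignment, list[str]]:
    """Drop sequences whose gap fraction strictly exceeds the threshold.

    A row with exactly ``max_gap_fraction * length`` gaps is kept (the rule
    excludes gaps *exceeding* the threshold). Row order is preserved.
    """
    cfg = cfg or FilterConfig()
    kept = []
    excluded: list[str] = []
    for rec in aln:
        gap_fraction = rec.seq.count(GAP) / aln.length
        if gap_fraction > cfg.max_gap_fraction:
            excluded.append(rec.id)
        else:
            kept.append(rec)
    if not kept:
        raise ValueError("alignment emptied: every sequence exceeds the gap threshold")
    return Alignment(kept), excluded


# -- column scoring --------------------------------------------------------

_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_CHAR_INDEX = {c: i for i, c in enumerate(_ALPHABET)}


@lru_cache(maxsize=None)
def _positive_pair_matrix(matrix_name: str) -> np.ndarray:
    """Boolean (21x21) table: True where the log-odds score is > 0."""
    m = substitution_matrices.load(matrix_name)
    out = np.zeros((len(_ALPHABET), len(_ALPHABET)), dtype=bool)
    for i, a in enumerate(_ALPHABET):
        for j, b in enumerate(_ALPHABET):
            try:
                out[i, j] = m[a, b] > 0
            except (KeyError, IndexError):
                out[i, j] = False
    return out


def column_scores(aln: Alignment, cfg: FilterConfig | None = None) -> np.ndarray:
    """Per-column reliability scores in ``[0, 1]``.

    ``score(c)`` is the number of unordered residue pairs in column *c* whose
    similarity-matrix entry is positive, divided by the number of unordered
    non-gap residue pairs. Columns with fewer than two residues score 0.
    """
    cfg = cfg or FilterConfig()
    if len(aln) < 2:
        raise ValueError("column scoring requires at least 2 sequences")
    positive = _positive_pair_matrix(cfg.similarity_matrix)
    k = len(_ALPHABET)

    # residue-type counts per column: counts[t, c]
    enc = np.full((len(aln), aln.length), -1, dtype=np.int16)
    for r, rec in enumerate(aln):
        row = np.frombuffer(rec.seq.encode("ascii"), dtype=np.uint8)
        for ch, idx in _CHAR_INDEX.items():
            enc[r, row == ord(ch)] = idx
    counts = np.zeros((k, aln.length), dtype=np.int64)
    for t in range(k):
        counts[t] = (enc == t).sum(axis=0)

    n_res = counts.sum(axis=0)
    total_pairs = n_res * (n_res - 1) // 2

    # pairs between distinct types a<b: n_a*n_b; within a type: n_a choose 2
    pos_pairs = np.zeros(aln.length, dtype=np.int64)
    for a in range(k):
        if positive[a, a]:
            pos_pairs += counts[a] * (counts[a] - 1) // 2
        for b in range(a + 1, k):
            if positive[a, b]:
                pos_pairs += counts[a] * counts[b]

    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(total_pairs > 0, pos_pairs / np.maximum(total_pairs, 1), 0.0)
    return scores


def trim_columns(
    aln: Alignment, cfg: FilterConfig | None = None
) -> tuple[Alignment, list[int]]:
    """Keep exactly the columns scoring at least ``min_column_score``.

    Returns the trimmed alignment and the kept 0-based column indices, in
    their original order. Raises if no column survives.
    """
    cfg = cfg or FilterConfig()
    scores = column_scores(aln, cfg)
    kept = [i for i in range(aln.length) if scores[i] >= cfg.min_column_score]
    if not kept:
        raise ValueError("column trimming removed every column")
    return aln.select_columns(kept), kept
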