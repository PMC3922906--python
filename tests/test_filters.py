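"""Hit acceptance, gap exclusion and column-trimming rules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from famclade.filters import (
    FilterConfig,
    column_scores,
    filter_hits,
    gap_filter,
    trim_columns,
)
from famclade.io_formats import Alignment, HitRecord, SequenceRecord


def make_hit(qid="q", sid="s", pid=50.0, alen=100, ev=1e-60) -> HitRecord:
    return HitRecord(qid, sid, pid, alen, "0", "0", "1", "100", "1", "100", ev, "200")


class TestFilterHits:
    QLEN = {"q": 100}

    def test_identity_boundary(self):
        accepted, rejected = filter_hits([make_hit(pid=29.9)], self.QLEN)
        assert accepted == [] and rejected[0][1] == "identity"
        accepted, _ = filter_hits([make_hit(pid=30.0)], self.QLEN)
        assert len(accepted) == 1  # "at least 30%" is inclusive

    def test_evalue_strictly_below_threshold(self):
        _, rejected = filter_hits([make_hit(pid=40, ev=1e-49)], self.QLEN)
        assert rejected[0][1] == "evalue"
        _, rejected = filter_hits([make_hit(pid=40, ev=1e-50)], self.QLEN)
        assert rejected[0][1] == "evalue"  # exactly at threshold: rejected
        accepted, _ = filter_hits([make_hit(pid=40, ev=1e-51)], self.QLEN)
        assert len(accepted) == 1

    def test_coverage_fragment_rule(self):
        _, rejected = filter_hits([make_hit(alen=49)], self.QLEN)
        assert rejected[0][1] == "coverage"
        accepted, _ = filter_hits([make_hit(alen=50)], self.QLEN)
        assert len(accepted) == 1

    def test_first_failing_reason_wins(self):
        _, rejected = filter_hits([make_hit(pid=10, ev=1.0, alen=1)], self.QLEN)
        assert rejected[0][1] == "identity"

    def test_empty_input(self):
        assert filter_hits([], {}) == ([], [])

    def test_missing_query_length_is_error(self):
        with pytest.raises(KeyError, match="q"):
            filter_hits([make_hit()], {})

    @given(
        pids=st.lists(st.floats(0, 100, allow_nan=False), min_size=0, max_size=20)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_partition_property(self, pids):
        hits = [make_hit(sid=f"s{i}", pid=p) for i, p in enumerate(pids)]
        accepted, rejected = filter_hits(hits, self.QLEN)
        assert len(accepted) + len(rejected) == len(hits)
        assert set(id(h) for h in accepted).isdisjoint(
            id(h) for h, _ in rejected
        )


class TestGapFilter:
    def _aln(self, *seqs):
        return Alignment([SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)])

    def test_strict_exceedance(self):
        full = "L" * 100
        with_31 = "L" * 69 + "-" * 31
        with_30 = "L" * 70 + "-" * 30
        kept, excluded = gap_filter(self._aln(full, with_31, with_30))
        assert excluded == ["s1"]  # 31% excluded, exactly 30% kept
        assert kept.ids() == ["s0", "s2"]

    def test_ungapped_alignment_untouched(self):
        aln = self._aln("MKL", "MVL")
        kept, excluded = gap_filter(aln)
        assert excluded == [] and kept.ids() == aln.ids()

    def test_all_excluded_is_error(self):
        with pytest.raises(ValueError, match="emptied"):
            gap_filter(self._aln("----L", "----V"))

    def test_order_preserved(self):
        aln = self._aln("MMMMMMMMMM", "M---------", "MMMMMMMMMV")
        kept, _ = gap_filter(aln)
        assert kept.ids() == ["s0", "s2"]


class TestColumnScores:
    def test_identical_column_scores_one(self):
        aln = Alignment([SequenceRecord(f"s{i}", "L") for i in range(5)])
        assert column_scores(aln)[0] == 1.0

    def test_all_gap_column_scores_zero(self):
        aln = Alignment(
            [SequenceRecord("a", "L-"), SequenceRecord("b", "L-")]
        )
        assert column_scores(aln)[1] == 0.0

    def test_single_residue_column_scores_zero(self):
        aln = Alignment(
            [SequenceRecord("a", "L"), SequenceRecord("b", "-"), SequenceRecord("c", "-")]
        )
        assert column_scores(aln)[0] == 0.0

    def test_two_and_two_column(self):
        # L/L and D/D pair positively under BLOSUM62; the four L/D pairs do
        # not: 2 positive of 6 total pairs.
        aln = Alignment(
            [
                SequenceRecord("a", "L"),
                SequenceRecord("b", "L"),
                SequenceRecord("c", "D"),
                SequenceRecord("d", "D"),
            ]
        )
        assert column_scores(aln)[0] == pytest.approx(2 / 6)


class TestTrimColumns:
    def _fixture(self):
        # columns 2 and 4 engineered to score < 0.40 (L vs D vs K mixtures)
        rows = [
            "MKLDL",
            "MKDDL",
            "MKLKL",
            "MKDKL",
        ]
        return Alignment([SequenceRecord(f"s{i}", r) for i, r in enumerate(rows)])

    def test_engineered_low_columns_dropped(self):
        aln = self._fixture()
        scores = column_scores(aln)
        trimmed, kept = trim_columns(aln)
        assert 2 not in kept and 3 not in kept
        assert all(scores[c] >= 0.40 for c in kept)
        assert trimmed.length == len(kept)

    def test_identical_sequences_keep_all(self):
        aln = Alignment([SequenceRecord(f"s{i}", "MKLV") for i in range(3)])
        _, kept = trim_columns(aln)
        assert kept == [0, 1, 2, 3]

    def test_idempotent(self):
        aln = self._fixture()
        once, kept1 = trim_columns(aln)
        twice, kept2 = trim_columns(once)
        assert [r.seq for r in twice] == [r.seq for r in once]
        assert kept2 == list(range(once.length))

    def test_nothing_survives_is_error(self):
        aln = Alignment([SequenceRecord("a", "L"), SequenceRecord("b", "D")])
        with pytest.raises(ValueError, match="every column"):
            trim_columns(aln)

    @given(threshold=st.floats(0.0, 1.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_lower_threshold_keeps_superset(self, threshold):
        aln = self._fixture()
        base = FilterConfig(min_column_score=threshold)
        try:
            _, kept_hi = trim_columns(aln, base)
        except ValueError:
            kept_hi = []
        _, kept_lo = trim_columns(aln, FilterConfig(min_column_score=0.0))
        assert set(kept_hi) <= set(kept_lo)
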