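"""Distances, neighbor joining, bipartitions, bootstrap, collapse."""

from __future__ import annotations

import numpy as np
import pytest

from famclade.io_formats import Alignment, SequenceRecord, parse_newick
from famclade.phylo_core import (
    Bipartition,
    BootstrapConfig,
    DistanceMatrix,
    NoSharedColumnsError,
    alignment_distances,
    bipartitions,
    bootstrap_support,
    collapse_low_support,
    model_distance,
    neighbor_joining,
    p_distance,
    support_from_trees,
)
from famclade.simulate import evolve_pair
from famclade.clans import root_by_outgroup

from conftest import path_distance_matrix, random_binary_tree


class TestPDistance:
    def test_identical(self):
        a = SequenceRecord("a", "ACDEFGHIKL")
        assert p_distance(a, SequenceRecord("b", "ACDEFGHIKL")) == (0.0, 10)

    def test_two_of_ten(self):
        a = SequenceRecord("a", "ACDEFGHIKL")
        b = SequenceRecord("b", "ACDEFGHIAA")
        assert p_distance(a, b) == (0.2, 10)

    def test_gaps_excluded_from_shared_columns(self):
        # 13 columns; 3 have a gap in one row; of the 10 shared, 3 differ
        a = SequenceRecord("a", "ACDEFGHIKLMNP")
        b2 = SequenceRecord("b", "ACD--GHIKWWW-")
        p, n = p_distance(a, b2)
        assert n == 10 and p == pytest.approx(0.3)

    def test_no_shared_columns(self):
        with pytest.raises(NoSharedColumnsError):
            p_distance(SequenceRecord("a", "A-"), SequenceRecord("b", "-A"))


class TestModelDistance:
    def test_zero_p_both_models(self):
        assert model_distance(0.0, "poisson") == 0.0
        a = SequenceRecord("a", "ACDEFGHIKL" * 5)
        assert model_distance(None, "jtt_ml", pair=(a, a)) == pytest.approx(
            0.0, abs=1e-4
        )

    def test_poisson_closed_form(self):
        assert model_distance(0.5, "poisson") == pytest.approx(np.log(2))

    def test_saturation_caps(self):
        with pytest.warns(UserWarning, match="capped"):
            assert model_distance(0.97, "poisson") == 10.0

    @pytest.mark.parametrize("seed", range(15))
    def test_jtt_ml_recovers_simulated_distance(self, seed):
        a, b = evolve_pair(0.5, 10000, seed)
        d = model_distance(None, "jtt_ml", pair=(a, b))
        assert d == pytest.approx(0.5, abs=0.05)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]),
        )
        t = neighbor_joining(dm)
        limbs = {c.label: c.length for c in t.root.children}
        assert limbs["A"] == pytest.approx(0.05)
        assert limbs["B"] == pytest.approx(0.15)
        assert limbs["C"] == pytest.approx(0.25)

    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 0.4], [0.4, 0]]))
        t = neighbor_joining(dm)
        d = path_distance_matrix(t)
        assert d[("A", "B")] == pytest.approx(0.4)

    def test_quartet_additive_recovery(self):
        gen = parse_newick("((A:0.1,B:0.2):0.1,(C:0.3,D:0.4):0.0);", rooted=False)
        dm = path_distance_matrix(gen)
        t = neighbor_joining(dm)
        assert bipartitions(t) == {Bipartition(frozenset({"C", "D"}))}
        assert np.allclose(path_distance_matrix(t).d, dm.d, atol=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_consistency_on_additive_distances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        gen = random_binary_tree([f"t{i:02d}" for i in range(n)], rng)
        dm = path_distance_matrix(gen)
        t = neighbor_joining(dm)
        assert bipartitions(t) == bipartitions(gen)
        assert np.allclose(path_distance_matrix(t).d, dm.d, atol=1e-9)

    def test_agrees_with_independent_nj_implementation(self):
        """Cross-check topology against dendropy's neighbor joining."""
        import dendropy

        rng = np.random.default_rng(42)
        gen = random_binary_tree([f"t{i}" for i in range(8)], rng)
        dm = path_distance_matrix(gen)
        csv = "," + ",".join(dm.labels) + "\n"
        for i, lab in enumerate(dm.labels):
            csv += lab + "," + ",".join(str(x) for x in dm.d[i]) + "\n"
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv), delimiter=","
        )
        dtree = pdm.nj_tree()
        ours = neighbor_joining(dm)
        theirs = parse_newick(
            dtree.as_string(schema="newick").replace("[&U] ", ""), rooted=False
        )
        assert bipartitions(ours) == bipartitions(theirs)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], np.array([[0, 1.0], [2.0, 0]]))


class TestBipartitions:
    def test_quartet_single_split(self):
        t = parse_newick("((A,B),(C,D));", rooted=False)
        assert bipartitions(t) == {Bipartition(frozenset({"C", "D"}))}

    def test_star_tree_empty(self):
        t = parse_newick("(A,B,C,D,E);", rooted=False)
        assert bipartitions(t) == set()

    @pytest.mark.parametrize("seed", range(10))
    def test_binary_tree_has_n_minus_3(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        t = random_binary_tree([f"t{i}" for i in range(n)], rng)
        assert len(bipartitions(t)) == n - 3

    @pytest.mark.parametrize("seed", range(8))
    def test_invariant_under_rerooting(self, seed):
        rng = np.random.default_rng(seed)
        t = random_binary_tree([f"t{i}" for i in range(7)], rng)
        before = bipartitions(t)
        for leaf in ("t0", "t3", "t6"):
            rerooted = root_by_outgroup(t, {leaf})
            assert bipartitions(rerooted) == before


def _zero_noise_alignment() -> tuple[Alignment, "object"]:
    """Alignment whose every bootstrap replicate yields the same NJ tree:
    half the columns split the two cherries, half separate every row."""
    cols_split = ["A", "A", "C", "C"]
    cols_all = ["D", "E", "F", "G"]
    seqs = ["".join(cols_split[i] * 50 + cols_all[i] * 50) for i in range(4)]
    aln = Alignment(
        [SequenceRecord(l, s) for l, s in zip(["a1", "a2", "b1", "b2"], seqs)]
    )
    ref = neighbor_joining(alignment_distances(aln))
    return aln, ref


class TestBootstrap:
    def test_forced_replicates_give_fractional_support(self):
        ref = parse_newick("((A,B),(C,D));", rooted=False)
        reps = [
            parse_newick("((A,B),(C,D));", rooted=False),
            parse_newick("((B,A),(D,C));", rooted=False),
            parse_newick("((A,C),(B,D));", rooted=False),
        ]
        out = support_from_trees(ref, reps)
        sup = [n.support for n in out.postorder() if n.support is not None]
        assert sup == [pytest.approx(2 / 3)] * len(sup)

    def test_zero_noise_alignment_all_supports_one(self):
        aln, ref = _zero_noise_alignment()
        out = bootstrap_support(aln, ref, BootstrapConfig(replicates=100, seed=5))
        sup = [n.support for n in out.postorder() if n.support is not None]
        assert sup and all(s == 1.0 for s in sup)

    def test_reproducible_for_same_seed(self):
        rng = np.random.default_rng(0)
        cfg = BootstrapConfig(replicates=30, seed=11)
        from famclade.simulate import SimConfig, simulate_family

        res = simulate_family(SimConfig(seq_length=120, seed=3))
        aln = Alignment(res.records)
        ref = neighbor_joining(alignment_distances(aln))
        s1 = bootstrap_support(aln, ref, cfg)
        s2 = bootstrap_support(aln, ref, cfg)
        sup1 = [n.support for n in s1.postorder() if n.support is not None]
        sup2 = [n.support for n in s2.postorder() if n.support is not None]
        assert sup1 == sup2
        assert all(0.0 <= s <= 1.0 for s in sup1)


class TestCollapse:
    def test_full_support_unchanged(self):
        t = parse_newick("(((A,B)1.0,C)1.0,(D,E)1.0);", rooted=False)
        out = collapse_low_support(t)
        assert bipartitions(out) == bipartitions(t)

    def test_exact_threshold_collapses(self):
        t = parse_newick("((A,B)0.75,(C,D));", rooted=False)
        out = collapse_low_support(t, 0.75)
        assert bipartitions(out) == set()  # strict '>' keeps nothing at 0.75

    def test_above_threshold_survives(self):
        t = parse_newick("((A,B)0.76,(C,D));", rooted=False)
        out = collapse_low_support(t, 0.75)
        assert bipartitions(out) == {Bipartition(frozenset({"C", "D"}))}

    def test_collapse_all_gives_star(self):
        t = parse_newick("(((A,B)0.1,C)0.2,(D,E)0.3);", rooted=False)
        out = collapse_low_support(t, 0.75)
        assert len(out.root.children) == 5
        assert sorted(out.leaf_labels()) == ["A", "B", "C", "D", "E"]

    def test_leafset_and_retained_paths_preserved(self):
        t = parse_newick("(((A:1,B:1)0.9:1,C:1)0.3:1,(D:1,E:1)0.8:1);", rooted=False)
        out = collapse_low_support(t, 0.75)
        assert sorted(out.leaf_labels()) == sorted(t.leaf_labels())
        # the 0.9 and 0.8 edges survive with their lengths
        d = path_distance_matrix(out)
        assert d[("A", "B")] == pytest.approx(2.0)
        assert d[("D", "E")] == pytest.approx(2.0)
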