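"""Rank-ladder reconciliation and group/supergroup assignment."""

from __future__ import annotations

import numpy as np
import pytest

from famclade.classify import (
    classify,
    compare_partitions,
    find_group_roots,
    find_supergroup_roots,
    ladder_lca,
    lca_map,
    roman,
)
from famclade.io_formats import parse_newick
from famclade.simulate import SimConfig, sim_taxonomy, simulate_family


class TestLadder:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("eudicot", "monocot", "angiosperm"),
            ("eudicot", "eudicot", "eudicot"),
            ("eudicot", "lycophyte", "vascular"),
            ("monocot", "bryophyte", "embryophyte"),
            ("green_algae", "eudicot", "viridiplantae"),
            ("angiosperm", "lycophyte", "vascular"),
        ],
    )
    def test_lca(self, a, b, expected):
        assert ladder_lca(a, b) == expected == ladder_lca(b, a)


class TestLcaMap:
    def test_ladder_tree_all_speciations(self, mini_taxonomy):
        t = parse_newick("(a1,(b1,(l1,(m1,e1))));")
        ann = lca_map(t, mini_taxonomy)
        internal = [a for a in ann.values() if a.event != "leaf"]
        assert all(a.event == "speciation" for a in internal)
        assert sorted(a.mapping for a in internal) == [
            "angiosperm",
            "embryophyte",
            "vascular",
            "viridiplantae",
        ]

    def test_eudicot_cherry_is_duplication(self, mini_taxonomy):
        ann = lca_map(parse_newick("(e1,e2);"), mini_taxonomy)
        root_ann = [a for a in ann.values() if a.event != "leaf"][0]
        assert (root_ann.mapping, root_ann.event) == ("eudicot", "duplication")

    def test_eudicot_monocot_node_is_angiosperm_speciation(self, mini_taxonomy):
        ann = lca_map(parse_newick("(e1,m1);"), mini_taxonomy)
        root_ann = [a for a in ann.values() if a.event != "leaf"][0]
        assert (root_ann.mapping, root_ann.event) == ("angiosperm", "speciation")

    def test_nonplant_leaf_rejected(self, mini_taxonomy):
        with pytest.raises(ValueError, match="prune outgroup"):
            lca_map(parse_newick("(n1,e1);"), mini_taxonomy)


class TestGroupRoots:
    def test_ladder_tree_single_group(self, mini_taxonomy):
        t = parse_newick("(a1,(b1,(l1,(m1,e1))));")
        ann = lca_map(t, mini_taxonomy)
        groups, unplaced = find_group_roots(t, ann)
        assert len(groups) == 1
        # the group root is the (m1, e1) cherry
        labels = {l.label for l in _leaves(groups[0])}
        assert labels == {"m1", "e1"}

    def test_angiosperm_duplication_gives_two_groups(self, mini_taxonomy):
        t = parse_newick("(((e1,m1),(e2,m2)),b1);")
        ann = lca_map(t, mini_taxonomy)
        groups, _ = find_group_roots(t, ann)
        assert len(groups) == 2

    def test_polytomy_speciation_gives_single_group(self, mini_taxonomy):
        # unresolved angiosperm node with eudicot, eudicot, monocot children:
        # no child maps to angiosperm, so it is a speciation -> one group
        t = parse_newick("(((e1,e2),e3,(m1,m2)),b1);")
        ann = lca_map(t, mini_taxonomy)
        groups, _ = find_group_roots(t, ann)
        assert len(groups) == 1
        assert {l.label for l in _leaves(groups[0])} == {"e1", "e2", "e3", "m1", "m2"}


class TestSupergroupRoots:
    def test_embryophyte_duplication_gives_two_supergroups(self, mini_taxonomy):
        t = parse_newick("((b1,(e1,m1)),(b2,(e2,m2)));")
        ann = lca_map(t, mini_taxonomy)
        roots, _ = find_supergroup_roots(t, ann)
        assert len(roots) == 2

    def test_angiosperm_duplication_stays_in_one_supergroup(self, mini_taxonomy):
        t = parse_newick("(((e1,m1),(e2,m2)),b1);")
        ann = lca_map(t, mini_taxonomy)
        roots, _ = find_supergroup_roots(t, ann)
        assert len(roots) == 1

    def test_ladder_tree_single_supergroup(self, mini_taxonomy):
        t = parse_newick("(a1,(b1,(l1,(m1,e1))));")
        ann = lca_map(t, mini_taxonomy)
        roots, unplaced = find_supergroup_roots(t, ann)
        assert len(roots) == 1
        # the algal leaf is an unplaced lineage-specific clade
        assert [l.label for u in unplaced for l in _leaves(u)] == ["a1"]


class TestClassify:
    def test_ladder_tree_labels(self, mini_taxonomy):
        t = parse_newick("(a1,(b1,(l1,(m1,e1))));")
        result = classify(t, mini_taxonomy)
        assert result.leaves["e1"].label == "A-I E"
        assert result.leaves["m1"].label == "A-I M"
        assert result.leaves["b1"].half is None

    def test_two_group_partition_structure(self, mini_taxonomy):
        t = parse_newick("(((e1,m1),(e2,m2)),b1);")
        result = classify(t, mini_taxonomy)
        part = result.group_partition()
        assert part["e1"] == part["m1"]
        assert part["e2"] == part["m2"]
        assert part["e1"] != part["e2"]
        assert {g for _, g in part.values()} == {"I", "II"}

    def test_no_duplication_single_group(self):
        cfg = SimConfig(dup_rate=0.0, loss_rate=0.0, seq_length=10, seed=2)
        res = simulate_family(cfg)
        result = classify(res.true_tree, sim_taxonomy(cfg))
        part = result.group_partition()
        assert set(v for v in part.values()) == {("A", "I")}

    def test_nonplant_leaves_pruned_automatically(self, mini_taxonomy):
        t = parse_newick("((n1,n2),(a1,(b1,(l1,(m1,e1)))));")
        result = classify(t, mini_taxonomy)
        assert "n1" not in result.leaves
        assert result.leaves["e1"].label == "A-I E"

    def test_invariant_to_child_order(self, mini_taxonomy):
        t1 = parse_newick("(((e1,m1),(e2,m2)),b1);")
        t2 = parse_newick("(b1,((m2,e2),(m1,e1)));")
        p1 = classify(t1, mini_taxonomy).group_partition()
        p2 = classify(t2, mini_taxonomy).group_partition()
        assert p1 == p2

    def test_anchor_pins_supergroup_letter(self, mini_taxonomy):
        t = parse_newick("((b1,(e1,m1)),(b2,(e2,m2)));")
        result = classify(t, mini_taxonomy, anchors={"e2": "A"})
        assert result.leaves["e2"].supergroup == "A"
        assert result.leaves["e1"].supergroup == "B"

    def test_collapse_before_classify_can_only_merge(self, mini_taxonomy):
        # weakly supported (e,m) cherries collapse into one polytomy that
        # maps to angiosperm as a speciation: two groups merge into one
        t = parse_newick("(((e1,m1)0.3,(e2,m2)0.3)0.9,b1);")
        sharp = classify(t, mini_taxonomy).group_partition()
        merged = classify(t, mini_taxonomy, collapse_threshold=0.75).group_partition()
        assert len({v for v in sharp.values()}) == 2
        assert len({v for v in merged.values()}) == 1


class TestComparePartitions:
    def test_identical(self, mini_taxonomy):
        cfg = SimConfig(dup_rate=0.3, loss_rate=0.0, seq_length=10, seed=9)
        res = simulate_family(cfg)
        result = classify(res.true_tree, sim_taxonomy(cfg))
        assert compare_partitions(result, res.truth) == (True, 0, 0)

    def test_merge_counted(self, mini_taxonomy):
        t = parse_newick("(((e1,m1),(e2,m2)),b1);")
        merged = classify(t, mini_taxonomy, collapse_threshold=None)

        class FakeTruth:
            true_group = {"e1": 1, "m1": 1, "e2": 2, "m2": 2}

        # collapse the cherries so both truth groups land in one polytomy
        flat = parse_newick("(((e1,m1)0.5,(e2,m2)0.5)0.9,b1);")
        coarse = classify(flat, mini_taxonomy, collapse_threshold=0.75)
        exact, merges, splits = compare_partitions(coarse, FakeTruth)
        assert (exact, merges, splits) == (False, 1, 0)

    def test_leafset_mismatch_is_error(self, mini_taxonomy):
        t = parse_newick("((e1,m1),b1);")
        result = classify(t, mini_taxonomy)

        class FakeTruth:
            true_group = {"e1": 1, "m1": 1, "e9": 1}

        with pytest.raises(ValueError, match="differ"):
            compare_partitions(result, FakeTruth)

    @pytest.mark.parametrize("seed", range(25))
    def test_true_tree_mu0_exact_and_lossy_coarsening(self, seed):
        cfg0 = SimConfig(dup_rate=0.4, loss_rate=0.0, seq_length=5, seed=seed)
        res0 = simulate_family(cfg0)
        r0 = classify(res0.true_tree, sim_taxonomy(cfg0))
        assert compare_partitions(r0, res0.truth)[0] is True

        cfg1 = SimConfig(dup_rate=0.4, loss_rate=0.25, seq_length=5, seed=seed)
        res1 = simulate_family(cfg1)
        r1 = classify(res1.true_tree, sim_taxonomy(cfg1))
        _, _, splits = compare_partitions(r1, res1.truth)
        assert splits == 0


class TestCollapseCoarsening:
    @pytest.mark.parametrize("seed", range(20))
    def test_within_group_collapse_leaves_partition_unchanged(self, seed):
        """Low supports strictly inside groups: contracting within-group
        edges rearranges a group internally but cannot move any leaf
        between groups, so the angiosperm partition is identical."""
        cfg = SimConfig(dup_rate=0.5, loss_rate=0.1, seq_length=5, seed=seed)
        res = simulate_family(cfg)
        tax = sim_taxonomy(cfg)
        tree = res.true_tree
        sharp_result = classify(tree, tax)
        inside: set[int] = set()
        for groups in sharp_result.group_roots.values():
            for root in groups.values():
                stack = list(root.children)
                while stack:
                    n = stack.pop()
                    if not n.is_leaf:
                        inside.add(id(n))
                        stack.extend(n.children)
        rng = np.random.default_rng(seed + 1000)
        for node in tree.postorder():
            if node.is_leaf or node is tree.root:
                continue
            node.support = (
                float(rng.uniform(0, 1)) if id(node) in inside else 1.0
            )
        sharp = classify(tree, tax).group_partition()
        coarse = classify(tree, tax, collapse_threshold=0.75).group_partition()
        assert coarse == sharp


class TestNaming:
    def test_roman_numerals(self):
        assert [roman(i) for i in (1, 2, 3, 4, 9, 14, 40)] == [
            "I", "II", "III", "IV", "IX", "XIV", "XL",
        ]

    def test_letters_deterministic_by_size_then_leaf(self, mini_taxonomy):
        # left supergroup is smaller: letters assigned by descending size
        t = parse_newick("((b1,(e1,m1)),(b2,((e2,m2),(e3,m1x))));")
        import famclade.io_formats as io

        tax = io.TaxonomyTable(
            {
                "e1": ("", "eudicot"), "e2": ("", "eudicot"), "e3": ("", "eudicot"),
                "m1x": ("", "monocot"), "m1": ("", "monocot"), "m2": ("", "monocot"),
                "b1": ("", "bryophyte"), "b2": ("", "bryophyte"),
            }
        )
        result = classify(t, tax)
        assert result.leaves["e2"].supergroup == "A"  # larger clade
        assert result.leaves["e1"].supergroup == "B"


def _leaves(node):
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        stack.extend(n.children)
    return out
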