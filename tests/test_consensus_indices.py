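"""Outgroup rooting, majority-rule consensus, and CI/RI computations."""

import numpy as np
import pytest

from morphoclad import (
    PhyloTree,
    RootedPhyloTree,
    character_max_steps,
    character_min_steps,
    fitch_length,
    homoplasy_indices,
    ingroup_node,
    majority_rule_consensus,
    root_with_outgroup,
)
from morphoclad.synthetic_data import perfect_signal_matrix

from helpers import make_matrix, random_binary_tree, random_matrix, star_tree


class TestRooting:
    def test_monophyletic_outgroup_splits_root(self):
        t = PhyloTree.from_newick("(((A,B),(C,D)),(O1,O2));")
        rooted = root_with_outgroup(t, ["O1", "O2"])
        assert rooted.meta["outgroup_monophyletic"] is True
        kids = {rooted.clade_leaves(c) for c in rooted.children[rooted.root]}
        assert kids == {frozenset({"O1", "O2"}), frozenset({"A", "B", "C", "D"})}
        assert rooted.clades()[ingroup_node(rooted)] == frozenset("ABCD")

    def test_single_taxon_outgroup_roots_on_pendant_branch(self):
        t = PhyloTree.from_newick("((A,B),(C,O));")
        rooted = root_with_outgroup(t, ["O"])
        assert rooted.meta["outgroup_monophyletic"] is True
        kids = {rooted.clade_leaves(c) for c in rooted.children[rooted.root]}
        assert frozenset({"O"}) in kids

    def test_nonmonophyletic_outgroup_flagged(self):
        # O1 and O2 separated by ingroup taxa on the unrooted tree
        t = PhyloTree.from_newick("((A,O1),(B,O2));")
        rooted = root_with_outgroup(t, ["O1", "O2"])
        assert rooted.meta["outgroup_monophyletic"] is False

    def test_whole_taxon_set_outgroup_rejected(self):
        t = PhyloTree.from_newick("((A,B),(C,D));")
        with pytest.raises(ValueError):
            root_with_outgroup(t, list("ABCD"))


class TestConsensus:
    def test_identical_trees_full_supports(self):
        trees = [PhyloTree.from_newick("((A,B),(C,D));") for _ in range(3)]
        cons = majority_rule_consensus(trees)
        index = trees[0].taxon_index()
        assert cons.tree.splits(index) == trees[0].splits(index)
        assert set(cons.supports.values()) == {100.0}

    def test_two_to_one_majority_retains_ab(self):
        trees = [
            PhyloTree.from_newick("((A,B),C,D);"),
            PhyloTree.from_newick("((A,B),C,D);"),
            PhyloTree.from_newick("((A,C),B,D);"),
        ]
        cons = majority_rule_consensus(trees)
        assert len(cons.supports) == 1
        (clade, support), = cons.supports.items()
        assert clade in (frozenset({"A", "B"}), frozenset({"C", "D"}))
        assert support == pytest.approx(200 / 3, abs=0.01)

    def test_exactly_half_clade_excluded(self):
        trees = [
            PhyloTree.from_newick("((A,B),(C,D));"),
            PhyloTree.from_newick("((A,C),(B,D));"),
        ]
        cons = majority_rule_consensus(trees)
        assert cons.supports == {}
        assert cons.tree.internal_edges() == []

    def test_supports_invariant_under_tree_order(self, rng):
        taxa = [f"t{i}" for i in range(8)]
        trees = [random_binary_tree(taxa, rng) for _ in range(7)]
        a = majority_rule_consensus(trees)
        b = majority_rule_consensus(list(reversed(trees)))
        assert a.supports == b.supports

    def test_taxon_set_mismatch_rejected(self):
        trees = [
            PhyloTree.from_newick("((A,B),(C,D));"),
            PhyloTree.from_newick("((A,B),(C,E));"),
        ]
        with pytest.raises(ValueError, match="taxon set"):
            majority_rule_consensus(trees)

    def test_consensus_clades_compatible_and_scorable(self, rng):
        """Retained clades nest into a valid (possibly polytomous) tree whose
        length is computable."""
        taxa = [f"t{i}" for i in range(10)]
        trees = [random_binary_tree(taxa, rng) for _ in range(9)]
        cons = majority_rule_consensus(trees)
        assert cons.tree.taxa() == sorted(taxa)
        m = random_matrix(taxa, n_chars=5, rng=rng)
        assert fitch_length(cons.tree, m).sum() >= 0


class TestStepBounds:
    @pytest.mark.parametrize(
        "column, m, g",
        [
            (["0", "1", "0", "1"], 1, 2),
            (["0", "1", "2", "3"], 3, 3),
            (["0"] * 317 + ["1"], 1, 1),
            (["0", "0", "0", "1", "2"], 2, 2),
            (["0", "0", "1", "1", "?"], 1, 2),
            (["0", "0", "0"], 0, 0),
        ],
    )
    def test_min_and_max_steps(self, column, m, g):
        assert character_min_steps(column) == m
        assert character_max_steps(column) == g

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            character_min_steps(["?", "?"])
        with pytest.raises(ValueError):
            character_max_steps(["?", "?"])

    def test_max_steps_equals_star_tree_fitch_length(self, rng):
        """Cross-module oracle: g_i is the star-tree length of the column."""
        for _ in range(20):
            n = int(rng.integers(4, 12))
            taxa = [f"t{i}" for i in range(n)]
            m = random_matrix(taxa, n_chars=1, rng=rng, missing_rate=0.2)
            col = list(m.cells[:, 0])
            if all(c == "?" for c in col):
                continue
            star = star_tree(taxa)
            assert character_max_steps(col) == int(fitch_length(star, m)[0])


class TestHomoplasyIndices:
    def test_perfect_signal_gives_unity(self):
        rt = RootedPhyloTree.from_newick("(((A,B),C),((D,E),F));")
        m = perfect_signal_matrix(rt)
        idx = homoplasy_indices(m, rt.unroot())
        assert idx.CI == pytest.approx(1.0)
        assert idx.RI == pytest.approx(1.0)
        assert (idx.per_character["ci"] == 1.0).all()

    def test_binary_character_changing_twice_has_ci_half(self):
        # parallel gains in B and D: two steps where one would suffice
        t = PhyloTree.from_newick("((A,B),(C,D));")
        m = make_matrix(["0", "1", "0", "1"], list("ABCD"))
        idx = homoplasy_indices(m, t)
        row = idx.per_character.iloc[0]
        assert (row["m"], row["s"], row["g"]) == (1, 2, 2)
        assert row["ci"] == pytest.approx(0.5)
        assert row["ri"] == pytest.approx(0.0)

    def test_ensemble_depends_only_on_lengths(self, rng):
        """Two different MP trees of equal length give identical CI and RI."""
        taxa = [f"t{i}" for i in range(6)]
        m = random_matrix(taxa, n_chars=6, rng=rng)
        t1 = random_binary_tree(taxa, rng)
        s = fitch_length(t1, m)
        a = homoplasy_indices(m, t1)
        b = homoplasy_indices(m, s)   # precomputed per-character lengths
        assert (a.M, a.S, a.G, a.CI, a.RI) == (b.M, b.S, b.G, b.CI, b.RI)

    def test_ri_boundary_identities(self, rng):
        """ri = 1 iff s = m; ri = 0 iff s = g (where defined)."""
        for _ in range(10):
            n = int(rng.integers(5, 10))
            taxa = [f"t{i}" for i in range(n)]
            m = random_matrix(taxa, n_chars=5, rng=rng, missing_rate=0.1)
            t = random_binary_tree(taxa, rng)
            idx = homoplasy_indices(m, t)
            for _, row in idx.per_character.iterrows():
                if not np.isnan(row["ri"]):
                    assert (row["ri"] == 1.0) == (row["s"] == row["m"])
                    assert (row["ri"] == 0.0) == (row["s"] == row["g"])

    def test_uninformative_character_ri_undefined(self):
        t = PhyloTree.from_newick("((A,B),(C,D));")
        m = make_matrix(["00", "10", "11", "11"], list("ABCD"))
        idx = homoplasy_indices(m, t)
        assert np.isnan(idx.per_character.iloc[0]["ri"])   # g == m == 1
        assert idx.M == 2   # uninformative character still counted in sums

    def test_inconsistent_supplied_length_rejected(self):
        t = PhyloTree.from_newick("((A,B),(C,D));")
        m = make_matrix(["0", "1", "0", "1"], list("ABCD"))
        with pytest.raises(ValueError):
            homoplasy_indices(m, np.array([0]))

    def test_exclude_uninformative_option(self):
        t = PhyloTree.from_newick("((A,B),(C,D));")
        m = make_matrix(["00", "10", "01", "01"], list("ABCD"))
        full = homoplasy_indices(m, t)
        trimmed = homoplasy_indices(m, t, exclude_uninformative=True)
        assert len(trimmed.per_character) < len(full.per_character)


class TestStrictConsensus:
    def test_threshold_one_keeps_only_universal_clades(self):
        trees = [
            PhyloTree.from_newick("(((A,B),C),(D,E));"),
            PhyloTree.from_newick("(((A,B),D),(C,E));"),
        ]
        cons = majority_rule_consensus(trees, threshold=1.0)
        assert set(cons.supports) in (
            {frozenset({"A", "B"})}, {frozenset({"C", "D", "E"})},
        )
        assert set(cons.supports.values()) == {100.0}
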