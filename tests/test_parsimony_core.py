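"""Fitch/Sankoff scoring, ACCTRAN/DELTRAN, transformation mapping, collapse."""

import dendropy
import numpy as np
import pytest
from dendropy.model import parsimony as dendropy_parsimony

from morphoclad import (
    PhyloTree,
    RootedPhyloTree,
    acctran_states,
    collapse_unsupported,
    deltran_states,
    encode_matrix,
    fitch_length,
    map_transformations,
    root_at_edge,
    synapomorphies_for_clade,
    write_nexus,
)

from helpers import (
    brute_force_length,
    make_matrix,
    random_binary_tree,
    random_matrix,
    star_tree,
)


class TestFitchLength:
    def test_constant_character_is_free(self):
        t = PhyloTree.from_newick("((A,B),(C,D));")
        m = make_matrix(["0", "0", "0", "0"], list("ABCD"))
        assert fitch_length(t, m)[0] == 0

    def test_four_taxon_micro_examples(self):
        # split AB|CD: a character matching the split costs 1, crossing it costs 2
        t = PhyloTree.from_newick("((A,B),(C,D));")
        m = make_matrix(["00", "01", "10", "11"], list("ABCD"))
        assert list(fitch_length(t, m)) == [1, 2]

    def test_star_tree_counts_terminal_changes(self):
        t = star_tree(list("ABCDE"))
        m = make_matrix(["0", "0", "0", "1", "2"], list("ABCDE"))
        assert fitch_length(t, m)[0] == 2  # n_nonmissing - modal frequency

    def test_leaf_taxon_mismatch_rejected(self, toy_matrix):
        t = PhyloTree.from_newick("((A,B),(C,X));")
        with pytest.raises(ValueError, match="absent"):
            fitch_length(t, toy_matrix)

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        """Exhaustive internal-labeling minimisation agrees on <=8-leaf,
        <=4-state instances, including missing data."""
        for _ in range(25):
            n = int(rng.integers(4, 9))
            taxa = [f"t{i}" for i in range(n)]
            m = random_matrix(taxa, n_chars=3, rng=rng)
            t = random_binary_tree(taxa, rng)
            assert np.array_equal(fitch_length(t, m), brute_force_length(t, m))

    def test_matches_dendropy_fitch_score(self, rng, tmp_path):
        """Independent library cross-check on a larger random instance."""
        taxa = [f"t{i}" for i in range(12)]
        m = random_matrix(taxa, n_chars=20, rng=rng, missing_rate=0.05)
        t = random_binary_tree(taxa, rng)
        p = tmp_path / "m.nex"
        write_nexus(m, p)
        dm = dendropy.StandardCharacterMatrix.get(path=str(p), schema="nexus")
        dt = dendropy.Tree.get(
            data=t.to_newick(), schema="newick", taxon_namespace=dm.taxon_namespace
        )
        score = dendropy_parsimony.fitch_down_pass(
            dt.postorder_node_iter(),
            taxon_state_sets_map=dm.taxon_state_sets_map(gaps_as_missing=True),
        )
        assert int(fitch_length(t, m).sum()) == score

    def test_root_invariance(self, rng):
        taxa = [f"t{i}" for i in range(7)]
        m = random_matrix(taxa, n_chars=5, rng=rng)
        t = random_binary_tree(taxa, rng)
        unrooted = fitch_length(t, m)
        for u, v in t.edges():
            assert np.array_equal(fitch_length(root_at_edge(t, u, v), m), unrooted)

    def test_wildcard_leaves_never_increase_length(self, rng):
        """Setting a leaf's row to '?' gives the same length as pruning it."""
        for _ in range(10):
            n = int(rng.integers(5, 9))
            taxa = [f"t{i}" for i in range(n)]
            m = random_matrix(taxa, n_chars=4, rng=rng, missing_rate=0.0)
            t = random_binary_tree(taxa, rng)
            victim = taxa[int(rng.integers(n))]
            # all-? row
            cells = m.cells.copy()
            cells[[x.taxon_id for x in m.taxa].index(victim)] = "?"
            m_wild = make_matrix(["".join(r) for r in cells], taxa)
            # pruned tree + matrix
            keep = [x for x in taxa if x != victim]
            rows = ["".join(r) for x, r in zip(taxa, m.cells) if x != victim]
            m_prune = make_matrix(rows, keep)
            t_prune = t.copy()
            leaf = next(k for k, lbl in t_prune.labels.items() if lbl == victim)
            hubs = list(t_prune.adj[leaf])
            t_prune.remove_node(leaf)
            for h in hubs:
                if not t_prune.is_leaf(h) and t_prune.degree(h) == 2:
                    t_prune.splice_degree2(h)
            full = fitch_length(t_prune, m_prune).sum()
            assert fitch_length(t, m_wild).sum() == full


class TestOptimizations:
    def test_totals_equal_fitch_length(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 9))
            taxa = [f"t{i}" for i in range(n)]
            m = random_matrix(taxa, n_chars=4, rng=rng)
            t = random_binary_tree(taxa, rng)
            u, v = t.edges()[0]
            rt = root_at_edge(t, u, v)
            expected = fitch_length(t, m)
            for opt in (acctran_states, deltran_states):
                assign = opt(rt, m)
                changes = np.zeros(4, dtype=int)
                for node, p in rt.parent.items():
                    changes += assign.states[node] != assign.states[p]
                assert np.array_equal(changes, expected), opt.__name__

    def test_single_derived_clade_change_on_stem(self):
        rt = RootedPhyloTree.from_newick("((A,B),(C,(D,E)));")
        m = make_matrix(["0", "0", "0", "1", "1"], list("ABCDE"))
        events = map_transformations(rt, m)
        assert len(events) == 1
        e = events[0]
        assert rt.clade_leaves(e.branch) == frozenset({"D", "E"})
        assert (e.from_state, e.to_state, e.ambiguous) == ("0", "1", False)

    def test_acctran_favours_reversal_deltran_parallelism(self):
        # A=B=C derived, D ancestral, outgroup anchors the root state
        rt = RootedPhyloTree.from_newick("(((A,B),(C,D)),OUT);")
        m = make_matrix(["1", "1", "1", "0", "0"], list("ABCD") + ["OUT"])
        clades = rt.clades()
        acc, dl = acctran_states(rt, m), deltran_states(rt, m)

        def changed(assign):
            return {
                clades[v]
                for v, p in rt.parent.items()
                if assign.states[v][0] != assign.states[p][0]
            }

        # accelerated: gain on the ABCD stem, reversal in D
        assert changed(acc) == {frozenset("ABCD"), frozenset("D")}
        # delayed: two parallel gains closer to the tips
        assert changed(dl) == {frozenset("AB"), frozenset("C")}

    def test_crossing_character_events_are_ambiguous(self):
        rt = RootedPhyloTree.from_newick("((A,B),(C,D));")
        m = make_matrix(["00", "01", "10", "11"], list("ABCD"))
        events = map_transformations(rt, m)
        # char 2 (A0,B1,C0,D1) changes twice; every placement can move
        assert all(e.ambiguous for e in events if e.char_index == 2)

    def test_anchored_synapomorphy_is_unambiguous_and_formatted(self):
        # nested outgroup taxa pin the root state, so the stem gains are
        # forced in every optimization
        rt = RootedPhyloTree.from_newick("((((A,B),(C,D)),O1),O2);")
        m = make_matrix(["11", "11", "10", "10", "00", "00"],
                        list("ABCD") + ["O1", "O2"])
        events = map_transformations(rt, m)
        clades = rt.clades()
        abcd = next(u for u, c in clades.items() if c == frozenset("ABCD"))
        ab = next(u for u, c in clades.items() if c == frozenset("AB"))
        syn_abcd = synapomorphies_for_clade(rt, events, abcd)
        syn_ab = synapomorphies_for_clade(rt, events, ab)
        assert (1, "1", False) in syn_abcd
        assert (2, "1", False) in syn_ab
        codes = [e.code() for e in events]
        assert "1¹" in codes and "2¹" in codes

    def test_synapomorphies_of_leaf_rejected(self, toy_matrix):
        rt = RootedPhyloTree.from_newick("((A,B),(C,D));")
        events = map_transformations(rt, toy_matrix)
        leaf = next(u for u, lbl in rt.labels.items() if lbl == "A")
        with pytest.raises(ValueError):
            synapomorphies_for_clade(rt, events, leaf)


class TestCollapse:
    def test_pendant_only_signal_collapses_to_star(self):
        t = PhyloTree.from_newick("((A,B),C,(D,E));")
        m = make_matrix(["10", "00", "00", "00", "01"], list("ABCDE"))
        collapsed = collapse_unsupported(t, m)
        assert collapsed.internal_edges() == []
        assert collapsed.n_leaves == 5

    def test_supported_branch_retained(self):
        t = PhyloTree.from_newick("((A,B),C,(D,E));")
        m = make_matrix(["1", "1", "0", "0", "0"], list("ABCDE"))
        collapsed = collapse_unsupported(t, m)
        index = t.taxon_index()
        assert len(collapsed.splits(index)) == 1  # AB|CDE survives, DE|ABC goes

    def test_identical_taxa_give_star(self):
        t = PhyloTree.from_newick("((A,B),(C,D));")
        m = make_matrix(["01", "01", "01", "01"], list("ABCD"))
        collapsed = collapse_unsupported(t, m)
        assert collapsed.internal_edges() == []

    def test_length_preserved(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 9))
            taxa = [f"t{i}" for i in range(n)]
            m = random_matrix(taxa, n_chars=3, rng=rng, missing_rate=0.3)
            t = random_binary_tree(taxa, rng)
            collapsed = collapse_unsupported(t, m)
            assert fitch_length(collapsed, m).sum() == fitch_length(t, m).sum()

    def test_collapse_agrees_with_exhaustive_labeling_census(self, rng):
        """On tiny instances, an edge is kept iff some minimum labeling
        changes across it — verified by enumerating all labelings."""
        import itertools

        for _ in range(8):
            taxa = [f"t{i}" for i in range(5)]
            m = random_matrix(taxa, n_chars=2, rng=rng, missing_rate=0.2)
            t = random_binary_tree(taxa, rng)
            enc = encode_matrix(m)
            # exhaustive: for each internal edge, can any optimal labeling
            # place a change there (any character)?
            keep_expected = set()
            root, parent, post = t._orient()
            internal = [u for u in post if not t.is_leaf(u)]
            for j, cd in enumerate(m.characters):
                states = [int(s) for s in cd.states]
                leaf_sets = {
                    u: (set(states) if m.cells[enc.row_of[t.labels[u]], j] == "?"
                        else {int(m.cells[enc.row_of[t.labels[u]], j])})
                    for u in post if t.is_leaf(u)
                }
                best, layouts = None, []
                for lab in itertools.product(states, repeat=len(internal)):
                    for leaf_lab in itertools.product(
                        *[sorted(leaf_sets[u]) for u in post if t.is_leaf(u)]
                    ):
                        assign = dict(zip(internal, lab))
                        assign.update(zip([u for u in post if t.is_leaf(u)], leaf_lab))
                        cost, changed = 0, set()
                        for u, v in t.edges():
                            if assign[u] != assign[v]:
                                cost += 1
                                changed.add((u, v))
                        if best is None or cost < best:
                            best, layouts = cost, [changed]
                        elif cost == best:
                            layouts.append(changed)
                for changed in layouts:
                    for e in changed:
                        keep_expected.add(e)
            expected_internal = {
                e for e in t.internal_edges() if e in keep_expected
            }
            collapsed = collapse_unsupported(t, m)
            index = t.taxon_index()
            assert len(collapsed.splits(index)) == len(expected_internal)
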