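"""Shared test utilities: matrix builders, random trees, brute-force oracles.

The oracles here are deliberately independent of the package's scoring path:
tree length is minimised by enumerating every internal-node labeling, and
search optima come from enumerating every unrooted topology.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np

from morphoclad import PhyloTree, encode_matrix
from morphoclad.matrix_io import CharacterDef, CharacterMatrix, TaxonRecord


def make_matrix(rows, taxa, groups=None, countries=None) -> CharacterMatrix:
    """Matrix from row strings like ["010", "1?0", ...]."""
    cells = np.array([list(r) for r in rows], dtype="<U1")
    chars = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j in range(cells.shape[1]):
            obs = tuple(sorted(set(cells[:, j]) - {"?"})) or ("0",)
            chars.append(
                CharacterDef(index=j + 1, name=f"c{j + 1}", states=obs,
                             kind="binary" if len(obs) == 2 else "multistate")
            )
    taxa_records = [
        TaxonRecord(
            taxon_id=t,
            group=(groups or {}).get(t, "ingroup"),
            country=(countries or {}).get(t),
        )
        for t in taxa
    ]
    return CharacterMatrix(taxa=taxa_records, characters=chars, cells=cells)


def star_tree(taxa) -> PhyloTree:
    t = PhyloTree()
    hub = t.new_node()
    for lbl in taxa:
        t.add_edge(hub, t.new_node(lbl))
    return t


def random_binary_tree(taxa, rng: np.random.Generator) -> PhyloTree:
    """Uniform-ish random unrooted binary topology via random addition."""
    t = PhyloTree()
    hub = t.new_node()
    for lbl in taxa[:3]:
        t.add_edge(hub, t.new_node(lbl))
    for lbl in taxa[3:]:
        edges = t.edges()
        u, v = edges[int(rng.integers(len(edges)))]
        mid = t.new_node()
        t.remove_edge(u, v)
        t.add_edge(u, mid)
        t.add_edge(mid, v)
        t.add_edge(mid, t.new_node(lbl))
    return t


def all_unrooted_topologies(taxa):
    """Every distinct unrooted binary topology on the given taxa (recursive
    stepwise addition: 1, 1, 3, 15, 105, 945 ... trees)."""
    def rec(trees, remaining):
        if not remaining:
            return trees
        lbl = remaining[0]
        out = []
        for t in trees:
            for u, v in t.edges():
                t2 = t.copy()
                mid = t2.new_node()
                t2.remove_edge(u, v)
                t2.add_edge(u, mid)
                t2.add_edge(mid, v)
                t2.add_edge(mid, t2.new_node(lbl))
                out.append(t2)
        return rec(out, remaining[1:])

    base = star_tree(taxa[:3])
    return rec([base], list(taxa[3:]))


def brute_force_length(tree: PhyloTree, matrix: CharacterMatrix) -> np.ndarray:
    """Minimum changes per character by exhaustive internal-labeling search."""
    enc = encode_matrix(matrix)
    root, parent, post = tree._orient()
    internal = [u for u in post if not tree.is_leaf(u)]
    total = np.zeros(len(matrix.characters), dtype=int)
    for j, cd in enumerate(matrix.characters):
        states = [int(s) for s in cd.states]
        leaf_sets = {}
        for u in post:
            if tree.is_leaf(u):
                c = matrix.cells[enc.row_of[tree.labels[u]], j]
                leaf_sets[u] = set(states) if c == "?" else {int(c)}
        best = None
        for lab in itertools.product(states, repeat=len(internal)):
            assign = dict(zip(internal, lab))
            cost = 0
            for u, v in tree.edges():
                su = leaf_sets[u] if tree.is_leaf(u) else {assign[u]}
                sv = leaf_sets[v] if tree.is_leaf(v) else {assign[v]}
                cost += 0 if su & sv else 1
            if best is None or cost < best:
                best = cost
        total[j] = best
    return total


def random_matrix(taxa, n_chars, rng, max_states=4, missing_rate=0.1) -> CharacterMatrix:
    rows = []
    k = int(rng.integers(2, max_states + 1))
    for _ in taxa:
        rows.append(
            "".join(
                "?" if rng.random() < missing_rate else str(int(rng.integers(k)))
                for _ in range(n_chars)
            )
        )
    return make_matrix(rows, list(taxa))
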