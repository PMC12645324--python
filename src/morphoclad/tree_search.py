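"""Heuristic maximum-parsimony search.

Starting trees come from random stepwise addition; branch swapping uses
tree bisection and reconnection (TBR), with SPR and NNI available as
restricted neighbourhoods.  Equally parsimonious trees accumulate in a
deduplicated buffer, PAUP*-style: every buffered tree is swapped once, and
strictly shorter trees restart the buffer.

Reconnection candidates are scored without materialising the neighbour:
for a bisection into fragments X and Y, the length of the rejoined tree is
``len(X) + len(Y) + #characters whose rooted state sets are disjoint``
(see :func:`morphoclad.parsimony_core.edge_root_sets`), so a whole TBR
neighbourhood reduces to one broadcast intersection per bisection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np

from .matrix_io import CharacterMatrix
from .parsimony_core import (
    EncodedMatrix,
    PhyloTree,
    encode_matrix,
    edge_root_sets,
    fitch_length,
    collapse_unsupported,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchConfig:
    """Settings for the heuristic search.

    ``max_trees`` caps the equally-parsimonious buffer (hitting the cap stops
    enqueueing but not swapping, like a MAXTREES-limited run).  With
    ``steepest_descent`` every neighbourhood is scanned fully before moving;
    the default accepts the first strictly shorter neighbour.
    """

    n_replicates: int = 20
    seed: int = 0
    max_trees: int = 10_000
    swap: Literal["tbr", "spr", "nni"] = "tbr"
    steepest_descent: bool = False

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.max_trees < 1:
            raise ValueError("max_trees must be >= 1")
        if self.swap not in ("tbr", "spr", "nni"):
            raise ValueError(f"unknown swap mode {self.swap!r}")


@dataclass
class TreeEnsemble:
    """All distinct shortest collapsed topologies found by a search."""

    trees: list[PhyloTree]
    length: int
    per_character_steps: np.ndarray
    config: SearchConfig
    replicate_lengths: list[int] = field(default_factory=list)
    buffer_overflowed: bool = False

    def __len__(self) -> int:
        return len(self.trees)


# ---------------------------------------------------------------------------
# Stepwise addition
# ---------------------------------------------------------------------------


def random_addition_tree(
    matrix: CharacterMatrix | EncodedMatrix,
    rng: np.random.Generator,
    order: list[str] | None = None,
) -> PhyloTree:
    """Build a starting tree by seeded-random stepwise addition.

    Taxa are inserted in a random order, each at the branch minimising the
    incremental Fitch length; ties break uniformly at random.
    """
    enc = matrix if isinstance(matrix, EncodedMatrix) else encode_matrix(matrix)
    labels = sorted(enc.row_of)
    if order is None:
        order = [labels[i] for i in rng.permutation(len(labels))]
    if len(order) < 3:
        raise ValueError("stepwise addition needs at least 3 taxa")
    t = PhyloTree()
    hub = t.new_node()
    for lbl in order[:3]:
        t.add_edge(hub, t.new_node(lbl))
    for lbl in order[3:]:
        edges, R, _total = edge_root_sets(t, enc)
        leaf_mask = enc.masks[enc.row_of[lbl], :]
        extra = ((R & leaf_mask[None, :]) == 0).sum(axis=1)
        best = np.flatnonzero(extra == extra.min())
        pick = int(best[rng.integers(len(best))]) if len(best) > 1 else int(best[0])
        u, v = edges[pick]
        mid = t.new_node()
        t.remove_edge(u, v)
        t.add_edge(u, mid)
        t.add_edge(mid, v)
        t.add_edge(mid, t.new_node(lbl))
    return t


# ---------------------------------------------------------------------------
# Bisection / reconnection
# ---------------------------------------------------------------------------


def _bisect(tree: PhyloTree, u: int, v: int) -> tuple[PhyloTree, PhyloTree]:
    """Split at edge (u, v); degree-2 stubs are spliced out."""
    t = tree.copy()
    t.remove_edge(u, v)
    for x in (u, v):
        if not t.is_leaf(x) and t.degree(x) == 2:
            t.splice_degree2(x)
        elif not t.is_leaf(x) and t.degree(x) == 0:  # isolated internal stub
            del t.adj[x]
    comp_u = _component(t, u if u in t.adj else t.nodes()[0])
    frag_a = _extract(t, comp_u)
    frag_b = _extract(t, set(t.adj) - comp_u)
    return frag_a, frag_b


def _component(t: PhyloTree, start: int) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        x = stack.pop()
        for y in t.adj[x]:
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return seen


def _extract(t: PhyloTree, nodes: set[int]) -> PhyloTree:
    sub = PhyloTree()
    ids = {}
    for x in sorted(nodes):
        ids[x] = sub.new_node(t.labels.get(x))
    for x in sorted(nodes):
        for y in t.adj[x]:
            if y in nodes and x < y:
                sub.add_edge(ids[x], ids[y])
    return sub


def _join(
    frag_a: PhyloTree, point_a: tuple[int, int] | int,
    frag_b: PhyloTree, point_b: tuple[int, int] | int,
) -> PhyloTree:
    """Reconnect two fragments by an edge between points on their branches.

    A point is either an edge (subdivided by a new junction node) or, for a
    single-leaf fragment, the leaf itself.
    """
    t = PhyloTree()
    ids_a = {x: t.new_node(frag_a.labels.get(x)) for x in frag_a.nodes()}
    ids_b = {x: t.new_node(frag_b.labels.get(x)) for x in frag_b.nodes()}
    for x, y in frag_a.edges():
        t.add_edge(ids_a[x], ids_a[y])
    for x, y in frag_b.edges():
        t.add_edge(ids_b[x], ids_b[y])

    def junction(ids, point):
        if isinstance(point, int):
            return ids[point]
        x, y = point
        j = t.new_node()
        t.remove_edge(ids[x], ids[y])
        t.add_edge(ids[x], j)
        t.add_edge(j, ids[y])
        return j

    t.add_edge(junction(ids_a, point_a), junction(ids_b, point_b))
    return t


def _attachment_points(frag: PhyloTree) -> list[tuple[int, int] | int]:
    if frag.n_leaves == 1:
        return [frag.nodes()[0]]
    return list(frag.edges())


def tbr_neighbors(tree: PhyloTree) -> Iterator[PhyloTree]:
    """All distinct topologies one TBR move away (input excluded).

    Bisects at every branch and reconnects every branch of one fragment to
    every branch of the other; duplicates are filtered by bipartition hash.
    """
    if tree.n_leaves < 4:
        return
    index = tree.taxon_index()
    seen = {tree.splits(index)}
    for u, v in tree.edges():
        frag_a, frag_b = _bisect(tree, u, v)
        for pa in _attachment_points(frag_a):
            for pb in _attachment_points(frag_b):
                cand = _join(frag_a, pa, frag_b, pb)
                h = cand.splits(index)
                if h not in seen:
                    seen.add(h)
                    yield cand


# ---------------------------------------------------------------------------
# Swap scoring
# ---------------------------------------------------------------------------


def _fragment_sets(frag: PhyloTree, enc: EncodedMatrix):
    """(attachment points, rooted state sets, total steps) for a fragment."""
    if frag.n_leaves == 1:
        leaf = frag.nodes()[0]
        mask = enc.masks[enc.row_of[frag.labels[leaf]], :]
        return [leaf], mask[None, :], 0
    edges, R, total = edge_root_sets(frag, enc)
    return list(edges), R, total


def _sweep(
    tree: PhyloTree,
    enc: EncodedMatrix,
    best_len: int,
    swap: str,
    steepest: bool,
    collect_equal: bool,
    equal_cap: int,
):
    """One pass over the neighbourhood of ``tree``.

    Returns ("better", new_tree, new_len) on improvement, else
    ("done", equal_trees) with equally parsimonious neighbours (possibly
    including re-creations of the input; the caller deduplicates).
    """
    equal: list[PhyloTree] = []
    best_improvement: tuple[int, PhyloTree] | None = None
    edges = tree.edges()
    if swap == "nni":
        edges = tree.internal_edges()
    for u, v in edges:
        frag_a, frag_b = _bisect(tree, u, v)
        pts_a, RA, tot_a = _fragment_sets(frag_a, enc)
        pts_b, RB, tot_b = _fragment_sets(frag_b, enc)
        if swap in ("spr", "nni"):
            # keep fragment A's original attachment point: the spliced edge
            ia = _original_point_index(tree, u, v, frag_a, pts_a)
            pts_a, RA = [pts_a[ia]], RA[ia : ia + 1]
            if swap == "nni":
                # reconnect only next to fragment B's original point
                ib0 = _original_point_index(tree, u, v, frag_b, pts_b)
                ib = _adjacent_point_indices(pts_b, ib0)
                pts_b = [pts_b[i] for i in ib]
                RB = RB[ib]
        extra = ((RA[:, None, :] & RB[None, :, :]) == 0).sum(axis=2)
        cost = tot_a + tot_b + extra
        mn = int(cost.min())
        if mn < best_len:
            ia, ib = np.unravel_index(int(np.argmin(cost)), cost.shape)
            cand = _join(frag_a, pts_a[ia], frag_b, pts_b[ib])
            if not steepest:
                return "better", cand, mn
            if best_improvement is None or mn < best_improvement[0]:
                best_improvement = (mn, cand)
        elif collect_equal and mn == best_len:
            for ia, ib in zip(*np.nonzero(cost == best_len)):
                if len(equal) >= equal_cap:
                    break
                equal.append(_join(frag_a, pts_a[int(ia)], frag_b, pts_b[int(ib)]))
    if best_improvement is not None:
        return "better", best_improvement[1], best_improvement[0]
    return "done", equal


def _original_point_index(tree, u, v, frag, pts) -> int:
    """Index of a fragment's attachment point recreating the original tree."""
    # the fragment contains whichever cut endpoint lies on its side; its
    # former neighbours (other than across the cut) were joined by the splice
    if frag.n_leaves == 1:
        return 0
    side = u if _holds(frag, tree, u, avoid=v) else v
    other = v if side == u else u
    nbrs = [w for w in tree.adj[side] if w != other]
    # map by split: the spliced edge separates nbrs[0]'s subtree from the rest
    target = _subtree_taxa(tree, nbrs[0], side)
    all_taxa = frozenset(frag.labels.values())
    for i, p in enumerate(pts):
        if isinstance(p, int):
            return i
        x, y = p
        tx = _subtree_taxa(frag, x, y)
        if tx == target or (all_taxa - tx) == target:
            return i
    return 0


def _adjacent_point_indices(pts, i0: int) -> list[int]:
    """Points sharing an endpoint with pts[i0] (nearest-neighbour moves)."""
    p0 = pts[i0]
    if isinstance(p0, int):
        return list(range(len(pts)))
    ends = set(p0)
    out = []
    for i, p in enumerate(pts):
        if isinstance(p, int) or ends & set(p):
            out.append(i)
    return out


def _holds(frag: PhyloTree, tree: PhyloTree, node: int, avoid: int) -> bool:
    """Does the fragment contain tree-node's side of the cut edge?  Cheap
    test via a representative leaf label, never crossing the cut."""
    lbl = _any_leaf_label(tree, node, avoid)
    return lbl in frag.labels.values()


def _any_leaf_label(tree: PhyloTree, node: int, avoid: int) -> str:
    if tree.is_leaf(node):
        return tree.labels[node]
    seen = {node, avoid}
    stack = [node]
    while stack:
        x = stack.pop()
        for y in tree.adj[x]:
            if y not in seen:
                if tree.is_leaf(y):
                    return tree.labels[y]
                seen.add(y)
                stack.append(y)
    raise RuntimeError("no leaf found")


def _subtree_taxa(tree: PhyloTree, node: int, away_from: int) -> frozenset[str]:
    out = set()
    seen = {away_from, node}
    stack = [node]
    if tree.is_leaf(node):
        out.add(tree.labels[node])
    while stack:
        x = stack.pop()
        for y in tree.adj[x]:
            if y not in seen:
                seen.add(y)
                if tree.is_leaf(y):
                    out.add(tree.labels[y])
                stack.append(y)
    return frozenset(out)


# ---------------------------------------------------------------------------
# Full search
# ---------------------------------------------------------------------------


def heuristic_search(matrix: CharacterMatrix, config: SearchConfig | None = None) -> TreeEnsemble:
    """Random-addition + branch-swapping search for most parsimonious trees.

    Each replicate builds a random-addition starting tree, then swaps:
    strictly shorter neighbours are accepted (restarting the buffer at the
    new length) and equal-length distinct topologies are enqueued until every
    buffered tree has been swapped or the buffer cap is reached.  The final
    ensemble holds all distinct shortest topologies, collapsed under the
    max-length-0 rule and deduplicated.
    """
    config = config or SearchConfig()
    enc = encode_matrix(matrix)
    rng = np.random.default_rng(config.seed)
    labels = sorted(enc.row_of)
    index = {t: i for i, t in enumerate(labels)}
    if len(labels) < 4:
        t = random_addition_tree(enc, rng) if len(labels) == 3 else None
        if t is None:
            raise ValueError("search needs at least 3 taxa")
        steps = fitch_length(t, enc)
        return TreeEnsemble([t], int(steps.sum()), steps, config, [int(steps.sum())])

    best_len: int | None = None
    buffer: dict[frozenset[int], PhyloTree] = {}
    unswapped: list[frozenset[int]] = []
    overflow = False
    rep_lengths: list[int] = []

    def admit(t: PhyloTree) -> None:
        nonlocal overflow
        h = t.splits(index)
        if h in buffer:
            return
        if len(buffer) >= config.max_trees:
            overflow = True
            return
        buffer[h] = t
        unswapped.append(h)

    for rep in range(config.n_replicates):
        current = random_addition_tree(enc, rng)
        length = int(fitch_length(current, enc).sum())
        # descend from this replicate's start regardless of the global best,
        # so a poor start can still reach (or beat) the incumbent length
        while True:
            result = _sweep(current, enc, length, config.swap,
                            config.steepest_descent, collect_equal=False, equal_cap=0)
            if result[0] == "better":
                _, current, length = result
            else:
                break
        rep_lengths.append(length)
        if best_len is None or length < best_len:
            best_len = length
            buffer.clear()
            unswapped.clear()
            admit(current)
        elif length == best_len:
            admit(current)
        # swap-saturate the buffer of equally parsimonious trees
        while unswapped:
            h = unswapped.pop(0)
            current = buffer[h]
            improving = True
            while improving:
                room = config.max_trees - len(buffer)
                result = _sweep(
                    current, enc, best_len, config.swap, config.steepest_descent,
                    collect_equal=room > 0, equal_cap=max(room, 0) + 8,
                )
                if result[0] == "better":
                    _, current, best_len = result
                    buffer.clear()
                    unswapped.clear()
                    admit(current)
                    unswapped.clear()  # current itself is being swapped now
                else:
                    improving = False
                    for t in result[1]:
                        admit(t)

    assert best_len is not None
    # collapse unsupported branches and deduplicate
    final: dict[frozenset[int], PhyloTree] = {}
    per_char: np.ndarray | None = None
    for t in buffer.values():
        c = collapse_unsupported(t, enc)
        h = c.splits(index)
        if h not in final:
            final[h] = c
            if per_char is None:
                per_char = fitch_length(c, enc)
    trees = list(final.values())
    assert per_char is not None
    length = int(per_char.sum())
    if overflow:
        logger.warning("tree buffer reached max_trees=%d; ensemble truncated", config.max_trees)
    return TreeEnsemble(
        trees=trees, length=length, per_character_steps=per_char,
        config=config, replicate_lengths=rep_lengths, buffer_overflowed=overflow,
    )
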