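"""Tree representation and unordered (Fitch/Wagner) parsimony machinery.

The scoring primitives operate on bitmask-encoded state sets: state symbol
``'k'`` maps to bit ``k`` of a ``uint16``, and a missing cell ``'?'`` maps to
the full mask of its character's declared states (a free wildcard, as in
PAUP*).  Binary trees are scored with the two-set Fitch recursion; trees with
polytomies fall back to a unit-cost dynamic program over states, which gives
the same minimum for binary trees and the hard-polytomy length otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import dendropy
import numpy as np

from .matrix_io import MISSING, CharacterMatrix

_BIG = 1 << 20
_NSTATES = 10  # symbols '0'..'9'

_SUPERSCRIPTS = str.maketrans("0123456789", "⁰¹²³⁴⁵⁶⁷⁸⁹")


# ---------------------------------------------------------------------------
# Tree structures
# ---------------------------------------------------------------------------


class PhyloTree:
    """Unrooted, possibly multifurcating tree with labelled leaves.

    Nodes are integer ids; leaves carry taxon labels.  The adjacency
    structure is mutable so that search moves (bisection, reconnection,
    stepwise addition) can be expressed as cheap local surgery.
    """

    __slots__ = ("adj", "labels", "_next")

    def __init__(self) -> None:
        self.adj: dict[int, list[int]] = {}
        self.labels: dict[int, str] = {}
        self._next = 0

    # -- construction -----------------------------------------------------

    def new_node(self, label: str | None = None) -> int:
        nid = self._next
        self._next += 1
        self.adj[nid] = []
        if label is not None:
            self.labels[nid] = label
        return nid

    def add_edge(self, u: int, v: int) -> None:
        self.adj[u].append(v)
        self.adj[v].append(u)

    def remove_edge(self, u: int, v: int) -> None:
        self.adj[u].remove(v)
        self.adj[v].remove(u)

    def remove_node(self, u: int) -> None:
        for v in list(self.adj[u]):
            self.remove_edge(u, v)
        del self.adj[u]
        self.labels.pop(u, None)

    def splice_degree2(self, u: int) -> None:
        """Remove an unlabelled degree-2 node, joining its two neighbours."""
        a, b = self.adj[u]
        self.remove_edge(u, a)
        self.remove_edge(u, b)
        del self.adj[u]
        self.add_edge(a, b)

    def copy(self) -> "PhyloTree":
        t = PhyloTree()
        t.adj = {u: list(vs) for u, vs in self.adj.items()}
        t.labels = dict(self.labels)
        t._next = self._next
        return t

    # -- queries ----------------------------------------------------------

    def is_leaf(self, u: int) -> bool:
        return u in self.labels

    def leaves(self) -> list[int]:
        return sorted(self.labels)

    def taxa(self) -> list[str]:
        return sorted(self.labels.values())

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def nodes(self) -> list[int]:
        return sorted(self.adj)

    def degree(self, u: int) -> int:
        return len(self.adj[u])

    def edges(self) -> list[tuple[int, int]]:
        return sorted(
            (u, v) for u in self.adj for v in self.adj[u] if u < v
        )

    def internal_edges(self) -> list[tuple[int, int]]:
        return [
            (u, v)
            for u, v in self.edges()
            if not self.is_leaf(u) and not self.is_leaf(v)
        ]

    # -- orientation ------------------------------------------------------

    def _orient(self, root: int | None = None) -> tuple[int, dict[int, int], list[int]]:
        """Orient from ``root`` (default: leaf with smallest label).

        Returns (root, parent map, postorder node list).
        """
        if root is None:
            root = min(self.labels, key=self.labels.__getitem__)
        parent: dict[int, int] = {root: -1}
        order: list[int] = []
        stack = [root]
        while stack:
            u = stack.pop()
            order.append(u)
            for v in self.adj[u]:
                if v != parent[u]:
                    parent[v] = u
                    stack.append(v)
        order.reverse()
        return root, parent, order

    # -- splits -----------------------------------------------------------

    def taxon_index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.taxa())}

    def splits(self, index: dict[str, int] | None = None, trivial: bool = False) -> frozenset[int]:
        """Canonical bipartition masks (side not containing taxon bit 0)."""
        if index is None:
            index = self.taxon_index()
        n = len(index)
        full = (1 << n) - 1
        root, parent, order = self._orient()
        down: dict[int, int] = {}
        for u in order:
            if self.is_leaf(u) and u != root:
                down[u] = 1 << index[self.labels[u]]
            elif u != root:
                m = 0
                for v in self.adj[u]:
                    if v != parent[u]:
                        m |= down[v]
                down[u] = m
        out = set()
        for u in order:
            if u == root:
                continue
            m = down[u]
            c = m if not (m & 1) else (m ^ full)
            k = bin(c).count("1")
            if trivial or 2 <= k <= n - 2:
                out.add(c)
        return frozenset(out)

    # -- newick -----------------------------------------------------------

    def to_newick(self) -> str:
        root, parent, _ = self._orient()
        base = self.adj[root][0]

        def rec(u: int, p: int) -> str:
            if self.is_leaf(u):
                return _quote(self.labels[u])
            parts = [rec(v, u) for v in self.adj[u] if v != p]
            return "(" + ",".join(parts) + ")"

        parts = [rec(v, base) for v in self.adj[base] if v != root]
        return "(" + _quote(self.labels[root]) + "," + ",".join(parts) + ");"

    @staticmethod
    def from_newick(s: str) -> "PhyloTree":
        rt = RootedPhyloTree.from_newick(s)
        return rt.unroot()

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree {self.n_leaves} leaves>"


class RootedPhyloTree:
    """Rooted tree with parent/children links and labelled leaves."""

    __slots__ = ("children", "parent", "root", "labels", "meta")

    def __init__(self) -> None:
        self.children: dict[int, list[int]] = {}
        self.parent: dict[int, int] = {}
        self.root: int = -1
        self.labels: dict[int, str] = {}
        self.meta: dict = {}

    def new_node(self, label: str | None = None) -> int:
        nid = len(self.children) if not self.children else max(self.children) + 1
        self.children[nid] = []
        if label is not None:
            self.labels[nid] = label
        return nid

    def attach(self, parent: int, child: int) -> None:
        self.children[parent].append(child)
        self.parent[child] = parent

    def is_leaf(self, u: int) -> bool:
        return not self.children[u]

    def nodes(self) -> list[int]:
        return sorted(self.children)

    def internal_nodes(self) -> list[int]:
        return [u for u in self.nodes() if self.children[u]]

    def taxa(self) -> list[str]:
        return sorted(self.labels.values())

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            u = stack.pop()
            order.append(u)
            stack.extend(self.children[u])
        order.reverse()
        return order

    def preorder(self) -> list[int]:
        return list(reversed(self.postorder()))

    def clade_leaves(self, u: int) -> frozenset[str]:
        out = []
        stack = [u]
        while stack:
            v = stack.pop()
            if self.is_leaf(v):
                out.append(self.labels[v])
            stack.extend(self.children[v])
        return frozenset(out)

    def clades(self) -> dict[int, frozenset[str]]:
        res: dict[int, frozenset[str]] = {}
        for u in self.postorder():
            if self.is_leaf(u):
                res[u] = frozenset([self.labels[u]])
            else:
                s: set[str] = set()
                for c in self.children[u]:
                    s |= res[c]
                res[u] = frozenset(s)
        return res

    def unroot(self) -> PhyloTree:
        t = PhyloTree()
        ids = {u: t.new_node(self.labels.get(u)) for u in self.nodes()}
        for u, cs in self.children.items():
            for c in cs:
                t.add_edge(ids[u], ids[c])
        r = ids[self.root]
        while r in t.adj and t.degree(r) == 2 and not t.is_leaf(r):
            nxt = t.adj[r][0]
            t.splice_degree2(r)
            r = nxt
        return t

    def to_newick(self, support: dict[frozenset[str], float] | None = None) -> str:
        clades = self.clades() if support else {}

        def rec(u: int) -> str:
            if self.is_leaf(u):
                return _quote(self.labels[u])
            s = "(" + ",".join(rec(c) for c in self.children[u]) + ")"
            if support and u != self.root:
                val = support.get(clades[u])
                if val is not None:
                    s += f"{val:.1f}"
            return s

        return rec(self.root) + ";"

    @staticmethod
    def from_newick(s: str) -> "RootedPhyloTree":
        dt = dendropy.Tree.get(data=s, schema="newick", suppress_internal_node_taxa=True)
        rt = RootedPhyloTree()

        def rec(dn) -> int:
            label = dn.taxon.label if dn.taxon is not None else None
            u = rt.new_node(label if dn.is_leaf() else None)
            for ch in dn.child_nodes():
                rt.attach(u, rec(ch))
            return u

        rt.root = rec(dt.seed_node)
        return rt

    def __repr__(self) -> str:  # pragma: no cover
        return f"<RootedPhyloTree {self.n_leaves} leaves>"


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


def root_at_edge(tree: PhyloTree, u: int, v: int) -> RootedPhyloTree:
    """Root an unrooted tree by subdividing edge (u, v) with a new root."""
    rt = RootedPhyloTree()
    ids: dict[int, int] = {}
    root = rt.new_node()
    rt.root = root

    def build(x: int, par: int, rpar: int) -> None:
        stack = [(x, par, rpar)]
        while stack:
            node, p, rp = stack.pop()
            nid = rt.new_node(tree.labels.get(node))
            rt.attach(rp, nid)
            ids[node] = nid
            for w in tree.adj[node]:
                if w != p:
                    stack.append((w, node, nid))

    build(u, v, root)
    build(v, u, root)
    return rt


# ---------------------------------------------------------------------------
# State encoding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EncodedMatrix:
    """Bitmask-encoded character matrix (one uint16 per cell)."""

    masks: np.ndarray            # (n_taxa, n_chars) uint16
    full: np.ndarray             # (n_chars,) uint16, mask of declared states
    row_of: dict[str, int]       # taxon label -> row
    n_states: np.ndarray         # (n_chars,) declared state counts

    @property
    def n_chars(self) -> int:
        return self.masks.shape[1]

    def leaf_masks(self, labels: Iterable[str]) -> np.ndarray:
        return self.masks[[self.row_of[t] for t in labels], :]


def encode_matrix(matrix: CharacterMatrix) -> EncodedMatrix:
    n_taxa = len(matrix.taxa)
    n_chars = len(matrix.characters)
    full = np.zeros(n_chars, dtype=np.uint16)
    for j, cd in enumerate(matrix.characters):
        m = 0
        for s in cd.states:
            m |= 1 << int(s)
        full[j] = m
    masks = np.zeros((n_taxa, n_chars), dtype=np.uint16)
    for i in range(n_taxa):
        for j in range(n_chars):
            c = matrix.cells[i, j]
            masks[i, j] = full[j] if c == MISSING else np.uint16(1 << int(c))
    row_of = {t.taxon_id: i for i, t in enumerate(matrix.taxa)}
    return EncodedMatrix(masks=masks, full=full, row_of=row_of,
                         n_states=np.array([len(c.states) for c in matrix.characters]))


def _leaf_mask_lookup(enc: EncodedMatrix) -> Callable[[str], np.ndarray]:
    return lambda label: enc.masks[enc.row_of[label], :]


# ---------------------------------------------------------------------------
# Fitch / Sankoff length
# ---------------------------------------------------------------------------


def _oriented(tree: PhyloTree | RootedPhyloTree):
    """Yield (postorder, children-of, leaf?, label-of, virtual_top) uniformly.

    For an unrooted tree the orientation hangs the tree from its first leaf;
    the returned ``extra_leaf`` is that leaf, to be folded into the final
    combination at the top.
    """
    if isinstance(tree, RootedPhyloTree):
        post = tree.postorder()
        kids = {u: list(tree.children[u]) for u in post}
        return post, kids, tree.labels, tree.root, None
    root, parent, post = tree._orient()
    kids = {u: [v for v in tree.adj[u] if v != parent[u]] for u in post}
    # root is a leaf; its single child is the effective top
    top = kids[root][0]
    post = [u for u in post if u != root]
    kids.pop(root)
    return post, kids, tree.labels, top, root


def fitch_length(tree: PhyloTree | RootedPhyloTree, matrix: CharacterMatrix | EncodedMatrix) -> np.ndarray:
    """Minimum number of state changes per character on ``tree``.

    Unordered equal-weight characters; missing cells are free wildcards.
    The result is independent of root placement.  Raises ``ValueError`` if
    tree leaves and matrix taxa disagree.
    """
    enc = matrix if isinstance(matrix, EncodedMatrix) else encode_matrix(matrix)
    post, kids, labels, top, extra_leaf = _oriented(tree)
    tree_taxa = set(labels.values())
    if not tree_taxa <= set(enc.row_of):
        missing = sorted(tree_taxa - set(enc.row_of))
        raise ValueError(f"tree leaves absent from matrix: {missing}")
    binary = all(len(kids[u]) in (0, 2) for u in post)
    if binary:
        return _fitch_binary(post, kids, labels, top, extra_leaf, enc)
    return _sankoff_length(post, kids, labels, top, extra_leaf, enc)


def _fitch_binary(post, kids, labels, top, extra_leaf, enc: EncodedMatrix) -> np.ndarray:
    steps = np.zeros(enc.n_chars, dtype=np.int64)
    down: dict[int, np.ndarray] = {}
    for u in post:
        if not kids[u]:
            down[u] = enc.masks[enc.row_of[labels[u]], :]
            continue
        a, b = (down[c] for c in kids[u])
        inter = a & b
        disjoint = inter == 0
        steps += disjoint
        down[u] = np.where(disjoint, a | b, inter)
    if extra_leaf is not None:
        a = down[top]
        b = enc.masks[enc.row_of[labels[extra_leaf]], :]
        steps += (a & b) == 0
    return steps


def _sankoff_length(post, kids, labels, top, extra_leaf, enc: EncodedMatrix) -> np.ndarray:
    cost = _sankoff_down(post, kids, labels, enc)
    c = cost[top]
    if extra_leaf is not None:
        leaf = _leaf_cost(enc.masks[enc.row_of[labels[extra_leaf]], :])
        c = leaf + np.minimum(c, c.min(axis=1, keepdims=True) + 1)
    return c.min(axis=1).astype(np.int64)


def _leaf_cost(mask_row: np.ndarray) -> np.ndarray:
    bits = (mask_row[:, None] >> np.arange(_NSTATES)[None, :]) & 1
    return np.where(bits.astype(bool), 0, _BIG).astype(np.int64)


def _sankoff_down(post, kids, labels, enc: EncodedMatrix) -> dict[int, np.ndarray]:
    """Unit-cost Sankoff tables: cost[u][char, state] over the subtree at u."""
    cost: dict[int, np.ndarray] = {}
    for u in post:
        if not kids[u]:
            cost[u] = _leaf_cost(enc.masks[enc.row_of[labels[u]], :])
            continue
        acc = np.zeros((enc.n_chars, _NSTATES), dtype=np.int64)
        for v in kids[u]:
            cv = cost[v]
            acc += np.minimum(cv, cv.min(axis=1, keepdims=True) + 1)
        cost[u] = acc
    return cost


# ---------------------------------------------------------------------------
# Directional edge state sets (used by stepwise addition and TBR scoring)
# ---------------------------------------------------------------------------


def edge_root_sets(tree: PhyloTree, enc: EncodedMatrix) -> tuple[list[tuple[int, int]], np.ndarray, int]:
    """For every edge, the Fitch state set of the tree rooted on that edge.

    Returns (edge list, R array of shape (n_edges, n_chars), total steps).
    Joining two fragments X, Y by an edge between points on edges eX, eY has
    Fitch length  total(X) + total(Y) + #chars{R_X(eX) & R_Y(eY) == 0},
    because the fragment length is invariant to where the fragment is rooted.
    Requires a binary unrooted tree with >= 2 leaves.
    """
    if tree.n_leaves == 1:
        raise ValueError("fragment with a single leaf has no edges")
    root, parent, post = tree._orient()
    kids = {u: [v for v in tree.adj[u] if v != parent[u]] for u in post}
    down: dict[int, np.ndarray] = {}
    steps = np.zeros(enc.n_chars, dtype=np.int64)
    for u in post:
        if tree.is_leaf(u):
            down[u] = enc.masks[enc.row_of[tree.labels[u]], :]
            continue
        a, b = (down[c] for c in kids[u])
        inter = a & b
        disjoint = inter == 0
        steps += disjoint
        down[u] = np.where(disjoint, a | b, inter)
    top = kids[root][0]
    root_mask = down[root]
    steps += (down[top] & root_mask) == 0
    total = int(steps.sum())
    # upward (rest-of-tree) sets
    up: dict[int, np.ndarray] = {top: root_mask}
    for u in reversed(post):  # preorder
        if u == root or tree.is_leaf(u):
            continue
        a, b = kids[u]
        up[a] = _combine(up[u], down[b])
        up[b] = _combine(up[u], down[a])
    edges = []
    rows = []
    for v in post:
        if v == root:
            continue
        edges.append((parent[v], v))
        rows.append(_combine(down[v], up[v]))
    return edges, np.asarray(rows), total


def _combine(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    inter = a & b
    return np.where(inter == 0, a | b, inter)


# ---------------------------------------------------------------------------
# ACCTRAN / DELTRAN optimization
# ---------------------------------------------------------------------------


@dataclass
class StateAssignment:
    """One state per node per character (a single minimum-length labeling)."""

    states: dict[int, np.ndarray]   # node -> (n_chars,) int8 state values
    optimization: str               # "acctran" | "deltran"

    def symbol(self, node: int, char_index: int) -> str:
        """State symbol at ``node`` for 1-based ``char_index``."""
        return str(int(self.states[node][char_index - 1]))


def _optimize(tree: RootedPhyloTree, enc: EncodedMatrix, accelerate: bool) -> StateAssignment:
    post = tree.postorder()
    kids = {u: list(tree.children[u]) for u in post}
    cost = _sankoff_down(post, kids, tree.labels, enc)
    n = enc.n_chars
    states: dict[int, np.ndarray] = {}
    states[tree.root] = np.argmin(cost[tree.root], axis=1).astype(np.int8)
    rows = np.arange(n)
    for u in tree.preorder():
        sp = states[u]
        for v in tree.children[u]:
            vals = cost[v] + (np.arange(_NSTATES)[None, :] != sp[:, None])
            mn = vals.min(axis=1)
            feas = vals == mn[:, None]
            if accelerate:
                fnp = feas.copy()
                fnp[rows, sp] = False
                has = fnp.any(axis=1)
                choice = np.where(has, np.argmax(fnp, axis=1), sp)
            else:
                keep = feas[rows, sp]
                choice = np.where(keep, sp, np.argmax(feas, axis=1))
            states[v] = choice.astype(np.int8)
    return StateAssignment(states=states, optimization="acctran" if accelerate else "deltran")


def acctran_states(tree: RootedPhyloTree, matrix: CharacterMatrix | EncodedMatrix) -> StateAssignment:
    """Accelerated-transformation labeling: changes as rootward as possible.

    A minimum-length labeling in which a node changes away from its parent's
    state whenever an equally parsimonious completion allows it, so reversals
    are favoured over parallelisms.  Ties among alternative states break
    toward the smallest state symbol.  Requires a rooted tree.
    """
    enc = matrix if isinstance(matrix, EncodedMatrix) else encode_matrix(matrix)
    return _optimize(tree, enc, accelerate=True)


def deltran_states(tree: RootedPhyloTree, matrix: CharacterMatrix | EncodedMatrix) -> StateAssignment:
    """Delayed-transformation labeling: changes as leafward as possible."""
    enc = matrix if isinstance(matrix, EncodedMatrix) else encode_matrix(matrix)
    return _optimize(tree, enc, accelerate=False)


@dataclass(frozen=True)
class TransformationEvent:
    """One character-state change placed on one branch.

    The branch is identified by its child node; ``ambiguous`` is true unless
    every minimum-length optimization places a change with these same
    endpoints on this branch — i.e. the event could be removed, relocated,
    or altered at no extra cost under a different optimization.
    """

    branch: int
    char_index: int          # 1-based
    from_state: str
    to_state: str
    ambiguous: bool

    def code(self) -> str:
        """Paper-style clade annotation, e.g. ``5¹`` for character 5 state 1."""
        return f"{self.char_index}{self.to_state.translate(_SUPERSCRIPTS)}"


def _events_of(tree: RootedPhyloTree, assign: StateAssignment) -> set[tuple[int, int, int, int]]:
    out = set()
    for v, p in tree.parent.items():
        sv, sp = assign.states[v], assign.states[p]
        for j in np.nonzero(sv != sp)[0]:
            out.add((v, int(j), int(sp[j]), int(sv[j])))
    return out


def _branch_forced_events(tree: RootedPhyloTree, enc: EncodedMatrix) -> dict[int, np.ndarray]:
    """Per branch (child node): boolean array over characters, true where
    EVERY minimum-length labeling places a change with the same endpoints on
    that branch.  Exact, via inside/outside unit-cost DP tables: a branch's
    attainable (parent-state, child-state) pairs are those whose combined
    inside + edge + outside cost equals the global minimum."""
    post = tree.postorder()
    kids = {u: list(tree.children[u]) for u in post}
    cost = _sankoff_down(post, kids, tree.labels, enc)
    n = enc.n_chars
    M = cost[tree.root].min(axis=1)
    out: dict[int, np.ndarray] = {tree.root: np.zeros((n, _NSTATES), dtype=np.int64)}
    step = (np.arange(_NSTATES)[:, None] != np.arange(_NSTATES)[None, :]).astype(np.int64)
    forced: dict[int, np.ndarray] = {}
    diag = np.arange(_NSTATES)
    for u in tree.preorder():
        if not kids[u]:
            continue
        contrib = {
            v: np.minimum(cost[v], cost[v].min(axis=1, keepdims=True) + 1)
            for v in kids[u]
        }
        total = sum(contrib.values())
        for v in kids[u]:
            B = out[u] + (total - contrib[v])
            out[v] = np.minimum(B, B.min(axis=1, keepdims=True) + 1)
            pair = B[:, :, None] + step[None, :, :] + cost[v][:, None, :]
            attain = pair == M[:, None, None]
            no_change_possible = ~attain[:, diag, diag].any(axis=1)
            unique = attain.reshape(n, -1).sum(axis=1) == 1
            forced[v] = no_change_possible & unique
    return forced


def map_transformations(
    tree: RootedPhyloTree,
    matrix: CharacterMatrix | EncodedMatrix,
    assignment: StateAssignment | None = None,
) -> list[TransformationEvent]:
    """Branch-by-branch change events under a single optimization.

    Uses the ACCTRAN labeling by default.  An event is unambiguous only if
    every minimum-length optimization places the identical change (same
    branch, same endpoints) there; all other events are flagged ambiguous.
    """
    enc = matrix if isinstance(matrix, EncodedMatrix) else encode_matrix(matrix)
    base = assignment or acctran_states(tree, enc)
    forced = _branch_forced_events(tree, enc)
    events = [
        TransformationEvent(
            branch=v, char_index=j + 1, from_state=str(f), to_state=str(t),
            ambiguous=not bool(forced[v][j]),
        )
        for (v, j, f, t) in sorted(_events_of(tree, base))
    ]
    return events


def events_to_tsv(events: Sequence[TransformationEvent], path) -> None:
    """Write transformation events as a TSV (branch, character, from, to,
    ambiguous)."""
    with open(path, "w") as fh:
        fh.write("branch\tchar_index\tfrom_state\tto_state\tambiguous\n")
        for e in events:
            fh.write(f"{e.branch}\t{e.char_index}\t{e.from_state}\t{e.to_state}\t"
                     f"{int(e.ambiguous)}\n")


def synapomorphies_for_clade(
    tree: RootedPhyloTree,
    events: Sequence[TransformationEvent],
    clade_node: int,
) -> list[tuple[int, str, bool]]:
    """Changes on the clade's stem branch: (character, derived state, ambiguous)."""
    if tree.is_leaf(clade_node):
        raise ValueError("clade node is a leaf; synapomorphies need an internal node")
    return [
        (e.char_index, e.to_state, e.ambiguous)
        for e in events
        if e.branch == clade_node
    ]


# ---------------------------------------------------------------------------
# Unsupported-branch collapse ("max-length = 0" rule)
# ---------------------------------------------------------------------------


def branch_can_change(tree: PhyloTree, matrix: CharacterMatrix | EncodedMatrix) -> dict[tuple[int, int], np.ndarray]:
    """For each internal edge: per character, can any minimum-length labeling
    place a change on it?  Computed exactly from inside/outside unit-cost
    dynamic-programming tables."""
    enc = matrix if isinstance(matrix, EncodedMatrix) else encode_matrix(matrix)
    root, parent, post = tree._orient()
    kids = {u: [v for v in tree.adj[u] if v != parent[u]] for u in post}
    cost = _sankoff_down(post, kids, tree.labels, enc)
    top = kids[root][0]
    root_leaf_cost = _leaf_cost(enc.masks[enc.row_of[tree.labels[root]], :])
    M = (root_leaf_cost + np.minimum(cost[top], cost[top].min(axis=1, keepdims=True) + 1)).min(axis=1)
    # outside tables: o[v][char, s] = min cost of everything outside subtree v
    # given node v takes state s (includes the parent edge cost).
    out: dict[int, np.ndarray] = {}
    b_root = root_leaf_cost
    out[top] = np.minimum(b_root, b_root.min(axis=1, keepdims=True) + 1)
    result: dict[tuple[int, int], np.ndarray] = {}
    for u in reversed(post):  # preorder
        if tree.is_leaf(u):
            continue
        contrib = {
            v: np.minimum(cost[v], cost[v].min(axis=1, keepdims=True) + 1)
            for v in kids[u]
        }
        total_contrib = sum(contrib.values())
        for v in kids[u]:
            B = out[u] + (total_contrib - contrib[v])  # cost outside subtree v given u's state
            out[v] = np.minimum(B, B.min(axis=1, keepdims=True) + 1)
            if not tree.is_leaf(v):
                # min over s_u != s_v of B[s_u], via first/second minima
                order = np.argsort(B, axis=1)
                first = order[:, 0]
                rows = np.arange(B.shape[0])
                bmin = B[rows, first]
                bsec = B[rows, order[:, 1]]
                states = np.arange(_NSTATES)[None, :]
                excl = np.where(states == first[:, None], bsec[:, None], bmin[:, None])
                X = (cost[v] + excl).min(axis=1)
                key = (u, v) if u < v else (v, u)
                result[key] = (X + 1) == M
    return result


def collapse_unsupported(tree: PhyloTree | RootedPhyloTree, matrix: CharacterMatrix | EncodedMatrix) -> PhyloTree:
    """Contract every internal branch whose maximum length is 0.

    A branch has maximum length 0 when no minimum-length optimization of any
    character places a change on it; such branches are unsupported and are
    collapsed into polytomies.  Tree length is unchanged.
    """
    ut = tree.unroot() if isinstance(tree, RootedPhyloTree) else tree.copy()
    if ut.n_leaves < 4:
        return ut
    can = branch_can_change(ut, matrix)
    to_collapse = [e for e, flags in can.items() if not flags.any()]
    if not to_collapse:
        return ut
    # contracted edges may chain; merge endpoint groups with union-find
    rep: dict[int, int] = {u: u for u in ut.adj}

    def find(x: int) -> int:
        while rep[x] != x:
            rep[x] = rep[rep[x]]
            x = rep[x]
        return x

    for u, v in to_collapse:
        ru, rv = find(u), find(v)
        if ru != rv:
            rep[max(ru, rv)] = min(ru, rv)
    new = PhyloTree()
    ids: dict[int, int] = {}
    for u in ut.nodes():
        r = find(u)
        if r not in ids:
            ids[r] = new.new_node(ut.labels.get(u))
    for u, v in ut.edges():
        ru, rv = find(u), find(v)
        if ru != rv:
            new.add_edge(ids[ru], ids[rv])
    return new
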