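"""Outgroup rooting, majority-rule consensus, and homoplasy indices.

The consistency index CI = M/S and retention index RI = (G−S)/(G−M) measure
how much homoplasy the most parsimonious solution implies: M is the sum over
characters of the minimum conceivable steps (observed states − 1), S the
realised tree length, and G the maximum conceivable steps (all changes on
terminal branches, i.e. the star-tree length).  CI = RI = 1 means a perfect
hierarchical fit; values fall as convergence, reversal or horizontal
transmission accumulate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .matrix_io import MISSING, CharacterMatrix
from .parsimony_core import (
    PhyloTree,
    RootedPhyloTree,
    fitch_length,
    root_at_edge,
)


@dataclass(frozen=True)
class Bipartition:
    """An internal branch of an unrooted tree, as its smaller taxon side,
    canonicalised against the full taxon set (stable under leaf order)."""

    side: frozenset[str]
    all_taxa: frozenset[str]

    def __post_init__(self):
        if not self.side or self.side == self.all_taxa:
            raise ValueError("bipartition sides must both be non-empty")

    def canonical(self) -> frozenset[str]:
        other = self.all_taxa - self.side
        a, b = sorted([self.side, other], key=lambda s: (len(s), sorted(s)))
        return a


@dataclass
class ConsensusTree:
    """Majority-rule consensus: tree plus per-clade support percentages."""

    tree: PhyloTree
    supports: dict[frozenset[str], float]   # clade leaf set -> % of trees
    n_trees: int
    threshold: float = 0.5


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------


def root_with_outgroup(tree: PhyloTree, outgroup_taxa: Iterable[str]) -> RootedPhyloTree:
    """Root an unrooted tree on the branch separating outgroup from ingroup.

    If the outgroup is not monophyletic on the unrooted tree, the root goes
    on the edge best separating outgroup from ingroup and the result is
    flagged via ``meta['outgroup_monophyletic'] = False``.
    """
    out = set(outgroup_taxa)
    taxa = set(tree.labels.values())
    if not out:
        raise ValueError("outgroup is empty")
    if not out < taxa:
        extra = sorted(out - taxa)
        if extra:
            raise ValueError(f"outgroup taxa not in tree: {extra}")
        raise ValueError("outgroup cannot be the whole taxon set")
    best_edge = None
    best_score = -1
    mono = False
    root, parent, order = tree._orient()
    below: dict[int, set[str]] = {}
    for u in order:
        if tree.is_leaf(u) and u != root:
            below[u] = {tree.labels[u]}
        elif u != root:
            s: set[str] = set()
            for v in tree.adj[u]:
                if v != parent[u]:
                    s |= below[v]
            below[u] = s
    n_out, n_in = len(out), len(taxa) - len(out)
    for u in order:
        if u == root:
            continue
        side = below[u]
        # how cleanly does this edge separate outgroup from ingroup?
        score = max(
            len(side & out) + (n_in - len(side - out)),
            (n_out - len(side & out)) + len(side - out),
        )
        if score > best_score:
            best_score = score
            best_edge = (parent[u], u)
        if side == out or side == taxa - out:
            mono = True
            best_edge = (parent[u], u)
            break
    assert best_edge is not None
    rooted = root_at_edge(tree, *best_edge)
    rooted.meta["outgroup_monophyletic"] = mono
    rooted.meta["outgroup"] = frozenset(out)
    return rooted


def ingroup_node(rooted: RootedPhyloTree) -> int:
    """Deepest node containing all ingroup (non-outgroup) taxa."""
    out = rooted.meta.get("outgroup", frozenset())
    ingroup = frozenset(rooted.taxa()) - out
    clades = rooted.clades()
    candidates = [u for u, c in clades.items() if ingroup <= c]
    return min(candidates, key=lambda u: len(clades[u]))


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------


def majority_rule_consensus(
    trees: Sequence[PhyloTree],
    threshold: float = 0.5,
) -> ConsensusTree:
    """Consensus retaining exactly the splits found in strictly more than
    ``threshold`` of the trees (default: the 50% majority rule).

    Retained clades are mutually compatible for any threshold >= 0.5; support
    is the percentage of trees containing the clade.  All trees must share
    one taxon set.
    """
    if not trees:
        raise ValueError("empty tree list")
    if threshold < 0.5:
        raise ValueError("threshold below 0.5 does not guarantee a tree")
    taxa = trees[0].taxa()
    for t in trees[1:]:
        if t.taxa() != taxa:
            raise ValueError("trees are not on the same taxon set")
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    full = (1 << n) - 1
    counts: Counter[int] = Counter()
    for t in trees:
        counts.update(t.splits(index))
    if threshold >= 1.0:
        # strict consensus: clades present in every tree
        kept = {m: c for m, c in counts.items() if c == len(trees)}
    else:
        kept = {m: c for m, c in counts.items() if c / len(trees) > threshold}
    # laminar check (guaranteed at >= 0.5, asserted anyway)
    masks = sorted(kept, key=lambda m: -bin(m).count("1"))
    for i, a in enumerate(masks):
        for b in masks[i + 1:]:
            assert (a & b) in (0, a, b) or (a | b) == full, "incompatible splits"
    # canonical masks exclude taxon 0; treat them as clades of a tree rooted
    # at taxon 0 and nest by containment
    tree = PhyloTree()
    leaf_ids = {t: tree.new_node(t) for t in taxa}
    top = tree.new_node()
    tree.add_edge(top, leaf_ids[taxa[0]])
    node_of: dict[int, int] = {}
    parent_mask: dict[int, int] = {}
    for m in masks:  # descending size: parents first
        best_parent = top
        bp_mask = None
        for pm, pn in node_of.items():
            if m & pm == m and (bp_mask is None or bin(pm).count("1") < bin(bp_mask).count("1")):
                best_parent, bp_mask = pn, pm
        nd = tree.new_node()
        tree.add_edge(best_parent, nd)
        node_of[m] = nd
        parent_mask[m] = bp_mask if bp_mask is not None else full
    for t in taxa[1:]:
        bit = 1 << index[t]
        best_parent, bp_mask = top, None
        for pm, pn in node_of.items():
            if pm & bit and (bp_mask is None or bin(pm).count("1") < bin(bp_mask).count("1")):
                best_parent, bp_mask = pn, pm
        tree.add_edge(best_parent, leaf_ids[t])
    supports = {
        _mask_to_clade(m, taxa): 100.0 * kept[m] / len(trees) for m in kept
    }
    return ConsensusTree(tree=tree, supports=supports, n_trees=len(trees), threshold=threshold)


def _mask_to_clade(mask: int, taxa: list[str]) -> frozenset[str]:
    return frozenset(t for i, t in enumerate(taxa) if mask >> i & 1)


def consensus_supports_by_clade(
    consensus: ConsensusTree, rooted: RootedPhyloTree
) -> dict[int, float]:
    """Support percentage per internal node of a rooted consensus, matching
    nodes to split supports by clade leaf set (root side collapsed)."""
    taxa = frozenset(rooted.taxa())
    out: dict[int, float] = {}
    for u, clade in rooted.clades().items():
        if rooted.is_leaf(u) or u == rooted.root:
            continue
        val = consensus.supports.get(clade)
        if val is None:
            val = consensus.supports.get(taxa - clade)
        if val is not None:
            out[u] = val
    return out


# ---------------------------------------------------------------------------
# Homoplasy indices
# ---------------------------------------------------------------------------


@dataclass
class HomoplasyIndices:
    """Per-character (m, s, g, ci, ri) and ensemble (M, S, G, CI, RI) values.

    ``ri`` is undefined (NaN) for characters with g = m (e.g. uninformative
    ones); such characters still contribute to the ensemble sums unless they
    were excluded up front.
    """

    per_character: pd.DataFrame   # columns: char_index, m, s, g, ci, ri
    M: int
    S: int
    G: int
    CI: float
    RI: float
    excluded_uninformative: bool = False


def character_min_steps(column: Sequence[str]) -> int:
    """Minimum conceivable steps: observed distinct states − 1."""
    observed = {s for s in column if s != MISSING}
    if not observed:
        raise ValueError("all-missing column has no minimum step count")
    return len(observed) - 1


def character_max_steps(column: Sequence[str]) -> int:
    """Maximum conceivable steps: changes if every derived occurrence arose
    on its own terminal branch — non-missing count minus the modal state's
    frequency.  Equals the Fitch length of the column on the star tree."""
    counts = Counter(s for s in column if s != MISSING)
    if not counts:
        raise ValueError("all-missing column has no maximum step count")
    return sum(counts.values()) - max(counts.values())


def homoplasy_indices(
    matrix: CharacterMatrix,
    tree_or_lengths: PhyloTree | RootedPhyloTree | np.ndarray | Sequence[int],
    exclude_uninformative: bool = False,
) -> HomoplasyIndices:
    """CI/RI census for a matrix against a tree (or precomputed per-character
    step counts).  Raises if the supplied lengths fall below the theoretical
    minimum (an inconsistent input)."""
    from .character_coding import is_parsimony_informative

    if isinstance(tree_or_lengths, (PhyloTree, RootedPhyloTree)):
        steps = fitch_length(tree_or_lengths, matrix)
    else:
        steps = np.asarray(tree_or_lengths, dtype=np.int64)
        if steps.shape != (matrix.n_characters,):
            raise ValueError(
                f"need one step count per character ({matrix.n_characters}), got {steps.shape}"
            )
    rows = []
    for j, cd in enumerate(matrix.characters):
        col = matrix.cells[:, j]
        if exclude_uninformative and not is_parsimony_informative(col):
            continue
        m = character_min_steps(col)
        g = character_max_steps(col)
        s = int(steps[j])
        if s < m:
            raise ValueError(f"character {cd.index}: supplied length {s} < minimum {m}")
        ci = m / s if s > 0 else np.nan
        ri = (g - s) / (g - m) if g > m else np.nan
        rows.append({"char_index": cd.index, "m": m, "s": s, "g": g, "ci": ci, "ri": ri})
    df = pd.DataFrame(rows)
    M, S, G = int(df["m"].sum()), int(df["s"].sum()), int(df["g"].sum())
    if S < M:
        raise ValueError(f"total length {S} below theoretical minimum {M}")
    CI = M / S if S > 0 else float("nan")
    RI = (G - S) / (G - M) if G > M else float("nan")
    return HomoplasyIndices(per_character=df, M=M, S=S, G=G, CI=CI, RI=RI,
                            excluded_uninformative=exclude_uninformative)


def indices_to_tsv(indices: HomoplasyIndices, path) -> None:
    """Per-character table plus a one-line ensemble summary."""
    indices.per_character.to_csv(path, sep="\t", index=False)
    with open(path, "a") as fh:
        fh.write(
            f"# ensemble\tM={indices.M}\tS={indices.S}\tG={indices.G}\t"
            f"CI={indices.CI:.3f}\tRI={indices.RI:.3f}\n"
        )
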