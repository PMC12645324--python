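"""Ground-truth simulator for vertical and horizontal trait transmission.

Characters evolve down a known ranked tree: along each branch a character
changes state with a fixed probability (vertical descent), and with an
adjustable per-character rate one lineage overwrites its state with that of
a contemporaneous lineage (horizontal copying), after which the copied state
is inherited by all its descendants — which is exactly what makes horizontal
transmission register as homoplasy on the true tree.  Missing data are
injected at a fixed rate.  Every change is logged, so tests can replay the
log and recover the matrix, and parameter-recovery experiments (tree
recovery at h = 0, CI decline as h grows) have exact ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .matrix_io import MISSING, CharacterDef, CharacterMatrix, TaxonRecord
from .parsimony_core import RootedPhyloTree


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``change_prob`` is the per-branch per-character state-change probability;
    ``horizontal_rate`` is the per-character probability of one horizontal
    copying event; ``missing_rate`` the per-cell '?' probability.
    ``ternary_fraction`` controls the binary/three-state character mix;
    ``outgroup_divergence`` is the change probability on each outgroup branch.
    """

    n_taxa: int = 40
    n_chars: int = 60
    outgroup_size: int = 2
    change_prob: float = 0.1
    horizontal_rate: float = 0.0
    missing_rate: float = 0.1
    ternary_fraction: float = 0.3
    outgroup_divergence: float = 0.5
    n_countries: int = 4
    seed: int = 0

    def __post_init__(self):
        for name in ("change_prob", "horizontal_rate", "missing_rate",
                     "ternary_fraction", "outgroup_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if self.outgroup_size < 1:
            raise ValueError("outgroup_size must be >= 1")
        if self.n_taxa - self.outgroup_size < 3:
            raise ValueError("need at least 3 ingroup taxa")


@dataclass(frozen=True)
class VerticalChange:
    branch: int          # child node id on the true tree
    char_index: int      # 1-based
    from_state: str
    to_state: str


@dataclass(frozen=True)
class HorizontalCopy:
    donor: int           # donor lineage (child node id of its branch)
    recipient: int
    char_index: int
    epoch: int           # rank of the next split at copy time
    state: str


@dataclass
class EventLog:
    root_states: list[str]                 # per character
    vertical: list[VerticalChange] = field(default_factory=list)
    horizontal: list[HorizontalCopy] = field(default_factory=list)
    missing_cells: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class SyntheticDataset:
    """True tree + generated matrix + event log + metadata."""

    true_tree: RootedPhyloTree
    ranks: dict[int, int]                  # internal node -> split rank
    matrix: CharacterMatrix
    event_log: EventLog
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------


def simulate_tree(
    n_taxa: int, rng: np.random.Generator | int, prefix: str = "t"
) -> tuple[RootedPhyloTree, dict[int, int]]:
    """Random ranked topology: starting from the root, a uniformly chosen
    open lineage splits at each step until ``n_taxa`` tips exist.  Node ranks
    record the splitting order and define contemporaneity for horizontal
    copying.  Seed-deterministic."""
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    t = RootedPhyloTree()
    root = t.new_node()
    t.root = root
    open_nodes = [root]
    ranks: dict[int, int] = {}
    rank = 0
    while len(open_nodes) < n_taxa:
        i = int(rng.integers(len(open_nodes)))
        node = open_nodes.pop(i)
        rank += 1
        ranks[node] = rank
        for _ in range(2):
            child = t.new_node()
            t.attach(node, child)
            open_nodes.append(child)
    width = len(str(n_taxa))
    for k, node in enumerate(sorted(open_nodes)):
        t.labels[node] = f"{prefix}{k + 1:0{width}d}"
    return t, ranks


# ---------------------------------------------------------------------------
# Character evolution
# ---------------------------------------------------------------------------


def evolve_characters(
    tree: RootedPhyloTree,
    ranks: dict[int, int],
    config: SimulationConfig,
    rng: np.random.Generator,
    n_states: Sequence[int],
    rng_horizontal: np.random.Generator | None = None,
) -> tuple[dict[str, list[str]], EventLog]:
    """Simulate all characters forward in time over the ranked splits.

    Returns leaf states (taxon label -> list of symbols) and the event log.
    Horizontal copies happen between lineages alive at the same epoch; the
    recipient's descendants inherit the copied state.  Horizontal decisions
    draw from ``rng_horizontal`` (default: the vertical stream), so paired
    runs that differ only in the horizontal rate share identical vertical
    histories when given separate streams.
    """
    if rng_horizontal is None:
        rng_horizontal = rng
    n_chars = len(n_states)
    internal = sorted(ranks, key=ranks.get)
    n_splits = len(internal)
    log = EventLog(root_states=[])
    leaf_states: dict[str, list[str]] = {lbl: [] for lbl in tree.labels.values()}
    for j in range(n_chars):
        K = n_states[j]
        s0 = int(rng.integers(K))
        log.root_states.append(str(s0))
        # schedule at most one horizontal copy for this character
        copy_epoch = -1
        if rng_horizontal.random() < config.horizontal_rate and n_splits >= 2:
            copy_epoch = int(rng_horizontal.integers(2, n_splits + 1))
        cur: dict[int, int] = {tree.root: s0}
        for node in internal:
            k = ranks[node]
            if k == copy_epoch and len(cur) >= 2:
                # a borrowing event: the recipient adopts a contemporaneous
                # variant different from its own; if the character is
                # monomorphic at this epoch there is nothing to adopt
                alive = sorted(cur)
                recipient = alive[int(rng_horizontal.integers(len(alive)))]
                donors = [a for a in alive if cur[a] != cur[recipient]]
                if donors:
                    donor = donors[int(rng_horizontal.integers(len(donors)))]
                    cur[recipient] = cur[donor]
                    log.horizontal.append(
                        HorizontalCopy(donor=donor, recipient=recipient,
                                       char_index=j + 1, epoch=k, state=str(cur[donor]))
                    )
            state = cur.pop(node)
            for child in tree.children[node]:
                s = state
                if K > 1 and rng.random() < config.change_prob:
                    s = (state + 1 + int(rng.integers(K - 1))) % K
                    log.vertical.append(
                        VerticalChange(branch=child, char_index=j + 1,
                                       from_state=str(state), to_state=str(s))
                    )
                cur[child] = s
        for node, state in cur.items():
            leaf_states[tree.labels[node]].append(str(state))
    return leaf_states, log


def replay_event_log(dataset: SyntheticDataset) -> dict[str, list[str]]:
    """Recompute leaf states purely from the true tree and the event log.

    Used as an integrity check: the replay must reproduce every non-missing
    matrix cell.
    """
    tree, ranks, log = dataset.true_tree, dataset.ranks, dataset.event_log
    n_chars = len(log.root_states)
    vertical = {(e.branch, e.char_index): e for e in log.vertical}
    horizontal: dict[tuple[int, int], HorizontalCopy] = {
        (e.epoch, e.char_index): e for e in log.horizontal
    }
    internal = sorted(ranks, key=ranks.get)
    leaf_states: dict[str, list[str]] = {lbl: [] for lbl in tree.labels.values()}
    for j in range(n_chars):
        cur: dict[int, str] = {tree.root: log.root_states[j]}
        for node in internal:
            k = ranks[node]
            ev = horizontal.get((k, j + 1))
            if ev is not None:
                cur[ev.recipient] = cur[ev.donor]
            state = cur.pop(node)
            for child in tree.children[node]:
                vc = vertical.get((child, j + 1))
                cur[child] = vc.to_state if vc is not None else state
        for node, state in cur.items():
            leaf_states[tree.labels[node]].append(state)
    return leaf_states


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------


def generate(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Simulate a complete dataset: ranked true tree, evolved characters,
    a basally attached diverged outgroup, missing cells, and metadata that
    assigns synthetic countries to the true tree's major clades.

    Randomness is split into independent streams (tree/states, vertical
    changes, horizontal copies, missing cells), so two runs with the same
    seed that differ only in ``horizontal_rate`` share the same tree and the
    same vertical history — the paired design used to show that horizontal
    transmission depresses the consistency index.
    """
    config = config or SimulationConfig()
    ss = np.random.SeedSequence(config.seed)
    rng_tree, rng_vert, rng_horiz, rng_miss = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    n_in = config.n_taxa - config.outgroup_size
    n_states = [
        3 if rng_tree.random() < config.ternary_fraction else 2
        for _ in range(config.n_chars)
    ]
    tree, ranks = simulate_tree(n_in, rng_tree)
    leaf_states, log = evolve_characters(
        tree, ranks, config, rng_vert, n_states, rng_horizontal=rng_horiz
    )

    # attach the outgroup basally: a long shared stem (change probability
    # outgroup_divergence per character) carries the divergence, and the
    # branches inside the outgroup subtree evolve at the ordinary rate — so
    # the outgroup is a coherent distant clade, not independent noise
    old_root = tree.root
    new_root = tree.new_node()
    tree.root = new_root
    tree.attach(new_root, old_root)
    og_leaves: list[int] = []
    og_branches: list[tuple[int, float]] = []  # (child node, change prob)
    if config.outgroup_size == 1:
        leaf = tree.new_node()
        tree.attach(new_root, leaf)
        og_leaves.append(leaf)
        og_branches.append((leaf, config.outgroup_divergence))
    else:
        anchor = tree.new_node()
        tree.attach(new_root, anchor)
        og_branches.append((anchor, config.outgroup_divergence))
        cur_node = anchor
        for i in range(config.outgroup_size):
            leaf = tree.new_node()
            tree.attach(cur_node, leaf)
            og_leaves.append(leaf)
            og_branches.append((leaf, config.change_prob))
            if config.outgroup_size - (i + 1) > 1:
                nxt = tree.new_node()
                tree.attach(cur_node, nxt)
                og_branches.append((nxt, config.change_prob))
                cur_node = nxt
    og_labels = []
    for i, leaf in enumerate(og_leaves):
        lbl = f"og{i + 1}"
        tree.labels[leaf] = lbl
        og_labels.append(lbl)
    # evolve each character down the outgroup subtree, branch by branch
    node_states: dict[int, list[int]] = {new_root: [int(s) for s in log.root_states]}
    for child, prob in og_branches:  # parents precede children by construction
        parent_states = node_states[tree.parent[child]]
        states = []
        for j in range(config.n_chars):
            s = parent_states[j]
            if rng_vert.random() < prob:
                s2 = (s + 1 + int(rng_vert.integers(n_states[j] - 1))) % n_states[j]
                log.vertical.append(
                    VerticalChange(branch=child, char_index=j + 1,
                                   from_state=str(s), to_state=str(s2))
                )
                s = s2
            states.append(s)
        node_states[child] = states
    for leaf in og_leaves:
        leaf_states[tree.labels[leaf]] = [str(s) for s in node_states[leaf]]
    # rank the new spine nodes ahead of the ingroup splits so replay
    # processes them first
    spine = [u for u in tree.children if tree.children[u] and u not in ranks]
    for off, u in enumerate(sorted(spine)):
        ranks[u] = off - len(spine)

    # countries: cut the ingroup true tree into major clades
    country_of = _assign_countries(tree, old_root, config.n_countries)

    labels = sorted(leaf_states)
    cells = np.array([leaf_states[lbl] for lbl in labels], dtype="<U1")
    miss = rng_miss.random(cells.shape) < config.missing_rate
    for (i, j) in zip(*np.nonzero(miss)):
        log.missing_cells.append((labels[int(i)], int(j) + 1))
    cells[miss] = MISSING
    taxa = [
        TaxonRecord(
            taxon_id=lbl,
            group="outgroup" if lbl in og_labels else "ingroup",
            country=None if lbl in og_labels else country_of[lbl],
        )
        for lbl in labels
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns are legitimate here
        chars = [
            CharacterDef(
                index=j + 1, name=f"trait_{j + 1}",
                states=tuple(str(s) for s in range(n_states[j])),
                kind="binary" if n_states[j] == 2 else "multistate",
            )
            for j in range(config.n_chars)
        ]
        matrix = CharacterMatrix(taxa=taxa, characters=chars, cells=cells)
    return SyntheticDataset(true_tree=tree, ranks=ranks, matrix=matrix,
                            event_log=log, config=config)


def _assign_countries(tree: RootedPhyloTree, ingroup_root: int, n_countries: int) -> dict[str, str]:
    """Split the ingroup subtree into up to n_countries clades (repeatedly
    dividing the largest) and label each with a synthetic country."""
    sizes: dict[int, int] = {}
    for u in tree.postorder():
        sizes[u] = 1 if tree.is_leaf(u) else sum(sizes[c] for c in tree.children[u])
    groups: list[int] = [ingroup_root]
    while len(groups) < n_countries:
        big = max(groups, key=lambda u: (sizes[u], u))
        if tree.is_leaf(big) or sizes[big] < 2:
            break
        groups.remove(big)
        groups.extend(tree.children[big])
    out: dict[str, str] = {}
    for gi, g in enumerate(sorted(groups)):
        for lbl in tree.clade_leaves(g):
            out[lbl] = f"country_{chr(ord('A') + gi)}"
    return out


def perfect_signal_matrix(tree: RootedPhyloTree) -> CharacterMatrix:
    """One binary character per internal branch, derived inside the clade:
    on its own tree such a matrix has CI = RI = 1 (no homoplasy at all)."""
    taxa_labels = tree.taxa()
    clades = tree.clades()
    cols = []
    for u in tree.internal_nodes():
        if u == tree.root:
            continue
        clade = clades[u]
        if len(clade) < 2 or len(clade) > len(taxa_labels) - 2:
            continue
        cols.append([("1" if t in clade else "0") for t in taxa_labels])
    if not cols:
        raise ValueError("tree has no informative internal branches")
    cells = np.array(cols, dtype="<U1").T
    chars = [
        CharacterDef(index=j + 1, name=f"clade_marker_{j + 1}", states=("0", "1"))
        for j in range(cells.shape[1])
    ]
    taxa = [TaxonRecord(taxon_id=t) for t in taxa_labels]
    return CharacterMatrix(taxa=taxa, characters=chars, cells=cells)
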