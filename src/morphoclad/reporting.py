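"""Result artifacts: clade naming, composition tables, tree comparison.

These operations turn a rooted consensus plus taxon metadata into the
summaries a cladistic study reports: which large clades exist, how taxa from
each country (or any metadata field) distribute over them, which clade is
"main" for each country, and how two alternative analyses differ in topology
and composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .matrix_io import TaxonRecord
from .parsimony_core import PhyloTree, RootedPhyloTree
from .consensus_indices import ingroup_node

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CladeNamingRules:
    """How to pick the principal clades of a rooted consensus.

    By default the largest mutually disjoint ingroup clades with at least
    ``min_size`` taxa are selected and labelled "clade 1", "clade 2", ... in
    descending size order.  ``explicit`` pins labels to exact taxon sets
    instead (each must be a clade of the tree); ``max_clades`` caps the count.
    """

    min_size: int = 2
    max_clades: int | None = None
    explicit: Mapping[str, frozenset[str]] | None = None


@dataclass
class MainCladeAssignment:
    """Per metadata value: the clade(s) holding the plurality of its taxa."""

    assignments: dict[str, tuple[str, ...]]   # value -> clade label(s)
    ties: dict[str, bool]


@dataclass
class CladeCompositionTable:
    """Counts of ingroup taxa per metadata value (rows) per clade (columns),
    with an "other" column for taxa outside every named clade."""

    counts: pd.DataFrame
    by: str
    main_clades: MainCladeAssignment

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())


def name_clades(
    rooted: RootedPhyloTree,
    rules: CladeNamingRules | None = None,
) -> dict[str, frozenset[str]]:
    """Stable labels ("clade 1", ... by descending size) for the principal
    clades of a rooted consensus.  Returns label -> clade taxon set."""
    rules = rules or CladeNamingRules()
    clades = rooted.clades()
    ingroup = clades[ingroup_node(rooted)]
    if rules.explicit is not None:
        available = set(clades.values())
        for label, taxa in rules.explicit.items():
            if frozenset(taxa) not in available:
                raise ValueError(f"{label!r}: taxon set is not a clade of the tree")
        return {lbl: frozenset(t) for lbl, t in rules.explicit.items()}
    candidates = sorted(
        {
            c
            for u, c in clades.items()
            if not rooted.is_leaf(u)
            and c < ingroup
            and len(c) >= rules.min_size
        },
        key=lambda c: (-len(c), sorted(c)),
    )
    chosen: list[frozenset[str]] = []
    for c in candidates:
        if all(not (c & d) for d in chosen):
            chosen.append(c)
        if rules.max_clades is not None and len(chosen) >= rules.max_clades:
            break
    if not chosen:
        logger.warning("clade naming rules matched nothing")
    return {f"clade {i + 1}": c for i, c in enumerate(chosen)}


def clade_composition(
    rooted: RootedPhyloTree,
    metadata: Iterable[TaxonRecord],
    clade_labels: Mapping[str, frozenset[str]],
    by: str = "country",
) -> CladeCompositionTable:
    """Cross-tabulate ingroup taxa by a metadata field against named clades.

    Taxa with no value for the field are binned as "unknown"; taxa outside
    every named clade are counted in an "other" column.  Row sums equal the
    number of ingroup taxa per value, and the grand total is the ingroup size.
    """
    records = {t.taxon_id: t for t in metadata}
    outgroup = rooted.meta.get("outgroup", frozenset())
    ingroup_taxa = [t for t in rooted.taxa() if t not in outgroup
                    and records.get(t, TaxonRecord(t)).group != "outgroup"]
    labels = list(clade_labels)
    rows: dict[str, dict[str, int]] = {}
    for taxon in ingroup_taxa:
        rec = records.get(taxon)
        value = getattr(rec, by, None) if rec is not None else None
        value = value if value else "unknown"
        clade = next((lbl for lbl in labels if taxon in clade_labels[lbl]), "other")
        rows.setdefault(value, {})[clade] = rows.setdefault(value, {}).get(clade, 0) + 1
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=labels + ["other"], fill_value=0
    ).fillna(0).astype(int)
    df = df.sort_index()
    assignments: dict[str, tuple[str, ...]] = {}
    ties: dict[str, bool] = {}
    for value, row in df.iterrows():
        named = row[labels] if labels else row
        best = int(named.max()) if len(named) else 0
        winners = tuple(lbl for lbl in labels if row[lbl] == best and best > 0)
        assignments[value] = winners
        ties[value] = len(winners) > 1
    return CladeCompositionTable(
        counts=df, by=by,
        main_clades=MainCladeAssignment(assignments=assignments, ties=ties),
    )


# ---------------------------------------------------------------------------
# Tree comparison
# ---------------------------------------------------------------------------


def rf_distance(tree_a: PhyloTree | RootedPhyloTree, tree_b: PhyloTree | RootedPhyloTree) -> tuple[int, float]:
    """Robinson–Foulds symmetric difference of bipartition sets.

    Returns (raw count, normalised by the maximum possible for the two trees'
    resolutions).  Requires identical taxon sets.
    """
    ta = tree_a.unroot() if isinstance(tree_a, RootedPhyloTree) else tree_a
    tb = tree_b.unroot() if isinstance(tree_b, RootedPhyloTree) else tree_b
    if ta.taxa() != tb.taxa():
        raise ValueError("trees are not on the same taxon set")
    index = {t: i for i, t in enumerate(ta.taxa())}
    sa, sb = ta.splits(index), tb.splits(index)
    raw = len(sa ^ sb)
    denom = len(sa) + len(sb)
    return raw, (raw / denom if denom else 0.0)


@dataclass
class AnalysisComparison:
    """Topology and composition differences between two analyses."""

    rf_raw: int
    rf_normalized: float
    main_clade_deltas: pd.DataFrame   # value, pct_in_main_a, pct_in_main_b, delta
    moved_taxa: list[tuple[str, str | None, str | None]]  # taxon, clade_a, clade_b


def compare_analyses(
    consensus_a: RootedPhyloTree,
    consensus_b: RootedPhyloTree,
    metadata: Iterable[TaxonRecord],
    clades_a: Mapping[str, frozenset[str]] | None = None,
    clades_b: Mapping[str, frozenset[str]] | None = None,
    by: str = "country",
) -> AnalysisComparison:
    """Compare two rooted consensus trees over the same taxa: RF distance,
    signed percentage-point change of each metadata value's share in its main
    clade, and the taxa whose principal clade changed."""
    metadata = list(metadata)
    clades_a = clades_a if clades_a is not None else name_clades(consensus_a)
    clades_b = clades_b if clades_b is not None else name_clades(consensus_b)
    if set(clades_a) != set(clades_b):
        raise ValueError(
            f"clade labels differ between analyses: {sorted(clades_a)} vs {sorted(clades_b)}"
        )
    rf_raw, rf_norm = rf_distance(consensus_a, consensus_b)
    comp_a = clade_composition(consensus_a, metadata, clades_a, by=by)
    comp_b = clade_composition(consensus_b, metadata, clades_b, by=by)
    values = sorted(set(comp_a.counts.index) | set(comp_b.counts.index))
    rows = []
    for v in values:
        pa = _pct_in_main(comp_a, v)
        pb = _pct_in_main(comp_b, v)
        rows.append({"value": v, "pct_in_main_a": pa, "pct_in_main_b": pb,
                     "delta": None if pa is None or pb is None else round(pb - pa, 2)})
    deltas = pd.DataFrame(rows)
    moved = []
    for t in sorted({r.taxon_id for r in metadata if r.group == "ingroup"}):
        la = next((l for l, s in clades_a.items() if t in s), None)
        lb = next((l for l, s in clades_b.items() if t in s), None)
        if la != lb:
            moved.append((t, la, lb))
    return AnalysisComparison(
        rf_raw=rf_raw, rf_normalized=rf_norm,
        main_clade_deltas=deltas, moved_taxa=moved,
    )


def _pct_in_main(comp: CladeCompositionTable, value: str) -> float | None:
    if value not in comp.counts.index:
        return None
    row = comp.counts.loc[value]
    winners = comp.main_clades.assignments.get(value, ())
    if not winners:
        return None
    total = int(row.sum())
    return round(100.0 * int(row[winners[0]]) / total, 2) if total else None
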