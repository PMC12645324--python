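# Methods

## The inference problem

morphoclad implements classical maximum-parsimony cladistics for matrices of
discrete morphological (or other cultural/artefactual) characters: given a
taxa × characters table of state symbols, find the unrooted tree(s)
minimising the total number of state changes, root them on a designated
outgroup, summarise the ensemble by majority-rule consensus, map the
character-state transformations that diagnose each clade, and quantify
homoplasy with the consistency and retention indices. A companion simulator
generates matrices with known transmission history so every stage can be
validated against ground truth.

All characters are unordered and equally weighted (Fitch/Wagner counting:
any change between two states costs one step), reversals and convergences
are free, and `?` marks both missing and inapplicable observations. These
are the standard settings for morphological parsimony in PAUP*-style
analyses and are fixed, not configurable: cost matrices, ordered characters
and weights are out of scope.

## Scoring

Characters are encoded as bitmask state sets (`'k'` → bit *k* of a
`uint16`); a `?` cell is the full declared state set, i.e. a free wildcard
that the optimization may resolve to any state. Binary trees are scored
with the two-set Fitch recursion vectorised across characters; trees with
polytomies (consensus trees) fall back to a unit-cost dynamic program over
states (a Sankoff recursion with 0/1 costs), which equals Fitch counting on
binary trees and gives the hard-polytomy length otherwise. Length is
invariant to root placement; the test suite checks both scorers against
exhaustive enumeration of internal labelings on all instances up to 8
leaves and against an independent library implementation.

Two scoring identities are used as cross-checks throughout: the per-character
maximum conceivable steps *g* equals the Fitch length of that column on the
star tree, and on a "perfect signal" matrix (one binary character per branch
of a known tree) every character has *s = m*, so CI = RI = 1.

## Ancestral states, transformations, ambiguity

ACCTRAN and DELTRAN labelings are built from exact unit-cost DP tables
(minimum total changes below every node for every state), resolved in
preorder: at each node the feasible states are those preserving the global
minimum given the parent's state; the accelerated variant changes state
whenever a feasible alternative exists (placing changes rootward, so
reversals are favoured over parallelisms), the delayed variant keeps the
parent's state whenever feasible. Ties among feasible states break toward
the smallest state symbol. Both labelings always total exactly the Fitch
length per character (asserted property).

A transformation event (branch, character, from→to) is flagged
**unambiguous** only when *every* minimum-length labeling places the
identical change on that branch. This is computed exactly from
inside/outside DP tables: for each branch the set of (parent-state,
child-state) pairs attainable at the global minimum is enumerated (≤ 10×10
per character); the event is forced iff no same-state pair is attainable
and exactly one pair attains the minimum. Comparing ACCTRAN against
DELTRAN labelings was considered and rejected: the two can coincide on
events that are nonetheless movable (e.g. two parallel changes on a
four-taxon tree), so the comparison under-reports ambiguity.

Synapomorphy lists for a clade are the events on its stem branch, formatted
in the conventional character-with-superscript-state style (e.g. `5¹`).

## Unsupported-branch collapse

An internal branch is collapsed (contracted into a polytomy) when its
maximum length over all minimum-length optimizations of every character is
zero — no optimization can place a change on it. This is computed exactly
from the same inside/outside tables (is there a minimum-cost assignment
with different states at the branch ends?) rather than from first-pass
state-set heuristics. Collapse never changes tree length (asserted).

## Heuristic search

Starting trees come from random stepwise addition: taxa in seeded-random
order, each attached at the branch minimising the incremental length, ties
broken uniformly at random. Branch swapping is TBR: bisect at every branch,
splice the cut stubs, and evaluate reconnecting every branch of one
fragment to every branch of the other. The key efficiency device is that a
fragment's length is invariant to where it is rooted, so the length of a
reconnected tree is

    len(X) + len(Y) + #characters whose rooted edge state sets are disjoint,

which turns a whole TBR neighbourhood into one broadcast bitwise-AND per
bisection; neighbours are only materialised when accepted. SPR and NNI are
provided as restrictions of the same machinery (fragment attachment pinned
to its original branch; reconnection limited to branches adjacent to the
original point).

Each replicate descends first-improvement (optionally steepest) to a local
optimum; equally parsimonious distinct topologies are enqueued in a buffer
capped at `max_trees` (default 10,000) and each buffered tree is swapped
once, PAUP*-style; any strictly shorter tree restarts the buffer at the new
length. Hitting the cap stops enqueueing but not swapping, mirroring a
MAXTREES-limited run, and is reported, not raised. Topologies are
deduplicated by canonical bipartition-set hash (splits as integer bitsets
over an alphabetical taxon index); the final ensemble is collapsed under
the max-length-0 rule and deduplicated again. With a fixed seed the entire
run is reproducible bit for bit.

At five leaves, note, TBR coincides with SPR (every bisection strands a
fragment with at most two leaves), giving 2(n−3)(2n−7) = 12 distinct
neighbours — not all 14 alternative topologies; search relies on repeated
moves, not one-step coverage.

## Rooting, consensus, indices

Rooting places the root on the branch separating the outgroup from the
ingroup when the outgroup is monophyletic on the unrooted tree; otherwise
the branch best separating the two sets is used and the result carries a
non-monophyly flag.

The majority-rule consensus retains exactly the bipartitions present in
strictly more than the threshold fraction (default 0.5) of trees — "more
than 50%" is strict, so exactly-half clades are excluded — with supports
reported as percentages to one decimal. Retained clades are mutually
compatible for thresholds ≥ 0.5; compatibility is asserted on every build.
The consensus topology is scorable like any tree (its polytomies scored as
hard polytomies), so a "consensus length" can be reported alongside the
ensemble length.

Homoplasy indices follow the standard definitions: per character,
m = (observed states − 1), s = realised steps on the evaluated tree,
g = steps if every change were terminal (= star-tree length);
ci = m/s, ri = (g−s)/(g−m); ensemble CI = ΣM/ΣS, RI = (ΣG−ΣS)/(ΣG−ΣM).
m is observed-states−1 for **all** characters, binary and multistate alike.
Characters with g = m (e.g. parsimony-uninformative ones) have an undefined
ri, reported as NaN; they remain in the ensemble sums by default (PAUP*
behaviour), with an option to exclude them. Ensemble CI and RI depend only
on the matrix and the per-character lengths, so equally long trees yield
identical ensemble values (asserted).

## Reporting

Principal clades are, by default, the largest mutually disjoint ingroup
clades above a size floor (default 2), labelled "clade 1, 2, …" in
descending size; explicit taxon-set selection is available when the clades
of interest are hand-picked. Composition tables cross-tabulate ingroup
taxa by a metadata field (country by default) against named clades, with an
"other" column for unplaced taxa; the "main clade" of a metadata value is
the plurality clade, with ties reported as dual assignments (a strict
majority rule would leave 50/50 countries unassigned). Tree comparison
uses the Robinson–Foulds symmetric difference, normalised by the total
split count of the two trees, plus signed percentage-point changes in each
value's main-clade share and the list of taxa whose principal clade
changed.

## The simulator

`synthetic_data.generate` produces a ranked random tree (a uniformly chosen
open lineage splits at each step — a Yule-type topology whose split order
defines contemporaneity), evolves each character forward in time, attaches
an outgroup, injects missing cells, and assigns synthetic "countries" to
the major clades of the true ingroup tree so the reporting layer can be
exercised end to end.

Transmission model, per character:

- **Vertical**: the root draws a uniform state; along every branch the
  state changes with probability `change_prob` to a uniformly chosen
  different state.
- **Horizontal**: with probability `horizontal_rate` the character
  experiences one borrowing event at a uniformly chosen epoch: a recipient
  lineage alive at that epoch adopts the state of a contemporaneous lineage
  carrying a *different* variant (if the character is monomorphic at that
  epoch there is no innovation to adopt and no event occurs), and the
  adopted state is inherited by all the recipient's descendants. This
  propagation is what converts borrowing into homoplasy on the true tree
  rather than into isolated autapomorphies. Contemporaneity is defined by
  split ranks, not branch lengths, because the inference side is purely
  topological.
- **Outgroup**: attached basally as its own subtree; a shared stem branch
  changes with probability `outgroup_divergence` per character (so the
  outgroup is a coherent, distant clade with stem synapomorphies), and
  branches inside the outgroup subtree evolve at the ordinary rate.
- **Missing data**: cells are independently replaced by `?` at
  `missing_rate`.

Every event (root states, vertical changes, borrowings, missing cells) is
logged; replaying the log down the true tree reproduces every non-missing
cell exactly (asserted), which pins the generator's semantics.

Randomness is split into four independent streams (tree/states, vertical,
horizontal, missing) derived from one seed. Two runs sharing a seed but
differing in `horizontal_rate` therefore share the identical tree and
vertical history, making comparisons across h a genuinely paired design.

Defaults (`SimulationConfig`): 40 taxa including 2 outgroup, 60 characters
(70% binary / 30% three-state), change_prob 0.1, horizontal_rate 0,
missing_rate 0.1, outgroup stem divergence 0.5 — a desk-scale dataset with
realistic levels of multiple hits (ensemble CI around 0.2 after search) and
roughly 10% missing cells.

What the simulator does **not** emulate: correlated characters, lineage- or
character-specific rates, inapplicable-state structure (all `?` are missing
at random), population-level processes, selection or attraction between
variants, and any actual artefact morphology. Passing recovery tests on
simulated data therefore shows the pipeline is correct and internally
consistent, not that real matrices satisfy these assumptions.

## Validation experiments and problem sizes

The test suite and the acceptance script use deliberately small problem
sizes so a full run stays in the minutes range on one CPU:

- Exhaustive oracles: Fitch vs brute-force labeling on random ≤8-leaf,
  ≤4-state instances; heuristic search vs enumeration of all topologies on
  ≤7 taxa; collapse vs an exhaustive census of optimal labelings on 5-leaf
  instances.
- **Recovery** (vertical-only): 12 ingroup + 2 outgroup taxa, 1000
  characters, change_prob 0.006, outgroup stem divergence 0.15, no missing
  data — about six expected supporting changes per branch and well under
  one expected extra hit per character. Under these low-noise conditions
  the search's ensemble length equals the true tree's length and the true
  tree is among the returned most parsimonious trees (Robinson–Foulds 0 to
  an ensemble member) on every seed tried; occasionally an equally
  parsimonious alternative also survives, leaving the consensus one
  polytomy short, which is why recovery is asserted against the ensemble
  rather than the consensus.
- **Homoplasy from borrowing**: 16 taxa, 30 characters, change_prob 0.1,
  missing 0.1, h = 0 vs h = 0.5 over 20 paired seeds; the mean ensemble CI
  decreases under borrowing (typically by ≈ 0.015–0.02, with ~18/20 pairs
  decreasing). Only the direction is asserted — no quantitative borrowing
  rate exists to target.

## Numerical and degenerate-input conventions

- State symbols are single characters `0`–`9`; `?` is the only missing
  marker, and inapplicable states are not distinguished from missing.
- Equal-width discretization uses left-closed/right-open bins with a closed
  last bin (the observed maximum falls in the top class); bounds default to
  the observed range and can be supplied explicitly; a constant measurement
  yields a degenerate single-state column with a warning, not an error.
- Constant columns are legal throughout (length 0, ci undefined as 0/0).
- All tie-breaks are deterministic (smallest state symbol, alphabetical
  taxon order, first-found edge) except where a seeded RNG is documented
  (addition order, attachment ties).
- Buffer overflow in search, non-monophyletic outgroups, and metadata gaps
  are reported conditions, never exceptions.

## Known limitations

- ACCTRAN/DELTRAN tie-breaking conventions for multistate characters vary
  between programs; branch-by-branch reproduction of another program's
  transformation labels is not guaranteed (totals and ambiguity flags are).
- The search is a heuristic: optimality is only guaranteed where the test
  suite enumerates (≤7 taxa); larger instances inherit the usual
  local-optimum caveats of TBR with random restarts.
- The per-character ci/ri census depends on which tree it is evaluated on;
  for consensus trees with polytomies the hard-polytomy length is used.
- RF distance saturates quickly for poorly resolved trees; the normalised
  value uses the two trees' actual split counts, so a star tree is at
  distance 1.0 from any resolved tree.
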