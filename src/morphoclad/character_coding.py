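"""Character construction: discretization, recoding, subsetting, screening.

These operations turn raw descriptive parameters into analysis-ready
characters: continuous measurements are cut into equal-width classes,
ornament-only columns can be dropped, states can be merged (e.g. collapsing
"present, engraved" and "present, plain" into "present"), and columns can be
screened for parsimony informativeness.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .matrix_io import MISSING, CharacterDef, CharacterMatrix


@dataclass(frozen=True)
class DiscretizationRule:
    """Equal-width binning of a continuous measurement into state classes.

    Bins are left-closed/right-open except the last, which is closed, so the
    maximum falls in the top class.  ``degenerate`` flags a constant
    measurement (zero width), which maps everything to state '0'.
    """

    n_classes: int
    min_value: float
    max_value: float
    degenerate: bool = False

    @property
    def bin_edges(self) -> tuple[float, ...]:
        w = (self.max_value - self.min_value) / self.n_classes
        return tuple(self.min_value + i * w for i in range(self.n_classes + 1))

    def state_of(self, v: float) -> str:
        if self.degenerate:
            return "0"
        if not (self.min_value <= v <= self.max_value):
            raise ValueError(f"value {v} outside [{self.min_value}, {self.max_value}]")
        w = (self.max_value - self.min_value) / self.n_classes
        k = min(int((v - self.min_value) // w), self.n_classes - 1)
        return str(k)

    def to_json(self) -> str:
        return json.dumps(
            {"n_classes": self.n_classes, "min_value": self.min_value,
             "max_value": self.max_value, "bin_edges": list(self.bin_edges)}
        )

    @staticmethod
    def from_json(s: str) -> "DiscretizationRule":
        d = json.loads(s)
        return DiscretizationRule(
            n_classes=d["n_classes"], min_value=d["min_value"], max_value=d["max_value"],
            degenerate=d["min_value"] == d["max_value"],
        )


def discretize_equal_width(
    values: Sequence[float | None],
    n_classes: int = 4,
    bounds: tuple[float, float] | None = None,
) -> tuple[DiscretizationRule, list[str]]:
    """Map measurements to states '0'..'n_classes-1' via equal-width classes.

    Missing entries (None or NaN) pass through as '?'.  Bounds default to the
    observed min/max; explicit bounds may be given for reproducibility.  A
    constant measurement yields a degenerate single-state rule and a warning.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    present = [v for v in values if v is not None and not math.isnan(v)]
    if not present:
        raise ValueError("all values missing; nothing to discretize")
    lo, hi = bounds if bounds is not None else (min(present), max(present))
    degenerate = lo == hi
    if degenerate:
        warnings.warn("constant measurement: all values map to state '0'", stacklevel=2)
    rule = DiscretizationRule(n_classes=n_classes, min_value=lo, max_value=hi,
                              degenerate=degenerate)
    states = [
        MISSING if v is None or math.isnan(v) else rule.state_of(v)
        for v in values
    ]
    return rule, states


def is_parsimony_informative(column: Sequence[str]) -> bool:
    """True iff at least two distinct states each occur in >= 2 taxa.

    Missing cells are ignored (a wildcard can always match the commonest
    state for free, so it never makes a character informative).  A column
    failing this test has the same length on every tree.
    """
    counts: dict[str, int] = {}
    for s in column:
        if s != MISSING:
            counts[s] = counts.get(s, 0) + 1
    return sum(1 for n in counts.values() if n >= 2) >= 2


def subset_characters(
    matrix: CharacterMatrix,
    keep: Callable[[CharacterDef], bool],
) -> CharacterMatrix:
    """New matrix with only the characters satisfying ``keep``, in original
    order; character indices are renumbered 1..k.  Taxa are untouched."""
    kept = [(j, c) for j, c in enumerate(matrix.characters) if keep(c)]
    if not kept:
        raise ValueError("predicate retains zero characters")
    cols = [j for j, _ in kept]
    chars = [replace(c, index=i + 1) for i, (_, c) in enumerate(kept)]
    return CharacterMatrix(
        taxa=list(matrix.taxa), characters=chars, cells=matrix.cells[:, cols].copy()
    )


def merge_states(
    matrix: CharacterMatrix,
    char_index: int,
    state_mapping: dict[str, str],
) -> CharacterMatrix:
    """Recode one character's states through a surjective symbol mapping.

    '?' always maps to '?'.  The character definition is updated (a 3-state
    column collapsed to two symbols becomes binary); collapsing everything to
    one state leaves a constant, uninformative column and a warning.
    """
    pos = {c.index: j for j, c in enumerate(matrix.characters)}
    if char_index not in pos:
        raise KeyError(f"no character with index {char_index}")
    j = pos[char_index]
    cd = matrix.characters[j]
    col = matrix.cells[:, j]
    unmapped = sorted(set(col) - set(state_mapping) - {MISSING})
    if unmapped:
        raise ValueError(f"character {char_index}: unmapped symbol(s) {unmapped}")
    new_col = np.array([MISSING if s == MISSING else state_mapping[s] for s in col], dtype="<U1")
    new_states = tuple(sorted({state_mapping[s] for s in cd.states if s in state_mapping}))
    if len(new_states) < 2:
        warnings.warn(
            f"character {char_index}: merge leaves a constant column (uninformative)",
            stacklevel=2,
        )
    new_labels = {
        state_mapping[s]: lbl for s, lbl in cd.state_labels.items() if s in state_mapping
    }
    if len(new_states) == 2:
        kind = "binary"
    elif cd.kind == "discretized_continuous":
        kind = cd.kind
    else:
        kind = "multistate"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        new_cd = replace(cd, states=new_states, state_labels=new_labels, kind=kind)
    cells = matrix.cells.copy()
    cells[:, j] = new_col
    chars = list(matrix.characters)
    chars[j] = new_cd
    return CharacterMatrix(taxa=list(matrix.taxa), characters=chars, cells=cells)
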