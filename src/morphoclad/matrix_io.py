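"""Reading, writing and summarising taxa × characters matrices.

Matrices hold discrete state symbols ``'0'``–``'9'`` with ``'?'`` marking
missing (or inapplicable) cells.  NEXUS is parsed through dendropy; CSV
matrices and taxon-metadata tables go through pandas.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = "?"
SYMBOLS = "0123456789"

Group = Literal["ingroup", "outgroup"]
Source = Literal["museum", "field", "private"]


@dataclass(frozen=True)
class TaxonRecord:
    """One evolutionary unit (a specimen standing for a group of artefacts)."""

    taxon_id: str
    group: Group = "ingroup"
    country: str | None = None
    population: str | None = None
    source: Source | None = None


@dataclass(frozen=True)
class CharacterDef:
    """One column of the matrix: a discrete, unordered character.

    ``index`` is 1-based, matching how characters are cited in clade
    annotations (e.g. ``5¹``).  ``states`` is the declared symbol set;
    ``kind`` distinguishes binary, multistate and discretized-continuous
    characters; ``decorative`` marks characters describing ornament rather
    than structure, so they can be subset away.
    """

    index: int
    name: str
    states: tuple[str, ...]
    kind: Literal["binary", "multistate", "discretized_continuous"] = "binary"
    state_labels: dict[str, str] = field(default_factory=dict)
    decorative: bool = False

    def __post_init__(self):
        for s in self.states:
            if s not in SYMBOLS:
                raise ValueError(f"character {self.index}: invalid state symbol {s!r}")
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"character {self.index}: duplicate state symbols")
        if len(self.states) < 2:
            warnings.warn(
                f"character {self.index} ({self.name!r}) declares fewer than 2 states",
                stacklevel=2,
            )
        if self.kind == "binary" and len(self.states) != 2:
            raise ValueError(f"character {self.index}: binary character must have 2 states")


def _infer_kind(states: Sequence[str]) -> str:
    return "binary" if len(states) == 2 else "multistate"


@dataclass
class CharacterMatrix:
    """Taxa × characters grid of state symbols with per-taxon metadata."""

    taxa: list[TaxonRecord]
    characters: list[CharacterDef]
    cells: np.ndarray  # (n_taxa, n_chars) of '<U1'

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype="<U1")
        ids = [t.taxon_id for t in self.taxa]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate taxon ids: {dupes}")
        if self.cells.shape != (len(self.taxa), len(self.characters)):
            raise ValueError(
                f"cell grid {self.cells.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.characters)} characters"
            )
        for j, cd in enumerate(self.characters):
            col = self.cells[:, j]
            bad = sorted(set(col) - set(cd.states) - {MISSING})
            if bad:
                raise ValueError(
                    f"character {cd.index}: undeclared symbol(s) {bad} in column"
                )

    # -- access -----------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def taxon_labels(self) -> list[str]:
        return [t.taxon_id for t in self.taxa]

    def column(self, char_index: int) -> np.ndarray:
        """Column of state symbols for a 1-based character index."""
        pos = {c.index: j for j, c in enumerate(self.characters)}
        return self.cells[:, pos[char_index]]

    def taxon(self, taxon_id: str) -> TaxonRecord:
        for t in self.taxa:
            if t.taxon_id == taxon_id:
                return t
        raise KeyError(taxon_id)

    def ingroup_taxa(self) -> list[TaxonRecord]:
        return [t for t in self.taxa if t.group == "ingroup"]

    def outgroup_taxa(self) -> list[TaxonRecord]:
        return [t for t in self.taxa if t.group == "outgroup"]


@dataclass(frozen=True)
class MatrixSummary:
    n_taxa: int
    n_characters: int
    n_binary: int
    n_multistate: int
    missing_proportion: float
    n_uninformative: int


def _defs_from_columns(cells: np.ndarray, names: Sequence[str] | None = None) -> list[CharacterDef]:
    defs = []
    for j in range(cells.shape[1]):
        observed = tuple(sorted(set(cells[:, j]) - {MISSING}))
        name = names[j] if names else f"char_{j + 1}"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tolerate constant columns here
            defs.append(
                CharacterDef(index=j + 1, name=name, states=observed,
                             kind=_infer_kind(observed))
            )
    return defs


# ---------------------------------------------------------------------------
# NEXUS
# ---------------------------------------------------------------------------


def read_nexus(path: str | Path, metadata_path: str | Path | None = None) -> CharacterMatrix:
    """Read a NEXUS standard-character matrix (TAXA + CHARACTERS/DATA blocks).

    State symbols are preserved verbatim; an optional metadata CSV joins
    group/country/population onto the taxa (see :func:`read_metadata`).
    """
    try:
        dm = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    except Exception as exc:  # dendropy raises several parser error types
        raise ValueError(f"cannot parse NEXUS matrix {path}: {exc}") from exc
    labels = [t.label for t in dm.taxon_namespace]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate taxon labels in NEXUS file")
    rows = []
    for tax in dm.taxon_namespace:
        rows.append([c.symbol for c in dm[tax]])
    lens = {len(r) for r in rows}
    if len(lens) != 1:
        raise ValueError(f"rows differ in length: {sorted(lens)}")
    cells = np.array(rows, dtype="<U1")
    meta = read_metadata(metadata_path) if metadata_path else {}
    taxa = [_apply_metadata(lbl, meta) for lbl in labels]
    _warn_missing_metadata(labels, meta)
    return CharacterMatrix(taxa=taxa, characters=_defs_from_columns(cells), cells=cells)


def write_nexus(matrix: CharacterMatrix, path: str | Path) -> None:
    """Write a matrix as a NEXUS file (symbols, taxon and character order preserved)."""
    lines = ["#NEXUS", "", "BEGIN TAXA;", f"    DIMENSIONS NTAX={matrix.n_taxa};"]
    lines.append("    TAXLABELS " + " ".join(_nexus_label(t.taxon_id) for t in matrix.taxa) + ";")
    lines += ["END;", "", "BEGIN CHARACTERS;",
              f"    DIMENSIONS NCHAR={matrix.n_characters};",
              f'    FORMAT DATATYPE=STANDARD MISSING={MISSING} SYMBOLS="{SYMBOLS}";',
              "    MATRIX"]
    width = max(len(t.taxon_id) for t in matrix.taxa) + 2
    for i, t in enumerate(matrix.taxa):
        lines.append("    " + _nexus_label(t.taxon_id).ljust(width) + "".join(matrix.cells[i]))
    lines += ["    ;", "END;", ""]
    Path(path).write_text("\n".join(lines))


def _nexus_label(label: str) -> str:
    if any(c in label for c in " ()[]{}/\\,;:=*'\"`+<>-"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------


def read_csv_matrix(matrix_path: str | Path, metadata_path: str | Path | None = None) -> CharacterMatrix:
    """Read a CSV matrix (taxon ids in the first column, one character per
    subsequent column) plus an optional metadata CSV keyed by taxon id.

    Taxa present in the matrix but absent from the metadata default to the
    ingroup with null country/population and a logged warning.
    """
    df = pd.read_csv(matrix_path, dtype=str, keep_default_na=False)
    ids = df.iloc[:, 0].tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate taxon ids: {dupes}")
    cells = df.iloc[:, 1:].to_numpy(dtype="<U1")
    names = list(df.columns[1:])
    meta = read_metadata(metadata_path) if metadata_path else {}
    if metadata_path is None:
        logger.warning("no metadata supplied; all %d taxa default to the ingroup", len(ids))
    taxa = [_apply_metadata(lbl, meta) for lbl in ids]
    _warn_missing_metadata(ids, meta)
    return CharacterMatrix(taxa=taxa, characters=_defs_from_columns(cells, names), cells=cells)


def write_csv_matrix(matrix: CharacterMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.cells, columns=[c.name for c in matrix.characters])
    df.insert(0, "taxon_id", matrix.taxon_labels())
    df.to_csv(path, index=False)


def read_metadata(path: str | Path | None) -> dict[str, TaxonRecord]:
    """Read a taxon-metadata CSV (taxon_id, group, country, population, source)."""
    if path is None or not Path(path).exists():
        if path is not None:
            logger.warning("metadata file %s not found; all taxa default to the ingroup", path)
        return {}
    df = pd.read_csv(path, dtype=str)
    records: dict[str, TaxonRecord] = {}
    for _, row in df.iterrows():
        tid = row["taxon_id"]
        if tid in records:
            raise ValueError(f"duplicate taxon id in metadata: {tid}")
        group = row.get("group", "ingroup")
        if pd.isna(group) or group not in ("ingroup", "outgroup"):
            group = "ingroup"

        def opt(key: str) -> str | None:
            val = row.get(key)
            return None if val is None or pd.isna(val) or val == "" else val

        records[tid] = TaxonRecord(
            taxon_id=tid, group=group, country=opt("country"),
            population=opt("population"), source=opt("source"),
        )
    return records


def write_metadata(taxa: Iterable[TaxonRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"taxon_id": t.taxon_id, "group": t.group, "country": t.country,
             "population": t.population, "source": t.source}
            for t in taxa
        ]
    ).to_csv(path, index=False)


def _apply_metadata(label: str, meta: dict[str, TaxonRecord]) -> TaxonRecord:
    return meta.get(label, TaxonRecord(taxon_id=label))


def _warn_missing_metadata(labels: Sequence[str], meta: dict[str, TaxonRecord]) -> None:
    if meta:
        absent = [l for l in labels if l not in meta]
        if absent:
            logger.warning(
                "%d taxa missing from metadata, defaulting to ingroup: %s%s",
                len(absent), ", ".join(absent[:5]), "..." if len(absent) > 5 else "",
            )


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------


def matrix_summary(matrix: CharacterMatrix) -> MatrixSummary:
    """Descriptive statistics: binary/multistate counts, missing-data
    proportion over the full grid, and parsimony-uninformative character count."""
    from .character_coding import is_parsimony_informative

    n_binary = sum(1 for c in matrix.characters if len(c.states) == 2)
    n_multi = sum(1 for c in matrix.characters if len(c.states) > 2)
    missing = float((matrix.cells == MISSING).sum()) / matrix.cells.size
    n_uninf = sum(
        1 for j in range(matrix.n_characters)
        if not is_parsimony_informative(matrix.cells[:, j])
    )
    return MatrixSummary(
        n_taxa=matrix.n_taxa, n_characters=matrix.n_characters,
        n_binary=n_binary, n_multistate=n_multi,
        missing_proportion=missing, n_uninformative=n_uninf,
    )
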