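"""Tabular input/output for screening evaluation.

Two kinds of table travel through the pipeline: an *affinity table*
(compounds x biological targets, experimental Ki in nM) and one or more
*score tables* (compounds x receptor structures, docking or rescoring
scores). Both are plain delimited text with the compound identifier in the
first column.

Affinity cells can be in one of three states:

* a positive Ki in nM,
* ``ND`` ("no detectable binding") — a real experimental outcome, stored as
  ``+inf`` so that it sorts as "weakest possible binder",
* MISSING (compound never tested on that target), stored as ``NaN``.

The two sentinels are deliberately distinct: ND participates in
categorization (it maps to the red traffic light), MISSING is excluded from
every downstream statistic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ND",
    "Direction",
    "Aggregation",
    "TableError",
    "AffinityTable",
    "ScoreTable",
    "TargetMap",
    "read_affinity_table",
    "read_score_table",
    "read_target_map",
    "align_tables",
    "write_affinity_table",
    "write_score_table",
    "write_category_matrix",
    "read_category_matrix",
]

#: sentinel for "no detectable binding" inside affinity matrices
ND = np.inf


class TableError(ValueError):
    """Malformed or inconsistent tabular input."""


class Direction(str, enum.Enum):
    """Orientation of a score: docking energies are lower-is-better."""

    LOWER_IS_BETTER = "lower_is_better"
    HIGHER_IS_BETTER = "higher_is_better"


class Aggregation(str, enum.Enum):
    """How several receptor structures of one target collapse to one column.

    ``per_structure`` keeps every structure as its own comparison (the
    in vitro column is replicated); ``best_score`` takes the best score under
    the table's direction; ``mean_score`` averages; ``single`` requires a
    one-to-one structure/target map.
    """

    SINGLE = "single"
    BEST_SCORE = "best_score"
    MEAN_SCORE = "mean_score"
    PER_STRUCTURE = "per_structure"


def _require_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if not i:
            raise TableError(f"empty {what} identifier")
        if i in seen:
            raise TableError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class AffinityTable:
    """Compounds x targets matrix of experimental Ki values (nM).

    ``values[i, j]`` is a positive Ki, ``+inf`` (ND) or ``NaN`` (MISSING).
    """

    compound_ids: list[str]
    target_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        shape = (len(self.compound_ids), len(self.target_ids))
        if self.values.size != shape[0] * shape[1]:
            raise TableError(
                f"affinity matrix shape {self.values.shape} does not match "
                f"{shape[0]} compounds x {shape[1]} targets"
            )
        self.values = self.values.reshape(shape)
        _require_unique(self.compound_ids, "compound")
        _require_unique(self.target_ids, "target")
        finite = np.isfinite(self.values)
        if np.any(self.values[finite] <= 0):
            raise TableError("affinity table contains non-positive Ki values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def is_nd(self) -> np.ndarray:
        return np.isposinf(self.values)

    def is_missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self, nd_token: str = "ND", missing_token: str = "") -> pd.DataFrame:
        cells = np.empty(self.values.shape, dtype=object)
        finite = np.isfinite(self.values)
        cells[finite] = [_fmt_number(x) for x in self.values[finite]]
        cells[self.is_nd()] = nd_token
        cells[self.is_missing()] = missing_token
        df = pd.DataFrame(cells, columns=self.target_ids)
        df.insert(0, "compound_id", self.compound_ids)
        return df


@dataclass
class ScoreTable:
    """Compounds x receptor structures matrix of real-valued scores.

    ``NaN`` marks a missing score. ``direction`` states which way is better
    (docking and rescoring energies: lower).
    """

    compound_ids: list[str]
    structure_ids: list[str]
    values: np.ndarray
    direction: Direction = Direction.LOWER_IS_BETTER

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.direction = Direction(self.direction)
        shape = (len(self.compound_ids), len(self.structure_ids))
        if self.values.size != shape[0] * shape[1]:
            raise TableError(
                f"score matrix shape {self.values.shape} does not match "
                f"{shape[0]} compounds x {shape[1]} structures"
            )
        self.values = self.values.reshape(shape)
        _require_unique(self.compound_ids, "compound")
        _require_unique(self.structure_ids, "structure")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def is_missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self, missing_token: str = "") -> pd.DataFrame:
        cells = np.empty(self.values.shape, dtype=object)
        ok = ~np.isnan(self.values)
        cells[ok] = [_fmt_number(x) for x in self.values[ok]]
        cells[~ok] = missing_token
        df = pd.DataFrame(cells, columns=self.structure_ids)
        df.insert(0, "compound_id", self.compound_ids)
        return df


@dataclass
class TargetMap:
    """Links score-table structure columns to affinity-table targets.

    Needed because several receptor structures (e.g. four homology models of
    one receptor) may correspond to a single in vitro column.
    """

    entries: dict[str, str]
    aggregation: Aggregation = Aggregation.PER_STRUCTURE

    def __post_init__(self) -> None:
        self.aggregation = Aggregation(self.aggregation)
        if not self.entries:
            raise TableError("target map has no entries")

    @classmethod
    def identity(
        cls, ids: Sequence[str], aggregation: Aggregation | str = Aggregation.SINGLE
    ) -> "TargetMap":
        """Map where each structure column *is* its target column."""
        return cls({i: i for i in ids}, Aggregation(aggregation))


def _fmt_number(x: float) -> str:
    return format(x, ".12g")


def _read_frame(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    # keep_default_na=False so empty cells arrive as "" and tokens like "NA"
    # are never silently converted
    if delimiter is None:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if df.shape[1] < 1:
        raise TableError(f"{path}: no columns found")
    return df


def _parse_cell(
    raw: str, nd_token: str, missing_token: str, row: str, col: str, allow_nd: bool
) -> float:
    cell = raw.strip()
    if cell == missing_token or cell == "":
        return np.nan
    if allow_nd and cell == nd_token:
        return ND
    try:
        return float(cell)
    except ValueError:
        raise TableError(
            f"non-numeric cell {raw!r} at compound {row!r}, column {col!r}"
        ) from None


def read_affinity_table(
    path: str | Path,
    nd_token: str = "ND",
    missing_token: str = "",
    delimiter: str | None = None,
) -> AffinityTable:
    """Read a compounds x targets Ki table (nM) from delimited text.

    Cells equal to ``nd_token`` become ND; cells equal to ``missing_token``
    (or empty) become MISSING. Any other non-numeric cell, a duplicate
    compound identifier, or a non-positive Ki is a hard error.
    """
    df = _read_frame(path, delimiter)
    compounds = [str(c) for c in df.iloc[:, 0]]
    _require_unique(compounds, "compound")
    targets = [str(c) for c in df.columns[1:]]
    values = np.empty((len(compounds), len(targets)))
    for j, col in enumerate(targets):
        for i, cpd in enumerate(compounds):
            v = _parse_cell(df.iloc[i, j + 1], nd_token, missing_token, cpd, col, True)
            if np.isfinite(v) and v <= 0:
                raise TableError(
                    f"non-positive Ki {v} at compound {cpd!r}, target {col!r}"
                )
            values[i, j] = v
    return AffinityTable(compounds, targets, values)


def read_score_table(
    path: str | Path,
    direction: Direction | str = Direction.LOWER_IS_BETTER,
    missing_token: str = "",
    delimiter: str | None = None,
) -> ScoreTable:
    """Read a compounds x structures score table; empty cells become MISSING."""
    df = _read_frame(path, delimiter)
    compounds = [str(c) for c in df.iloc[:, 0]]
    _require_unique(compounds, "compound")
    structures = [str(c) for c in df.columns[1:]]
    values = np.empty((len(compounds), len(structures)))
    for j, col in enumerate(structures):
        for i, cpd in enumerate(compounds):
            values[i, j] = _parse_cell(df.iloc[i, j + 1], "", missing_token, cpd, col, False)
    return ScoreTable(compounds, structures, values, Direction(direction))


def read_target_map(
    path: str | Path,
    aggregation: Aggregation | str = Aggregation.PER_STRUCTURE,
    delimiter: str | None = None,
) -> TargetMap:
    """Read a two-column (structure_id, target_id) map."""
    df = _read_frame(path, delimiter)
    if df.shape[1] < 2:
        raise TableError(f"{path}: target map needs two columns (structure, target)")
    structures = [str(s) for s in df.iloc[:, 0]]
    _require_unique(structures, "structure")
    return TargetMap(dict(zip(structures, (str(t) for t in df.iloc[:, 1]))), aggregation)


def write_affinity_table(
    table: AffinityTable,
    path: str | Path,
    nd_token: str = "ND",
    missing_token: str = "",
) -> None:
    table.to_frame(nd_token, missing_token).to_csv(path, index=False)


def write_score_table(table: ScoreTable, path: str | Path, missing_token: str = "") -> None:
    table.to_frame(missing_token).to_csv(path, index=False)


def align_tables(
    aff: AffinityTable, score: ScoreTable, target_map: TargetMap
) -> tuple[AffinityTable, ScoreTable]:
    """Restrict both tables to shared compounds and pair columns per the map.

    The output pair has identical compound ordering (the affinity table's
    order) and one column per comparison. Under ``per_structure`` every
    structure column is kept and the in vitro column is replicated for each
    structure of the same target; under ``best_score`` / ``mean_score`` the
    structures of one target collapse to a single column; ``single`` demands
    a one-to-one map.
    """
    score_index = {c: i for i, c in enumerate(score.compound_ids)}
    shared = [c for c in aff.compound_ids if c in score_index]
    if not shared:
        raise TableError("affinity and score tables share no compounds")

    unmapped = [s for s in score.structure_ids if s not in target_map.entries]
    if unmapped:
        raise TableError(f"score columns not covered by target map: {unmapped}")
    aff_col = {t: j for j, t in enumerate(aff.target_ids)}
    for s, t in target_map.entries.items():
        if s in score.structure_ids and t not in aff_col:
            raise TableError(f"target map sends {s!r} to unknown target {t!r}")

    aff_rows = [aff.compound_ids.index(c) for c in shared]
    score_rows = [score_index[c] for c in shared]
    a = aff.values[aff_rows, :]
    s = score.values[score_rows, :]
    agg = target_map.aggregation

    if agg is Aggregation.PER_STRUCTURE:
        cols = list(score.structure_ids)
        a_out = np.column_stack(
            [a[:, aff_col[target_map.entries[c]]] for c in cols]
        )
        s_out = s
        out_ids = cols
    else:
        # group structure columns by mapped target, in affinity-table order
        groups: dict[str, list[int]] = {}
        for j, st in enumerate(score.structure_ids):
            groups.setdefault(target_map.entries[st], []).append(j)
        out_ids = [t for t in aff.target_ids if t in groups]
        if agg is Aggregation.SINGLE:
            multi = {t: g for t, g in groups.items() if len(g) > 1}
            if multi:
                raise TableError(
                    f"aggregation 'single' but several structures map to {sorted(multi)}"
                )
        a_out = np.column_stack([a[:, aff_col[t]] for t in out_ids])
        cols_out = []
        for t in out_ids:
            block = s[:, groups[t]]
            if agg is Aggregation.SINGLE:
                col = block[:, 0]
            elif agg is Aggregation.BEST_SCORE:
                with np.errstate(invalid="ignore"):
                    fn = np.nanmin if score.direction is Direction.LOWER_IS_BETTER else np.nanmax
                    allnan = np.all(np.isnan(block), axis=1)
                    col = np.where(allnan, np.nan, fn(np.where(np.isnan(block),
                        np.inf if score.direction is Direction.LOWER_IS_BETTER else -np.inf,
                        block), axis=1))
            else:  # MEAN_SCORE
                allnan = np.all(np.isnan(block), axis=1)
                with np.errstate(invalid="ignore"):
                    col = np.where(allnan, np.nan, np.nanmean(np.where(allnan[:, None], 0.0, block), axis=1))
            cols_out.append(col)
        s_out = np.column_stack(cols_out)

    aligned_aff = AffinityTable(list(shared), list(out_ids), a_out)
    aligned_score = ScoreTable(list(shared), list(out_ids), s_out, score.direction)
    return aligned_aff, aligned_score


# --- category matrix serialization (letters G/Y/R) ------------------------

_LETTER = {2: "G", 1: "Y", 0: "R"}
_CODE = {v: k for k, v in _LETTER.items()}


def write_category_matrix(matrix, path: str | Path, missing_token: str = "") -> None:
    """Serialize a traffic-light matrix as CSV with single-letter cells."""
    codes = matrix.codes
    cells = np.empty(codes.shape, dtype=object)
    for code, letter in _LETTER.items():
        cells[codes == code] = letter
    cells[codes < 0] = missing_token
    df = pd.DataFrame(cells, columns=matrix.target_ids)
    df.insert(0, "compound_id", matrix.compound_ids)
    df.to_csv(path, index=False)


def read_category_matrix(path: str | Path, provenance: str = "file", delimiter: str | None = None):
    """Read a G/Y/R matrix written by :func:`write_category_matrix`."""
    from .partition import CategoryMatrix

    df = _read_frame(path, delimiter)
    compounds = [str(c) for c in df.iloc[:, 0]]
    _require_unique(compounds, "compound")
    targets = [str(c) for c in df.columns[1:]]
    codes = np.full((len(compounds), len(targets)), -1, dtype=np.int8)
    for j, col in enumerate(targets):
        for i, cpd in enumerate(compounds):
            cell = str(df.iloc[i, j + 1]).strip()
            if cell == "":
                continue
            if cell not in _CODE:
                raise TableError(
                    f"unknown category letter {cell!r} at compound {cpd!r}, column {col!r}"
                )
            codes[i, j] = _CODE[cell]
    return CategoryMatrix(compounds, targets, codes, provenance)
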