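"""Traffic-light categorization of affinities and docking scores.

Experimental Ki values and docking/rescoring scores are reduced to three
categories — green (active / good score), yellow (a deliberate buffer for
moderate values, absorbing assay uncertainty around hard cutoffs) and red
(inactive / poor score).

In vitro schemes cut on Ki in nM. The permissive scheme: green below
1000 nM, yellow for any weaker but measurable affinity, red for no
detectable binding. The sensitive scheme: green below 100 nM, yellow for
100–1000 nM, red above 1000 nM or not detectable.

In silico schemes either split the observed score *range* by fractions
(default: best 20% of the range green, next 20% yellow, remaining 60% red)
or apply fixed score cutoffs (default, for rescoring energies: green at
-100 or better, yellow down to -90, red beyond).

Boundary conventions (documented, deliberate): "below" is strict, so a Ki
exactly at a green cutoff is yellow; score boundaries are resolved toward
the better category, so a score exactly at the 20% mark, or exactly at a
fixed cutoff, still earns that cutoff's color.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .tables_io import AffinityTable, Direction, ScoreTable, TableError

__all__ = [
    "Category",
    "MISSING_CODE",
    "CategoryMatrix",
    "InVitroScheme",
    "InSilicoMode",
    "RangeScope",
    "InSilicoScheme",
    "categorize_ki",
    "score_range",
    "categorize_score",
    "categorize_affinity_table",
    "categorize_score_table",
]

#: code used in category/rank matrices for "not tested / no score"
MISSING_CODE = -1


class Category(enum.IntEnum):
    """Traffic-light category; the integer value is also the ternary rank."""

    RED = 0
    YELLOW = 1
    GREEN = 2

    @property
    def letter(self) -> str:
        return {Category.GREEN: "G", Category.YELLOW: "Y", Category.RED: "R"}[self]


@dataclass
class CategoryMatrix:
    """Compounds x targets grid of traffic-light codes.

    ``codes[i, j]`` is a :class:`Category` value (0/1/2) or ``MISSING_CODE``.
    ``provenance`` records which scheme produced the grid.
    """

    compound_ids: list[str]
    target_ids: list[str]
    codes: np.ndarray
    provenance: str

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        shape = (len(self.compound_ids), len(self.target_ids))
        if self.codes.size != shape[0] * shape[1]:
            raise ValueError(f"category matrix shape {self.codes.shape} != {shape}")
        self.codes = self.codes.reshape(shape)
        if not self.provenance:
            raise ValueError("category matrix requires a provenance label")
        bad = (self.codes < MISSING_CODE) | (self.codes > Category.GREEN)
        if np.any(bad):
            raise ValueError("category codes must be -1 (missing), 0, 1 or 2")

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    def is_missing(self) -> np.ndarray:
        return self.codes == MISSING_CODE


@dataclass(frozen=True)
class InVitroScheme:
    """Ki partition: green strictly below ``green_below`` nM; yellow up to
    ``yellow_upper`` nM inclusive (``None`` = any measurable value); red
    otherwise. ND is always red."""

    green_below: float = 1000.0
    yellow_upper: float | None = None
    nd_is_red: bool = True

    def __post_init__(self) -> None:
        if self.green_below <= 0:
            raise ValueError("green_below must be a positive Ki (nM)")
        if self.yellow_upper is not None and self.yellow_upper < self.green_below:
            raise ValueError("yellow_upper must be >= green_below (or None)")
        if not self.nd_is_red:
            raise ValueError("no-detectable-binding is red by definition")

    @classmethod
    def permissive(cls) -> "InVitroScheme":
        """Green < 1000 nM, yellow = any weaker measurable affinity."""
        return cls(1000.0, None)

    @classmethod
    def sensitive(cls) -> "InVitroScheme":
        """Green < 100 nM, yellow 100-1000 nM, red > 1000 nM or ND."""
        return cls(100.0, 1000.0)

    @property
    def label(self) -> str:
        upper = "inf" if self.yellow_upper is None else format(self.yellow_upper, "g")
        return f"in_vitro[green<{self.green_below:g}nM,yellow<={upper}nM,ND=red]"


class InSilicoMode(str, enum.Enum):
    RANGE_FRACTION = "range_fraction"
    FIXED_CUTOFF = "fixed_cutoff"


class RangeScope(str, enum.Enum):
    PER_COLUMN = "per_column"
    GLOBAL = "global"


@dataclass(frozen=True)
class InSilicoScheme:
    """Score partition.

    ``range_fraction`` colors by position inside the observed score range:
    within ``green_frac`` of the span from the best score -> green, within
    ``green_frac + yellow_frac`` -> yellow, else red (boundaries inclusive
    toward the better color; a zero-width span is all green).
    ``fixed_cutoff`` colors by absolute score (lower-is-better): green at or
    below ``green_max``, yellow at or below ``yellow_max``, red above.
    """

    mode: InSilicoMode = InSilicoMode.RANGE_FRACTION
    green_frac: float = 0.20
    yellow_frac: float = 0.20
    green_max: float = -100.0
    yellow_max: float = -90.0
    range_scope: RangeScope = RangeScope.PER_COLUMN

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", InSilicoMode(self.mode))
        object.__setattr__(self, "range_scope", RangeScope(self.range_scope))
        if not (self.green_frac > 0 and self.yellow_frac > 0):
            raise ValueError("green_frac and yellow_frac must be positive")
        if self.green_frac + self.yellow_frac >= 1:
            raise ValueError("green_frac + yellow_frac must be < 1")
        if not self.green_max < self.yellow_max:
            raise ValueError("green_max must be below yellow_max")

    @classmethod
    def fractions(
        cls,
        green: float = 0.20,
        yellow: float = 0.20,
        scope: RangeScope | str = RangeScope.PER_COLUMN,
    ) -> "InSilicoScheme":
        return cls(InSilicoMode.RANGE_FRACTION, green, yellow, range_scope=RangeScope(scope))

    @classmethod
    def cutoffs(cls, green_max: float = -100.0, yellow_max: float = -90.0) -> "InSilicoScheme":
        return cls(InSilicoMode.FIXED_CUTOFF, green_max=green_max, yellow_max=yellow_max)

    @property
    def label(self) -> str:
        if self.mode is InSilicoMode.RANGE_FRACTION:
            return (
                f"in_silico[range:{self.green_frac:g}/{self.yellow_frac:g},"
                f"scope={self.range_scope.value}]"
            )
        return f"in_silico[cutoff:green<={self.green_max:g},yellow<={self.yellow_max:g}]"


def categorize_ki(value: float, scheme: InVitroScheme) -> int:
    """Category code for one Ki (nM), ND (``+inf``) or MISSING (``NaN``)."""
    if np.isnan(value):
        return MISSING_CODE
    if np.isposinf(value):
        return int(Category.RED)
    if value <= 0:
        raise ValueError(f"Ki must be positive, got {value}")
    if value < scheme.green_below:
        return int(Category.GREEN)
    if scheme.yellow_upper is None or value <= scheme.yellow_upper:
        return int(Category.YELLOW)
    return int(Category.RED)


def score_range(
    column: np.ndarray, direction: Direction | str = Direction.LOWER_IS_BETTER
) -> tuple[float, float]:
    """(best, worst) extremes of a score column; MISSING values are ignored."""
    col = np.asarray(column, dtype=float)
    col = col[~np.isnan(col)]
    if col.size == 0:
        raise TableError("score range undefined: all values missing")
    if Direction(direction) is Direction.LOWER_IS_BETTER:
        return float(col.min()), float(col.max())
    return float(col.max()), float(col.min())


def categorize_score(
    value: float,
    rng: tuple[float, float],
    scheme: InSilicoScheme,
    direction: Direction | str = Direction.LOWER_IS_BETTER,
) -> int:
    """Category code for one score given its column's (best, worst) range."""
    direction = Direction(direction)
    if np.isnan(value):
        return MISSING_CODE
    if scheme.mode is InSilicoMode.FIXED_CUTOFF:
        if direction is not Direction.LOWER_IS_BETTER:
            raise ValueError("fixed_cutoff schemes are defined for lower-is-better scores")
        if value <= scheme.green_max:
            return int(Category.GREEN)
        if value <= scheme.yellow_max:
            return int(Category.YELLOW)
        return int(Category.RED)
    best, worst = rng
    span = abs(worst - best)
    if span == 0:
        return int(Category.GREEN)
    offset = abs(value - best)
    if offset <= scheme.green_frac * span:
        return int(Category.GREEN)
    if offset <= (scheme.green_frac + scheme.yellow_frac) * span:
        return int(Category.YELLOW)
    return int(Category.RED)


def categorize_affinity_table(aff: AffinityTable, scheme: InVitroScheme) -> CategoryMatrix:
    """Cell-wise Ki categorization of a whole affinity table."""
    codes = np.full(aff.shape, MISSING_CODE, dtype=np.int8)
    v = aff.values
    known = ~np.isnan(v)
    codes[np.isposinf(v)] = Category.RED
    finite = np.isfinite(v)
    codes[finite & (v < scheme.green_below)] = Category.GREEN
    yellow = finite & (v >= scheme.green_below)
    if scheme.yellow_upper is not None:
        codes[yellow & (v > scheme.yellow_upper)] = Category.RED
        yellow &= v <= scheme.yellow_upper
    codes[yellow] = Category.YELLOW
    codes[~known] = MISSING_CODE
    return CategoryMatrix(
        list(aff.compound_ids), list(aff.target_ids), codes, scheme.label
    )


def categorize_score_table(score: ScoreTable, scheme: InSilicoScheme) -> CategoryMatrix:
    """Cell-wise score categorization; range per column or global per scheme."""
    codes = np.full(score.shape, MISSING_CODE, dtype=np.int8)
    if (
        scheme.mode is InSilicoMode.RANGE_FRACTION
        and scheme.range_scope is RangeScope.GLOBAL
        and score.values.size > 0
    ):
        if np.all(np.isnan(score.values)):
            raise TableError("score range undefined: table entirely missing")
        global_rng = score_range(score.values.ravel(), score.direction)
    for j, structure in enumerate(score.structure_ids):
        col = score.values[:, j]
        if col.size == 0:
            continue
        if scheme.mode is InSilicoMode.RANGE_FRACTION:
            if scheme.range_scope is RangeScope.PER_COLUMN:
                if np.all(np.isnan(col)):
                    raise TableError(f"column {structure!r} is entirely missing")
                rng = score_range(col, score.direction)
            else:
                rng = global_rng
        else:
            rng = (np.nan, np.nan)  # unused by fixed_cutoff
        for i in range(col.size):
            codes[i, j] = categorize_score(col[i], rng, scheme, score.direction)
    provenance = f"{scheme.label}|direction={score.direction.value}"
    return CategoryMatrix(
        list(score.compound_ids), list(score.structure_ids), codes, provenance
    )
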