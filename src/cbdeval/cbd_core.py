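"""City Block Distance (CBD) statistics on traffic-light rank matrices.

The agreement between an in vitro binding profile and an in silico screening
result is measured with the L1 (taxicab / city-block) metric on integer
ranks. Categories map to ranks as 0 (red), 1 (yellow), 2 (green); a binary
variant collapses yellow and green to 1 ("active") to remove boundary
effects between adjacent categories.

For an in vitro rank matrix v and an in silico rank matrix s of identical
shape, the total CBD is

    d1(v, s) = sum_ij |v_ij - s_ij|

over entries ranked on both sides. Derived statistics:

* ``avg_bpc`` — average "blocks per compound", total / number of compounds
  contributing at least one compared entry; the method's average-error unit.
* ``cbd_max`` — the largest CBD any in silico assignment could reach against
  the fixed in vitro matrix: per entry, max(v, R - v).
* ``cbd_rel = total / cbd_max`` — normalized error in [0, 1]; values below
  the random expectation indicate better-than-random screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .partition import MISSING_CODE, CategoryMatrix

__all__ = [
    "RankMatrix",
    "CBDResult",
    "ranks_from_categories",
    "binarize",
    "cbd",
    "cbd_max",
    "cbd_rel",
    "round2",
]


def round2(x: float) -> float:
    """Round half-up to 2 decimal places (presentation convention)."""
    if x != x:  # NaN
        return x
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class RankMatrix:
    """Compounds x targets matrix of integer ranks in {0..max_rank}.

    ``MISSING_CODE`` (-1) marks entries with no rank. ``max_rank`` is 2 for
    the ternary red/yellow/green system and 1 for the binary one.
    """

    compound_ids: list[str]
    target_ids: list[str]
    ranks: np.ndarray
    max_rank: int = 2
    provenance: str = "ranks"

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=np.int64)
        shape = (len(self.compound_ids), len(self.target_ids))
        if self.ranks.size != shape[0] * shape[1]:
            raise ValueError(f"rank matrix shape {self.ranks.shape} != {shape}")
        self.ranks = self.ranks.reshape(shape)
        if self.max_rank not in (1, 2):
            raise ValueError("max_rank must be 1 (binary) or 2 (ternary)")
        bad = (self.ranks < MISSING_CODE) | (self.ranks > self.max_rank)
        if np.any(bad):
            raise ValueError(f"ranks must lie in {{0..{self.max_rank}}} or be -1 (missing)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ranks.shape

    def is_missing(self) -> np.ndarray:
        return self.ranks == MISSING_CODE


@dataclass
class CBDResult:
    """All CBD statistics of one in vitro / in silico comparison.

    ``per_entry`` holds |v - s| where both sides are ranked and NaN where the
    pair is incomplete; ``per_compound`` / ``per_target`` are its row / column
    sums, ``total`` their grand sum. ``summary()`` returns the rounded
    presentation values.
    """

    compound_ids: list[str]
    target_ids: list[str]
    per_entry: np.ndarray
    per_compound: np.ndarray
    per_target: np.ndarray
    total: int
    n_compared: int
    avg_bpc: float
    cbd_max: int
    cbd_rel: float
    provenance: str = ""

    def summary(self) -> dict:
        return {
            "total": int(self.total),
            "n_compared": int(self.n_compared),
            "avg_bpc": round2(self.avg_bpc),
            "cbd_max": int(self.cbd_max),
            "cbd_rel": None if self.cbd_rel != self.cbd_rel else round2(self.cbd_rel),
            "provenance": self.provenance,
        }


_TERNARY = {MISSING_CODE: MISSING_CODE, 0: 0, 1: 1, 2: 2}
_BINARY = {MISSING_CODE: MISSING_CODE, 0: 0, 1: 1, 2: 1}


def ranks_from_categories(cat: CategoryMatrix, max_rank: int = 2) -> RankMatrix:
    """Map traffic-light categories to integer ranks.

    Ternary (``max_rank=2``): red -> 0, yellow -> 1, green -> 2.
    Binary (``max_rank=1``): red -> 0, yellow and green -> 1.
    """
    if max_rank not in (1, 2):
        raise ValueError("max_rank must be 1 or 2")
    table = _TERNARY if max_rank == 2 else _BINARY
    lut = np.array([table[MISSING_CODE], table[0], table[1], table[2]], dtype=np.int64)
    ranks = lut[cat.codes.astype(np.int64) + 1]
    mode = "ternary" if max_rank == 2 else "binary"
    return RankMatrix(
        list(cat.compound_ids),
        list(cat.target_ids),
        ranks,
        max_rank,
        provenance=f"{cat.provenance}|ranks={mode}",
    )


def binarize(r: RankMatrix) -> RankMatrix:
    """Collapse a ternary rank matrix to binary: {1, 2} -> 1, 0 -> 0."""
    if r.max_rank == 1:
        raise ValueError("rank matrix is already binary")
    ranks = np.where(r.ranks > 0, 1, r.ranks)
    return RankMatrix(
        list(r.compound_ids),
        list(r.target_ids),
        ranks,
        max_rank=1,
        provenance=f"{r.provenance}|binarized",
    )


def _check_comparable(v: RankMatrix, s: RankMatrix) -> None:
    if v.shape != s.shape:
        raise ValueError(f"rank matrices differ in shape: {v.shape} vs {s.shape}")
    if v.max_rank != s.max_rank:
        raise ValueError(
            f"rank matrices differ in max_rank: {v.max_rank} vs {s.max_rank}"
        )
    if v.compound_ids != s.compound_ids or v.target_ids != s.target_ids:
        raise ValueError("rank matrices differ in compound/target ordering")


def cbd(v: RankMatrix, s: RankMatrix) -> CBDResult:
    """City Block Distance between an in vitro and an in silico rank matrix.

    Entries missing on either side are excluded from every sum; a compound
    with no compared entry does not count toward the ``avg_bpc`` denominator.
    ``cbd_max`` is evaluated on the in vitro matrix ``v`` (the fixed ground
    truth).
    """
    _check_comparable(v, s)
    both = ~(v.is_missing() | s.is_missing())
    per_entry = np.where(both, np.abs(v.ranks - s.ranks), np.nan)
    per_compound = np.nansum(np.where(both, per_entry, 0.0), axis=1).astype(np.int64)
    per_target = np.nansum(np.where(both, per_entry, 0.0), axis=0).astype(np.int64)
    total = int(per_compound.sum())
    n_compared = int(both.sum())
    compounds_with_data = int(np.any(both, axis=1).sum())
    avg_bpc = total / compounds_with_data if compounds_with_data else float("nan")
    vmax = cbd_max(v)
    rel = cbd_rel(total, vmax) if vmax > 0 else float("nan")
    return CBDResult(
        compound_ids=list(v.compound_ids),
        target_ids=list(v.target_ids),
        per_entry=per_entry,
        per_compound=per_compound,
        per_target=per_target,
        total=total,
        n_compared=n_compared,
        avg_bpc=avg_bpc,
        cbd_max=vmax,
        cbd_rel=rel,
        provenance=f"v:{v.provenance} | s:{s.provenance}",
    )


def cbd_max(v: RankMatrix) -> int:
    """Largest CBD attainable against ``v`` over all rank assignments.

    Per ranked entry the farthest admissible rank contributes
    ``max(v, R - v)``; missing entries contribute nothing. For binary
    matrices this is simply the count of ranked entries.
    """
    ranked = ~v.is_missing()
    r = v.ranks[ranked]
    return int(np.maximum(r, v.max_rank - r).sum())


def cbd_rel(total: int, max_value: int) -> float:
    """Relative CBD, ``total / cbd_max`` in [0, 1]; NaN when undefined."""
    if max_value == 0:
        return float("nan")
    if not 0 <= total <= max_value:
        raise ValueError(f"total {total} outside [0, cbd_max={max_value}]")
    return total / max_value
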