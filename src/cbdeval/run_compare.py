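"""Registry of labeled CBD evaluation runs and cross-run correlation.

An evaluation campaign produces a family of labeled runs — e.g. the test-set
runs (first docking, rescoring, redocking, redocking + rescoring, each in
ternary and binary form) and the matching validation-set runs. Agreement
between two families is summarized by the Pearson correlation of a chosen
per-run statistic (``avg_bpc`` by default: the quantity quoted per run for
both sets).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .cbd_core import CBDResult, round2

__all__ = ["RunRecord", "RunRegistry", "run_vector", "pearson_r", "compare_runs"]

_FIELDS = ("total", "avg_bpc", "cbd_rel")


@dataclass
class RunRecord:
    """One labeled evaluation run: schemes applied plus its CBD result."""

    run_id: str
    in_vitro_scheme: str
    in_silico_scheme: str
    rank_mode: str  # "ternary" | "binary"
    result: CBDResult

    def summary(self) -> dict:
        d = {"run_id": self.run_id,
             "in_vitro_scheme": self.in_vitro_scheme,
             "in_silico_scheme": self.in_silico_scheme,
             "rank_mode": self.rank_mode}
        d.update(self.result.summary())
        return d


@dataclass
class RunRegistry:
    """Ordered collection of runs with unique identifiers."""

    runs: list[RunRecord] = field(default_factory=list)

    def add(self, record: RunRecord) -> None:
        if any(r.run_id == record.run_id for r in self.runs):
            raise ValueError(f"duplicate run_id {record.run_id!r}")
        self.runs.append(record)

    def __len__(self) -> int:
        return len(self.runs)

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for r in self.runs:
                fh.write(json.dumps(r.summary()) + "\n")


def run_vector(runs: list[RunRecord], field_name: str = "avg_bpc") -> np.ndarray:
    """Extract one statistic from >= 2 runs, in registry order."""
    if field_name not in _FIELDS:
        raise ValueError(f"unknown field {field_name!r}; choose from {_FIELDS}")
    if len(runs) < 2:
        raise ValueError("need at least two runs to build a comparison vector")
    return np.array([getattr(r.result, field_name) for r in runs], dtype=float)


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation and its square.

    Undefined (NaN, NaN) when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if x.size < 2:
        raise ValueError("need at least two points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r = float(stats.pearsonr(x, y).statistic)
    return r, r * r


def compare_runs(
    runs_a: list[RunRecord], runs_b: list[RunRecord], field_name: str = "avg_bpc"
) -> dict:
    """Pearson correlation between two equally long families of runs."""
    xa = run_vector(runs_a, field_name)
    xb = run_vector(runs_b, field_name)
    if xa.size != xb.size:
        raise ValueError("run families differ in length")
    r, r2 = pearson_r(xa, xb)
    return {
        "field": field_name,
        "n_runs": int(xa.size),
        "r": None if r != r else round2(r),
        "r_squared": None if r2 != r2 else round2(r2),
        "r_raw": None if r != r else r,
        "r_squared_raw": None if r2 != r2 else r2,
    }
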