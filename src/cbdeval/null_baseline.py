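"""Randomization baselines for CBD totals.

"Better than random" is made concrete by comparing an observed CBD total to
the distribution of totals obtained from random in silico rank matrices
scored against the same fixed in vitro matrix. Two null models:

* ``uniform`` — each in silico rank drawn independently and uniformly from
  {0..R} (random 0-1-2 or 0-1 assignments);
* ``permutation`` — the observed in silico ranks are shuffled within each
  target column, preserving every column's rank multiset.

A closed form accompanies the uniform null: per ranked in vitro entry the
expected contribution is E|v - U| with U uniform on {0..R} (ternary: 1 for
v in {0, 2}, 2/3 for v = 1; binary: 1/2 per entry).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .cbd_core import RankMatrix, cbd

__all__ = ["NullMode", "NullSpec", "NullResult", "sample_null_cbd", "expected_uniform_cbd"]


class NullMode(str, Enum):
    UNIFORM = "uniform"
    PERMUTATION = "permutation"


@dataclass(frozen=True)
class NullSpec:
    """How to sample the null: mode, number of draws, RNG seed."""

    mode: NullMode = NullMode.UNIFORM
    n_draws: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", NullMode(self.mode))
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


@dataclass
class NullResult:
    """Sampled null distribution of CBD totals against a fixed in vitro matrix.

    ``empirical_quantile`` is the fraction of null totals <= the observed one
    (ties count): small values mean the observed agreement is much better
    than random.
    """

    samples: np.ndarray
    mean: float
    sd: float
    empirical_quantile: float
    observed: int
    spec: NullSpec

    def to_dict(self) -> dict:
        return {
            "mode": self.spec.mode.value,
            "n_draws": int(self.spec.n_draws),
            "seed": int(self.spec.seed),
            "observed": int(self.observed),
            "mean": float(self.mean),
            "sd": float(self.sd),
            "empirical_quantile": float(self.empirical_quantile),
        }


def sample_null_cbd(
    v: RankMatrix,
    spec: NullSpec,
    observed: int,
    s: RankMatrix | None = None,
) -> NullResult:
    """Sample the null distribution of CBD totals against ``v``.

    ``uniform`` mode needs only ``v``; ``permutation`` mode shuffles the
    observed in silico matrix ``s`` within each target column and therefore
    requires it. Reproducible for a given ``spec.seed``.
    """
    if observed < 0:
        raise ValueError("observed CBD must be non-negative")
    rng = np.random.default_rng(spec.seed)
    ranked = ~v.is_missing()
    vflat = v.ranks[ranked].astype(np.int64)

    if spec.mode is NullMode.UNIFORM:
        draws = rng.integers(0, v.max_rank + 1, size=(spec.n_draws, vflat.size))
        totals = np.abs(draws - vflat[None, :]).sum(axis=1)
    else:
        if s is None:
            raise ValueError("permutation null requires the observed in silico matrix")
        totals = np.zeros(spec.n_draws, dtype=np.int64)
        for j in range(v.shape[1]):
            v_col = v.ranks[:, j]
            s_col = s.ranks[:, j]
            present = s_col != -1
            s_vals = s_col[present].astype(np.int64)
            if s_vals.size == 0:
                continue
            # one permutation per draw: argsort of random keys
            keys = rng.random((spec.n_draws, s_vals.size))
            perms = s_vals[np.argsort(keys, axis=1)]
            shuffled = np.full((spec.n_draws, v.shape[0]), -1, dtype=np.int64)
            shuffled[:, present] = perms
            both = (v_col != -1)[None, :] & (shuffled != -1)
            diffs = np.where(both, np.abs(shuffled - v_col[None, :]), 0)
            totals += diffs.sum(axis=1)

    samples = np.asarray(totals, dtype=np.int64)
    return NullResult(
        samples=samples,
        mean=float(samples.mean()),
        sd=float(samples.std(ddof=1)) if samples.size > 1 else 0.0,
        empirical_quantile=float(np.mean(samples <= observed)),
        observed=int(observed),
        spec=spec,
    )


def expected_uniform_cbd(v: RankMatrix) -> float:
    """Closed-form mean CBD total under the uniform null.

    Per ranked entry: E|v - U| = (1 / (R+1)) * sum_{u=0}^{R} |v - u|.
    """
    ranked = ~v.is_missing()
    r = v.ranks[ranked].astype(np.int64)
    if r.size == 0:
        return 0.0
    u = np.arange(v.max_rank + 1)
    per_entry = np.abs(r[:, None] - u[None, :]).mean(axis=1)
    return float(per_entry.sum())
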