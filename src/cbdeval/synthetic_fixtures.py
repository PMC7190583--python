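"""Synthetic affinity/score tables and actives/decoys lists.

A compounds x targets benchmark is simulated from a simple generative model:

* per cell, log10 Ki ~ Uniform(lo, hi) (log-uniform affinities spread
  compounds evenly over the traffic-light categories);
* with probability ``nd_fraction`` the cell becomes ND (no detectable
  binding);
* the docking score of a measurable cell is linear in log10 Ki plus
  Gaussian noise: score = intercept + slope * log10Ki + N(0, noise_sd), with
  positive slope so stronger binders get lower (better) scores;
* ND cells still receive a score — real docking scores non-binders too —
  drawn uniformly from a "worst-decile" band just beyond the worst
  measurable score (band width: 10% of the measurable score span, floor 1
  score unit). Keeping ND scores strictly worse than every measurable score
  makes a noiseless simulation perfectly consistent with its affinities.

Defaults place scores in a docking-like range: log10 Ki in (0, 5) (1 nM to
100 uM), slope 2 and intercept -12 map them to scores in about (-12, -2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enrichment import EnrichmentInput
from .tables_io import ND, AffinityTable, Direction, ScoreTable

__all__ = ["SimSpec", "generate_dataset", "generate_actives_decoys"]


@dataclass(frozen=True)
class SimSpec:
    """Parameters of the synthetic benchmark generator."""

    n_compounds: int = 39
    target_ids: tuple[str, ...] = ("A1", "A2A", "A3")
    log_ki_range: tuple[float, float] = (0.0, 5.0)  # log10 nM
    nd_fraction: float = 0.0
    slope: float = 2.0  # score units per log10 nM (positive: low Ki -> low score)
    intercept: float = -12.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        if not self.target_ids:
            raise ValueError("need at least one target")
        lo, hi = self.log_ki_range
        if not lo < hi:
            raise ValueError("log_ki_range must satisfy lo < hi")
        if not 0 <= self.nd_fraction < 1:
            raise ValueError("nd_fraction must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def to_dict(self) -> dict:
        return {
            "n_compounds": self.n_compounds,
            "target_ids": list(self.target_ids),
            "log_ki_range": list(self.log_ki_range),
            "nd_fraction": self.nd_fraction,
            "slope": self.slope,
            "intercept": self.intercept,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }


def generate_dataset(spec: SimSpec) -> tuple[AffinityTable, ScoreTable]:
    """Simulate a paired affinity table and score table (one structure per
    target, structure ids equal to target ids). Deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_compounds, len(spec.target_ids)
    lo, hi = spec.log_ki_range

    log_ki = rng.uniform(lo, hi, size=(n, m))
    nd = rng.random(size=(n, m)) < spec.nd_fraction

    aff = 10.0 ** log_ki
    aff[nd] = ND

    scores = spec.intercept + spec.slope * log_ki
    if spec.noise_sd > 0:
        scores = scores + rng.normal(0.0, spec.noise_sd, size=(n, m))

    measurable = ~nd
    if nd.any():
        if measurable.any():
            best = scores[measurable].min()
            worst = scores[measurable].max()
            band = max(0.1 * (worst - best), 1.0)
        else:
            worst, band = 0.0, 1.0
        scores[nd] = rng.uniform(worst, worst + band, size=int(nd.sum()))

    width = max(3, len(str(n)))
    compounds = [f"cpd{i + 1:0{width}d}" for i in range(n)]
    targets = list(spec.target_ids)
    return (
        AffinityTable(compounds, targets, aff),
        ScoreTable(compounds, list(targets), scores, Direction.LOWER_IS_BETTER),
    )


def generate_actives_decoys(
    n_act: int,
    n_dec: int,
    separation: float,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> EnrichmentInput:
    """Gaussian actives/decoys score lists for enrichment evaluation.

    Actives ~ N(-separation, noise_sd), decoys ~ N(0, noise_sd), lower is
    better; ``separation`` in score units controls how well they separate.
    """
    if n_act < 1 or n_dec < 1:
        raise ValueError("n_act and n_dec must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    actives = rng.normal(-separation, noise_sd, size=n_act)
    decoys = rng.normal(0.0, noise_sd, size=n_dec)
    return EnrichmentInput(actives, decoys, Direction.LOWER_IS_BETTER)
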