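"""Actives-vs-decoys enrichment: ROC curves and AUC.

A docking setup that enriches known actives should rank them ahead of
decoys. The ROC curve steps through the pooled score list from best to
worst; ties between actives and decoys appear as diagonal segments. The
AUC is computed by the trapezoidal rule, which with this tie handling is
identical to the Mann-Whitney pair-counting statistic

    AUC = (#{active beats decoy} + 0.5 * #{ties}) / (n_act * n_dec).

0.5 is random ranking, 1.0 perfect separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables_io import Direction

__all__ = ["EnrichmentInput", "RocCurve", "roc_curve", "auc_only"]


@dataclass
class EnrichmentInput:
    """Scores of known actives and decoys, with the score orientation."""

    active_scores: np.ndarray
    decoy_scores: np.ndarray
    direction: Direction = Direction.LOWER_IS_BETTER

    def __post_init__(self) -> None:
        self.active_scores = np.asarray(self.active_scores, dtype=float).ravel()
        self.decoy_scores = np.asarray(self.decoy_scores, dtype=float).ravel()
        self.direction = Direction(self.direction)
        if self.active_scores.size == 0 or self.decoy_scores.size == 0:
            raise ValueError("active and decoy score lists must both be non-empty")
        if np.any(np.isnan(self.active_scores)) or np.any(np.isnan(self.decoy_scores)):
            raise ValueError("enrichment scores must not contain NaN")


@dataclass
class RocCurve:
    """ROC points from (0,0) to (1,1) and the area under them."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


def roc_curve(inp: EnrichmentInput) -> RocCurve:
    """ROC curve of actives vs decoys with Mann-Whitney tie handling."""
    # orient so that larger = better, independent of input direction
    sign = -1.0 if inp.direction is Direction.LOWER_IS_BETTER else 1.0
    act = sign * inp.active_scores
    dec = sign * inp.decoy_scores
    n_act, n_dec = act.size, dec.size

    thresholds = np.unique(np.concatenate([act, dec]))[::-1]
    # counts of actives/decoys at each unique score value
    act_at = np.array([(act == t).sum() for t in thresholds])
    dec_at = np.array([(dec == t).sum() for t in thresholds])
    tpr = np.concatenate([[0.0], np.cumsum(act_at) / n_act])
    fpr = np.concatenate([[0.0], np.cumsum(dec_at) / n_dec])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, auc=auc)


def auc_only(inp: EnrichmentInput) -> float:
    """Scalar AUC of actives vs decoys."""
    return roc_curve(inp).auc
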