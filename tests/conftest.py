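import numpy as np
import pytest

from cbdeval import AffinityTable, RankMatrix, ScoreTable


def make_ranks(ranks, max_rank=2, provenance="test") -> RankMatrix:
    """Build a RankMatrix from a 2-D list, generating placeholder ids."""
    arr = np.atleast_2d(np.asarray(ranks, dtype=np.int64))
    compounds = [f"c{i}" for i in range(arr.shape[0])]
    targets = [f"t{j}" for j in range(arr.shape[1])]
    return RankMatrix(compounds, targets, arr, max_rank, provenance)


@pytest.fixture
def rank_factory():
    return make_ranks


@pytest.fixture
def small_affinity() -> AffinityTable:
    """2x2 Ki table: one strong binder, one ND, one weak, one moderate."""
    return AffinityTable(
        ["cpdA", "cpdB"],
        ["A1", "A3"],
        np.array([[40.0, np.inf], [1500.0, 200.0]]),
    )


@pytest.fixture
def small_scores() -> ScoreTable:
    return ScoreTable(
        ["cpdA", "cpdB"],
        ["A1", "A3"],
        np.array([[-11.0, -3.0], [-6.5, -9.0]]),
    )
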