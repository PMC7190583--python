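import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbdeval import (
    AffinityTable,
    Category,
    Direction,
    InSilicoScheme,
    InVitroScheme,
    MISSING_CODE,
    ScoreTable,
    TableError,
    categorize_affinity_table,
    categorize_ki,
    categorize_score,
    categorize_score_table,
    score_range,
)

ND = np.inf
PERMISSIVE = InVitroScheme.permissive()  # green < 1000 nM, yellow any measurable
SENSITIVE = InVitroScheme.sensitive()  # green < 100, yellow 100-1000, red beyond


class TestCategorizeKi:
    @pytest.mark.parametrize(
        "value,scheme,expected",
        [
            (40.0, SENSITIVE, Category.GREEN),  # potent, selective ligand
            (40.0, PERMISSIVE, Category.GREEN),
            (ND, PERMISSIVE, Category.RED),  # no detectable binding
            (ND, SENSITIVE, Category.RED),
            (1000.0, PERMISSIVE, Category.YELLOW),  # "below 1000" is strict
            (999.9, PERMISSIVE, Category.GREEN),
            (100.0, SENSITIVE, Category.YELLOW),  # boundary goes to the buffer
            (1000.0, SENSITIVE, Category.YELLOW),  # inclusive upper bound
            (2500.0, SENSITIVE, Category.RED),
            (50_000.0, PERMISSIVE, Category.YELLOW),  # measurable but weak
        ],
    )
    def test_rule_table(self, value, scheme, expected):
        assert categorize_ki(value, scheme) == expected

    def test_missing_stays_missing(self):
        assert categorize_ki(np.nan, PERMISSIVE) == MISSING_CODE

    @given(
        a=st.floats(min_value=0.1, max_value=1e6),
        b=st.floats(min_value=0.1, max_value=1e6),
        scheme=st.sampled_from([PERMISSIVE, SENSITIVE]),
    )
    @settings(deadline=None)
    def test_monotone_in_ki(self, a, b, scheme):
        """A stronger binder never gets a worse color."""
        lo, hi = min(a, b), max(a, b)
        assert categorize_ki(lo, scheme) >= categorize_ki(hi, scheme)

    def test_invalid_schemes_rejected(self):
        with pytest.raises(ValueError):
            InVitroScheme(green_below=-1)
        with pytest.raises(ValueError):
            InVitroScheme(green_below=1000, yellow_upper=100)


class TestScoreRange:
    def test_lower_is_better(self):
        assert score_range([-12, -4, -8]) == (-12.0, -4.0)

    def test_single_value_degenerate(self):
        assert score_range([-7.0]) == (-7.0, -7.0)

    def test_direction_flip(self):
        assert score_range([3, 9], Direction.HIGHER_IS_BETTER) == (9.0, 3.0)

    def test_missing_ignored_and_all_missing_errors(self):
        assert score_range([np.nan, -5.0]) == (-5.0, -5.0)
        with pytest.raises(TableError):
            score_range([np.nan, np.nan])


class TestCategorizeScore:
    FRACTIONS = InSilicoScheme.fractions()
    CUTOFFS = InSilicoScheme.cutoffs()  # green <= -100, yellow <= -90

    def test_range_fraction_splits_20_20_60(self):
        col = [-12.0, -10.0, -8.0, -6.0, -4.0, -2.0]
        rng = score_range(col)
        got = [categorize_score(v, rng, self.FRACTIONS) for v in col]
        assert got == [2, 2, 1, 0, 0, 0]  # G G Y R R R

    @pytest.mark.parametrize(
        "value,expected",
        [
            (-105.0, Category.GREEN),
            (-95.0, Category.YELLOW),
            (-89.9, Category.RED),
            (-100.0, Category.GREEN),  # boundary favors the better color
            (-90.0, Category.YELLOW),
        ],
    )
    def test_fixed_cutoffs(self, value, expected):
        assert categorize_score(value, (np.nan, np.nan), self.CUTOFFS) == expected

    def test_fixed_cutoffs_require_lower_is_better(self):
        with pytest.raises(ValueError):
            categorize_score(-95.0, (np.nan, np.nan), self.CUTOFFS,
                             Direction.HIGHER_IS_BETTER)

    def test_zero_span_is_green(self):
        assert categorize_score(-7.0, (-7.0, -7.0), self.FRACTIONS) == Category.GREEN

    def test_missing_stays_missing(self):
        assert categorize_score(np.nan, (-10.0, -2.0), self.FRACTIONS) == MISSING_CODE

    @given(
        scores=st.lists(st.integers(-50, 50).map(float), min_size=2, max_size=20),
        shift=st.integers(-100, 100).map(float),
        scale=st.sampled_from([0.25, 0.5, 1.0, 2.0, 4.0, 8.0]),
    )
    @settings(deadline=None, max_examples=200)
    def test_affine_invariance_of_range_fraction(self, scores, shift, scale):
        """Shifting/scaling every score in a column leaves the colors alone.

        Scores, shifts and scales are kept exactly representable so the
        mathematical invariance is not blurred by rounding."""
        rng = score_range(scores)
        before = [categorize_score(v, rng, self.FRACTIONS) for v in scores]
        moved = [v * scale + shift for v in scores]
        rng2 = score_range(moved)
        after = [categorize_score(v, rng2, self.FRACTIONS) for v in moved]
        assert before == after

    def test_green_fraction_converges_on_uniform_grid(self):
        """On 1000 distinct evenly spaced scores ~20% must be green (+-1)."""
        col = np.linspace(-120.0, -20.0, 1000)
        rng = score_range(col)
        greens = sum(
            categorize_score(v, rng, self.FRACTIONS) == Category.GREEN for v in col
        )
        assert abs(greens - 200) <= 1


class TestCategorizeTables:
    def test_affinity_table_cellwise(self, small_affinity):
        m = categorize_affinity_table(small_affinity, PERMISSIVE)
        assert m.codes.tolist() == [[2, 0], [1, 2]]  # G R / Y G
        assert "1000" in m.provenance

    def test_all_nd_table_is_all_red(self):
        aff = AffinityTable(["c1", "c2"], ["A1"], np.full((2, 1), np.inf))
        m = categorize_affinity_table(aff, PERMISSIVE)
        assert np.all(m.codes == Category.RED)

    def test_empty_table_gives_empty_matrix(self):
        aff = AffinityTable([], ["A1"], np.empty((0, 1)))
        assert categorize_affinity_table(aff, PERMISSIVE).shape == (0, 1)
        score = ScoreTable([], ["A1"], np.empty((0, 1)))
        assert categorize_score_table(score, InSilicoScheme.fractions()).shape == (0, 1)

    def test_score_table_per_column(self):
        score = ScoreTable(
            [f"c{i}" for i in range(6)], ["m1"],
            np.array([[-12.0], [-10.0], [-8.0], [-6.0], [-4.0], [-2.0]]),
        )
        m = categorize_score_table(score, InSilicoScheme.fractions())
        assert m.codes.ravel().tolist() == [2, 2, 1, 0, 0, 0]

    def test_identical_columns_make_scope_irrelevant(self):
        col = np.array([[-12.0], [-8.0], [-3.0]])
        score = ScoreTable(["c1", "c2", "c3"], ["m1", "m2"], np.hstack([col, col]))
        per_col = categorize_score_table(score, InSilicoScheme.fractions(scope="per_column"))
        glob = categorize_score_table(score, InSilicoScheme.fractions(scope="global"))
        assert np.array_equal(per_col.codes, glob.codes)

    def test_constant_column_all_green(self):
        score = ScoreTable(["c1", "c2"], ["m1"], np.array([[-7.0], [-7.0]]))
        m = categorize_score_table(score, InSilicoScheme.fractions())
        assert np.all(m.codes == Category.GREEN)

    def test_all_missing_column_is_hard_error(self):
        score = ScoreTable(["c1"], ["m1", "m2"], np.array([[np.nan, -5.0]]))
        with pytest.raises(TableError, match="m1"):
            categorize_score_table(score, InSilicoScheme.fractions())

    def test_fixed_cutoff_ignores_rest_of_column(self):
        """A cell's color under fixed cutoffs doesn't depend on neighbors."""
        scheme = InSilicoScheme.cutoffs()
        a = ScoreTable(["c1", "c2"], ["m1"], np.array([[-95.0], [-200.0]]))
        b = ScoreTable(["c1", "c2"], ["m1"], np.array([[-95.0], [-1.0]]))
        ca = categorize_score_table(a, scheme)
        cb = categorize_score_table(b, scheme)
        assert ca.codes[0, 0] == cb.codes[0, 0] == Category.YELLOW
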