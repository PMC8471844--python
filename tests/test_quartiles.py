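import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import boxplot_oracle, fivenum_oracle

from karyostd.errors import EmptyInputError
from karyostd.quartiles import (
    boxplot_stats,
    summarize_karyotype,
    summary_table,
    tukey_hinges,
)
from karyostd.ranking import IdentifiedChromosome


# Frozen reference values computed with R's fivenum()/boxplot.stats(),
# the canonical implementation of the hinge/fence semantics replicated here.
R_FIVENUM_CASES = [
    ([1, 2, 3, 4, 5], (1, 2, 3, 4, 5)),
    ([1, 2, 3, 4, 5, 100], (1, 2, 3.5, 5, 100)),
    ([7], (7, 7, 7, 7, 7)),
    ([0, 0, 0, 0], (0, 0, 0, 0, 0)),
    (
        [49.445, 19.887, 5.785, 3.487, 12.187, 39.601, 17.003, 48.603, 8.293],
        (3.487, 8.293, 17.003, 39.601, 49.445),
    ),
    (
        [22.955, 8.587, 11.574, 38.641, 4.815, 22.672, 4.235, 28.033, 0.435,
         49.287, 15.829, 31.972],
        (0.435, 6.701, 19.2505, 30.0025, 49.287),
    ),
    (
        [14.761, 49.835, 45.301, 49.437, 3.282, 31.352, 24.524, 48.551, 18.111,
         34, 13.186, 9.286, 9.257, 18.965, 42.351, 24.904, 39.529, 41.923,
         22.845, 39.974],
        (3.282, 16.436, 28.128, 42.137, 49.835),
    ),
]


class TestTukeyHinges:
    @pytest.mark.parametrize("values,expected", R_FIVENUM_CASES)
    def test_matches_r_fivenum(self, values, expected):
        lo, med, hi = tukey_hinges(values)
        assert (lo, med, hi) == pytest.approx(expected[1:4])

    def test_empty_input(self):
        with pytest.raises(EmptyInputError):
            tukey_hinges([])


class TestBoxplotStats:
    def test_outlier_beyond_upper_fence(self):
        # hinges 2 and 5, fences 2-4.5 and 5+4.5: 100 is eliminated
        s = boxplot_stats([1, 2, 3, 4, 5, 100])
        assert (s.q0, s.q1, s.q2, s.q3, s.q4) == (1, 2, 3.5, 5, 5)
        assert s.outliers == (100,)
        assert s.n == 5

    def test_degenerate_all_equal(self):
        s = boxplot_stats([0, 0, 0, 0])
        assert (s.q0, s.q1, s.q2, s.q3, s.q4) == (0, 0, 0, 0, 0)
        assert s.outliers == ()

    def test_infinite_whisker_disables_fences(self):
        s = boxplot_stats([1, 2, 3, 4, 5, 100], whisker_coef=math.inf)
        assert (s.q0, s.q4) == (1, 100)
        assert s.outliers == ()

    def test_linear_method_differs_from_hinges_where_expected(self):
        # type-7 quartiles of 1..6 are (2.25, 4.75); hinges are (2, 5)
        hinge = boxplot_stats([1, 2, 3, 4, 5, 6], method="hinge")
        linear = boxplot_stats([1, 2, 3, 4, 5, 6], method="linear")
        assert (hinge.q1, hinge.q3) == (2, 5)
        assert (linear.q1, linear.q3) == (2.25, 4.75)
        assert hinge.q2 == linear.q2 == 3.5

    def test_whiskers_are_data_values_not_fences(self, rng):
        x = list(rng.normal(25, 8, 40))
        s = boxplot_stats(x)
        assert s.q0 in x and s.q4 in x

    @given(
        values=st.lists(st.floats(0, 50, allow_nan=False), min_size=1, max_size=30),
        coef=st.sampled_from([0.0, 1.0, 1.5, 3.0]),
    )
    @settings(max_examples=400, derandomize=True)
    def test_matches_brute_force_oracle(self, values, coef):
        s = boxplot_stats(values, whisker_coef=coef)
        q0, q1, q2, q3, q4, out = boxplot_oracle(values, coef)
        assert (s.q0, s.q1, s.q2, s.q3, s.q4) == (q0, q1, q2, q3, q4)
        assert list(s.outliers) == out

    @given(values=st.lists(st.floats(0, 50, allow_nan=False), min_size=1, max_size=30))
    @settings(max_examples=300, derandomize=True)
    def test_median_unaffected_by_fences_and_ordering_invariant(self, values):
        s = boxplot_stats(values)
        assert s.q0 <= s.q1 <= s.q2 <= s.q3 <= s.q4
        assert s.q2 == fivenum_oracle(values)[2]
        lo = s.q1 - 1.5 * s.iqr
        hi = s.q3 + 1.5 * s.iqr
        assert all(v < lo or v > hi for v in s.outliers)


class TestSummarizeKaryotype:
    @staticmethod
    def chrom(index, i_values, lengths=None):
        return IdentifiedChromosome(
            index=index,
            i_values=list(i_values),
            lengths=list(lengths or [10.0] * len(i_values)),
        )

    def test_one_summary_per_chromosome_with_means(self):
        chroms = [self.chrom(k, [50 - k, 50 - k, 49 - k]) for k in range(1, 51)]
        summaries = summarize_karyotype(chroms)
        assert len(summaries) == 50
        assert summaries[0].mean_i == pytest.approx((49 + 49 + 48) / 3)

    def test_all_telocentric(self):
        (s,) = summarize_karyotype([self.chrom(1, [0, 0, 0, 0])])
        assert (s.stats.q0, s.stats.q2, s.stats.q4) == (0, 0, 0)

    def test_median_of_three(self):
        (s,) = summarize_karyotype([self.chrom(1, [48, 48, 0])])
        assert s.stats.q2 == 48

    def test_empty_list(self):
        with pytest.raises(EmptyInputError):
            summarize_karyotype([])

    def test_summary_table_round_trips(self, tmp_path):
        chroms = [self.chrom(k, [40 - k, 41 - k, 42 - k]) for k in range(1, 4)]
        summaries = summarize_karyotype(chroms)
        df = summary_table("SP", summaries)
        path = tmp_path / "summary.tsv"
        df.to_csv(path, sep="\t", index=False)
        import pandas as pd

        back = pd.read_csv(path, sep="\t")
        pd.testing.assert_frame_equal(back, df)
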