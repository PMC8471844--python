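import numpy as np
import pytest

import karyostd as ks
from karyostd.comparison import (
    comparison_table,
    divergence_summary,
    format_runs,
    interval_overlap,
    permutation_median_test,
)
from karyostd.errors import CardinalityError, EmptyInputError, KaryostdError
from karyostd.quartiles import summarize_karyotype
from karyostd.ranking import IdentifiedChromosome


def chroms_from_medians(medians, spread=0.0):
    return [
        IdentifiedChromosome(
            index=k + 1,
            i_values=[m - spread, m, m, m + spread] if m > spread else [m] * 4,
            lengths=[10.0] * 4,
        )
        for k, m in enumerate(medians)
    ]


class TestIntervalOverlap:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((0, 5), (4, 10), True),
            ((0, 3), (4, 10), False),
            ((0, 0), (0, 0), True),  # shared degenerate all-telocentric point
            ((4, 10), (0, 5), True),
        ],
    )
    def test_closed_interval_semantics(self, a, b, expected):
        assert interval_overlap(a, b) is expected

    def test_malformed_interval(self):
        with pytest.raises(KaryostdError):
            interval_overlap((5, 0), (0, 1))


class TestCompareKaryotypes:
    def test_identical_karyotypes_never_diverge(self):
        meds = [40.0, 30.0, 20.0, 0.0]
        s = {sp: summarize_karyotype(chroms_from_medians(meds, 1.0)) for sp in "AB"}
        res = ks.compare_karyotypes(s)
        assert res.divergence_counts[("A", "B")] == 0

    def test_single_engineered_divergence(self):
        base = [45.0, 40.0, 35.0, 30.0, 11.0, 5.0]
        other = list(base)
        other[4] = 21.0  # chr5 interval [20,22] vs [10,12]
        s = {
            "A": summarize_karyotype(chroms_from_medians(base, 1.0)),
            "B": summarize_karyotype(chroms_from_medians(other, 1.0)),
        }
        res = ks.compare_karyotypes(s)
        assert res.divergence_counts[("A", "B")] == 1
        assert res.divergent_indices(("A", "B")) == [5]

    def test_all_telocentric_block_never_flagged(self):
        meds = [40.0] * 3 + [0.0] * 11
        s = {
            sp: summarize_karyotype(chroms_from_medians(meds, 2.0))
            for sp in ("A", "B", "C")
        }
        res = ks.compare_karyotypes(s)
        for c in res.comparisons[3:]:
            assert not c.flagged

    def test_divergence_invariant_under_species_relabeling(self, rng):
        meds_a = sorted(rng.uniform(0, 50, 10), reverse=True)
        meds_b = sorted(rng.uniform(0, 50, 10), reverse=True)
        sa = summarize_karyotype(chroms_from_medians(meds_a, 1.0))
        sb = summarize_karyotype(chroms_from_medians(meds_b, 1.0))
        r1 = ks.compare_karyotypes({"X": sa, "Y": sb})
        r2 = ks.compare_karyotypes({"Y": sb, "X": sa})
        assert r1.divergence_counts == r2.divergence_counts

    def test_divergence_vanishes_as_noise_shrinks(self, rng):
        """Species drawn from one shared karyotype stop diverging as noise -> 0."""
        meds = sorted(rng.uniform(5, 50, 20), reverse=True)
        counts = []
        for noise in (2.0, 0.5, 0.0):
            s = {}
            for sp in ("A", "B"):
                jitter = rng.normal(0, noise, 20)
                chroms = [
                    IdentifiedChromosome(
                        index=k + 1,
                        i_values=list(np.clip(m + jitter[k] + rng.normal(0, noise, 6), 0, 50)),
                        lengths=[10.0] * 6,
                    )
                    for k, m in enumerate(meds)
                ]
                s[sp] = summarize_karyotype(chroms)
            counts.append(ks.compare_karyotypes(s).divergence_counts[("A", "B")])
        assert counts[-1] == 0

    def test_mismatched_counts_rejected(self):
        s = {
            "A": summarize_karyotype(chroms_from_medians([40.0, 30.0])),
            "B": summarize_karyotype(chroms_from_medians([40.0])),
        }
        with pytest.raises(CardinalityError):
            ks.compare_karyotypes(s)

    def test_single_species_rejected(self):
        with pytest.raises(EmptyInputError):
            ks.compare_karyotypes({"A": summarize_karyotype(chroms_from_medians([40.0]))})

    def test_species_grand_means_and_table(self):
        meds = [40.0, 20.0, 0.0]
        s = {sp: summarize_karyotype(chroms_from_medians(meds)) for sp in "AB"}
        res = ks.compare_karyotypes(s)
        assert res.species_means["A"]["mean_i"] == pytest.approx(20.0)
        table = comparison_table(res)
        assert len(table) == 3  # one pair x three chromosomes
        assert table["overlap"].all()
        assert "0 divergent" in divergence_summary(res)


class TestHelpers:
    @pytest.mark.parametrize(
        "indices,expected",
        [
            ([], "none"),
            ([5], "5"),
            ([12, 13, 14, 30], "12-14, 30"),
            ([8, 11, 12, 13, 31], "8, 11-13, 31"),
        ],
    )
    def test_format_runs(self, indices, expected):
        assert format_runs(indices) == expected

    def test_permutation_test_separates_distinct_pools(self, rng):
        a = list(rng.normal(40, 0.5, 20))
        b = list(rng.normal(10, 0.5, 20))
        p_diff = permutation_median_test(a, b, n_permutations=499, rng=rng)
        p_same = permutation_median_test(a, list(rng.normal(40, 0.5, 20)),
                                         n_permutations=499, rng=rng)
        assert p_diff < 0.05 < p_same
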