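"""Unit and property tests for the group-comparison statistics.

The scipy implementations (mannwhitneyu, fisher_exact) act as
independent reference oracles; the package's own implementations are the
code under test.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from denovoprio import (DataError, compare_denovo_vs_private,
                        fisher_exact_rxc, wilcoxon_ranksum)
from denovoprio.deleteriousness import _montecarlo_pvalue, _table_logpmf
from denovoprio.synthetic_data import VariantCohortConfig, gen_variant_cohorts


class TestWilcoxon:
    def test_single_pair_exact(self):
        r = wilcoxon_ranksum([1.0], [2.0])
        assert r.p_value == 1.0
        assert not r.tie_corrected and not r.continuity_corrected

    def test_recurrent_vs_nonrecurrent_worked_example(self):
        rec = [26.3, 26.3, 26.3, 27.3, 27.3]
        nonrec = [25.5, 22.9, 23.4]
        r = wilcoxon_ranksum(rec, nonrec)
        assert r.tie_corrected and r.continuity_corrected
        assert r.p_value == pytest.approx(0.0314, abs=1e-4)
        ref = stats.mannwhitneyu(rec, nonrec, method="asymptotic",
                                 use_continuity=True)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_identical_samples_near_one(self):
        x = list(range(20))
        r = wilcoxon_ranksum(x, x)
        assert r.p_value >= 0.9

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=6)
        y = rng.normal(size=7)
        r = wilcoxon_ranksum(x, y)
        ref = stats.mannwhitneyu(x, y, method="exact")
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_asymptotic_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        x = np.round(rng.normal(size=40), 1)  # rounding forces ties
        y = np.round(rng.normal(0.3, size=35), 1)
        r = wilcoxon_ranksum(x, y)
        ref = stats.mannwhitneyu(x, y, method="asymptotic", use_continuity=True)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_exact_matches_permutation_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=5)
        y = rng.normal(1.0, size=5)
        r = wilcoxon_ranksum(x, y)

        def u_stat(a, b):
            ranks = stats.rankdata(np.concatenate([a, b]))
            return ranks[: len(a)].sum() - len(a) * (len(a) + 1) / 2

        ref = stats.permutation_test(
            (x, y), u_stat, permutation_type="independent",
            alternative="two-sided", n_resamples=np.inf,
        )
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(0.5, size=9)
        p0 = wilcoxon_ranksum(x, y).p_value
        p1 = wilcoxon_ranksum(np.exp(x), np.exp(y)).p_value
        assert p0 == pytest.approx(p1, rel=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(DataError):
            wilcoxon_ranksum([], [1.0])


class TestFisher:
    def test_diagonal_table_closed_form(self):
        r = fisher_exact_rxc([[5, 0], [0, 5]])
        assert r.p_value == pytest.approx(2 / 252, rel=1e-9)

    def test_homogeneous_table(self):
        assert fisher_exact_rxc([[3, 3], [3, 3]]).p_value == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_2x2_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 15, size=(2, 2))
        table += 1  # avoid degenerate margins
        r = fisher_exact_rxc(table)
        ref = stats.fisher_exact(table)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_enumeration_matches_montecarlo(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 8, size=(2, 3)) + 1
        exact = fisher_exact_rxc(table).p_value
        n_draws = 40_000
        mc = _montecarlo_pvalue(np.asarray(table), n_draws,
                                np.random.default_rng(seed + 100))
        se = np.sqrt(exact * (1 - exact) / n_draws)
        assert abs(mc - exact) <= 3 * se + 2 / n_draws

    def test_large_table_uses_montecarlo_consistently(self):
        table = np.array([[150, 160], [140, 170]])
        exact = fisher_exact_rxc(table, enum_limit=1000).p_value
        mc = fisher_exact_rxc(table, enum_limit=100, n_montecarlo=50_000,
                              seed=0).p_value
        se = np.sqrt(exact * (1 - exact) / 50_000)
        assert abs(mc - exact) <= 4 * se

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_row_and_column_permutation(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 10, size=(2, 3)) + 1
        p0 = fisher_exact_rxc(table).p_value
        p1 = fisher_exact_rxc(table[::-1, ::-1]).p_value
        perm = table[:, rng.permutation(3)]
        p2 = fisher_exact_rxc(perm).p_value
        assert p0 == pytest.approx(p1, rel=1e-9)
        assert p0 == pytest.approx(p2, rel=1e-9)

    def test_not_anticonservative_under_null(self):
        # validity check: exact test never rejects above nominal rate
        rng = np.random.default_rng(7)
        rej = 0
        n_sims = 400
        for _ in range(n_sims):
            a = rng.binomial(30, 0.5)
            b = rng.binomial(30, 0.5)
            if fisher_exact_rxc([[a, 30 - a], [b, 30 - b]]).p_value <= 0.05:
                rej += 1
        assert rej / n_sims <= 0.055

    def test_degenerate_table_rejected(self):
        with pytest.raises(DataError):
            fisher_exact_rxc([[5, 5]])
        with pytest.raises(DataError):
            fisher_exact_rxc([[5, 0], [7, 0]])

    def test_negative_cells_rejected(self):
        with pytest.raises(DataError):
            fisher_exact_rxc([[1, -1], [2, 3]])


class TestCohortComparison:
    def test_separated_cohorts_significant(self):
        denovo, private = gen_variant_cohorts(
            VariantCohortConfig(n_denovo=100, n_private=100, seed=3)
        )
        res = compare_denovo_vs_private(denovo, private, seed=0)
        assert res["cadd"].method == "wilcoxon_ranksum"
        assert res["cadd"].p_value < 0.01
        assert res["sift"].method == "fisher_exact"
        assert res["polyphen"].p_value < 0.01

    def test_identical_cohorts_null(self):
        denovo, _ = gen_variant_cohorts(VariantCohortConfig(seed=5))
        res = compare_denovo_vs_private(denovo, denovo, seed=0)
        assert res["cadd"].p_value > 0.9
        assert res["sift"].p_value == 1.0

    def test_fully_separated_bins_tiny_p(self):
        cfg = VariantCohortConfig(n_denovo=20, n_private=20,
                                  damaging_fraction_denovo=1.0,
                                  damaging_fraction_private=0.0, seed=1)
        denovo, private = gen_variant_cohorts(cfg)
        res = compare_denovo_vs_private(denovo, private, scores=("sift",))
        assert res["sift"].p_value < 1e-6

    def test_empty_cohort_rejected(self):
        denovo, _ = gen_variant_cohorts(VariantCohortConfig(seed=0))
        with pytest.raises(DataError):
            compare_denovo_vs_private(denovo, [])
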