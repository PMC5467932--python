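import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from petph.errors import (ConstantInputError, DegenerateVarianceError,
                          DomainError, TableError)
from petph.phantom import default_cohort_spec, make_cohort
from petph.stats import (GroupSummary, bland_altman, build_tables, p_display,
                         spearman, summarize, t_test_from_summary, t_test_raw)


def moment_matched_sample(mean: float, sd: float, n: int) -> np.ndarray:
    """A sample whose mean and (n−1)-denominator SD are exactly as given."""
    z = np.linspace(-1.0, 1.0, n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


class TestTTest:
    def test_identical_summaries_null(self):
        g = GroupSummary(1.0, 0.5, 10)
        res = t_test_from_summary(g, g)
        assert res.statistic == 0.0
        assert res.p_two_sided == pytest.approx(1.0)

    def test_summary_equals_scipy_on_moment_matched_samples(self):
        """Summary-statistic Welch/pooled tests agree with raw-sample tests
        computed by an independent implementation (scipy) to 1e-10."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            m1, m2 = rng.normal(0, 2, 2)
            s1, s2 = rng.uniform(0.2, 3.0, 2)
            n1, n2 = rng.integers(4, 40, 2)
            x = moment_matched_sample(m1, s1, int(n1))
            y = moment_matched_sample(m2, s2, int(n2))
            for method, equal_var in (("welch", False), ("pooled", True)):
                ours = t_test_from_summary(summarize(x), summarize(y), method)
                ref = sps.ttest_ind(x, y, equal_var=equal_var)
                assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
                assert ours.p_two_sided == pytest.approx(ref.pvalue, abs=1e-10)
                raw = t_test_raw(x, y, method)
                assert raw.statistic == pytest.approx(ours.statistic, abs=1e-10)

    def test_welch_equals_pooled_for_balanced_equal_variance(self):
        g1 = GroupSummary(1.2, 0.7, 15)
        g2 = GroupSummary(0.8, 0.7, 15)
        w = t_test_from_summary(g1, g2, "welch")
        p = t_test_from_summary(g1, g2, "pooled")
        assert w.statistic == pytest.approx(p.statistic, abs=1e-12)
        assert w.df == pytest.approx(p.df, abs=1e-9)
        assert w.p_two_sided == pytest.approx(p.p_two_sided, abs=1e-12)

    def test_welch_df_bounded_by_pooled_df(self):
        g1 = GroupSummary(0.5, 0.15, 30)
        g2 = GroupSummary(0.37, 0.09, 8)
        res = t_test_from_summary(g1, g2, "welch")
        assert res.df <= g1.n + g2.n - 2

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            t_test_from_summary(GroupSummary(1.0, 0.0, 5), GroupSummary(2.0, 0.0, 5))

    def test_ci_contains_mean_difference(self):
        g1 = GroupSummary(2.04, 0.73, 21)
        g2 = GroupSummary(1.59, 0.38, 8)
        res = t_test_from_summary(g1, g2)
        lo, hi = res.ci_95
        assert lo < g1.mean - g2.mean < hi

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(m1=st.floats(-3, 3), m2=st.floats(-3, 3),
           s1=st.floats(0.1, 2.0), s2=st.floats(0.1, 2.0),
           n1=st.integers(4, 50), n2=st.integers(4, 50))
    def test_summary_test_equivalent_to_raw_test(self, m1, m2, s1, s2, n1, n2):
        x = moment_matched_sample(m1, s1, n1)
        y = moment_matched_sample(m2, s2, n2)
        ours = t_test_from_summary(GroupSummary(m1, s1, n1),
                                   GroupSummary(m2, s2, n2))
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert ours.p_two_sided == pytest.approx(ref.pvalue, abs=1e-10)


class TestSpearman:
    def test_monotone_function_gives_unit_rho(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        res = spearman(x, np.exp(x))
        assert res.statistic == pytest.approx(1.0)
        res = spearman(x, -np.exp(x))
        assert res.statistic == pytest.approx(-1.0)

    def test_matches_classic_d_squared_formula_without_ties(self):
        rng = np.random.default_rng(2)
        x = rng.permutation(6).astype(float)
        y = rng.permutation(6).astype(float)
        d = sps.rankdata(x) - sps.rankdata(y)
        n = len(x)
        rho_classic = 1 - 6 * np.sum(d**2) / (n * (n**2 - 1))
        assert spearman(x, y).statistic == pytest.approx(rho_classic, abs=1e-12)

    def test_matches_scipy_with_ties_and_missing(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 5, 30).astype(float)
        y = x + rng.normal(0, 2, 30)
        x[3] = np.nan
        y[7] = np.nan
        keep = np.isfinite(x) & np.isfinite(y)
        ref = sps.spearmanr(x[keep], y[keep])
        res = spearman(x, y)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.df == keep.sum() - 2

    def test_invariant_under_strictly_monotone_transform(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        base = spearman(x, y).statistic
        assert spearman(np.exp(x), y).statistic == pytest.approx(base)
        assert spearman(x, y**3).statistic == pytest.approx(base)

    def test_constant_vector_signaled(self):
        with pytest.raises(ConstantInputError):
            spearman(np.ones(10), np.arange(10.0))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(DomainError):
            spearman(np.arange(3.0), np.arange(3.0))


class TestBlandAltman:
    def test_perfect_agreement(self):
        r1 = np.array([1.0, 2.0, 3.5, 4.2])
        res = bland_altman(r1, r1)
        assert res.mean_diff == 0.0
        assert (res.loa_lower, res.loa_upper) == (0.0, 0.0)
        assert res.r == pytest.approx(1.0)

    def test_constant_offset(self):
        r1 = np.array([1.0, 2.0, 3.0])
        res = bland_altman(r1 + 0.25, r1)
        assert res.mean_diff == pytest.approx(0.25)
        assert res.loa_lower == pytest.approx(0.25)
        assert res.loa_upper == pytest.approx(0.25)

    def test_midpoint_of_limits_equals_mean_difference(self):
        rng = np.random.default_rng(6)
        r1 = rng.normal(2.0, 0.5, 50)
        r2 = r1 + rng.normal(-0.06, 0.03, 50)
        res = bland_altman(r1, r2)
        assert (res.loa_lower + res.loa_upper) / 2 == pytest.approx(res.mean_diff)
        assert res.loa_upper - res.mean_diff == pytest.approx(1.96 * res.sd_diff)

    def test_simulated_limits_match_population_values(self):
        # diffs ~ N(-0.06, 0.033): limits converge to about (-0.125, 0.005)
        rng = np.random.default_rng(7)
        n = 10_000
        r2 = rng.normal(1.0, 0.2, n)
        r1 = r2 + rng.normal(-0.06, 0.033, n)
        res = bland_altman(r1, r2)
        assert res.loa_lower == pytest.approx(-0.06 - 1.96 * 0.033, abs=0.003)
        assert res.loa_upper == pytest.approx(-0.06 + 1.96 * 0.033, abs=0.003)

    def test_single_pair_rejected(self):
        with pytest.raises(DomainError):
            bland_altman([1.0], [1.0])


class TestPDisplay:
    @pytest.mark.parametrize("p,expected", [(0.0060, 0.01), (0.043, 0.04),
                                            (0.638, 0.6), (0.51, 0.5),
                                            (0.0006, 0.0006), (1.0, 1.0)])
    def test_publication_rounding(self, p, expected):
        assert p_display(p) == pytest.approx(expected)


class TestBuildTables:
    def test_single_group_rejected(self):
        records, _ = make_cohort(default_cohort_spec(seed=1))
        controls = [r for r in records if r.group.value == "control"]
        with pytest.raises(TableError):
            build_tables(controls)

    def test_tables_cover_measures_and_sizes(self):
        records, _ = make_cohort(default_cohort_spec(seed=1))
        tables = build_tables(records)
        groups = tables["groups"].set_index("measure")
        assert groups.loc["lung_suv_m", "n_ph"] == 30
        assert groups.loc["lung_suv_m", "n_control"] == 8
        assert set(tables["pet_vs_ntprobnp"]["pet_measure"]) >= {
            "rved_volume", "rves_volume", "rvef", "rv_lv_ratio"}

    def test_strain_correlations_use_pairwise_complete_pairs(self):
        records, _ = make_cohort(default_cohort_spec(seed=1))
        tables = build_tables(records)
        row = tables["pet_vs_echo"].set_index(["pet_measure", "echo_measure"])
        assert row.loc[("rvef", "strain"), "n"] == 36  # two strain values missing
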