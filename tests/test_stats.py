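"""Unit and property tests for the correlation/test statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cibias.stats import (
    CorrelationResult,
    DegenerateDataError,
    binomial_sign_test,
    chi_square_independence,
    compare_slopes,
    pearson_rmf,
    tally_correlations,
)


class TestPearsonRmf:
    def test_perfect_correlation(self):
        x = np.arange(1.0, 11.0)
        res = pearson_rmf(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.p_two_tailed == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_product_moment(self):
        # sxy=11, sxx=20, syy=8.75 -> r = 11/sqrt(175)
        res = pearson_rmf([2, 4, 6, 8], [1, 3, 2, 5])
        assert res.r == pytest.approx(11 / math.sqrt(175), abs=1e-12)
        assert res.slope == pytest.approx(11 / 20, abs=1e-12)
        assert res.n == 4 and res.df == 2

    def test_t_and_p_for_moderate_negative_r_at_n27(self):
        # r=-0.34 over 27 lines is marginally non-significant two-tailed
        x = np.random.default_rng(3).normal(size=27)
        # construct y with exact sample correlation -0.34
        y = np.random.default_rng(4).normal(size=27)
        xd = (x - x.mean()) / x.std()
        yd = y - y.mean()
        yd -= xd * (xd @ yd) / (xd @ xd)  # orthogonalize
        yd /= yd.std()
        target = -0.34
        yy = target * xd + math.sqrt(1 - target**2) * yd
        res = pearson_rmf(x, yy)
        assert res.r == pytest.approx(-0.34, abs=1e-9)
        assert res.df == 25
        assert res.t_stat == pytest.approx(-1.80, abs=0.01)
        assert res.p_two_tailed == pytest.approx(0.08, abs=0.005)

    def test_matches_scipy_linregress_and_pearsonr(self, rng):
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            res = pearson_rmf(x, y)
            r_ref, p_ref = sps.pearsonr(x, y)
            lr = sps.linregress(x, y)
            assert res.r == pytest.approx(r_ref, abs=1e-12)
            assert res.p_two_tailed == pytest.approx(p_ref, abs=1e-10)
            assert res.slope == pytest.approx(lr.slope, abs=1e-12)
            assert res.slope_se == pytest.approx(lr.stderr, abs=1e-12)

    def test_slope_t_equals_correlation_t(self, rng):
        # for simple regression slope/se and r*sqrt(df)/sqrt(1-r^2) coincide
        for _ in range(20):
            x = rng.normal(size=9)
            y = rng.normal(size=9)
            res = pearson_rmf(x, y)
            assert res.slope / res.slope_se == pytest.approx(res.t_stat, abs=1e-9)

    @given(
        st.integers(min_value=0, max_value=2**31),
        st.floats(min_value=0.1, max_value=50.0),
        st.floats(min_value=-100.0, max_value=100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_affine_invariance(self, seed, scale, shift):
        g = np.random.default_rng(seed)
        x = g.normal(size=8)
        y = g.normal(size=8)
        r = pearson_rmf(x, y).r
        assert pearson_rmf(y, x).r == pytest.approx(r, abs=1e-12)
        assert pearson_rmf(scale * x + shift, y).r == pytest.approx(r, abs=1e-9)
        assert pearson_rmf(-scale * x, y).r == pytest.approx(-r, abs=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least 3"):
            pearson_rmf([1, 2], [3, 4])
        with pytest.raises(ValueError, match="length mismatch"):
            pearson_rmf([1, 2, 3], [1, 2, 3, 4])
        with pytest.raises(DegenerateDataError):
            pearson_rmf([5, 5, 5, 5], [1, 2, 3, 4])
        with pytest.raises(DegenerateDataError):
            pearson_rmf([1, 2, 3, 4], [5, 5, 5, 5])


class TestCompareSlopes:
    def test_identical_slopes(self):
        res = compare_slopes(0.7, 0.2, 10, 0.7, 0.3, 10)
        assert res.t_stat == 0.0
        assert res.p_two_tailed == pytest.approx(1.0)

    def test_hand_computed_t(self):
        res = compare_slopes(1.0, 0.5, 10, 0.0, 0.5, 10)
        assert res.t_stat == pytest.approx(1 / math.sqrt(0.5), abs=1e-12)

    def test_df_for_27_and_25_point_regressions(self):
        assert compare_slopes(-0.3, 0.2, 27, 0.05, 0.2, 25).df == 48

    @given(
        st.floats(min_value=-5, max_value=5),
        st.floats(min_value=-5, max_value=5),
        st.floats(min_value=0.01, max_value=2),
        st.floats(min_value=0.01, max_value=2),
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, b1, b2, se1, se2):
        t12 = compare_slopes(b1, se1, 10, b2, se2, 12).t_stat
        t21 = compare_slopes(b2, se2, 12, b1, se1, 10).t_stat
        assert t12 == pytest.approx(-t21, abs=1e-12)

    def test_degenerate_zero_standard_errors(self):
        res = compare_slopes(1.0, 0.0, 5, 0.0, 0.0, 5)
        assert math.isinf(res.t_stat) and res.t_stat > 0
        assert res.p_two_tailed == 0.0
        res = compare_slopes(0.5, 0.0, 5, 0.5, 0.0, 5)
        assert res.t_stat == 0.0 and res.p_two_tailed == 1.0


def _corr(r, n):
    """CorrelationResult with consistent t/p for a given r and n."""
    df = n - 2
    t = r * math.sqrt(df) / math.sqrt(1 - r * r)
    p = 2 * sps.t.sf(abs(t), df)
    return CorrelationResult(r=r, t_stat=t, df=df, p_two_tailed=p,
                             slope=r, slope_se=1.0, n=n)


class TestTallies:
    def test_empty(self):
        t = tally_correlations([])
        assert (t.n_positive, t.n_negative, t.n_sig_positive, t.n_sig_negative) \
            == (0, 0, 0, 0)

    def test_sign_and_significance_split(self):
        # critical |r| at n=10, alpha=0.05 is ~0.632
        t = tally_correlations([_corr(0.9, 10), _corr(-0.9, 10), _corr(0.1, 10)])
        assert t.n_positive == 2 and t.n_negative == 1
        assert t.n_sig_positive == 1 and t.n_sig_negative == 1

    def test_undefined_entries_skipped_and_counted(self):
        t = tally_correlations([_corr(0.5, 10), None, None])
        assert t.n_positive == 1 and t.n_undefined == 2
        assert t.n_total == 3

    def test_zero_r_counts_as_positive(self):
        t = tally_correlations([_corr(0.0, 10)])
        assert t.n_positive == 1 and t.n_negative == 0


class TestChiSquare:
    def test_perfect_independence(self):
        chi2, df, p = chi_square_independence([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        # all expected counts are 5 -> chi2 = 4 * (2^2/5) = 3.2
        chi2, df, p = chi_square_independence([[3, 7], [7, 3]])
        assert chi2 == pytest.approx(3.2, abs=1e-12)
        assert df == 1

    def test_df_of_6x2_table(self):
        table = np.arange(1, 13).reshape(6, 2)
        _, df, _ = chi_square_independence(table)
        assert df == 5

    def test_matches_brute_force_oracle_on_small_tables(self, rng):
        def oracle(obs):
            obs = np.asarray(obs, float)
            exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            chi2 = ((obs - exp) ** 2 / exp).sum()
            df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
            return chi2, df, sps.chi2.sf(chi2, df)

        # exhaustive 2x2 with entries 1..6, plus random 3x3 tables
        for a in range(1, 7):
            for b in range(1, 7):
                for c in range(1, 7):
                    for d in range(1, 7):
                        tab = [[a, b], [c, d]]
                        got = chi_square_independence(tab)
                        want = oracle(tab)
                        assert got[0] == pytest.approx(want[0], abs=1e-8)
                        assert got[1] == want[1]
                        assert got[2] == pytest.approx(want[2], abs=1e-8)
        for _ in range(50):
            tab = rng.integers(1, 7, size=(3, 3))
            got = chi_square_independence(tab)
            want = oracle(tab)
            assert got[0] == pytest.approx(want[0], abs=1e-8)
            assert got[1] == want[1]

    def test_zero_margin_identified(self):
        with pytest.raises(ValueError, match="row 1"):
            chi_square_independence([[1, 2], [0, 0]])
        with pytest.raises(ValueError, match="column 0"):
            chi_square_independence([[0, 2], [0, 3]])


class TestBinomialSignTest:
    def test_exact_null_split(self):
        z, p = binomial_sign_test(9, 18)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_all_successes_enumeration(self):
        z, p = binomial_sign_test(18, 18)
        assert z == pytest.approx(9 / math.sqrt(4.5), abs=1e-12)  # 4.2426
        assert p == pytest.approx(2 * 0.5**18, rel=1e-9)

    @pytest.mark.parametrize("k,n", [(18, 18), (31, 31)])
    def test_published_splits_exceed_z_bound(self, k, n):
        z, p = binomial_sign_test(k, n)
        assert z > 2.84
        assert p < 0.001

    def test_exact_p_matches_pmf_enumeration(self):
        # minimum-likelihood two-sided p, all n <= 12 at p0=0.5 and a biased p0
        for p0 in (0.5, 0.3):
            for n in range(1, 13):
                masses = sps.binom.pmf(np.arange(n + 1), n, p0)
                for k in range(n + 1):
                    expected = masses[masses <= masses[k] * (1 + 1e-9)].sum()
                    _, p = binomial_sign_test(k, n, p0)
                    assert p == pytest.approx(min(1.0, expected), abs=1e-8)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            binomial_sign_test(5, 4)
        with pytest.raises(ValueError):
            binomial_sign_test(1, 4, p0=1.0)


def test_p_monotone_decreasing_in_abs_t_at_fixed_df():
    df = 8
    ts = np.linspace(0, 6, 30)
    ps = [2 * sps.t.sf(t, df) for t in ts]
    rs = ts / np.sqrt(df + ts**2)
    # realized through pearson results: larger |r| at fixed n -> smaller p
    results = [_corr(float(r), df + 2) for r in rs]
    pvals = [res.p_two_tailed for res in results]
    assert all(p1 >= p2 - 1e-12 for p1, p2 in zip(pvals, pvals[1:]))
    assert pvals == pytest.approx(ps, abs=1e-12)
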