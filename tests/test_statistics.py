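"""The four MANOVA statistics, their F approximations and Bartlett's chi-square."""

import math

import numpy as np
import pytest
import scipy.linalg as sla
import scipy.stats as sps

import manovasim as ms
from manovasim.core import EigenSpectrum, roy_null_cdf
from conftest import random_sample


def spectrum(lambdas, s=None, q=2, v=27, p=2):
    lams = tuple(float(x) for x in lambdas)
    return EigenSpectrum(lambdas=lams, s=s or len(lams), q=q, v=v, p=p)


class TestStatisticValues:
    def test_null_spectrum(self):
        spec = spectrum([0.0, 0.0])
        assert ms.wilks_lambda(spec) == 1.0
        assert ms.pillai_trace(spec) == 0.0
        assert ms.hotelling_lawley(spec) == 0.0
        assert ms.roy_largest_root(spec) == 0.0

    def test_unit_roots(self):
        spec = spectrum([1.0, 1.0])
        assert ms.wilks_lambda(spec) == pytest.approx(0.25)
        assert ms.pillai_trace(spec) == pytest.approx(1.0)
        assert ms.hotelling_lawley(spec) == pytest.approx(2.0)
        assert ms.roy_largest_root(spec) == pytest.approx(0.5)

    def test_wilks_equals_determinant_ratio(self):
        sample = random_sample(13, sizes=(9, 10, 11), p=2, shifts=(0, 0.3, 0.8))
        pair = ms.sscp_matrices(sample)
        spec = ms.eigen_spectrum(pair, sample.g, sample.N)
        det_ratio = np.linalg.det(pair.W) / np.linalg.det(pair.B + pair.W)
        assert ms.wilks_lambda(spec) == pytest.approx(det_ratio, rel=1e-10)

    def test_single_root_identities(self):
        spec = spectrum([0.7], q=1, v=20, p=2)
        lam = ms.wilks_lambda(spec)
        V = ms.pillai_trace(spec)
        U = ms.hotelling_lawley(spec)
        theta = ms.roy_largest_root(spec)
        assert V == pytest.approx(1.0 - lam, rel=1e-12)
        assert U == pytest.approx(V / (1.0 - V), rel=1e-12)
        assert theta == pytest.approx(V, rel=1e-12)


class TestFApproximation:
    def test_univariate_reduces_to_anova(self):
        sample = random_sample(21, sizes=(8, 9, 10), p=1, shifts=(0.0, 0.5, 1.2))
        res = ms.manova_test(sample)
        F, pval = sps.f_oneway(*[b.ravel() for b in sample.groups])
        r = res.results["wilks"]
        assert r.F_or_chi2 == pytest.approx(F, rel=1e-10)
        assert (r.df1, r.df2) == (2.0, float(sample.N - 3))
        assert r.p_value == pytest.approx(pval, rel=1e-10)
        assert r.exact_flag

    def test_two_group_all_four_identical(self):
        # s = 1: each statistic carries the same exact F test
        sample = random_sample(33, sizes=(9, 12), p=2, shifts=(0.0, 0.6))
        res = ms.manova_test(sample)
        ref = res.results["wilks"]
        for name in ms.TESTS:
            r = res.results[name]
            assert r.exact_flag
            assert r.F_or_chi2 == pytest.approx(ref.F_or_chi2, rel=1e-8)
            assert (r.df1, r.df2) == (ref.df1, ref.df2)
            assert r.p_value == pytest.approx(ref.p_value, rel=1e-8)

    def test_pillai_boundary_null(self):
        res = ms.f_approximation("pillai", spectrum([0.0], q=1, v=20, p=2), p=2)
        assert res.F_or_chi2 == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_insufficient_error_df(self):
        # v = p: Pillai/HL auxiliary n* < 0 drives df2 <= 0
        spec = spectrum([0.5, 0.2], q=2, v=2, p=2)
        with pytest.raises(ms.InsufficientErrorDfError):
            ms.f_approximation("hotelling", spec, p=2)

    def test_matches_r_summary_manova(self):
        """Frozen oracle: R 4.3.3 stats::summary.manova on this exact dataset
        (statistic, F, df1, df2, p for W/P/HL; F and dfs for Roy, whose
        statistic R reports as lambda_max and whose printed p is the
        anti-conservative bound)."""
        rng = np.random.default_rng(20240917)
        blocks = []
        for i, n in enumerate((8, 10, 12)):
            x = rng.normal(size=(n, 3))
            x[:, 0] += 0.5 * i
            blocks.append(x)
        res = ms.manova_test(ms.GroupedSample(tuple(blocks)))
        expected = {
            "wilks": (0.800267945053, 0.982056695599, 6, 50, 0.447341156935),
            "pillai": (0.208321849682, 1.00768993039, 6, 52, 0.430514219289),
            "hotelling": (0.238847827649, 0.955391310596, 6, 48, 0.465223911372),
        }
        for name, (stat, F, df1, df2, p) in expected.items():
            r = res.results[name]
            assert r.statistic_value == pytest.approx(stat, rel=1e-9)
            assert r.F_or_chi2 == pytest.approx(F, rel=1e-9)
            assert (r.df1, r.df2) == (df1, df2)
            assert r.p_value == pytest.approx(p, rel=1e-9)
        roy = res.results["roy"]
        lam_max = 0.178824442526  # R's Roy statistic
        assert roy.statistic_value == pytest.approx(lam_max / (1 + lam_max), rel=1e-9)
        assert roy.F_or_chi2 == pytest.approx(1.54981183522, rel=1e-9)
        assert (roy.df1, roy.df2) == (3, 26)
        # exact largest-root p can only exceed the F-bound p (0.225377...)
        assert roy.p_value >= 0.225377509974


class TestRoyNullDistribution:
    def test_matches_wishart_monte_carlo(self):
        """Exact s=2 largest-root CDF vs a brute-force two-Wishart simulation."""
        rng = np.random.default_rng(7)
        p, q, v = 2, 2, 27
        thetas = np.empty(20000)
        for i in range(20000):
            Xb = rng.normal(size=(q, p))
            Xw = rng.normal(size=(v, p))
            B, W = Xb.T @ Xb, Xw.T @ Xw
            thetas[i] = sla.eigh(B, B + W, eigvals_only=True).max()
        for x in (0.15, 0.25, 0.35):
            emp = float((thetas <= x).mean())
            se = math.sqrt(emp * (1 - emp) / 20000)
            assert float(roy_null_cdf(x, p, q, v)) == pytest.approx(emp, abs=4 * se)

    def test_s1_reduces_to_beta_and_f_bound(self):
        p, q, v = 3, 1, 20
        theta = 0.31
        cdf = float(roy_null_cdf(theta, p, q, v))
        df1, df2 = max(p, q), v - max(p, q) + q
        F = df2 * (theta / (1 - theta)) / df1
        assert cdf == pytest.approx(sps.f.cdf(F, df1, df2), rel=1e-8)

    def test_cdf_monotone_and_bounded(self):
        xs = np.linspace(0, 1, 101)
        cdf = np.asarray(roy_null_cdf(xs, 2, 2, 27))
        assert cdf[0] == 0.0 and cdf[-1] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(cdf) >= 0)


class TestBartlett:
    def test_lambda_one_gives_zero(self):
        for mode in ("standard", "as_printed"):
            r = ms.bartlett_chi2(1.0, N=30, p=2, g=3, mode=mode)
            assert r.F_or_chi2 == 0.0 and r.p_value == pytest.approx(1.0)

    def test_as_printed_arithmetic(self):
        # L = -((30-1-5)/2) ln 0.5 = 12 ln 2
        r = ms.bartlett_chi2(0.5, N=30, p=2, g=3, mode="as_printed")
        assert r.F_or_chi2 == pytest.approx(12 * math.log(2), rel=1e-12)
        assert r.df1 == 4.0 and r.df2 is None and r.approx_kind == "chi2"

    def test_standard_differs_from_as_printed(self):
        a = ms.bartlett_chi2(0.5, N=30, p=2, g=3, mode="standard")
        b = ms.bartlett_chi2(0.5, N=30, p=2, g=3, mode="as_printed")
        assert a.F_or_chi2 == pytest.approx(26.5 * math.log(2), rel=1e-12)
        assert a.F_or_chi2 != b.F_or_chi2

    def test_invalid_lambda(self):
        with pytest.raises(ms.InvalidInputError):
            ms.bartlett_chi2(0.0, N=30, p=2, g=3)

    def test_large_sample_agrees_with_rao_f(self):
        # chi-square and Rao-F p-values converge for large N at a small effect
        sample = random_sample(55, sizes=(1667, 1667, 1666), p=2,
                               shifts=(0.0, 0.05, 0.1))
        res = ms.manova_test(sample)
        wl = res.results["wilks"]
        bart = ms.bartlett_chi2(wl.statistic_value, sample.N, sample.p, sample.g)
        assert bart.p_value == pytest.approx(wl.p_value, abs=1e-3)


class TestManovaTest:
    def test_identical_groups_never_reject(self):
        block = np.random.default_rng(2).normal(size=(8, 2))
        res = ms.manova_test(ms.GroupedSample((block.copy(), block.copy(), block.copy())))
        for name in ms.TESTS:
            assert res.results[name].p_value == pytest.approx(1.0)
            assert not res.rejects[name]

    def test_pvalues_valid_and_distinct_when_s2(self):
        res = ms.manova_test(random_sample(99, sizes=(10, 10, 10), p=2))
        pvals = [res.results[t].p_value for t in ms.TESTS]
        assert all(0.0 <= p <= 1.0 for p in pvals)
        assert len({round(p, 12) for p in pvals}) == 4

    def test_univariate_reject_flag_matches_anova(self):
        for seed in (1, 2, 3, 4):
            sample = random_sample(seed, sizes=(10, 10, 10), p=1,
                                   shifts=(0.0, 0.4, 0.8))
            res = ms.manova_test(sample, alpha=0.05)
            _, pval = sps.f_oneway(*[b.ravel() for b in sample.groups])
            assert res.rejects["wilks"] == (pval < 0.05)

    def test_invalid_alpha(self):
        with pytest.raises(ms.InvalidInputError):
            ms.manova_test(random_sample(1), alpha=1.5)
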