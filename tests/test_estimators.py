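"""Univariable MR estimator suite and diagnostics."""

import numpy as np
import pytest

from mrmediate.errors import DataError
from mrmediate.estimators import (
    cochran_q,
    ivw,
    leave_one_out,
    mr_egger,
    mr_presso,
    se_from_or_p,
    summarize_or,
    wald_ratio,
    weighted_median,
    MREstimate,
)
from mrmediate.gwas_io import HarmonizedSet


def hset(gamma, Gamma, sigma_Gamma, sigma_gamma=None):
    gamma = np.asarray(gamma, float)
    if sigma_gamma is None:
        sigma_gamma = np.full_like(gamma, 1e-6)
    return HarmonizedSet.from_arrays(gamma, sigma_gamma, Gamma, sigma_Gamma)


class TestWaldRatio:
    def test_direct_division(self):
        e = wald_ratio(0.1, 0.02, 0.05, 0.02)
        assert e.beta == pytest.approx(0.5)
        assert e.se == pytest.approx(0.2)

    def test_null_effect(self):
        e = wald_ratio(0.1, 0.02, 0.0, 0.02)
        assert e.beta == 0.0
        assert e.pvalue == pytest.approx(1.0)

    def test_negative_gamma_sign(self):
        e = wald_ratio(-0.1, 0.02, 0.05, 0.02)
        assert e.beta == pytest.approx(-0.5)
        assert e.se == pytest.approx(0.2)

    def test_zero_gamma_raises(self):
        with pytest.raises(DataError):
            wald_ratio(0.0, 0.02, 0.05, 0.02)


class TestIVW:
    def test_single_snp_equals_wald(self):
        h = hset([0.1], [0.05], [0.02])
        e = ivw(h, "fixed")
        w = wald_ratio(0.1, 1e-6, 0.05, 0.02)
        assert e.beta == pytest.approx(w.beta)
        assert e.se == pytest.approx(w.se)

    def test_closed_form(self):
        h = hset([0.1, 0.2, 0.3], [0.02, 0.05, 0.04], [0.01] * 3)
        e = ivw(h, "fixed")
        assert e.beta == pytest.approx(0.024 / 0.14)
        assert e.se == pytest.approx(0.01 / np.sqrt(0.14))

    def test_identical_ratios_no_heterogeneity(self):
        g = np.array([0.1, 0.2, 0.3])
        h = hset(g, 0.5 * g, [0.01] * 3)
        fe = ivw(h, "fixed")
        re = ivw(h, "random")
        assert fe.beta == pytest.approx(0.5)
        assert re.beta == pytest.approx(0.5)
        assert re.se == pytest.approx(fe.se)  # Q=0 -> floor at 1

    def test_random_effects_inflates_se_under_heterogeneity(self):
        h = hset([0.1, 0.2, 0.3, 0.1], [0.08, 0.02, 0.3, -0.05], [0.01] * 4)
        assert ivw(h, "random").se > ivw(h, "fixed").se

    def test_scale_property(self):
        h1 = hset([0.1, 0.2, 0.3], [0.02, 0.05, 0.04], [0.01] * 3)
        h2 = hset([0.1, 0.2, 0.3], [0.02, 0.05, 0.04], [0.03] * 3)
        e1, e2 = ivw(h1, "fixed"), ivw(h2, "fixed")
        assert e2.beta == pytest.approx(e1.beta)
        assert e2.se == pytest.approx(3 * e1.se)

    def test_zero_gamma_rows_excluded(self):
        h = hset([0.1, 0.0, 0.3], [0.02, 0.05, 0.04], [0.01] * 3)
        assert ivw(h, "fixed").n_snp == 2


class TestEgger:
    def test_exact_affine_fit(self):
        g = np.array([0.1, 0.2, 0.3])
        res = mr_egger(hset(g, 0.01 + 0.3 * g, [0.01] * 3))
        assert res.slope.beta == pytest.approx(0.3, abs=1e-12)
        assert res.intercept == pytest.approx(0.01, abs=1e-12)

    def test_two_snps_rejected(self):
        with pytest.raises(DataError):
            mr_egger(hset([0.1, 0.2], [0.05, 0.06], [0.01] * 2))

    def test_collinear_design_rejected(self):
        with pytest.raises(DataError):
            mr_egger(hset([0.2, 0.2, -0.2], [0.05, 0.06, 0.04], [0.01] * 3))

    def test_nesting_no_intercept_equals_ivw(self, random_harmonized):
        h = random_harmonized(J=12, seed=3)
        res = mr_egger(h, intercept=False)
        assert res.slope.beta == pytest.approx(ivw(h, "fixed").beta, abs=1e-10)

    def test_orientation_invariance(self, random_harmonized):
        """Negating gamma and Gamma of some SNPs leaves the fit unchanged."""
        h = random_harmonized(J=10, seed=4)
        res1 = mr_egger(h)
        tab = h.table.copy()
        flip = np.array([1, -1] * 5, float)
        tab["gamma.exposure"] *= flip
        tab["Gamma"] *= flip
        res2 = mr_egger(HarmonizedSet(["exposure"], tab))
        assert res2.slope.beta == pytest.approx(res1.slope.beta)
        assert res2.intercept == pytest.approx(res1.intercept)


class TestWeightedMedian:
    def test_equal_weights_middle_ratio(self):
        g = np.array([0.1, 0.1, 0.1])
        ratios = np.array([0.2, 0.5, 0.9])
        e = weighted_median(hset(g, ratios * g, [0.01] * 3), n_boot=50, seed=1)
        assert e.beta == pytest.approx(0.5)

    def test_unequal_weights_interpolation(self):
        # weights proportional to (0.6, 0.2, 0.2): cumulative midpoints
        # (0.3, 0.7, 0.9); interpolating 0.5 between 0.2 and 0.5 gives 0.35
        w = np.array([0.6, 0.2, 0.2])
        g = np.sqrt(w)
        ratios = np.array([0.2, 0.5, 0.9])
        e = weighted_median(hset(g, ratios * g, [1.0] * 3), n_boot=50, seed=1)
        assert e.beta == pytest.approx(0.35)

    def test_constant_ratio_recovered(self):
        g = np.array([0.1, 0.2, 0.3])
        e = weighted_median(hset(g, 0.7 * g, [0.01] * 3), n_boot=50, seed=1)
        assert e.beta == pytest.approx(0.7)

    def test_seeded_determinism_and_order_invariance(self, random_harmonized):
        h = random_harmonized(J=9, seed=5)
        e1 = weighted_median(h, n_boot=100, seed=11)
        perm = h.table.sample(frac=1, random_state=2).reset_index(drop=True)
        e2 = weighted_median(HarmonizedSet(["exposure"], perm), n_boot=100, seed=11)
        assert e1.beta == e2.beta
        assert e1.se == e2.se


class TestCochranQ:
    def test_identical_ratios(self):
        g = np.array([0.1, 0.2, 0.3])
        q = cochran_q(hset(g, 0.5 * g, [0.01] * 3))
        assert q.Q == pytest.approx(0.0, abs=1e-20)
        assert q.pvalue == pytest.approx(1.0)
        assert q.df == 2

    def test_discordant_snp_detected(self):
        g = np.full(10, 0.1)
        G = 0.5 * g
        G[0] = 0.5  # wildly discordant ratio
        q = cochran_q(hset(g, G, [0.02] * 10))
        # direct computation oracle
        beta = G @ g / (g @ g)
        v = (g / 0.02) ** 2
        Q_expected = float(np.sum(v * (G / g - beta) ** 2))
        assert q.Q == pytest.approx(Q_expected)
        assert q.pvalue < 0.05


class TestLeaveOneOut:
    def test_identical_ratio_rows_equal_full(self):
        g = np.array([0.1, 0.2, 0.3])
        h = hset(g, 0.5 * g, [0.01] * 3)
        full = ivw(h, "fixed").beta
        for _, est in leave_one_out(h):
            assert est.beta == pytest.approx(full)

    def test_two_snps_each_equals_other_wald(self):
        h = hset([0.1, 0.2], [0.05, 0.12], [0.01, 0.02])
        res = dict(leave_one_out(h))
        assert res["rs000001"].beta == pytest.approx(0.12 / 0.2)
        assert res["rs000002"].beta == pytest.approx(0.05 / 0.1)

    def test_matches_ivw_on_reduced_set(self, random_harmonized):
        h = random_harmonized(J=8, seed=7)
        for vid, est in leave_one_out(h):
            reduced = h.subset([v for v in h.variant_ids if v != vid])
            assert est.beta == pytest.approx(ivw(reduced, "fixed").beta)


class TestPresso:
    def _clean(self, seed=0, J=20):
        rng = np.random.default_rng(seed)
        g = rng.normal(0.1, 0.03, J)
        sg = np.full(J, 1e-4)
        sG = np.full(J, 0.01)
        G = 0.5 * g + rng.normal(0, sG)
        return hset(g, G, sG, sg)

    def test_seeded_determinism(self):
        h = self._clean(1)
        r1 = mr_presso(h, n_sim=200, seed=9)
        r2 = mr_presso(h, n_sim=200, seed=9)
        assert r1.global_rss == r2.global_rss
        assert r1.global_p == r2.global_p
        assert r1.outlier_p == r2.outlier_p

    def test_order_invariance(self):
        h = self._clean(2)
        r1 = mr_presso(h, n_sim=200, seed=9)
        perm = h.table.sample(frac=1, random_state=3).reset_index(drop=True)
        r2 = mr_presso(HarmonizedSet(["exposure"], perm), n_sim=200, seed=9)
        assert r1.global_rss == r2.global_rss
        assert r1.outlier_ids == r2.outlier_ids

    def test_implanted_outliers_flagged_and_corrected(self):
        h = self._clean(3)
        tab = h.table.copy()
        tab.loc[[2, 7], "Gamma"] += 10 * tab.loc[[2, 7], "sigma_Gamma"]
        res = mr_presso(HarmonizedSet(["exposure"], tab), n_sim=500, seed=4)
        assert {"rs000003", "rs000008"} <= set(res.outlier_ids)
        assert res.global_p < 0.05
        assert res.corrected is not None
        assert res.distortion_p is not None
        assert abs(res.corrected.beta - 0.5) < 0.05

    def test_too_few_snps(self):
        with pytest.raises(DataError):
            mr_presso(self._clean(1, J=3), n_sim=200, seed=1)


class TestSummarizeOR:
    def test_firmicutes_style_reconstruction(self):
        beta = np.log(1.68)
        se = se_from_or_p(1.68, 0.003)
        assert se == pytest.approx(0.17481, abs=1e-4)
        o, lo, hi = summarize_or(MREstimate("ivw_fe", beta, se, 0.003, 10))
        assert round(o, 2) == 1.68
        assert round(lo, 2) == 1.19
        assert round(hi, 2) == 2.37

    def test_null_symmetric(self):
        o, lo, hi = summarize_or(MREstimate("ivw_fe", 0.0, 0.1, 1.0, 5))
        assert o == pytest.approx(1.0)
        assert lo * hi == pytest.approx(1.0)

    def test_protective_lower_bound(self):
        beta = np.log(0.6)
        se = se_from_or_p(0.6, 0.010)
        _, lo, _ = summarize_or(MREstimate("ivw_fe", beta, se, 0.010, 10))
        assert round(lo, 2) == 0.41


@pytest.mark.parametrize("estimator", ["ivw_fe", "ivw_re", "egger", "wm"])
def test_sign_equivariance(estimator, random_harmonized):
    """Negating all outcome effects negates beta and preserves se and p.

    (Negating gamma and Gamma *jointly* leaves every ratio-based estimate
    unchanged, so the meaningful equivariance is in the outcome effects.)
    """
    h = random_harmonized(J=10, seed=6)
    tab = h.table.copy()
    tab["Gamma"] *= -1
    hneg = HarmonizedSet(["exposure"], tab)

    def run(hh):
        if estimator == "ivw_fe":
            return ivw(hh, "fixed")
        if estimator == "ivw_re":
            return ivw(hh, "random")
        if estimator == "egger":
            return mr_egger(hh).slope
        return weighted_median(hh, n_boot=100, seed=13)

    e1, e2 = run(h), run(hneg)
    assert e2.beta == pytest.approx(-e1.beta)
    if estimator != "wm":  # the bootstrap draws are not sign-mirrored
        assert e2.se == pytest.approx(e1.se)
        assert e2.pvalue == pytest.approx(e1.pvalue)


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        ratios=st.lists(
            st.floats(-5, 5, allow_nan=False), min_size=3, max_size=20
        ),
        scale=st.floats(0.01, 1.0),
    )
    def test_ivw_and_wm_bounded_by_ratio_extremes(ratios, scale):
        """IVW and the weighted median are convex combinations of per-SNP ratios."""
        g = np.full(len(ratios), 0.1)
        G = 0.1 * np.asarray(ratios)
        sG = np.full(len(ratios), scale)
        h = hset(g, G, sG)
        lo, hi = min(ratios), max(ratios)
        eps = 1e-9 * max(1.0, abs(lo), abs(hi))
        assert lo - eps <= ivw(h, "fixed").beta <= hi + eps
        wm = weighted_median(h, n_boot=10, seed=0)
        assert lo - eps <= wm.beta <= hi + eps

except ImportError:  # pragma: no cover - hypothesis is a test extra
    pass


def test_joint_negation_is_a_no_op(random_harmonized):
    """Flipping every SNP's orientation (gamma and Gamma together) changes nothing."""
    h = random_harmonized(J=10, seed=8)
    tab = h.table.copy()
    tab["gamma.exposure"] *= -1
    tab["Gamma"] *= -1
    hflip = HarmonizedSet(["exposure"], tab)
    assert ivw(hflip, "fixed").beta == pytest.approx(ivw(h, "fixed").beta)
    assert mr_egger(hflip).slope.beta == pytest.approx(mr_egger(h).slope.beta)
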