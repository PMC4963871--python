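"""Design-based estimation: weighted means, Taylor SEs, paired tests."""

import numpy as np
import pytest

from hbi_swap import (
    design_df,
    paired_t,
    survey_mean,
    taylor_se,
    weighted_mean,
    weighted_prevalence,
)


class TestWeightedMean:
    def test_simple_example(self):
        assert weighted_mean([2, 4], [1, 3]) == pytest.approx(3.5)

    def test_equal_weights_reduce_to_arithmetic_mean(self):
        x = [1.0, 2.0, 7.0]
        assert weighted_mean(x, [2.0] * 3) == pytest.approx(np.mean(x))

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        w = rng.uniform(0.1, 5.0, size=50)
        num = 0.0
        den = 0.0
        for xi, wi in zip(x, w):
            num += wi * xi
            den += wi
        assert weighted_mean(x, w) == pytest.approx(num / den, abs=1e-12)

    def test_empty_and_invalid_inputs(self):
        with pytest.raises(ValueError):
            weighted_mean([], [])
        with pytest.raises(ValueError):
            weighted_mean([1.0], [0.0])


class TestTaylorSE:
    def test_hand_computed_two_psu_fixture(self):
        """Self-weighting single-stratum design vs the textbook formula.

        x = (1,2,3,4), w = 1, PSUs (A,A,B,B): linearized scores
        z = (x - 2.5)/4, PSU totals (-0.5, +0.5), variance
        = 2/(2-1) * ((-0.5)^2 + 0.5^2) = 1.0, so SE = 1.0.
        """
        se = taylor_se([1, 2, 3, 4], [1, 1, 1, 1], ["s1"] * 4, ["A", "A", "B", "B"])
        assert se == pytest.approx(1.0, abs=1e-12)

    def test_identical_psu_totals_give_zero_se(self):
        se = taylor_se([3, 5, 3, 5], [1, 1, 1, 1], ["s1"] * 4, ["A", "A", "B", "B"])
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_weight_rescaling_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=40)
        w = rng.uniform(0.5, 2.0, size=40)
        strata = np.repeat([f"s{i}" for i in range(5)], 8)
        psus = np.tile(["A", "A", "A", "A", "B", "B", "B", "B"], 5)
        est1 = survey_mean(x, w, strata, psus)
        est2 = survey_mean(x, 7.3 * w, strata, psus)
        assert est2.estimate == pytest.approx(est1.estimate, abs=1e-12)
        assert est2.se == pytest.approx(est1.se, abs=1e-12)

    def test_all_single_psu_strata_rejected(self):
        with pytest.raises(ValueError, match="collapse"):
            taylor_se([1, 2], [1, 1], ["s1", "s2"], ["A", "A"])

    def test_design_df(self):
        strata = ["s1", "s1", "s2", "s2", "s2"]
        psus = ["A", "B", "A", "B", "C"]
        assert design_df(strata, psus) == 5 - 2


class TestBruteforceOracle:
    def test_small_fixture_matches_direct_arithmetic(self):
        """All estimates on a <=10-person fixture agree with hand arithmetic to 1e-10."""
        x = np.array([2.0, 4.0, 1.0, 5.0, 3.0, 8.0])
        w = np.array([1.0, 2.0, 1.5, 0.5, 2.5, 1.0])
        strata = np.array(["s1", "s1", "s1", "s2", "s2", "s2"])
        psus = np.array(["A", "A", "B", "A", "B", "B"])
        est = survey_mean(x, w, strata, psus)
        mean = (w * x).sum() / w.sum()
        assert abs(est.estimate - mean) < 1e-10
        z = w * (x - mean) / w.sum()
        var = 0.0
        for h in ("s1", "s2"):
            totals = []
            for j in ("A", "B"):
                sel = (strata == h) & (psus == j)
                totals.append(z[sel].sum())
            tbar = np.mean(totals)
            var += 2.0 / 1.0 * sum((t - tbar) ** 2 for t in totals)
        assert abs(est.se - np.sqrt(var)) < 1e-10

    def test_domain_estimate_matches_subset_mean(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        w = np.array([1.0, 1.0, 2.0, 2.0])
        mask = np.array([True, False, True, False])
        est = survey_mean(x, w, domain_mask=mask)
        assert est.estimate == pytest.approx((1.0 + 6.0) / 3.0, abs=1e-12)
        assert est.n_unweighted == 2


class TestPrevalence:
    def test_prevalences_sum_to_100(self):
        rng = np.random.default_rng(0)
        cats = rng.choice(list("abc"), size=60)
        w = rng.uniform(0.5, 2.0, size=60)
        prev = weighted_prevalence(cats, w)
        assert sum(p.estimate for p in prev.values()) == pytest.approx(100.0, abs=1e-9)


class TestPairedT:
    _strata = np.repeat(["s1", "s2", "s3"], 4)
    _psus = np.tile(["A", "A", "B", "B"], 3)

    def test_identical_arms_not_significant(self):
        x = np.arange(12.0)
        res = paired_t(x, x, np.ones(12), self._strata, self._psus)
        assert res.statistic == 0.0
        assert res.p_raw == 1.0
        assert not res.significant

    def test_constant_nonzero_difference_flagged(self):
        x = np.arange(12.0)
        res = paired_t(x + 5.0, x, np.ones(12), self._strata, self._psus)
        assert res.statistic is None
        assert res.flagged

    def test_bonferroni_is_min_one_m_p(self):
        """p_bonf = min(1, m p) against the closed-form t computation."""
        from scipy import stats

        rng = np.random.default_rng(1)
        obs = rng.normal(1.0, 1.0, 12)
        pred = rng.normal(0.0, 1.0, 12)
        w = np.ones(12)
        res_m1 = paired_t(obs, pred, w, self._strata, self._psus, m_comparisons=1)
        res_m8 = paired_t(obs, pred, w, self._strata, self._psus, m_comparisons=8)
        assert res_m1.p_bonferroni == pytest.approx(res_m1.p_raw)
        assert res_m8.p_bonferroni == pytest.approx(min(1.0, 8 * res_m8.p_raw))
        # closed form: weighted mean difference / taylor SE, df = PSUs - strata
        d = obs - pred
        t_expected = weighted_mean(d, w) / taylor_se(d, w, self._strata, self._psus)
        assert res_m1.statistic == pytest.approx(t_expected, abs=1e-12)
        assert res_m1.df == 6 - 3
        assert res_m1.p_raw == pytest.approx(
            2 * stats.t.sf(abs(t_expected), 3), abs=1e-12
        )

    def test_type_i_error_calibrated_under_null(self):
        """With mean-zero paired differences the test rejects at about the 5% level."""
        rng = np.random.default_rng(99)
        n, n_strata, n_psus = 600, 15, 2
        strata = np.arange(n) % n_strata
        psus = (np.arange(n) // n_strata) % n_psus
        reps, rejections = 400, 0
        for _ in range(reps):
            d = rng.normal(0.0, 1.0, n)
            w = rng.lognormal(0.0, 0.4, n)
            res = paired_t(d, np.zeros(n), w, strata, psus)
            rejections += res.significant
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * se
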