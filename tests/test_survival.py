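import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from survscan.survival import (SurvivalSample, bh_fdr, cox_binary_fit,
                               km_estimate, logrank_test)
from conftest import random_survival


def naive_logrank(time, event, group):
    """Independent oracle: explicit risk-set tabulation per event time."""
    time, event, group = map(np.asarray, (time, event, group))
    O = E = V = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        s = ((time == t) & (event == 1) & (group == 1)).sum()
        O += s
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = (O - E) ** 2 / V
    return chi2, stats.chi2.sf(chi2, 1)


class TestSurvivalSample:
    def test_validation(self):
        SurvivalSample(time=1.0, event=1, group=0)
        with pytest.raises(ValueError):
            SurvivalSample(time=-1.0, event=1, group=0)
        with pytest.raises(ValueError):
            SurvivalSample(time=1.0, event=2, group=0)


class TestKaplanMeier:
    def test_hand_worked_product_limit(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(km.at_risk, [3, 2, 1])
        # Greenwood: S_k * sqrt(sum d/(n(n-d))); SE -> 0 when S hits 0
        np.testing.assert_allclose(
            km.greenwood_se[:2],
            [2 / 3 * np.sqrt(1 / 6), 1 / 3 * np.sqrt(1 / 6 + 1 / 2)])
        assert km.greenwood_se[2] == 0.0

    def test_all_censored_gives_flat_curve(self):
        km = km_estimate([1.0, 2.0], [0, 0])
        assert km.times.size == 0
        assert km.survival_at(5.0) == 1.0

    def test_no_censoring_matches_empirical_survivor_function(self, rng):
        t = rng.exponential(5.0, 80)
        km = km_estimate(t, np.ones(80, dtype=int))
        # product-limit telescopes to the empirical survivor fraction;
        # equality holds up to cumprod rounding
        emp = [np.mean(t > tk) for tk in km.times]
        np.testing.assert_allclose(km.survival, emp, rtol=1e-12)

    def test_event_precedes_tied_censoring(self):
        # censored subject at the event time stays in the risk set
        km = km_estimate([1.0, 1.0], [1, 0])
        np.testing.assert_array_equal(km.at_risk, [2])
        np.testing.assert_allclose(km.survival, [0.5])

    def test_survival_non_increasing(self, rng):
        t, e, _ = random_survival(rng, 60, tie_free=False)
        km = km_estimate(t, e)
        assert np.all(np.diff(km.survival) <= 0)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [1, 1, 0, 1, 1, 0]
        g = [0, 0, 0, 1, 1, 1]
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_brute_force_tabulation(self, rng):
        for tie_free in (True, False):
            t, e, g = random_survival(rng, 50, tie_free=tie_free)
            chi2, p = logrank_test(t, e, g)
            chi2_ref, p_ref = naive_logrank(t, e, g)
            assert chi2 == pytest.approx(chi2_ref, rel=1e-12)
            assert p == pytest.approx(p_ref, rel=1e-12)

    def test_separated_groups_hand_tabulation(self):
        # group A events at 1, 2; group B events at 3, 4
        t, e, g = [1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], [0, 0, 1, 1]
        chi2, _ = logrank_test(t, e, g)
        chi2_ref, _ = naive_logrank(t, e, g)
        assert chi2 == pytest.approx(chi2_ref, rel=1e-12)
        assert chi2 > 0

    def test_label_swap_invariance(self, rng):
        t, e, g = random_survival(rng, 40)
        assert logrank_test(t, e, g)[0] == pytest.approx(
            logrank_test(t, e, 1 - g)[0], rel=1e-12)

    def test_degenerate_inputs_are_errors(self):
        with pytest.raises(ValueError, match="both groups"):
            logrank_test([1, 2], [1, 1], [1, 1])
        with pytest.raises(ValueError, match="event"):
            logrank_test([1, 2], [0, 0], [0, 1])


class TestCoxBinaryFit:
    def test_symmetric_experience_gives_unit_hazard_ratio(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [1, 1, 0, 1, 1, 0]
        g = [0, 0, 0, 1, 1, 1]
        fit = cox_binary_fit(t, e, g)
        assert fit.beta == pytest.approx(0.0, abs=1e-12)
        assert fit.hr == pytest.approx(1.0)
        assert fit.converged
        # Wald CI at beta = 0 is symmetric on the log scale
        assert fit.ci_low * fit.ci_high == pytest.approx(1.0, rel=1e-9)

    def test_score_test_equals_logrank_without_ties(self, rng):
        for _ in range(10):
            t, e, g = random_survival(rng, 80)
            if e.sum() == 0 or g.min() == g.max():
                continue
            fit = cox_binary_fit(t, e, g)
            chi2, _ = logrank_test(t, e, g)
            assert fit.score_chi2 == pytest.approx(chi2, rel=1e-8)

    def test_matches_lifelines_with_heavy_ties(self, rng):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd
        t, e, g = random_survival(rng, 120, tie_free=False)
        fit = cox_binary_fit(t, e, g, ties="efron")
        cph = lifelines.CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "g": g}), "t", "e",
            fit_options={"precision": 1e-12})
        assert fit.beta == pytest.approx(cph.params_["g"], abs=1e-7)
        assert fit.se == pytest.approx(cph.standard_errors_["g"], rel=1e-7)

    def test_breslow_and_efron_agree_without_ties(self, rng):
        t, e, g = random_survival(rng, 60)
        fe = cox_binary_fit(t, e, g, ties="efron")
        fb = cox_binary_fit(t, e, g, ties="breslow")
        assert fe.beta == pytest.approx(fb.beta, rel=1e-9)

    def test_monotone_likelihood_is_flagged(self):
        fit = cox_binary_fit([1.0, 5.0], [1, 0], [1, 0])
        assert not fit.converged
        assert abs(fit.beta) >= 14.0

    def test_hazard_ratio_reflects_group_risk(self, cohort_factory):
        c = cohort_factory(seed=7, n=300, hr=3.0, true_cutoff_pct=0.5)
        g = (c.expr > np.median(c.expr)).astype(int)
        fit = cox_binary_fit(c.os_time, c.os_event, g)
        assert fit.hr > 1.5
        assert fit.ci_low <= fit.hr <= fit.ci_high


class TestBHFDR:
    def test_worked_examples(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_p_is_an_error(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(1e-12, 1.0, exclude_min=False), min_size=1,
                    max_size=40))
    def test_dominates_p_and_matches_statsmodels(self, p):
        from statsmodels.stats.multitest import multipletests
        q = bh_fdr(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, ref, rtol=1e-12, atol=1e-15)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(1e-9, 1.0), min_size=2, max_size=20),
           st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, p, rand):
        idx = list(range(len(p)))
        rand.shuffle(idx)
        q = bh_fdr(p)
        q_perm = bh_fdr([p[i] for i in idx])
        np.testing.assert_allclose(q_perm, q[idx], rtol=1e-12)
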