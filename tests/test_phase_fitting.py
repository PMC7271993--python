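"""Censored MLE, BIC ranking and the descriptive statistics."""

import numpy as np
import pytest
from scipy import stats

from trailcycle.phase_fitting import (
    CensoredDurationFitter, CensoredSample, bic_rank, censored_loglik,
    fit_censored, pearson_with_ci, proportion_difference, rank_sum_test,
)


@pytest.fixture(scope="module")
def lognormal_sample():
    rng = np.random.default_rng(100)
    return np.exp(rng.normal(1.96, 0.27, size=5000))


class TestCensoredFit:
    def test_uncensored_mle_recovers_parameters(self, lognormal_sample):
        res = fit_censored(CensoredSample(lognormal_sample), "lognormal")
        assert res.params["mu"] == pytest.approx(1.96, abs=0.02)
        assert res.params["sigma"] == pytest.approx(0.27, abs=0.02)
        assert res.bic == pytest.approx(
            res.n_params * np.log(5000) - 2 * res.loglik)

    def test_uncensored_equals_closed_form_log_mle(self, lognormal_sample):
        # with no censoring the lognormal MLE has a closed form
        res = fit_censored(CensoredSample(lognormal_sample), "lognormal")
        logs = np.log(lognormal_sample)
        assert res.params["mu"] == pytest.approx(logs.mean(), abs=1e-4)
        assert res.params["sigma"] == pytest.approx(logs.std(), abs=1e-4)

    def test_censored_recovery_vs_grid_search_oracle(self, lognormal_sample):
        x = np.minimum(lognormal_sample, 9.5)
        cens = lognormal_sample > 9.5
        assert 0.05 < cens.mean() < 0.25
        sample = CensoredSample(x, cens)
        res = fit_censored(sample, "lognormal")
        assert res.params["mu"] == pytest.approx(1.96, abs=0.03)
        # independent oracle: brute-force grid maximization of the same
        # censored likelihood written from scipy primitives
        mus = np.linspace(1.85, 2.05, 81)
        sigmas = np.linspace(0.2, 0.35, 61)
        best, best_ll = None, -np.inf
        for mu in mus:
            for s in sigmas:
                dist = stats.lognorm(s=s, scale=np.exp(mu))
                ll = dist.logpdf(x[~cens]).sum() + dist.logsf(x[cens]).sum()
                if ll > best_ll:
                    best, best_ll = (mu, s), ll
        assert res.params["mu"] == pytest.approx(best[0], abs=0.005)
        assert res.params["sigma"] == pytest.approx(best[1], abs=0.005)
        assert res.loglik >= best_ll - 1e-6

    def test_censored_fit_matches_lifelines(self, lognormal_sample):
        lifelines = pytest.importorskip("lifelines")
        x = np.minimum(lognormal_sample, 12.0)
        observed = lognormal_sample <= 12.0
        lf = lifelines.LogNormalFitter().fit(x, event_observed=observed)
        res = fit_censored(CensoredSample(x, ~observed), "lognormal")
        assert res.params["mu"] == pytest.approx(lf.mu_, abs=1e-3)
        assert res.params["sigma"] == pytest.approx(lf.sigma_, abs=1e-3)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_censored(CensoredSample(np.full(50, 3.0)), "lognormal")
        with pytest.raises(ValueError):
            fit_censored(CensoredSample(np.array([1.0, 2.0, 3.0]),
                                        np.array([False, True, True])),
                         "lognormal")

    def test_loglik_reduces_to_uncensored(self, lognormal_sample):
        s_all = CensoredSample(lognormal_sample)
        theta = np.array([1.96, np.log(0.27)])
        ll = censored_loglik(theta, s_all, "lognormal")
        ref = stats.lognorm(s=0.27, scale=np.exp(1.96)).logpdf(lognormal_sample).sum()
        assert ll == pytest.approx(ref)


class TestBicRanking:
    def test_lognormal_wins_on_lognormal_data(self):
        rng = np.random.default_rng(101)
        x = np.exp(rng.normal(1.96, 0.27, size=400))
        fits = bic_rank(CensoredSample(x))
        assert fits[0].family == "lognormal"
        by_family = {f.family: f for f in fits}
        assert by_family["normal"].delta_bic > 2.0

    def test_n_params_override_changes_penalty_only(self):
        rng = np.random.default_rng(102)
        x = np.exp(rng.normal(1.96, 0.27, size=400))
        sample = CensoredSample(x)
        default = fit_censored(sample, "gamma")
        wide = fit_censored(sample, "gamma", n_params_override=4)
        assert wide.loglik == pytest.approx(default.loglik)
        assert wide.bic == pytest.approx(default.bic + 2 * np.log(400))

    def test_estimator_interface(self):
        rng = np.random.default_rng(103)
        x = np.exp(rng.normal(2.0, 0.3, size=300))
        fitter = CensoredDurationFitter().fit(x)
        assert fitter.best_.family == "lognormal"
        assert fitter.get_params()["families"] == fitter.families

    def test_bic_scale_invariance_of_ranking(self):
        # scale families: rescaling durations shifts every BIC equally
        rng = np.random.default_rng(104)
        x = np.exp(rng.normal(1.96, 0.27, size=300))
        fams = ("lognormal", "weibull")
        r1 = bic_rank(CensoredSample(x), fams)
        r2 = bic_rank(CensoredSample(x * 60.0), fams)
        assert [f.family for f in r1] == [f.family for f in r2]
        d1 = r1[1].bic - r1[0].bic
        d2 = r2[1].bic - r2[0].bic
        assert d1 == pytest.approx(d2, abs=0.1)


class TestCorrelationsAndTests:
    def test_pearson_perfect_and_null(self, rng):
        x = rng.normal(size=200)
        rho, lo, hi = pearson_with_ci(x, x)
        assert rho == pytest.approx(1.0)
        y = rng.normal(size=200)
        rho, lo, hi = pearson_with_ci(x, y)
        assert lo < 0 < hi

    def test_pearson_phase_vs_cycle_closed_form(self, nci_params, rng):
        # rho(T_g1, T_g1 + T_s) from lognormal moments
        from trailcycle.cycle_model import sample_phase_durations
        tg1, ts = sample_phase_durations(100_000, nci_params, rng)
        rho, _, _ = pearson_with_ci(tg1, tg1 + ts)
        m1, m2 = tg1.mean(), ts.mean()
        s1, s2 = nci_params.sigma_g1, nci_params.sigma_s
        v1 = m1 ** 2 * np.expm1(s1 ** 2)
        v2 = m2 ** 2 * np.expm1(s2 ** 2)
        c = m1 * m2 * np.expm1(nci_params.rho_log * s1 * s2)
        expected = (v1 + c) / np.sqrt(v1 * (v1 + v2 + 2 * c))
        assert rho == pytest.approx(expected, abs=0.01)
        assert expected == pytest.approx(0.85, abs=0.01)

    def test_rank_sum_identity_and_separation(self, rng):
        a = rng.normal(size=100)
        assert rank_sum_test(a, a) >= 0.99
        assert rank_sum_test(a, a + 50.0) < 1e-10
        with pytest.raises(ValueError):
            rank_sum_test(a, [])

    def test_rank_sum_type_one_error_calibration(self):
        rng = np.random.default_rng(105)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            a = np.exp(rng.normal(1.96, 0.27, size=400))
            b = np.exp(rng.normal(1.96, 0.27, size=400))
            rejections += rank_sum_test(a, b) < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_proportion_criteria_equal_and_extreme(self):
        res = proportion_difference(76, 100, 76, 100)
        assert not res["z_test_significant"]
        assert not res["margin_criterion_significant"]
        res = proportion_difference(100, 100, 0, 100)
        assert res["z_test_significant"]
        assert res["margin_criterion_significant"]

    def test_proportion_criteria_can_disagree(self):
        # a 0.76 vs 0.72 contrast at a few hundred cells per group: the
        # margin-of-error criterion (pooled SE over n1+n2) fires while
        # the standard pooled z-test does not
        res = proportion_difference(418, 550, 360, 500)
        pbar = (418 + 360) / 1050
        margin = 1.959963984540054 * np.sqrt(pbar * (1 - pbar) / 1050)
        se = np.sqrt(pbar * (1 - pbar) * (1 / 550 + 1 / 500))
        z = (418 / 550 - 360 / 500) / se
        p_oracle = 2 * stats.norm.sf(abs(z))
        assert res["margin_of_error"] == pytest.approx(margin)
        assert res["z_test_p"] == pytest.approx(p_oracle, abs=1e-9)
        assert res["margin_criterion_significant"]
        assert not res["z_test_significant"]
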