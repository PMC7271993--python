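"""PAD model: closed-form death times, KDE likelihood, sweeps."""

import numpy as np
import pytest
from scipy import stats

from trailcycle.apoptosis_kinetics import (
    ApoptosisParams, PADEstimator, death_time, death_times, draw_cohort_base,
    estimate_pad, kde_density, mean_progression_curve, negll_pad,
    simulate_cohort, synchronization_sweep,
)
from trailcycle.cycle_model import GrowthRates

RATES = GrowthRates.from_durations(7.4, 9.0, 0.45)


def euler_death_times(c0, rates, m, p, pad, variant="release_at_division",
                      dt=1e-4, t_max=40.0):
    """Forward-Euler oracle for the piecewise-linear closed form."""
    c0 = np.atleast_1d(np.asarray(c0, float))
    m = np.broadcast_to(np.asarray(m, float), c0.shape)
    segs = rates.segments()
    c = c0.copy()
    A = np.zeros_like(c)
    td = np.full_like(c, np.inf)
    alive = np.ones(c.shape, bool)
    t = 0.0
    while t < t_max and alive.any():
        rate = np.zeros_like(c)
        for lo, hi, g in segs:
            msk = (c >= lo) & (c < hi)
            rate[msk] = np.broadcast_to(g, c.shape)[msk]
        within = c - np.floor(c)
        gen = np.floor(c)
        decel = (gen == 0) & (within > pad)
        if variant == "extended_second_generation":
            decel |= (gen == 1) & (within > pad)
        slope = np.where(decel, m - p, m)
        A = np.maximum(A + slope * dt, 0.0)
        t += dt
        hit = alive & (A >= 1.0)
        td[hit] = t
        alive &= ~hit
        c = c + rate * dt
    return td


class TestDeathTime:
    def test_no_deceleration_before_pad(self):
        # early-G1 cell reaches A = 1 before crossing pad: t = 1/m
        assert death_times(0.0, RATES, 0.4, 0.2, 0.52)[0] == \
            pytest.approx(2.5)

    def test_zero_coupling_gives_reciprocal_slope(self, rng):
        c0 = rng.random(100)
        td = death_times(c0, RATES, 0.4, 0.0, 0.52)
        assert np.allclose(td, 2.5)

    def test_decelerated_death_before_division(self):
        td = death_times(0.6, RATES, 0.4, 0.2, 0.52)[0]
        assert td == pytest.approx(5.0)

    def test_floor_until_division_release(self):
        # m < p: A pinned at 0 until division, then rises at m
        td = death_times(0.7, RATES, 0.15, 0.2, 0.52)[0]
        t_div = (1.0 - 0.7) / (0.55 / 9.0)
        assert td == pytest.approx(t_div + 1.0 / 0.15, abs=1e-9)

    def test_scalar_wrapper_and_horizon(self):
        params = ApoptosisParams(p=0.2, pad=0.52)
        assert death_time(0.0, RATES, params, 0.4) == pytest.approx(2.5)
        assert death_time(0.7, RATES, params, 0.15, horizon=5.0) is None

    @pytest.mark.parametrize("variant", ["release_at_division",
                                         "extended_second_generation"])
    def test_agrees_with_forward_euler(self, variant):
        rng = np.random.default_rng(80)
        n = 60
        r = GrowthRates.from_durations(rng.uniform(5, 10, n),
                                       rng.uniform(6, 12, n), 0.45,
                                       rng.uniform(5, 10, n),
                                       rng.uniform(6, 12, n))
        c0 = rng.random(n)
        m = 1.0 / np.exp(rng.normal(1.0, 0.39, n))
        closed = death_times(c0, r, m, 0.2, 0.52, variant=variant)
        euler = euler_death_times(c0, r, m, 0.2, 0.52, variant=variant)
        ok = np.isfinite(closed) & np.isfinite(euler)
        assert ok.mean() > 0.9
        assert np.max(np.abs(closed[ok] - euler[ok])) < 1e-3

    def test_monotone_in_p_and_m(self, rng):
        c0 = rng.random(200)
        base = death_times(c0, RATES, 0.4, 0.1, 0.52)
        slower = death_times(c0, RATES, 0.4, 0.3, 0.52)
        faster = death_times(c0, RATES, 0.6, 0.1, 0.52)
        assert np.all(slower >= base - 1e-12)
        assert np.all(faster <= base + 1e-12)

    def test_fast_death_regime_near_mitosis(self):
        # treated just before division: deceleration window is negligible
        c0 = 0.999
        m = 0.4
        td = death_times(c0, RATES, m, 0.3, 0.52)[0]
        t_div = (1.0 - c0) / (0.55 / 9.0)
        assert td == pytest.approx(t_div + 1.0 / m, abs=0.05)


class TestCohorts:
    def test_mean_slope_matches_reciprocal_lognormal(self, nci_params):
        rng = np.random.default_rng(81)
        base = draw_cohort_base(1_000_000, nci_params, rng)
        # closed form: E[1/X] = exp(-mu + sigma^2/2)
        assert base.m.mean() == pytest.approx(np.exp(-1.0 + 0.39 ** 2 / 2),
                                              abs=0.001)
        assert base.m.mean() == pytest.approx(0.4, abs=0.005)

    def test_uncoupled_death_times_are_lognormal(self, nci_params):
        rng = np.random.default_rng(82)
        c0, td, n_alive = simulate_cohort(
            50_000, nci_params, rng, ApoptosisParams(p=0.0, pad=0.52))
        assert n_alive == 0
        ks = stats.kstest(td, stats.lognorm(s=0.39, scale=np.e).cdf)
        assert ks.statistic < 0.01
        assert td.mean() == pytest.approx(2.9, abs=0.05)

    def test_bimodal_deaths_just_below_pad(self, nci_params):
        rng = np.random.default_rng(83)
        c0, td, _ = simulate_cohort(
            20_000, nci_params, rng, ApoptosisParams(p=0.3, pad=0.52),
            c0_scheme="uniform", window=(0.47, 0.52))
        early = (td < 4.0).mean()
        late = (td > 6.0).mean()
        assert early > 0.1 and late > 0.1


@pytest.fixture(scope="module")
def cohort(nci_params):
    rng = np.random.default_rng(84)
    c0, td, _ = simulate_cohort(20_000, nci_params, rng,
                                ApoptosisParams(p=0.2, pad=0.52),
                                horizon=19.25)
    return c0, td


class TestKdeLikelihood:
    def test_matches_scipy_gaussian_kde(self, cohort):
        c0, td = cohort
        rng = np.random.default_rng(85)
        q_c0, q_t = rng.random(200), rng.random(200) * 12 + 0.5
        ours = kde_density(q_c0, q_t, c0, td)
        ref = stats.gaussian_kde(np.vstack([c0, td]), bw_method="silverman")(
            np.vstack([q_c0, q_t]))
        assert np.max(np.abs(ours - ref) / np.maximum(ref, 1e-12)) < 1e-5

    def test_far_outside_point_hits_floor(self, cohort):
        c0, td = cohort
        val = negll_pad(np.array([0.5]), np.array([500.0]), c0, td)
        assert val == pytest.approx(-np.log(1e-9), abs=1e-6)

    def test_permutation_invariance(self, cohort):
        c0, td = cohort
        rng = np.random.default_rng(86)
        qc, qt = c0[:50], td[:50]
        perm = rng.permutation(50)
        assert negll_pad(qc, qt, c0, td) == \
            pytest.approx(negll_pad(qc[perm], qt[perm], c0, td))

    def test_self_consistency_prefers_true_parameters(self, cohort,
                                                      nci_params):
        c0, td = cohort
        rng = np.random.default_rng(87)
        base = draw_cohort_base(30_000, nci_params, rng)
        vals = {}
        for p in (0.0, 0.2, 0.35):
            mtd = death_times(base.c0, base.rates, base.m, p, 0.52,
                              horizon=19.25)
            dead = np.isfinite(mtd)
            vals[p] = negll_pad(c0[:500], td[:500], base.c0[dead], mtd[dead])
        assert vals[0.2] < vals[0.0]
        assert vals[0.2] < vals[0.35]

    def test_degenerate_cohort_rejected(self):
        with pytest.raises(ValueError):
            negll_pad([0.5], [1.0], np.full(100, 0.3), np.linspace(1, 5, 100))


class TestEstimatePad:
    def test_unidentifiable_pad_at_zero_p(self, nci_params):
        rng = np.random.default_rng(88)
        c0, td, _ = simulate_cohort(600, nci_params, rng,
                                    ApoptosisParams(p=0.0, pad=0.5),
                                    horizon=19.25)
        est = estimate_pad(c0, td, nci_params,
                           p_grid=np.array([0.0, 0.1, 0.2]),
                           pad_grid=np.linspace(0.3, 0.9, 7),
                           n_reps=2, cohort_size=8000,
                           rng=np.random.default_rng(89), horizon=19.25)
        assert est.region[0, :].all()   # p = 0 row fully inside the region

    def test_estimator_interface_recovers_coarsely(self, nci_params):
        rng = np.random.default_rng(90)
        c0, td, _ = simulate_cohort(900, nci_params, rng,
                                    ApoptosisParams(p=0.2, pad=0.52),
                                    horizon=19.25)
        est = PADEstimator(phase_params=nci_params,
                           p_grid=np.arange(0.0, 0.41, 0.1),
                           pad_grid=np.arange(0.32, 0.93, 0.1),
                           n_reps=2, cohort_size=10_000, horizon=19.25,
                           random_state=91).fit(np.column_stack([c0, td]))
        assert est.ci_p_[0] <= 0.2 <= est.ci_p_[1]
        assert est.ci_pad_[0] - 0.05 <= 0.52 <= est.ci_pad_[1] + 0.05


class TestSweepAndCurves:
    def test_zero_coupling_equalizes_windows(self, nci_params):
        rng = np.random.default_rng(92)
        sweep = synchronization_sweep(
            [(0.0, 0.1), (0.5, 0.6), (0.9, 1.0)], nci_params, rng,
            params=ApoptosisParams(p=0.0, pad=0.5), n_per_window=4000)
        med = sweep["median_t_death"].to_numpy()
        assert np.ptp(med) < 0.2

    def test_mean_progression_slopes_and_monotonicity(self, nci_params):
        # slow progression so the mean trajectory reaches the
        # deceleration point before A hits 1
        m, p, pad = 0.1, 0.05, 0.52
        t, A = mean_progression_curve(0.1, nci_params, m, p, pad)
        slopes = np.diff(A) / np.diff(t)
        # first segment: native slope; beyond pad: decelerated
        assert slopes[0] == pytest.approx(m)
        assert any(np.isclose(s, m - p) for s in slopes)
        assert np.all(np.diff(A) >= -1e-12)
        assert A[-1] == pytest.approx(1.0)
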