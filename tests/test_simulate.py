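"""Tests of the cohort generator against closed-form and quadrature oracles."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest

from astailor.simulate import (
    ScenarioConfig,
    SubjectLatent,
    assemble_observed,
    covariate_value,
    draw_biopsy_schedule,
    draw_latents,
    draw_subject,
    event_time_transform,
    simulate_cohort,
)


def hazard(config, a0, a1, t):
    """Proportional-hazards intensity implied by the closed-form generator,
    derived independently: lambda(t) = (shape/nu) u^{shape-1}
    exp{beta^T a0 + r(a01+a02)^2 + [beta^T a1 + r(a11+a12)^2] log u},
    u = (t - entry)/nu. Used only as a quadrature oracle."""
    beta = np.asarray(config.beta)
    u = (t - config.entry_offset) / config.nu
    r = config.r_nl
    log_rate = (
        a0[1:] @ beta
        + r * (a0[0] + a0[1]) ** 2
        + (a1[1:] @ beta + r * (a1[0] + a1[1]) ** 2) * np.log(u)
    )
    return config.nu_shape / config.nu * u ** (config.nu_shape - 1) * np.exp(log_rate)


def survival_by_quadrature(config, a0, a1, t):
    integral, _ = quad(
        lambda u: hazard(config, a0, a1, u), config.entry_offset, t, limit=200
    )
    return np.exp(-integral)


class TestEventTimeTransform:
    def test_zero_exponential_gives_entry_time(self, scenario1):
        a0 = np.full(4, 0.3)
        a1 = np.full(4, 0.1)
        T, gamma = event_time_transform(scenario1, a0, a1, 0.0)
        assert T == pytest.approx(12.0)
        assert gamma > 0

    def test_monotone_in_exponential_draw(self, scenario1):
        a0 = np.array([0.1, -0.4, 0.2, 0.5])
        a1 = np.array([0.0, 0.1, -0.1, 0.05])
        draws = np.linspace(0.01, 5.0, 20)
        T, gamma = event_time_transform(scenario1, a0, a1, draws)
        assert gamma > 0
        assert np.all(np.diff(T) > 0)

    @pytest.mark.parametrize(
        "a0,a1",
        [
            (np.zeros(4), np.zeros(4)),
            (np.array([0.5, -0.8, 0.3, 0.9]), np.array([0.1, 0.05, -0.1, 0.02])),
            (np.array([-0.2, 0.6, -0.5, -0.1]), np.array([-0.05, 0.1, 0.0, 0.1])),
        ],
    )
    def test_survival_matches_hazard_quadrature(self, scenario1, a0, a1):
        """10^5 draws at fixed slopes: empirical survival matches numerical
        integration of the implied hazard within 3 Monte-Carlo SE."""
        rng = np.random.default_rng(12)
        n = 100_000
        T, _ = event_time_transform(scenario1, a0, a1, rng.exponential(size=n))
        for t in (24.0, 48.0, 96.0):
            s_hat = (T > t).mean()
            s_true = survival_by_quadrature(scenario1, a0, a1, t)
            se = np.sqrt(s_true * (1 - s_true) / n)
            assert abs(s_hat - s_true) < 3 * max(se, 1e-4)


class TestCovariateValue:
    def test_at_characteristic_time_returns_intercept(self, scenario1):
        lat = SubjectLatent(
            a0=np.array([0.5, 0, 0, 0]), a1=np.array([2.0, 0, 0, 0]),
            T_true=50.0, C=100.0,
        )
        assert covariate_value(scenario1, lat, 0, scenario1.nu) == pytest.approx(0.5)

    def test_zero_slope_is_flat(self, scenario1):
        lat = SubjectLatent(
            a0=np.array([0.7, 0, 0, 0]), a1=np.zeros(4), T_true=50.0, C=100.0
        )
        for t in (5.0, 30.0, 120.0):
            assert covariate_value(scenario1, lat, 0, t) == pytest.approx(0.7)

    def test_nonpositive_time_rejected(self, scenario1):
        lat = SubjectLatent(np.zeros(4), np.zeros(4), 50.0, 100.0)
        with pytest.raises(ValueError):
            covariate_value(scenario1, lat, 0, 0.0)

    def test_measurement_noise_variance(self, scenario1):
        lat = SubjectLatent(np.zeros(4), np.zeros(4), 50.0, 100.0)
        rng = np.random.default_rng(5)
        vals = np.array(
            [covariate_value(scenario1, lat, 1, 40.0, True, rng) for _ in range(100_000)]
        )
        # sample variance of the noise within 3 SE of meas_var
        se = scenario1.meas_var * np.sqrt(2 / len(vals))
        assert abs(vals.var() - scenario1.meas_var) < 3 * se


class TestBiopsySchedule:
    def test_gap_and_start_bounds(self, scenario1):
        rng = np.random.default_rng(0)
        for _ in range(200):
            sched = draw_biopsy_schedule(scenario1, rng)
            assert 12.0 <= sched[0] <= 72.0
            gaps = np.diff(sched)
            assert np.all(gaps >= 24.0) and np.all(gaps <= 72.0)
            # stopping rule: the penultimate time still admitted another biopsy
            assert sched[-2] + 24.0 <= 150.0

    def test_wide_gap_terminates_quickly(self):
        cfg = ScenarioConfig.for_scenario(1, T_gap=80.0)
        rng = np.random.default_rng(1)
        lengths = [len(draw_biopsy_schedule(cfg, rng)) for _ in range(100)]
        assert max(lengths) <= 2

    def test_gap_distribution_uniform(self, scenario1):
        rng = np.random.default_rng(2)
        gaps = np.concatenate(
            [np.diff(draw_biopsy_schedule(scenario1, rng)) for _ in range(10_000)]
        )
        stat = kstest(gaps, "uniform", args=(24.0, 48.0))
        assert stat.pvalue > 0.01


class TestAssembleObserved:
    def _latent(self, T, C):
        return SubjectLatent(a0=np.zeros(4), a1=np.zeros(4), T_true=T, C=C)

    def test_dropout_after_first_positive(self, scenario1):
        rng = np.random.default_rng(0)
        subj = assemble_observed(self._latent(50, 100), [30, 55, 80], scenario1, rng)
        assert list(subj.biopsy_times) == [30, 55]
        assert list(subj.results) == [0, 1]
        assert subj.dropped_out
        assert subj.neg_pos_pair() == (30.0, 55.0)

    def test_censoring_is_terminal(self, scenario1):
        rng = np.random.default_rng(0)
        subj = assemble_observed(self._latent(50, 40), [30, 55, 80], scenario1, rng)
        assert list(subj.biopsy_times) == [30]
        assert list(subj.results) == [0]
        assert not subj.dropped_out

    def test_missed_biopsy_relinks_adjacency(self, scenario1):
        # force the miss at 55 with a rigged uniform stream
        cfg = scenario1.with_(miss_prob=0.5)

        class RiggedRNG:
            def __init__(self):
                self.draws = iter([0.9, 0.1, 0.9])  # keep 30, miss 55, keep 80
                self._normal = np.random.default_rng(0)

            def random(self):
                return next(self.draws)

            def normal(self, loc, scale, size=None):
                return self._normal.normal(loc, scale, size)

        subj = assemble_observed(
            self._latent(50, 1000), [30, 55, 80], cfg, RiggedRNG()
        )
        assert list(subj.biopsy_times) == [30, 80]
        assert list(subj.results) == [0, 1]
        assert subj.neg_pos_pair() == (30.0, 80.0)

    def test_landmark_covariates_attached(self, scenario1):
        rng = np.random.default_rng(0)
        subj = assemble_observed(self._latent(50, 100), [30, 55, 80], scenario1, rng)
        for t in scenario1.landmarks:
            assert t in subj.covariates_at
            assert len(subj.covariates_at[t]) == scenario1.p


class TestCohort:
    def test_same_seed_identical(self, scenario1):
        a = simulate_cohort(50, scenario1, seed=9)
        b = simulate_cohort(50, scenario1, seed=9)
        for sa, sb in zip(a.subjects, b.subjects):
            np.testing.assert_array_equal(sa.biopsy_times, sb.biopsy_times)
            np.testing.assert_array_equal(sa.results, sb.results)
            for t in sa.covariates_at:
                np.testing.assert_array_equal(
                    sa.covariates_at[t], sb.covariates_at[t]
                )
        for la, lb in zip(a.truth, b.truth):
            assert la.T_true == lb.T_true and la.C == lb.C

    def test_invariants_hold_exhaustively(self, cohort500, scenario1):
        for subj, lat in zip(cohort500.subjects, cohort500.truth):
            assert lat.T_true >= scenario1.entry_offset
            assert scenario1.censor_lo <= lat.C <= scenario1.censor_hi
            assert np.all(np.diff(subj.biopsy_times) > 0)
            assert subj.results.sum() <= 1
            if subj.results.sum() == 1:
                assert subj.results[-1] == 1  # positive is last
            for t, r in zip(subj.biopsy_times, subj.results):
                assert t < lat.C
                assert r == (lat.T_true <= t)

    def test_bracketing_pair_without_censoring(self):
        cfg = ScenarioConfig.for_scenario(1, censor_lo=10_000.0, censor_hi=10_001.0)
        cohort = simulate_cohort(300, cfg, seed=11)
        for subj, lat in zip(cohort.subjects, cohort.truth):
            pair = subj.neg_pos_pair()
            if pair is not None:
                lo, hi = pair
                assert lo < lat.T_true <= hi

    def test_event_rate_matches_monte_carlo(self, scenario1):
        cohort = simulate_cohort(2000, scenario1, seed=13)
        T = np.array([lat.T_true for lat in cohort.truth])
        rng = np.random.default_rng(17)
        _, _, T_mc, _ = draw_latents(scenario1, 1_000_000, rng)
        p_hat = (T <= 150).mean()
        p_mc = (T_mc <= 150).mean()
        se = np.sqrt(p_mc * (1 - p_mc) / len(T))
        assert abs(p_hat - p_mc) < 3 * se


def test_draw_subject_roundtrip(scenario1):
    rng = np.random.default_rng(4)
    lat = draw_subject(scenario1, rng)
    assert lat.T_true >= 12.0
    assert 12.0 <= lat.C <= 150.0
    assert lat.a0.shape == (4,) and lat.a1.shape == (4,)


def test_degenerate_config_raises():
    # log-time slopes forced so beta^T a1 is hugely negative -> gamma <= 0
    cfg = ScenarioConfig.for_scenario(
        1, nu_shape=1e-6, slope_mean=(-0.1, 50.0),
        slope_cov=((0.82**2, -0.005), (-0.005, 0.13**2)),
    )
    with pytest.raises(ValueError, match="degenerate"):
        draw_latents(cfg, 10, np.random.default_rng(0))
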