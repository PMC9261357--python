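import math

import numpy as np
import pytest

from wormspan import (
    IntervalDataset,
    LogisticParams,
    curve_summaries,
    fit_logistic_mle,
    km_right_censored,
    npmle_interval,
    rsm_to_intervals,
    run_rsm_trial,
    run_tlm_trial,
    run_trial_set,
    sample_death_times,
    tlm_to_intervals,
)
from wormspan.simulate import ObservationRecord, RSMTrialResult


def _rsm_trial(obs):
    n = obs[0].n_live + obs[0].n_dead
    return RSMTrialResult(
        n_per_plate=n,
        scoring_interval=1.0,
        n_plates_prepared=len(obs),
        observations=list(obs),
        terminated_early=False,
    )


class TestConversions:
    def test_tlm_interval_mode_uses_previous_observation(self, reference):
        trial = run_tlm_trial(30, reference, rng=np.random.default_rng(2))
        data = tlm_to_intervals(trial, mode="interval")
        np.testing.assert_allclose(data.right - data.left, 1.0)
        # a death recorded at day 6 sits in (5, 6]
        if 6.0 in data.right:
            assert data.left[list(data.right).index(6.0)] == 5.0

    def test_tlm_right_mode_gives_exact_events(self, reference):
        trial = run_tlm_trial(30, reference, rng=np.random.default_rng(2))
        data = tlm_to_intervals(trial, mode="right")
        np.testing.assert_array_equal(data.left, data.right)
        assert data.n == 30

    def test_first_observation_death_under_two_day_scoring(self):
        dist = LogisticParams(1.5, 1e-9)  # everyone dies at 1.5 d
        trial = run_tlm_trial(5, dist, interval=2.0, rng=np.random.default_rng(0))
        data = tlm_to_intervals(trial, mode="interval")
        assert data.left.tolist() == [0.0]
        assert data.right.tolist() == [2.0]

    def test_rsm_current_status_intervals(self):
        trial = _rsm_trial([ObservationRecord(time=10.0, n_live=3, n_dead=2)])
        data = rsm_to_intervals(trial)
        rows = {(l, r): w for l, r, w in zip(data.left, data.right, data.weights)}
        assert rows == {(0.0, 10.0): 2.0, (10.0, np.inf): 3.0}

    def test_rsm_two_observation_hand_construction(self):
        trial = _rsm_trial(
            [
                ObservationRecord(time=5.0, n_live=2, n_dead=0),
                ObservationRecord(time=25.0, n_live=0, n_dead=2),
            ]
        )
        data = rsm_to_intervals(trial)
        assert data.n == 4
        assert set(zip(data.left, data.right)) == {(5.0, np.inf), (0.0, 25.0)}


class TestLogisticMLE:
    def test_symmetric_interval_dataset_centres_at_twenty(self):
        # the dataset maps to itself under t -> 40 - t (with interval
        # endpoints swapped), so the location estimate must sit at 20
        data = IntervalDataset.from_records(
            [17.0, 21.0], [19.0, 23.0], [40.0, 40.0]
        )
        fit = fit_logistic_mle(data)
        assert fit.converged
        assert fit.mu_hat == pytest.approx(20.0, abs=1e-4)
        assert fit.median == fit.mean == fit.mu_hat

    def test_parameter_recovery_at_large_n(self, reference, rng):
        x = sample_death_times(10_000, reference, rng)
        t = np.ceil(x)
        data = IntervalDataset.from_records(t - 1.0, t)
        fit = fit_logistic_mle(data)
        assert fit.mu_hat == pytest.approx(20.0, abs=0.1)
        assert fit.s_hat == pytest.approx(2.0, abs=0.1)
        assert fit.q95 == pytest.approx(fit.mu_hat + fit.s_hat * math.log(19.0))

    def test_weight_scaling_leaves_estimates_unchanged(self, reference, rng):
        trial = run_rsm_trial(20, reference, rng=rng)
        data = rsm_to_intervals(trial)
        scaled = IntervalDataset(data.left, data.right, data.weights * 7)
        f1, f2 = fit_logistic_mle(data), fit_logistic_mle(scaled)
        assert f2.mu_hat == pytest.approx(f1.mu_hat, abs=1e-3)
        assert f2.s_hat == pytest.approx(f1.s_hat, abs=1e-3)
        assert f2.loglik == pytest.approx(7 * f1.loglik, rel=1e-6)

    def test_all_alive_data_flagged_non_identifiable(self):
        data = IntervalDataset.from_records([5.0, 10.0], [np.inf, np.inf], [3, 3])
        fit = fit_logistic_mle(data)
        assert not fit.converged
        assert np.isnan(fit.mu_hat)

    def test_exact_event_times_are_refused(self):
        data = IntervalDataset.from_records([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            fit_logistic_mle(data)

    def test_recovery_across_generating_medians(self):
        # across 500 replica-set trials the mean location estimate stays
        # within 0.1 day of the generating median
        for mu in (16.0, 20.0, 24.0):
            trials = run_trial_set(
                "RSM", 500, 7, dist=LogisticParams(mu, 2.0), sample_size=20
            )
            mus = [fit_logistic_mle(rsm_to_intervals(t)).mu_hat for t in trials]
            assert np.mean(mus) == pytest.approx(mu, abs=0.1)


class TestKaplanMeier:
    def test_product_limit_without_censoring_is_empirical(self):
        data = IntervalDataset.from_records([1, 2, 3, 4], [1, 2, 3, 4])
        curve = km_right_censored(data)
        np.testing.assert_allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])
        summ = curve_summaries(curve)
        # median matches the sample median (midpoint at the exact 0.5 tie)
        assert summ.median == np.median([1, 2, 3, 4]) == 2.5
        assert summ.mean == pytest.approx(2.5)

    def test_point_mass(self):
        data = IntervalDataset.from_records([5.0] * 4, [5.0] * 4)
        curve = km_right_censored(data)
        summ = curve_summaries(curve)
        assert summ.median == summ.mean == summ.q95 == 5.0

    def test_censoring_reduces_risk_set(self):
        data = IntervalDataset.from_records([1.0, 2.0, 3.0], [1.0, np.inf, 3.0])
        curve = km_right_censored(data)
        np.testing.assert_allclose(curve.survival, [2 / 3, 0.0])

    def test_current_status_data_refused(self, reference, rng):
        trial = run_rsm_trial(10, reference, rng=rng)
        with pytest.raises(ValueError):
            km_right_censored(rsm_to_intervals(trial))

    def test_no_events_is_an_error(self):
        data = IntervalDataset.from_records([3.0], [np.inf])
        with pytest.raises(ValueError):
            km_right_censored(data)


class TestNPMLE:
    def test_degenerate_intervals_reduce_to_km(self, reference, rng):
        trial = run_tlm_trial(40, reference, rng=rng)
        data = tlm_to_intervals(trial, mode="right")
        km = km_right_censored(data)
        turnbull = npmle_interval(data)
        np.testing.assert_allclose(turnbull.times, km.times)
        np.testing.assert_allclose(turnbull.survival, km.survival, atol=1e-8)

    def test_two_class_closed_form(self):
        data = IntervalDataset.from_records(
            [0.0, 10.0], [10.0, np.inf], [5.0, 5.0]
        )
        curve = npmle_interval(data)
        assert curve.times.tolist() == [5.0]  # midpoint of (0, 10]
        assert curve.survival.tolist() == [0.5]
        assert curve.mass_at_inf == pytest.approx(0.5)

    def test_dominates_parametric_likelihood(self, reference):
        trial = run_tlm_trial(60, reference, rng=np.random.default_rng(8))
        data = tlm_to_intervals(trial, mode="interval")
        turnbull = npmle_interval(data)
        fit = fit_logistic_mle(data)
        assert turnbull.loglik >= fit.loglik - 1e-6


class TestCurveSummaries:
    def test_step_quantiles_and_restricted_mean(self):
        data = IntervalDataset.from_records([1, 2, 3, 4], [1, 2, 3, 4])
        summ = curve_summaries(km_right_censored(data))
        assert summ.mean == pytest.approx(np.mean([1, 2, 3, 4]))
        assert summ.q95 == 4.0

    def test_median_undefined_when_curve_stays_high(self):
        data = IntervalDataset.from_records(
            [1.0, 2.0, 2.0, 2.0], [1.0, np.inf, np.inf, np.inf]
        )
        curve = km_right_censored(data)
        summ = curve_summaries(curve)
        assert np.isnan(summ.median)
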