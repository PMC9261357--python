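import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormspan import (
    NO_ERROR,
    ErrorModel,
    LogisticParams,
    error_probability,
    run_rsm_trial,
    run_tlm_trial,
    run_trial_set,
)


class TestErrorModel:
    def test_constant_rate(self):
        m = ErrorModel(kind="constant", max_p=0.02)
        assert error_probability(5.0, m) == 0.02
        assert error_probability(40.0, m) == 0.02

    def test_late_onset_is_half_max_at_curve_median(self):
        m = ErrorModel(kind="late_onset", max_p=0.04, curve_mu=20.0, curve_s=2.0)
        assert error_probability(20.0, m) == pytest.approx(0.02)

    def test_onset_curves_start_at_zero(self):
        for kind in ("late_onset", "mid_onset"):
            m = ErrorModel(kind=kind, max_p=0.10, curve_mu=20.0, curve_s=2.0)
            assert error_probability(0.0, m) < 1e-4

    def test_mid_onset_is_late_onset_time_scaled(self):
        late = ErrorModel(kind="late_onset", max_p=0.1, curve_mu=20.0, curve_s=2.0)
        mid = ErrorModel(kind="mid_onset", max_p=0.1, curve_mu=20.0, curve_s=2.0)
        for t in (5.0, 10.0, 13.3, 20.0):
            assert error_probability(t, mid) == pytest.approx(
                error_probability(1.5 * t, late)
            )

    @given(t=st.lists(st.floats(0.0, 60.0), min_size=2, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_time_dependent_curves_monotone(self, t):
        ts = np.sort(np.asarray(t))
        for kind in ("late_onset", "mid_onset"):
            m = ErrorModel(kind=kind, max_p=0.1, curve_mu=20.0, curve_s=2.0)
            p = error_probability(ts, m)
            assert np.all(np.diff(p) >= -1e-12)
            assert np.all(p <= 0.1 + 1e-12)

    def test_resolved_fills_curve_from_generator(self):
        m = ErrorModel(kind="mid_onset", max_p=0.02)
        r = m.resolved(LogisticParams(16.0, 1.6))
        assert (r.curve_mu, r.curve_s) == (16.0, 1.6)

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError):
            ErrorModel(kind="sometimes")
        with pytest.raises(ValueError):
            ErrorModel(kind="constant", max_p=1.5)
        with pytest.raises(ValueError):
            ErrorModel(kind="late_onset", effect="both")


class TestTLM:
    def test_single_animal_bookkeeping(self):
        # an animal dying at 5.5 days is seen alive through day 5 and
        # found dead at the day-6 scoring
        dist = LogisticParams(5.5, 1e-9)
        trial = run_tlm_trial(1, dist, rng=np.random.default_rng(0))
        times = [o.time for o in trial.observations]
        assert times == list(np.arange(0.0, 7.0))
        assert [o.n_live for o in trial.observations] == [1] * 6 + [0]
        assert [o.n_dead for o in trial.observations] == [0] * 6 + [1]
        assert trial.recorded_death_times[0] == 6.0

    @pytest.mark.parametrize(
        "error",
        [
            NO_ERROR,
            ErrorModel(kind="constant", max_p=0.1),
            ErrorModel(kind="mid_onset", max_p=0.1),
            ErrorModel(kind="late_onset", effect="hazard", max_p=0.1),
        ],
        ids=["none", "constant", "mid_misscore", "late_hazard"],
    )
    def test_conservation_of_animals(self, error, reference):
        trial = run_tlm_trial(60, reference, error=error, rng=np.random.default_rng(3))
        assert sum(o.n_dead for o in trial.observations) == 60
        assert np.sum(np.isnan(trial.recorded_death_times)) == 0

    def test_no_error_records_ceiling_of_death_time(self, reference, rng):
        for interval in (1.0, 2.0, 3.0):
            trial = run_tlm_trial(40, reference, interval=interval, rng=rng)
            expected = interval * np.ceil(trial.true_death_times / interval)
            expected = np.maximum(expected, 0.0)
            np.testing.assert_allclose(trial.recorded_death_times, expected)

    def test_zero_rate_misscore_bit_identical_to_no_error(self, reference):
        a = run_tlm_trial(50, reference, rng=np.random.default_rng(5))
        b = run_tlm_trial(
            50,
            reference,
            error=ErrorModel(kind="constant", max_p=0.0),
            rng=np.random.default_rng(5),
        )
        np.testing.assert_array_equal(a.recorded_death_times, b.recorded_death_times)
        assert a.observations == b.observations

    def test_hazard_only_shortens_recorded_lifespans(self, reference):
        haz = ErrorModel(kind="mid_onset", effect="hazard", max_p=0.3)
        base = run_tlm_trial(80, reference, rng=np.random.default_rng(9))
        trial = run_tlm_trial(80, reference, error=haz, rng=np.random.default_rng(9))
        # same seed => same death times; handling deaths can only move
        # recorded deaths earlier, never later
        np.testing.assert_array_equal(base.true_death_times, trial.true_death_times)
        assert np.all(trial.recorded_death_times <= base.recorded_death_times + 1e-12)

    def test_extreme_misscore_hits_truncation_cap(self):
        # a short-lived cohort under severe mis-scoring: dead animals are
        # usually called alive, so the plate cannot empty before the
        # 10x-max-lifespan cap cuts the trial off
        dist = LogisticParams(0.5, 1e-9)
        stuck = ErrorModel(kind="constant", max_p=0.6)
        trial = run_tlm_trial(5, dist, error=stuck, rng=np.random.default_rng(1))
        assert trial.truncated
        assert sum(o.n_dead for o in trial.observations) == 5


class TestRSM:
    def test_plates_prepared_covers_horizon_plus_two(self, reference, rng):
        trial = run_rsm_trial(20, reference, rng=rng)
        # 99% mortality of logistic(20,2) is at 29.19 d -> 30 daily plates + 2
        assert trial.n_plates_prepared == 32

    def test_counts_sum_to_plate_size(self, reference, rng):
        err = ErrorModel(kind="constant", max_p=0.05)
        trial = run_rsm_trial(15, reference, error=err, rng=rng)
        for obs in trial.observations:
            assert obs.n_live + obs.n_dead + obs.n_censored == 15

    def test_each_plate_scored_once_at_its_scheduled_time(self, reference, rng):
        trial = run_rsm_trial(10, reference, interval=3.0, rng=rng)
        times = [o.time for o in trial.observations]
        assert times == [3.0 * (k + 1) for k in range(len(times))]
        assert len(times) <= trial.n_plates_prepared

    def test_deterministic_cohort_two_consecutive_dead_rule(self):
        # all animals die at 10.5 d: plates through day 10 are fully
        # alive, days 11 and 12 fully dead, and the trial stops there
        dist = LogisticParams(10.5, 1e-9)
        trial = run_rsm_trial(
            5, dist, rng=np.random.default_rng(0), termination="immediate"
        )
        lives = [o.n_live for o in trial.observations]
        assert lives == [5] * 10 + [0, 0]
        assert trial.observations[-1].time == 12.0
        assert trial.terminated_early

    def test_planned_horizon_scan_ignores_early_all_dead_plates(self, reference):
        # tiny replicates are often all-dead well before the planning
        # horizon by chance; the default rule keeps scoring until the
        # planned end of the experiment (t >= 31 for daily scoring)
        for seed in range(20):
            trial = run_rsm_trial(3, reference, rng=np.random.default_rng(seed))
            assert trial.observations[-1].time >= 31.0
            early_all_dead = any(
                o.n_live == 0 and o.time < 29.0 for o in trial.observations
            )
            if early_all_dead:
                break
        assert early_all_dead, "expected at least one early all-dead plate"


class TestTrialSets:
    def test_same_master_seed_is_bit_identical(self, reference):
        kw = dict(dist=reference, sample_size=12)
        a = run_trial_set("RSM", 4, 123, **kw)
        b = run_trial_set("RSM", 4, 123, **kw)
        for ta, tb in zip(a, b):
            assert ta.observations == tb.observations

    def test_substreams_are_order_independent(self, reference):
        # trial i only depends on child seed i, not on earlier trials
        full = run_tlm_trial(
            20,
            reference,
            rng=np.random.Generator(
                np.random.PCG64(np.random.SeedSequence(99).spawn(3)[2])
            ),
        )
        from_set = run_trial_set("TLM", 3, 99, dist=reference, sample_size=20)[2]
        np.testing.assert_array_equal(
            full.recorded_death_times, from_set.recorded_death_times
        )

    def test_rejects_bad_arguments(self, reference):
        with pytest.raises(ValueError):
            run_trial_set("TLM", 0, 1, dist=reference, sample_size=5)
        with pytest.raises(ValueError):
            run_trial_set("XLM", 2, 1, dist=reference, sample_size=5)
        with pytest.raises(ValueError):
            run_tlm_trial(0, reference)
        with pytest.raises(ValueError):
            run_rsm_trial(0, reference)
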