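"""Unified-model mathematics: closed forms, chaining, fitting."""

import numpy as np
import pytest
from sklearn.base import clone

from sleepacuity import ump
from sleepacuity.errors import FittingError, InputError

from conftest import make_week_timeline


class TestCircadian:
    def test_zero_phase_gives_zero(self, ref_params):
        p = ref_params
        assert ump.circadian(10.0 - p.phi, 10.0, p) == pytest.approx(0.0)

    def test_quarter_period_reaches_amplitude(self, ref_params):
        p = ref_params
        t_w = 8.0
        t = t_w - p.phi + p.tau / 4.0
        assert ump.circadian(t, t_w, p) == pytest.approx(0.97)

    def test_periodicity(self, ref_params):
        p = ref_params
        t = np.linspace(0, 48, 17)
        np.testing.assert_allclose(
            ump.circadian(t, 8.0, p), ump.circadian(t + p.tau, 8.0, p), atol=1e-12
        )


class TestReservoir:
    def test_zero_dt_is_identity(self, ref_params):
        for state in ("wake", "sleep"):
            assert ump.propagate_reservoir(3.7, 0.0, state, ref_params) == pytest.approx(3.7)

    def test_wake_branch_relaxes_to_upper_limit(self, ref_params):
        val = ump.propagate_reservoir(-5.0, 1e5, "wake", ref_params)
        assert val == pytest.approx(ref_params.U, abs=1e-9)

    def test_sleep_branch_fixed_point(self, ref_params):
        lo = -2.0 * ref_params.U
        for dt in (0.1, 5.0, 100.0):
            assert ump.propagate_reservoir(lo, dt, "sleep", ref_params) == pytest.approx(lo)

    def test_negative_dt_rejected(self, ref_params):
        with pytest.raises(InputError):
            ump.propagate_reservoir(0.0, -1.0, "wake", ref_params)


class TestHomeostatic:
    def test_onset_value_is_S0(self, ref_params):
        for state in ("wake", "sleep"):
            assert ump.homeostatic(5.0, 5.0, state, 2.5, 6.0, ref_params) == pytest.approx(2.5)

    def test_wake_limit_is_upper_reservoir(self, ref_params):
        val = ump.homeostatic(500.0, 0.0, "wake", -8.0, 0.0, ref_params)
        assert val == pytest.approx(ref_params.U, abs=1e-9)

    def test_semigroup_oracle(self, ref_params):
        """Chained evaluation through a split equals direct evaluation.

        This is the independent correctness oracle for the closed forms: both
        routes must solve the same ODE, so they agree to machine precision.
        """
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(500):
            S0 = rng.uniform(-25, 25)
            L0 = rng.uniform(-25, 25)
            total = rng.uniform(0.01, 30.0)
            split = rng.uniform(0.0, total)
            for state in ("wake", "sleep"):
                direct = float(ump.homeostatic(total, 0.0, state, S0, L0, ref_params))
                S_mid = float(ump.homeostatic(split, 0.0, state, S0, L0, ref_params))
                L_mid = ump.propagate_reservoir(L0, split, state, ref_params)
                chained = float(ump.homeostatic(total, split, state, S_mid, L_mid, ref_params))
                worst = max(worst, abs(direct - chained))
        assert worst < 1e-9


class TestPredict:
    def test_degenerate_parameters_give_constant(self, week_timeline):
        p = ump.UMPParams(v=55.0, beta=0.0, tau=24.0, phi=0.0, alpha=0.0,
                          S0_init=0.0, U=10.0, L0_init=5.0)
        out = ump.predict(p, week_timeline, np.linspace(1, 150, 40))
        np.testing.assert_allclose(out, 55.0, atol=1e-12)

    def test_pure_sinusoid(self, week_timeline):
        p = ump.UMPParams(v=0.0, beta=1.0, tau=24.0, phi=0.0, alpha=0.0,
                          S0_init=0.0, U=10.0, L0_init=5.0)
        t = np.linspace(0.0, 23.0, 400)  # first wake interval, anchor 0
        out = ump.predict(p, week_timeline, t)
        np.testing.assert_allclose(out, 0.97 * np.sin(2 * np.pi * t / 24.0), atol=1e-12)
        assert np.max(np.abs(out)) <= 0.97 + 1e-12

    def test_homeostatic_term_continuous_at_transitions(self, ref_params, week_timeline):
        """With beta=0 the prediction is continuous across every transition;
        the circadian anchor reset is the only discontinuity source."""
        import dataclasses
        p = dataclasses.replace(ref_params, beta=0.0)
        eps = 1e-7
        for _, start, _ in week_timeline.intervals[1:]:
            before = ump.predict(p, week_timeline, [start - eps])[0]
            after = ump.predict(p, week_timeline, [start + eps])[0]
            assert abs(before - after) < 1e-4  # O(eps) slope difference only

    def test_long_wake_limit(self, ref_params):
        tl = make_week_timeline(n_days=1)
        # extend the final wake interval far beyond tau_w
        state, start, _ = tl.intervals[-1]
        tl.intervals[-1] = (state, start, start + 25 * ref_params.tau_w)
        t = start + 20 * ref_params.tau_w
        expected = (
            ref_params.v
            + ref_params.beta * float(ump.circadian(t, start, ref_params))
            + ref_params.alpha * ref_params.U
        )
        assert ump.predict(ref_params, tl, [t])[0] == pytest.approx(expected, abs=1e-6)

    def test_shift_of_time_origin_is_neutral(self, ref_params, week_timeline):
        """Shifting timeline and query times together leaves scores unchanged
        (the model only sees t - t_w and t - t0)."""
        import copy
        t = np.linspace(9.0, 150.0, 25)
        base = ump.predict(ref_params, week_timeline, t)
        shifted = copy.deepcopy(week_timeline)
        shifted.intervals = [(s, a + 24.0, b + 24.0) for s, a, b in shifted.intervals]
        np.testing.assert_allclose(
            base, ump.predict(ref_params, shifted, t + 24.0), atol=1e-10
        )

    def test_outside_span_rejected(self, ref_params, week_timeline):
        with pytest.raises(InputError):
            ump.predict(ref_params, week_timeline, [1e6])


class TestFitQuality:
    def test_mean_predictor_scores_one(self):
        rng = np.random.default_rng(3)
        obs = rng.normal(50, 8, 40)
        assert ump.fit_quality(obs, np.full(40, obs.mean())) == pytest.approx(1.0)

    def test_worse_than_mean_scores_below_one(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.array([10.0, -10.0, 10.0, -10.0])
        assert ump.fit_quality(obs, pred) < 1.0

    def test_half_sd_rmse_scores_two(self):
        obs = np.array([-1.0, 1.0, -1.0, 1.0])  # population sd 1
        pred = obs - np.array([0.5, -0.5, 0.5, -0.5])  # rmse 0.5
        assert ump.fit_quality(obs, pred) == pytest.approx(2.0)

    def test_short_input_rejected(self):
        with pytest.raises(InputError):
            ump.fit_quality([1.0], [1.0])


class TestFit:
    def test_noiseless_self_consistency(self, ref_params, week_timeline):
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(8.0, 7 * 24.0, 18))
        y = ump.predict(ref_params, week_timeline, t)
        res = ump.fit(np.column_stack([t, y]), week_timeline, seed=1)
        assert res.converged
        assert res.rmse < 1e-6

    def test_noisy_recovery_bounded_by_noise(self, ref_params, week_timeline):
        noise_sd = 5.0
        for seed in (0, 1):
            rng = np.random.default_rng(seed)
            t = np.sort(rng.uniform(8.0, 6 * 24.0, 18))
            y = ump.predict(ref_params, week_timeline, t) + rng.normal(0, noise_sd, 18)
            res = ump.fit(np.column_stack([t, y]), week_timeline, seed=seed)
            assert res.rmse < 1.5 * noise_sd

    def test_underdetermined_rejected(self, week_timeline):
        obs = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(FittingError):
            ump.fit(obs, week_timeline)

    def test_estimator_api(self, ref_params, week_timeline):
        rng = np.random.default_rng(2)
        t = np.sort(rng.uniform(8.0, 7 * 24.0, 20))
        y = ump.predict(ref_params, week_timeline, t) + rng.normal(0, 2.0, 20)
        est = ump.UnifiedPerformanceModel(timeline=week_timeline, random_state=0, n_starts=4)
        cloned = clone(est)  # sklearn contract: params survive cloning
        assert cloned.get_params()["n_starts"] == 4
        cloned.fit(t.reshape(-1, 1), y)
        assert cloned.params_.tau > 0
        assert cloned.fit_quality_ > 1.0
        assert cloned.predict(t[:3].reshape(-1, 1)).shape == (3,)


class TestCrossValidation:
    def test_individual_holds_out_distinct_days(self, ref_params, week_timeline):
        rng = np.random.default_rng(7)
        t = np.sort(np.concatenate([d * 24 + rng.uniform(9, 21, 3) for d in range(7)]))
        y = ump.predict(ref_params, week_timeline, t)
        cv = ump.cross_validate_individual(t, y, week_timeline, n_iter=3, seed=0, n_starts=4)
        days = [it.held_out for it in cv.iterations]
        assert len(days) == 3 and len(set(days)) == 3
        # generalization of an exact model: held-out error is numerically zero
        assert all(it.test_rmse < 1e-5 for it in cv.iterations)

    def test_individual_needs_four_days(self, ref_params, week_timeline):
        t = np.array([1.0, 2.0, 25.0, 26.0, 49.0, 50.0, 52.0, 53.0, 54.0])
        with pytest.raises(InputError):
            ump.cross_validate_individual(t, t, week_timeline)

    def test_group_holds_out_distinct_participants(self, ref_params, week_timeline):
        rng = np.random.default_rng(9)
        datasets = {}
        for pid in ("A", "B", "C"):
            t = np.sort(rng.uniform(8.0, 7 * 24.0, 18))
            y = ump.predict(ref_params, week_timeline, t) + rng.normal(0, 2, 18)
            datasets[pid] = (t, y, week_timeline)
        cv = ump.cross_validate_group(datasets, n_iter=3, seed=0, n_starts=2, max_nfev=100)
        held = [it.held_out for it in cv.iterations]
        assert sorted(held) == ["A", "B", "C"]

    def test_group_needs_three_participants(self, week_timeline):
        with pytest.raises(InputError):
            ump.cross_validate_group({"A": (None, None, None), "B": (None, None, None)})
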