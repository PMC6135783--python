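import numpy as np
import pytest

from audiomotor.hvd import (
    TrialRecording,
    decompose,
    extract_window,
    omse_direct,
    vf_force,
)


class TestTrialRecording:
    def test_rejects_non_finite_and_short_trials(self):
        with pytest.raises(ValueError, match="finite"):
            TrialRecording(np.array([[1.0, np.nan]] * 3), 100.0)
        with pytest.raises(ValueError, match="2 samples"):
            TrialRecording(np.ones((1, 4)), 100.0)

    def test_duration_and_times(self):
        trial = TrialRecording(np.ones((100, 4)), sample_rate=50.0, t0=1.0)
        assert trial.duration == pytest.approx(2.0)
        assert trial.times[0] == pytest.approx(1.0)
        assert trial.times[-1] == pytest.approx(1.0 + 99 / 50.0)


class TestVfForce:
    def test_constant_fingers_sum_to_constant_vf(self):
        trial = TrialRecording(np.full((10, 4), 5.0), 100.0)
        np.testing.assert_allclose(vf_force(trial), 20.0)

    def test_micro_dataset_row_sums(self, micro_trials):
        np.testing.assert_allclose(vf_force(micro_trials[0]), [3.0, 5.0])

    def test_single_finger_is_identity(self):
        forces = np.arange(5.0)[:, None]
        trial = TrialRecording(forces, 100.0)
        np.testing.assert_allclose(vf_force(trial), forces[:, 0])


class TestExtractWindow:
    def test_default_window_keeps_9000_of_20000_samples(self):
        trial = TrialRecording(np.random.default_rng(0).normal(5, 1, (20000, 4)), 1000.0)
        window = extract_window(trial)
        assert window.n_samples == 9000
        assert window.t0 == pytest.approx(6.0)
        np.testing.assert_array_equal(window.forces, trial.forces[6000:15000])

    def test_full_window_is_identity(self):
        trial = TrialRecording(np.random.default_rng(1).normal(5, 1, (200, 4)), 100.0)
        window = extract_window(trial, 0.0, trial.duration)
        np.testing.assert_array_equal(window.forces, trial.forces)

    def test_empty_or_out_of_bounds_window_rejected(self):
        trial = TrialRecording(np.ones((100, 4)), 100.0)
        with pytest.raises(ValueError, match="empty window"):
            extract_window(trial, 0.5, 0.5)
        with pytest.raises(ValueError, match="outside"):
            extract_window(trial, 0.0, 2.0)
        with pytest.raises(ValueError, match="outside"):
            extract_window(trial, -0.5, 1.0)


class TestDecompose:
    def test_micro_dataset_reproduces_hand_computed_components(self, micro_trials):
        res = decompose(micro_trials, f_T=20.0)
        assert res.omse == pytest.approx(226.5, abs=1e-12)
        assert res.se == pytest.approx(225.0, abs=1e-12)
        assert res.ve_off == pytest.approx(1.0, abs=1e-12)
        assert res.ve_on == pytest.approx(0.5, abs=1e-12)
        assert res.var_on == pytest.approx(1.5, abs=1e-12)
        assert res.cov_on == pytest.approx(-1.0, abs=1e-12)
        assert res.var_off == pytest.approx(0.5, abs=1e-12)
        assert res.cov_off == pytest.approx(0.5, abs=1e-12)
        assert res.grand_mean == pytest.approx(5.0)
        assert res.bias == pytest.approx(15.0)
        np.testing.assert_allclose(res.trial_offsets, [-1.0, 1.0])

    def test_omse_against_brute_force_squared_deviations(self, micro_trials):
        # VF samples are 3, 5, 6, 6 against a 20 N target.
        expected = (17**2 + 15**2 + 14**2 + 14**2) / 4
        assert omse_direct(micro_trials, 20.0) == pytest.approx(expected)
        assert decompose(micro_trials, 20.0).omse == pytest.approx(expected)

    def test_constant_trials_at_target_have_zero_error(self):
        trials = [TrialRecording(np.full((20, 4), 5.0), 100.0) for _ in range(3)]
        res = decompose(trials, f_T=20.0)
        for name in ("omse", "ve", "se", "ve_on", "ve_off", "var_on", "cov_on", "var_off", "cov_off"):
            assert getattr(res, name) == pytest.approx(0.0, abs=1e-15)

    def test_silent_finger_contributes_nothing(self, random_trials):
        with_zero = [
            TrialRecording(np.hstack([t.forces, np.zeros((t.n_samples, 1))]), t.sample_rate)
            for t in random_trials
        ]
        a = decompose(random_trials)
        b = decompose(with_zero)
        assert b.var_on == pytest.approx(a.var_on)
        assert b.cov_on == pytest.approx(a.cov_on)
        assert b.var_off == pytest.approx(a.var_off)
        assert b.cov_off == pytest.approx(a.cov_off)

    def test_conservation_identities_on_random_trial_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            trials = [
                TrialRecording(rng.normal(5, rng.uniform(0.1, 2), (40, 4)), 100.0)
                for _ in range(4)
            ]
            res = decompose(trials)
            direct = omse_direct(trials)
            assert abs(res.omse - direct) <= 1e-9 * direct
            assert res.omse == pytest.approx(res.se + res.ve_on + res.ve_off, rel=1e-9)
            assert res.ve_on == pytest.approx(res.var_on + res.cov_on, rel=1e-9, abs=1e-12)
            assert res.ve_off == pytest.approx(res.var_off + res.cov_off, rel=1e-9, abs=1e-12)

    def test_constant_shift_moves_only_bias_terms(self, random_trials):
        shifted = [
            TrialRecording(t.forces + 0.5, t.sample_rate) for t in random_trials
        ]
        a = decompose(random_trials)
        b = decompose(shifted)
        assert b.grand_mean == pytest.approx(a.grand_mean + 2.0)  # 4 fingers x 0.5 N
        assert b.se == pytest.approx((20.0 - a.grand_mean - 2.0) ** 2)
        for name in ("ve", "ve_on", "ve_off", "var_on", "cov_on", "var_off", "cov_off"):
            assert getattr(b, name) == pytest.approx(getattr(a, name), rel=1e-9)

    def test_trial_order_permutation_invariance(self, random_trials):
        a = decompose(random_trials)
        b = decompose(random_trials[::-1])
        for name in ("omse", "ve", "se", "ve_on", "ve_off", "var_on", "cov_on", "var_off", "cov_off"):
            assert getattr(b, name) == pytest.approx(getattr(a, name), rel=1e-12)
        np.testing.assert_allclose(b.trial_offsets, a.trial_offsets[::-1])

    def test_degenerate_inputs_rejected(self, random_trials):
        with pytest.raises(ValueError, match="at least 2 trials"):
            decompose(random_trials[:1])
        mixed = random_trials[:2] + [TrialRecording(np.ones((7, 4)), 100.0)]
        with pytest.raises(ValueError, match="inconsistent"):
            decompose(mixed)
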