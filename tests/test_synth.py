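"""Synthetic session generator: templates, activations, EMG statistics."""

import numpy as np
import pytest
from scipy import stats

from emgkin import SimulationConfig, generate_motion_trial, generate_session
from emgkin.synth import (
    MOTION_TEMPLATES,
    N_DOFS,
    activation_from_kinematics,
    _trial_rng,
    default_crosstalk_matrix,
    synthesize_emg,
)


def _no_jitter_config(**kw) -> SimulationConfig:
    return SimulationConfig(seed=5, amp_jitter_frac=0.0, duration_jitter_frac=0.0, **kw)


class TestMotionTrial:
    def test_zero_jitter_makes_repetitions_identical(self):
        cfg = _no_jitter_config()
        trials = [generate_motion_trial(cfg, r) for r in range(3)]
        for t in trials[1:]:
            np.testing.assert_array_equal(t, trials[0])

    @pytest.mark.parametrize("motion_id", sorted(MOTION_TEMPLATES))
    def test_trial_starts_and_ends_at_initial_posture(self, motion_id):
        cfg = SimulationConfig(seed=9, motion_id=motion_id)
        for rep in (0, 7):
            trial = generate_motion_trial(cfg, rep)
            np.testing.assert_allclose(trial[:, 0], cfg.initial_posture_deg, atol=1e-9)
            np.testing.assert_allclose(trial[:, -1], cfg.initial_posture_deg, atol=1e-9)

    def test_peak_amplitude_matches_closed_form_template_maximum(self):
        # the template maximum is amplitude * jitter factor, reached exactly at
        # the per-DoF peak fraction; reproduce the jitter draw independently
        cfg = SimulationConfig(seed=21, motion_id="M1")
        rep = 4
        rng = _trial_rng(cfg, rep, stream=1)
        amp_factor = 1.0 + cfg.amp_jitter_frac * rng.uniform(-1.0, 1.0, size=N_DOFS)
        trial = generate_motion_trial(cfg, rep)
        tmpl = MOTION_TEMPLATES["M1"]["amplitude"]
        extremum = np.where(np.array(tmpl) >= 0, trial.max(axis=1), trial.min(axis=1))
        np.testing.assert_allclose(extremum, np.array(tmpl) * amp_factor, rtol=1e-6)

    def test_peak_jitter_bounded_by_fifteen_percent(self):
        cfg = SimulationConfig(seed=2, motion_id="M3")
        sfe_peaks = [generate_motion_trial(cfg, r)[1].max() for r in range(15)]
        amp = MOTION_TEMPLATES["M3"]["amplitude"][1]
        assert all(abs(p / amp - 1.0) <= 0.15 for p in sfe_peaks)

    def test_invalid_motion_id_rejected(self):
        with pytest.raises(ValueError, match="motion_id"):
            SimulationConfig(seed=0, motion_id="M9")


class TestActivation:
    def test_resting_at_initial_posture_gives_zero_activation(self):
        cfg = _no_jitter_config()
        angles = np.tile(cfg.initial_posture_deg[:, None], (1, 100))
        act = activation_from_kinematics(angles, cfg)
        np.testing.assert_array_equal(act, np.zeros_like(act))

    def test_linearity_before_rectification(self):
        gains = np.zeros((8, 8))
        gains[0, 1] = 0.01  # one muscle driven by one (positive) angle deviation
        cfg = _no_jitter_config(activation_gain_matrix=gains)
        angles = np.zeros((4, 50))
        angles[1] = np.linspace(0, 40, 50)
        act1 = activation_from_kinematics(angles, cfg)
        act2 = activation_from_kinematics(
            np.vstack([angles[:1], 2 * angles[1:2], angles[2:]]), cfg
        )
        # velocity gain is zero here, so doubling the deviation doubles the drive
        np.testing.assert_allclose(act2[0], 2 * act1[0], atol=1e-12)

    def test_hand_computed_gain_times_deviation(self):
        gains = np.zeros((8, 8))
        gains[2, 0] = 0.02  # 0.02 per degree on SAA
        cfg = _no_jitter_config(activation_gain_matrix=gains)
        angles = np.zeros((4, 10))
        angles[0] = 30.0
        act = activation_from_kinematics(angles, cfg)
        # after the first-sample velocity transient the value is 0.02 * 30
        assert act[2, -1] == pytest.approx(0.6, abs=1e-12)

    def test_wrong_gain_shape_rejected(self):
        with pytest.raises(ValueError, match="activation_gain_matrix"):
            SimulationConfig(seed=0, activation_gain_matrix=np.zeros((8, 5)))


class TestEmgSynthesis:
    def test_zero_activation_yields_baseline_noise_mav(self):
        cfg = _no_jitter_config(baseline_noise_sd=0.2)
        n = 20000
        act = np.zeros((8, n))
        emg = synthesize_emg(act, cfg, np.random.default_rng(7))
        sd = cfg.baseline_noise_sd
        expected_mav = sd * np.sqrt(2 / np.pi)
        se = sd * np.sqrt(1 - 2 / np.pi) / np.sqrt(n)
        mav = np.abs(emg.samples).mean(axis=1)
        assert np.all(np.abs(mav - expected_mav) < 3 * se)

    def test_identity_crosstalk_zero_noise_channel_equals_source(self):
        cfg = _no_jitter_config(crosstalk_matrix=np.eye(8), baseline_noise_sd=0.0)
        act = np.abs(np.random.default_rng(0).normal(1.0, 0.2, size=(8, 5000)))
        emg1 = synthesize_emg(act, cfg, np.random.default_rng(42))
        # doubling activations with the same noise draw doubles each channel
        emg2 = synthesize_emg(2 * act, cfg, np.random.default_rng(42))
        np.testing.assert_allclose(emg2.samples, 2 * emg1.samples, rtol=1e-12)

    def test_amplitude_modulation_doubles_mav_exactly(self):
        cfg = _no_jitter_config(baseline_noise_sd=0.0)
        act = np.ones((8, 4000))
        act[:, :2000] = 0.5
        m1 = np.abs(synthesize_emg(act, cfg, np.random.default_rng(3)).samples).mean()
        m2 = np.abs(synthesize_emg(2 * act, cfg, np.random.default_rng(3)).samples).mean()
        assert m2 == pytest.approx(2 * m1, rel=1e-12)

    def test_active_sources_super_gaussian_rest_gaussian(self, default_pair):
        session = default_pair[0]
        factor = session.config.upsample_factor
        motion_rest = np.ones(session.motion.n_samples, dtype=bool)
        for s, e in session.repetition_intervals:
            motion_rest[s:e] = False
        emg_rest = np.repeat(motion_rest, factor)[: session.emg.n_samples]
        active = session.emg.samples[0, ~emg_rest]
        rest = session.emg.samples[0, emg_rest]
        assert active.size > 1e4 and rest.size > 1e4
        assert stats.kurtosis(active) > 0.5
        assert abs(stats.kurtosis(rest)) < 0.3

    def test_activity_covariance_not_diagonal(self, small_session):
        c = np.cov(small_session.emg.samples)
        off = c - np.diag(np.diag(c))
        assert np.max(np.abs(off)) > 0.05 * np.max(np.diag(c))


class TestSession:
    def test_session_duration_matches_configured_segments(self):
        cfg = _no_jitter_config()
        session = generate_session(cfg, 1)
        rep_n = int(round(cfg.rep_duration_s * 50)) + 1
        rest_n = int(round(cfg.rest_duration_s * 50))
        assert session.motion.n_samples == cfg.n_repetitions * (rep_n + rest_n)
        assert session.motion.duration_s == pytest.approx(
            cfg.n_repetitions * (cfg.rep_duration_s + cfg.rest_duration_s), abs=1.0
        )
        assert session.emg.n_samples == session.motion.n_samples * cfg.upsample_factor
        assert len(session.repetition_intervals) == cfg.n_repetitions

    def test_default_session_approximately_75_seconds(self):
        session = generate_session(SimulationConfig(seed=0), 1)
        assert session.motion.duration_s == pytest.approx(75.0, abs=3.0)

    def test_same_seed_is_bit_identical(self, small_config):
        a = generate_session(small_config, 1)
        b = generate_session(small_config, 1)
        np.testing.assert_array_equal(a.emg.samples, b.emg.samples)
        np.testing.assert_array_equal(a.motion.angles_deg, b.motion.angles_deg)
        assert a.repetition_intervals == b.repetition_intervals

    def test_session2_drift_is_pure_per_channel_gain(self, small_config):
        import dataclasses

        no_drift = dataclasses.replace(
            small_config, inter_session_gain_drift=np.ones(8)
        )
        s2 = generate_session(small_config, 2)
        s2_flat = generate_session(no_drift, 2)
        ratio = s2.emg.samples / s2_flat.emg.samples
        np.testing.assert_allclose(
            ratio, np.tile(small_config.inter_session_gain_drift[:, None], (1, ratio.shape[1])),
            rtol=1e-10,
        )

    def test_rest_intervals_have_zero_ground_truth_activation(self, small_session):
        session = small_session
        factor = session.config.upsample_factor
        # interior of the first rest gap, away from interpolation ramps
        start = (session.repetition_intervals[0][1] + 3) * factor
        end = (session.repetition_intervals[1][0] - 3) * factor
        assert np.all(session.ground_truth_activations[:, start:end] == 0.0)

    def test_crosstalk_dominance_enforced(self):
        bad = default_crosstalk_matrix()
        bad[2, 3] = 2.0
        with pytest.raises(ValueError, match="diagonally dominant"):
            SimulationConfig(seed=0, crosstalk_matrix=bad)

    def test_rate_multiple_enforced(self):
        with pytest.raises(ValueError, match="integer multiple"):
            SimulationConfig(seed=0, emg_rate_hz=999)
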