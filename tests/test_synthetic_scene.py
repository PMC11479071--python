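"""Generator contracts: RR series statistics, scene physics, study tables."""

import numpy as np
import pytest

from pulsebeam import (
    AcquisitionConfig,
    SceneParams,
    StudyParams,
    generate_rr_series,
    generate_study,
    render_cube,
)
from pulsebeam.preprocess import demodulate_phase, phase_compensate
from pulsebeam.synthetic_scene import match_rr


class TestGenerateRRSeries:
    def test_constant_series_when_all_variability_off(self):
        p = SceneParams(seed=0, rr_mean_ms=800.0, rr_sd_ms=0.0, lf_mod=(0.0, 0.1), hf_mod=(0.0, 0.3))
        gt = generate_rr_series(p, 8.0)
        assert np.allclose(gt.rr_true_ms, 800.0)
        assert np.allclose(np.diff(gt.beat_times_s), 0.8)

    def test_pure_lf_modulation_sd_matches_sampled_sinusoid(self):
        # a sampled sinusoid of amplitude a has SD a/sqrt(2)
        p = SceneParams(seed=1, rr_mean_ms=800.0, rr_sd_ms=30.0 / np.sqrt(2),
                        lf_mod=(30.0, 0.10), hf_mod=(0.0, 0.3))
        gt = generate_rr_series(p, 300.0 * 0.8 + 10)  # ~300 beats
        sd = gt.rr_true_ms.std(ddof=1)
        assert sd == pytest.approx(30.0 / np.sqrt(2), rel=0.10)

    def test_total_sd_budget_split_between_modulation_and_noise(self):
        p = SceneParams(seed=2, rr_mean_ms=800.0, rr_sd_ms=37.0, lf_mod=(25.0, 0.1), hf_mod=(30.0, 0.3))
        gt = generate_rr_series(p, 600.0)
        assert gt.rr_true_ms.std(ddof=1) == pytest.approx(37.0, rel=0.15)

    def test_deterministic_under_fixed_seed(self):
        p = SceneParams(seed=123)
        a = generate_rr_series(p, 60.0)
        b = generate_rr_series(p, 60.0)
        assert np.array_equal(a.beat_times_s, b.beat_times_s)

    def test_excess_modulation_rejected(self):
        p = SceneParams(seed=0, rr_sd_ms=5.0, lf_mod=(30.0, 0.1), hf_mod=(0.0, 0.3))
        with pytest.raises(ValueError, match="modulation"):
            generate_rr_series(p, 60.0)

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            generate_rr_series(SceneParams(seed=0, rr_mean_ms=800.0), 1.0)

    def test_movement_bursts_flag_whole_seconds(self):
        p = SceneParams(seed=0, movement_bursts=((10.2, 2.0, 5e-3),))
        gt = generate_rr_series(p, 30.0)
        assert gt.movement_seconds == frozenset({10, 11, 12})


class TestRenderCube:
    def test_frame_count_follows_window(self, short_cfg):
        assert short_cfg.n_frames == 15000
        assert AcquisitionConfig().n_frames == 75000  # 300 s x 250 fps

    def test_noiseless_phase_reconstructs_displacement(self, clean_scene, short_cfg):
        params, truth, cube = clean_scene
        comp = phase_compensate(cube)
        target_bin = cube.nearest_bin(params.target_range_m)
        phase = demodulate_phase(comp.frames[target_bin])
        d_rec = phase * params.carrier_wavelength_m / (4 * np.pi)
        d_rec -= d_rec.mean()
        t = np.arange(short_cfg.n_frames) / short_cfg.fps
        d_true = params.resp_amp_m * np.sin(2 * np.pi * params.resp_freq_hz * t)
        from pulsebeam.synthetic_scene import _heart_displacement
        d_true = d_true + _heart_displacement(t, truth.beat_times_s, params.heart_amp_m,
                                              params.heart_pulse_width_s)
        d_true = d_true - d_true.mean()
        rel_err = np.abs(d_rec - d_true).max() / np.abs(d_true).max()
        assert rel_err < 0.01

    def test_reference_bin_phase_equals_jitter(self, short_cfg):
        params = SceneParams(seed=5, snr_db=None, phase_jitter_sd_rad=0.05)
        truth = generate_rr_series(params, short_cfg.window_s)
        cube = render_cube(truth, params, short_cfg)
        # bin 0 phase must be the jitter walk up to a constant
        ph = np.unwrap(np.angle(cube.frames[0]))
        ref = render_cube(truth, SceneParams(seed=5, snr_db=None, phase_jitter_sd_rad=0.0),
                          short_cfg)
        ph0 = np.unwrap(np.angle(ref.frames[0]))
        jitter = ph - ph0
        assert np.abs(jitter - jitter[0]).max() > 0.5  # jitter is actually present
        assert np.allclose(np.abs(cube.frames[0]), params.direct_path_amp)

    def test_heartbeat_pulse_maxima_align_with_beat_times(self, clean_scene, short_cfg):
        params, truth, _ = clean_scene
        t = np.arange(short_cfg.n_frames) / short_cfg.fps
        from pulsebeam.synthetic_scene import _heart_displacement
        d = _heart_displacement(t, truth.beat_times_s, params.heart_amp_m, params.heart_pulse_width_s)
        for b in truth.beat_times_s[5:10]:
            k = int(round(b * short_cfg.fps))
            window = d[k - 10 : k + 11]
            assert np.argmax(window) == pytest.approx(10, abs=1)  # within one frame

    def test_target_outside_window_rejected(self, short_cfg):
        params = SceneParams(seed=0, target_range_m=2.0)
        truth = generate_rr_series(SceneParams(seed=0), short_cfg.window_s)
        with pytest.raises(ValueError, match="target_range"):
            render_cube(truth, params, short_cfg)

    def test_render_is_pure_function_of_params(self, short_cfg):
        params = SceneParams(seed=9)
        truth = generate_rr_series(params, short_cfg.window_s)
        a = render_cube(truth, params, short_cfg)
        b = render_cube(truth, params, short_cfg)
        assert np.array_equal(a.frames, b.frames)


class TestMatchRR:
    def test_identical_sequences_match_fully(self):
        beats = np.arange(0.0, 30.0, 0.8)
        est, true = match_rr(beats, beats)
        assert np.array_equal(est, true)
        assert len(est) == len(beats) - 1

    def test_missed_beat_pairs_are_dropped(self):
        true = np.arange(0.0, 30.0, 0.8)
        est = np.delete(true, 10)
        rr_est, rr_true = match_rr(est, true)
        # the merged interval spanning the missed beat is not paired
        assert len(rr_est) == len(est) - 2
        assert np.allclose(rr_est, rr_true)


class TestGenerateStudy:
    def test_group_counts_and_total(self):
        df = generate_study(StudyParams(seed=0, group_counts={"control3": 90, "high": 12}))
        assert len(df) == 102
        assert (df["group"] == "high").sum() == 12

    def test_zero_method_noise_gives_identical_methods(self):
        p = StudyParams(seed=1, method_bias=(0, 0, 0, 0), method_sd=(0, 0, 0, 0))
        df = generate_study(p)
        for name in ("mean_rr_ms", "sdnn_ms", "rmssd_ms", "lf_hf"):
            assert np.allclose(df[f"radar_{name}"], df[f"ref_{name}"])

    def test_deterministic_under_fixed_seed(self):
        a = generate_study(StudyParams(seed=3))
        b = generate_study(StudyParams(seed=3))
        assert a.equals(b)

    def test_vas_scores_respect_group_bins(self):
        df = generate_study(StudyParams(seed=4))
        high = df[df["group"] == "high"]["vas"]
        ctrl1 = df[df["group"] == "control1"]["vas"]
        assert (high >= 7.5).all()
        assert (ctrl1 < 2.5).all()
        assert np.allclose(df["vas"] * 2, np.round(df["vas"] * 2))  # 0.5 resolution

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            StudyParams(seed=0, method_sd=(-1.0, 0, 0, 0))


def test_heart_amp_must_stay_below_resp_amp():
    with pytest.raises(ValueError, match="resp_amp"):
        SceneParams(heart_amp_m=5e-3, resp_amp_m=4e-3)
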