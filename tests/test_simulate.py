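import numpy as np
import pytest

import respiradar as rr
from respiradar.pattern import detect_breath_extrema, evaluate_csr_pattern
from respiradar.preprocess import preprocess_matrix
from respiradar.simulate import PatternParams, SubjectScript, csr_envelope


class TestWaveforms:
    def test_length_is_duration_times_rate(self):
        w = rr.gen_respiratory_waveform(PatternParams("eupnea"), 15.0, 17.0)
        assert w.size == 255

    def test_eupnea_15bpm_has_3_to_4_prominent_peaks(self):
        p = PatternParams("eupnea", rate_bpm=15, noise_sd=0.02, seed=1)
        w = rr.gen_respiratory_waveform(p, 15.0, 17.0)
        peaks, _, _ = detect_breath_extrema(w)
        assert 3 <= peaks.size <= 4  # one breath per 4 s

    def test_eupnea_dominant_frequency_within_one_dft_bin(self):
        for rate_bpm in (10, 15, 20):
            p = PatternParams("eupnea", rate_bpm=rate_bpm, noise_sd=0.0, seed=2)
            w = rr.gen_respiratory_waveform(p, 15.0, 17.0)
            freqs = np.fft.rfftfreq(w.size, 1 / 17.0)
            peak = freqs[np.argmax(np.abs(np.fft.rfft(w - w.mean())))]
            assert abs(peak - rate_bpm / 60.0) <= freqs[1]

    def test_zero_amplitude_apnea_fails_signal_quality(self):
        # flat + noise: irregular sub-breath wiggles must not pass the SQI
        p = PatternParams("apnea", amplitude=0.0, noise_sd=0.02, seed=3)
        w = rr.gen_respiratory_waveform(p, 15.0, 17.0)
        assert not rr.evaluate_signal_quality(rr.RespChunk(w)).passed
        # strictly flat: zero-range normalisation path, zero breaths
        flat = rr.RespChunk(np.zeros(255))
        q = rr.evaluate_signal_quality(flat)
        assert q.n_valid_breaths == 0 and not q.passed

    def test_csr_phase_chunks_show_monotone_amplitude(self):
        p = PatternParams(
            "csr", rate_bpm=20, csr_period_s=40, apnea_fraction=0.3, seed=4
        )
        w = rr.gen_respiratory_waveform(p, 40.0, 17.0)
        active = 0.7 * 40.0  # 28 s; envelope peak at 14 s
        crescendo = rr.RespChunk(w[: int(13 * 17)])
        decrescendo = rr.RespChunk(w[int(15 * 17) : int(28 * 17)])
        assert evaluate_csr_pattern(crescendo)
        assert evaluate_csr_pattern(decrescendo)

    def test_csr_envelope_zero_during_apnea_gap(self):
        t = np.linspace(0, 40, 800)
        env = csr_envelope(t, 40.0, 0.3)
        assert np.all(env[(t % 40) > 28.5] == 0.0)

    def test_kussmaul_is_deeper_and_faster_than_eupnea(self):
        eup = rr.gen_respiratory_waveform(
            PatternParams("eupnea", rate_bpm=15, amplitude=1.0, seed=5), 15.0, 17.0
        )
        kus = rr.gen_respiratory_waveform(
            PatternParams("kussmaul", rate_bpm=30, amplitude=2.5, seed=5), 15.0, 17.0
        )
        assert np.ptp(kus) > np.ptp(eup)
        n_eup, _, _ = detect_breath_extrema(eup)
        n_kus, _, _ = detect_breath_extrema(kus)
        assert n_kus.size > n_eup.size

    def test_unknown_pattern_rejected(self):
        with pytest.raises(ValueError, match="unknown pattern"):
            PatternParams("sighing")

    def test_determinism(self):
        p = PatternParams("nonstationary", seed=9)
        a = rr.gen_respiratory_waveform(p, 15.0, 17.0)
        b = rr.gen_respiratory_waveform(p, 15.0, 17.0)
        np.testing.assert_array_equal(a, b)


class TestRadarMatrix:
    def test_shape_and_determinism(self, scene):
        script = SubjectScript.stationary(
            1, [0, 0.5, 2.0], [0, 0, -1], PatternParams("eupnea"), 10.0
        )
        a = rr.gen_radar_matrix(scene, 1, [script], 10.0, seed=7)
        b = rr.gen_radar_matrix(scene, 1, [script], 10.0, seed=7)
        assert a.values.shape == (170, 180)
        np.testing.assert_array_equal(a.values, b.values)

    def test_variance_maximal_at_chest_bin(self, scene):
        script = SubjectScript.stationary(
            1, [0, 0.5, 2.09], [0, 0, -1], PatternParams("eupnea", rate_bpm=15), 15.0
        )
        m = rr.gen_radar_matrix(scene, 1, [script], 15.0, seed=8)
        cleaned = preprocess_matrix(m)
        variances = cleaned.values[:, 37:44].var(axis=0)
        assert 37 + int(np.argmax(variances)) == 40

    def test_empty_scene_is_rank_one_up_to_noise(self, scene):
        m = rr.gen_radar_matrix(scene, 1, [], 15.0, noise_sd=0.0, seed=9)
        out = rr.svd_clutter_removal(m, 1)
        assert np.linalg.norm(out.values) < 0.05 * np.linalg.norm(m.values)

    def test_subject_facing_away_leaves_chest_bin_at_noise_floor(self, scene):
        # facing +z, radar 1 behind at -z: orientation gain clips to zero
        script = SubjectScript.stationary(
            1, [0, 0.5, 2.0], [0, 0, 1], PatternParams("eupnea", rate_bpm=15), 15.0
        )
        m = rr.gen_radar_matrix(scene, 1, [script], 15.0, noise_sd=0.05, seed=10)
        cleaned = preprocess_matrix(m)
        chest_bin = round(2.0 / scene.range_res_m)
        far_bins = cleaned.values[:, 100:150]
        assert cleaned.values[:, chest_bin].var() < 5 * far_bins.var(axis=0).mean()

    def test_out_of_range_subject_contributes_nothing(self, scene):
        near = SubjectScript.stationary(
            1, [0, 0.5, 2.0], [0, 0, -1], PatternParams("eupnea"), 15.0
        )
        far = SubjectScript.stationary(
            2, [0, 0.5, 12.0], [0, 0, -1], PatternParams("kussmaul"), 15.0
        )
        with_far = rr.gen_radar_matrix(scene, 1, [near, far], 15.0, seed=11)
        without = rr.gen_radar_matrix(scene, 1, [near], 15.0, seed=11)
        np.testing.assert_array_equal(with_far.values, without.values)


class TestSkeletonStream:
    def test_noise_free_round_trip_recovers_ground_truth(self, scene):
        script = SubjectScript.stationary(
            3, [0.5, 0.4, 2.5], [0, 0, -1], PatternParams("eupnea"), 10.0
        )
        stream = rr.gen_skeleton_stream(scene, [script], 10.0, noise_sd_m=0.0)
        assert len(stream) == 10
        for s in stream:
            assert s.frame == "rotated"
            recovered = rr.rotate_to_reference(s.chest, scene.rotation_angle_deg)
            np.testing.assert_allclose(recovered, script.chest_at(s.t), atol=1e-9)

    def test_stationary_script_detected_stationary(self, scene):
        script = SubjectScript.stationary(
            1, [0.5, 0.4, 2.5], [0, 0, -1], PatternParams("eupnea"), 15.0
        )
        stream = rr.gen_skeleton_stream(scene, [script], 15.0, noise_sd_m=0.0)
        mids = [
            (
                s.t,
                rr.shoulder_midpoint(
                    rr.rotate_to_reference(s.l_shoulder, scene.rotation_angle_deg),
                    rr.rotate_to_reference(s.r_shoulder, scene.rotation_angle_deg),
                ),
            )
            for s in stream
        ]
        assert rr.detect_motion(mids, threshold_mps=0.7) == "stationary"

    def test_walking_script_detected_moving(self, scene):
        script = SubjectScript.walking(1, [-2, 0.5, 2], [2, 0.5, 3], speed_mps=1.2)
        stream = rr.gen_skeleton_stream(scene, [script], 3.0, noise_sd_m=0.0)
        mids = [
            (
                s.t,
                rr.shoulder_midpoint(
                    rr.rotate_to_reference(s.l_shoulder, scene.rotation_angle_deg),
                    rr.rotate_to_reference(s.r_shoulder, scene.rotation_angle_deg),
                ),
            )
            for s in stream
        ]
        assert rr.detect_motion(mids, threshold_mps=0.7) == "moving"

    def test_shoulder_separation_constant(self, scene):
        script = SubjectScript.walking(1, [-2, 0.5, 2], [2, 0.5, 2], speed_mps=1.0)
        for t in (0.0, 1.0, 2.5):
            l, r = script.shoulders_at(t)
            assert np.linalg.norm(l - r) == pytest.approx(script.shoulder_width)


class TestTrainingDatabase:
    def test_balanced_counts_and_chunk_length(self):
        chunks, labels = rr.gen_training_database(n_per_class=1, seed=0)
        assert len(chunks) == 5 and all(len(c) == 255 for c in chunks)
        chunks, labels = rr.gen_training_database(n_per_class=4, seed=0)
        assert len(chunks) == 20
        for pattern in set(labels):
            assert labels.count(pattern) == 4

    def test_default_database_size_is_250(self):
        chunks, labels = rr.gen_training_database(seed=1)
        assert len(chunks) == 250
        assert all(labels.count(p) == 50 for p in set(labels))

    def test_same_seed_identical_chunks(self):
        a, la = rr.gen_training_database(n_per_class=2, seed=5)
        b, lb = rr.gen_training_database(n_per_class=2, seed=5)
        assert la == lb
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.samples, cb.samples)
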