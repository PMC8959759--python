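import numpy as np
import pytest

import respiradar as rr
from respiradar.simulate import PatternParams, SubjectScript
from respiradar.stream import WindowResult, process_window, sliding_windows


class TestSlidingWindows:
    def test_second_window_is_3_to_18(self):
        wins = sliding_windows(18.0)
        assert wins == [(0.0, 15.0), (3.0, 18.0)]

    def test_single_window_stream(self):
        assert sliding_windows(15.0) == [(0.0, 15.0)]

    def test_three_windows_in_21_s(self):
        assert len(sliding_windows(21.0)) == 3

    def test_short_stream_empty(self):
        assert sliding_windows(10.0) == []

    def test_window_count_formula_for_60s(self):
        wins = sliding_windows(60.0)
        assert len(wins) == (60 - 15) // 3 + 1  # 16

    def test_consecutive_windows_share_overlap(self):
        for a, b in zip(sliding_windows(60.0)[:-1], sliding_windows(60.0)[1:]):
            assert a[1] - b[0] == pytest.approx(12.0)
            # 12 s at 17 Hz -> 204 shared samples
            assert round((a[1] - b[0]) * 17) == 204

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            sliding_windows(30.0, window_s=10.0, overlap_s=12.0)


def make_session(scene, scripts, duration, tmp_path, seed=0):
    """Write a full simulated session directory and return its path."""
    outdir = tmp_path / "session"
    outdir.mkdir(exist_ok=True)
    scene.save(outdir / "scene.yaml")
    from respiradar import io as rio

    for i, radar in enumerate(scene.radars):
        m = rr.gen_radar_matrix(scene, radar.id, scripts, duration, seed=seed + i)
        rio.write_radar_csv(m, outdir / rio.radar_csv_name(radar.id))
    skel = rr.gen_skeleton_stream(scene, scripts, duration, seed=seed + 100)
    rio.write_skeleton_csv(skel, outdir / "skeleton.csv")
    return outdir


class TestProcessWindow:
    def test_stationary_eupnea_subject_full_result(self, scene, trained_classifier):
        script = SubjectScript.stationary(
            1,
            [0.0, 0.5, 2.0],
            [0, 0, -1],
            PatternParams("eupnea", rate_bpm=15, seed=3),
            15.0,
        )
        matrices = {
            r.id: rr.gen_radar_matrix(scene, r.id, [script], 15.0, seed=50 + r.id)
            for r in scene.radars
        }
        skel = rr.gen_skeleton_stream(scene, [script], 15.0)
        (res,) = process_window(scene, matrices, skel, trained_classifier)
        assert res.status == "stationary"
        assert res.assignment.radar_id == 1
        assert res.label.label == "eupnea"
        assert res.rr_bpm == pytest.approx(15.0, abs=0.5)

    def test_walking_subject_status_only(self, scene, trained_classifier):
        # pacing back and forth through the whole window at ~0.8 m/s
        script = SubjectScript(
            subject_id=1,
            waypoints=[
                (0.0, np.array([-2.0, 0.5, 2.0])),
                (5.0, np.array([2.0, 0.5, 2.5])),
                (10.0, np.array([-2.0, 0.5, 2.0])),
                (15.0, np.array([2.0, 0.5, 2.5])),
            ],
            facing=[0, 0, -1],
            pattern_schedule=[],
        )
        matrices = {
            r.id: rr.gen_radar_matrix(scene, r.id, [script], 15.0, seed=60 + r.id)
            for r in scene.radars
        }
        skel = rr.gen_skeleton_stream(scene, [script], 15.0)
        (res,) = process_window(scene, matrices, skel, trained_classifier)
        assert res.status == "moving"
        assert res.label is None and res.rr_bpm is None

    def test_csr_subject_gets_label_but_no_rr(self, scene, trained_classifier):
        params = PatternParams(
            "csr", rate_bpm=22, csr_period_s=40, apnea_fraction=0.3, amplitude=1.5, seed=4
        )
        # full CSR cycle is 40 s; the first 15-s window sits in the crescendo
        script = SubjectScript.stationary(1, [0.0, 0.5, 2.0], [0, 0, -1], params, 40.0)
        matrices = {
            r.id: rr.gen_radar_matrix(
                scene, r.id, [script], 40.0, seed=70 + r.id
            ).slice_time(1.0, 16.0)
            for r in scene.radars
        }
        skel = [s for s in rr.gen_skeleton_stream(scene, [script], 40.0) if 1 <= s.t < 16]
        (res,) = process_window(
            scene, matrices, skel, trained_classifier, window=(1.0, 16.0)
        )
        assert res.status == "stationary"
        assert res.label.label == "csr"
        assert res.rr_bpm is None

    def test_missing_radar_matrix_yields_uncovered(self, scene, trained_classifier):
        script = SubjectScript.stationary(
            1, [0.0, 0.5, 2.0], [0, 0, -1], PatternParams("eupnea", seed=5), 15.0
        )
        skel = rr.gen_skeleton_stream(scene, [script], 15.0)
        (res,) = process_window(scene, {}, skel, trained_classifier)
        assert res.status == "stationary"
        assert res.assignment.radar_id is None
        assert res.assignment.reason == "uncovered"

    def test_rr_gate_enforced_by_container(self):
        with pytest.raises(ValueError, match="eupnea"):
            WindowResult(
                window_index=0,
                t_start=0.0,
                t_end=15.0,
                subject_id=1,
                status="moving",
                rr_bpm=15.0,
            )


class TestRunPipeline:
    def test_two_subject_60s_scene(self, scene, tmp_path):
        scripts = [
            SubjectScript.stationary(
                1,
                [-0.8, 0.5, 2.0],
                [0.4, 0, -1],  # squarely facing radar 1
                PatternParams("eupnea", rate_bpm=16, seed=1),
                60.0,
            ),
            SubjectScript.stationary(
                2,
                [0.9, 0.5, 3.2],
                [-0.27, 0, -0.96],  # also facing radar 1, 1.2 m farther
                PatternParams("eupnea", rate_bpm=18, seed=2),
                60.0,
            ),
        ]
        session = make_session(scene, scripts, 60.0, tmp_path)
        log = tmp_path / "log.csv"
        results = rr.run_pipeline(
            session / "scene.yaml", session, output_path=log, seed=0
        )
        # 16 windows x 2 subjects
        assert len(results) == 32
        assert log.exists()
        # most windows of both stationary eupnea subjects carry an RR
        for sid, rate in ((1, 16.0), (2, 18.0)):
            rrs = [r.rr_bpm for r in results if r.subject_id == sid and r.rr_bpm]
            assert len(rrs) >= 10
            assert abs(np.median(rrs) - rate) < 0.7

    def test_rerun_identical_log(self, scene, tmp_path):
        scripts = [
            SubjectScript.stationary(
                1, [0.0, 0.5, 2.0], [0, 0, -1], PatternParams("eupnea", seed=3), 21.0
            )
        ]
        session = make_session(scene, scripts, 21.0, tmp_path)
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        rr.run_pipeline(session / "scene.yaml", session, output_path=a, seed=0)
        rr.run_pipeline(session / "scene.yaml", session, output_path=b, seed=0)
        assert a.read_bytes() == b.read_bytes()

    def test_empty_input_dir_rejected(self, scene, tmp_path):
        empty = tmp_path / "empty"
        empty.mkdir()
        cfg = tmp_path / "scene.yaml"
        scene.save(cfg)
        with pytest.raises(FileNotFoundError):
            rr.run_pipeline(cfg, empty)

    def test_experiment5_style_fallback(self, scene, tmp_path, trained_classifier):
        """Two subjects nearly equidistant from their preferred radar: the
        30-cm rule must reassign one of them."""
        # both ~2 m from radar 1 (difference ~5 cm), subject 2 also covered
        # by radar 2 on the side wall
        scripts = [
            SubjectScript.stationary(
                1,
                [-0.35, 0.5, 1.97],
                [0.17, 0, -1],
                PatternParams("eupnea", rate_bpm=14, seed=6),
                15.0,
            ),
            SubjectScript.stationary(
                2,
                [0.35, 0.5, 1.99],
                [-0.17, 0, -1],
                PatternParams("eupnea", rate_bpm=19, seed=7),
                15.0,
            ),
        ]
        d1 = rr.distance_to_radar([-0.35, 0.5, 1.97], scene.radar(1).position)
        d2 = rr.distance_to_radar([0.35, 0.5, 1.99], scene.radar(1).position)
        assert abs(d1 - d2) < 0.3  # genuinely conflicting geometry on radar 1
        matrices = {
            r.id: rr.gen_radar_matrix(scene, r.id, scripts, 15.0, seed=80 + r.id)
            for r in scene.radars
        }
        skel = rr.gen_skeleton_stream(scene, scripts, 15.0)
        results = process_window(scene, matrices, skel, trained_classifier)
        by_sid = {r.subject_id: r for r in results}
        r1, r2 = by_sid[1].assignment, by_sid[2].assignment
        assert r1.radar_id is not None and r2.radar_id is not None
        if r1.radar_id == r2.radar_id:
            assert abs(r1.chest_distance_m - r2.chest_distance_m) >= 0.3
        assert "fallback_separation" in (r1.reason, r2.reason)
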