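import numpy as np
import pytest

import respiradar as rr


@pytest.fixture(scope="session")
def scene():
    return rr.default_scene()


@pytest.fixture(scope="session")
def trained_classifier():
    """Classifier trained once on the standard 250-chunk synthetic database."""
    return rr.train_default_classifier(seed=0)


@pytest.fixture()
def eupnea_chunk():
    params = rr.PatternParams("eupnea", rate_bpm=15, noise_sd=0.02, seed=42)
    return rr.RespChunk(rr.gen_respiratory_waveform(params, 15.0, 17.0))


def one_subject_scene_rr(scene, rate_bpm, seed, chest=(0.0, 0.5, 2.03), clutter_sd=1.0):
    """Full single-subject simulate -> preprocess -> extract -> RR run.

    Returns (RREstimate or None, selected bin, true bin).
    """
    params = rr.PatternParams("eupnea", rate_bpm=rate_bpm, seed=seed)
    script = rr.SubjectScript.stationary(
        1, chest=list(chest), facing=[0.0, 0.0, -1.0], params=params, duration_s=15.0
    )
    matrix = rr.gen_radar_matrix(
        scene, 1, [script], 15.0, clutter_sd=clutter_sd, seed=1000 + seed
    )
    cleaned = rr.preprocess_matrix(matrix)
    dist = rr.distance_to_radar(chest, scene.radar(1).position)
    chunk = rr.extract_respiratory_signal(cleaned, dist)
    est = rr.estimate_rr(rr.bandpass_filter(chunk))
    true_bin = int(round(dist / scene.range_res_m))
    return est, chunk.range_bin, true_bin
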