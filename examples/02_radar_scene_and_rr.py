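"""Simulate one subject in front of a radar and recover their breathing rate.

A subject 2.09 m from radar 1, breathing at 15 breaths/min, modulates range
bin 40 (2.09 m / 5.22 cm). The pipeline removes clutter, finds the
maximum-variance bin near the chest, band-passes 0.1-0.5 Hz and estimates
the rate from the mean peak-to-peak interval. The printed estimate should be
within ~0.5 breaths/min of the scripted 15.
"""

import respiradar as rr

scene = rr.default_scene()
params = rr.PatternParams("eupnea", rate_bpm=15, seed=7)
script = rr.SubjectScript.stationary(
    1, chest=[0.0, 0.5, 2.09], facing=[0, 0, -1], params=params, duration_s=15.0
)

matrix = rr.gen_radar_matrix(scene, 1, [script], 15.0, clutter_sd=1.0, seed=7)
print(f"radar matrix: {matrix.values.shape} (slow time x range bins)")

cleaned = rr.preprocess_matrix(matrix)
dist = rr.distance_to_radar([0.0, 0.5, 2.09], scene.radar(1).position)
chunk = rr.extract_respiratory_signal(cleaned, dist)
print(f"chest distance {dist:.2f} m -> selected range bin {chunk.range_bin}")

est = rr.estimate_rr(rr.bandpass_filter(chunk))
print(
    f"estimated RR = {est.rr_bpm:.2f} breaths/min "
    f"({est.n_peaks} breaths, mean interval {est.mean_interval_s:.2f} s); "
    f"scripted rate was 15"
)
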