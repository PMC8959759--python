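"""Sliding-window orchestration of the full per-window pipeline.

The stream is processed in 15-s windows with 12-s overlap (3-s stride): the
n-th window covers [(n-1)(T-m), nT-(n-1)m]. Within each window, per
subject: motion status from the skeleton; for stationary subjects, radar
selection, respiratory-signal extraction from the selected (clutter-removed)
matrix, pattern classification plus morphological discrimination, and —
only when the final label is eupnea and the signal quality index passed —
respiration-rate estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as rio
from .config import SceneConfig
from .localization import (
    MOVING,
    STATIONARY,
    detect_motion,
    distance_to_radar,
    shoulder_midpoint,
    transform_sample,
)
from .pattern import (
    PatternClassifier,
    PatternLabel,
    classify,
    discriminate,
    extract_features,
    train_classifier,
)
from .preprocess import preprocess_matrix
from .radar_select import UNCOVERED, RadarAssignment, assign_radars
from .respsignal import bandpass_filter, estimate_rr, extract_respiratory_signal
from .simulate import gen_training_database
from .types import OVERLAP_S, WINDOW_S, RadarFrameMatrix, SkeletonSample

logger = logging.getLogger(__name__)


@dataclass
class WindowResult:
    """Per-subject outcome of one sliding window."""

    window_index: int
    t_start: float
    t_end: float
    subject_id: int
    status: str
    assignment: RadarAssignment | None = None
    label: PatternLabel | None = None
    rr_bpm: float | None = None

    def __post_init__(self) -> None:
        if self.rr_bpm is not None and (
            self.status != STATIONARY or self.label is None or self.label.label != "eupnea"
        ):
            raise ValueError("RR may only be reported for stationary eupnea windows")


def sliding_windows(
    stream_length_s: float,
    window_s: float = WINDOW_S,
    overlap_s: float = OVERLAP_S,
) -> list[tuple[float, float]]:
    """(start, end) intervals of every complete analysis window."""
    if not window_s > overlap_s >= 0:
        raise ValueError("need window_s > overlap_s >= 0")
    if stream_length_s < window_s:
        return []
    stride = window_s - overlap_s
    n = int(np.floor((stream_length_s - window_s) / stride + 1e-9)) + 1
    return [(i * stride, i * stride + window_s) for i in range(n)]


def train_default_classifier(
    seed: int = 0, n_per_class: int = 50, n_trees: int = 100
) -> PatternClassifier:
    """Train the pattern classifier on a synthetic balanced database."""
    chunks, labels = gen_training_database(n_per_class=n_per_class, seed=seed)
    features = [extract_features(c) for c in chunks]
    return train_classifier(features, labels, n_trees=n_trees, seed=seed)


def process_window(
    scene: SceneConfig,
    matrices: dict[int, RadarFrameMatrix],
    skeletons: list[SkeletonSample],
    classifier: PatternClassifier,
    window: tuple[float, float] = (0.0, WINDOW_S),
    window_index: int = 0,
    preprocess: bool = True,
    svd_components: int = 1,
) -> list[WindowResult]:
    """Run the full pipeline on one window's slices of all streams.

    ``matrices`` maps radar_id to that radar's matrix slice for the window;
    ``skeletons`` are the skeleton samples falling inside the window (any
    frame; transformed here if needed).
    """
    t0, t1 = window
    results: list[WindowResult] = []

    by_subject: dict[int, list[SkeletonSample]] = {}
    for s in skeletons:
        by_subject.setdefault(s.subject_id, []).append(
            transform_sample(s, scene.rotation_angle_deg)
        )

    stationary_subjects: dict[int, dict] = {}
    status: dict[int, str] = {}
    for sid, samples in sorted(by_subject.items()):
        midpoints = [
            (s.t, shoulder_midpoint(s.l_shoulder, s.r_shoulder)) for s in samples
        ]
        st = detect_motion(midpoints, threshold_mps=scene.motion_threshold_mps)
        status[sid] = st
        if st == STATIONARY:
            # position over the window = mean of the skeleton samples in it
            stationary_subjects[sid] = {
                "chest": np.mean([s.chest for s in samples], axis=0),
                "l_shoulder": np.mean([s.l_shoulder for s in samples], axis=0),
                "r_shoulder": np.mean([s.r_shoulder for s in samples], axis=0),
            }
        else:
            results.append(
                WindowResult(
                    window_index=window_index,
                    t_start=t0,
                    t_end=t1,
                    subject_id=sid,
                    status=MOVING,
                )
            )

    if not stationary_subjects:
        return sorted(results, key=lambda r: r.subject_id)

    assignments = assign_radars(stationary_subjects, scene)
    cleaned: dict[int, RadarFrameMatrix] = {}
    for a in assignments:
        sid = a.subject_id
        if a.radar_id is not None and a.radar_id not in matrices:
            logger.warning(
                "radar %d selected for subject %d but no matrix available",
                a.radar_id,
                sid,
            )
            a = RadarAssignment(
                subject_id=sid,
                radar_id=None,
                orientation_angle_deg=None,
                chest_distance_m=None,
                reason=UNCOVERED,
            )
        if a.radar_id is None:
            results.append(
                WindowResult(
                    window_index=window_index,
                    t_start=t0,
                    t_end=t1,
                    subject_id=sid,
                    status=STATIONARY,
                    assignment=a,
                )
            )
            continue

        if a.radar_id not in cleaned:
            m = matrices[a.radar_id]
            cleaned[a.radar_id] = (
                preprocess_matrix(m, n_components=svd_components) if preprocess else m
            )
        chunk = extract_respiratory_signal(
            cleaned[a.radar_id], a.chest_distance_m, subject_id=sid
        )
        label = discriminate(classify(classifier, extract_features(chunk)), chunk)
        rr = None
        if label.label == "eupnea":
            est = estimate_rr(bandpass_filter(chunk))
            rr = est.rr_bpm if est is not None else None
        results.append(
            WindowResult(
                window_index=window_index,
                t_start=t0,
                t_end=t1,
                subject_id=sid,
                status=STATIONARY,
                assignment=a,
                label=label,
                rr_bpm=rr,
            )
        )
    return sorted(results, key=lambda r: r.subject_id)


def run_pipeline(
    config_path: str | Path,
    input_dir: str | Path,
    output_path: str | Path | None = None,
    model_path: str | Path | None = None,
    window_s: float = WINDOW_S,
    overlap_s: float = OVERLAP_S,
    seed: int = 0,
    svd_components: int = 1,
) -> list[WindowResult]:
    """Batch pipeline over a recorded/simulated session directory.

    Expects ``radar_<id>.csv`` files (one per scene radar; missing radars
    are tolerated with a warning) and a ``skeleton.csv``. Emits one flat log
    row per (window, subject) if ``output_path`` is given.
    """
    scene = SceneConfig.load(config_path)
    input_dir = Path(input_dir)
    skeleton_path = input_dir / "skeleton.csv"
    if not skeleton_path.exists():
        raise FileNotFoundError(f"no skeleton.csv in {input_dir}")

    matrices: dict[int, RadarFrameMatrix] = {}
    for radar in scene.radars:
        p = input_dir / rio.radar_csv_name(radar.id)
        if p.exists():
            matrices[radar.id] = rio.read_radar_csv(
                p, radar.id, slow_rate=scene.slow_rate_hz, range_res_m=scene.range_res_m
            )
        else:
            logger.warning("radar file %s missing; radar %d unavailable", p, radar.id)
    if not matrices:
        raise FileNotFoundError(f"no radar_<id>.csv files in {input_dir}")

    skeletons = rio.read_skeleton_csv(skeleton_path)
    duration = min(m.duration_s for m in matrices.values())

    if model_path is not None:
        classifier = PatternClassifier.load(model_path)
    else:
        classifier = train_default_classifier(seed=seed)

    results: list[WindowResult] = []
    for i, (t0, t1) in enumerate(sliding_windows(duration, window_s, overlap_s)):
        win_matrices = {rid: m.slice_time(t0, t1) for rid, m in matrices.items()}
        win_skeletons = [s for s in skeletons if t0 <= s.t < t1]
        results.extend(
            process_window(
                scene,
                win_matrices,
                win_skeletons,
                classifier,
                window=(t0, t1),
                window_index=i,
                svd_components=svd_components,
            )
        )

    # workflow gate: RR only ever accompanies a stationary eupnea label
    assert all(
        r.rr_bpm is None or (r.label is not None and r.label.label == "eupnea")
        for r in results
    )
    if output_path is not None:
        rio.write_window_log(results, output_path)
    return results
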