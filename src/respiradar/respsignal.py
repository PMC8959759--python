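"""Respiratory-signal extraction and respiration-rate estimation.

The chest of a stationary subject sits at a known distance from the selected
radar (from the skeleton), but the depth camera localises the chest only to
within a few tens of cm, while a range bin is ~5 cm. The extractor therefore
searches ±3 range bins (about the thickness of a human torso) around the
nominal chest bin and takes the slow-time series with maximum variance —
breathing micro-motion dominates the variance of the clutter-removed matrix.

The respiration rate of a normal-breathing chunk is the reciprocal of the
mean peak-to-peak interval: RR = 60 / mean(dt) breaths/min, after a 3rd-order
Butterworth band-pass of 0.1–0.5 Hz (6–30 breaths/min) applied forward and
backward so peak times are not shifted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .pattern import detect_breath_extrema
from .types import RadarFrameMatrix, RespChunk

#: band-pass corner frequencies (Hz); 0.1–0.5 Hz spans 6–30 breaths/min
BAND_LOW_HZ = 0.1
BAND_HIGH_HZ = 0.5
BAND_ORDER = 3


@dataclass
class RREstimate:
    rr_bpm: float
    n_peaks: int
    mean_interval_s: float


def chest_range_bin(chest_distance_m: float, range_res_m: float) -> int:
    """Nominal range bin of the chest: its radar distance in units of the
    range resolution, rounded."""
    return int(round(chest_distance_m / range_res_m))


def extract_respiratory_signal(
    matrix: RadarFrameMatrix,
    chest_distance_m: float,
    halfwidth_bins: int = 3,
    subject_id: int | None = None,
) -> RespChunk:
    """Select the maximum-variance slow-time series within ±``halfwidth_bins``
    of the nominal chest bin of a (clutter-removed) radar matrix."""
    if not 0 <= chest_distance_m <= matrix.n_bins * matrix.range_res_m:
        raise ValueError(
            f"chest distance {chest_distance_m:.2f} m beyond radar range "
            f"{matrix.n_bins * matrix.range_res_m:.2f} m"
        )
    center = chest_range_bin(chest_distance_m, matrix.range_res_m)
    lo = max(center - halfwidth_bins, 0)
    hi = min(center + halfwidth_bins, matrix.n_bins - 1)
    variances = matrix.values[:, lo : hi + 1].var(axis=0)
    best = lo + int(np.argmax(variances))
    return RespChunk(
        samples=matrix.values[:, best],
        rate_hz=matrix.slow_rate,
        subject_id=subject_id,
        radar_id=matrix.radar_id,
        range_bin=best,
        t_start=matrix.t0,
    )


def bandpass_filter(
    chunk: RespChunk,
    low_hz: float = BAND_LOW_HZ,
    high_hz: float = BAND_HIGH_HZ,
    order: int = BAND_ORDER,
) -> RespChunk:
    """Zero-phase Butterworth band-pass of a chunk (default 0.1–0.5 Hz)."""
    if low_hz >= high_hz:
        raise ValueError(f"invalid band: low {low_hz} >= high {high_hz}")
    if chunk.rate_hz <= 2 * high_hz:
        raise ValueError("sampling rate must exceed twice the upper cutoff")
    sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=chunk.rate_hz, output="sos")
    return chunk.replace_samples(sosfiltfilt(sos, chunk.samples))


def estimate_rr(chunk: RespChunk) -> RREstimate | None:
    """Respiration rate from the mean peak-to-peak interval of a band-passed
    chunk; ``None`` when fewer than two breaths are detected."""
    peaks, _, _ = detect_breath_extrema(chunk.samples, median_kernel=5)
    if peaks.size < 2:
        return None
    dt = float(np.mean(np.diff(peaks)) / chunk.rate_hz)
    return RREstimate(rr_bpm=60.0 / dt, n_peaks=int(peaks.size), mean_interval_s=dt)
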