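"""Core data containers shared across the pipeline.

Coordinate conventions follow the depth camera: the *reference* frame has
x pointing right, y down and z forward, origin at the camera focal point.
Skeleton joints arrive in a *rotated* frame (the camera is tilted about its
x-axis) and are transformed to the reference frame before any geometry is
computed. Radar observations are slow-time x fast-time amplitude matrices;
each fast-time column ("range bin") corresponds to a ~5.22 cm slice of
distance from the radar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: slow-time sampling rate every stream is resampled to (Hz)
SLOW_RATE_HZ = 17.0
#: radar range resolution (m per range bin)
RANGE_RES_M = 0.0522
#: configured maximum recording distance of the radar (m)
MAX_RECORD_RANGE_M = 9.4
#: number of complete range bins within the recording range
N_RANGE_BINS = int(MAX_RECORD_RANGE_M / RANGE_RES_M)  # 180
#: analysis window length and overlap (s)
WINDOW_S = 15.0
OVERLAP_S = 12.0

ROTATED = "rotated"
REFERENCE = "reference"

JOINT_NAMES = ("chest", "l_shoulder", "r_shoulder")


def as_point(p) -> np.ndarray:
    """Coerce a 3-vector to a float ndarray and validate it."""
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("point coordinates must be finite")
    return a


@dataclass
class RadarFrameMatrix:
    """Slow-time x fast-time amplitude matrix from one radar.

    Rows are slow-time samples (observations), columns are fast-time range
    bins. ``values[k, b]`` is the echo amplitude at time ``t0 + k/slow_rate``
    and distance ``b * range_res_m`` from the radar.
    """

    radar_id: int
    values: np.ndarray
    slow_rate: float = SLOW_RATE_HZ
    range_res_m: float = RANGE_RES_M
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("radar matrix must be 2-D (slow time x range bins)")
        if self.slow_rate <= 0:
            raise ValueError("slow_rate must be positive")

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.slow_rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.slow_rate

    def slice_time(self, start_s: float, end_s: float) -> "RadarFrameMatrix":
        """Rows with t in [start_s, end_s); times are absolute (include t0)."""
        k0 = int(round((start_s - self.t0) * self.slow_rate))
        k1 = int(round((end_s - self.t0) * self.slow_rate))
        k0 = max(k0, 0)
        return RadarFrameMatrix(
            radar_id=self.radar_id,
            values=self.values[k0:k1],
            slow_rate=self.slow_rate,
            range_res_m=self.range_res_m,
            t0=self.t0 + k0 / self.slow_rate,
        )


@dataclass
class SkeletonSample:
    """One timestamped skeleton observation of a single subject.

    Only the three joints the pipeline uses are kept: chest and the two
    shoulders. ``frame`` records whether coordinates are still in the tilted
    camera frame or already transformed to the reference frame.
    """

    t: float
    subject_id: int
    chest: np.ndarray
    l_shoulder: np.ndarray
    r_shoulder: np.ndarray
    frame: str = ROTATED

    def __post_init__(self) -> None:
        self.chest = as_point(self.chest)
        self.l_shoulder = as_point(self.l_shoulder)
        self.r_shoulder = as_point(self.r_shoulder)
        if self.frame not in (ROTATED, REFERENCE):
            raise ValueError(f"unknown frame tag {self.frame!r}")


@dataclass
class RespChunk:
    """One windowed respiratory waveform tied to a subject/radar/range bin.

    At the defaults (15 s window, 17 Hz) a chunk holds 255 samples.
    """

    samples: np.ndarray
    rate_hz: float = SLOW_RATE_HZ
    subject_id: int | None = None
    radar_id: int | None = None
    range_bin: int | None = None
    t_start: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()

    def __len__(self) -> int:
        return self.samples.size

    def times(self) -> np.ndarray:
        return self.t_start + np.arange(len(self)) / self.rate_hz

    def replace_samples(self, samples: np.ndarray) -> "RespChunk":
        return RespChunk(
            samples=samples,
            rate_hz=self.rate_hz,
            subject_id=self.subject_id,
            radar_id=self.radar_id,
            range_bin=self.range_bin,
            t_start=self.t_start,
        )
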