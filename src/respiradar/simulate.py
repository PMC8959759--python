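"""Scene and waveform simulator: the hardware-free data source.

Everything the pipeline consumes — radar matrices, skeleton streams,
labelled training chunks — can be generated here with the statistical
structure the downstream stages assume:

* Respiratory waveforms for five patterns: eupnea (quasi-sinusoidal chest
  displacement with small cycle-to-cycle jitter), Kussmaul (deeper and
  faster), apnea (near-flat segments interleaving short runs of breaths),
  Cheyne-Stokes respiration (a crescendo-decrescendo amplitude envelope
  with an apnea gap, cycle longer than one 15-s chunk), and non-stationary
  (random-walk movement artifacts uncorrelated with breathing).
* Radar matrices built from a simple additive echo model: per-bin static
  clutter, white noise, and the subject's displacement waveform modulating
  the bin at the chest's range (with triangular spillover to the adjacent
  bins), scaled by an orientation gain — the cosine of the angle between
  the facing direction and the subject-to-radar direction, clipped at zero,
  and zero outside the antenna beam.
* Skeleton streams emitted in the *rotated* camera frame (the inverse of
  the reference-frame transform, plus isotropic noise), so the localization
  stage is exercised rather than bypassed.

All generators are deterministic given their seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import SceneConfig
from .localization import rotate_to_rotated
from .types import (
    N_RANGE_BINS,
    SLOW_RATE_HZ,
    RadarFrameMatrix,
    RespChunk,
    SkeletonSample,
    as_point,
)

logger = logging.getLogger(__name__)

#: triangular spillover of the chest echo into adjacent range bins
SPREAD_WEIGHTS = ((-1, 0.5), (0, 1.0), (1, 0.5))


@dataclass
class PatternParams:
    """Parameters of one simulated breathing (or artifact) segment."""

    pattern: str
    rate_bpm: float = 15.0
    amplitude: float = 1.0
    csr_period_s: float = 40.0
    apnea_fraction: float = 0.3
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        from .pattern import PATTERNS

        if self.pattern not in PATTERNS:
            raise ValueError(
                f"unknown pattern {self.pattern!r}; expected one of {PATTERNS}"
            )
        if self.pattern not in ("apnea", "nonstationary") and not (
            6 <= self.rate_bpm <= 40
        ):
            raise ValueError("rate_bpm must lie in [6, 40] for breathing patterns")
        if self.pattern == "csr" and self.csr_period_s <= 15:
            raise ValueError("csr_period_s must exceed one 15-s chunk")
        if not 0 <= self.apnea_fraction <= 1:
            raise ValueError("apnea_fraction must lie in [0, 1]")


def _jittered_phase(
    t: np.ndarray, rate_bpm: float, rng: np.random.Generator, jitter: float = 0.03
) -> np.ndarray:
    """Breathing phase (in cycles) with small cycle-to-cycle period jitter."""
    period = 60.0 / rate_bpm
    n_cycles = int(np.ceil(t[-1] / period)) + 2 if t.size else 1
    periods = period * (1.0 + jitter * rng.standard_normal(n_cycles))
    periods = np.clip(periods, 0.5 * period, 1.5 * period)
    boundaries = np.concatenate([[0.0], np.cumsum(periods)])
    return np.interp(t, boundaries, np.arange(boundaries.size, dtype=float))


def _apnea_mask(
    t: np.ndarray, apnea_fraction: float, rng: np.random.Generator, cycle_s: float = 12.0
) -> np.ndarray:
    """Smooth 0/1 envelope alternating breathing runs with flat apnea gaps."""
    mask = np.ones_like(t)
    ramp = 0.75  # s, raised-cosine edges
    pos = rng.uniform(0.0, 0.3 * cycle_s)
    while pos < t[-1] + cycle_s:
        gap = apnea_fraction * cycle_s * rng.uniform(0.8, 1.2)
        start, end = pos, pos + gap
        inside = (t > start) & (t < end)
        mask[inside] = 0.0
        lead = (t >= start - ramp) & (t <= start)
        mask[lead] = 0.5 * (1 + np.cos(np.pi * (t[lead] - (start - ramp)) / ramp))
        trail = (t >= end) & (t <= end + ramp)
        mask[trail] = 0.5 * (1 - np.cos(np.pi * (t[trail] - end) / ramp))
        pos += cycle_s * rng.uniform(0.9, 1.1)
    return mask


def csr_envelope(t: np.ndarray, period_s: float, apnea_fraction: float) -> np.ndarray:
    """Cheyne-Stokes amplitude envelope: a raised-cosine hump over the
    active part of each cycle, zero during the apnea gap."""
    active = (1.0 - apnea_fraction) * period_s
    s = np.mod(t, period_s) / active
    env = np.where(s < 1.0, np.sin(np.pi * np.clip(s, 0.0, 1.0)) ** 2, 0.0)
    return env


def gen_respiratory_waveform(
    params: PatternParams, duration_s: float, rate_hz: float = SLOW_RATE_HZ
) -> np.ndarray:
    """Chest-displacement waveform of one breathing pattern.

    Returns ``round(duration_s * rate_hz)`` samples in arbitrary
    displacement units.
    """
    if duration_s <= 0 or rate_hz <= 0:
        raise ValueError("duration and rate must be positive")
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    rng = np.random.default_rng(params.seed)
    p = params.pattern

    if p in ("eupnea", "kussmaul"):
        phase = _jittered_phase(t, params.rate_bpm, rng)
        x = params.amplitude * np.sin(2 * np.pi * phase)
    elif p == "apnea":
        phase = _jittered_phase(t, params.rate_bpm, rng)
        mask = _apnea_mask(t, params.apnea_fraction, rng)
        x = params.amplitude * mask * np.sin(2 * np.pi * phase)
    elif p == "csr":
        env = csr_envelope(t, params.csr_period_s, params.apnea_fraction)
        x = params.amplitude * env * np.sin(2 * np.pi * params.rate_bpm / 60.0 * t)
    elif p == "nonstationary":
        # random-walk drift plus occasional step artifacts, no breathing
        x = np.cumsum(rng.normal(0.0, 0.15 * params.amplitude, n))
        for _ in range(rng.integers(1, 4)):
            k = rng.integers(0, max(n - 1, 1))
            x[k:] += rng.normal(0.0, 2.0 * params.amplitude)
    else:  # pragma: no cover - guarded by PatternParams
        raise ValueError(f"unknown pattern {p!r}")

    return x + rng.normal(0.0, params.noise_sd, n)


# ----------------------------------------------------------------- scripts


@dataclass
class SubjectScript:
    """Scripted ground truth for one subject: where they are, which way
    they face, and how they breathe over time.

    ``waypoints`` are (time_s, chest position) pairs in the reference frame,
    linearly interpolated; ``facing`` is a unit direction in the xz plane
    (constant). Shoulders are placed symmetrically about the chest,
    perpendicular to the facing direction, ``shoulder_width`` apart.
    """

    subject_id: int
    waypoints: list[tuple[float, np.ndarray]]
    facing: np.ndarray
    pattern_schedule: list[tuple[float, float, PatternParams]]
    shoulder_width: float = 0.4

    def __post_init__(self) -> None:
        if not self.waypoints:
            raise ValueError("script needs at least one waypoint")
        self.waypoints = [(float(t), as_point(p)) for t, p in self.waypoints]
        f = as_point(self.facing)
        norm = float(np.hypot(f[0], f[2]))
        if norm == 0:
            raise ValueError("facing must have a nonzero xz component")
        self.facing = np.array([f[0] / norm, 0.0, f[2] / norm])
        spans = sorted((s, e) for s, e, _ in self.pattern_schedule)
        for (s0, e0), (s1, _) in zip(spans[:-1], spans[1:]):
            if s1 < e0:
                raise ValueError("pattern schedule intervals overlap")

    @classmethod
    def stationary(
        cls,
        subject_id: int,
        chest,
        facing,
        params: PatternParams,
        duration_s: float,
    ) -> "SubjectScript":
        return cls(
            subject_id=subject_id,
            waypoints=[(0.0, as_point(chest))],
            facing=facing,
            pattern_schedule=[(0.0, duration_s, params)],
        )

    @classmethod
    def walking(
        cls,
        subject_id: int,
        start,
        end,
        speed_mps: float,
        facing=None,
    ) -> "SubjectScript":
        start, end = as_point(start), as_point(end)
        travel = float(np.linalg.norm(end - start)) / speed_mps
        if facing is None:
            facing = end - start
        return cls(
            subject_id=subject_id,
            waypoints=[(0.0, start), (travel, end)],
            facing=facing,
            pattern_schedule=[],
        )

    def chest_at(self, t: float) -> np.ndarray:
        ts = np.array([w[0] for w in self.waypoints])
        pts = np.stack([w[1] for w in self.waypoints])
        return np.array([np.interp(t, ts, pts[:, i]) for i in range(3)])

    def shoulders_at(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """(left, right) shoulder positions at time t."""
        chest = self.chest_at(t)
        f = self.facing
        right_dir = np.array([-f[2], 0.0, f[0]])  # facing rotated -90 deg in xz
        half = 0.5 * self.shoulder_width
        return chest - half * right_dir, chest + half * right_dir

    def displacement(self, duration_s: float, rate_hz: float = SLOW_RATE_HZ) -> np.ndarray:
        """Chest displacement over [0, duration_s]; zero outside scheduled
        breathing segments."""
        n = int(round(duration_s * rate_hz))
        x = np.zeros(n)
        for start_s, end_s, params in self.pattern_schedule:
            k0 = int(round(start_s * rate_hz))
            seg = gen_respiratory_waveform(params, min(end_s, duration_s) - start_s, rate_hz)
            x[k0 : k0 + seg.size] = seg[: max(n - k0, 0)]
        return x


# ------------------------------------------------------------ radar matrix


def _orientation_gain(
    chest: np.ndarray, facing: np.ndarray, radar, beam_half_angle_deg: float
) -> float:
    """Cosine of the angle between the facing direction and the
    subject-to-radar direction (clipped at 0); zero outside the beam."""
    v = radar.position - chest
    v_xz = np.array([v[0], v[2]])
    nv = float(np.linalg.norm(v_xz))
    if nv == 0:
        return 0.0
    u = v_xz / nv
    b = np.array([radar.boresight[0], radar.boresight[2]])
    beam_cos = float(np.clip(np.dot(-u, b), -1.0, 1.0))
    if np.degrees(np.arccos(beam_cos)) > beam_half_angle_deg:
        return 0.0
    f = np.array([facing[0], facing[2]])
    return float(max(np.dot(f, u), 0.0))


def gen_radar_matrix(
    scene: SceneConfig,
    radar_id: int,
    scripts: list[SubjectScript],
    duration_s: float,
    clutter_sd: float = 1.0,
    noise_sd: float = 0.05,
    echo_gain: float = 1.0,
    seed: int | None = 0,
) -> RadarFrameMatrix:
    """Simulate one radar's slow-time x fast-time amplitude matrix.

    Additive echo model per slow-time sample ``k`` and range bin ``b``:
    constant per-bin clutter + white noise + for each subject inside the
    beam, ``echo_gain * orientation_gain * displacement[k]`` at the chest's
    bin, with triangular spillover to the two adjacent bins. Subjects beyond
    the radar's recording range contribute nothing.
    """
    radar = scene.radar(radar_id)
    rate = scene.slow_rate_hz
    n = int(round(duration_s * rate))
    rng = np.random.default_rng(seed)
    clutter = rng.normal(0.0, clutter_sd, N_RANGE_BINS)
    values = clutter[None, :] + rng.normal(0.0, noise_sd, (n, N_RANGE_BINS))

    times = np.arange(n) / rate
    for script in scripts:
        disp = script.displacement(duration_s, rate)
        out_of_range = False
        for k, t in enumerate(times):
            chest = script.chest_at(t)
            dist = float(np.linalg.norm(chest - radar.position))
            if dist >= radar.max_range_m:
                out_of_range = True
                continue
            gain = _orientation_gain(
                chest, script.facing, radar, scene.beam_half_angle_deg
            )
            if gain == 0.0:
                continue
            center = int(round(dist / scene.range_res_m))
            for off, w in SPREAD_WEIGHTS:
                b = center + off
                if 0 <= b < N_RANGE_BINS:
                    values[k, b] += echo_gain * gain * w * disp[k]
        if out_of_range:
            logger.info(
                "subject %d beyond radar %d recording range for part of the scene",
                script.subject_id,
                radar_id,
            )
    return RadarFrameMatrix(
        radar_id=radar_id,
        values=values,
        slow_rate=rate,
        range_res_m=scene.range_res_m,
    )


# --------------------------------------------------------- skeleton stream


def gen_skeleton_stream(
    scene: SceneConfig,
    scripts: list[SubjectScript],
    duration_s: float,
    fps: float = 1.0,
    noise_sd_m: float = 0.0,
    seed: int | None = 0,
) -> list[SkeletonSample]:
    """Skeleton joints at ``fps`` (the camera runs at 1 fps), emitted in the
    rotated camera frame with isotropic position noise."""
    if fps <= 0:
        raise ValueError("fps must be positive")
    rng = np.random.default_rng(seed)
    angle = scene.rotation_angle_deg
    samples: list[SkeletonSample] = []
    n_frames = int(round(duration_s * fps))
    for i in range(n_frames):
        t = i / fps
        for script in scripts:
            chest = script.chest_at(t)
            l_sh, r_sh = script.shoulders_at(t)
            joints = [
                rotate_to_rotated(p, angle) + rng.normal(0.0, noise_sd_m, 3)
                for p in (chest, l_sh, r_sh)
            ]
            samples.append(
                SkeletonSample(
                    t=t,
                    subject_id=script.subject_id,
                    chest=joints[0],
                    l_shoulder=joints[1],
                    r_shoulder=joints[2],
                    frame="rotated",
                )
            )
    return samples


# ------------------------------------------------------- training database


def _sample_params(pattern: str, rng: np.random.Generator) -> PatternParams:
    """Draw realistic per-chunk parameters for one training example."""
    seed = int(rng.integers(0, 2**31))
    if pattern == "eupnea":
        return PatternParams(
            "eupnea",
            rate_bpm=rng.uniform(14, 20),
            amplitude=rng.uniform(0.8, 1.2),
            noise_sd=0.03,
            seed=seed,
        )
    if pattern == "kussmaul":
        return PatternParams(
            "kussmaul",
            rate_bpm=rng.uniform(24, 34),
            amplitude=rng.uniform(2.0, 3.0),
            noise_sd=0.03,
            seed=seed,
        )
    if pattern == "apnea":
        return PatternParams(
            "apnea",
            rate_bpm=rng.uniform(10, 16),
            amplitude=rng.uniform(0.5, 1.0),
            apnea_fraction=rng.uniform(0.6, 0.85),
            noise_sd=0.03,
            seed=seed,
        )
    if pattern == "csr":
        return PatternParams(
            "csr",
            rate_bpm=rng.uniform(18, 26),
            amplitude=rng.uniform(1.0, 2.0),
            csr_period_s=rng.uniform(36, 60),
            apnea_fraction=rng.uniform(0.2, 0.3),
            noise_sd=0.03,
            seed=seed,
        )
    return PatternParams(
        "nonstationary", amplitude=rng.uniform(0.5, 1.5), noise_sd=0.03, seed=seed
    )


def gen_training_database(
    n_per_class: int = 50,
    chunk_s: float = 15.0,
    rate_hz: float = SLOW_RATE_HZ,
    seed: int | None = 0,
) -> tuple[list[RespChunk], list[str]]:
    """Balanced labelled chunk database: 5 classes x ``n_per_class``.

    The default reproduces a 250-chunk database (50 per class). CSR chunks
    are cut from within the active (crescendo/decrescendo) part of a full
    CSR cycle, so each shows the monotone-amplitude morphology the
    discriminator tests for.
    """
    from .pattern import PATTERNS

    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    chunks: list[RespChunk] = []
    labels: list[str] = []
    for pattern in PATTERNS:
        for _ in range(n_per_class):
            params = _sample_params(pattern, rng)
            if pattern == "csr":
                # cut from within the crescendo/decrescendo phase, keeping a
                # small margin from the near-zero envelope edges so the chunk
                # shows the phase rather than the apnea boundary
                full = gen_respiratory_waveform(params, params.csr_period_s, rate_hz)
                active = (1.0 - params.apnea_fraction) * params.csr_period_s
                margin = 0.05 * active
                start = rng.uniform(margin, max(active - chunk_s - margin, margin))
                k0 = int(round(start * rate_hz))
                n = int(round(chunk_s * rate_hz))
                samples = full[k0 : k0 + n]
            else:
                samples = gen_respiratory_waveform(params, chunk_s, rate_hz)
            chunks.append(RespChunk(samples=samples, rate_hz=rate_hz))
            labels.append(pattern)
    return chunks, labels
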