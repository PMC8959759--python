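"""Scene configuration: radar poses, camera tilt and decision thresholds.

A :class:`SceneConfig` is the single source of truth for the monitoring
geometry. Radar boresights lie in the horizontal (xz) plane of the reference
camera frame; the beam test and the orientation angle are both evaluated on
that plane, matching how wall-mounted radars at chest height see seated
subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .types import (
    MAX_RECORD_RANGE_M,
    RANGE_RES_M,
    SLOW_RATE_HZ,
    as_point,
)


@dataclass
class RadarSpec:
    """Pose of one radar: position in the reference frame and a unit
    boresight vector in the xz plane."""

    id: int
    position: np.ndarray
    boresight: np.ndarray
    max_range_m: float = MAX_RECORD_RANGE_M

    def __post_init__(self) -> None:
        self.position = as_point(self.position)
        b = as_point(self.boresight)
        norm = float(np.hypot(b[0], b[2]))
        if norm == 0:
            raise ValueError("boresight must have a nonzero xz component")
        # project onto the xz plane and normalise
        self.boresight = np.array([b[0] / norm, 0.0, b[2] / norm])


@dataclass
class SceneConfig:
    radars: list[RadarSpec]
    rotation_angle_deg: float = -30.0
    beam_half_angle_deg: float = 30.0
    max_detect_range_m: float = 5.0
    range_res_m: float = RANGE_RES_M
    slow_rate_hz: float = SLOW_RATE_HZ
    motion_threshold_mps: float = 0.7
    min_bin_separation: int = 6

    def __post_init__(self) -> None:
        if self.beam_half_angle_deg <= 0 or self.max_detect_range_m <= 0:
            raise ValueError("beam half-angle and detection range must be positive")
        if self.motion_threshold_mps <= 0 or self.range_res_m <= 0:
            raise ValueError("thresholds must be positive")
        ids = [r.id for r in self.radars]
        if len(ids) != len(set(ids)):
            raise ValueError("radar ids must be unique")

    @property
    def min_separation_m(self) -> float:
        """Smallest chest-distance difference (m) at which two subjects can
        share a radar without their signals landing in overlapping bins."""
        return self.min_bin_separation * self.range_res_m

    def radar(self, radar_id: int) -> RadarSpec:
        for r in self.radars:
            if r.id == radar_id:
                return r
        raise KeyError(f"no radar with id {radar_id}")

    # ------------------------------------------------------------------ I/O

    def to_dict(self) -> dict:
        return {
            "rotation_angle_deg": self.rotation_angle_deg,
            "beam_half_angle_deg": self.beam_half_angle_deg,
            "max_detect_range_m": self.max_detect_range_m,
            "range_res_m": self.range_res_m,
            "slow_rate_hz": self.slow_rate_hz,
            "motion_threshold_mps": self.motion_threshold_mps,
            "min_bin_separation": self.min_bin_separation,
            "radars": [
                {
                    "id": r.id,
                    "position": [float(v) for v in r.position],
                    "boresight": [float(v) for v in r.boresight],
                }
                for r in self.radars
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        try:
            radars = [
                RadarSpec(
                    id=int(r["id"]),
                    position=r["position"],
                    boresight=r["boresight"],
                )
                for r in d["radars"]
            ]
        except (KeyError, TypeError) as exc:
            raise ValueError(f"malformed scene config: {exc}") from exc
        kwargs = {
            k: d[k]
            for k in (
                "rotation_angle_deg",
                "beam_half_angle_deg",
                "max_detect_range_m",
                "range_res_m",
                "slow_rate_hz",
                "motion_threshold_mps",
                "min_bin_separation",
            )
            if k in d
        }
        return cls(radars=radars, **kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "SceneConfig":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise ValueError(f"scene config {path} is not a mapping")
        return cls.from_dict(d)


def default_scene() -> SceneConfig:
    """Laboratory-style layout: three radars on different walls of a room,
    all boresights pointing into the monitored area, camera tilted -30 deg."""
    return SceneConfig(
        radars=[
            RadarSpec(id=1, position=[0.0, 0.5, 0.0], boresight=[0.0, 0.0, 1.0]),
            RadarSpec(id=2, position=[-2.5, 0.5, 2.5], boresight=[1.0, 0.0, 0.0]),
            RadarSpec(id=3, position=[2.5, 0.5, 2.5], boresight=[-1.0, 0.0, 0.0]),
        ]
    )
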