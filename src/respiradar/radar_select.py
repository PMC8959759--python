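"""Per-subject radar selection.

Each stationary subject should be monitored by the radar that (a) covers
them (inside the beam and within detection range) and (b) they most squarely
face. Orientation is quantified by the angle at the shoulder midpoint M
between the right shoulder R and the radar D, computed on the horizontal
(xz) plane by the law of cosines:

    angle(RMD) = arccos((RM^2 + MD^2 - RD^2) / (2 RM MD))

A subject facing the radar head-on gives 90 deg, so the covering radar with
the angle closest to 90 deg wins. With two subjects, a radar cannot separate
them if their chest distances to it differ by less than 6 range bins
(~30 cm): their echoes land in overlapping bins and the extracted signals
would be corrupted. In that case the subject facing the contested radar less
squarely falls back to its next-best covering radar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RadarSpec, SceneConfig
from .localization import distance_to_radar, shoulder_midpoint
from .types import as_point

BEST_ANGLE = "best_angle"
FALLBACK_SEPARATION = "fallback_separation"
UNCOVERED = "uncovered"


@dataclass
class RadarAssignment:
    """Outcome of radar selection for one subject."""

    subject_id: int
    radar_id: int | None
    orientation_angle_deg: float | None
    chest_distance_m: float | None
    reason: str

    def __post_init__(self) -> None:
        if (self.radar_id is None) != (self.reason == UNCOVERED):
            raise ValueError("radar_id must be None exactly when reason is 'uncovered'")


def _xz(p) -> np.ndarray:
    p = as_point(p)
    return np.array([p[0], p[2]])


def in_detection_area(chest, radar: RadarSpec, scene: SceneConfig) -> bool:
    """True iff the chest lies inside the radar's beam cone (on the xz
    plane) and closer than the detection range.

    With the boresight along +z this reduces to the familiar planar test
    60 deg < arctan(|dz|/|dx|) <= 90 deg for a 60 deg beam.
    """
    chest = as_point(chest)
    d = distance_to_radar(chest, radar.position)
    if d >= scene.max_detect_range_m or d == 0.0:
        return False
    v = _xz(chest) - _xz(radar.position)
    nv = np.linalg.norm(v)
    if nv == 0.0:
        return True  # directly above/below the radar: on-axis in the xz plane
    b = _xz(radar.boresight)
    cos_angle = float(np.clip(np.dot(v, b) / nv, -1.0, 1.0))
    angle = np.degrees(np.arccos(cos_angle))
    return angle <= scene.beam_half_angle_deg


def orientation_angle(l_shoulder, r_shoulder, radar_pos) -> float:
    """Angle (deg) at the shoulder midpoint between the right shoulder and
    the radar, on the xz plane. 90 deg means the subject squarely faces the
    radar; 0/180 deg mean the radar lies along the shoulder axis."""
    r = _xz(r_shoulder)
    m = (_xz(l_shoulder) + r) / 2.0
    d = _xz(radar_pos)
    rm = np.linalg.norm(r - m)
    md = np.linalg.norm(d - m)
    if rm == 0.0 or md == 0.0:
        raise ValueError("degenerate geometry: coincident shoulders or radar at midpoint")
    rd = np.linalg.norm(d - r)
    cos_a = (rm**2 + md**2 - rd**2) / (2.0 * rm * md)
    return float(np.degrees(np.arccos(np.clip(cos_a, -1.0, 1.0))))


def _candidates(subject: dict, scene: SceneConfig) -> list[tuple[float, int, float, float]]:
    """Covering radars for one subject, sorted by |angle - 90| then radar id.

    Returns (|angle-90|, radar_id, angle, chest_distance) tuples.
    """
    out = []
    for radar in scene.radars:
        if not in_detection_area(subject["chest"], radar, scene):
            continue
        ang = orientation_angle(
            subject["l_shoulder"], subject["r_shoulder"], radar.position
        )
        dist = distance_to_radar(subject["chest"], radar.position)
        out.append((abs(ang - 90.0), radar.id, ang, dist))
    out.sort()
    return out


def assign_radars(subjects: dict[int, dict], scene: SceneConfig) -> list[RadarAssignment]:
    """Assign one radar (or none) to every stationary subject.

    ``subjects`` maps subject_id -> {"chest", "l_shoulder", "r_shoulder"}
    points in the reference frame. Each subject initially receives the
    covering radar whose orientation angle is closest to 90 deg (ties broken
    by lower radar id). Conflicts - two subjects on the same radar with
    chest distances closer than ``scene.min_separation_m`` - are resolved by
    demoting the subject whose angle is farther from 90 deg to its next-best
    covering radar, repeatedly, until no conflict remains; a subject with no
    viable radar left is reported uncovered. The result is independent of
    the iteration order of ``subjects``.
    """
    cand = {sid: _candidates(subj, scene) for sid, subj in sorted(subjects.items())}
    choice = {sid: 0 for sid in cand}  # index into each candidate list

    def current(sid):
        lst = cand[sid]
        i = choice[sid]
        return lst[i] if i < len(lst) else None

    while True:
        # group assigned subjects by radar
        by_radar: dict[int, list[int]] = {}
        for sid in cand:
            c = current(sid)
            if c is not None:
                by_radar.setdefault(c[1], []).append(sid)
        conflict = None
        for radar_id in sorted(by_radar):
            sids = by_radar[radar_id]
            for i, a in enumerate(sids):
                for b in sids[i + 1 :]:
                    if abs(current(a)[3] - current(b)[3]) < scene.min_separation_m:
                        # the subject facing the radar less squarely yields;
                        # ties broken by higher subject id for determinism
                        loser = max(a, b, key=lambda s: (current(s)[0], s))
                        conflict = loser
                        break
                if conflict is not None:
                    break
            if conflict is not None:
                break
        if conflict is None:
            break
        choice[conflict] += 1

    out = []
    for sid in sorted(cand):
        c = current(sid)
        if c is None:
            out.append(
                RadarAssignment(
                    subject_id=sid,
                    radar_id=None,
                    orientation_angle_deg=None,
                    chest_distance_m=None,
                    reason=UNCOVERED,
                )
            )
        else:
            reason = BEST_ANGLE if choice[sid] == 0 else FALLBACK_SEPARATION
            out.append(
                RadarAssignment(
                    subject_id=sid,
                    radar_id=c[1],
                    orientation_angle_deg=c[2],
                    chest_distance_m=c[3],
                    reason=reason,
                )
            )
    return out
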