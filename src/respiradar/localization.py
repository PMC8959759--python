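"""Subject localization from depth-camera skeletons.

The camera is mounted on a pole and tilted downwards about its x-axis by an
angle ``A`` (negative for a downward tilt; -30 deg here). Joint coordinates
therefore arrive in a *rotated* frame and are mapped back to the reference
frame with the standard x-axis rotation matrix

    [1    0       0   ]
    [0  cos A  -sin A ]
    [0  sin A   cos A ]

After the transform, Euclidean joint-radar distances and the shoulder
midpoint are straightforward geometry. A threshold on the average speed of
the shoulder midpoint classifies each subject as moving or stationary; only
stationary subjects proceed to respiratory analysis.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np

from .types import REFERENCE, ROTATED, SkeletonSample, as_point

logger = logging.getLogger(__name__)

MOVING = "moving"
STATIONARY = "stationary"


def _rotation_matrix(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rotate_to_reference(p_rot, angle_deg: float) -> np.ndarray:
    """Map a point from the rotated (tilted) camera frame to the reference
    frame by rotating about the x-axis by ``angle_deg``."""
    return _rotation_matrix(angle_deg) @ as_point(p_rot)


def rotate_to_rotated(p_ref, angle_deg: float) -> np.ndarray:
    """Inverse of :func:`rotate_to_reference` (rotation by ``-angle_deg``)."""
    return _rotation_matrix(-angle_deg) @ as_point(p_ref)


def transform_sample(sample: SkeletonSample, angle_deg: float) -> SkeletonSample:
    """Transform all three joints of a skeleton sample to the reference frame."""
    if sample.frame == REFERENCE:
        return sample
    return SkeletonSample(
        t=sample.t,
        subject_id=sample.subject_id,
        chest=rotate_to_reference(sample.chest, angle_deg),
        l_shoulder=rotate_to_reference(sample.l_shoulder, angle_deg),
        r_shoulder=rotate_to_reference(sample.r_shoulder, angle_deg),
        frame=REFERENCE,
    )


def distance_to_radar(joint, radar_pos) -> float:
    """Euclidean distance (m) between a joint and a radar, both in the
    reference frame."""
    return float(np.linalg.norm(as_point(joint) - as_point(radar_pos)))


def shoulder_midpoint(l_shoulder, r_shoulder) -> np.ndarray:
    """Midpoint of the two shoulders; the reference point for motion
    detection."""
    return (as_point(l_shoulder) + as_point(r_shoulder)) / 2.0


def detect_motion(
    midpoints: Sequence[tuple[float, np.ndarray]],
    threshold_mps: float = 0.7,
) -> str:
    """Classify a trajectory of (time, shoulder-midpoint) pairs.

    Average speed is total path length divided by elapsed time; the subject
    is ``moving`` iff it exceeds ``threshold_mps`` (0.7 m/s, about a slow
    walking speed). Path length, rather than net displacement, is used so
    that back-and-forth fidgeting is not mistaken for stillness.
    """
    if len(midpoints) < 2:
        logger.debug("motion detection with <2 samples; assuming stationary")
        return STATIONARY
    pts = sorted(midpoints, key=lambda tp: tp[0])
    elapsed = pts[-1][0] - pts[0][0]
    if elapsed <= 0:
        return STATIONARY
    path = sum(
        float(np.linalg.norm(as_point(b[1]) - as_point(a[1])))
        for a, b in zip(pts[:-1], pts[1:])
    )
    return MOVING if path / elapsed > threshold_mps else STATIONARY
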