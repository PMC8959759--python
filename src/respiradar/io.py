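"""CSV readers and writers for the pipeline's on-disk formats.

One file per radar (plain numeric CSV: rows = slow-time samples, one column
per range bin), one skeleton file (long format: time_s, subject_id,
joint_name, x, y, z in the rotated camera frame), a training-database file
(label plus one column per chunk sample) and the flat per-window result log.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import RANGE_RES_M, SLOW_RATE_HZ, RadarFrameMatrix, RespChunk, SkeletonSample

logger = logging.getLogger(__name__)


def radar_csv_name(radar_id: int) -> str:
    return f"radar_{radar_id}.csv"


def write_radar_csv(matrix: RadarFrameMatrix, path: str | Path) -> None:
    np.savetxt(path, matrix.values, fmt="%.6g", delimiter=",")


def read_radar_csv(
    path: str | Path,
    radar_id: int,
    slow_rate: float = SLOW_RATE_HZ,
    range_res_m: float = RANGE_RES_M,
    t0: float = 0.0,
) -> RadarFrameMatrix:
    values = np.loadtxt(path, delimiter=",", ndmin=2)
    return RadarFrameMatrix(
        radar_id=radar_id,
        values=values,
        slow_rate=slow_rate,
        range_res_m=range_res_m,
        t0=t0,
    )


def write_skeleton_csv(samples: list[SkeletonSample], path: str | Path) -> None:
    rows = []
    for s in samples:
        for joint in ("chest", "l_shoulder", "r_shoulder"):
            p = getattr(s, joint)
            rows.append(
                {
                    "time_s": s.t,
                    "subject_id": s.subject_id,
                    "joint_name": joint,
                    "x": p[0],
                    "y": p[1],
                    "z": p[2],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_skeleton_csv(path: str | Path, frame: str = "rotated") -> list[SkeletonSample]:
    """Read a skeleton stream; rows with missing joints are dropped with a
    warning rather than failing the whole file."""
    df = pd.read_csv(path)
    required = {"time_s", "subject_id", "joint_name", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"skeleton CSV missing columns: {sorted(missing)}")
    samples: list[SkeletonSample] = []
    for (t, sid), grp in df.groupby(["time_s", "subject_id"], sort=True):
        joints = {
            row.joint_name: np.array([row.x, row.y, row.z])
            for row in grp.itertuples()
        }
        if not {"chest", "l_shoulder", "r_shoulder"} <= set(joints):
            logger.warning(
                "skipping skeleton frame t=%s subject=%s: missing joints", t, sid
            )
            continue
        samples.append(
            SkeletonSample(
                t=float(t),
                subject_id=int(sid),
                chest=joints["chest"],
                l_shoulder=joints["l_shoulder"],
                r_shoulder=joints["r_shoulder"],
                frame=frame,
            )
        )
    return samples


def write_training_csv(
    chunks: list[RespChunk], labels: list[str], path: str | Path
) -> None:
    n = len(chunks[0].samples)
    cols = {"label": labels}
    data = np.stack([c.samples for c in chunks])
    for i in range(n):
        cols[f"s{i}"] = data[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_training_csv(
    path: str | Path, rate_hz: float = SLOW_RATE_HZ
) -> tuple[list[RespChunk], list[str]]:
    df = pd.read_csv(path)
    labels = df["label"].tolist()
    values = df.drop(columns=["label"]).to_numpy(dtype=float)
    chunks = [RespChunk(samples=row, rate_hz=rate_hz) for row in values]
    return chunks, labels


def write_window_log(results: list, path: str | Path) -> None:
    """Flatten WindowResult records into one auditable CSV row per
    (window, subject)."""
    rows = []
    for r in results:
        a = r.assignment
        rows.append(
            {
                "window_index": r.window_index,
                "t_start": r.t_start,
                "t_end": r.t_end,
                "subject_id": r.subject_id,
                "status": r.status,
                "radar_id": "" if a is None or a.radar_id is None else a.radar_id,
                "orientation_angle_deg": ""
                if a is None or a.orientation_angle_deg is None
                else round(a.orientation_angle_deg, 3),
                "chest_distance_m": ""
                if a is None or a.chest_distance_m is None
                else round(a.chest_distance_m, 4),
                "assign_reason": "" if a is None else a.reason,
                "label": "" if r.label is None else r.label.label,
                "label_source": "" if r.label is None else r.label.source,
                "rr_bpm": "" if r.rr_bpm is None else round(r.rr_bpm, 3),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
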