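"""Stream preprocessing: resampling, background subtraction, SVD clutter
removal.

All sensors are brought to a common 17 Hz slow-time rate. Static clutter
(echoes from walls and furniture, constant along slow time) is removed in
two stages: subtraction of a per-bin background estimate, then truncation of
the dominant singular component(s) of the matrix, which captures whatever
static structure the background estimate missed.
"""

from __future__ import annotations

import numpy as np

from .types import RadarFrameMatrix, SLOW_RATE_HZ


def resample(signal, src_rate: float, dst_rate: float = SLOW_RATE_HZ) -> np.ndarray:
    """Linearly resample a 1-D signal from ``src_rate`` to ``dst_rate``.

    The output spans the same duration as the input; the breathing band
    (< 0.5 Hz) is far below Nyquist at 17 Hz so linear interpolation is
    adequate.
    """
    if src_rate <= 0 or dst_rate <= 0:
        raise ValueError("sampling rates must be positive")
    x = np.asarray(signal, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 samples to resample")
    duration = x.size / src_rate
    n_out = int(round(duration * dst_rate))
    t_src = np.arange(x.size) / src_rate
    t_dst = np.arange(n_out) / dst_rate
    return np.interp(t_dst, t_src, x)


def estimate_background(matrix: RadarFrameMatrix, prefix_s: float = 5.0) -> np.ndarray:
    """Per-bin mean amplitude over a calibration prefix (default the first
    5 s), or over the whole recording if it is shorter than the prefix."""
    n = int(round(prefix_s * matrix.slow_rate))
    rows = matrix.values[:n] if n >= 1 and matrix.n_samples >= n else matrix.values
    return rows.mean(axis=0)


def remove_background(matrix: RadarFrameMatrix, background) -> RadarFrameMatrix:
    """Subtract a per-bin background amplitude vector from every slow-time
    row."""
    bg = np.asarray(background, dtype=float).ravel()
    if bg.size != matrix.n_bins:
        raise ValueError(
            f"background length {bg.size} != number of range bins {matrix.n_bins}"
        )
    return RadarFrameMatrix(
        radar_id=matrix.radar_id,
        values=matrix.values - bg[None, :],
        slow_rate=matrix.slow_rate,
        range_res_m=matrix.range_res_m,
        t0=matrix.t0,
    )


def svd_clutter_removal(
    matrix: RadarFrameMatrix, n_components: int = 1
) -> RadarFrameMatrix:
    """Subtract the top ``n_components`` singular triplets of the matrix.

    Static clutter is (near-)constant along slow time, hence concentrated in
    the leading singular component; removing it leaves the micro-motion
    signal. ``n_components=0`` is the identity.
    """
    rows, cols = matrix.values.shape
    if n_components < 0 or n_components >= min(rows, cols):
        raise ValueError(
            f"n_components must be in [0, {min(rows, cols)}), got {n_components}"
        )
    if n_components == 0:
        return matrix
    u, s, vt = np.linalg.svd(matrix.values, full_matrices=False)
    k = n_components
    clutter = (u[:, :k] * s[:k]) @ vt[:k]
    return RadarFrameMatrix(
        radar_id=matrix.radar_id,
        values=matrix.values - clutter,
        slow_rate=matrix.slow_rate,
        range_res_m=matrix.range_res_m,
        t0=matrix.t0,
    )


def preprocess_matrix(
    matrix: RadarFrameMatrix,
    background: np.ndarray | None = None,
    n_components: int = 1,
) -> RadarFrameMatrix:
    """Standard radar-matrix cleanup for one analysis window.

    SVD clutter removal is applied to the raw matrix, where static clutter —
    constant along slow time and spread over all bins — dominates the
    leading singular component by orders of magnitude over the single-bin
    breathing signal. Any residual per-bin bias is then removed by
    background subtraction. (Subtracting an accurate background *first*
    would promote the breathing signal itself to the dominant component and
    the SVD step would strip it.)
    """
    cleaned = svd_clutter_removal(matrix, n_components)
    bg = estimate_background(cleaned) if background is None else background
    return remove_background(cleaned, bg)
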