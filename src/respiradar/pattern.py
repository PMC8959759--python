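"""Respiration-pattern classification and the morphological discriminator.

Each 15-s chunk is classified into one of five patterns — eupnea (normal
breathing), Cheyne-Stokes respiration (CSR), Kussmaul respiration, apnea,
and non-stationary (movement artifacts or respiration-irrelevant signal) —
in two stages:

1. A random-forest classifier (100 trees) over 13 statistical features:
   signal-peak statistics, instantaneous-frequency statistics from the
   Hilbert analytic phase, and short-term energies of 5-s segments.
2. A morphological discriminator that can override the classifier:
   a signal quality index (SQI) rejects chunks without regular, prominent
   breaths (relabelled non-stationary), and a crescendo/decrescendo test on
   peak amplitudes confirms or demotes CSR labels (a failed CSR becomes
   eupnea).

The SQI breath detector — median filter (kernel 5), min-max normalisation
to [0, 1], peak/trough detection at prominence > 0.15, a valid breath being
two consecutive peaks enclosing a trough — is the single breath detector of
the package; respiration-rate estimation reuses it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from scipy.signal import find_peaks, hilbert, medfilt
from sklearn.ensemble import RandomForestClassifier

from .types import RespChunk

PATTERNS = ("eupnea", "csr", "kussmaul", "apnea", "nonstationary")

CLASSIFIER = "classifier"
DISCRIMINATOR_OVERRIDE = "discriminator_override"

#: prominence threshold for breath peaks/troughs on a [0,1]-normalised signal
PEAK_PROMINENCE = 0.15
#: SQI limit on the normalised standard deviation of breath intervals
MAX_INTERVAL_NSD = 0.25
#: SQI minimum number of valid breaths per 15-s chunk
MIN_VALID_BREATHS = 3

FEATURE_NAMES = (
    "peak_amp_variability",
    "peak_amp_mean",
    "peak_amp_max",
    "n_peaks",
    "if_variability",
    "if_mean",
    "if_max",
    "if_min",
    "if_range",
    "ste_variability",
    "ste_max",
    "ste_min",
    "ste_range",
)


@dataclass
class PatternLabel:
    label: str
    source: str = CLASSIFIER

    def __post_init__(self) -> None:
        if self.label not in PATTERNS:
            raise ValueError(f"unknown pattern label {self.label!r}")


@dataclass
class QualityReport:
    """Outcome of the SQI evaluation of one chunk."""

    n_valid_breaths: int
    breath_intervals_s: list[float]
    interval_nsd: float
    passed: bool


@dataclass
class FeatureVector:
    peak_amp_variability: float
    peak_amp_mean: float
    peak_amp_max: float
    n_peaks: float
    if_variability: float
    if_mean: float
    if_max: float
    if_min: float
    if_range: float
    ste_variability: float
    ste_max: float
    ste_min: float
    ste_range: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


# --------------------------------------------------------------- detection


def normalize_unit(x: np.ndarray) -> np.ndarray:
    """Min-max normalise to [0, 1]; a zero-range signal maps to zeros."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def detect_breath_extrema(
    samples: np.ndarray, median_kernel: int | None = 5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Detect prominent peaks and troughs of a respiratory signal.

    Returns ``(peaks, troughs, filtered)``: indices of peaks and troughs on
    the median-filtered, [0,1]-normalised signal (prominence > 0.15), plus
    the filtered-normalised signal itself.
    """
    x = np.asarray(samples, dtype=float)
    if median_kernel is not None and x.size >= median_kernel:
        x = medfilt(x, kernel_size=median_kernel)
    x = normalize_unit(x)
    if x.max() == x.min():
        return np.array([], dtype=int), np.array([], dtype=int), x
    peaks, _ = find_peaks(x, prominence=PEAK_PROMINENCE)
    troughs, _ = find_peaks(-x, prominence=PEAK_PROMINENCE)
    return peaks, troughs, x


# ---------------------------------------------------------------- features


def extract_features(chunk: RespChunk) -> FeatureVector:
    """Compute the 13 statistical features of one chunk.

    Peak amplitudes are measured on the mean-subtracted raw signal at the
    locations found by the shared breath detector (run here without the
    median filter: the classifier sees the resampled, clutter-removed chunk
    as-is). Instantaneous frequency is the derivative of the unwrapped
    analytic-signal phase over 2*pi, with 0.5 s discarded at each end to
    avoid Hilbert edge artifacts. Short-term energies are taken over three
    non-overlapping 5-s segments.
    """
    x = np.asarray(chunk.samples, dtype=float)
    rate = chunk.rate_hz
    if x.size < 2 * rate:
        raise ValueError("chunk too short for feature extraction")
    detrended = x - x.mean()

    flat = x.max() == x.min()

    # time-domain (signal peak) features
    peaks, _, _ = detect_breath_extrema(x, median_kernel=None)
    if peaks.size == 0:
        pk_var = pk_mean = pk_max = 0.0
    else:
        amps = detrended[peaks]
        pk_var = float(np.std(amps))
        pk_mean = float(np.mean(amps))
        pk_max = float(np.max(amps))

    # time-frequency features: instantaneous frequency via Hilbert transform
    if flat:
        if_var = if_mean = if_max = if_min = 0.0
    else:
        phase = np.unwrap(np.angle(hilbert(detrended)))
        inst_f = np.diff(phase) * rate / (2.0 * np.pi)
        edge = int(round(0.5 * rate))
        core = inst_f[edge : inst_f.size - edge] if inst_f.size > 2 * edge else inst_f
        if_var = float(np.std(core))
        if_mean = float(np.mean(core))
        if_max = float(np.max(core))
        if_min = float(np.min(core))

    # short-term energy over 5-s segments (three per 15-s chunk)
    seg_len = int(round(5.0 * rate))
    n_seg = max(x.size // seg_len, 1)
    energies = [
        float(np.sum(detrended[i * seg_len : (i + 1) * seg_len] ** 2))
        for i in range(n_seg)
    ]
    ste_var = float(np.std(energies))
    ste_max = float(np.max(energies))
    ste_min = float(np.min(energies))

    return FeatureVector(
        peak_amp_variability=pk_var,
        peak_amp_mean=pk_mean,
        peak_amp_max=pk_max,
        n_peaks=float(peaks.size),
        if_variability=if_var,
        if_mean=if_mean,
        if_max=if_max,
        if_min=if_min,
        if_range=if_max - if_min,
        ste_variability=ste_var,
        ste_max=ste_max,
        ste_min=ste_min,
        ste_range=ste_max - ste_min,
    )


# -------------------------------------------------------------- classifier


class PatternClassifier:
    """Random-forest respiration-pattern classifier (default 100 trees)."""

    def __init__(self, n_trees: int = 100, seed: int | None = 0):
        self.model = RandomForestClassifier(n_estimators=n_trees, random_state=seed)

    def fit(self, features: list[FeatureVector], labels: list[str]) -> "PatternClassifier":
        if len(set(labels)) < 2:
            raise ValueError("training database must contain at least 2 classes")
        X = np.stack([f.to_array() for f in features])
        self.model.fit(X, np.asarray(labels))
        return self

    def predict(self, features: FeatureVector | list[FeatureVector]) -> list[str]:
        single = isinstance(features, FeatureVector)
        fv = [features] if single else features
        X = np.stack([f.to_array() for f in fv])
        return list(self.model.predict(X))

    def save(self, path: str | Path) -> None:
        joblib.dump(self.model, path)

    @classmethod
    def load(cls, path: str | Path) -> "PatternClassifier":
        obj = cls.__new__(cls)
        obj.model = joblib.load(path)
        return obj


def train_classifier(
    features: list[FeatureVector],
    labels: list[str],
    n_trees: int = 100,
    seed: int | None = 0,
) -> PatternClassifier:
    """Train the random-forest pattern classifier on a labelled database."""
    return PatternClassifier(n_trees=n_trees, seed=seed).fit(features, labels)


def classify(model: PatternClassifier, features: FeatureVector) -> PatternLabel:
    return PatternLabel(label=model.predict(features)[0], source=CLASSIFIER)


# ----------------------------------------------------------- discriminator


def evaluate_signal_quality(chunk: RespChunk) -> QualityReport:
    """Morphological signal quality index of one chunk.

    Valid breaths are consecutive prominent peaks enclosing at least one
    prominent trough. The chunk passes iff there are >= 3 valid breath
    intervals and their normalised standard deviation (SD/mean) is < 0.25.
    """
    x = np.asarray(chunk.samples, dtype=float)
    if x.size < 5:
        raise ValueError("chunk too short for quality evaluation")
    peaks, troughs, _ = detect_breath_extrema(x, median_kernel=5)

    intervals: list[float] = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        if np.any((troughs > a) & (troughs < b)):
            intervals.append(float((b - a) / chunk.rate_hz))
    n_valid = len(intervals)
    if n_valid >= 2 and np.mean(intervals) > 0:
        nsd = float(np.std(intervals) / np.mean(intervals))
    else:
        nsd = float("inf") if n_valid == 0 else 0.0
    passed = nsd < MAX_INTERVAL_NSD and n_valid >= MIN_VALID_BREATHS
    return QualityReport(
        n_valid_breaths=n_valid,
        breath_intervals_s=intervals,
        interval_nsd=nsd,
        passed=passed,
    )


def evaluate_csr_pattern(chunk: RespChunk) -> bool:
    """Crescendo/decrescendo test for Cheyne-Stokes morphology.

    Let the maximum-amplitude peak be the boundary; the chunk matches CSR
    iff peak amplitudes strictly increase up to the boundary and strictly
    decrease after it. (A pure crescendo or pure decrescendo phase — the
    boundary at an end — satisfies this vacuously on the empty side.)
    """
    peaks, _, filtered = detect_breath_extrema(chunk.samples, median_kernel=5)
    if peaks.size < 2:
        return False
    amps = filtered[peaks]
    b = int(np.argmax(amps))
    before = amps[: b + 1]
    after = amps[b:]
    return bool(np.all(np.diff(before) > 0) and np.all(np.diff(after) < 0))


def discriminate(classifier_label: PatternLabel, chunk: RespChunk) -> PatternLabel:
    """Apply the morphological discriminator to a classifier label.

    Apnea bypasses the quality gate (a true apnea chunk has too few breaths
    to ever pass it). Otherwise a chunk failing the SQI is relabelled
    non-stationary; a CSR label additionally requires the crescendo/
    decrescendo test, demoting to eupnea when it fails.
    """
    label = classifier_label.label
    if label == "apnea":
        return classifier_label
    quality = evaluate_signal_quality(chunk)
    if not quality.passed:
        final = "nonstationary"
    elif label == "csr":
        final = "csr" if evaluate_csr_pattern(chunk) else "eupnea"
    else:
        final = label
    if final == label:
        return classifier_label
    return PatternLabel(label=final, source=DISCRIMINATOR_OVERRIDE)
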