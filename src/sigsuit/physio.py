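"""Physiological signal-quality assessment for ECG segments.

Three R-peak detectors from distinct algorithm families are run on each
10-s ECG segment, and three plausibility conditions are checked on the
beat-to-beat (RR) intervals of each detector's output:

1. the estimated heart rate lies in the adult range [40, 180] beats/min
   (HR = 60 / mean RR by default; median RR available);
2. no RR interval exceeds 3 s (at most one missed beat);
3. max(RR) / min(RR) <= 2.2.

Each condition is voted over the three detectors (majority: at least 2
of 3); a segment is of good quality iff all three condition votes pass.
Bounds are non-strict.  A detector that finds fewer than two beats has
no RR interval and fails all conditions (condition 3 needs at least two
intervals, hence three beats).

The bundled detectors are re-implementations in the families commonly
used for this task — a Pan-Tompkins-style derivative/energy detector, a
two-moving-averages detector, and a stationary-wavelet-detail detector —
not clones of any specific third-party tool.  ``assess_quality`` also
accepts externally supplied beat lists, so annotation files or other
detectors can be plugged in unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pywt
from scipy import signal as sp_signal

from .exceptions import ConfigurationError, ModalityError
from .segmentation import Modality, Segment

__all__ = [
    "BeatSequence",
    "PhysioResult",
    "DETECTOR_IDS",
    "detect_qrs",
    "condition_hr",
    "condition_max_gap",
    "condition_rr_ratio",
    "assess_quality",
    "physio_summary",
    "beats_from_table",
]

DETECTOR_IDS = (1, 2, 3)

HR_BOUNDS = (40.0, 180.0)      # beats/min, Condition 1
MAX_RR_GAP_S = 3.0             # seconds, Condition 2
MAX_RR_RATIO = 2.2             # Condition 3


@dataclass(frozen=True)
class BeatSequence:
    """Ordered R-peak times (seconds from segment start) of one detector."""

    detector_id: int | str
    beat_times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.beat_times, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ConfigurationError("beat times must be strictly increasing")
        object.__setattr__(self, "beat_times", t)

    @property
    def rr(self) -> np.ndarray:
        """RR intervals in seconds."""
        return np.diff(self.beat_times)


@dataclass(frozen=True)
class PhysioResult:
    """Per-detector beats and condition outcomes for one ECG segment."""

    beats: dict
    per_condition: dict          # detector_id -> (c1, c2, c3)
    condition_votes: tuple       # majority vote per condition
    good_quality: bool


def _beat_array(beats) -> np.ndarray:
    if isinstance(beats, BeatSequence):
        return beats.beat_times
    return np.asarray(beats, dtype=float)


def condition_hr(
    beats, bounds: tuple[float, float] = HR_BOUNDS, estimator: str = "mean"
) -> bool:
    """Condition 1: estimated heart rate within the plausible adult range."""
    t = _beat_array(beats)
    if t.size < 2:
        return False
    rr = np.diff(t)
    rr_rep = float(np.mean(rr)) if estimator == "mean" else float(np.median(rr))
    hr = 60.0 / rr_rep
    return bool(bounds[0] <= hr <= bounds[1])


def condition_max_gap(beats, max_gap_s: float = MAX_RR_GAP_S) -> bool:
    """Condition 2: no beat-to-beat interval longer than ``max_gap_s``."""
    t = _beat_array(beats)
    if t.size < 2:
        return False
    return bool(np.diff(t).max() <= max_gap_s)


def condition_rr_ratio(beats, max_ratio: float = MAX_RR_RATIO) -> bool:
    """Condition 3: max(RR)/min(RR) bounded; needs at least two intervals."""
    t = _beat_array(beats)
    if t.size < 3:
        return False
    rr = np.diff(t)
    return bool(rr.max() / rr.min() <= max_ratio)


# --------------------------------------------------------------------------
# R-peak detectors
# --------------------------------------------------------------------------

_REFINE_S = 0.10       # half-width of the raw-signal refinement window
_MIN_RR_S = 0.25       # refractory period, 240 beats/min


def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 2) -> np.ndarray:
    hi = min(hi, 0.45 * fs)
    if hi <= lo:
        return x - np.mean(x)
    sos = sp_signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sp_signal.sosfiltfilt(sos, x)


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    w = max(1, w)
    return np.convolve(x, np.ones(w) / w, mode="same")


def _refine_peaks(x: np.ndarray, fs: float, candidates: np.ndarray) -> np.ndarray:
    """Snap candidate indices to the raw-signal maximum nearby, dedupe."""
    if candidates.size == 0:
        return candidates
    half = int(round(_REFINE_S * fs))
    refined = []
    for c in candidates:
        a, b = max(0, c - half), min(x.size, c + half + 1)
        refined.append(a + int(np.argmax(x[a:b])))
    refined = np.unique(refined)
    # enforce the refractory period, keeping the taller peak of close pairs
    keep: list[int] = []
    min_gap = int(round(_MIN_RR_S * fs))
    for idx in refined:
        if keep and idx - keep[-1] < min_gap:
            if x[idx] > x[keep[-1]]:
                keep[-1] = int(idx)
        else:
            keep.append(int(idx))
    return np.asarray(keep, dtype=int)


def _detect_pan_tompkins(x: np.ndarray, fs: float) -> np.ndarray:
    """Derivative/energy detector in the Pan-Tompkins family."""
    y = _bandpass(x, fs, 5.0, 15.0)
    energy = np.gradient(y) ** 2
    integ = _moving_average(energy, int(round(0.15 * fs)))
    if integ.max() <= 0:
        return np.empty(0, dtype=int)
    peaks, _ = sp_signal.find_peaks(
        integ, height=0.25 * integ.max(), distance=max(1, int(round(_MIN_RR_S * fs)))
    )
    return peaks


def _detect_two_moving_averages(x: np.ndarray, fs: float) -> np.ndarray:
    """Event/background moving-average comparison on squared bandpassed ECG."""
    y = _bandpass(x, fs, 8.0, 20.0, order=3)
    s = y * y
    ma_qrs = _moving_average(s, int(round(0.12 * fs)))
    ma_beat = _moving_average(s, int(round(0.60 * fs)))
    if s.max() <= 0:
        return np.empty(0, dtype=int)
    above = ma_qrs > ma_beat + 0.08 * s.mean()
    edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False])).astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    min_width = int(round(0.08 * fs))
    peaks = [a + int(np.argmax(s[a:b])) for a, b in zip(starts, ends) if b - a >= min_width]
    return np.asarray(peaks, dtype=int)


def _detect_swt(x: np.ndarray, fs: float) -> np.ndarray:
    """Stationary-wavelet-detail energy detector (filter-bank family)."""
    # pick the decomposition level whose detail band covers ~8-16 Hz
    level = int(np.clip(round(np.log2(fs / 16.0)), 1, 8))
    pad = (-x.size) % (1 << level)
    xp = np.pad(x, (0, pad), mode="edge") if pad else x
    coeffs = pywt.swt(xp, "db3", level=level, trim_approx=False, norm=True)
    detail = coeffs[0][1][: x.size]
    energy = _moving_average(detail * detail, int(round(0.10 * fs)))
    if energy.max() <= 0:
        return np.empty(0, dtype=int)
    peaks, _ = sp_signal.find_peaks(
        energy, height=0.20 * energy.max(), distance=max(1, int(round(_MIN_RR_S * fs)))
    )
    return peaks


_DETECTORS = {
    1: _detect_pan_tompkins,
    2: _detect_two_moving_averages,
    3: _detect_swt,
}


def detect_qrs(segment: Segment, detector_id: int) -> BeatSequence:
    """Run one of the three bundled R-peak detectors on an ECG segment.

    Returns a possibly empty, strictly increasing list of R-peak times in
    seconds from segment start; deterministic on fixed input.
    """
    if segment.modality is not Modality.ECG:
        raise ModalityError(f"QRS detection requires ECG, got {segment.modality}")
    if detector_id not in _DETECTORS:
        raise ConfigurationError(f"unknown detector id {detector_id!r}")
    x = segment.samples
    if x.size < 2 or x.max() == x.min():
        return BeatSequence(detector_id, np.empty(0))
    candidates = _DETECTORS[detector_id](x, segment.fs)
    idx = _refine_peaks(x, segment.fs, candidates)
    return BeatSequence(detector_id, idx / segment.fs)


def assess_quality(
    segment: Optional[Segment] = None,
    detectors: Sequence[int] = DETECTOR_IDS,
    external_beats: Optional[Iterable[BeatSequence]] = None,
    hr_estimator: str = "mean",
) -> PhysioResult:
    """Evaluate the three plausibility conditions with majority voting.

    Either a segment (the bundled detectors run on it) or an iterable of
    externally supplied :class:`BeatSequence` objects must be given.
    """
    if external_beats is not None:
        sequences = list(external_beats)
    elif segment is not None:
        sequences = [detect_qrs(segment, d) for d in detectors]
    else:
        raise ConfigurationError("assess_quality needs a segment or external beats")
    if not sequences:
        raise ConfigurationError("no beat sequences to assess")
    per_condition = {
        seq.detector_id: (
            condition_hr(seq, estimator=hr_estimator),
            condition_max_gap(seq),
            condition_rr_ratio(seq),
        )
        for seq in sequences
    }
    majority = (len(sequences) // 2) + 1
    votes = tuple(
        sum(flags[i] for flags in per_condition.values()) >= majority for i in range(3)
    )
    return PhysioResult(
        beats={seq.detector_id: seq for seq in sequences},
        per_condition=per_condition,
        condition_votes=votes,
        good_quality=all(votes),
    )


def physio_summary(results: Iterable[PhysioResult | bool]) -> float:
    """Percentage of ECG segments labelled good quality."""
    labels = [
        r.good_quality if isinstance(r, PhysioResult) else bool(r) for r in results
    ]
    if not labels:
        raise ConfigurationError("physio_summary requires at least one segment")
    return 100.0 * sum(labels) / len(labels)


def beats_from_table(table, fs: float | None = None) -> BeatSequence:
    """Build a BeatSequence from an annotation table (detector bypass).

    ``table`` is a pandas DataFrame or a path to a CSV with a ``time_s``
    column, or a ``sample_index`` column combined with ``fs``.
    """
    import pandas as pd

    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table)
    if "time_s" in df.columns:
        times = df["time_s"].to_numpy(dtype=float)
    elif "sample_index" in df.columns:
        if fs is None:
            raise ConfigurationError("fs is required with sample_index annotations")
        times = df["sample_index"].to_numpy(dtype=float) / fs
    else:
        raise ConfigurationError("annotation table needs a time_s or sample_index column")
    return BeatSequence("external", np.sort(times))
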