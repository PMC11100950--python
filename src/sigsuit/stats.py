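"""Statistical signal-quality indicators.

Six numerical per-segment statistics:

* upper/lower **envelope std** — the segment is min-max scaled to
  [-1, 1], split into consecutive non-overlapping sub-windows (2 s for
  ECG/EEG, 5 s for respiration), and the sample standard deviation
  (N-1 denominator) of the per-sub-window maxima (upper) and minima
  (lower) is reported; noisy peaks inflate both.
* **skewness** / **kurtosis** — standardized third and fourth moments of
  the amplitude distribution; kurtosis uses the non-excess convention
  (Gaussian -> 3).  The moments use the population (N) normalization for
  sigma by default; ``sigma_ddof=1`` selects the sample convention.
* **spectral entropy** — Shannon entropy of the normalized power
  spectral density in bits, scaled by log2(M) (the white-noise maximum
  over M frequency bins) into [0, 1].  The PSD is a one-sided periodogram
  of the raw, unwindowed, undetrended segment (segmentation is the only
  preprocessing anywhere in the pipeline), DC bin included.
* **zero-crossing rate** — fraction of adjacent sample pairs whose
  product is strictly negative, count / (N-1); exact zeros contribute no
  crossing.

Degenerate segments (zero variance / zero power) yield ``nan`` for the
statistics that are undefined there; summaries exclude ``nan``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .exceptions import ConfigurationError
from .segmentation import Modality, Segment

__all__ = [
    "NOT_COMPUTABLE",
    "SUBWINDOW_S",
    "StatResult",
    "StatSummary",
    "envelope_std",
    "skewness",
    "kurtosis",
    "spectral_entropy",
    "entropy_from_psd",
    "zero_crossing_rate",
    "compute_stats",
    "stat_summary",
]

#: Sentinel for statistics that are undefined on a segment.
NOT_COMPUTABLE = float("nan")

#: Envelope sub-window length in seconds per modality.
SUBWINDOW_S = {
    Modality.EEG: 2.0,
    Modality.ECG: 2.0,
    Modality.RESP_CAPNO: 5.0,
    Modality.RESP_AIRFLOW: 5.0,
}

STAT_NAMES = ("skewness", "kurtosis", "entropy", "zcr", "upper_env_std", "lower_env_std")


@dataclass(frozen=True)
class StatResult:
    """The six statistical SQIs of one segment.

    ``degenerate`` marks a constant segment, where the envelope scaling
    is undefined and (0, 0) is reported by convention.
    """

    skewness: float
    kurtosis: float
    entropy: float
    zcr: float
    upper_env_std: float
    lower_env_std: float
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in STAT_NAMES}


def _samples(segment) -> np.ndarray:
    return segment.samples if isinstance(segment, Segment) else np.asarray(segment, float)


def envelope_std(
    segment: Segment | np.ndarray,
    fs: float | None = None,
    subwindow_s: float | None = None,
) -> tuple[float, float]:
    """Std of the per-sub-window maxima and minima of the scaled segment.

    Returns ``(upper_env_std, lower_env_std)``; a constant segment (zero
    amplitude range) is degenerate and returns ``(0.0, 0.0)``.
    """
    if isinstance(segment, Segment):
        fs = segment.fs
        if subwindow_s is None:
            subwindow_s = SUBWINDOW_S[segment.modality]
    elif fs is None or subwindow_s is None:
        raise ConfigurationError("fs and subwindow_s are required for bare arrays")
    x = _samples(segment)
    w = int(round(subwindow_s * fs))
    if w < 1:
        raise ConfigurationError("sub-window shorter than one sample")
    k = x.size // w
    if k < 2:
        raise ConfigurationError("segment must span at least two sub-windows")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return 0.0, 0.0
    y = 2.0 * (x - lo) / (hi - lo) - 1.0
    blocks = y[: k * w].reshape(k, w)
    upper = float(blocks.max(axis=1).std(ddof=1))
    lower = float(blocks.min(axis=1).std(ddof=1))
    return upper, lower


def skewness(segment: Segment | np.ndarray, sigma_ddof: int = 0) -> float:
    """Standardized third moment; ``nan`` when the std is zero."""
    x = _samples(segment)
    sig = x.std(ddof=sigma_ddof)
    if sig == 0.0 or not np.isfinite(sig):
        return NOT_COMPUTABLE
    return float(np.mean(((x - x.mean()) / sig) ** 3))


def kurtosis(segment: Segment | np.ndarray, sigma_ddof: int = 0) -> float:
    """Standardized fourth moment, non-excess (Gaussian -> 3)."""
    x = _samples(segment)
    sig = x.std(ddof=sigma_ddof)
    if sig == 0.0 or not np.isfinite(sig):
        return NOT_COMPUTABLE
    return float(np.mean(((x - x.mean()) / sig) ** 4))


def entropy_from_psd(p: np.ndarray) -> float:
    """Scaled Shannon entropy of an (unnormalized) PSD vector.

    The vector is normalized to sum 1 over its M bins; the result is
    ``-(1/log2 M) * sum(p_i log2 p_i)`` with ``0 * log 0 = 0``, so a
    uniform PSD gives exactly 1 and a single-bin PSD gives 0.
    """
    p = np.asarray(p, dtype=float)
    total = p.sum()
    if p.size < 2 or total <= 0 or not np.isfinite(total):
        return NOT_COMPUTABLE
    q = p / total
    nz = q[q > 0]
    return float(-(nz * np.log2(nz)).sum() / math.log2(p.size))


def spectral_entropy(
    segment: Segment | np.ndarray,
    fs: float | None = None,
    window: str = "boxcar",
    detrend: bool = False,
) -> float:
    """Normalized spectral entropy in [0, 1].

    Uses a one-sided periodogram (DC included) of the raw segment; the
    estimator window and detrending are exposed but default to none, in
    line with the no-preprocessing policy.
    """
    if isinstance(segment, Segment):
        fs = segment.fs
    elif fs is None:
        raise ConfigurationError("fs is required when passing a bare array")
    x = _samples(segment)
    _, pxx = sp_signal.periodogram(
        x, fs=fs, window=window, detrend="constant" if detrend else False
    )
    return entropy_from_psd(pxx)


def zero_crossing_rate(segment: Segment | np.ndarray) -> float:
    """Fraction of adjacent sample pairs with strictly opposite signs."""
    x = _samples(segment)
    if x.size < 2:
        raise ConfigurationError("zero-crossing rate needs at least 2 samples")
    return float(np.count_nonzero(x[1:] * x[:-1] < 0) / (x.size - 1))


def compute_stats(segment: Segment, sigma_ddof: int = 0) -> StatResult:
    """All six statistical SQIs of one segment."""
    x = segment.samples
    degenerate = bool(x.max() == x.min())
    upper, lower = envelope_std(segment)
    return StatResult(
        skewness=skewness(x, sigma_ddof=sigma_ddof),
        kurtosis=kurtosis(x, sigma_ddof=sigma_ddof),
        entropy=spectral_entropy(segment),
        zcr=zero_crossing_rate(x),
        upper_env_std=upper,
        lower_env_std=lower,
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class StatSummary:
    """Dataset summary of the statistical SQIs.

    ``per_record`` holds per-record arithmetic means over segments
    (``nan`` values excluded); ``mean``/``std`` are taken across records
    ("record_mean") or across all pooled segments ("pooled").
    """

    per_record: pd.DataFrame
    mean: pd.Series
    std: pd.Series
    aggregation: str


def stat_summary(
    results_by_record: Mapping[str, Sequence[StatResult]],
    aggregation: str = "record_mean",
) -> StatSummary:
    """Mean +/- std of each statistic, per record then dataset-wide."""
    if aggregation not in ("record_mean", "pooled"):
        raise ConfigurationError(f"unknown aggregation mode: {aggregation}")
    if not results_by_record:
        raise ConfigurationError("stat_summary requires at least one record")
    frames = {
        rid: pd.DataFrame([r.as_dict() for r in results])
        for rid, results in results_by_record.items()
    }
    per_record = pd.DataFrame({rid: df.mean() for rid, df in frames.items()}).T
    per_record.index.name = "record_id"
    if per_record.isna().all().all():
        raise ConfigurationError("no computable segments in any record")
    if aggregation == "record_mean":
        mean, std = per_record.mean(), per_record.std(ddof=1)
    else:
        pooled = pd.concat(frames.values(), ignore_index=True)
        mean, std = pooled.mean(), pooled.std(ddof=1)
    return StatSummary(per_record, mean, std, aggregation)
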