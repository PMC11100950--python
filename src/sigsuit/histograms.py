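"""Cross-dataset histogram analysis of the statistical SQIs.

Per-SQI histograms are aggregated over all segments of a dataset,
normalized by the number of included values, and compared across
datasets via the Pearson correlation of the two frequency vectors on a
shared 1000-bin grid.  Because spectral entropy depends on the sampling
rate, one dataset's entropy values can be affinely matched to the other
dataset's mean and variance before comparison.  Trimodal entropy
histograms (a central physiological mode with low/high outlier peaks)
admit automatic outlier thresholds at the minima between the three
dominant peaks; those thresholds act as a bad-quality classifier whose
precision and recall are evaluated against the physiological labels.

Binning ranges default to [0, 1] for the bounded SQIs (entropy,
zero-crossing rate, envelope stds) and to conventional display ranges
for the unbounded ones; values outside the range are excluded, not
clipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sp_signal

from .exceptions import ConfigurationError
from .segmentation import Modality

__all__ = [
    "DEFAULT_SQI_RANGES",
    "Histogram",
    "HistogramPair",
    "OutlierThresholds",
    "build_histogram",
    "histogram_pair",
    "histogram_correlation",
    "match_histogram",
    "find_outlier_thresholds",
    "outlier_detection_metrics",
    "plot_back_to_back",
]

#: Default binning range per (SQI, modality); modality ``None`` applies
#: to every modality.
DEFAULT_SQI_RANGES = {
    ("entropy", None): (0.0, 1.0),
    ("zcr", None): (0.0, 1.0),
    ("upper_env_std", None): (0.0, 1.0),
    ("lower_env_std", None): (0.0, 1.0),
    ("skewness", Modality.EEG): (-4.0, 4.0),
    ("skewness", Modality.ECG): (-8.0, 8.0),
    ("skewness", Modality.RESP_CAPNO): (-4.0, 4.0),
    ("skewness", Modality.RESP_AIRFLOW): (-4.0, 4.0),
    ("kurtosis", Modality.EEG): (0.0, 20.0),
    ("kurtosis", Modality.ECG): (0.0, 50.0),
    ("kurtosis", Modality.RESP_CAPNO): (0.0, 10.0),
    ("kurtosis", Modality.RESP_AIRFLOW): (0.0, 10.0),
}


def default_range(sqi: str, modality: Modality | None = None) -> tuple[float, float]:
    """Default binning range for an SQI (modality-specific where needed)."""
    if (sqi, None) in DEFAULT_SQI_RANGES:
        return DEFAULT_SQI_RANGES[(sqi, None)]
    key = (sqi, Modality(modality) if modality is not None else None)
    if key not in DEFAULT_SQI_RANGES:
        raise ConfigurationError(f"no default range for SQI {sqi!r} / {modality!r}")
    return DEFAULT_SQI_RANGES[key]


@dataclass(frozen=True)
class Histogram:
    """Normalized binned distribution: frequencies sum to 1."""

    edges: np.ndarray
    freq: np.ndarray
    n: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass(frozen=True)
class HistogramPair:
    """Two normalized histograms on a shared grid plus their correlation."""

    edges: np.ndarray
    freq_a: np.ndarray
    freq_b: np.ndarray
    correlation: float

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass(frozen=True)
class OutlierThresholds:
    """Lower/upper cut points on the SQI axis; outside = outlier."""

    lower: float
    upper: float

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ConfigurationError("lower threshold must be below upper")


def build_histogram(
    values: Sequence[float],
    value_range: tuple[float, float],
    n_bins: int = 1000,
) -> Histogram:
    """Histogram normalized by the count of included values.

    NaN values and values outside ``value_range`` are excluded (the
    range is a display/analysis choice, not a clipping operation).
    """
    if n_bins < 2:
        raise ConfigurationError("n_bins must be at least 2")
    lo, hi = value_range
    if not lo < hi:
        raise ConfigurationError("histogram range must satisfy lo < hi")
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    v = v[(v >= lo) & (v <= hi)]
    if v.size == 0:
        raise ConfigurationError("no values fall inside the histogram range")
    counts, edges = np.histogram(v, bins=n_bins, range=(lo, hi))
    return Histogram(edges=edges, freq=counts / v.size, n=int(v.size))


def histogram_correlation(freq_a: np.ndarray, freq_b: np.ndarray) -> float:
    """Pearson correlation of two frequency vectors on a shared grid.

    Returns ``nan`` when either vector has zero variance.
    """
    a = np.asarray(freq_a, dtype=float)
    b = np.asarray(freq_b, dtype=float)
    if a.shape != b.shape:
        raise ConfigurationError("frequency vectors must share the bin grid")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def histogram_pair(
    values_a: Sequence[float],
    values_b: Sequence[float],
    value_range: tuple[float, float],
    n_bins: int = 1000,
) -> HistogramPair:
    """Histograms of two samples on one grid, with their correlation."""
    ha = build_histogram(values_a, value_range, n_bins)
    hb = build_histogram(values_b, value_range, n_bins)
    return HistogramPair(
        edges=ha.edges,
        freq_a=ha.freq,
        freq_b=hb.freq,
        correlation=histogram_correlation(ha.freq, hb.freq),
    )


def match_histogram(
    values: Sequence[float], target_mean: float, target_var: float
) -> np.ndarray:
    """Affinely rescale a sample to a target mean and variance.

    ``y = (x - mu) / sigma * sigma_target + mu_target``; idempotent when
    the targets equal the source moments.  NaN values pass through.
    """
    if target_var < 0:
        raise ConfigurationError("target variance must be non-negative")
    v = np.asarray(values, dtype=float)
    finite = v[np.isfinite(v)]
    if finite.size < 2:
        raise ConfigurationError("need at least two finite values to match moments")
    mu, sigma = finite.mean(), finite.std()
    if sigma == 0:
        raise ConfigurationError("source variance is zero; matching undefined")
    return (v - mu) / sigma * np.sqrt(target_var) + target_mean


def find_outlier_thresholds(
    hist: Histogram, smooth_frac: float = 0.02, min_separation_frac: float = 0.05
) -> Optional[OutlierThresholds]:
    """Valley thresholds between the three dominant histogram peaks.

    The frequency vector is smoothed with a moving average of width
    ``smooth_frac`` of the bin count, local maxima at least
    ``min_separation_frac`` of the axis apart are located, and the three
    highest are taken as the peaks; the thresholds are the bin centers
    of the minimum smoothed frequency between peaks 1-2 and 2-3 (the
    middle of the plateau when the minimum is flat).  Returns ``None``
    when fewer than three separated peaks exist (unimodal or bimodal
    distribution).
    """
    freq = hist.freq
    w = max(1, int(round(smooth_frac * freq.size)))
    smooth = np.convolve(freq, np.ones(w) / w, mode="same")
    distance = max(1, int(round(min_separation_frac * freq.size)))
    peaks, _ = sp_signal.find_peaks(smooth, distance=distance)
    if peaks.size < 3:
        return None
    top = peaks[np.argsort(smooth[peaks])[-3:]]
    p1, p2, p3 = np.sort(top)
    centers = hist.centers

    def valley(a: int, b: int) -> int:
        # middle of the minimum plateau, so empty gaps split midway
        window = smooth[a : b + 1]
        at_min = np.flatnonzero(window == window.min())
        return a + int(at_min[at_min.size // 2])

    return OutlierThresholds(
        lower=float(centers[valley(p1, p2)]), upper=float(centers[valley(p2, p3)])
    )


def outlier_detection_metrics(
    values: Sequence[float],
    thresholds: OutlierThresholds,
    bad_labels: Sequence[bool],
) -> tuple[float, float]:
    """Precision and recall of the threshold classifier vs. labels.

    A segment is predicted bad when its value falls below the lower or
    above the upper threshold; ``bad_labels`` marks the reference bad
    segments (positives).  Precision is ``nan`` when nothing is
    predicted bad.
    """
    v = np.asarray(values, dtype=float)
    bad = np.asarray(bad_labels, dtype=bool)
    if v.shape != bad.shape:
        raise ConfigurationError("values and labels must align")
    predicted = (v < thresholds.lower) | (v > thresholds.upper)
    tp = int(np.count_nonzero(predicted & bad))
    fp = int(np.count_nonzero(predicted & ~bad))
    fn = int(np.count_nonzero(~predicted & bad))
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    return precision, recall


def plot_back_to_back(pair: HistogramPair, path, labels=("A", "B"), title: str = ""):
    """Mirrored (back-to-back) normalized histogram plot of a pair."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    centers = pair.centers
    width = pair.edges[1] - pair.edges[0]
    ax.bar(centers, pair.freq_a, width=width, color="tab:blue", label=labels[0])
    ax.bar(centers, -pair.freq_b, width=width, color="tab:orange", label=labels[1])
    ax.axhline(0.0, color="black", linewidth=0.6)
    ax.set_xlabel("SQI value")
    ax.set_ylabel("normalized frequency")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
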