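"""Rule-based signal-quality indicators.

Two boolean per-segment rules:

* **Constant data** — a segment is flagged when any run of
  ``w_length = round(0.5 s * fs)`` consecutive, exactly equal sample
  values exists anywhere in it.  Sustained constant values are almost
  always sensor-contact loss or clipping, never physiology.
* **Out-of-range data** — a segment is flagged when its minimum or
  maximum exceeds the clinically normal amplitude interval of its
  modality: EEG [-110, 110] uV, ECG [-3.5, 3.5] mV, capnography
  [0, 50] mmHg.  Dimensionless airflow has no defensible range, so the
  check is *not applicable* (``None``) there and such segments are
  excluded from out-of-range denominators.

A segment passes the rules iff it is neither constant nor out of range
(a not-applicable range check does not count as a violation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .segmentation import Modality, Segment

__all__ = [
    "DEFAULT_RANGES",
    "RuleResult",
    "RuleSummary",
    "detect_constant",
    "check_range",
    "evaluate_rules",
    "rule_summary",
]

#: Clinically normal amplitude intervals per modality (closed intervals in
#: physical units); ``None`` = no range applicable.
DEFAULT_RANGES: dict[Modality, Optional[tuple[float, float]]] = {
    Modality.EEG: (-110.0, 110.0),
    Modality.ECG: (-3.5, 3.5),
    Modality.RESP_CAPNO: (0.0, 50.0),
    Modality.RESP_AIRFLOW: None,
}


@dataclass(frozen=True)
class RuleResult:
    """Boolean rule outcomes for one segment.

    ``out_of_range`` is ``None`` when no amplitude range is defined for
    the modality (not applicable).
    """

    has_constant: bool
    out_of_range: Optional[bool]

    @property
    def pass_rules(self) -> bool:
        """True iff not constant and not (applicably) out of range."""
        return not self.has_constant and self.out_of_range is not True


def _samples(segment) -> np.ndarray:
    return segment.samples if isinstance(segment, Segment) else np.asarray(segment, float)


def _max_equal_run(x: np.ndarray, tol: float) -> int:
    """Length (in samples) of the longest run of equal consecutive values."""
    if x.size < 2:
        return x.size
    if tol == 0.0:
        eq = x[1:] == x[:-1]
    else:
        eq = np.abs(np.diff(x)) <= tol
    if not eq.any():
        return 1
    padded = np.concatenate(([False], eq, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    run_lengths = edges[1::2] - edges[0::2]
    return int(run_lengths.max()) + 1


def detect_constant(
    segment: Segment | np.ndarray,
    min_duration_s: float = 0.5,
    fs: float | None = None,
    tol: float = 0.0,
) -> bool:
    """True iff the segment contains a constant run of >= ``min_duration_s``.

    The run length is ``w_length = round(min_duration_s * fs)`` samples and
    equality is exact by default (flatlines from sensor loss or clipping
    reproduce identical quantized values); ``tol`` optionally allows an
    absolute tolerance.

    Raises
    ------
    ConfigurationError
        If ``w_length`` is below 2 samples or exceeds the segment length.
    """
    if isinstance(segment, Segment):
        fs = segment.fs
    elif fs is None:
        raise ConfigurationError("fs is required when passing a bare array")
    x = _samples(segment)
    w_length = int(round(min_duration_s * fs))
    if w_length < 2:
        raise ConfigurationError("constant-run window must span at least 2 samples")
    if w_length > x.size:
        raise ConfigurationError("constant-run window longer than the segment")
    return _max_equal_run(x, tol) >= w_length


def check_range(
    segment: Segment,
    ranges: Mapping[Modality, Optional[tuple[float, float]]] | None = None,
) -> Optional[bool]:
    """Out-of-range flag: True, False, or ``None`` when not applicable.

    A segment is out of range iff its maximum exceeds the upper bound or
    its minimum falls below the lower bound of the modality interval.
    """
    ranges = DEFAULT_RANGES if ranges is None else ranges
    interval = ranges.get(segment.modality)
    if interval is None:
        return None
    lo, hi = interval
    if not lo < hi:
        raise ConfigurationError(f"invalid amplitude range {interval} for {segment.modality}")
    x = segment.samples
    return bool(x.max() > hi or x.min() < lo)


def evaluate_rules(
    segment: Segment,
    ranges: Mapping[Modality, Optional[tuple[float, float]]] | None = None,
    min_duration_s: float = 0.5,
    tol: float = 0.0,
) -> RuleResult:
    """Apply both rule-based indicators to one segment."""
    return RuleResult(
        has_constant=detect_constant(segment, min_duration_s=min_duration_s, tol=tol),
        out_of_range=check_range(segment, ranges),
    )


@dataclass(frozen=True)
class RuleSummary:
    """Per-record percentages and the dataset-level aggregate.

    ``per_record`` has one row per record with columns ``constant_pct``
    and ``out_of_range_pct`` (the latter NaN when no segment of the
    record had an applicable range).  ``constant_pct`` /
    ``out_of_range_pct`` are the dataset-level values under
    ``aggregation`` ("record_mean": arithmetic mean over records;
    "pooled": counts pooled over all segments).
    """

    per_record: pd.DataFrame
    constant_pct: float
    out_of_range_pct: float
    aggregation: str


def rule_summary(
    results_by_record: Mapping[str, Sequence[RuleResult]],
    aggregation: str = "record_mean",
) -> RuleSummary:
    """Summarize rule flags as percentages.

    Not-applicable range checks are excluded from the out-of-range
    denominator; if every segment is not applicable the percentage is NaN.
    """
    if aggregation not in ("record_mean", "pooled"):
        raise ConfigurationError(f"unknown aggregation mode: {aggregation}")
    if not results_by_record:
        raise ConfigurationError("rule_summary requires at least one record")
    rows = {}
    const_num = const_den = 0
    oor_num = oor_den = 0
    for rid, results in results_by_record.items():
        if not results:
            raise ConfigurationError(f"record {rid!r} has no segments")
        n = len(results)
        n_const = sum(r.has_constant for r in results)
        applicable = [r for r in results if r.out_of_range is not None]
        n_oor = sum(r.out_of_range for r in applicable)
        rows[rid] = {
            "constant_pct": 100.0 * n_const / n,
            "out_of_range_pct": (
                100.0 * n_oor / len(applicable) if applicable else float("nan")
            ),
        }
        const_num += n_const
        const_den += n
        oor_num += n_oor
        oor_den += len(applicable)
    per_record = pd.DataFrame.from_dict(rows, orient="index")
    per_record.index.name = "record_id"
    if aggregation == "record_mean":
        constant_pct = float(per_record["constant_pct"].mean())
        oor = per_record["out_of_range_pct"].dropna()
        out_of_range_pct = float(oor.mean()) if len(oor) else float("nan")
    else:
        constant_pct = 100.0 * const_num / const_den
        out_of_range_pct = 100.0 * oor_num / oor_den if oor_den else float("nan")
    return RuleSummary(per_record, constant_pct, out_of_range_pct, aggregation)
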