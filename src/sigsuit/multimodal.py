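"""Multimodal suitability: joint per-segment evaluation of channel sets.

A time-aligned set of segments (one per channel, same record and start
time) is suitable for multimodal analysis iff every channel in the
combination passes the rule-based SQIs — no constant data and no
(applicable) out-of-range data.  A channel whose modality has no
amplitude range (dimensionless airflow) is constrained by the
constant-data rule only.  Only the rule-based indicators enter the joint
criterion by default; requiring the ECG physiological label in addition
is available as an option.

Suitability percentages are reported for every combination of 2, 3 and
4 channels, with a mean +/- std across the combinations of each size.
Dataset-level percentages are segment-pooled by default (proportions
over all aligned sets); record-averaged aggregation is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .physio import PhysioResult
from .rules import RuleResult
from .segmentation import Segment

__all__ = [
    "AlignedSegmentSet",
    "SuitabilityReport",
    "align_segments",
    "multimodal_suitable",
    "suitability_table",
]


@dataclass(frozen=True)
class AlignedSegmentSet:
    """Per-channel rule results for one record at one start time."""

    record_id: str
    start_s: float
    rules: Mapping[str, RuleResult]
    physio: Mapping[str, PhysioResult] = field(default_factory=dict)


def align_segments(
    channel_segments: Mapping[str, Sequence[Segment]],
) -> list[dict[str, Segment]]:
    """Group per-channel segment lists by shared start time.

    Returns one ``{channel: segment}`` mapping per start time present in
    *every* channel, ordered by start; start times present in only some
    channels are dropped.
    """
    if not channel_segments:
        return []
    by_channel: dict[str, dict[float, Segment]] = {}
    for channel, segs in channel_segments.items():
        table: dict[float, Segment] = {}
        for seg in segs:
            key = round(float(seg.start_s), 6)
            if key in table:
                raise ConfigurationError(
                    f"duplicate start time {seg.start_s} in channel {channel!r}"
                )
            table[key] = seg
        by_channel[channel] = table
    common = set.intersection(*(set(t) for t in by_channel.values()))
    return [
        {channel: by_channel[channel][s] for channel in channel_segments}
        for s in sorted(common)
    ]


def multimodal_suitable(
    aligned: AlignedSegmentSet,
    channels: Sequence[str],
    require_physio: bool = False,
) -> bool:
    """True iff every listed channel passes the rule-based SQIs.

    ``require_physio`` additionally demands a good-quality physiological
    label wherever one exists for a channel in the combination.
    """
    for channel in channels:
        if channel not in aligned.rules:
            raise ConfigurationError(f"channel {channel!r} missing from aligned set")
        if not aligned.rules[channel].pass_rules:
            return False
        if require_physio and channel in aligned.physio:
            if not aligned.physio[channel].good_quality:
                return False
    return True


@dataclass(frozen=True)
class SuitabilityReport:
    """Suitability percentages per combination and per combination size.

    ``per_combination`` maps a channel tuple to its percentage;
    ``by_size`` has one row per combination size with mean and std (ddof
    1) across the combinations of that size; ``pair_matrix`` mirrors the
    upper-triangular pairwise layout.
    """

    per_combination: dict[tuple[str, ...], float]
    by_size: pd.DataFrame
    pair_matrix: pd.DataFrame
    aggregation: str

    def percentage(self, *channels: str) -> float:
        return self.per_combination[tuple(sorted(channels))]


def suitability_table(
    aligned_sets: Sequence[AlignedSegmentSet],
    channels: Sequence[str],
    sizes: Sequence[int] = (2, 3, 4),
    aggregation: str = "pooled",
    require_physio: bool = False,
) -> SuitabilityReport:
    """Suitability percentages over all channel combinations of the sizes.

    ``aggregation="pooled"`` computes each percentage over all aligned
    sets; ``"record_mean"`` averages per-record percentages.
    """
    if aggregation not in ("pooled", "record_mean"):
        raise ConfigurationError(f"unknown aggregation mode: {aggregation}")
    if not aligned_sets:
        raise ConfigurationError("no aligned segment sets supplied")
    channels = list(channels)
    for aset in aligned_sets:
        for channel in channels:
            if channel not in aset.rules:
                raise ConfigurationError(f"channel {channel!r} missing from aligned set")
    sizes = [k for k in sizes if k <= len(channels)]

    def pct(combo: tuple[str, ...]) -> float:
        flags = [
            multimodal_suitable(aset, combo, require_physio=require_physio)
            for aset in aligned_sets
        ]
        if aggregation == "pooled":
            return 100.0 * sum(flags) / len(flags)
        per_record: dict[str, list[bool]] = {}
        for aset, flag in zip(aligned_sets, flags):
            per_record.setdefault(aset.record_id, []).append(flag)
        return float(
            np.mean([100.0 * sum(v) / len(v) for v in per_record.values()])
        )

    per_combination: dict[tuple[str, ...], float] = {}
    for k in sizes:
        for combo in combinations(sorted(channels), k):
            per_combination[combo] = pct(combo)

    rows = []
    for k in sizes:
        vals = [v for combo, v in per_combination.items() if len(combo) == k]
        rows.append(
            {
                "size": k,
                "n_combinations": len(vals),
                "mean_pct": float(np.mean(vals)),
                "std_pct": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            }
        )
    by_size = pd.DataFrame(rows).set_index("size")

    ordered = sorted(channels)
    pair_matrix = pd.DataFrame(index=ordered, columns=ordered, dtype=float)
    if 2 in sizes:
        for a, b in combinations(ordered, 2):
            pair_matrix.loc[a, b] = per_combination[(a, b)]
    return SuitabilityReport(per_combination, by_size, pair_matrix, aggregation)
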