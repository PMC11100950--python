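"""Configuration and the end-to-end pipeline driver.

``run_pipeline`` takes records (read from EDF files, track tables, or
generated synthetically from the config), segments every channel,
applies the rule-based, statistical, and — for ECG — physiological SQIs,
aggregates unimodal summaries, joint multimodal suitability tables, and
writes the report bundle as plain CSV plus a machine-readable run log
(config hash + seed), so a rerun with the same config and seed is
byte-identical.

``compare_datasets`` implements the cross-dataset histogram analysis:
per-SQI histogram correlations on a 1000-bin grid, with optional
mean/variance matching of one dataset's entropy values to the other's.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import histograms as hg
from .exceptions import ConfigurationError
from .multimodal import AlignedSegmentSet, align_segments, suitability_table
from .physio import assess_quality, physio_summary
from .rules import DEFAULT_RANGES, evaluate_rules, rule_summary
from .segmentation import Modality, SignalRecord, segment_record
from .stats import STAT_NAMES, compute_stats, stat_summary
from .synthetic import CorruptionConfig, WaveformSpec, default_spec, gen_dataset

__all__ = ["ChannelConfig", "PipelineConfig", "PipelineReport", "run_pipeline", "compare_datasets"]


@dataclass(frozen=True)
class ChannelConfig:
    """One channel of the inventory: name, modality and generator knobs."""

    name: str
    modality: str
    fs: Optional[float] = None
    amplitude: Optional[float] = None
    rate: Optional[float] = None
    noise_sd: Optional[float] = None

    def spec(self, duration: float, seed: int) -> WaveformSpec:
        overrides = {
            k: v
            for k, v in dict(
                fs=self.fs, amplitude=self.amplitude, rate=self.rate, noise_sd=self.noise_sd
            ).items()
            if v is not None
        }
        return default_spec(self.modality, duration=duration, seed=seed, **overrides)


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, serializable to YAML.

    The default channel inventory mirrors the four-signal setting the
    suitability tables are built around: two EEG channels, one ECG, one
    respiration channel.
    """

    channels: list = field(
        default_factory=lambda: [
            ChannelConfig("EEG1", "EEG"),
            ChannelConfig("EEG2", "EEG"),
            ChannelConfig("ECG", "ECG"),
            ChannelConfig("Resp", "RESP_CAPNO"),
        ]
    )
    n_records: int = 5
    duration_s: float = 60.0
    corruption_probability: float = 0.1
    window_s: float = 10.0
    step_s: float = 5.0
    rule_aggregation: str = "record_mean"
    stat_aggregation: str = "record_mean"
    multimodal_aggregation: str = "pooled"
    include_physio: bool = True
    histogram_bins: int = 1000
    seed: int = 0

    def __post_init__(self):
        self.channels = [
            c if isinstance(c, ChannelConfig) else ChannelConfig(**c) for c in self.channels
        ]

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    @property
    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


@dataclass(frozen=True)
class PipelineReport:
    """Report bundle of one pipeline run."""

    segments: pd.DataFrame            # per-segment SQI table
    rule_table: pd.DataFrame          # per-channel constant/out-of-range %
    stat_table: pd.DataFrame          # per-channel mean +/- std per SQI
    physio_table: pd.DataFrame        # ECG good-quality %
    suitability: object               # SuitabilityReport
    run_log: dict


def _score_records(
    records: Mapping[str, Mapping[str, SignalRecord]], config: PipelineConfig
) -> tuple[pd.DataFrame, list[AlignedSegmentSet]]:
    rows = []
    aligned_sets: list[AlignedSegmentSet] = []
    for rid, channels in records.items():
        seg_lists = {
            ch: segment_record(rec, config.window_s, config.step_s)
            for ch, rec in channels.items()
        }
        seg_results: dict[str, dict[float, dict]] = {ch: {} for ch in seg_lists}
        for ch, segs in seg_lists.items():
            for seg in segs:
                rule = evaluate_rules(seg)
                stats = compute_stats(seg)
                entry = {"rule": rule, "stats": stats, "physio": None}
                if config.include_physio and seg.modality is Modality.ECG:
                    entry["physio"] = assess_quality(seg)
                seg_results[ch][round(seg.start_s, 6)] = entry
                row = {
                    "record_id": rid,
                    "channel": ch,
                    "modality": seg.modality.value,
                    "start_s": seg.start_s,
                    "has_constant": rule.has_constant,
                    "out_of_range": rule.out_of_range,
                    "pass_rules": rule.pass_rules,
                }
                row.update(stats.as_dict())
                row["good_quality"] = (
                    entry["physio"].good_quality if entry["physio"] is not None else None
                )
                rows.append(row)
        for aligned in align_segments(seg_lists):
            start = round(next(iter(aligned.values())).start_s, 6)
            aligned_sets.append(
                AlignedSegmentSet(
                    record_id=rid,
                    start_s=start,
                    rules={ch: seg_results[ch][start]["rule"] for ch in aligned},
                    physio={
                        ch: seg_results[ch][start]["physio"]
                        for ch in aligned
                        if seg_results[ch][start]["physio"] is not None
                    },
                )
            )
    segments = pd.DataFrame(rows)
    return segments, aligned_sets


def run_pipeline(
    config: PipelineConfig,
    records: Optional[Mapping[str, Mapping[str, SignalRecord]]] = None,
    input_paths: Optional[Sequence] = None,
    out_dir=None,
) -> PipelineReport:
    """Run segmentation -> SQIs -> summaries -> suitability end to end.

    Inputs, in order of precedence: ``records`` (in-memory), EDF
    ``input_paths``, else a synthetic dataset generated from the config.
    When ``out_dir`` is given the report bundle is written there as CSV
    files plus ``run_log.json``.
    """
    if records is None and input_paths:
        from .io import read_edf

        records = {}
        for p in input_paths:
            recs = read_edf(p)
            records[recs[0].record_id] = {r.channel: r for r in recs}
    if records is None:
        specs = {c.name: c.spec(config.duration_s, config.seed) for c in config.channels}
        bundle = gen_dataset(
            specs,
            CorruptionConfig(probability=config.corruption_probability, seed=config.seed),
            n_records=config.n_records,
        )
        records = bundle.records
    if not records:
        raise ConfigurationError("no records to analyse")

    segments, aligned_sets = _score_records(records, config)

    channel_names = sorted({ch for chans in records.values() for ch in chans})
    rule_rows = []
    stat_rows = []
    for ch in channel_names:
        sub = segments[segments["channel"] == ch]
        by_record_rules = {
            rid: [
                _rule_from_row(row) for _, row in grp.iterrows()
            ]
            for rid, grp in sub.groupby("record_id")
        }
        rs = rule_summary(by_record_rules, aggregation=config.rule_aggregation)
        rule_rows.append(
            {
                "channel": ch,
                "constant_pct": rs.constant_pct,
                "out_of_range_pct": rs.out_of_range_pct,
            }
        )
        means = {
            rid: grp[list(STAT_NAMES)].mean() for rid, grp in sub.groupby("record_id")
        }
        per_record = pd.DataFrame(means).T
        if config.stat_aggregation == "record_mean":
            mean, std = per_record.mean(), per_record.std(ddof=1)
        else:
            mean = sub[list(STAT_NAMES)].mean()
            std = sub[list(STAT_NAMES)].std(ddof=1)
        row = {"channel": ch}
        for name in STAT_NAMES:
            row[f"{name}_mean"] = mean[name]
            row[f"{name}_std"] = std[name]
        stat_rows.append(row)
    rule_table = pd.DataFrame(rule_rows).set_index("channel")
    stat_table = pd.DataFrame(stat_rows).set_index("channel")

    physio_rows = []
    ecg = segments[segments["good_quality"].notna()]
    for ch, grp in ecg.groupby("channel"):
        physio_rows.append(
            {"channel": ch, "good_quality_pct": physio_summary(grp["good_quality"].tolist())}
        )
    physio_table = (
        pd.DataFrame(physio_rows).set_index("channel")
        if physio_rows
        else pd.DataFrame(columns=["good_quality_pct"])
    )

    suitability = suitability_table(
        aligned_sets,
        channel_names,
        sizes=(2, 3, 4),
        aggregation=config.multimodal_aggregation,
    )

    run_log = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "n_records": len(records),
        "n_segments": int(len(segments)),
        "n_aligned_sets": len(aligned_sets),
    }
    report = PipelineReport(segments, rule_table, stat_table, physio_table, suitability, run_log)
    if out_dir is not None:
        _write_report(report, out_dir)
    return report


def _rule_from_row(row):
    from .rules import RuleResult

    oor = row["out_of_range"]
    return RuleResult(
        has_constant=bool(row["has_constant"]),
        out_of_range=None if pd.isna(oor) else bool(oor),
    )


def _write_report(report: PipelineReport, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.6f"
    report.segments.to_csv(out / "segments.csv", index=False, float_format=fmt)
    report.rule_table.to_csv(out / "summary_rules.csv", float_format="%.2f")
    report.stat_table.to_csv(out / "summary_stats.csv", float_format=fmt)
    report.physio_table.to_csv(out / "summary_physio.csv", float_format="%.2f")
    combos = pd.DataFrame(
        [
            {"channels": "+".join(combo), "size": len(combo), "suitable_pct": pct}
            for combo, pct in report.suitability.per_combination.items()
        ]
    )
    combos.to_csv(out / "suitability_combinations.csv", index=False, float_format="%.2f")
    report.suitability.by_size.to_csv(out / "suitability_by_size.csv", float_format="%.2f")
    (out / "run_log.json").write_text(json.dumps(report.run_log, indent=2, sort_keys=True))


def compare_datasets(
    segments_a: pd.DataFrame,
    segments_b: pd.DataFrame,
    n_bins: int = 1000,
    match_entropy: bool = False,
) -> pd.DataFrame:
    """Per-channel, per-SQI histogram correlations between two datasets.

    Both inputs are per-segment tables from :func:`run_pipeline`.
    Channels are matched by name; for each SQI the two value sets are
    binned on the shared default grid and the Pearson correlation of the
    normalized frequency vectors is reported.  With ``match_entropy``,
    dataset B's entropy values are first affinely matched to dataset A's
    mean and variance.
    """
    shared = sorted(set(segments_a["channel"]) & set(segments_b["channel"]))
    if not shared:
        raise ConfigurationError("datasets share no channel names")
    rows = []
    for ch in shared:
        sub_a = segments_a[segments_a["channel"] == ch]
        sub_b = segments_b[segments_b["channel"] == ch]
        modality = Modality(sub_a["modality"].iloc[0])
        row = {"channel": ch}
        for name in STAT_NAMES:
            va = sub_a[name].to_numpy(dtype=float)
            vb = sub_b[name].to_numpy(dtype=float)
            if name == "entropy" and match_entropy:
                finite = np.isfinite(va)
                vb = hg.match_histogram(vb, va[finite].mean(), va[finite].var())
            rng = hg.default_range(name, modality)
            try:
                pair = hg.histogram_pair(va, vb, rng, n_bins)
                row[name] = pair.correlation
            except ConfigurationError:
                row[name] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("channel")
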