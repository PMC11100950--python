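"""Synthetic multimodal waveform generator with ground-truth artifacts.

Emulates the signal classes the pipeline targets — quasi-periodic ECG
with a controllable heart rate, band-limited (<= 30 Hz) EEG-like noise,
and slow periodic respiration (capnography in mmHg or dimensionless
airflow) — plus injectable artifacts of the kinds the quality rules are
built to catch: flatlines, out-of-range excursions, clipping, broadband
sawtooth noise, and dropouts.  Every generator is deterministic under
its seed, clean signals stay within ~90% of their modality's amplitude
range (so only injected artifacts trip the range rule), and every
injected artifact comes with a ground-truth annotation, which makes each
downstream stage testable without external data.

The ECG beat model is a sum of fixed-width Gaussian kernels (P, Q, R, S,
T) placed at the beat times, with optional fractional RR jitter; it is
the simplest waveform that exercises R-peak detectors and the RR-based
plausibility conditions.  No arrhythmia, sleep-stage, or anesthesia
morphology is modelled.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np
from scipy import signal as sp_signal

from .exceptions import BoundsError, ConfigurationError
from .rules import DEFAULT_RANGES
from .segmentation import Modality, SignalRecord

__all__ = [
    "ArtifactKind",
    "WaveformSpec",
    "ArtifactAnnotation",
    "CorruptionConfig",
    "ECGRecord",
    "DatasetBundle",
    "default_spec",
    "gen_ecg",
    "gen_eeg",
    "gen_resp",
    "generate",
    "inject_artifact",
    "gen_dataset",
]


class ArtifactKind(str, Enum):
    FLATLINE = "FLATLINE"
    OUT_OF_RANGE = "OUT_OF_RANGE"
    CLIPPING = "CLIPPING"
    SAWTOOTH = "SAWTOOTH"
    DROPOUT = "DROPOUT"


@dataclass(frozen=True)
class WaveformSpec:
    """Parameters of one clean synthetic channel.

    ``amplitude`` is the peak amplitude in modality units (uV, mV, mmHg,
    or dimensionless); ``rate`` is the fundamental physiological rate
    (beats/min for ECG, breaths/min for respiration, ignored for EEG);
    ``noise_sd`` is the additive Gaussian noise level in modality units.
    Regenerating with the same spec (including seed) is bit-identical.
    """

    modality: Modality
    fs: float
    duration: float
    amplitude: float
    rate: Optional[float] = None
    noise_sd: float = 0.0
    rr_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "modality", Modality(self.modality))
        if not self.fs > 0:
            raise ConfigurationError("fs must be positive")
        if not self.duration > 0:
            raise ConfigurationError("duration must be positive")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ConfigurationError("amplitude and noise_sd must be non-negative")


#: Realistic per-modality defaults: sampling rates follow common monitor
#: settings (500 Hz ECG, 128 Hz EEG, 62.5 Hz capnography, 25 Hz airflow)
#: and amplitudes sit well inside the clinical ranges.
_DEFAULTS = {
    Modality.ECG: dict(fs=500.0, amplitude=1.5, rate=70.0, noise_sd=0.02),
    Modality.EEG: dict(fs=128.0, amplitude=50.0, rate=None, noise_sd=0.0),
    Modality.RESP_CAPNO: dict(fs=62.5, amplitude=38.0, rate=14.0, noise_sd=0.3),
    Modality.RESP_AIRFLOW: dict(fs=25.0, amplitude=1.0, rate=14.0, noise_sd=0.02),
}


def default_spec(modality: Modality | str, duration: float = 60.0, seed: int = 0, **overrides) -> WaveformSpec:
    """A WaveformSpec with realistic defaults for the modality."""
    modality = Modality(modality)
    params = dict(_DEFAULTS[modality], duration=duration, seed=seed)
    params.update(overrides)
    return WaveformSpec(modality=modality, **params)


@dataclass(frozen=True)
class ArtifactAnnotation:
    """Ground truth for one injected artifact (times in seconds)."""

    kind: ArtifactKind
    start: float
    duration: float
    channel: str = ""
    record_id: str = ""
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "kind", ArtifactKind(self.kind))
        if self.start < 0 or self.duration <= 0:
            raise ConfigurationError("artifact start must be >= 0 and duration > 0")


@dataclass(frozen=True)
class CorruptionConfig:
    """Per-channel corruption model for dataset generation.

    Each non-overlapping ``span_s`` span of each channel is corrupted
    independently with probability ``probability`` (a scalar or a
    per-channel mapping); the artifact kind is drawn from ``weights``.
    The default mixture uses only the kinds the rule-based SQIs detect
    deterministically, so the drawn corruption rate is recoverable.
    """

    probability: float | Mapping[str, float] = 0.1
    weights: Mapping[ArtifactKind, float] = field(
        default_factory=lambda: {
            ArtifactKind.FLATLINE: 0.4,
            ArtifactKind.OUT_OF_RANGE: 0.4,
            ArtifactKind.DROPOUT: 0.2,
        }
    )
    span_s: float = 10.0
    seed: int = 0

    def __post_init__(self):
        probs = (
            self.probability.values()
            if isinstance(self.probability, Mapping)
            else [self.probability]
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("corruption probabilities must lie in [0, 1]")
        total = sum(self.weights.values())
        if not np.isclose(total, 1.0):
            raise ConfigurationError("artifact mixture weights must sum to 1")

    def prob_for(self, channel: str) -> float:
        if isinstance(self.probability, Mapping):
            return float(self.probability[channel])
        return float(self.probability)


class ECGRecord(NamedTuple):
    record: SignalRecord
    beat_times: np.ndarray


# --------------------------------------------------------------------------
# Clean generators
# --------------------------------------------------------------------------

# ECG kernel table: (relative amplitude, offset from R in s, width sigma in s)
_ECG_WAVES = (
    (0.15, -0.20, 0.035),   # P
    (-0.10, -0.035, 0.012), # Q
    (1.00, 0.0, 0.014),     # R
    (-0.18, 0.033, 0.012),  # S
    (0.30, 0.25, 0.060),    # T
)


def gen_ecg(spec: WaveformSpec, record_id: str = "ecg", channel: str = "") -> ECGRecord:
    """Quasi-periodic ECG with one sharp positive R peak per beat.

    Beats start half an RR interval into the record and repeat every
    ``60 / rate`` seconds (optionally jittered by the fractional
    ``rr_jitter``); the ground-truth beat times are returned alongside
    the record.  The R peak reaches ~``amplitude``.
    """
    if spec.modality is not Modality.ECG:
        raise ConfigurationError("gen_ecg requires an ECG spec")
    if spec.rate is None or not 1.0 <= spec.rate <= 300.0:
        raise ConfigurationError("ECG rate must lie in [1, 300] beats/min")
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    rr = 60.0 / spec.rate
    beats = []
    bt = 0.5 * rr
    while bt < spec.duration:
        beats.append(bt)
        step = rr * (1.0 + spec.rr_jitter * rng.standard_normal()) if spec.rr_jitter else rr
        bt += max(step, 0.2)
    beats = np.asarray(beats)
    x = np.zeros(n)
    for b in beats:
        lo = max(0, int((b - 0.5) * spec.fs))
        hi = min(n, int((b + 0.6) * spec.fs) + 1)
        tt = t[lo:hi]
        for amp, off, sig in _ECG_WAVES:
            x[lo:hi] += amp * np.exp(-0.5 * ((tt - b - off) / sig) ** 2)
    x *= spec.amplitude
    if spec.noise_sd:
        x = x + rng.normal(0.0, spec.noise_sd, size=n)
    rec = SignalRecord(record_id, Modality.ECG, x, spec.fs, channel=channel or "ECG")
    return ECGRecord(rec, beats)


def gen_eeg(spec: WaveformSpec, record_id: str = "eeg", channel: str = "") -> SignalRecord:
    """Zero-mean band-limited (< 30 Hz) EEG-like noise.

    White Gaussian noise is low-pass filtered (zero-phase Butterworth,
    25 Hz cutoff) and scaled so its standard deviation is amplitude / 3,
    placing >= 99% of samples within +/- amplitude.  ``noise_sd`` adds
    unfiltered broadband noise on top (0 by default, keeping out-of-band
    power < 5% of the total).
    """
    if spec.modality is not Modality.EEG:
        raise ConfigurationError("gen_eeg requires an EEG spec")
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    x = np.zeros(n)
    if spec.amplitude > 0:
        w = rng.standard_normal(n)
        cutoff = 25.0
        if spec.fs / 2 > cutoff and n > 30:
            sos = sp_signal.butter(4, cutoff, btype="lowpass", fs=spec.fs, output="sos")
            w = sp_signal.sosfiltfilt(sos, w)
        sd = w.std()
        if sd > 0:
            x = w / sd * (spec.amplitude / 3.0)
    if spec.noise_sd:
        x = x + rng.normal(0.0, spec.noise_sd, size=n)
    return SignalRecord(record_id, Modality.EEG, x, spec.fs, channel=channel or "EEG")


def gen_resp(spec: WaveformSpec, record_id: str = "resp", channel: str = "") -> SignalRecord:
    """Slow periodic respiration waveform at ``rate`` breaths/min.

    Capnography: a raised-cosine CO2 wave in [baseline, amplitude] mmHg,
    baseline chosen >= 5 noise standard deviations above zero so clean
    samples stay in [0, amplitude].  Airflow: a zero-mean sinusoid of
    peak ``amplitude`` (dimensionless).
    """
    if spec.modality not in (Modality.RESP_CAPNO, Modality.RESP_AIRFLOW):
        raise ConfigurationError("gen_resp requires a respiration spec")
    if spec.rate is None or not 2.0 <= spec.rate <= 60.0:
        raise ConfigurationError("respiration rate must lie in [2, 60] breaths/min")
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    f = spec.rate / 60.0
    if spec.modality is Modality.RESP_CAPNO:
        base = max(0.05 * spec.amplitude, 5.0 * spec.noise_sd)
        wave = 0.5 * (1.0 + np.cos(2.0 * np.pi * f * t - np.pi))
        x = base + (spec.amplitude - base) * wave
    else:
        x = spec.amplitude * np.sin(2.0 * np.pi * f * t)
    if spec.noise_sd:
        x = x + rng.normal(0.0, spec.noise_sd, size=n)
    return SignalRecord(
        record_id, spec.modality, x, spec.fs, channel=channel or spec.modality.value
    )


def generate(spec: WaveformSpec, record_id: str = "rec", channel: str = "") -> SignalRecord:
    """Dispatch on modality; for ECG the beat times are discarded."""
    if spec.modality is Modality.ECG:
        return gen_ecg(spec, record_id, channel).record
    if spec.modality is Modality.EEG:
        return gen_eeg(spec, record_id, channel)
    return gen_resp(spec, record_id, channel)


# --------------------------------------------------------------------------
# Artifact injection
# --------------------------------------------------------------------------


def inject_artifact(record: SignalRecord, annotation: ArtifactAnnotation) -> SignalRecord:
    """Return a new record with the annotated artifact applied.

    The input record is never modified.  Spans are aligned to sample
    boundaries (durations rounded to the nearest sample).
    """
    if annotation.start + annotation.duration > record.duration + 0.5 / record.fs:
        raise BoundsError("artifact extends beyond the record")
    x = record.samples.copy()
    i0 = int(round(annotation.start * record.fs))
    n = int(round(annotation.duration * record.fs))
    if n < 1 or i0 < 0 or i0 + n > x.size:
        raise BoundsError("artifact span outside the record samples")
    sl = slice(i0, i0 + n)
    params = annotation.parameters
    kind = annotation.kind
    if kind is ArtifactKind.FLATLINE:
        x[sl] = params.get("value", x[i0])
    elif kind is ArtifactKind.DROPOUT:
        x[sl] = 0.0
    elif kind is ArtifactKind.OUT_OF_RANGE:
        interval = DEFAULT_RANGES.get(record.modality)
        if "excursion" in params:
            excursion = float(params["excursion"])
        elif interval is not None:
            excursion = 1.2 * (interval[1] - interval[0])
        else:
            excursion = 10.0 * max(np.abs(x).max(), 1.0)
        bump = excursion * np.sin(np.pi * np.arange(n) / max(n - 1, 1))
        x[sl] = x[sl] + bump
    elif kind is ArtifactKind.CLIPPING:
        level = float(params.get("level", 0.6 * np.abs(record.samples).max()))
        x[sl] = np.clip(x[sl], -level, level)
    elif kind is ArtifactKind.SAWTOOTH:
        freq = float(params.get("frequency", 25.0))
        amp = float(params.get("amplitude", 2.0 * np.abs(record.samples).max() or 1.0))
        tt = np.arange(n) / record.fs
        x[sl] = x[sl] + amp * sp_signal.sawtooth(2.0 * np.pi * freq * tt, width=0.5)
    else:  # pragma: no cover - exhaustive over ArtifactKind
        raise ConfigurationError(f"unknown artifact kind {kind}")
    return replace(record, samples=x)


# --------------------------------------------------------------------------
# Dataset generation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DatasetBundle:
    """Generated multichannel records plus full ground truth.

    ``records`` maps record_id -> {channel -> SignalRecord};
    ``annotations`` lists every injected artifact (sorted by record,
    channel, start); ``corrupted`` maps (record_id, channel, span_index)
    -> bool; ``beat_times`` holds clean ground-truth R times per
    (record_id, channel) for ECG channels.
    """

    records: dict
    annotations: list
    corrupted: dict
    beat_times: dict


def _channel_stream_seed(master_seed: int, channel: str) -> int:
    digest = hashlib.sha256(channel.encode()).digest()
    return int.from_bytes(digest[:4], "little")


def _draw_artifact(
    rng: np.random.Generator,
    cfg: CorruptionConfig,
    kinds: list[ArtifactKind],
    cum_weights: np.ndarray,
    span_start: float,
    span_s: float,
) -> ArtifactAnnotation:
    kind = kinds[int(np.searchsorted(cum_weights, rng.random(), side="right"))]
    if kind in (ArtifactKind.FLATLINE, ArtifactKind.DROPOUT):
        duration = rng.uniform(0.8, 2.0)
    elif kind is ArtifactKind.OUT_OF_RANGE:
        duration = rng.uniform(0.5, 1.5)
    else:
        duration = rng.uniform(1.0, min(3.0, span_s - 1.0))
    margin = 0.5
    latest = span_start + span_s - margin - duration
    start = rng.uniform(span_start + margin, max(latest, span_start + margin))
    return ArtifactAnnotation(kind=kind, start=start, duration=duration)


def gen_dataset(
    channel_specs: Mapping[str, WaveformSpec],
    corruption: CorruptionConfig | None = None,
    n_records: int = 1,
    record_id_prefix: str = "rec",
) -> DatasetBundle:
    """Generate ``n_records`` multichannel records with drawn corruption.

    All channels of a record share the duration (validated).  Corruption
    events are drawn independently per channel and per non-overlapping
    ``span_s`` span; each channel uses its own random stream derived from
    the master seed and the channel name, so adding channels does not
    perturb existing ones.  Deterministic under the corruption seed.
    """
    if not channel_specs:
        raise ConfigurationError("channel_specs must not be empty")
    durations = {spec.duration for spec in channel_specs.values()}
    if len(durations) != 1:
        raise ConfigurationError("all channels of a record must share duration")
    duration = durations.pop()
    corruption = corruption if corruption is not None else CorruptionConfig(probability=0.0)
    span_s = corruption.span_s
    n_spans = int(duration // span_s)
    kinds = list(corruption.weights.keys())
    cum_weights = np.cumsum([corruption.weights[k] for k in kinds])

    records: dict[str, dict[str, SignalRecord]] = {}
    annotations: list[ArtifactAnnotation] = []
    corrupted: dict[tuple[str, str, int], bool] = {}
    beat_times: dict[tuple[str, str], np.ndarray] = {}

    for r in range(n_records):
        rid = f"{record_id_prefix}{r:04d}"
        records[rid] = {}
        for channel, spec in channel_specs.items():
            ch_seed = _channel_stream_seed(corruption.seed, channel)
            # unique per (spec seed, channel, record); big ints are fine seeds
            wave_seed = ((spec.seed + 1) << 64) + (ch_seed << 32) + r
            wave_spec = replace(spec, seed=wave_seed)
            if spec.modality is Modality.ECG:
                rec, beats = gen_ecg(wave_spec, rid, channel)
                beat_times[(rid, channel)] = beats
            else:
                rec = generate(wave_spec, rid, channel)
            rng = np.random.default_rng([corruption.seed, ch_seed, r])
            p = corruption.prob_for(channel)
            for s in range(n_spans):
                hit = bool(rng.random() < p)
                corrupted[(rid, channel, s)] = hit
                if hit:
                    ann = _draw_artifact(rng, corruption, kinds, cum_weights, s * span_s, span_s)
                    ann = ArtifactAnnotation(
                        kind=ann.kind,
                        start=ann.start,
                        duration=ann.duration,
                        channel=channel,
                        record_id=rid,
                        parameters=ann.parameters,
                    )
                    rec = inject_artifact(rec, ann)
                    annotations.append(ann)
            records[rid][channel] = rec
    annotations.sort(key=lambda a: (a.record_id, a.channel, a.start))
    return DatasetBundle(records, annotations, corrupted, beat_times)
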