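"""Signal containers and fixed-window segmentation.

The analysis unit throughout the package is a 10-second window with a
5-second step (50% overlap).  Segmentation is the *only* preprocessing
applied to a record: no resampling, filtering, detrending or baseline
removal, so every downstream quality indicator sees the raw samples.
Windows are defined on sample indices (start index = round(start_s * fs))
which keeps channels with different sampling rates on a shared wall-clock
grid without resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .exceptions import ConfigurationError

__all__ = [
    "Modality",
    "MODALITY_UNITS",
    "SignalRecord",
    "Segment",
    "segment_record",
]


class Modality(str, Enum):
    """Signal classes covered by the pipeline."""

    EEG = "EEG"
    ECG = "ECG"
    RESP_CAPNO = "RESP_CAPNO"
    RESP_AIRFLOW = "RESP_AIRFLOW"


#: Physical units per modality: microvolt EEG, millivolt ECG, mmHg
#: capnography; oro-nasal airflow is dimensionless.
MODALITY_UNITS = {
    Modality.EEG: "uV",
    Modality.ECG: "mV",
    Modality.RESP_CAPNO: "mmHg",
    Modality.RESP_AIRFLOW: "",
}


def _as_modality(value) -> Modality:
    if isinstance(value, Modality):
        return value
    try:
        return Modality(str(value))
    except ValueError as exc:
        raise ConfigurationError(f"unknown modality: {value!r}") from exc


@dataclass(frozen=True)
class SignalRecord:
    """One channel of one subject: raw samples in physical units.

    Parameters
    ----------
    record_id : str
        Identifier of the recording (subject/session).
    modality : Modality
        Signal class; fixes the physical units and the applicable
        amplitude range.
    samples : numpy.ndarray
        Amplitudes in physical units (uV, mV, mmHg or dimensionless).
    fs : float
        Sampling rate in Hz.
    channel : str
        Channel label within the record (e.g. ``"EEG1"``); defaults to the
        modality name.
    units : str
        Unit label; defaults to the modality convention.
    """

    record_id: str
    modality: Modality
    samples: np.ndarray
    fs: float
    channel: str = ""
    units: str = field(default="")
    #: physical (min, max) the 16-bit EDF encoding used, when the record
    #: came from or is destined for an EDF file; None otherwise
    physical_range: tuple[float, float] | None = None

    def __post_init__(self):
        object.__setattr__(self, "modality", _as_modality(self.modality))
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ConfigurationError("samples must be a non-empty 1-D array")
        if not self.fs > 0:
            raise ConfigurationError("sampling rate must be positive")
        object.__setattr__(self, "samples", samples)
        if not self.channel:
            object.__setattr__(self, "channel", self.modality.value)
        if self.units == "":
            object.__setattr__(self, "units", MODALITY_UNITS[self.modality])

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs


@dataclass(frozen=True)
class Segment:
    """A fixed-length windowed view of a record.

    ``samples`` is the bit-exact slice of the parent record; ``start_s``
    is the window offset in seconds on the segmentation grid.
    """

    record_id: str
    modality: Modality
    start_s: float
    samples: np.ndarray
    fs: float
    channel: str = ""

    def __post_init__(self):
        object.__setattr__(self, "modality", _as_modality(self.modality))
        if not self.channel:
            object.__setattr__(self, "channel", self.modality.value)

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


def segment_record(
    record: SignalRecord, window_s: float = 10.0, step_s: float = 5.0
) -> list[Segment]:
    """Split a record into fixed-length overlapping segments.

    Windows of ``window_s`` seconds are placed every ``step_s`` seconds
    starting at 0; each holds exactly ``round(window_s * fs)`` samples.
    A trailing span shorter than one window is discarded, so the number of
    segments is ``floor((duration - window_s) / step_s) + 1`` for records
    at least one window long, and 0 otherwise.

    Raises
    ------
    ConfigurationError
        If ``window_s <= 0`` or ``step_s`` is not in ``(0, window_s]``.
    """
    if window_s <= 0:
        raise ConfigurationError("window_s must be positive")
    if not 0 < step_s <= window_s:
        raise ConfigurationError("step_s must be in (0, window_s]")
    wlen = int(round(window_s * record.fs))
    if wlen < 1:
        raise ConfigurationError("window shorter than one sample")
    n = record.samples.size
    segments: list[Segment] = []
    i = 0
    while True:
        start_idx = int(round(i * step_s * record.fs))
        if start_idx + wlen > n:
            break
        segments.append(
            Segment(
                record_id=record.record_id,
                modality=record.modality,
                start_s=i * step_s,
                samples=record.samples[start_idx : start_idx + wlen],
                fs=record.fs,
                channel=record.channel,
            )
        )
        i += 1
    return segments
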