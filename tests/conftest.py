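import numpy as np
import pytest

import sigsuit as ss


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_ecg_10s():
    """10 s clean synthetic ECG at 60 beats/min, 500 Hz, with beat truth."""
    spec = ss.default_spec("ECG", duration=10.0, seed=7, rate=60.0)
    return ss.gen_ecg(spec)


@pytest.fixture
def eeg_segment():
    rec = ss.gen_eeg(ss.default_spec("EEG", duration=10.0, seed=3))
    return ss.segment_record(rec)[0]


def make_segment(samples, fs, modality="EEG", record_id="r0"):
    return ss.Segment(
        record_id=record_id,
        modality=ss.Modality(modality),
        start_s=0.0,
        samples=np.asarray(samples, dtype=float),
        fs=fs,
    )
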