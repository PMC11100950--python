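import numpy as np
import pytest
from scipy import signal as sp_signal

import sigsuit as ss
from sigsuit.exceptions import BoundsError, ConfigurationError


class TestGenECG:
    def test_beat_count_matches_rate(self):
        rec, beats = ss.gen_ecg(ss.default_spec("ECG", duration=10.0, seed=0, rate=60.0))
        assert abs(len(beats) - 10) <= 1

    def test_determinism(self):
        spec = ss.default_spec("ECG", duration=10.0, seed=7)
        a, beats_a = ss.gen_ecg(spec)
        b, beats_b = ss.gen_ecg(spec)
        np.testing.assert_array_equal(a.samples, b.samples)
        np.testing.assert_array_equal(beats_a, beats_b)

    def test_mean_rr_interval(self):
        _, beats = ss.gen_ecg(ss.default_spec("ECG", duration=60.0, seed=1, rate=72.0, fs=250.0))
        assert np.diff(beats).mean() == pytest.approx(60.0 / 72.0, rel=0.01)

    def test_peak_amplitude_near_spec(self):
        rec, _ = ss.gen_ecg(ss.default_spec("ECG", duration=10.0, seed=2, amplitude=1.5))
        assert np.abs(rec.samples).max() <= 1.5 * 1.1

    def test_invalid_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            ss.gen_ecg(ss.default_spec("ECG", duration=10.0, rate=400.0))


class TestGenEEG:
    def test_amplitude_within_modality_range(self):
        rec = ss.gen_eeg(ss.default_spec("EEG", duration=10.0, seed=1, amplitude=50.0))
        assert np.abs(rec.samples).max() <= 110.0
        inside = np.abs(rec.samples) <= 50.0
        assert inside.mean() >= 0.99

    def test_zero_amplitude_zero_noise_all_zero(self):
        spec = ss.WaveformSpec("EEG", fs=128.0, duration=10.0, amplitude=0.0, noise_sd=0.0)
        assert np.all(ss.gen_eeg(spec).samples == 0.0)

    def test_band_limited_below_30hz(self):
        rec = ss.gen_eeg(ss.default_spec("EEG", duration=30.0, seed=5))
        f, p = sp_signal.periodogram(rec.samples, fs=rec.fs)
        assert p[f > 30.0].sum() / p.sum() < 0.05

    def test_zero_mean(self):
        rec = ss.gen_eeg(ss.default_spec("EEG", duration=30.0, seed=6))
        assert abs(rec.samples.mean()) < 0.05 * 50.0


class TestGenResp:
    def test_capnography_within_range(self):
        spec = ss.default_spec("RESP_CAPNO", duration=60.0, seed=3, rate=12.0, amplitude=40.0)
        rec = ss.gen_resp(spec)
        assert rec.samples.min() >= 0.0
        assert rec.samples.max() <= 50.0

    def test_airflow_zero_mean(self):
        rec = ss.gen_resp(ss.default_spec("RESP_AIRFLOW", duration=60.0, seed=3, rate=12.0))
        assert abs(rec.samples.mean()) <= 0.01 * 1.0

    def test_dominant_frequency(self):
        spec = ss.default_spec("RESP_CAPNO", duration=120.0, seed=4, rate=12.0)
        rec = ss.gen_resp(spec)
        f, p = sp_signal.periodogram(rec.samples, fs=rec.fs)
        assert f[1:][np.argmax(p[1:])] == pytest.approx(0.2, abs=0.02)

    def test_rate_bounds(self):
        with pytest.raises(ConfigurationError):
            ss.gen_resp(ss.default_spec("RESP_CAPNO", duration=10.0, rate=1.0))


class TestInjectArtifact:
    def test_flatline_triggers_constant_rule(self, clean_ecg_10s):
        rec = ss.inject_artifact(
            clean_ecg_10s.record, ss.ArtifactAnnotation(kind="FLATLINE", start=2.0, duration=0.6)
        )
        assert ss.detect_constant(ss.segment_record(rec)[0])
        # input unmodified
        assert not ss.detect_constant(ss.segment_record(clean_ecg_10s.record)[0])

    def test_out_of_range_triggers_range_rule(self, clean_ecg_10s):
        rec = ss.inject_artifact(
            clean_ecg_10s.record,
            ss.ArtifactAnnotation(kind="OUT_OF_RANGE", start=4.0, duration=1.0,
                                  parameters={"excursion": 4.0}),
        )
        seg = ss.segment_record(rec)[0]
        assert rec.samples.max() > 3.5
        assert ss.check_range(seg) is True

    def test_dropout_is_constant_zero(self, clean_ecg_10s):
        rec = ss.inject_artifact(
            clean_ecg_10s.record, ss.ArtifactAnnotation(kind="DROPOUT", start=1.0, duration=0.6)
        )
        assert ss.detect_constant(ss.segment_record(rec)[0])
        i0 = int(1.0 * rec.fs)
        assert np.all(rec.samples[i0 : i0 + int(0.6 * rec.fs)] == 0.0)

    def test_clipping_saturates(self, clean_ecg_10s):
        rec = ss.inject_artifact(
            clean_ecg_10s.record,
            ss.ArtifactAnnotation(kind="CLIPPING", start=0.0, duration=10.0,
                                  parameters={"level": 0.5}),
        )
        assert rec.samples.max() <= 0.5 + 1e-12

    def test_sawtooth_raises_zcr(self):
        # noiseless ECG crosses zero only around the QRS complex; a
        # superimposed high-frequency triangle wave dominates the crossings
        rec, _ = ss.gen_ecg(
            ss.default_spec("ECG", duration=10.0, seed=4, rate=60.0, noise_sd=0.0)
        )
        noisy = ss.inject_artifact(
            rec,
            ss.ArtifactAnnotation(kind="SAWTOOTH", start=0.0, duration=10.0,
                                  parameters={"frequency": 40.0, "amplitude": 3.0}),
        )
        zcr_clean = ss.zero_crossing_rate(ss.segment_record(rec)[0])
        zcr_noisy = ss.zero_crossing_rate(ss.segment_record(noisy)[0])
        assert zcr_noisy > 3 * zcr_clean

    def test_out_of_bounds_rejected(self, clean_ecg_10s):
        with pytest.raises(BoundsError):
            ss.inject_artifact(
                clean_ecg_10s.record, ss.ArtifactAnnotation(kind="DROPOUT", start=9.0, duration=2.0)
            )


class TestGenDataset:
    SPECS = {
        "EEG1": ss.default_spec("EEG", duration=10.0, seed=1),
        "ECG": ss.default_spec("ECG", duration=10.0, seed=2, fs=250.0),
        "Resp": ss.default_spec("RESP_CAPNO", duration=10.0, seed=3),
    }

    def test_zero_corruption_all_pass(self):
        bundle = ss.gen_dataset(self.SPECS, ss.CorruptionConfig(probability=0.0, seed=5), 10)
        assert bundle.annotations == []
        for channels in bundle.records.values():
            for rec in channels.values():
                seg = ss.segment_record(rec)[0]
                assert ss.evaluate_rules(seg).pass_rules

    def test_same_seed_identical(self):
        a = ss.gen_dataset(self.SPECS, ss.CorruptionConfig(probability=0.3, seed=9), 5)
        b = ss.gen_dataset(self.SPECS, ss.CorruptionConfig(probability=0.3, seed=9), 5)
        assert [(x.record_id, x.channel, x.kind, x.start) for x in a.annotations] == [
            (x.record_id, x.channel, x.kind, x.start) for x in b.annotations
        ]
        for rid in a.records:
            for ch in a.records[rid]:
                np.testing.assert_array_equal(
                    a.records[rid][ch].samples, b.records[rid][ch].samples
                )

    def test_adding_channel_does_not_perturb_existing(self):
        cfg = ss.CorruptionConfig(probability=0.3, seed=9)
        small = ss.gen_dataset({"ECG": self.SPECS["ECG"]}, cfg, 5)
        big = ss.gen_dataset(self.SPECS, cfg, 5)
        for rid in small.records:
            np.testing.assert_array_equal(
                small.records[rid]["ECG"].samples, big.records[rid]["ECG"].samples
            )

    def test_corruption_rate_recovered(self):
        p = 0.2
        n = 400
        bundle = ss.gen_dataset(self.SPECS, ss.CorruptionConfig(probability=p, seed=21), n)
        fails = {ch: 0 for ch in self.SPECS}
        for channels in bundle.records.values():
            for ch, rec in channels.items():
                seg = ss.segment_record(rec, 10, 10)[0]
                fails[ch] += not ss.evaluate_rules(seg).pass_rules
        se = (p * (1 - p) / n) ** 0.5
        for ch, k in fails.items():
            assert abs(k / n - p) < 3 * se, ch

    def test_flags_match_ground_truth_exactly(self):
        """Every corrupted span is flagged and every clean span passes."""
        bundle = ss.gen_dataset(self.SPECS, ss.CorruptionConfig(probability=0.3, seed=13), 50)
        for rid, channels in bundle.records.items():
            for ch, rec in channels.items():
                seg = ss.segment_record(rec, 10, 10)[0]
                expected_bad = bundle.corrupted[(rid, ch, 0)]
                assert ss.evaluate_rules(seg).pass_rules == (not expected_bad)

    def test_mismatched_durations_rejected(self):
        specs = dict(self.SPECS)
        specs["EEG1"] = ss.default_spec("EEG", duration=20.0, seed=1)
        with pytest.raises(ConfigurationError):
            ss.gen_dataset(specs, ss.CorruptionConfig(seed=1), 1)


def test_corruption_config_validation():
    with pytest.raises(ConfigurationError):
        ss.CorruptionConfig(probability=1.5)
    with pytest.raises(ConfigurationError):
        ss.CorruptionConfig(weights={ss.ArtifactKind.FLATLINE: 0.5})
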