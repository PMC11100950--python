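import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sigsuit as ss
from sigsuit.exceptions import ConfigurationError


def brute_force_confusion(values, lower, upper, bad):
    tp = fp = fn = 0
    for v, b in zip(values, bad):
        pred = v < lower or v > upper
        if pred and b:
            tp += 1
        elif pred and not b:
            fp += 1
        elif not pred and b:
            fn += 1
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return precision, recall


class TestBuildHistogram:
    def test_frequencies_sum_to_one(self, rng):
        h = ss.build_histogram(rng.random(5000), (0, 1), 100)
        assert h.freq.sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_sample_near_flat(self, rng):
        h = ss.build_histogram(rng.random(200_000), (0, 1), 50)
        assert np.all(np.abs(h.freq - 0.02) < 0.005)

    def test_single_bin(self):
        h = ss.build_histogram(np.full(100, 0.5), (0, 1), 10)
        assert h.freq.max() == 1.0

    def test_out_of_range_and_nan_excluded(self):
        values = [0.5] * 8 + [2.0, float("nan")]
        h = ss.build_histogram(values, (0, 1), 10)
        assert h.n == 8
        assert h.freq.sum() == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            ss.build_histogram([5.0], (0, 1), 10)


class TestCorrelation:
    def test_identical_histograms_r_one(self, rng):
        v = rng.normal(0.5, 0.1, 10_000)
        pair = ss.histogram_pair(v, v, (0, 1), 1000)
        assert pair.correlation == pytest.approx(1.0, abs=1e-12)

    def test_same_distribution_high_r(self, rng):
        a = rng.normal(0.5, 0.1, 150_000)
        b = rng.normal(0.5, 0.1, 150_000)
        pair = ss.histogram_pair(a, b, (0, 1), 1000)
        assert pair.correlation > 0.95

    def test_different_shapes_low_r_matches_oracle(self, rng):
        uniform = rng.random(50_000)
        peaked = rng.normal(0.5, 0.02, 50_000)
        pair = ss.histogram_pair(uniform, peaked, (0, 1), 200)
        # independent brute-force Pearson on the binned vectors
        a, b = pair.freq_a, pair.freq_b
        expected = float(
            ((a - a.mean()) * (b - b.mean())).sum()
            / math.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
        )
        assert pair.correlation == pytest.approx(expected, abs=1e-12)
        assert pair.correlation < 0.5

    def test_symmetry_and_zero_variance(self):
        a = np.array([0.2, 0.3, 0.5])
        b = np.array([0.5, 0.3, 0.2])
        assert ss.histogram_correlation(a, b) == ss.histogram_correlation(b, a)
        assert math.isnan(ss.histogram_correlation(a, np.full(3, 1 / 3)))


class TestMatchHistogram:
    def test_matching_to_own_moments_is_identity(self, rng):
        v = rng.normal(3.0, 2.0, 1000)
        out = ss.match_histogram(v, v.mean(), v.var())
        np.testing.assert_allclose(out, v, atol=1e-10)

    def test_targets_reproduced(self, rng):
        v = rng.standard_normal(10_000)
        out = ss.match_histogram(v, 0.5, 0.04)
        assert out.mean() == pytest.approx(0.5, abs=1e-10)
        assert out.var() == pytest.approx(0.04, abs=1e-10)

    def test_matching_increases_correlation_on_shifted_data(self, rng):
        a = rng.normal(0.5, 0.10, 80_000)
        b = rng.normal(0.65, 0.07, 80_000)  # biased sampling-rate analogue
        before = ss.histogram_pair(a, b, (0, 1), 200).correlation
        matched = ss.match_histogram(b, a.mean(), a.var())
        after = ss.histogram_pair(a, matched, (0, 1), 200).correlation
        assert after > before

    def test_zero_variance_rejected(self):
        with pytest.raises(ConfigurationError):
            ss.match_histogram(np.full(10, 1.0), 0.0, 1.0)


class TestOutlierThresholds:
    def _trimodal(self, rng, n=30_000, means=(0.2, 0.5, 0.8), sd=0.04, weights=(0.2, 0.6, 0.2)):
        comp = rng.choice(3, size=n, p=weights)
        return rng.normal(np.asarray(means)[comp], sd)

    def test_three_gaussian_valleys_recovered(self, rng):
        values = self._trimodal(rng)
        h = ss.build_histogram(values, (0, 1), 1000)
        thr = ss.find_outlier_thresholds(h)
        assert thr is not None
        # valleys of well-separated equal-sd mixture lie near the midpoints
        assert abs(thr.lower - 0.35) < 0.05
        assert abs(thr.upper - 0.65) < 0.05

    def test_symmetric_mixture_symmetric_thresholds(self, rng):
        values = self._trimodal(rng, weights=(0.25, 0.5, 0.25))
        thr = ss.find_outlier_thresholds(ss.build_histogram(values, (0, 1), 1000))
        assert (thr.lower + thr.upper) / 2 == pytest.approx(0.5, abs=0.03)

    def test_unimodal_not_computable(self, rng):
        values = rng.normal(0.5, 0.05, 20_000)
        h = ss.build_histogram(values, (0, 1), 200)
        assert ss.find_outlier_thresholds(h) is None


class TestOutlierMetrics:
    def test_perfect_predictions(self):
        values = np.array([0.1, 0.9, 0.5, 0.55])
        bad = np.array([True, True, False, False])
        thr = ss.OutlierThresholds(0.3, 0.7)
        assert ss.outlier_detection_metrics(values, thr, bad) == (1.0, 1.0)

    def test_nothing_predicted(self):
        values = np.array([0.5, 0.5])
        thr = ss.OutlierThresholds(0.0, 1.0)
        precision, recall = ss.outlier_detection_metrics(values, thr, [True, False])
        assert math.isnan(precision)
        assert recall == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        values=st.lists(st.floats(0, 1, width=32), min_size=1, max_size=50),
        labels=st.data(),
    )
    def test_matches_brute_force_confusion_matrix(self, values, labels):
        bad = labels.draw(
            st.lists(st.booleans(), min_size=len(values), max_size=len(values))
        )
        thr = ss.OutlierThresholds(0.25, 0.75)
        got = ss.outlier_detection_metrics(np.array(values), thr, np.array(bad))
        expected = brute_force_confusion(values, 0.25, 0.75, bad)
        for g, e in zip(got, expected):
            assert (math.isnan(g) and math.isnan(e)) or g == pytest.approx(e)

    def test_artifact_driven_entropy_outliers(self):
        """Injected broadband/flat artifacts push ECG spectral entropy to the
        extremes; thresholding detects them with high precision."""
        rng = np.random.default_rng(77)
        entropies, bad = [], []
        for i in range(120):
            rec, _ = ss.gen_ecg(ss.default_spec("ECG", duration=10.0, seed=i, fs=250.0))
            corrupt = i % 3 == 0
            if corrupt:
                kind = "SAWTOOTH" if i % 2 else "DROPOUT"
                rec = ss.inject_artifact(
                    rec,
                    ss.ArtifactAnnotation(
                        kind=kind, start=1.0, duration=8.0,
                        parameters={"frequency": 60.0, "amplitude": 2.0},
                    ),
                )
            seg = ss.segment_record(rec)[0]
            entropies.append(ss.spectral_entropy(seg))
            bad.append(corrupt)
        entropies = np.array(entropies)
        clean = entropies[~np.array(bad)]
        thr = ss.OutlierThresholds(clean.min() - 0.02, clean.max() + 0.02)
        precision, recall = ss.outlier_detection_metrics(entropies, thr, bad)
        expected = brute_force_confusion(entropies, thr.lower, thr.upper, bad)
        assert (precision, recall) == expected
        assert precision == pytest.approx(1.0)
        assert recall > 0.5


def test_default_ranges():
    assert ss.default_range("entropy") == (0.0, 1.0)
    assert ss.default_range("kurtosis", "ECG") == (0.0, 50.0)
    with pytest.raises(ConfigurationError):
        ss.default_range("unknown_sqi")


def test_back_to_back_plot(tmp_path, rng):
    pair = ss.histogram_pair(rng.random(1000), rng.random(1000), (0, 1), 50)
    out = tmp_path / "hist.png"
    ss.plot_back_to_back(pair, out, labels=("A", "B"), title="entropy")
    assert out.stat().st_size > 0
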