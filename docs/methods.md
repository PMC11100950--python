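# Methods

## Segmentation

Records are split into windows of `window_s = 10` s placed every
`step_s = 5` s (50% overlap).  Windows are defined on sample indices
(`start index = round(start_s · fs)`, length `round(window_s · fs)`), so
channels with different sampling rates share a wall-clock grid without
resampling.  Trailing spans shorter than one window are discarded: every
indicator assumes a full 10 s of support.  No other preprocessing is
applied anywhere — no filtering, resampling, detrending, or baseline
removal — so the indicators see the rawest possible signal.  (R-peak
detectors filter *internally*; that is part of the detection algorithm,
not of the data path.)

## Rule-based indicators

**Constant data.**  A segment is flagged iff some run of
`w = round(0.5 s · fs)` consecutive samples is exactly equal.  Equality
is exact by default because flatlines produced by sensor loss or
clipping repeat identical quantized values; an absolute tolerance
parameter (default 0) is exposed for floating-point sources.  The
implementation reduces to the longest run of zero first-differences and
is property-tested against a brute-force all-runs scan.  By
construction the rule is monotone: flagged at window `w` implies flagged
at any shorter window.

**Out-of-range data.**  A segment is flagged iff its minimum or maximum
leaves the modality's clinically normal interval: EEG [−110, 110] µV,
ECG [−3.5, 3.5] mV, capnography [0, 50] mmHg.  Dimensionless airflow has
no defensible range; its range check returns *not applicable*, such
segments are excluded from out-of-range denominators, and in multimodal
suitability a not-applicable check never counts as a violation.

Summary percentages are reported record-averaged by default (arithmetic
mean of per-record percentages) with a segment-pooled alternative; the
two differ whenever record lengths differ.

## Statistical indicators

All six statistics are per-segment and deterministic.

* **Envelope std**: the segment is min–max scaled to [−1, 1], split
  into consecutive non-overlapping sub-windows — 2 s for ECG/EEG
  (5 maxima/minima per segment), 5 s for respiration (2 each) — and the
  sample std (N−1) of the sub-window maxima (upper) and minima (lower)
  is taken.  Scaling is per segment, the analysis unit throughout.  A
  constant segment has no defined scaling and reports (0, 0) with a
  degenerate flag.
* **Skewness / kurtosis**: standardized third/fourth moments with the
  population (N) normalization for σ, matching
  `scipy.stats.skew(bias=True)` and `kurtosis(fisher=False, bias=True)`
  (Gaussian → 3).  The σ ddof is exposed as an option; the bundled
  brute-force oracle pins whichever convention is configured.  Zero
  variance yields NaN (not computable).
* **Spectral entropy**: one-sided periodogram of the raw segment
  (boxcar window, no detrending — consistent with the no-preprocessing
  policy), normalized to sum 1 over its M bins (DC included), Shannon
  entropy in bits divided by log₂ M.  The estimator, window, and
  detrending are options since nothing forces this particular choice; a
  uniform PSD gives exactly 1, a one-bin PSD exactly 0, all-zero
  segments NaN.
* **Zero-crossing rate**: count of strictly negative adjacent products
  over N−1.  Exact zeros contribute no crossing (strict inequality as
  defined); no mean removal is applied, so a signal riding a DC offset
  legitimately scores near zero.

Summaries are per-record means over segments (NaN excluded), then
mean ± std across records; a pooled-over-segments mode exists because
the choice is not forced by anything and both are defensible.

## Physiological ECG indicators

Three R-peak detectors from distinct algorithm families run per
segment:

1. *Derivative–energy* (Pan–Tompkins family): 5–15 Hz zero-phase
   band-pass, squared derivative, 150 ms moving-average integration,
   peaks above 25% of the segment maximum with a 250 ms refractory
   period.
2. *Two moving averages*: 8–20 Hz band-pass, squared, 120 ms event
   average compared against a 600 ms background average plus an offset;
   blocks at least 80 ms wide become candidates.
3. *Stationary-wavelet detail* (filter-bank family): db3 SWT detail at
   the level whose band covers ≈ 8–16 Hz, squared, 100 ms smoothed,
   peak-picked.

All candidates are refined to the raw-signal maximum within ±100 ms and
deduplicated with the 250 ms refractory rule, so on clean signals the
three detectors agree to within a few milliseconds.  These are
re-implementations in the named families, not clones of any specific
published tool; `assess_quality` accepts external beat sequences so any
detector or annotation file can be plugged in.

Conditions per detector: (1) HR = 60 / mean(RR) ∈ [40, 180] beats/min
(mean over the segment; a median estimator is an option), (2)
max(RR) ≤ 3 s, (3) max(RR)/min(RR) ≤ 2.2.  All bounds are non-strict.
A detector with fewer than two beats has no RR interval and fails all
three; condition 3 needs at least two intervals (three beats).  Each
condition passes on a 2-of-3 majority, and a segment is good quality
iff all three votes pass.  Voting is symmetric in detector order.

## Multimodal suitability

Per-channel segments are aligned by shared start time (start times
present in only some channels are dropped).  A combination of channels
is suitable in an aligned set iff every member passes the rule-based
SQIs; only the rule-based indicators enter by default (they are the
ones defined for every modality), with an option to additionally
require the ECG physiological label.  Percentages are computed for all
combinations of sizes 2, 3, 4, with mean ± std across combinations of
each size; pooled over segments by default, record-averaged as an
option.  Useful invariants, all tested: suitability is non-increasing
in combination size; it respects the Bonferroni lower bound
`Σ pass_rates − (k−1)·100`; a singleton combination equals the
channel's unimodal pass rate.

## Histogram analysis

Histograms aggregate all segments of a dataset and are normalized by
the number of included values.  Bounded SQIs (entropy, zcr, envelope
stds) are binned on [0, 1]; skewness and kurtosis on conventional
display ranges (e.g. [0, 50] for ECG kurtosis, [−8, 8] for ECG
skewness).  Values outside the range are *excluded*, not clipped — the
range is an analysis window, and clipping would fabricate mass at the
edges.  Cross-dataset similarity is the Pearson correlation of the two
frequency vectors on a shared 1000-bin grid.  Formal two-sample tests
are deliberately avoided: at these sample sizes they flag trivially
small differences.

Because spectral entropy depends on the sampling rate, one dataset's
entropy values can be affinely matched
(`y = (x − μ)/σ · σ_target + μ_target`) to the other's moments before
comparison; the transform is exact to numerical precision and idempotent
at the source moments.

Trimodal entropy histograms (a central physiological mode flanked by a
low-entropy flatline mode and a high-entropy noise mode) yield automatic
outlier thresholds: the frequency vector is smoothed with a moving
average of 2% of the bins, local maxima at least 5% of the axis apart
are found, the three highest are the peaks, and each threshold is the
minimum smoothed frequency between adjacent peaks — taken at the middle
of the plateau when the minimum is flat, so empty gaps split midway.
Fewer than three separated peaks returns not-computable.  The smoothing
width, separation, and bin count are design choices, exposed as
parameters.  Thresholded values act as a bad-quality classifier whose
precision and recall are computed against the physiological labels.

## Synthetic data generator

The generator defines the study conditions for all tests and for the
acceptance script.

* **ECG**: Gaussian kernels for P, Q, R, S, T at fixed offsets/widths
  placed at beat times (first beat half an RR interval in, optional
  fractional RR jitter), scaled so the R peak reaches the spec
  amplitude (default 1.5 mV at 500 Hz, 70 beats/min, 0.02 mV additive
  noise).  Ground-truth beat times are returned.  At high heart rates
  adjacent waves overlap slightly; morphology realism (arrhythmia,
  axis, noise color) is out of scope — the waveform exists to exercise
  R-peak detectors and RR-based rules.
* **EEG**: white Gaussian noise low-passed at 25 Hz (zero-phase
  Butterworth) and scaled to std = amplitude/3, so ≥ 99% of samples lie
  within ±amplitude (default 50 µV at 128 Hz) and out-of-band power
  stays below 5%.
* **Respiration**: raised-cosine capnography in [baseline, amplitude]
  mmHg with the baseline at least 5 noise-stds above zero (default
  38 mmHg, 14 breaths/min, 62.5 Hz), or a zero-mean sinusoid for
  dimensionless airflow (25 Hz).

Defaults keep clean signals within ~90% of each modality's amplitude
range, so only injected artifacts trip the range rule.  Artifacts are
sample-aligned spans: FLATLINE (constant), DROPOUT (zero), OUT_OF_RANGE
(half-sine excursion defaulting to 1.2× the range width), CLIPPING
(saturation), SAWTOOTH (additive triangle wave; a generic stand-in for
broadband interference such as electrocautery, whose parameters are
free).  Dataset generation draws corruption independently per channel
and per non-overlapping 10 s span with a configurable probability; the
default artifact mixture (flatline 0.4 / out-of-range 0.4 / dropout
0.2) contains only kinds the rule-based SQIs detect deterministically,
which makes the drawn corruption rate exactly recoverable in
expectation — clipping and sawtooth default to weight 0 and are injected
explicitly where the statistical and physiological indicators are the
subject.  Each channel has its own random stream derived from the
master seed and a hash of the channel name, so adding a channel never
perturbs the others; everything is bit-reproducible under its seed.

What passing tests on this generator do *not* show: robustness to real
electrode artifacts, drifting baselines, arrhythmias, or colored noise.
The generator establishes that the machinery is correct, not that the
thresholds are clinically optimal.

## File formats

EDF reading and writing are implemented against the EDF field layout
(16-bit samples, per-signal physical/digital scaling, one data-record
duration chosen in 1–10 s so that every channel's samples-per-record is
integral; trailing partial records are padded with the last value).
Physical bounds are chosen to fit EDF's 8-character ASCII header fields
and are carried on records read from files, so write → read → write is
byte-identical and a record already on the quantization grid
(`edf_quantized`) round-trips bit-exactly.  The reader is cross-checked
against MNE's independent EDF implementation in the test suite.
Track-table CSVs (time/value pairs or a bare value column at a known
rate) map onto the uniform sampling grid with gaps as NaN; the fill
policy materializes gaps as a constant value so that data loss is caught
by the constant-data rule.  All report outputs are plain CSV with fixed
float formatting plus a JSON run log (config hash + seed and no
timestamps), making a rerun with the same config and seed
byte-identical.

## Problem sizes

The test suite and acceptance script use synthetic datasets sized for
tight statistical checks at desk scale: 800–1000 single-span records
for corruption-rate recovery (3-standard-error binomial bands), 30 000
samples for valley recovery on a three-Gaussian mixture, 300 ECG
segments for the entropy-outlier experiment, and 20–60 s records
elsewhere.  These sizes are the package's own choice of experiment
scale; all quantities are reported with the `n` actually used.
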