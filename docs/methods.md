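# Methods

This note documents the models, conventions and numerical choices behind
pulseline, in the order the data flows through the pipeline, followed by
the synthetic validation harness and its limits.

## Preprocessing

Raw waveforms are (1) upsampled with an interpolating cubic spline to a
uniform high rate (default 1000 Hz) so that peak times are resolved to
1 ms regardless of the sensor rate, (2) high-pass filtered at 0.5 Hz to
remove baseline wander, and (3) smoothed with a Savitzky–Golay filter
(3rd-order, 100 ms window) to suppress spike artifacts while keeping peak
timing.

Choices the design left open:

- **Stage order.** Interpolation runs before filtering so that a single
  filter design applies to every input rate.
- **Butterworth order and phase.** Order 2, applied forward and backward
  (`sosfiltfilt`): peak times must not shift, so zero phase is mandatory;
  the effective magnitude response is the square of the one-pass response
  (≈ −0.01 dB at 2 Hz, ≈ −40 dB at 0.05 Hz for the 0.5 Hz cutoff).
- **Smoothing window.** `round(window_ms × rate / 1000)` to the nearest
  odd integer, at least polyorder + 2; edges are mirror-padded (edge
  distortion is consumed by windowing anyway).
- **Non-finite samples are a hard error.** Artifact handling belongs to
  the cleaning stage, which sees detected peaks; silently imputing inside
  a filter would hide exactly the evidence cleaning needs.

## Windowed detection

Each window (default 10 s, moved by 10 s; overlap is the complementary
view of the same parameter) is affinely scaled so its minimum maps to 0
and maximum to 100, making the amplitude threshold (default 50) a
percentage of the window's dynamic range and the detector invariant to
gain and offset. Peaks must clear the threshold and be ≥ 250 ms apart;
heights, prominences and half-prominence widths come from
`scipy.signal`'s peak machinery. A constant window cannot be scaled and
is discarded as degenerate.

For ECG, amplitude-only detection can mistake prominent P or T waves for
beats. The clustering mode lowers the detection floor to 5 (so all three
wave types are caught), z-scores the per-window feature triple (width,
height, prominence), and runs k-means with k = 3 and 10 restarts under a
fixed internal seed — reruns must be bit-identical. The retained cluster
maximises (prominence centroid − width centroid) in z units, ties broken
toward the narrower cluster; R waves are narrow and prominent, P/T wide
and low. With fewer than 6 candidates, or fewer than 3 distinct feature
vectors, clustering is meaningless: detection falls back to the plain
threshold and the window carries a `clustering_fallback` flag.

Because a window can open or close mid-beat, the first and last peak may
have their bases measured on a partial wave; their prominences are
recomputed against the baseline (height − prominence) of the nearest
interior neighbour.

## Metrics

Intervals are carried in milliseconds throughout. RMSSD divides the sum
of squared successive differences by the number of differences (interval
count − 1); SDNN and SDSD use the sample (n − 1) standard deviation.
PNN20/PNN50 are the fractions of successive differences exceeding
20/50 ms. HF power cubic-interpolates the IBI tachogram onto a uniform
4 Hz grid and integrates the Welch periodogram over 0.15–0.4 Hz; it
returns NaN with fewer than 4 intervals or a beat span under ~6.7 s (one
period of the lower band edge), since spectral estimation needs more data
than the time-domain measures.

## Cleaning

Two parallel series are produced: the *uncleaned* series keeps every
window with at least `min_peaks` (default 3, the minimum for RMSSD); the
*cleaned* series additionally requires

- BPM and RMSSD inside the preset range (values exactly at a bound pass,
  so the liberal lower RMSSD bound of 0 imposes no constraint);
- no peak height, prominence or interbeat interval deviating from the
  window median by more than the preset threshold in **robust z units**:
  raw MAD deviations are divided by the normal-consistency constant
  1.4826, so a threshold of 5 means five (robust) standard deviations.
  Read as raw MAD multiples instead, 5 units would be ~3.4 σ and
  ordinary beat-to-beat variability would trip the rule on perfectly
  clean recordings;
- the first-to-last-peak span covering at least half the window.

Presets: liberal (BPM 20–200, RMSSD 0–300 ms, 7 units), moderate
(30–190, 5–262, 5; default), conservative (40–180, 10–200, 4).

Two degenerate-denominator safeguards: when the MAD is exactly zero, any
value off the median by more than a 1e-9 relative epsilon is flagged (a
lone spike among identical values is precisely the targeted artifact);
and the MAD denominator is floored at the measurement resolution
(0.5 scaled units for heights/prominences, 2 ms for intervals — the
peak-time quantisation at the 1 kHz analysis rate), because below that
scale "deviation in MAD units" is a ratio of numerical noise. The floors
are resolution constants, identical across presets.

MAD screening is strictly per window; pooling across windows would
confound artifact rejection with genuine slow HR changes.

## Synthetic recordings

The generator produces labelled recordings for parameter-recovery
studies; its defaults are the study conditions used by the validation
harness.

- **Intervals**: i.i.d. Gaussian, mean 60000/BPM ms, σ = RMSSD/√2
  (successive differences of i.i.d. values have variance 2σ², giving the
  target RMSSD analytically), truncated at ±3σ and floored at 250 ms.
  The stored ground truth (`true_bpm`, `true_rmssd_ms`) is recomputed
  from the realized beat times with the metrics module's own formulas.
- **PPG waveform**: per beat, a systolic Gaussian bump (amplitude 1,
  σ = 6% of the local interval) plus a dicrotic bump (amplitude 0.4 at
  +30% of the interval, σ = 10%).
- **ECG waveform**: R wave (amplitude 1, σ = 12 ms) with P before
  (−160 ms, amplitude 0.15, σ = 25 ms) and T after (+250 ms, amplitude
  0.3, σ = 50 ms).
- **Degradation**: the clean 1 kHz rendering is first resampled
  (anti-aliased polyphase) to the deployment rate, then white Gaussian
  noise is added at the requested SNR *at that rate* (power measured
  after mean removal). Adding wideband noise before anti-aliased
  downsampling would silently discard most of the noise power — at 20 Hz
  only 2% of a 1 kHz noise band survives — and a nominal 0.01 dB would
  behave like ~17 dB; a low-rate sensor's noise is in-band by
  construction.
- All randomness derives from the single spec seed.

What the generator does **not** model: autocorrelated interval dynamics,
respiratory sinus arrhythmia, waveform morphology changes, motion
artifacts, baseline drift. Passing recovery tests therefore demonstrate
the estimation chain's accuracy under controlled noise and sampling
conditions, not robustness to physiological or ambulatory confounds —
which is exactly what the real-data benchmark script is for.

## Validation statistics

- **ICC(A,1)** — two-way, absolute agreement, single measure — from the
  two-way ANOVA mean squares of the subjects × (truth, estimate) table;
  verified in tests against an independent implementation.
- **RMSE** over pairs with a finite estimate (recordings whose cleaned
  series is empty are excluded and counted).
- **Paired Cohen's d** = mean(diff)/SD(diff); the conversion from a
  paired t statistic is d = t/√n with n = df + 1 pairs.
- **Paired-t sample size**: smallest n whose noncentral-t power reaches
  the target (doubling bracket + binary search; two-sided by default,
  which reproduces the 171-subject design of the anxiety simulation).
  The wrong-signed-tail term of the two-sided power is guarded against
  NaN from `scipy.stats.nct` deep in the tail, where it is numerically 0.
- **Jerk magnitude**: per-axis Δa/Δt on a uniform grid (1 ppm
  tolerance), Euclidean norm across axes, averaged over time.

## Simulated anxiety experiment

Each subject's safe-condition RMSSD is drawn from N(23, 7) ms truncated
to [5, 262]; the threat condition subtracts a per-subject difference
drawn from N(d·σ, σ) with σ = 7 ms, so the population paired d equals
the nominal effect (a constant shift would be degenerate: zero
difference variance, unbounded d). Heart rate (N(74, 13), constant
within subject) is unaffected. Both conditions are rendered, degraded,
analyzed, and the effect re-estimated as the paired d of per-subject
mean cleaned RMSSD; repeats give a confidence interval.

## Problem sizes

The acceptance script runs the full 273-recording grid (BPM 60–120 step
5 × RMSSD 0–100 step 5) with five-minute recordings, as in the original
study design; one grid condition takes about a minute on one CPU. The
test suite exercises the same machinery on a half-density grid with
two-minute recordings and a 1-minute-recording anxiety experiment —
sizes chosen so the whole suite stays in the minutes range while
preserving the qualitative pattern (excellent recovery at moderate SNR,
collapse at 0.01 dB). Shorter recordings mean fewer windows per
estimate, so the scaled-down RMSSD RMSE is expectedly somewhat larger
than the full-scale value.

## Known limitations

- The i.i.d. interval model makes per-window RMSSD estimates slightly
  concave-biased (Jensen: average of per-window root-mean-squares falls
  below the recording-level value by a few percent at high RMSSD); this
  is a property of windowed RMSSD estimation itself, visible in the
  recovery grid's residual ~2 ms RMSE floor.
- HF power from 10 s windows is statistically fragile and reported
  as-is (often NaN); it is not screened by the cleaning rules.
- Only BPM and RMSSD are range-screened; the remaining metrics inherit
  whatever windows survive.
- Wrist-PPG-grade motion artifacts are out of the generator's scope; the
  cleaning rules were exercised against additive white noise only.
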