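# Methods

This note records the modeling choices behind stressbox: what each stage
assumes, which parameters matter and why they hold their defaults, what
the synthetic generator does and does not emulate, and where the design
was genuinely open.

## Signal conditioning

Each channel gets the conditioning chain appropriate to its content.

**ECG (250 Hz).** Power-line interference is removed with a second-order
IIR notch at 50 Hz. The quality factor Q = 30 keeps the stop band about
1.7 Hz wide, narrow enough that rhythm content just above or below the
line frequency is essentially untouched. The filter is applied
forward-backward, so it is zero-phase: R-wave timing — the quantity all
HRV features derive from — is not shifted. Broadband noise is then
attenuated by wavelet smoothing: a `db6` decomposition of depth 10
(reduced automatically, with a warning, when the record is too short to
support that depth) with a universal soft threshold
sigma·sqrt(2 ln N) on every detail band, sigma estimated from the finest
band's median absolute deviation. Soft thresholding is a *nonlinear*
shrinkage; the other three filters are linear, and the test suite checks
superposition only for those three.

**GSR (32 Hz).** An order-6 Butterworth low-pass at 0.5 Hz, applied
forward-backward (zero phase, magnitude response squared). Skin
conductance is a slow signal; the pass band keeps the tonic level and
slow phasic responses while removing tremor and sensor noise. DC gain is
exactly 1, so conductance levels in microsiemens are preserved.

**Respiration (32 Hz).** A Blackman-windowed FIR band-pass with a nominal
0.5–35 Hz band. At a 32 Hz sampling rate the nominal upper edge exceeds
the 16 Hz Nyquist frequency and is clamped to 15 Hz with a warning; the
nominal band is simply not realizable at this rate. The FIR length
defaults to 4·fs + 1 taps (129 at 32 Hz), a deliberate compromise: long
enough to reject slow baseline drift, short enough that breathing just
below the 0.5 Hz edge is attenuated but not annihilated. This matters
because resting respiration (~0.2 Hz at 12 breaths/min) lies *below* the
nominal low edge; the downstream rate estimator locates a spectral peak
and is invariant to amplitude scaling, so a partially attenuated
breathing component is still recovered exactly — the tests confirm rate
recovery to ±0.5 breaths/min at 12 and 24.8 breaths/min through the
faithful filter.

## R-peak detection

No detector algorithm is canonical for this class of data, so the package
uses the field-default energy scheme: band-pass 5–15 Hz (QRS energy),
differentiate, square, integrate over a 150 ms moving window, threshold
at 20% of the 99th percentile, enforce a 0.25 s refractory period, then
refine each detection to the local maximum of the input waveform. The
refinement iterates its ±100 ms search window, which matters at record
edges where the filter transient biases the energy peak by tens of
milliseconds. On synthetic ECGs with known beat times the detector
recovers every beat to within one sample (±4 ms). Detected intervals
outside a physiologic guard band of [0.25, 3.0] s are flagged; features
are computed on guard-filtered intervals without interpolating gaps.

## HRV features

**Time domain.** Mean HR = 60/mean(RR); SDNN is the sample (n−1)
standard deviation; RMSSD the root mean square of successive differences;
NN50 counts |ΔRR| strictly greater than 50 ms (a difference equal to
50 ms up to float rounding of the subtraction does not count) and
pNN50 = NN50/(n−1).

**Poincaré axes.** SD1² = ½·mean(ΔRR²) and SD2² = 2·var(RR) − SD1²
(population variance, clipped at zero). This is the standard HRV-toolkit
parameterization, chosen over the literal 45°-rotated-coordinate standard
deviations because it makes two identities *exact* rather than
asymptotic: RMSSD = SD1·√2 and SD1² + SD2² = 2·var(RR). The rotated
coordinates differ only by the squared mean successive difference, which
is O(1/n) for stationary series; the suite checks agreement at 1e-4 and
the identities at 1e-10.

**Approximate entropy.** ApEn(m, r, N) = Φᵐ(r) − Φᵐ⁺¹(r) with
Φᵐ = mean over templates of ln(fraction of templates within Chebyshev
distance r), self-matches included; defaults m = 2 and r = 0.2·sd (the
canonical parameterization). A zero-variance series gets an r floor of
1e-12 so constant input returns exactly 0. For a perfectly periodic
alternating series the value is not exactly zero at finite N — edge
templates make the two template counts unequal — but O(1/N), about 5e-5
at N = 100; the implementation agrees with a direct O(N²)
template-counting oracle to 1e-9.

**Frequency domain.** The RR series is analyzed over VLF [0.003, 0.04),
LF [0.04, 0.15) and HF [0.15, 0.4) Hz (half-open edges: no sample of the
spectrum is counted in two bands). Two estimators are provided:

- *AR spectrum*: the tachogram (RR in ms anchored at each interval's
  closing beat) is cubic-spline interpolated (not-a-knot, so cubic trends
  are reproduced exactly) onto a uniform 4 Hz grid — the HRV convention,
  comfortably covering the 0.4 Hz band edge — mean-removed, and fitted
  with an AR(10) model by Burg's method (stable at order 10 on short
  records, unlike Yule–Walker). The one-sided density is evaluated on 512
  frequencies up to 2 Hz.
- *Lomb–Scargle spectrum*: computed directly on the uneven (beat time,
  RR) pairs, mean-removed, over 0.003–0.4 Hz with 4× frequency
  oversampling. The raw periodogram is rescaled so its integral over the
  computed grid equals the series variance in ms², making Lomb and AR
  band powers commensurable. Band LF/HF ratios are unaffected by this
  global rescale.

Band powers are trapezoidal integrals of the density; total power is
defined as TP = VLF + LF + HF (the three-band sum), and LF/HF is reported
as NaN rather than infinity when HF is zero. On two-tone synthetic RR
series (tones at the band centers 0.1 and 0.25 Hz) the Lomb LF/HF
recovers the ground-truth amplitude-squared ratio within 20% in at least
18 of 20 seeded runs at 400 beats.

## GSR and respiration features

GSR is summarized in non-overlapping 30 s windows (mean and SD per
window; trailing partial windows are dropped to keep window statistics
unbiased) plus an overall mean/SD over the record — for records that
divide evenly into windows the two means coincide. Respiration rate is
the dominant frequency of a Welch spectrum (30 s segments, zero-padded
16× for resolution well under 0.5 breaths/min) over the physiologic band
0.05–1.0 Hz, times 60. The estimate is rejected unless the in-band peak
is at least 3× the in-band median density; Welch averaging is what makes
this gate meaningful — a single raw periodogram of white noise routinely
produces spurious peak-to-median ratios above 3, averaged segments do
not.

## Rule-based labeling

A sample is labeled by majority vote of directional rules. Two rules are
absolute: LF/HF above 3 votes stressed, below 2 votes relaxed (between 2
and 3 abstains); respiration above 25 breaths/min votes stressed, below
votes relaxed. Nine rules compare against the same subject's baseline
phase: increases of HR, LF, ApEn, SD1 and GSR vote stressed, as do
decreases of HF, SD2, pNN50 and RMSSD; opposite shifts vote relaxed;
equality or a missing value abstains. The final label is the majority of
non-abstaining votes, a tie resolves to relaxed, and a sample on which
every rule abstains raises an explicit error rather than defaulting. How
the original study aggregated these cues into a single label is not
recoverable; majority voting is this package's documented proxy. Note the
rule set is internally tension-laden by construction (SD1 is proportional
to RMSSD yet the two vote in opposite directions); the majority vote
absorbs this.

## The 1-D K-means feature

Features are min-max scaled to [0, 1] — HRV features span four orders of
magnitude, and unscaled Euclidean distance would be dominated by total
power — then clustered with Lloyd's algorithm from k-means++ starts (10
restarts, best inertia kept, fully seeded). The implementation is
in-package rather than delegated so that the per-iteration objective is
exposed: the suite asserts inertia is non-increasing across iterations,
that every centroid equals the mean of its members at convergence, and
that on instances small enough to enumerate (n ≤ 8, k = 2) the restarted
fit reaches the exhaustive-partition optimum.

Each sample is then replaced by one scalar derived from its assigned
centroid. The default mapping is the mean of the centroid's coordinates —
one number blending every feature through the cluster structure; the
Euclidean distance to the assigned centroid is available as an
alternative (`mapping="centroid_distance"`), since the scalarization is a
genuinely open design point. Samples sharing a cluster share a scalar, so
the output takes at most k distinct values. Default k follows the label
cardinality (2 binary, 5 five-class); otherwise k maximizes the mean
silhouette over 2–8 (ties to the smallest k).

## The CART classifier

The split search sorts a feature once (stable sort), reorders labels by
that permutation, and sweeps every boundary between distinct adjacent
values using prefix counts — class counts on each side come from O(1)
arithmetic. The impurity of a side is the product of its class fractions
p₀·p₁, and a boundary's score is the *unweighted* sum of the two sides'
products; this literal form is the default, with the classical
size-weighted Gini available via `impurity="weighted"`. A fixed-threshold
shortcut (`fixed_cutoff=0.5`, sensible for min-max-scaled features)
evaluates a single boundary instead of the sweep. The returned cutoff is
the first sorted value strictly above the winning boundary, so the
routing predicate x < Θ exactly reproduces the found partition. On 500
random instances the sweep's minimum matches an exhaustive O(n²)
threshold search exactly (same arithmetic, bit-identical).

Trees are grown recursively — best (feature, cutoff) by minimal score,
route left iff xᵢ < Θ, leaves labeled by training majority — with
deterministic tie-breaks throughout: lowest boundary index, then lowest
feature index, then lowest cutoff, and leaf ties to class 0. Two fits of
the same data therefore agree exactly, and strictly increasing transforms
of any feature leave all training-set predictions unchanged. Growth stops
at purity, a depth limit (default 5), or when a child would fall below
`min_samples_leaf`; these explicit controls stand in for
description-length pruning, for which no formula was available.

One consequence of the cutoff-at-observed-value convention: the threshold
of a perfect split sits *on* the smallest training value of the upper
class, so a held-out sample below every training value of its class is
routed to the other side. Training accuracy on consistent data is 100%,
but cross-validated accuracy on separable data is bounded by
(n − folds)/n rather than 1. Midpoint thresholds would remove this edge
effect at the cost of departing from the split rule implemented here.

## Evaluation harness

Cross-validation is stratified (with 50-sample datasets and 10 folds,
unstratified folds can lose a class entirely) and seeded. Folds in which
precision or recall is undefined (no predicted or no true positives)
contribute NaN and are excluded from that metric's mean with a warning.
The pipeline used for the five-class comparison embeds min-max scaling
*before* chi-squared feature selection (chi-squared requires nonnegative
inputs) and a classifier, all re-fit inside each fold so no test-fold
statistics leak into training; grid search is exhaustive over the given
grid. The t test defaults to Welch (unequal variances across experiment
phases are the norm; the pooled variant is selectable), with p ≤ 0.05
read as rejecting the null of no difference; degenerate zero-variance
groups return p = 1 (equal means) or p = 0 (shifted) by convention. MSE
and R² treat class labels as integers, which is meaningful for the
ordered five-level stress scale. The boosting, SVM and naive-Bayes
comparators are thin adapters over scikit-learn and xgboost carrying the
study hyperparameters (gradient boosting: learning rate 1, 100
estimators, depth 1; SVM: polynomial kernel, degree 3); the package's own
classifier is the CART module.

## Synthetic data: what it emulates, what it does not

The generator exists because the study's recordings are private; it
produces data whose correct answers are known in closed form.

- **RR series**: rrₙ = mean_rr + a_lf·sin(2π·0.1·tₙ) +
  a_hf·sin(2π·0.25·tₙ) + noise. Two sinusoids at the band centers rather
  than an AR process, so the true band-power ratio is exactly
  a_lf²/a_hf² and spectral parameter recovery can be scored
  quantitatively.
- **ECG**: a Gaussian QRS bump (20 ms width, unit amplitude) at each beat
  time over 0.02-SD baseline noise, with optional 0.1-amplitude 50 Hz
  interference to exercise the notch.
- **GSR**: tonic level plus exponential-decay phasic pulses plus noise.
- **Respiration**: a sinusoid at rate/60 Hz plus 0.01 Hz drift and noise.

The four-phase study profile generates 13 subjects × 4 phases of 150 s
each — the usable-cohort shape of the data the pipeline is designed for —
with 3% multiplicative between-subject jitter. Stressor phases (T2, T3)
get mean RR 0.70/0.73 s, LF-dominated modulation (true LF/HF ≈ 7.7/6.4),
breathing at 27/26 breaths/min and skin conductance near 6 µS; baseline
and recovery phases (T1, T4) get mean RR ≈ 0.85 s, HF-balanced modulation
(LF/HF < 1), ~12 breaths/min and ~3 µS. These magnitudes follow the
directional structure physiological stress imposes (faster heart rate,
sympathetic-band dominance, rapid breathing, elevated conductance under
stress). The end-to-end check requires the rule labeler to recover the
phase design for at least 90% of subject-phases.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: realistic ECG morphology (P/T waves, ectopy,
electrode motion artifact), respiratory sinus arrhythmia coupling between
the respiration and RR channels, skin-conductance habituation,
non-stationarity within a phase, or the idiosyncratic, partly
psychological character of real stress responses. Results on synthetic
data validate the *computations*, not clinical performance.

## Numerical conventions and degenerate inputs

- All randomized operations take an integer seed; generators are
  deterministic given their seed.
- Spectra clip negative densities at zero; a constant RR series yields
  zero Lomb power (no variance, no rescale) and an AR-spectrum parameter
  error (an AR model of a constant is undefined).
- A constant series has ApEn exactly 0 (r floor), zero SDNN/RMSSD/SD1/SD2,
  and is invalid input for clustering-based splits only when all feature
  values coincide (no threshold can separate equal values; such nodes
  become leaves).
- Signal text files round-trip bit-exactly (17-significant-digit
  formatting); feature-table CSVs round-trip to within one float ulp
  (pandas parser), with column order preserved exactly.
- Published-table consistency checks compare recomputed LF/HF ratios to
  printed 2-decimal ratios within one unit in the last printed digit,
  because the printed band-power inputs carry only three significant
  figures.

## Known limitations

- The R-peak detector is validated on synthetic morphology only; real
  ECG would warrant amplitude-adaptive thresholds and T-wave rejection.
- The unweighted two-sided impurity (the default split score) can prefer
  splits that isolate single samples where the size-weighted Gini would
  not; the weighted variant exists precisely for that comparison.
- Skin-conductance analysis is deliberately limited to windowed
  statistics; no phasic/tonic decomposition or event detection.
- The binary CART handles two classes only; multi-class work goes through
  the comparator adapters, as designed.
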