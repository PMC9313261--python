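# Methods

This note documents the models and procedures `fecgkit` implements, the
parameters that matter, the synthetic data it is validated on, and the
numerical conventions — in enough detail that a result produced by the
package can be interpreted and reproduced without reading the source.

## Signal model

An abdominal recording is modeled as an instantaneous linear mixture

    x(k) = A s(k) + n(k)

where `s(k)` stacks the maternal and fetal cardiac source signals, `A` is
the (channels × sources) lead-field matrix determined by electrode
geometry, and `n(k)` collects baseline drift, power-line interference,
broadband EMG-like noise and impulsive artifacts. The working assumptions
are: the sources are statistically independent and non-Gaussian
(ECG is strongly super-Gaussian), the mixture is instantaneous
(propagation delays across the abdomen are negligible at ECG bandwidths),
and there are at least as many usable channels as cardiac sources. All
amplitudes are carried internally in microvolts; all sample indices are
0-based; windows are specified in milliseconds and converted per
recording, so 500 Hz and 1 kHz records run through identical settings.

## Pipeline stages

### Invalid-sample repair

Invalid samples are NaNs, samples at a declared saturation limit, and
members of flat (constant) runs of ≥ 200 ms — the signatures of electrode
detachment and amplifier clipping. They are replaced by a cubic spline
through the remaining valid samples (boundary runs by the spline's
natural extrapolation). A channel more than 50 % invalid is repaired but
reported unusable rather than silently passed on.

### Channel quality gate (sample entropy)

Each channel is cut into non-overlapping 10 s segments — at most six, so
longer recordings are judged on their first minute — and each segment is
scored with sample entropy: with embedding dimension m, tolerance r and
series length N, SampEn(m, r, N) = −ln(ΣA / ΣB), where B counts template
pairs of length m within Chebyshev distance r (self-matches excluded) and
A those still matching at length m + 1. Regular, ECG-dominated traces
score low; noise-dominated traces score high. A channel is excluded when
its segment mean exceeds 1.5; if fewer than two channels survive, the two
lowest-scoring channels are retained (flagged `fallback_used`) because
source separation needs at least two sensors.

Parameters: m = 2 and r = 0.2 × segment SD (the standard choice for
short physiological series); the segment is decimated to 125 Hz before
scoring to bound the O(N²) pair count — entropy estimates at this scale
discriminate quality ranking equally well at a sixteenth of the cost.
SampEn is +∞ when no template pair survives at length m + 1 (capped at
ln N for averaging) and 0 for a constant segment.

### Noise canceling

In order: a zero-phase IIR notch (default 50 Hz, Q = 35; configurable to
60 Hz), a zero-phase 4th-order Butterworth high-pass at 1 Hz against
baseline drift, and an outlier-gated median filter (10 ms window) that
replaces only samples deviating > 8 MAD from their local median, so
single-sample impulses are removed while QRS complexes — wider than the
window — pass through. All three are phase-neutral: on clean synthetic
ECG the QRS apexes move by at most one sample (asserted in the tests).

### Maternal QRS detection (ADT)

The detection signal is built by a stationary wavelet decomposition
(db4), keeping only detail scales whose dyadic bands intersect 10–30 Hz
(where QRS energy concentrates), rectifying, and smoothing with a 150 ms
moving average — one positive hump per heartbeat, polarity-independent.

The adaptive dual-threshold detector maintains a low/high threshold pair
derived from the mean of the last 10 accepted peak amplitudes
(`P_prior`): after every acceptance thr_L = 0.3·mean(P_prior) and
thr_H = 0.7·mean(P_prior). A candidate local maximum P (outside a 250 ms
refractory window) is accepted outright when P ≥ thr_H; when
thr_L < P < thr_H it is accepted provisionally if it also exceeds 0.45 ×
the last accepted amplitude, re-anchoring thr_L = 0.45·P and
thr_H = thr_L + |P − mean(P_prior)|/2. Both thresholds are clamped from
below at lim_L = 0.1 and lim_H = 0.3 times the initialization estimate
(the mean of the five largest maxima in the first 2 s, which also seeds
the history), so a run of small noise peaks cannot drag the thresholds to
zero. Accepted indices are refined to the raw-signal extremum within
±40 ms. The detector runs on every retained channel; detections are fused
by majority vote with 50 ms single-linkage clustering.

Two conventions here are deliberate interpretations: the threshold
formulas use the *mean* of the stored peak amplitudes (a sum would make
the thresholds grow with the history length, which is dimensionally
inconsistent with thresholds compared against single amplitudes), and the
provisional-path acceptance event is made explicit as described above.
Both are exposed in `PipelineConfig`.

### Maternal ECG cancellation (JADE)

After centering and eigenvalue whitening (eigenvalues below 1e−10 of the
largest are dropped, so rank-deficient input reduces dimension instead of
failing), the JADE algorithm — Jacobi rotations jointly diagonalizing the
parallel set of fourth-order cumulant matrices — estimates an orthogonal
rotation and hence the unmixing matrix. JADE has no random
initialization; separation is bit-reproducible. Components are ordered by
back-projected sensor-space energy and sign-fixed so the largest mixing
coefficient is positive.

A component is labeled maternal when ≥ 80 % of its own detected peaks
(the ADT detector applied to the component) fall within ±50 ms of the
maternal annotation; at least one component (the best-matching) is always
labeled. The maternal estimate is the back-projection of the maternal
components plus the maternal share of the removed channel means (the mean
vector resolved onto the estimated mixing columns); the residual is the
recording minus this estimate, so estimate + residual reconstructs the
input exactly, and back-projecting *all* components leaves a residual of
exactly zero.

### Fetal QRS detection

The residual channels are denoised by translation-invariant wavelet
thresholding: an undecimated (stationary) db4 decomposition without
per-level renormalization — so white noise has the same level at every
scale — soft-thresholded at the universal threshold λ = σ√(2 ln N), with
σ = MAD(finest details)/0.6745. The undecimated transform avoids the
shift-dependent artifacts an ordinary DWT leaves around sharp fetal
deflections; on synthetic fetal ECG at 0 dB SNR it gains ≈ 5.8 dB.
A second JADE pass on the denoised residual concentrates the fetal
source into a single component (rank-deficient residuals yield fewer
components than channels, by the whitening rule above).

Detection is a beat-by-beat forward search on each component: from the
last accepted beat, the search region is one fetal RR prior wide
([0.375 s, 0.545 s] after the beat, i.e. 110–160 bpm); the absolute first
difference is weighted by a trapezoidal window centered on the predicted
next beat (plateau ±25 ms, 100 ms linear ramps, floor 0.1) whose center
tracks the running median of the last 8 RR intervals; the weighted
maximum is accepted if it exceeds an adaptive threshold (initialized at
half the 75th percentile of derivative maxima in the first 3 s, updated
as thr ← 0.8·thr + 0.2·(0.5·amplitude)). When nothing crosses the
threshold the regional maximum is accepted anyway — keeping the RR series
defined — the region is temporarily widened (×1.2, capped at ×1.6), and
the forced fraction is reported as a low-confidence flag. Apexes are
refined to the component extremum within ±20 ms and a 100 ms refractory
contract is enforced (config-switchable). The best component is the one
whose RR series best matches the prior:
score = (fraction of RR in range) − 0.5 × (coefficient of variation),
ties broken toward lower CV, then lower index.

### Evaluation

Detections are matched one-to-one to reference beats within a ±50 ms
window, greedily in increasing order of absolute time difference. When
both annotations respect the 100 ms refractory contract, each detection
can reach at most one reference, and greedy matching provably attains the
maximum-cardinality assignment (the tests verify this against a
brute-force assignment oracle); for hypothetical contract-violating
inputs greedy matching may differ from the optimum. From TP/FP/FN:
Se = TP/(TP+FN), PPV = TP/(TP+FP), ACC = TP/(TP+FP+FN),
F1 = 2TP/(2TP+FN+FP), as percentages. Ratios with zero denominators are
NaN and flagged, never silently zero. Rounding is decimal half-up to two
places, applied only at the reporting boundary.

Summaries report both pooled metrics (from summed counts) and macro
averages (arithmetic mean of per-recording percentages) with population
SD (n divisor; the convention is recorded in the summary output). FHR is
60/RR in bpm attributed to the later beat of each interval; Bland–Altman
agreement uses pairs from intervals whose bounding beats are both matched
and consecutive on both sides, with limits of agreement at bias ± 1.96 SD.

### Bundled benchmark counts

`fecgkit/data/ds_recording_counts.csv` carries the per-recording TP/FP/FN
counts of a published three-posture abdominal-ECG benchmark (twelve
two-minute recordings, three subjects, supine/seated/standing; 3309
expert-annotated fetal beats). All summary numbers are recomputed from
these counts, never transcribed. One cell of that source's printed metric
table is inconsistent with its own counts — r05's printed PPV of 98.53
against 267/271 = 98.524, which rounds to 98.52 under every standard
convention — and its companion text reports a pooled ACC (95.86) and FP
total (18) that contradict the table's own sums (ΣFP = 71 gives
ACC = 97.37). The package reports only count-derived values; the
regression tests pin the 47 consistent cells exactly and the
count-implied value for the inconsistent one. The source's printed
per-posture SDs also match neither the population- nor the sample-SD
convention at two decimals; no test asserts them.

## Synthetic data generator

The generator exists so every stage has a test surface with exact ground
truth. Each cardiac source is a sum-of-Gaussians PQRST train: five
Gaussian deflections per beat with fixed relative amplitudes and widths
(a compressed variant for the fetus), R apexes at closed-form positions —
hence exact beat annotations. RR intervals are i.i.d.
Normal(60/HR, hrv_sd) truncated at ±3 SD. Defaults model a term
pregnancy: maternal 80 bpm (RR jitter SD 30 ms, R amplitude 300 µV on the
abdomen), fetal 140 bpm (jitter 15 ms, R amplitude 30 µV — mid of the
10–60 µV range), 3 channels at 500 Hz, 120 s.

The default 3×2 mixing matrix gives every channel a full-amplitude
maternal projection and a channel-dependent fetal projection *including a
polarity flip* — the fetal heart is a localized source whose lead vectors
differ strongly across abdominal sites, while the maternal ECG is seen
broadly. The two columns are far from collinear; near-collinear lead
vectors would make the mixture unseparable for any algorithm and do not
represent a usable electrode montage. Amplitude invariants are enforced
at generation: mixed fetal peaks within [10, 60] µV and a
maternal-to-fetal ratio ≥ 3 on every channel (both overridable for
degenerate test constructions).

Noise defaults, each motivated by the artifact it emulates: 0.25 Hz
sinusoidal baseline (respiration) at 50 µV; 50 Hz power line at 20 µV;
white Gaussian broadband (EMG-like) at 5 µV SD; single-sample impulses at
0.2/s, ±150 µV; optional 24-bit quantization at a ±185 mV full scale.
Everything is driven by one seed; identical seeds give bit-identical
recordings.

What the generator does *not* emulate — and what passing tests therefore
do not show about real recordings: fetal movement and time-varying lead
fields, uterine-contraction EMG bursts, electrode impedance drift,
colored (non-white) EMG spectra, maternal/fetal heart-rate variability
beyond stationary jitter, ectopic beats, and overlapping
maternal–fetal QRS morphology changes. Results on synthetic data bound
the chain's correctness, not its clinical performance.

## Numerical choices and degenerate inputs

- SWT lengths are padded (edge mode) to a multiple of 2^levels and
  trimmed after reconstruction; decomposition depth adapts to the
  sampling rate (maternal band selection) and signal length (denoising).
- JADE's Jacobi sweep stops when every rotation angle in a sweep is below
  1e−6/√T; non-convergence after 100 sweeps raises with diagnostics
  (never observed on ≤ 4-channel input).
- Whitening drops eigenvalues < 1e−10 × the largest: duplicated channels
  reduce the component count instead of producing numerical garbage.
- A constant (flat) detector input yields forced acceptances only and is
  flagged low-confidence; a constant SampEn segment scores 0.
- Tie-breaks: best-channel selection prefers lower RR coefficient of
  variation, then lower component index; apex-refinement collisions keep
  the larger-amplitude apex.
- Reported problem sizes: the default validation recording is 120 s of
  3-channel 500 Hz signal (≈ 280 fetal beats); the noise-robustness sweep
  uses 60 s recordings over broadband SD {1.25, 2.5, 5, 10, 20} µV with
  five seeds per level.

## Known limitations

- The instantaneous-mixture assumption breaks for recordings with strong
  electrode motion; no time-varying unmixing is attempted.
- No search-back for missed maternal beats; a maternal beat missed by all
  channels' ADT passes leaves maternal residue that the fetal stage must
  reject via the RR prior.
- Forced acceptance guarantees a defined RR series but fabricates beats
  on signal dropouts; consumers should honor the low-confidence flag.
- The WFDB reader covers single-segment, single-.dat, format-16 records —
  sufficient for the common research exports, not the full format zoo.
- With two channels and two cardiac sources plus noise, the
  sensor-count condition holds only marginally; three or more channels
  are recommended (the default).
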