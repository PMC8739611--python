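# Methods

## Scope and model

`cardiotrait` analyses short single-lead resting ECG (the reference recording
condition is Lead I at 2000 Hz for 120 s) and screens 62 ECG-derived features
for monotone associations with seven personality traits (the HEXACO six plus
Disintegration), each scored continuously on [1, 5]. The analysis chain is:
delineation → feature extraction → category binning → stratified
train/test split → tuned random forest with cross-validation → exact
binomial confidence interval on held-out accuracy → Spearman screening of
the top-ranked features. All stages are deterministic given their seeds.

## Synthetic data generator

The generator is the package's test bed and defines the conditions every
validation claim refers to.

**Beat template.** Each beat is a sum of five raised-cosine (Hann) bumps with
disjoint, sample-grid-snapped supports. The QRS complex splits its duration
1:2:1 across Q, R and S with adjoining supports; the P wave ends before the
QRS onset and the T wave begins after the QRS offset. Consequences: the
sample at each true peak index equals the configured amplitude exactly, each
peak is a local extremum, and every onset/offset is a known integer sample —
an exact oracle for the delineator. Wave offsets are fixed relative to each
R peak rather than warped by the RR process; planted intervals are therefore
exactly constant across beats, which keeps the ground truth trivially
checkable. A validity check requires the template span (PR interval + QT) to
fit inside the mean RR.

**Template defaults** (typical Lead I morphology): P 0.15 mV / 100 ms,
Q −0.10 mV, R 1.0 mV, S −0.20 mV (QRS 80 ms total), T 0.30 mV / 180 ms;
PR interval 160 ms, QT 400 ms; heart rate 70 bpm; fs 2000 Hz; 120 s.

**RR process.** RR(t) = 60/HR + a_LF·sin(2π·0.10·t) + a_HF·sin(2π·0.25·t)
(+ optional white jitter), with the two tones placed centrally in the
conventional LF (0.04–0.15 Hz) and HF (0.15–0.40 Hz) bands so spectral HRV
features have a known provenance; defaults a_LF = a_HF = 20 ms. This is a
deliberately simple two-tone process: it gives separable spectral mass for
band-power tests but does not emulate 1/f-like real HRV spectra, respiratory
non-stationarity, ectopy or artifact — passing tests demonstrate correct
computation, not robustness to pathological recordings.

**Cohorts.** Trait scores are drawn from truncated normal distributions on
[1, 5] with per-trait means and SDs matching the reference student sample
(e.g. Disintegration 2.07 ± 0.50, Openness 3.85 ± 0.59). Thirteen template
knobs (heart rate, the five wave amplitudes, five durations/intervals, and
the two RR-modulation depths) receive independent unit-variance
inter-subject variability at documented physiological scales, clipped to
hard bounds. A *planted link* couples one knob to one trait through a
Gaussian copula: the knob's latent z becomes r·z_trait + √(1−r²)·ε with
r = 2·sin(π·ρ/6), the classical relation that makes the population Spearman
correlation equal ρ for bivariate normal variables. Bound clipping and
extraction noise attenuate the realized coefficient slightly (a planted 0.8
typically realizes near 0.70–0.78 at n = 200). The feature→knob map covers
17 features; planting an unmapped feature raises an error listing the
mappable ones.

## Delineation

**Preprocessing** is a zero-phase FIR low-pass (cutoff 55 Hz, 10 Hz
transition) followed by a spectral mask that zeroes the sub-0.5 Hz band
(baseline wander; DC exactly) and the 50 ± 1 Hz powerline bins. The mask has
a binary magnitude response, so preprocessing is idempotent to well under 1%
RMS — a useful property when pipelines are re-entered. Records shorter than
2 s are rejected.

**R detection** is derivative-energy based: band-pass 5–25 Hz,
differentiate, square, integrate over 150 ms, pick peaks above an adaptive
threshold (30% of the median of the top-third candidate heights) with a
250 ms refractory, then refine each detection to the local maximum of the
band-limited signal within ±50 ms. Detections implying a median heart rate
outside 30–200 bpm raise an error.

**Wave peaks** are windowed extrema relative to each R peak (defaults, ms:
P in [−300, −70] with the window floor clamped to 0.45·RR_prev, Q in
[−80, −10], S in [10, 80], T in [100, 450] clamped to 0.62·RR_next), with
Lead-I sign conventions. A wave whose baseline-referenced amplitude is below
3% of the beat's R amplitude is treated as missing and the beat is dropped
(never imputed); the dropped fraction is logged and more than 50% dropped
raises an error.

**Onsets/offsets** use a slope-threshold rule: walk outward from the peak
and stop where |smoothed derivative| falls below 5% of the wave's shoulder
slope (its maximum within 130 ms of the peak) or below a noise floor set at
twice the 20th percentile of |derivative| over the record (the flattest
fifth of a recording is isoelectric baseline even at high heart rates). QRS
edges are measured on a full-band baseline-corrected copy (a 40 Hz filter
would smear the narrow Q/S edges); P and T edges on the band-limited copy
(their content is low-frequency, and the narrower band suppresses broadband
noise). Amplitudes are measured on the full-band copy after two-stage
median-filter baseline estimation (0.2 s then 0.6 s windows), which zeroes
the isoelectric line without attenuating wave heights.

On noiseless synthetic records the median fiducial error is ≤ 2 ms at
500–2000 Hz; under broadband noise at 10% of the R amplitude, R detection
stays above 99% sensitivity/precision while P/T edges degrade gracefully and
ill-formed beats are dropped.

## Feature conventions

- Sample (n−1) standard deviations throughout; medians use the midpoint rule
  for even counts.
- `HR_mean` averages instantaneous rates 60/RR (configurable alternative:
  60/mean RR). `pnn50` divides by the total number of RR intervals, the
  convention of the reference feature table (not the successive-difference
  count used by some HRV software); both choices are documented here because
  they differ by one count.
- The HRV triangular index bins the RR histogram at one sampling period
  (1/fs) by default — the reference convention — with the conventional
  1/128 s available through configuration. At 1/fs binning and 2-min records
  the index is nearly the interval count divided by the maximal bin count of
  an almost-unique histogram; it is retained for completeness and excluded
  from the clinically relevant subset.
- Spectral HRV: cubic-spline interpolation of the tachogram to a uniform
  4 Hz grid, mean removal, Welch periodogram (64 s Hann segments, 50%
  overlap); powers are band integrals in s². Total power integrates from
  0.003 Hz (a 2-min record resolves nothing below ~0.008 Hz anyway) to
  0.40 Hz. A Lomb–Scargle alternative on the irregular series is provided
  for validation of band dominance; its absolute scale is
  estimator-dependent. When HF = 0 the LF/HF ratio is reported as missing
  (NaN) rather than infinity. Records spanning less than 60 s refuse
  spectral features.
- Poincaré: SD1 = SDSD/√2; SD2 is defined through the ellipse identity
  SD2² = 2·SDNN² − SD1² (clipped at zero). The rotated-scatter definition
  (SD of (RR_{i+1}+RR_i)/√2) agrees with this only up to O(1/n) edge terms
  because the first and last intervals each appear once rather than twice;
  the ellipse form is used so the identity SD1² + SD2² = 2·SDNN² holds
  exactly, which is also what the test suite asserts at 1e−10.
- Bazett correction divides QT by √RR using the RR interval immediately
  preceding each beat's QRS; beats without a preceding detected RR are
  excluded from QTnorm only. A `bazett_literal` flag switches to QT/RR for
  sensitivity analyses against sources that print the formula without the
  radical.
- Relative amplitudes default to (a_y − a_x)/|a_R| — signed, scale-free,
  Lead-I signs preserved; since the originating convention is not published,
  `relative_amplitude_mode` offers plain differences and magnitude ratios.
- Ek weights are configuration, not code. The shipped default is a labelled
  placeholder (zero intercept, equal weights 0.2) that keeps the index
  well-defined on synthetic data; it is **not** the published calibration,
  which users must supply via `ek_weights`.

## Classification workflow

Scores are binned with strict lower bounds at the .50 boundaries
(1.50 → 1, 1.51 → 2, …, 4.51 → 5); the printed two-decimal ranges leave
(1.50, 1.51) formally unassigned, and the half-open rule reproduces the
printed mapping while covering arbitrary-precision scores. The 75/25 split
is stratified per category with largest-remainder allocation, so each
category's train share is within one subject of 75% and the overall train
fraction is exact; singleton categories go to train with a warning.
Tuning grids default to ntree ∈ {250, 500, 1000} and
mtry ∈ {⌊√p/2⌋, ⌊√p⌋, ⌊2√p⌋}; folds shrink to the smallest class count when
necessary. Ties in CV accuracy resolve to the first grid entry. The held-out
accuracy carries a Clopper–Pearson interval from beta quantiles —
beta(α/2; k, n−k+1) to beta(1−α/2; k+1, n−k) — reported in percent to one
decimal (half away from zero). Importances are impurity-based, rescaled so
the maximum is 100. Mean CV accuracy and the single-test-set CI are
reported side by side, mirroring the mixed convention of the reference
workflow.

Spearman correlations use midranks; p-values come from the t approximation
for n ≥ 10 and exhaustive rank-permutation enumeration for n ≤ 9, where the
approximation is poor. No multiplicity correction is applied in the default
report — the screening convention mirrored here — with a Benjamini–Hochberg
column available as an explicitly-marked extension.

## Validation and problem sizes

The test suite validates each statistic against independent brute-force
reimplementations (1000 random series), the CI against binomial-CDF
bisection for all (k, n) with n ≤ 30, delineation against the generator's
exact fiducials across random heart rates in 50–90 bpm, and the full
pipeline by parameter recovery: planted HR/PR/QT are recovered within
1 bpm / 5 ms / 5 ms on noiseless records, and a planted Spearman-0.7
trait–feature link at n = 150 yields above-baseline classification accuracy
with the planted feature in the importance top 3 in ≥ 9 of 10 seeds.
Validation cohorts use 500 Hz / 80 s records (1000 Hz for interval-recovery
checks) and 70–150 subjects: large enough for stable rank correlations and
forest tuning, small enough that the whole suite runs in minutes on one CPU.
The acceptance script mirrors these sizes.

## Known limitations

- The simulator's morphology is smooth and artifact-free; delineation
  windows and thresholds are tuned for normal sinus morphology and will not
  handle bundle-branch blocks, atrial fibrillation or ectopy.
- Onset/offset placement under heavy broadband noise (≥5% of R amplitude)
  degrades for the low-slope P and T boundaries; beats are dropped rather
  than imputed, which biases per-beat SD features downward in very noisy
  records.
- The Ek index is only as meaningful as the supplied weights; the placeholder
  is a structural stand-in.
- Category binning concentrates traits with small SD (e.g. Disintegration)
  into one class; classification headroom over the majority baseline is then
  small regardless of effect size — an inherent property of the workflow,
  visible in the recovery simulations.
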