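# Methods

## The noise-corrected similarity estimator

Population representations are compared with the Pearson correlation of
population vectors.  For the **spatial** code, each unit's response is
averaged over the analysis window (sound onset to 100 ms after sound
offset) and the vector has one entry per unit; for the
**spatio-temporal** code, window bins are concatenated across units at
5 ms (electrophysiology) or 43.5 ms (imaging) resolution.

Trial-averaged vectors retain noise residues that attenuate raw
correlations toward zero, and the attenuation differs across regions and
recording techniques, so uncorrected comparisons conflate tuning with
measurement quality.  The corrected estimator splits each sound's R
trials into two random halves; half-averages a, b (sound s) and c, d
(sound s′) give

    rho_hat = mean[r(a,c), r(a,d), r(b,c), r(b,d)] / sqrt(r(a,b)·r(c,d))

The numerator's attenuation factor is the geometric mean of the two
split-half reliabilities in the denominator, so the ratio converges on
the noiseless correlation as the number of units grows.  Splits are
redrawn `n_resamples` = 20 times.

Numerical choices:

* **Combination across resamples.**  The cross terms and the two
  reliabilities are averaged separately across resamples and the ratio
  is taken once ("ratio of averages").  Averaging per-resample ratios is
  noticeably less stable because individual reliability draws can be
  near zero.  The choice is recorded in each matrix's metadata.
* **Clipping and undefined values.**  Finite estimates are clipped into
  [−1, 1].  When a mean reliability is ≤ 0 the representation is noise
  dominated and the ratio is meaningless; such entries are marked
  undefined (NaN) and excluded from all downstream averages rather than
  clipped, because clipping a noise-dominated ratio would fabricate ±1.
* **Odd R.**  One half receives the extra trial; the assignment is
  rerandomized each resample.
* **Zero-variance half-averages.**  The affected resample's terms are
  dropped; if every resample drops, the value is undefined.
* **Full matrices.**  `rsa_matrix` draws two independent half-splits per
  sound per resample (a row-role and a column-role split) shared across
  pairs, standardizes the half-average matrices and obtains all pairwise
  cross-half correlations as matrix products.  This is statistically
  equivalent to per-pair splitting for off-diagonal entries, makes the
  307-sound matrix tractable (three S×N products per resample instead of
  ~10⁶ vector correlations), and gives unbiased diagonal entries
  (independent splits of the same trials), which approach 1 for reliable
  populations.  The matrix is symmetrized by averaging the two pair
  orders before the ratio.
* **Region statistics** use the paired Wilcoxon signed-rank test over
  identical sound-pair sets (zeros split across signs; the all-zero
  case returns p = 1 by convention).

## Stimulus catalog

The default catalog holds 307 sounds, ≤ 500 ms each, presented 12 times
at 1-s onset intervals.  Waveforms carry 10-ms raised-cosine
onset/offset ramps and are RMS-calibrated to their level in dB SPL
(re 20 µPa) *after* ramping, so calibration is exact (< 0.1 dB) even for
short sounds.  Intensity-ramped stimuli follow a linear-in-dB
trajectory between 50 and 70 dB and are excluded from the fixed-RMS
rule, as are decomposition reconstructions, which are defined as the
literal sample-wise sum of their component waveforms at stored onsets.

Where the protocol under-determines exact members, the package fixes
one documented enumeration:

* pure tones: 14 log-spaced frequencies spanning 2–60 kHz inclusive, at
  50 and 70 dB; intensity ramps use the 13 grid tones below 50 kHz;
* chords: all 2–4-tone combinations of the low/mid/high pools (11
  each), the 2–3-tone combinations of the broad pool (10), and five
  fixed harmonic stacks of {4, 8, 12, 16} kHz; component phases are
  drawn once from the catalog seed and stored;
* chirps: a duration series (25–400 ms, 6–12 kHz) and five 500-ms
  frequency-range families spanning 4–50 kHz, each up and down;
  sweeps are logarithmic in frequency, and the down direction is the
  time reversal of the up frequency track;
* noises: 8th-order Butterworth band-pass on white Gaussian noise;
  the 14 filtered variants are nine octave-bandwidths (0.5–4.5 in
  0.5-octave steps, log-centered on 10 kHz) plus five 1-kHz narrowbands;
  ten dual-narrowband sounds are intensity-ramped pairs;
* AM: eight carriers (8 and 12 kHz tones, five chords, broadband
  noise) × six modulation frequencies log-spaced 4–160 Hz, 100%
  sinusoidal depth starting at zero modulation phase;
* complex sounds: 15 synthetic surrogate identities (seeded compositions
  of chirps, click trains and noise bands standing in for unavailable
  recordings) × forward/reversed × 50/70 dB;
* decompositions: the four decomposed identities' 27 components at
  70 dB, the eight intro chirps again at 50 dB, and each identity's
  reconstruction at 70 dB, 50 dB and time-reversed at 70 dB (47 total).

The default sample rate is 192 kHz (Nyquist-guarded against the 80-kHz
catalog ceiling) and is configurable downward for fast tests.

## Preprocessing

Imaging traces: 70% neuropil subtraction; F0 = sliding 3rd percentile
of the Gaussian-smoothed corrected trace over a 60-s window (long
relative to transients, short relative to session drift); f = ΔF/F;
deconvolution r = f′ + f/τ with τ = 2 s, central differences interior
and one-sided at the ends; 31-ms Gaussian smoothing truncated at ±4σ
with reflective edges.  Units with nonpositive F0 are flagged and
excluded rather than silently producing NaNs.

Trial windows: imaging −0.2→+0.8 s at the frame rate (22.9 Hz),
baseline −0.2→−0.02 s; electrophysiology −0.3→+1.0 s at 1-ms bins,
baseline −0.3→0 s.  The per-trial baseline mean is subtracted from
every bin.  Unit selection keeps units whose mean across-trial-pair
Pearson correlation of the binned temporal response (5-ms bins ephys,
42-ms bins imaging), averaged over all sounds and the full extracted
window, exceeds 0.05 (ephys) or 0.3 (imaging); zero-variance trial
pairs contribute 0, which is conservative toward rejection.  The two
printed imaging bin widths (42 ms for reliability, 43.5 ms for
spatio-temporal vectors) are kept as two distinct parameters.  Pooling
concatenates sessions into a virtual population and permutes trial
identity independently per (unit, sound) to limit noise correlations.

## Synthetic populations

The generator emulates the statistical structure the analyses consume:
units with log-Gaussian frequency tuning (centers uniform over the
2–60 kHz grid in log space), band-pass AM tuning in log modulation
frequency, bounded direction selectivity, sigmoidal intensity gain
(thresholds 40–72 dB), lognormal response amplitudes, and per-unit
onset/sustained temporal kernels.  Stimuli reduce to feature summaries
(component frequencies, passbands, level, modulation frequency,
direction); band stimuli drive units through the closed-form overlap of
the Gaussian tuning curve with the passband.  Regime presets control
sharpness: `cn_like` (1.6-octave widths, large unselective response
component), `ic_like` (0.8), `ac_like` (0.35, sparse and
direction-selective).  These produce progressively decorrelated ground
truths by construction, a scaled-down analogue of the recorded
hierarchy, not a fit to it.

Noise is independent across units (mirroring trial-shuffled virtual
populations): Poisson counts on 1-ms bins over a spontaneous baseline
for ephys-like data, additive Gaussian noise on imaging bins for
imaging-like data.  A `linear_compound` switch makes every compound's
noiseless response the exact sum of its catalog pure-tone component
responses, so summed-component similarity is exactly 1 and any deviation
measured elsewhere is attributable to the population, not the pipeline.

What the generator does *not* emulate: noise correlations between
units (available as an option but off by default), adaptation across
trials, non-stationary baselines, cell-type structure, or any fitted
relationship to real recordings.  Passing tests therefore certify the
*estimators* (bias, exactness, ordering recovery), not biological
claims about real data.

The estimator validation condition uses two 500-unit patterns with
pattern correlation 0.5 observed through 12 trials with Gaussian noise
of variance 8, which attenuates the naive trial-averaged correlation to
≈ 0.3 (attenuation factor 1/(1+σ²/R) = 0.6); the corrected estimator's
mean bias over 50 seeds stays within ±0.05.

## Tuning analyses

Distance tuning curves assign each eligible sound pair its absolute
feature difference (octaves of tone frequency, of AM modulation
frequency, or of noise bandwidth), snap distances to the nearest 0.05
octave to absorb grid arithmetic, and report per-bin mean ± SEM with
pair counts; bins are labeled by the mean true distance (the smallest
tone-grid step is ≈ 0.38 octave).  Matched-pair contrasts implement
fixed matching rules; on the default catalog they yield 14
tone-intensity pairs, 15 complex-intensity pairs (forward renditions,
50 vs 70 dB), 15 complex-direction pairs (70 dB, forward vs reversed),
5 sweep-direction pairs (the 500-ms range families; the 6–12 kHz
duration series is excluded so the count matches the protocol), 13
ramp-direction pairs and 105 complex-identity pairs.

Summed-component comparisons resolve a compound's components to the
nearest grid tones at the compound's level (chords, AM carriers) or to
all grid tones inside its range (sweeps, noises).  Within each
resample every component's trials are half-split, half-averages are
summed element-wise with halves paired consistently across components,
and the noise-corrected estimator runs with the summed construct's own
split-half reliability.  Temporal reconstructions place component
response time courses at their stored onsets on the compound's bin grid
(overlaps add) before the same comparison; the spatial code
time-averages after summation.

Salience profiles divide each unit's window-averaged responses by the
unit's maximum across sounds (units with nonpositive maxima excluded
and counted), then normalize category means by the mean over complex
sounds at 70 dB.

## Cochlear periphery

Geometry is exact and closed-form: x = −56.5 + 82.5·log10(CF) (% from
apex, CF in kHz), N(x) = −0.0038x² + 0.375x + 7.9 fibers per IHC
(nearest-integer rounding), SR = 91.1·τ_Ca^2.66 (τ_Ca in ms, SR in
spikes/s), with τ_Ca drawn log-uniformly over the interval mapping to
SR ∈ [0.5, 95].  The default map tiles 5–50 kHz at 12 IHCs/octave
(40 IHCs, positions 1.17–81.88%, increments 2.07%).  Note the published
mouse summary figures of 691 total fibers and 82.8%/83.9% coverage are
not jointly consistent with these formulas on this grid (the rounded
polynomial sums to 590 fibers here); the package reports formula values
rather than reverse-engineering the summary numbers.

The response cascade is deliberately phenomenological rather than
biophysical: per-CF gammatone band-pass (scipy's IIR design), half-wave
rectification with 0.3-power compression, 1-kHz low-pass envelope
extraction, divisive exponential adaptation (τ = 60 ms), and
inhomogeneous Poisson spiking on top of the fiber's spontaneous rate.
It reproduces tonotopic rate profiles and the "blurred diagonal"
population similarity structure; it does not model middle-ear transfer,
two-tone suppression, refractoriness, or fitted membrane dynamics.

## Problem sizes and determinism

Analyses in the test-suite and examples run populations of 40–500 units
over 2–60 sound subsets with 12 trials and 20 resamples — sizes at
which every property checked (bias bounds, exactness at zero noise,
regime ordering in 10/10 seeds) is stable while the whole suite
completes in seconds.  All randomness flows through
`numpy.random.default_rng` seeds; the pipeline derives per-stage seeds
by hashing (global seed, stage name), so reruns are bit-identical.

## Known limitations

* Complex sounds are synthetic surrogates, not recordings; analyses of
  complex-sound identity are exercised structurally, not acoustically.
* The periphery model is a stand-in for a six-stage biophysical cascade
  and should not be used for quantitative auditory-nerve predictions.
* The estimator remains high-variance for small populations (tens of
  units); the validation suite flags N < 50 conditions.
* Undefined similarity entries are excluded pairwise from averages; no
  imputation is attempted.
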