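# poptune

Noise-corrected population tuning analysis for auditory neural data.

## The problem

How sharply a brain region is tuned to a sound feature is classically
measured neuron by neuron, but single-cell tuning indexes assume a
response model, are corrupted by trial-to-trial variability, and say
nothing about the population code as a whole.  `poptune` implements the
population-level alternative: representational similarity analysis (RSA)
with a noise-corrected Pearson metric.  Each sound *s* evokes a
population vector **v**_s (one entry per neuron, time-averaged for the
"spatial" code or all time bins concatenated for the "spatio-temporal"
code); the similarity of two sounds is the Pearson correlation
ρ(**v**_s, **v**_s′), and the sounds × sounds matrix of these values
summarizes the population's tuning to every feature at once.  Along a
processing hierarchy, sharper tuning appears as *decorrelation*: a drop
in pairwise similarity.

Raw correlations of trial-averaged vectors are biased toward 0 by
residual trial noise.  The package's core estimator removes this bias by
split-half resampling: trials of each sound are split into random
halves whose averages give vectors a, b (sound *s*) and c, d (sound
*s*′), and

```
rho_hat = mean[ r(a,c), r(a,d), r(b,c), r(b,d) ]
          / sqrt( r(a,b) · r(c,d) )
```

with *r* the plain Pearson correlation.  Splits are redrawn 20 times;
numerator and split-half reliabilities are averaged separately before
the ratio, the estimate is clipped to [−1, 1], and noise-dominated pairs
(mean reliability ≤ 0) are marked undefined rather than clipped.

The package is aimed at systems neuroscientists analyzing trial-resolved
auditory responses (Neuropixels spike trains or 2-photon calcium
imaging) and at method developers who need a fully synthetic, ground-
truth-controlled testbed for population similarity metrics.

## What's inside

| module                | contents |
| --------------------- | -------- |
| `poptune.stimuli`     | the 307-sound catalog (tones, intensity ramps, chords, chirps, noises, AM sounds, complex surrogates, decompositions) and calibrated waveform synthesis |
| `poptune.preprocess`  | ΔF/F, linear deconvolution (r = f′ + f/τ), trial extraction with baseline subtraction, reliability-based unit selection, virtual-population pooling |
| `poptune.similarity`  | plain and noise-corrected Pearson similarity, vectorized RSA matrices, mean-similarity summaries |
| `poptune.tuning`      | distance tuning curves, matched-pair contrasts, summed-component (linearity) comparisons, salience profiles, paired Wilcoxon region statistics |
| `poptune.periphery`   | mouse cochlear tonotopy/innervation/spontaneous-rate formulas and a phenomenological auditory-nerve simulator |
| `poptune.synthpop`    | synthetic populations with exact representational ground truth, and the estimator validation suite |
| `poptune.pipeline` / `poptune.cli` | reproducible stage orchestration and a thin `poptune` command-line wrapper |

## Worked example

Recovering a known pattern correlation that trial noise hides
(`examples/02_noise_corrected_estimator.py`):

```
true pattern correlation : 0.493
naive estimate           : 0.300 (biased toward 0)
noise-corrected estimate : 0.504
```

Two 500-unit patterns were built with correlation ≈ 0.5 and observed
through 12 noisy trials each.  The naive trial-averaged correlation is
attenuated to 0.30; the split-half corrected estimator recovers the true
value to within ±0.05.

Decorrelation across synthetic processing stages
(`examples/03_regime_decorrelation.py`):

```
regime      mean off-diagonal similarity (ground truth)
cn_like     0.779 +/- 0.009   (0.780)
ic_like     0.412 +/- 0.017   (0.415)
ac_like     0.098 +/- 0.013   (0.102)
```

Three regimes with progressively sharper unit tuning produce
progressively decorrelated pure-tone representations, and the pipeline
estimate tracks the noiseless ground truth of each population.

The other scripts in `examples/` demonstrate catalog construction,
population frequency-tuning curves, and the cochlear periphery model.

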