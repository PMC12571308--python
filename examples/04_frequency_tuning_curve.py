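"""Population frequency-tuning curve and an intensity contrast.

A similarity matrix over the pure tones is collapsed into a tuning
curve: mean similarity versus octave distance between tone frequencies.
The tone-intensity contrast measures how similar the same frequency is
across 50 vs 70 dB SPL (14 matched pairs).
"""

from poptune import build_catalog, generate_population, rsa_matrix
from poptune.synthpop import SyntheticPopulationSpec
from poptune.tuning import contrast_similarity, distance_tuning_curve

catalog = build_catalog(seed=0)
tones = [s.sound_id for s in catalog.by_category("pure_tone")]
spec = SyntheticPopulationSpec(
    n_units=150, modality="imaging", regime="ic_like",
    noise={"gaussian_sigma": 0.3}, seed=4,
)
tensor, _ = generate_population(spec, catalog, sound_ids=tones)
matrix = rsa_matrix(tensor, code="spatial", n_resamples=20, seed=5)

curve = distance_tuning_curve(matrix, catalog, "tone_octave_distance")
print("octave distance   similarity (n pairs)")
for b, m, s, n in zip(curve.bins, curve.mean, curve.sem, curve.n_pairs):
    print(f"   {b:5.2f}          {m:+.3f} +/- {s:.3f}  ({n})")

res = contrast_similarity(matrix, catalog, "tone_intensity")
print(
    f"\nsame tone, 50 vs 70 dB: {res['mean']:.3f} +/- {res['sem']:.3f} "
    f"over {res['n']} pairs"
)
print(
    "-> similarity decays with frequency separation (the population tuning"
    "\n   curve); intensity pairs stay highly similar for this regime."
)
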