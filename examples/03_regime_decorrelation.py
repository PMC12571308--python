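"""Decorrelation across synthetic processing stages.

Three synthetic regimes emulate the sharpening of tuning along the
auditory pathway (broad -> intermediate -> sharp/sparse).  The mean
off-diagonal entry of the noise-corrected similarity matrix over the 28
pure tones drops accordingly — the population-level signature of
representational decorrelation.
"""

from poptune import build_catalog, generate_population, mean_similarity, rsa_matrix
from poptune.synthpop import SyntheticPopulationSpec

catalog = build_catalog(seed=0)
tones = [s.sound_id for s in catalog.by_category("pure_tone")]

print("regime      mean off-diagonal similarity (ground truth)")
for regime in ("cn_like", "ic_like", "ac_like"):
    spec = SyntheticPopulationSpec(
        n_units=150, modality="imaging", regime=regime,
        noise={"gaussian_sigma": 0.3}, seed=1,
    )
    tensor, truth = generate_population(spec, catalog, sound_ids=tones)
    matrix = rsa_matrix(tensor, code="spatial", n_resamples=20, seed=2)
    mean, sem, n = mean_similarity(matrix)
    print(f"{regime:<10}  {mean:.3f} +/- {sem:.3f}   ({truth.mean_offdiag_similarity():.3f})")
print(
    "-> pipeline estimates track the noiseless ground truth; sharper tuning"
    "\n   regimes produce progressively decorrelated representations."
)
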