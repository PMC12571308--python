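"""Why noise correction matters: naive vs corrected similarity.

Two population patterns are generated with a known Pearson correlation
of 0.5; independent trial noise is added at a level where the naive
trial-averaged correlation is attenuated to ~0.3.  The split-half
noise-corrected estimator recovers the true value.
"""

import numpy as np

from poptune import naive_similarity, noise_corrected_similarity
from poptune.synthpop import correlated_pair_population

naive_vals, corrected_vals, truths = [], [], []
for seed in range(20):
    tensor, true_rho = correlated_pair_population(
        n_units=500, rho=0.5, noise_sigma=np.sqrt(8.0), trials=12, seed=seed
    )
    naive_vals.append(naive_similarity(tensor, 0, 1))
    corrected_vals.append(
        noise_corrected_similarity(tensor, 0, 1, n_resamples=20, seed=seed)
    )
    truths.append(true_rho)

print(f"true pattern correlation : {np.mean(truths):.3f}")
print(f"naive estimate           : {np.mean(naive_vals):.3f} (biased toward 0)")
print(f"noise-corrected estimate : {np.mean(corrected_vals):.3f}")
print(
    "-> trial noise attenuates the naive correlation by ~40%; the split-half"
    "\n   corrected estimator removes the attenuation without peeking at the truth."
)
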