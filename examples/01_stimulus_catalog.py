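"""Build the 307-sound stimulus catalog and synthesize a calibrated waveform.

The catalog enumerates eight sound categories (tones, intensity ramps,
chords, chirps, noises, AM sounds, complex surrogates, decompositions);
every waveform carries 10-ms raised-cosine ramps and is RMS-calibrated
to its level in dB SPL re 20 uPa.
"""

import numpy as np

from poptune import build_catalog, synthesize

catalog = build_catalog(seed=0)
print(f"catalog size: {len(catalog)} sounds")
for category, count in sorted(catalog.category_counts().items()):
    print(f"  {category:>14}: {count}")

stim = catalog["am_8kHz_fm4.0Hz"]
wave = synthesize(stim)
rms_db = 20 * np.log10(np.sqrt(np.mean(wave**2)) / 20e-6)
print(f"\n{stim.sound_id}: {len(wave)} samples at {stim.sample_rate/1e3:.0f} kHz")
print(f"measured level {rms_db:.2f} dB SPL (target {stim.level:.0f} dB)")
print("-> a 4 Hz amplitude-modulated 8 kHz tone, calibrated to within 0.1 dB.")
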