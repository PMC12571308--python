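"""Resolution of compound sounds to their pure-tone catalog components.

Summed-representation analyses compare a compound sound (chord, AM sound,
frequency sweep, filtered noise) with the sum of the population responses
to the pure tones it is built from.  The catalog tone grid is log-spaced,
so nominal component frequencies (e.g. chord members at 4, 5, 8 kHz) are
mapped to the nearest grid tone at the compound's level; sweeps and
noises resolve to every grid tone inside their frequency range.
"""

from __future__ import annotations

import numpy as np

from .stimuli import StimulusCatalog, TONE_FREQS_KHZ, _tone_id

__all__ = ["component_tone_ids", "nearest_tone_id", "tones_in_range"]


def nearest_tone_id(freq_khz: float, level_db: float) -> str:
    """Catalog id of the grid pure tone nearest in log-frequency."""
    grid = np.asarray(TONE_FREQS_KHZ)
    k = int(np.argmin(np.abs(np.log2(grid) - np.log2(freq_khz))))
    return _tone_id(grid[k], level_db)


def tones_in_range(low_khz: float, high_khz: float, level_db: float) -> list:
    """Ids of all grid tones with frequency inside [low, high] kHz."""
    return [
        _tone_id(f, level_db)
        for f in TONE_FREQS_KHZ
        if low_khz <= f <= high_khz
    ]


def component_tone_ids(catalog: StimulusCatalog, compound) -> list:
    """Pure-tone component ids for a compound catalog entry.

    * chord — nearest grid tone for each chord member, at the chord level;
    * am (tone or chord carrier) — nearest grid tones of the carrier;
    * chirp — all grid tones traversed by the sweep, at the sweep level;
    * noise (band kinds) — all grid tones inside the passband.

    Raises for categories without a tone decomposition.
    """
    stim = catalog[compound] if isinstance(compound, str) else compound
    p = stim.params
    if stim.category == "chord":
        ids = [nearest_tone_id(f, stim.level) for f in p["freqs_khz"]]
    elif stim.category == "am":
        if p["carrier_kind"] == "noise":
            ids = tones_in_range(2.0, 80.0, stim.level)
        else:
            ids = [nearest_tone_id(f, stim.level) for f in p["carrier_freqs_khz"]]
    elif stim.category == "chirp":
        lo, hi = sorted((p["f0_khz"], p["f1_khz"]))
        ids = tones_in_range(lo, hi, stim.level)
    elif stim.category == "noise" and p["kind"] in ("broadband", "band", "narrow"):
        ids = tones_in_range(p["low_khz"], p["high_khz"], stim.level)
    else:
        raise ValueError(f"{stim.sound_id}: no pure-tone decomposition for this category")
    seen: dict = {}
    for i in ids:
        seen.setdefault(i, None)
    out = [i for i in seen if i in catalog._index]
    if not out:
        raise ValueError(f"{stim.sound_id}: no catalog tones match its components")
    return out
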