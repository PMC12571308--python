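import numpy as np
import pytest

from poptune.stimuli import build_catalog
from poptune.synthpop import SyntheticPopulationSpec, generate_population


@pytest.fixture(scope="session")
def catalog():
    """Default 307-sound catalog (parametric only; no waveforms rendered)."""
    return build_catalog(seed=0)


@pytest.fixture(scope="session")
def tone_ids(catalog):
    return [s.sound_id for s in catalog.by_category("pure_tone")]


@pytest.fixture(scope="session")
def small_population(catalog, tone_ids):
    """Noisy imaging-like population over the pure tones (known ground truth)."""
    spec = SyntheticPopulationSpec(
        n_units=120,
        modality="imaging",
        regime="ic_like",
        noise={"gaussian_sigma": 0.3},
        seed=11,
    )
    tensor, truth = generate_population(spec, catalog, sound_ids=tone_ids)
    return tensor, truth


@pytest.fixture(scope="session")
def noiseless_population(catalog, tone_ids):
    spec = SyntheticPopulationSpec(
        n_units=80,
        modality="imaging",
        regime="ic_like",
        noise={"gaussian_sigma": 0.0},
        seed=7,
    )
    tensor, truth = generate_population(spec, catalog, sound_ids=tone_ids)
    return tensor, truth
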