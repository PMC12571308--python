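"""Feature tuning curves, contrasts, linearity comparisons, statistics."""

import numpy as np
import pytest

from poptune.components import component_tone_ids
from poptune.similarity import SimilarityMatrix, rsa_matrix
from poptune.preprocess import TrialTensor
from poptune.synthpop import SyntheticPopulationSpec, generate_population
from poptune.tuning import (
    contrast_pairs,
    contrast_similarity,
    distance_tuning_curve,
    reconstruct_from_components,
    region_contrast,
    salience_profile,
    summed_component_similarity,
)


@pytest.fixture(scope="module")
def tone_matrix(catalog, tone_ids, noiseless_population):
    tensor, _ = noiseless_population
    return rsa_matrix(tensor, "spatial", n_resamples=4, seed=0)


class TestDistanceTuningCurve:
    def test_pair_counts_follow_grid_combinatorics(self, catalog, tone_matrix):
        curve = distance_tuning_curve(tone_matrix, catalog, "tone_octave_distance")
        # 14-tone grid at each of two levels: adjacent-step bin has 13
        # pairs per level, next 12, ... down to 1
        assert list(curve.n_pairs) == [2 * k for k in range(13, 0, -1)]
        assert np.all(np.diff(curve.bins) > 0)

    def test_flat_matrix_gives_flat_curve(self, catalog, tone_ids):
        vals = np.full((len(tone_ids), len(tone_ids)), 0.7)
        np.fill_diagonal(vals, 1.0)
        m = SimilarityMatrix(values=vals, sound_ids=tone_ids)
        curve = distance_tuning_curve(m, catalog, "tone_octave_distance")
        assert np.allclose(curve.mean, 0.7)
        assert np.allclose(curve.sem, 0.0)

    def test_sharper_generative_tuning_gives_faster_decay(self, catalog, tone_ids):
        """Tuning-width recovery: the curve at a fixed distance is ordered
        by the generative width (closed-form Gaussian-overlap oracle: in the
        noiseless limit similarity decays with distance at a rate set by the
        tuning width)."""
        first_bins = {}
        for width, name in [(2.0, "broad"), (0.9, "mid"), (0.35, "sharp")]:
            spec = SyntheticPopulationSpec(
                n_units=150,
                modality="imaging",
                regime={
                    "tuning_width_oct": width,
                    "common_offset": 0.0,
                    "threshold": 0.0,
                    "am_width_oct": 1.0,
                    "am_depth": 0.0,
                    "direction_max": 0.0,
                },
                noise={"gaussian_sigma": 0.0},
                seed=8,
            )
            tensor, _ = generate_population(spec, catalog, sound_ids=tone_ids)
            m = rsa_matrix(tensor, "spatial", n_resamples=3, seed=1)
            curve = distance_tuning_curve(m, catalog, "tone_octave_distance")
            # similarity remaining at ~1.5 octaves distance
            k = np.argmin(np.abs(curve.bins - 1.5))
            first_bins[name] = curve.mean[k]
        assert first_bins["broad"] > first_bins["mid"] > first_bins["sharp"]

    def test_unknown_feature_and_empty_selection_raise(self, catalog, tone_matrix):
        with pytest.raises(ValueError, match="unknown"):
            distance_tuning_curve(tone_matrix, catalog, "nope")
        with pytest.raises(ValueError, match="no eligible"):
            distance_tuning_curve(tone_matrix, catalog, "am_logfreq_distance")


class TestContrasts:
    @pytest.mark.parametrize(
        "contrast,n",
        [
            ("tone_intensity", 14),
            ("complex_intensity", 15),
            ("complex_direction", 15),
            ("sweep_direction", 5),
            ("ramp_direction", 13),
            ("complex_identity", 105),
        ],
    )
    def test_catalog_implied_pair_counts(self, catalog, contrast, n):
        assert len(contrast_pairs(catalog, contrast)) == n

    def test_block_structured_matrix_gives_unit_contrast(self, catalog):
        pairs = contrast_pairs(catalog, "tone_intensity")
        ids = sorted({s for p in pairs for s in p})
        vals = np.eye(len(ids))
        m = SimilarityMatrix(values=vals, sound_ids=ids)
        for a, b in pairs:
            ia, ib = ids.index(a), ids.index(b)
            m.values[ia, ib] = m.values[ib, ia] = 1.0
        res = contrast_similarity(m, catalog, "tone_intensity")
        assert res["mean"] == 1.0 and res["n"] == 14

    def test_zero_pair_match_raises(self, catalog, tone_ids):
        m = SimilarityMatrix(values=np.eye(len(tone_ids)), sound_ids=tone_ids)
        with pytest.raises(ValueError, match="zero pairs"):
            contrast_similarity(m, catalog, "sweep_direction")


@pytest.fixture(scope="module")
def linear_population(catalog):
    """Noiseless linear population over chords, AMs, sweeps and their tones."""
    chords = [s.sound_id for s in catalog.by_category("chord")[:3]]
    ams = ["am_8kHz_fm4.0Hz", "am_chord_low_fm17.5Hz"]
    sweeps = ["chirp_4-50kHz_up"]
    compounds = chords + ams + sweeps
    comps = sorted({t for c in compounds for t in component_tone_ids(catalog, c)})
    subset = compounds + comps
    spec = SyntheticPopulationSpec(
        n_units=80,
        modality="imaging",
        regime="ic_like",
        noise={"gaussian_sigma": 0.0},
        linear_compound=True,
        seed=21,
    )
    tensor, _ = generate_population(spec, catalog, sound_ids=subset)
    return tensor, compounds


class TestSummedComponents:
    def test_linear_noiseless_population_gives_unity_for_every_compound(
        self, catalog, linear_population
    ):
        tensor, compounds = linear_population
        for c in compounds:
            v = summed_component_similarity(
                tensor, c, code="spatial", n_resamples=4, seed=2, catalog=catalog
            )
            assert v == pytest.approx(1.0, abs=1e-9), c

    def test_component_scaling_leaves_similarity_unchanged(self, catalog, linear_population):
        tensor, compounds = linear_population
        comp_ids = component_tone_ids(catalog, compounds[0])
        scaled = TrialTensor(
            values=tensor.values.copy(),
            bin_width=tensor.bin_width,
            window=tensor.window,
            modality=tensor.modality,
            sound_ids=tensor.sound_ids,
        )
        for cid in comp_ids:
            scaled.values[:, tensor.sound_ids.index(cid)] *= 2.0
        v0 = summed_component_similarity(
            tensor, compounds[0], comp_ids, n_resamples=4, seed=3
        )
        v1 = summed_component_similarity(
            scaled, compounds[0], comp_ids, n_resamples=4, seed=3
        )
        assert v1 == pytest.approx(v0, abs=1e-9)

    def test_unrelated_compound_pattern_gives_near_zero(self, catalog, linear_population):
        tensor, compounds = linear_population
        comp_ids = component_tone_ids(catalog, compounds[0])
        broken = TrialTensor(
            values=tensor.values.copy(),
            bin_width=tensor.bin_width,
            window=tensor.window,
            modality=tensor.modality,
            sound_ids=tensor.sound_ids,
        )
        rng = np.random.default_rng(9)
        ic = tensor.sound_ids.index(compounds[0])
        random_pattern = rng.normal(1.0, 0.5, size=(tensor.n_units, 1, 1))
        active = broken.values[:, ic] != 0
        broken.values[:, ic] = np.where(active, random_pattern, 0.0)
        vals = [
            summed_component_similarity(broken, compounds[0], comp_ids, n_resamples=10, seed=s)
            for s in range(10)
        ]
        assert abs(np.nanmean(vals)) < 0.25

    def test_missing_component_listed_in_error(self, linear_population):
        tensor, compounds = linear_population
        with pytest.raises(ValueError, match="ghost_sound"):
            summed_component_similarity(tensor, compounds[0], ["ghost_sound"])


class TestReconstruction:
    @staticmethod
    @pytest.fixture(scope="class")
    def tiling_tensor():
        """Linear noiseless population: complex = components tiling in time."""
        rng = np.random.default_rng(12)
        U, R = 40, 8
        bin_width = 0.1
        window = (0.0, 0.6)
        n_bins = 6
        amp1 = rng.lognormal(size=U)
        amp2 = rng.lognormal(size=U)
        values = np.zeros((U, 3, R, n_bins))
        # component A active bins 0-2, component B active bins 0-2 of its own
        # frame; complex = A at onset 0 plus B at onset 0.3
        values[:, 1, :, 0:3] = amp1[:, None, None]
        values[:, 2, :, 0:3] = amp2[:, None, None]
        values[:, 0, :, 0:3] = amp1[:, None, None]
        values[:, 0, :, 3:6] = amp2[:, None, None]
        return TrialTensor(
            values=values,
            bin_width=bin_width,
            window=window,
            modality="imaging",
            sound_ids=["cpx", "compA", "compB"],
        )

    def test_tiling_components_reconstruct_exactly(self, tiling_tensor):
        durations = {"cpx": 0.5, "compA": 0.2, "compB": 0.2}
        v = reconstruct_from_components(
            tiling_tensor,
            "cpx",
            [("compA", 0.0), ("compB", 0.3)],
            code="spatial",
            n_resamples=4,
            seed=1,
            durations=durations,
        )
        assert v == pytest.approx(1.0, abs=1e-9)

    def test_misaligned_onset_reduces_spatiotemporal_similarity(self, tiling_tensor):
        durations = {"cpx": 0.5, "compA": 0.2, "compB": 0.2}
        good = reconstruct_from_components(
            tiling_tensor, "cpx", [("compA", 0.0), ("compB", 0.3)],
            code="spatiotemporal", n_resamples=4, seed=1, durations=durations,
        )
        shifted = reconstruct_from_components(
            tiling_tensor, "cpx", [("compA", 0.0), ("compB", 0.4)],
            code="spatiotemporal", n_resamples=4, seed=1, durations=durations,
        )
        assert good == pytest.approx(1.0, abs=1e-9)
        assert shifted < good

    def test_empty_component_list_rejected(self, tiling_tensor):
        with pytest.raises(ValueError, match="empty"):
            reconstruct_from_components(tiling_tensor, "cpx", [])


class TestSalience:
    def test_reference_category_normalizes_to_one(self, catalog):
        # only reference-level complex sounds present, so the category mean
        # coincides with the reference mean
        ids = [s.sound_id for s in catalog.by_category("complex") if s.level == 70.0][:8] + [
            s.sound_id for s in catalog.by_category("pure_tone")[:6]
        ]
        spec = SyntheticPopulationSpec(
            n_units=50, modality="imaging", noise={"gaussian_sigma": 0.1}, seed=3
        )
        tensor, _ = generate_population(spec, catalog, sound_ids=ids)
        res = salience_profile(tensor, catalog)
        assert res["profile"]["complex"] == pytest.approx(1.0)

    def test_per_unit_normalization_removes_unit_gain(self, catalog):
        ids = [s.sound_id for s in catalog.by_category("complex")[:4]] + [
            s.sound_id for s in catalog.by_category("pure_tone")[:4]
        ]
        spec = SyntheticPopulationSpec(
            n_units=40, modality="imaging", noise={"gaussian_sigma": 0.0}, seed=4
        )
        tensor, _ = generate_population(spec, catalog, sound_ids=ids)
        res0 = salience_profile(tensor, catalog)
        tensor.values[0] *= 2.0  # double one unit's responses
        res1 = salience_profile(tensor, catalog)
        for k in res0["profile"]:
            assert res1["profile"][k] == pytest.approx(res0["profile"][k], abs=1e-12)

    def test_generative_category_gains_recovered(self, catalog):
        ids = [s.sound_id for s in catalog.by_category("complex")[:6]] + [
            s.sound_id for s in catalog.by_category("pure_tone")[:6]
        ]
        gains = {"pure_tone": 0.5, "complex": 1.0}
        spec = SyntheticPopulationSpec(
            n_units=300,
            modality="imaging",
            noise={"gaussian_sigma": 0.0},
            category_gains=gains,
            seed=5,
        )
        tensor, _ = generate_population(spec, catalog, sound_ids=ids)
        res = salience_profile(tensor, catalog)
        # profile ratio tracks the generative gain ratio (approximately:
        # per-unit max normalization interacts with overlapping patterns)
        assert res["profile"]["pure_tone"] < res["profile"]["complex"]


class TestRegionContrast:
    def test_identical_sets_give_p_one(self):
        vals = np.linspace(0.1, 0.9, 30)
        res = region_contrast(vals, vals.copy())
        assert res.p_value == 1.0

    def test_constant_shift_detected(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(0.3, 0.9, 100)
        res = region_contrast(a, a - 0.2)
        assert res.p_value < 1e-3

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            region_contrast([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_nan_pairs_removed_pairwise(self):
        a = np.array([0.5, np.nan, 0.7, 0.9])
        b = np.array([0.4, 0.5, np.nan, 0.8])
        res = region_contrast(a, b)
        assert res.n_pairs == 2
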