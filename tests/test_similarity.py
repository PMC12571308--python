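"""Noise-corrected Pearson estimator and RSA matrices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from poptune.preprocess import TrialTensor
from poptune.similarity import (
    SimilarityMatrix,
    mean_similarity,
    naive_similarity,
    noise_corrected_similarity,
    pearson,
    rsa_matrix,
)
from poptune.synthpop import correlated_pair_population


def _closed_form_pearson(u, v):
    u, v = np.asarray(u, float), np.asarray(v, float)
    uc, vc = u - u.mean(), v - v.mean()
    return float((uc * vc).sum() / np.sqrt((uc**2).sum() * (vc**2).sum()))


class TestPearson:
    def test_identity_and_antisymmetry(self):
        u = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson(u, u) == pytest.approx(1.0)
        assert pearson(u, -u) == pytest.approx(-1.0)

    def test_against_closed_form_oracle(self):
        u, v = [1.0, 2.0, 3.0], [1.0, 2.0, 4.0]
        assert pearson(u, v) == pytest.approx(_closed_form_pearson(u, v), abs=1e-12)
        # frozen oracle value
        assert pearson(u, v) == pytest.approx(0.9819805060619659, abs=1e-12)

    def test_zero_variance_is_undefined(self):
        assert np.isnan(pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 2.0], [1.0, 2.0, 3.0])

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(-100.0, 100.0), min_size=3, max_size=20),
        st.floats(0.1, 100.0),
        st.floats(-50.0, 50.0),
    )
    def test_affine_invariance_and_bounds(self, xs, scale, shift):
        rng = np.random.default_rng(0)
        u = np.array(xs)
        if np.std(u) < 1e-3:  # near-degenerate inputs are numerically ill-posed
            return
        v = rng.normal(size=len(u))
        r = pearson(u, v)
        assert -1.0 <= r <= 1.0
        assert pearson(u * scale + shift, v) == pytest.approx(r, abs=1e-6)


def _pattern_tensor(patterns, R=8, noise=0.0, seed=0):
    """Tensor whose trials are fixed unit patterns (plus optional noise)."""
    rng = np.random.default_rng(seed)
    U = patterns.shape[1]
    S = patterns.shape[0]
    values = np.repeat(patterns.T[:, :, None, None], R, axis=2).astype(float)
    if noise:
        values = values + rng.normal(0, noise, size=values.shape)
    return TrialTensor(
        values=values,
        bin_width=0.5,
        window=(0.0, 0.5),
        modality="imaging",
        sound_ids=[f"s{i}" for i in range(S)],
    )


class TestNoiseCorrectedSimilarity:
    def test_identical_noiseless_patterns_give_one(self):
        rng = np.random.default_rng(0)
        p = rng.normal(size=50)
        tensor = _pattern_tensor(np.stack([p, p]))
        assert noise_corrected_similarity(tensor, 0, 1, seed=1) == pytest.approx(1.0)

    def test_orthogonal_noiseless_patterns_give_their_pattern_correlation(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=400)
        w = rng.normal(size=400)
        v = w - u * _closed_form_pearson(u, w) * np.std(w) / np.std(u)  # decorrelate
        tensor = _pattern_tensor(np.stack([u, v]))
        rho = _closed_form_pearson(u, v)
        assert abs(rho) < 0.05
        assert noise_corrected_similarity(tensor, 0, 1, seed=2) == pytest.approx(rho, abs=1e-9)

    def test_corrects_attenuation_where_naive_is_biased(self):
        # N=500 units, R=12 trials, noise tuned so the naive estimate ~0.3
        errs_c, errs_n = [], []
        for seed in range(15):
            tensor, true_rho = correlated_pair_population(
                500, 0.5, np.sqrt(8.0), trials=12, seed=seed
            )
            est = noise_corrected_similarity(tensor, 0, 1, n_resamples=20, seed=seed)
            nai = naive_similarity(tensor, 0, 1)
            errs_c.append(est - true_rho)
            errs_n.append(nai - true_rho)
        assert abs(np.mean(errs_c)) < 0.05
        assert np.mean(errs_n) < -0.1

    def test_requires_four_trials(self):
        tensor = _pattern_tensor(np.random.default_rng(0).normal(size=(2, 20)), R=3)
        with pytest.raises(ValueError, match="4 trials"):
            noise_corrected_similarity(tensor, 0, 1)

    def test_noise_dominated_pair_is_undefined_not_clipped(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(30, 2, 12, 1))  # pure noise, no signal
        tensor = TrialTensor(
            values=values, bin_width=0.5, window=(0.0, 0.5), modality="imaging",
            sound_ids=["a", "b"],
        )
        vals = [
            noise_corrected_similarity(tensor, 0, 1, seed=s) for s in range(20)
        ]
        finite = [v for v in vals if np.isfinite(v)]
        assert all(-1.0 <= v <= 1.0 for v in finite)
        assert any(np.isnan(v) for v in vals)


class TestRsaMatrix:
    def test_noiseless_matrix_equals_ground_truth(self, noiseless_population):
        tensor, truth = noiseless_population
        m = rsa_matrix(tensor, "spatial", n_resamples=5, seed=0)
        gt = truth.similarity_matrix("spatial")
        assert np.nanmax(np.abs(m.values - gt)) < 1e-10

    def test_diagonal_is_one_within_resampling_tolerance(self, small_population):
        tensor, _ = small_population
        m = rsa_matrix(tensor, "spatial", n_resamples=20, seed=1)
        diag = np.diag(m.values)
        assert np.nanmean(np.abs(diag - 1.0)) < 0.05

    def test_matrix_is_symmetric_and_bounded(self, small_population):
        tensor, _ = small_population
        m = rsa_matrix(tensor, "spatial", n_resamples=10, seed=2)
        assert np.allclose(m.values, m.values.T, equal_nan=True)
        finite = m.values[np.isfinite(m.values)]
        assert finite.min() >= -1.0 and finite.max() <= 1.0

    def test_sound_permutation_equivariance(self, noiseless_population):
        tensor, _ = noiseless_population
        ids = tensor.sound_ids[:6]
        m = rsa_matrix(tensor, "spatial", n_resamples=4, seed=3, sound_ids=ids)
        perm = ids[::-1]
        mp = rsa_matrix(tensor, "spatial", n_resamples=4, seed=3, sound_ids=perm)
        # noiseless: entries are exact pattern correlations, so reordering
        # sounds permutes the matrix
        reindex = [perm.index(s) for s in ids]
        assert np.allclose(m.values, mp.values[np.ix_(reindex, reindex)], atol=1e-10)

    def test_matrix_agrees_with_single_pair_estimator(self, small_population):
        tensor, _ = small_population
        m = rsa_matrix(tensor, "spatial", n_resamples=20, seed=4)
        pairs = [(0, 5), (2, 9), (1, 12)]
        for i, j in pairs:
            v = noise_corrected_similarity(tensor, i, j, n_resamples=20, seed=99)
            assert m.values[i, j] == pytest.approx(v, abs=0.06)

    def test_spatiotemporal_code_runs_and_differs(self, small_population):
        tensor, _ = small_population
        m_sp = rsa_matrix(tensor, "spatial", n_resamples=5, seed=5)
        m_st = rsa_matrix(tensor, "spatiotemporal", n_resamples=5, seed=5)
        assert m_st.values.shape == m_sp.values.shape
        assert not np.allclose(m_st.values, m_sp.values, equal_nan=True)


class TestMeanSimilarity:
    def test_all_ones_matrix(self):
        m = SimilarityMatrix(values=np.ones((4, 4)), sound_ids=list("abcd"))
        mean, sem, n = mean_similarity(m)
        assert mean == 1.0 and sem == 0.0 and n == 6

    def test_single_pair_subset(self):
        vals = np.eye(3)
        vals[0, 1] = vals[1, 0] = 0.5
        m = SimilarityMatrix(values=vals, sound_ids=list("abc"))
        mean, sem, n = mean_similarity(m, pair_subset=[("a", "b")])
        assert mean == 0.5 and sem == 0.0 and n == 1

    def test_matches_brute_force_average(self, noiseless_population):
        tensor, _ = noiseless_population
        m = rsa_matrix(tensor, "spatial", n_resamples=4, seed=6)
        mean, _, n = mean_similarity(m)
        iu, ju = np.triu_indices(len(m.sound_ids), k=1)
        brute = np.nanmean(m.values[iu, ju])
        assert mean == pytest.approx(brute, abs=1e-12)

    def test_empty_subset_rejected(self):
        m = SimilarityMatrix(values=np.ones((2, 2)), sound_ids=list("ab"))
        with pytest.raises(ValueError):
            mean_similarity(m, pair_subset=[])

    def test_save_load_roundtrip(self, tmp_path):
        vals = np.array([[1.0, 0.3], [0.3, 1.0]])
        m = SimilarityMatrix(values=vals, sound_ids=["x", "y"], code="spatial")
        path = tmp_path / "m.h5"
        m.save(path)
        again = SimilarityMatrix.load(path)
        assert np.allclose(again.values, vals)
        assert again.sound_ids == ["x", "y"]
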