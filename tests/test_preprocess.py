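"""dF/F, deconvolution, trial extraction and reliability screening."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

from poptune.preprocess import (
    CalciumTrace,
    TrialTensor,
    deconvolve,
    dff,
    extract_trials,
    pool_virtual_population,
    select_reliable_units,
    unit_reliability,
)

FR = 22.9


class TestDff:
    def test_constant_fluorescence_gives_zero_dff(self):
        trace = dff(np.full(3000, 5.0))
        assert not trace.flagged
        assert np.allclose(trace.f, 0.0, atol=1e-12)

    def test_transient_peak_against_direct_percentile_oracle(self):
        n = 6000
        F = np.full(n, 10.0)
        peak_idx = n // 2
        transient = 4.0 * np.exp(-np.arange(200) / 40.0)
        F[peak_idx : peak_idx + 200] += transient
        trace = dff(F, baseline_window=120.0, frame_rate=FR)
        # oracle: with a long window the 3rd percentile of the smoothed
        # trace stays at the resting level, so peak dF/F ~ transient / rest
        assert trace.F0[peak_idx] == pytest.approx(10.0, rel=0.02)
        assert trace.f.max() == pytest.approx(4.0 / 10.0, rel=0.05)

    def test_neuropil_subtraction_is_linear(self):
        rng = np.random.default_rng(0)
        F = 10.0 + rng.random(2000)
        F_np = F / 2
        t0 = dff(F, F_np, neuropil_fraction=0.0)
        t7 = dff(F, F_np, neuropil_fraction=0.7)
        assert np.allclose(t0.F - t7.F, 0.35 * F)

    def test_nonpositive_baseline_flags_unit(self):
        trace = dff(np.full(2000, -1.0))
        assert trace.flagged


class TestDeconvolve:
    def test_constant_dff_gives_rate_c_over_tau(self):
        trace = CalciumTrace(f=np.full(500, 3.0), frame_rate=FR, tau_decay=2.0)
        r = deconvolve(trace, smooth=False)
        assert np.allclose(r, 3.0 / 2.0)

    def test_indicator_decay_deconvolves_to_zero(self):
        # f = exp(-t/tau) satisfies f' = -f/tau exactly, so r ~ 0
        fr = 1000.0
        t = np.arange(5000) / fr
        trace = CalciumTrace(f=np.exp(-t / 2.0), frame_rate=fr, tau_decay=2.0)
        r = deconvolve(trace, smooth=False)
        assert np.abs(r[1:-1]).max() < 1e-6

    def test_linear_ramp_matches_symbolic_derivative(self):
        # oracle: f = a t  ->  r = a + a t / tau on the sample grid
        a, tau, fr = 0.4, 2.0, FR
        t = np.arange(300) / fr
        trace = CalciumTrace(f=a * t, frame_rate=fr, tau_decay=tau)
        r = deconvolve(trace, smooth=False)
        expected = a + a * t / tau
        assert np.allclose(r[1:-1], expected[1:-1], rtol=1e-9)

    def test_impulse_recovery_through_indicator_kernel(self):
        # spikes convolved with exp(-t/tau) then deconvolved recover the
        # spike train up to smoothing blur
        fr, tau = 100.0, 2.0
        n = 2000
        rate = np.zeros(n)
        rate[[300, 900, 1500]] = 1.0
        t = np.arange(n) / fr
        kernel = np.exp(-t / tau)
        f = np.convolve(rate, kernel)[:n]
        trace = CalciumTrace(f=f, frame_rate=fr, tau_decay=tau, smoothing_sigma=0.031)
        r = deconvolve(trace)
        blurred = gaussian_filter1d(rate * fr, 0.031 * fr, mode="reflect")
        assert np.corrcoef(r, blurred)[0, 1] > 0.99

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            deconvolve(CalciumTrace(f=np.array([1.0, 2.0])))


class TestExtractTrials:
    def test_deterministic_burst_lands_in_expected_bins(self):
        spikes = np.array([10.050 + k * 0.001 for k in range(10)])
        onsets = {"s0": [10.0]}
        tensor = extract_trials([spikes], onsets, ["s0"], "ephys", recording_duration=20.0)
        t = tensor.times
        resp = tensor.values[0, 0, 0]
        window = (t >= 0.05) & (t < 0.060)
        # baseline is empty of spikes so subtraction leaves counts intact
        assert resp[window].sum() == pytest.approx(10.0)
        assert resp[t < 0].sum() == pytest.approx(0.0)

    def test_stationary_poisson_baseline_subtracts_to_zero_mean(self):
        rng = np.random.default_rng(1)
        duration, rate = 400.0, 20.0
        spikes = np.sort(rng.uniform(0, duration, int(duration * rate)))
        onsets = {"s0": list(np.arange(5.0, 395.0, 2.0))}
        tensor = extract_trials([spikes], onsets, ["s0"], "ephys", recording_duration=duration)
        post = tensor.values[0, 0, :, tensor.times >= 0]
        assert abs(post.mean()) < 0.01

    def test_imaging_windows_match_hand_sliced_oracle(self):
        fr = 22.9
        trace = np.arange(3000, dtype=float)
        onsets = {"s0": [10.0, 20.0]}
        tensor = extract_trials(
            [trace], onsets, ["s0"], "imaging", recording_duration=3000 / fr, frame_rate=fr
        )
        n_bins = tensor.n_bins
        start = int(round((10.0 - 0.2) * fr))
        manual = trace[start : start + n_bins]
        base = (tensor.times >= -0.2) & (tensor.times < -0.02)
        assert np.allclose(tensor.values[0, 0, 0], manual - manual[base].mean())

    def test_onset_near_edge_raises_when_trials_incomplete(self):
        spikes = np.array([1.0, 2.0])
        onsets = {"s0": [0.1, 5.0], "s1": [5.0, 6.0]}
        with pytest.raises(ValueError, match="complete trials"):
            extract_trials([spikes], onsets, ["s0", "s1"], "ephys", recording_duration=10.0)


def _tensor_from_values(values, modality="ephys", bin_width=0.001):
    window = (-0.3, -0.3 + values.shape[-1] * bin_width)
    return TrialTensor(
        values=values,
        bin_width=bin_width,
        window=window,
        modality=modality,
        sound_ids=[f"s{i}" for i in range(values.shape[1])],
    )


class TestReliability:
    def test_identical_nonconstant_trials_have_reliability_one(self):
        base = np.sin(np.linspace(0, 6, 200))
        values = np.tile(base, (1, 2, 6, 1))
        tensor = _tensor_from_values(values)
        rel = unit_reliability(tensor)
        assert rel[0] == pytest.approx(1.0)
        kept = select_reliable_units(tensor, threshold=0.05)
        assert kept.n_units == 1

    def test_independent_noise_unit_rejected(self):
        rng = np.random.default_rng(3)
        signal_unit = np.tile(np.sin(np.linspace(0, 6, 200)), (1, 3, 8, 1))
        noise_unit = rng.normal(size=(1, 3, 8, 200))
        values = np.concatenate([signal_unit, noise_unit])
        tensor = _tensor_from_values(values)
        kept = select_reliable_units(tensor, threshold=0.05)
        assert kept.n_units == 1

    def test_zero_variance_unit_scores_zero_not_nan(self):
        values = np.zeros((1, 2, 6, 200))
        tensor = _tensor_from_values(values)
        rel = unit_reliability(tensor)
        assert rel[0] == 0.0

    def test_threshold_monotone_never_adds_units(self):
        rng = np.random.default_rng(4)
        signal = np.sin(np.linspace(0, 6, 200))
        values = (
            signal[None, None, None, :] * rng.uniform(0.1, 1.0, size=(12, 1, 1, 1))
            + rng.normal(size=(12, 3, 8, 200))
        )
        tensor = _tensor_from_values(values)
        kept = set()
        prev = None
        for th in (0.0, 0.05, 0.1, 0.2):
            try:
                sel = select_reliable_units(tensor, threshold=th)
                ids = frozenset(id(m) for m in sel.unit_meta)
                count = sel.n_units
            except ValueError:
                count = 0
            if prev is not None:
                assert count <= prev
            prev = count

    def test_empty_survivor_set_names_threshold(self):
        values = np.zeros((2, 2, 6, 100))
        tensor = _tensor_from_values(values)
        with pytest.raises(ValueError, match="0.9"):
            select_reliable_units(tensor, threshold=0.9)


class TestVirtualPopulation:
    def _make(self, n_units, seed):
        rng = np.random.default_rng(seed)
        return _tensor_from_values(rng.normal(size=(n_units, 3, 8, 50)))

    def test_pooling_concatenates_units(self):
        pooled = pool_virtual_population([self._make(4, 0), self._make(3, 1)], seed=2)
        assert pooled.n_units == 7

    def test_shuffle_is_deterministic_and_mean_preserving(self):
        a = self._make(4, 0)
        p1 = pool_virtual_population([a], seed=5)
        p2 = pool_virtual_population([a], seed=5)
        assert np.array_equal(p1.values, p2.values)
        assert np.allclose(p1.values.mean(axis=2), a.values.mean(axis=2))

    def test_mismatched_catalogs_rejected(self):
        a = self._make(2, 0)
        b = self._make(2, 1)
        b.sound_ids = ["x0", "x1", "x2"]
        with pytest.raises(ValueError, match="catalog"):
            pool_virtual_population([a, b])
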