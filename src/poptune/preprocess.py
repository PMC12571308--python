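"""Response preprocessing: dF/F, deconvolution, trial extraction, reliability.

Turns raw per-unit recordings — spike times (electrophysiology) or ROI
fluorescence traces (2-photon imaging) — into baseline-subtracted
:class:`TrialTensor` arrays indexed ``(unit, sound, trial, time_bin)``.

Modality conventions:

* electrophysiology: trial window -0.3 to +1.0 s around sound onset,
  1-ms bins, baseline window -0.3 to 0 s;
* imaging: trial window -0.2 to +0.8 s at the frame rate (22.9 Hz by
  default), baseline window -0.2 to -0.02 s.  Fluorescence is converted
  to dF/F (70% neuropil subtraction, sliding 3rd-percentile baseline),
  linearly deconvolved (``r = f' + f/tau``, tau = 2 s) and smoothed with
  a 31-ms Gaussian.

Unit selection keeps units whose across-trial response reliability
(mean pairwise Pearson correlation of binned temporal responses, averaged
over sounds) exceeds 0.05 (ephys, 5-ms bins) or 0.3 (imaging, 42-ms bins).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d, percentile_filter

__all__ = [
    "CalciumTrace",
    "TrialTensor",
    "dff",
    "deconvolve",
    "extract_trials",
    "select_reliable_units",
    "pool_virtual_population",
    "MODALITY_DEFAULTS",
]

MODALITY_DEFAULTS = {
    "ephys": {
        "window": (-0.3, 1.0),
        "baseline_window": (-0.3, 0.0),
        "bin_width": 0.001,
        "reliability_bin": 0.005,
        "reliability_threshold": 0.05,
    },
    "imaging": {
        "window": (-0.2, 0.8),
        "baseline_window": (-0.2, -0.02),
        "bin_width": 1.0 / 22.9,
        "reliability_bin": 0.042,
        "reliability_threshold": 0.3,
    },
}


@dataclass
class CalciumTrace:
    """dF/F trace for one ROI with deconvolution parameters."""

    f: np.ndarray               # dF/F
    frame_rate: float = 22.9
    tau_decay: float = 2.0      # indicator decay (s)
    smoothing_sigma: float = 0.031  # post-deconvolution Gaussian (s)
    F: np.ndarray | None = None
    F0: np.ndarray | None = None
    flagged: bool = False       # True when F0 <= 0 somewhere (excluded unit)


@dataclass
class TrialTensor:
    """Baseline-subtracted responses, indexed (unit, sound, trial, time_bin)."""

    values: np.ndarray
    bin_width: float
    window: tuple
    modality: str
    sound_ids: list
    unit_meta: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.ndim != 4:
            raise ValueError("values must be (unit, sound, trial, time_bin)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trial tensor contains non-finite values")
        if self.modality not in MODALITY_DEFAULTS:
            raise ValueError(f"unknown modality {self.modality!r}")
        if not self.unit_meta:
            self.unit_meta = [{} for _ in range(self.n_units)]

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_sounds(self) -> int:
        return self.values.shape[1]

    @property
    def n_trials(self) -> int:
        return self.values.shape[2]

    @property
    def n_bins(self) -> int:
        return self.values.shape[3]

    @property
    def times(self) -> np.ndarray:
        """Bin-start times relative to sound onset (s)."""
        return self.window[0] + np.arange(self.n_bins) * self.bin_width

    def stimulus_bins(self, extra_after_offset: float = 0.0, duration: float | None = None):
        """Boolean mask of bins from sound onset to ``duration + extra_after_offset``."""
        if duration is None:
            duration = 0.5
        t = self.times
        return (t >= 0) & (t < duration + extra_after_offset)

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            h5.create_dataset("values", data=self.values, compression="gzip")
            h5.attrs["bin_width"] = self.bin_width
            h5.attrs["window"] = self.window
            h5.attrs["modality"] = self.modality
            h5.create_dataset(
                "sound_ids", data=np.array(self.sound_ids, dtype=h5py.string_dtype())
            )

    @classmethod
    def load(cls, path) -> "TrialTensor":
        import h5py

        with h5py.File(path, "r") as h5:
            return cls(
                values=h5["values"][...],
                bin_width=float(h5.attrs["bin_width"]),
                window=tuple(h5.attrs["window"]),
                modality=str(h5.attrs["modality"]),
                sound_ids=[s.decode() for s in h5["sound_ids"][...]],
            )


# ---------------------------------------------------------------------------
# fluorescence preprocessing
# ---------------------------------------------------------------------------


def dff(
    F: np.ndarray,
    F_np: np.ndarray | None = None,
    neuropil_fraction: float = 0.7,
    percentile: float = 3.0,
    baseline_filter_sigma: float = 2.0,
    baseline_window: float = 60.0,
    frame_rate: float = 22.9,
    tau_decay: float = 2.0,
) -> CalciumTrace:
    """Compute dF/F with neuropil subtraction and a sliding-percentile baseline.

    ``baseline_filter_sigma`` (s) smooths the corrected trace before the
    sliding ``percentile`` over ``baseline_window`` (s) defines F0.  Units
    where F0 is not strictly positive are flagged rather than silently
    producing NaNs.
    """
    F = np.asarray(F, dtype=float)
    if F_np is None:
        F_np = np.zeros_like(F)
    F_np = np.asarray(F_np, dtype=float)
    if F.shape != F_np.shape:
        raise ValueError("F and F_np must share length")
    if not 0.0 <= neuropil_fraction <= 1.0:
        raise ValueError("neuropil_fraction must lie in [0, 1]")
    corrected = F - neuropil_fraction * F_np
    smoothed = gaussian_filter1d(
        corrected, sigma=max(baseline_filter_sigma * frame_rate, 1e-9), mode="reflect"
    )
    size = max(int(round(baseline_window * frame_rate)), 1)
    F0 = percentile_filter(smoothed, percentile, size=size, mode="reflect")
    flagged = bool(np.any(F0 <= 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(F0 > 0, (corrected - F0) / F0, 0.0)
    return CalciumTrace(
        f=f, frame_rate=frame_rate, tau_decay=tau_decay, F=corrected, F0=F0, flagged=flagged
    )


def deconvolve(trace: CalciumTrace, smooth: bool = True) -> np.ndarray:
    """Firing-rate proxy ``r = f' + f/tau`` from a dF/F trace.

    The derivative uses central differences (one-sided at the ends); the
    result is Gaussian-smoothed with ``trace.smoothing_sigma`` unless
    ``smooth=False``.
    """
    f = np.asarray(trace.f, dtype=float)
    if f.size < 3:
        raise ValueError("trace too short to deconvolve (need >= 3 samples)")
    if trace.tau_decay <= 0:
        raise ValueError("tau_decay must be positive")
    dt = 1.0 / trace.frame_rate
    r = np.gradient(f, dt) + f / trace.tau_decay
    if smooth:
        sigma_frames = trace.smoothing_sigma * trace.frame_rate
        if sigma_frames > 0:
            r = gaussian_filter1d(r, sigma=sigma_frames, mode="reflect", truncate=4.0)
    return r


# ---------------------------------------------------------------------------
# trial extraction
# ---------------------------------------------------------------------------


def _bin_spikes(spike_times, onset, window, bin_width):
    edges = np.arange(window[0], window[1] + bin_width / 2, bin_width) + onset
    counts, _ = np.histogram(spike_times, bins=edges)
    return counts.astype(float)


def extract_trials(
    units,
    onsets,
    sound_ids,
    modality: str,
    recording_duration: float | None = None,
    frame_rate: float = 22.9,
    unit_meta: list | None = None,
) -> TrialTensor:
    """Slice per-unit recordings into a baseline-subtracted TrialTensor.

    ``units`` is a list of per-unit data: spike-time arrays (``ephys``) or
    deconvolved rate traces sampled at ``frame_rate`` (``imaging``).
    ``onsets`` maps each sound id (ordered as ``sound_ids``) to its list of
    trial onset times (s).  Every sound must retain the same number of
    complete trials; onsets whose window leaves the recording are dropped,
    and a sound dropping below the common trial count raises.
    """
    spec = MODALITY_DEFAULTS[modality]
    window = spec["window"]
    baseline = spec["baseline_window"]
    if modality == "ephys":
        bin_width = spec["bin_width"]
    else:
        bin_width = 1.0 / frame_rate
    n_bins = int(round((window[1] - window[0]) / bin_width))

    # complete trials per sound
    valid_onsets = []
    for sid in sound_ids:
        ons = np.asarray(onsets[sid], dtype=float)
        ok = ons + window[0] >= 0
        if recording_duration is not None:
            ok &= ons + window[1] <= recording_duration
        valid_onsets.append(ons[ok])
    n_trials = min(len(o) for o in valid_onsets)
    if n_trials == 0:
        raise ValueError("a sound has no complete trials inside the recording")
    if any(len(o) < len(np.atleast_1d(onsets[sid])) for o, sid in zip(valid_onsets, sound_ids)):
        expected = max(len(np.atleast_1d(onsets[sid])) for sid in sound_ids)
        if n_trials < expected:
            raise ValueError(
                f"sounds have fewer than {expected} complete trials (got {n_trials})"
            )
    valid_onsets = [o[:n_trials] for o in valid_onsets]

    values = np.zeros((len(units), len(sound_ids), n_trials, n_bins))
    t_rel = window[0] + np.arange(n_bins) * bin_width
    base_mask = (t_rel >= baseline[0]) & (t_rel < baseline[1])
    for u, unit in enumerate(units):
        for s, ons in enumerate(valid_onsets):
            for r, onset in enumerate(ons):
                if modality == "ephys":
                    resp = _bin_spikes(np.asarray(unit), onset, window, bin_width)
                else:
                    trace = np.asarray(unit, dtype=float)
                    start = int(round((onset + window[0]) * frame_rate))
                    idx = start + np.arange(n_bins)
                    if idx[0] < 0 or idx[-1] >= len(trace):
                        raise ValueError("imaging trial window outside recording")
                    resp = trace[idx]
                values[u, s, r] = resp - resp[base_mask].mean()
    return TrialTensor(
        values=values,
        bin_width=bin_width,
        window=window,
        modality=modality,
        sound_ids=list(sound_ids),
        unit_meta=unit_meta or [],
    )


# ---------------------------------------------------------------------------
# reliability-based unit selection
# ---------------------------------------------------------------------------


def _rebin(values: np.ndarray, bin_width: float, target_bin: float) -> np.ndarray:
    """Sum-pool the time axis to approximately ``target_bin`` wide bins."""
    factor = max(int(round(target_bin / bin_width)), 1)
    n = values.shape[-1] // factor * factor
    if n == 0:
        return values
    shape = values.shape[:-1] + (n // factor, factor)
    return values[..., :n].reshape(shape).sum(axis=-1)


def unit_reliability(tensor: TrialTensor, reliability_bin: float | None = None) -> np.ndarray:
    """Per-unit reliability: mean across-trial-pair Pearson correlation
    of the binned temporal response, averaged over sounds.

    Zero-variance traces contribute a correlation of 0 (conservative
    toward rejection).
    """
    spec = MODALITY_DEFAULTS[tensor.modality]
    if reliability_bin is None:
        reliability_bin = spec["reliability_bin"]
    v = _rebin(tensor.values, tensor.bin_width, reliability_bin)
    U, S, R, T = v.shape
    centered = v - v.mean(axis=-1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=-1))
    # pairwise trial correlations per (unit, sound)
    gram = np.einsum("usrt,usqt->usrq", centered, centered)
    denom = norms[:, :, :, None] * norms[:, :, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(denom > 0, gram / np.where(denom > 0, denom, 1.0), 0.0)
    iu, ju = np.triu_indices(R, k=1)
    pair_mean = corr[:, :, iu, ju].mean(axis=-1)
    return pair_mean.mean(axis=-1)


def select_reliable_units(
    tensor: TrialTensor,
    threshold: float | None = None,
    reliability_bin: float | None = None,
) -> TrialTensor:
    """Keep units whose reliability exceeds the modality threshold."""
    spec = MODALITY_DEFAULTS[tensor.modality]
    if threshold is None:
        threshold = spec["reliability_threshold"]
    rel = unit_reliability(tensor, reliability_bin)
    keep = rel > threshold
    if not np.any(keep):
        raise ValueError(
            f"no unit passes the reliability threshold {threshold} "
            f"({tensor.modality}); max reliability was {rel.max():.3f}"
        )
    return TrialTensor(
        values=tensor.values[keep],
        bin_width=tensor.bin_width,
        window=tensor.window,
        modality=tensor.modality,
        sound_ids=tensor.sound_ids,
        unit_meta=[m for m, k in zip(tensor.unit_meta, keep) if k],
    )


def pool_virtual_population(tensors: list, seed: int = 0) -> TrialTensor:
    """Concatenate sessions into one virtual population, shuffling trial
    identity independently for every (unit, sound) to limit noise
    correlations between simultaneously recorded units."""
    if not tensors:
        raise ValueError("no tensors to pool")
    first = tensors[0]
    for t in tensors[1:]:
        if t.sound_ids != first.sound_ids:
            raise ValueError("sessions have mismatched catalogs")
        if t.n_trials != first.n_trials or t.n_bins != first.n_bins:
            raise ValueError("sessions have mismatched trial structure")
        if t.modality != first.modality:
            raise ValueError("sessions have mismatched modalities")
    values = np.concatenate([t.values for t in tensors], axis=0)
    meta = [m for t in tensors for m in t.unit_meta]
    rng = np.random.default_rng(seed)
    out = np.empty_like(values)
    for u in range(values.shape[0]):
        for s in range(values.shape[1]):
            out[u, s] = values[u, s, rng.permutation(values.shape[2])]
    return TrialTensor(
        values=out,
        bin_width=first.bin_width,
        window=first.window,
        modality=first.modality,
        sound_ids=first.sound_ids,
        unit_meta=meta,
    )
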