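"""Mouse cochlear geometry and a phenomenological auditory-nerve simulator.

The geometry follows the standard mouse tonotopic map and innervation
measurements:

* basilar-membrane position (percent from apex):
  ``x = -56.5 + 82.5 * log10(CF)`` with CF in kHz;
* auditory-nerve fibers per inner hair cell:
  ``N = -0.0038 x^2 + 0.375 x + 7.9``;
* spontaneous rate from the calcium-clearance time constant:
  ``SR = 91.1 * tau_Ca^2.66`` with tau_Ca in ms and SR in spikes/s.

The default map tiles 5–50 kHz with 12 inner hair cells per octave
(40 IHCs) and draws one tau_Ca per fiber so spontaneous rates span
0.5–95 spikes/s.

The response model is deliberately phenomenological: a gammatone
filterbank at each fiber's characteristic frequency, half-wave
rectification with power-law compression, a low-pass envelope stage with
exponential adaptation, and inhomogeneous Poisson spike generation on top
of the fiber's spontaneous rate.  It reproduces the qualitative structure
of auditory-nerve population responses (tonotopic "blurred diagonal"
similarity), not fitted biophysics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "CochlearMap",
    "position_from_cf",
    "fibers_per_ihc",
    "sr_from_tau",
    "tau_from_sr",
    "build_cochlear_map",
    "simulate_anf_responses",
]

SR_COEFF = 91.1
SR_EXPONENT = 2.66
SR_RANGE_SPIKES_PER_S = (0.5, 95.0)


def position_from_cf(cf):
    """Basilar-membrane position (% from apex) for a characteristic frequency (kHz)."""
    cf = np.asarray(cf, dtype=float)
    if np.any(cf <= 0):
        raise ValueError("characteristic frequency must be positive (kHz)")
    return -56.5 + 82.5 * np.log10(cf)


def fibers_per_ihc(x):
    """Auditory-nerve fibers innervating one IHC at position ``x`` (% from apex).

    Returns the real-valued polynomial; integer counts round to nearest.
    """
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 100)):
        raise ValueError("position must lie in [0, 100] percent from apex")
    return -0.0038 * x**2 + 0.375 * x + 7.9


def sr_from_tau(tau_ca_ms):
    """Spontaneous rate (spikes/s) from the calcium-clearance time constant (ms)."""
    tau = np.asarray(tau_ca_ms, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau_Ca must be positive (ms)")
    return SR_COEFF * tau**SR_EXPONENT


def tau_from_sr(sr_spikes_per_s):
    """Inverse of :func:`sr_from_tau`: tau_Ca (ms) producing a target rate."""
    sr = np.asarray(sr_spikes_per_s, dtype=float)
    if np.any(sr <= 0):
        raise ValueError("spontaneous rate must be positive")
    return (sr / SR_COEFF) ** (1.0 / SR_EXPONENT)


@dataclass
class CochlearMap:
    """Per-fiber cochlear geometry: CF grid, positions, innervation, rates."""

    cf_khz: np.ndarray          # per IHC
    x_percent: np.ndarray       # per IHC
    n_fibers: np.ndarray        # per IHC (integer)
    fiber_cf_khz: np.ndarray    # per fiber
    fiber_ihc: np.ndarray       # per fiber: index of the innervated IHC
    tau_ca_ms: np.ndarray       # per fiber
    sr_spikes_per_s: np.ndarray # per fiber

    @property
    def n_ihc(self) -> int:
        return len(self.cf_khz)

    @property
    def total_fibers(self) -> int:
        return len(self.fiber_cf_khz)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "fiber_id": np.arange(self.total_fibers),
                "ihc": self.fiber_ihc,
                "cf_khz": self.fiber_cf_khz,
                "x_percent": self.x_percent[self.fiber_ihc],
                "tau_ca_ms": self.tau_ca_ms,
                "sr_spikes_per_s": self.sr_spikes_per_s,
            }
        )


def build_cochlear_map(config: dict | None = None, seed: int = 0) -> CochlearMap:
    """Build the cochlear map: CF grid, positions, fiber counts and rates.

    Defaults tile 5–50 kHz at 12 IHCs per octave (40 IHCs).  Per-fiber
    tau_Ca is drawn log-uniformly over the interval mapping to spontaneous
    rates in 0.5–95 spikes/s.
    """
    cfg = dict(config or {})
    cf_min = float(cfg.pop("cf_min_khz", 5.0))
    cf_max = float(cfg.pop("cf_max_khz", 50.0))
    per_octave = int(cfg.pop("ihc_per_octave", 12))
    sr_lo, sr_hi = cfg.pop("sr_range", SR_RANGE_SPIKES_PER_S)
    if cfg:
        raise ValueError(f"unknown config keys: {sorted(cfg)}")
    if not (0 < cf_min < cf_max) or per_octave < 1:
        raise ValueError("invalid CF range or density")
    n_ihc = int(np.floor(per_octave * np.log2(cf_max / cf_min))) + 1
    cf = cf_min * 2.0 ** (np.arange(n_ihc) / per_octave)
    x = position_from_cf(cf)
    counts = np.rint(fibers_per_ihc(np.clip(x, 0, 100))).astype(int)
    counts = np.maximum(counts, 1)
    fiber_ihc = np.repeat(np.arange(n_ihc), counts)
    rng = np.random.default_rng(seed)
    tau_lo, tau_hi = tau_from_sr(sr_lo), tau_from_sr(sr_hi)
    tau = np.exp(rng.uniform(np.log(tau_lo), np.log(tau_hi), size=len(fiber_ihc)))
    return CochlearMap(
        cf_khz=cf,
        x_percent=x,
        n_fibers=counts,
        fiber_cf_khz=cf[fiber_ihc],
        fiber_ihc=fiber_ihc,
        tau_ca_ms=tau,
        sr_spikes_per_s=sr_from_tau(tau),
    )


def _fiber_rate(
    wave: np.ndarray,
    sample_rate: float,
    cf_hz: float,
    sr_spont: float,
    rate_scale: float,
    adaptation_tau_s: float,
) -> np.ndarray:
    """Driven firing rate (spikes/s) for one fiber, on the waveform grid."""
    b, a = signal.gammatone(cf_hz, "iir", fs=sample_rate)
    bm = signal.lfilter(b, a, wave)
    # half-wave rectification + compressive nonlinearity (re 20 uPa)
    drive = np.maximum(bm, 0.0) / 20e-6
    drive = drive**0.3
    # envelope low-pass (1 kHz) approximating IHC membrane filtering
    sos = signal.butter(2, min(1000.0, 0.45 * sample_rate), fs=sample_rate, output="sos")
    env = np.maximum(signal.sosfilt(sos, drive), 0.0)
    # exponential short-term adaptation (divisive)
    alpha = 1.0 / (adaptation_tau_s * sample_rate)
    kernel_len = int(5 * adaptation_tau_s * sample_rate)
    t = np.arange(kernel_len)
    kernel = alpha * np.exp(-alpha * t)
    slow = signal.fftconvolve(env, kernel)[: len(env)]
    adapted = env / (1.0 + slow)
    return sr_spont + rate_scale * adapted


def simulate_anf_responses(
    cmap: CochlearMap,
    wave: np.ndarray,
    sample_rate: float,
    seed: int = 0,
    rate_scale: float = 300.0,
    adaptation_tau_s: float = 0.06,
    pad_s: float = 0.05,
) -> list:
    """Simulate spike trains for every fiber of the map.

    Returns a list of per-fiber spike-time arrays (s, relative to waveform
    onset).  ``pad_s`` seconds of silence are appended so offset activity and
    spontaneous firing after the sound are represented.  Deterministic given
    ``seed``.
    """
    if sample_rate < 2.0 * np.max(cmap.fiber_cf_khz) * 1e3:
        raise ValueError("sample rate violates Nyquist for the highest CF")
    wave = np.concatenate([wave, np.zeros(int(pad_s * sample_rate))])
    rng = np.random.default_rng(seed)
    dt = 1.0 / sample_rate
    spikes = []
    # one rate profile per IHC (fibers on an IHC share the filterbank drive)
    rates_by_ihc: dict = {}
    for fiber in range(cmap.total_fibers):
        ihc = cmap.fiber_ihc[fiber]
        if ihc not in rates_by_ihc:
            rates_by_ihc[ihc] = _fiber_rate(
                wave,
                sample_rate,
                cmap.fiber_cf_khz[fiber] * 1e3,
                0.0,
                rate_scale,
                adaptation_tau_s,
            )
        rate = rates_by_ihc[ihc] + cmap.sr_spikes_per_s[fiber]
        p = np.clip(rate * dt, 0.0, 1.0)
        idx = np.nonzero(rng.random(len(p)) < p)[0]
        spikes.append(idx * dt)
    return spikes
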