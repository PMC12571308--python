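"""Stimulus catalog construction and waveform synthesis.

The experimental protocol this package models probes auditory neural
populations with a catalog of 307 short sounds (each at most 500 ms,
repeated 12 times, 1 s between onsets) drawn from eight categories:

* ``pure_tone``    — 14 log-spaced frequencies 2–60 kHz x {50, 70} dB SPL (28)
* ``ramp``         — linear-in-dB intensity ramps 50<->70 dB on the 13 tone
                     frequencies below 50 kHz, up and down (26)
* ``chord``        — 2–4 tone sums from low/mid/high/broad/harmonic pools (48)
* ``chirp``        — frequency sweeps: a 6–12 kHz duration series and five
                     500-ms range families, both directions (20)
* ``noise``        — broadband, octave-band-filtered and narrowband Gaussian
                     noises, some intensity-ramped (30)
* ``am``           — sinusoidally amplitude-modulated carriers, 8 carriers x
                     6 modulation frequencies 4–160 Hz (48)
* ``complex``      — 15 synthetic complex-sound identities, forward and
                     time-reversed, at 50 and 70 dB (60)
* ``decomposition``— components of four complex identities and the
                     reconstructions summing them at stored onsets (47)

Levels are RMS-referenced dB SPL (re 20 uPa) and every waveform carries
10-ms raised-cosine onset/offset ramps.  Catalog construction is purely
parametric (fast); waveforms are synthesized on demand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "Stimulus",
    "StimulusCatalog",
    "build_catalog",
    "synthesize",
    "make_complex_surrogates",
    "spl_to_pascal",
    "CATEGORIES",
]

CATEGORIES = (
    "pure_tone",
    "ramp",
    "chord",
    "chirp",
    "noise",
    "am",
    "complex",
    "decomposition",
)

#: reference pressure for dB SPL (Pa)
P_REF = 20e-6

#: raised-cosine on/off ramp duration (s)
RAMP_DURATION = 0.010

DEFAULT_SAMPLE_RATE = 192_000.0

# 14 log-spaced pure-tone frequencies, 2–60 kHz inclusive
TONE_FREQS_KHZ = tuple(np.geomspace(2.0, 60.0, 14))

# chord pools (kHz); low/mid/high contribute 11 combinations each
CHORD_POOLS = {
    "low": (2.0, 4.0, 5.0, 8.0),
    "mid": (10.0, 12.0, 16.0, 20.0),
    "high": (25.0, 32.0, 40.0, 50.0),
    "broad": (6.0, 12.0, 20.0, 40.0),
    "harmo": (4.0, 8.0, 12.0, 16.0),
}

# 6 modulation frequencies log-spaced over 4–160 Hz
AM_MOD_FREQS_HZ = tuple(4.0 * (160.0 / 4.0) ** (k / 5) for k in range(6))

# five 500-ms sweep ranges (kHz) spanning 4–50 kHz
CHIRP_RANGES_KHZ = ((4.0, 50.0), (4.0, 12.0), (12.0, 50.0), (4.0, 25.0), (8.0, 50.0))
CHIRP_DURATIONS_S = (0.025, 0.050, 0.100, 0.200, 0.400)

# band-filtered noises: 9 octave bandwidths centered at 10 kHz
NOISE_BAND_WIDTHS_OCT = tuple(0.5 * k for k in range(1, 10))
NOISE_BAND_CENTER_KHZ = 10.0
# five 1-kHz-wide narrowband noises
NOISE_NARROW_CENTERS_KHZ = (4.0, 8.0, 12.0, 16.0, 25.0)
# dual narrowband ramped pairs, matching chord frequencies
NOISE_DUAL_PAIRS_KHZ = ((4.0, 8.0), (10.0, 20.0), (12.0, 25.0), (16.0, 32.0), (5.0, 10.0))


def spl_to_pascal(level_db: float) -> float:
    """RMS pressure (Pa) for a level in dB SPL re 20 uPa."""
    return P_REF * 10.0 ** (level_db / 20.0)


@dataclass(frozen=True)
class Stimulus:
    """One catalog entry: category, synthesis parameters, level, duration."""

    sound_id: str
    category: str
    duration: float
    level: float
    params: dict
    sample_rate: float = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not (0 < self.duration <= 0.5):
            raise ValueError(f"duration must lie in (0, 0.5] s, got {self.duration}")


@dataclass
class StimulusCatalog:
    """Ordered stimulus list plus the presentation protocol."""

    stimuli: list
    trials_per_sound: int = 12
    inter_onset_interval: float = 1.0
    seed: int = 0
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {s.sound_id: s for s in self.stimuli}
        if len(self._index) != len(self.stimuli):
            raise ValueError("duplicate sound_ids in catalog")

    def __len__(self) -> int:
        return len(self.stimuli)

    def __iter__(self):
        return iter(self.stimuli)

    def __getitem__(self, sound_id: str) -> Stimulus:
        return self._index[sound_id]

    def by_category(self, category: str) -> list:
        return [s for s in self.stimuli if s.category == category]

    @property
    def sound_ids(self) -> list:
        return [s.sound_id for s in self.stimuli]

    def category_counts(self) -> dict:
        counts: dict = {}
        for s in self.stimuli:
            counts[s.category] = counts.get(s.category, 0) + 1
        return counts

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "sound_id": s.sound_id,
                "category": s.category,
                "duration": s.duration,
                "level": s.level,
                "sample_rate": s.sample_rate,
                "params": json.dumps(s.params, sort_keys=True),
            }
            for s in self.stimuli
        ]
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "trials_per_sound": self.trials_per_sound,
            "inter_onset_interval": self.inter_onset_interval,
            "seed": self.seed,
            "stimuli": [
                {
                    "sound_id": s.sound_id,
                    "category": s.category,
                    "duration": s.duration,
                    "level": s.level,
                    "sample_rate": s.sample_rate,
                    "params": s.params,
                }
                for s in self.stimuli
            ],
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StimulusCatalog":
        payload = json.loads(text)
        stimuli = [
            Stimulus(
                sound_id=d["sound_id"],
                category=d["category"],
                duration=d["duration"],
                level=d["level"],
                params=d["params"],
                sample_rate=d["sample_rate"],
            )
            for d in payload["stimuli"]
        ]
        return cls(
            stimuli=stimuli,
            trials_per_sound=payload["trials_per_sound"],
            inter_onset_interval=payload["inter_onset_interval"],
            seed=payload["seed"],
        )


# ---------------------------------------------------------------------------
# catalog enumeration
# ---------------------------------------------------------------------------


def _combinations(pool, sizes):
    from itertools import combinations

    out = []
    for k in sizes:
        out.extend(combinations(pool, k))
    return out


def _tone_id(freq_khz: float, level_db: float) -> str:
    return f"tone_{freq_khz:07.3f}kHz_{level_db:.0f}dB"


def build_catalog(protocol_config: dict | None = None, seed: int = 0) -> StimulusCatalog:
    """Enumerate the default 307-sound catalog.

    ``protocol_config`` may override ``sample_rate`` (with a Nyquist guard
    against the highest frequency in the catalog, 80 kHz), ``trials_per_sound``
    and ``inter_onset_interval``.  ``seed`` fixes the random chord/noise
    phases and the complex-surrogate compositions; identical seeds yield
    byte-identical catalogs.
    """
    cfg = dict(protocol_config or {})
    sr = float(cfg.pop("sample_rate", DEFAULT_SAMPLE_RATE))
    trials = int(cfg.pop("trials_per_sound", 12))
    ioi = float(cfg.pop("inter_onset_interval", 1.0))
    if cfg:
        raise ValueError(f"unknown protocol_config keys: {sorted(cfg)}")
    max_khz = 80.0
    if sr < 2.0 * max_khz * 1e3:
        raise ValueError(
            f"sample_rate {sr} Hz violates Nyquist for the {max_khz} kHz catalog ceiling"
        )
    rng = np.random.default_rng(seed)
    stimuli: list = []

    # --- pure tones (28)
    for f in TONE_FREQS_KHZ:
        for lvl in (50.0, 70.0):
            stimuli.append(
                Stimulus(
                    sound_id=_tone_id(f, lvl),
                    category="pure_tone",
                    duration=0.5,
                    level=lvl,
                    params={"freq_khz": f, "level_db": lvl},
                    sample_rate=sr,
                )
            )

    # --- intensity ramps (26): 13 lowest tone frequencies, up and down
    for f in TONE_FREQS_KHZ[:13]:
        for direction in ("up", "down"):
            start, end = (50.0, 70.0) if direction == "up" else (70.0, 50.0)
            stimuli.append(
                Stimulus(
                    sound_id=f"ramp_{f:07.3f}kHz_{direction}",
                    category="ramp",
                    duration=0.5,
                    level=70.0,
                    params={
                        "freq_khz": f,
                        "direction": direction,
                        "start_db": start,
                        "end_db": end,
                    },
                    sample_rate=sr,
                )
            )

    # --- chords (48)
    pool_sizes = {
        "low": (2, 3, 4),
        "mid": (2, 3, 4),
        "high": (2, 3, 4),
        "broad": (2, 3),  # 10 combinations
    }
    for pool_name, sizes in pool_sizes.items():
        for combo in _combinations(CHORD_POOLS[pool_name], sizes):
            phases = rng.uniform(0, 2 * np.pi, size=len(combo))
            fid = "-".join(f"{f:g}" for f in combo)
            stimuli.append(
                Stimulus(
                    sound_id=f"chord_{pool_name}_{fid}",
                    category="chord",
                    duration=0.5,
                    level=70.0,
                    params={
                        "freqs_khz": list(combo),
                        "pool": pool_name,
                        "phases": [float(p) for p in phases],
                    },
                    sample_rate=sr,
                )
            )
    harmo = CHORD_POOLS["harmo"]
    harmo_sets = [
        (harmo[0], harmo[1]),
        (harmo[0], harmo[1], harmo[2]),
        (harmo[0], harmo[1], harmo[2], harmo[3]),
        (harmo[0], harmo[2], harmo[3]),
        (harmo[1], harmo[3]),
    ]
    for combo in harmo_sets:
        phases = rng.uniform(0, 2 * np.pi, size=len(combo))
        fid = "-".join(f"{f:g}" for f in combo)
        stimuli.append(
            Stimulus(
                sound_id=f"chord_harmo_{fid}",
                category="chord",
                duration=0.5,
                level=70.0,
                params={
                    "freqs_khz": list(combo),
                    "pool": "harmo",
                    "phases": [float(p) for p in phases],
                },
                sample_rate=sr,
            )
        )

    # --- chirps (20)
    for dur in CHIRP_DURATIONS_S:
        for direction in ("up", "down"):
            stimuli.append(
                Stimulus(
                    sound_id=f"chirp_dur{dur * 1e3:.0f}ms_{direction}",
                    category="chirp",
                    duration=dur,
                    level=50.0,
                    params={
                        "f0_khz": 6.0,
                        "f1_khz": 12.0,
                        "direction": direction,
                        "family": "duration",
                    },
                    sample_rate=sr,
                )
            )
    for f0, f1 in CHIRP_RANGES_KHZ:
        for direction in ("up", "down"):
            stimuli.append(
                Stimulus(
                    sound_id=f"chirp_{f0:g}-{f1:g}kHz_{direction}",
                    category="chirp",
                    duration=0.5,
                    level=50.0,
                    params={
                        "f0_khz": f0,
                        "f1_khz": f1,
                        "direction": direction,
                        "family": "range",
                    },
                    sample_rate=sr,
                )
            )

    # --- noises (30)
    bb_lo, bb_hi = 2.0, 80.0
    for lvl in (50.0, 70.0):
        stimuli.append(
            Stimulus(
                sound_id=f"noise_bb_{lvl:.0f}dB",
                category="noise",
                duration=0.5,
                level=lvl,
                params={
                    "kind": "broadband",
                    "low_khz": bb_lo,
                    "high_khz": bb_hi,
                    "noise_seed": int(rng.integers(2**31)),
                },
                sample_rate=sr,
            )
        )
    for dur in (0.1, 0.5):
        for direction in ("up", "down"):
            start, end = (50.0, 70.0) if direction == "up" else (70.0, 50.0)
            stimuli.append(
                Stimulus(
                    sound_id=f"noise_bb_ramp{dur * 1e3:.0f}ms_{direction}",
                    category="noise",
                    duration=dur,
                    level=70.0,
                    params={
                        "kind": "broadband_ramp",
                        "low_khz": bb_lo,
                        "high_khz": bb_hi,
                        "direction": direction,
                        "start_db": start,
                        "end_db": end,
                        "noise_seed": int(rng.integers(2**31)),
                    },
                    sample_rate=sr,
                )
            )
    for width in NOISE_BAND_WIDTHS_OCT:
        lo = NOISE_BAND_CENTER_KHZ * 2.0 ** (-width / 2)
        hi = NOISE_BAND_CENTER_KHZ * 2.0 ** (width / 2)
        stimuli.append(
            Stimulus(
                sound_id=f"noise_band_{width:.1f}oct",
                category="noise",
                duration=0.5,
                level=70.0,
                params={
                    "kind": "band",
                    "low_khz": lo,
                    "high_khz": hi,
                    "bandwidth_octaves": width,
                    "center_khz": NOISE_BAND_CENTER_KHZ,
                    "noise_seed": int(rng.integers(2**31)),
                },
                sample_rate=sr,
            )
        )
    for center in NOISE_NARROW_CENTERS_KHZ:
        stimuli.append(
            Stimulus(
                sound_id=f"noise_narrow_{center:g}kHz",
                category="noise",
                duration=0.5,
                level=70.0,
                params={
                    "kind": "narrow",
                    "low_khz": center - 0.5,
                    "high_khz": center + 0.5,
                    "center_khz": center,
                    "noise_seed": int(rng.integers(2**31)),
                },
                sample_rate=sr,
            )
        )
    for c1, c2 in NOISE_DUAL_PAIRS_KHZ:
        for direction in ("up", "down"):
            start, end = (50.0, 70.0) if direction == "up" else (70.0, 50.0)
            stimuli.append(
                Stimulus(
                    sound_id=f"noise_dual_{c1:g}+{c2:g}kHz_{direction}",
                    category="noise",
                    duration=0.5,
                    level=70.0,
                    params={
                        "kind": "dual_ramp",
                        "centers_khz": [c1, c2],
                        "direction": direction,
                        "start_db": start,
                        "end_db": end,
                        "noise_seed": int(rng.integers(2**31)),
                    },
                    sample_rate=sr,
                )
            )

    # --- AM sounds (48): 8 carriers x 6 modulation frequencies
    carriers = [
        {"carrier_kind": "tone", "carrier_freqs_khz": [8.0], "carrier_name": "8kHz"},
        {"carrier_kind": "tone", "carrier_freqs_khz": [12.0], "carrier_name": "12kHz"},
    ]
    am_chords = {
        "low": list(CHORD_POOLS["low"]),
        "mid": list(CHORD_POOLS["mid"]),
        "high": list(CHORD_POOLS["high"]),
        "broad": list(CHORD_POOLS["broad"][:3]),
        "harmo": list(CHORD_POOLS["harmo"]),
    }
    for name, freqs in am_chords.items():
        carriers.append(
            {"carrier_kind": "chord", "carrier_freqs_khz": freqs, "carrier_name": f"chord_{name}"}
        )
    carriers.append(
        {"carrier_kind": "noise", "carrier_freqs_khz": [], "carrier_name": "noise"}
    )
    for carrier in carriers:
        for fm in AM_MOD_FREQS_HZ:
            phases = rng.uniform(0, 2 * np.pi, size=max(len(carrier["carrier_freqs_khz"]), 1))
            stimuli.append(
                Stimulus(
                    sound_id=f"am_{carrier['carrier_name']}_fm{fm:.1f}Hz",
                    category="am",
                    duration=0.5,
                    level=70.0,
                    params={
                        **carrier,
                        "fm_hz": fm,
                        "phases": [float(p) for p in phases],
                        "noise_seed": int(rng.integers(2**31)),
                    },
                    sample_rate=sr,
                )
            )

    # --- complex surrogates (60) and decomposition sounds (47)
    stimuli.extend(make_complex_surrogates(15, seed=int(rng.integers(2**31)), sample_rate=sr))
    stimuli.extend(_decomposition_sounds(int(rng.integers(2**31)), sr))

    return StimulusCatalog(
        stimuli=stimuli, trials_per_sound=trials, inter_onset_interval=ioi, seed=seed
    )


# ---------------------------------------------------------------------------
# complex surrogates and decompositions
# ---------------------------------------------------------------------------


def _surrogate_components(identity: int, rng: np.random.Generator) -> list:
    """Random component plan for one complex-sound identity.

    Components are short chirps, noise-click trains and band-limited noise
    bursts arranged on a 500-ms grid, mimicking the richness of natural
    vocalization-like sounds.
    """
    n_parts = int(rng.integers(3, 6))
    onsets = np.sort(rng.uniform(0.0, 0.35, size=n_parts))
    comps = []
    for onset in onsets:
        kind = rng.choice(["chirp", "clicks", "band"])
        dur = float(rng.uniform(0.05, 0.14))
        if kind == "chirp":
            f0 = float(rng.uniform(3.0, 20.0))
            comps.append(
                {
                    "kind": "chirp",
                    "onset_s": float(onset),
                    "duration": dur,
                    "f0_khz": f0,
                    "f1_khz": f0 * float(rng.uniform(1.5, 3.0)),
                    "direction": str(rng.choice(["up", "down"])),
                }
            )
        elif kind == "clicks":
            comps.append(
                {
                    "kind": "clicks",
                    "onset_s": float(onset),
                    "duration": dur,
                    "rate_hz": float(rng.uniform(30.0, 80.0)),
                    "center_khz": float(rng.uniform(4.0, 30.0)),
                    "noise_seed": int(rng.integers(2**31)),
                }
            )
        else:
            lo = float(rng.uniform(2.0, 20.0))
            comps.append(
                {
                    "kind": "band",
                    "onset_s": float(onset),
                    "duration": dur,
                    "low_khz": lo,
                    "high_khz": lo * float(rng.uniform(1.3, 2.5)),
                    "noise_seed": int(rng.integers(2**31)),
                }
            )
    return comps


def make_complex_surrogates(
    n_identities: int, seed: int = 0, sample_rate: float = DEFAULT_SAMPLE_RATE
) -> list:
    """Synthetic stand-ins for the recorded complex sounds.

    Each identity is a seeded composition of parameterized components with
    stored onset times; the four variants (forward/reversed x 50/70 dB)
    expand ``n_identities`` identities into ``4 * n_identities`` catalog
    entries.
    """
    if n_identities < 1:
        raise ValueError("n_identities must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for ident in range(n_identities):
        comps = _surrogate_components(ident, rng)
        for direction in ("forward", "reversed"):
            for lvl in (50.0, 70.0):
                out.append(
                    Stimulus(
                        sound_id=f"complex_{ident:02d}_{direction}_{lvl:.0f}dB",
                        category="complex",
                        duration=0.5,
                        level=lvl,
                        params={
                            "identity": ident,
                            "direction": direction,
                            "components": comps,
                        },
                        sample_rate=sample_rate,
                    )
                )
    return out


def _decomposition_plan(rng: np.random.Generator) -> dict:
    """Component plans for the four decomposed complex identities.

    Mirrors the printed decompositions: a natural-environment sound made of
    five amplitude-ramped filtered noises, two bird-call-like sequences of
    intro chirps plus click/chirp trains (repeated twice), and a
    dolphin-call-like sequence of chirps plus harmonic click trains.
    """
    plans = {}
    # natural environment: 5 concurrent ramped filtered noises in 2-12 kHz
    env = []
    edges = np.geomspace(2.0, 12.0, 6)
    for i in range(5):
        env.append(
            {
                "kind": "ramped_band",
                "onset_s": 0.0,
                "duration": 0.5,
                "low_khz": float(edges[i]),
                "high_khz": float(edges[i + 1]),
                "start_db_offset": -20.0,
                "noise_seed": int(rng.integers(2**31)),
            }
        )
    plans["nat_env"] = {"components": env, "repeats": 1}

    def chirp(onset, dur, f0, f1, direction="up", intro=False):
        return {
            "kind": "chirp",
            "onset_s": onset,
            "duration": dur,
            "f0_khz": f0,
            "f1_khz": f1,
            "direction": direction,
            "intro": intro,
        }

    def clicks(onset, dur, rate, center):
        return {
            "kind": "clicks",
            "onset_s": onset,
            "duration": dur,
            "rate_hz": rate,
            "center_khz": center,
            "noise_seed": int(rng.integers(2**31)),
        }

    def chirp_train(onset, dur, rate, f0, f1):
        return {
            "kind": "chirp_train",
            "onset_s": onset,
            "duration": dur,
            "rate_hz": rate,
            "f0_khz": f0,
            "f1_khz": f1,
        }

    # bird call 1: 2 intro chirps, 2 noise-click trains, 1 chirp train @55 Hz
    plans["bird1"] = {
        "components": [
            chirp(0.000, 0.020, 4.0, 16.0, intro=True),
            chirp(0.030, 0.020, 5.0, 20.0, intro=True),
            clicks(0.060, 0.060, 60.0, 8.0),
            clicks(0.130, 0.060, 60.0, 12.0),
            chirp_train(0.200, 0.050, 55.0, 6.0, 12.0),
        ],
        "repeats": 2,
    }
    # bird call 2: 4 intro chirps, 3 click trains, 2 chirp trains @44 Hz
    plans["bird2"] = {
        "components": [
            chirp(0.000, 0.015, 3.0, 12.0, intro=True),
            chirp(0.020, 0.015, 4.0, 16.0, intro=True),
            chirp(0.040, 0.015, 5.0, 20.0, intro=True),
            chirp(0.060, 0.015, 6.0, 24.0, intro=True),
            clicks(0.080, 0.040, 50.0, 6.0),
            clicks(0.125, 0.040, 50.0, 10.0),
            clicks(0.170, 0.030, 50.0, 16.0),
            chirp_train(0.205, 0.020, 44.0, 4.0, 8.0),
            chirp_train(0.228, 0.020, 44.0, 8.0, 16.0),
        ],
        "repeats": 2,
    }
    # dolphin call: 2 fast chirps, click train @8.1 kHz, 5 harmonics of
    # 11.6 kHz modulated down 0.7 octave over 200 ms
    dolphin = [
        chirp(0.000, 0.020, 6.0, 24.0, intro=True),
        chirp(0.025, 0.020, 8.0, 30.0, intro=True),
        clicks(0.050, 0.190, 70.0, 8.1),
    ]
    for k in range(1, 6):
        f_hi = 11.6 * k
        dolphin.append(chirp(0.050, 0.200, f_hi * 2.0**-0.7, f_hi, "down"))
    plans["dolphin"] = {"components": dolphin, "repeats": 2}
    return plans


def _decomposition_sounds(seed: int, sr: float) -> list:
    """Enumerate the 47 decomposition-category entries.

    27 components at 70 dB, the 8 intro chirps again at 50 dB, and the
    four reconstructions at 70 dB, 50 dB and time-reversed at 70 dB
    (4 x 3 = 12): 27 + 8 + 12 = 47.
    """
    rng = np.random.default_rng(seed)
    plans = _decomposition_plan(rng)
    out = []
    recon_members: dict = {}
    for ident, plan in plans.items():
        comp_ids = []
        for i, comp in enumerate(plan["components"]):
            sid = f"decomp_{ident}_c{i:02d}_70dB"
            out.append(
                Stimulus(
                    sound_id=sid,
                    category="decomposition",
                    duration=max(comp["duration"], 0.05),
                    level=70.0,
                    params={
                        "identity": ident,
                        "role": "component",
                        "component": comp,
                        "comp_index": i,
                    },
                    sample_rate=sr,
                )
            )
            comp_ids.append((sid, comp["onset_s"]))
            if comp.get("intro"):
                out.append(
                    Stimulus(
                        sound_id=f"decomp_{ident}_c{i:02d}_50dB",
                        category="decomposition",
                        duration=max(comp["duration"], 0.05),
                        level=50.0,
                        params={
                            "identity": ident,
                            "role": "component",
                            "component": comp,
                            "comp_index": i,
                        },
                        sample_rate=sr,
                    )
                )
        recon_members[ident] = (comp_ids, plan["repeats"])
    for ident, (comp_ids, repeats) in recon_members.items():
        span = max(o for _, o in comp_ids) + max(
            plans[ident]["components"][i]["duration"] for i in range(len(comp_ids))
        )
        onsets = []
        for rep in range(repeats):
            shift = rep * min(span, 0.25)
            onsets.extend([(sid, onset + shift) for sid, onset in comp_ids])
        for lvl, direction in ((70.0, "forward"), (50.0, "forward"), (70.0, "reversed")):
            out.append(
                Stimulus(
                    sound_id=f"decomp_{ident}_recon_{direction}_{lvl:.0f}dB",
                    category="decomposition",
                    duration=0.5,
                    level=lvl,
                    params={
                        "identity": ident,
                        "role": "reconstruction",
                        "direction": direction,
                        "component_onsets": [[sid, float(t)] for sid, t in onsets],
                        "level_offset_db": lvl - 70.0,
                        "repeats": repeats,
                    },
                    sample_rate=sr,
                )
            )
    return out


# ---------------------------------------------------------------------------
# waveform synthesis
# ---------------------------------------------------------------------------


def _raised_cosine_ramp(n_samples: int, sr: float) -> np.ndarray:
    """Multiplicative envelope with 10-ms raised-cosine on/off ramps."""
    env = np.ones(n_samples)
    n_ramp = int(round(RAMP_DURATION * sr))
    n_ramp = min(n_ramp, n_samples // 2)
    if n_ramp > 0:
        t = np.arange(n_ramp) / n_ramp
        ramp = 0.5 * (1.0 - np.cos(np.pi * t))
        env[:n_ramp] = ramp
        env[-n_ramp:] = ramp[::-1]
    return env


def _calibrate(wave: np.ndarray, level_db: float) -> np.ndarray:
    rms = np.sqrt(np.mean(wave**2))
    if rms == 0:
        raise ValueError("cannot calibrate an all-zero waveform")
    return wave * (spl_to_pascal(level_db) / rms)


def _band_noise(n: int, sr: float, low_khz: float, high_khz: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    nyq = sr / 2.0
    lo = max(low_khz * 1e3 / nyq, 1e-6)
    hi = min(high_khz * 1e3 / nyq, 1.0 - 1e-6)
    sos = signal.butter(8, [lo, hi], btype="bandpass", output="sos")
    return signal.sosfilt(sos, white)


def chirp_frequency_track(stim: Stimulus, t: np.ndarray) -> np.ndarray:
    """Instantaneous frequency (Hz) of a chirp at times ``t`` (s)."""
    p = stim.params
    f0, f1 = p["f0_khz"] * 1e3, p["f1_khz"] * 1e3
    T = stim.duration
    track = f0 * (f1 / f0) ** (np.clip(t, 0, T) / T)
    if p["direction"] == "down":
        track = f0 * (f1 / f0) ** ((T - np.clip(t, 0, T)) / T)
    return track


def _log_chirp(f0: float, f1: float, duration: float, sr: float, direction: str) -> np.ndarray:
    n = int(round(duration * sr))
    t = np.arange(n) / sr
    if direction == "down":
        # phase integral of the time-reversed frequency track
        k = np.log(f1 / f0)
        freq = f1 * np.exp(-k * t / duration)
    else:
        k = np.log(f1 / f0)
        freq = f0 * np.exp(k * t / duration)
    phase = 2 * np.pi * np.cumsum(freq) / sr
    return np.sin(phase)


def _db_ramp_envelope(n: int, sr: float, start_db: float, end_db: float) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)
    level = start_db + (end_db - start_db) * t
    return 10.0 ** (level / 20.0) * P_REF * np.sqrt(2.0)


def _synth_component(comp: dict, sr: float, level_db: float) -> np.ndarray:
    """Waveform of one complex/decomposition component, calibrated and ramped."""
    n = int(round(comp["duration"] * sr))
    if comp["kind"] == "chirp":
        wave = _log_chirp(
            comp["f0_khz"] * 1e3, comp["f1_khz"] * 1e3, comp["duration"], sr, comp["direction"]
        )
    elif comp["kind"] == "chirp_train":
        period = int(round(sr / comp["rate_hz"]))
        single = _log_chirp(
            comp["f0_khz"] * 1e3,
            comp["f1_khz"] * 1e3,
            min(0.8 * period / sr, comp["duration"]),
            sr,
            "up",
        )
        wave = np.zeros(n)
        pos = 0
        while pos < n:
            seg = single[: n - pos]
            wave[pos : pos + len(seg)] += seg
            pos += period
    elif comp["kind"] == "clicks":
        period = int(round(sr / comp["rate_hz"]))
        click_len = max(int(round(0.002 * sr)), 2)
        base = _band_noise(
            click_len, sr, comp["center_khz"] * 0.8, comp["center_khz"] * 1.25, comp["noise_seed"]
        )
        wave = np.zeros(n)
        pos = 0
        while pos < n:
            seg = base[: n - pos]
            wave[pos : pos + len(seg)] += seg
            pos += period
    elif comp["kind"] == "band":
        wave = _band_noise(n, sr, comp["low_khz"], comp["high_khz"], comp["noise_seed"])
    elif comp["kind"] == "ramped_band":
        wave = _band_noise(n, sr, comp["low_khz"], comp["high_khz"], comp["noise_seed"])
        start = level_db + comp.get("start_db_offset", -20.0)
        wave = wave / np.sqrt(np.mean(wave**2)) / np.sqrt(2.0)
        wave = wave * _db_ramp_envelope(n, sr, start, level_db)
        return wave * _raised_cosine_ramp(n, sr)
    else:
        raise ValueError(f"unknown component kind {comp['kind']!r}")
    wave = wave * _raised_cosine_ramp(n, sr)
    if np.all(wave == 0):
        return wave
    return _calibrate(wave, level_db)


def synthesize(stim: Stimulus, catalog: StimulusCatalog | None = None) -> np.ndarray:
    """Render a stimulus to pressure samples (Pa) at ``stim.sample_rate``.

    Waveforms carry 10-ms raised-cosine onset/offset ramps and, except for
    intensity-ramped stimuli and component-sum reconstructions, are
    RMS-calibrated to the stimulus level (dB SPL re 20 uPa) after ramping.
    Reconstruction entries of the ``decomposition`` category need ``catalog``
    to resolve their component waveforms.
    """
    sr = stim.sample_rate
    n = int(round(stim.duration * sr))
    t = np.arange(n) / sr
    p = stim.params
    for v in p.values():
        if isinstance(v, float) and not np.isfinite(v):
            raise ValueError(f"non-finite parameter in {stim.sound_id}")

    if stim.category == "pure_tone":
        f = p["freq_khz"] * 1e3
        if f >= sr / 2:
            raise ValueError("tone frequency violates Nyquist")
        wave = np.sin(2 * np.pi * f * t) * _raised_cosine_ramp(n, sr)
        return _calibrate(wave, stim.level)

    if stim.category == "ramp":
        f = p["freq_khz"] * 1e3
        carrier = np.sin(2 * np.pi * f * t)
        env = _db_ramp_envelope(n, sr, p["start_db"], p["end_db"])
        return carrier * env * _raised_cosine_ramp(n, sr)

    if stim.category == "chord":
        wave = np.zeros(n)
        for f, ph in zip(p["freqs_khz"], p["phases"]):
            wave += np.sin(2 * np.pi * f * 1e3 * t + ph)
        wave *= _raised_cosine_ramp(n, sr)
        return _calibrate(wave, stim.level)

    if stim.category == "chirp":
        wave = _log_chirp(
            p["f0_khz"] * 1e3, p["f1_khz"] * 1e3, stim.duration, sr, p["direction"]
        )
        wave *= _raised_cosine_ramp(n, sr)
        return _calibrate(wave, stim.level)

    if stim.category == "noise":
        kind = p["kind"]
        if kind in ("broadband", "band", "narrow"):
            wave = _band_noise(n, sr, p["low_khz"], p["high_khz"], p["noise_seed"])
            wave *= _raised_cosine_ramp(n, sr)
            return _calibrate(wave, stim.level)
        if kind == "broadband_ramp":
            wave = _band_noise(n, sr, p["low_khz"], p["high_khz"], p["noise_seed"])
            wave = wave / np.sqrt(np.mean(wave**2)) / np.sqrt(2.0)
            env = _db_ramp_envelope(n, sr, p["start_db"], p["end_db"])
            return wave * env * _raised_cosine_ramp(n, sr)
        if kind == "dual_ramp":
            wave = np.zeros(n)
            rng = np.random.default_rng(p["noise_seed"])
            for center in p["centers_khz"]:
                band = _band_noise(
                    n, sr, center - 0.5, center + 0.5, int(rng.integers(2**31))
                )
                wave += band / np.sqrt(np.mean(band**2)) / np.sqrt(2.0)
            env = _db_ramp_envelope(n, sr, p["start_db"], p["end_db"])
            return wave * env * _raised_cosine_ramp(n, sr)
        raise ValueError(f"unknown noise kind {kind!r}")

    if stim.category == "am":
        if p["carrier_kind"] == "tone":
            carrier = np.sin(2 * np.pi * p["carrier_freqs_khz"][0] * 1e3 * t + p["phases"][0])
        elif p["carrier_kind"] == "chord":
            carrier = np.zeros(n)
            for f, ph in zip(p["carrier_freqs_khz"], p["phases"]):
                carrier += np.sin(2 * np.pi * f * 1e3 * t + ph)
        else:
            carrier = _band_noise(n, sr, 2.0, 80.0, p["noise_seed"])
        # 100% sinusoidal modulation depth, starting at zero modulation phase
        env = 0.5 * (1.0 - np.cos(2 * np.pi * p["fm_hz"] * t))
        wave = carrier * env * _raised_cosine_ramp(n, sr)
        return _calibrate(wave, stim.level)

    if stim.category == "complex":
        wave = np.zeros(n)
        for comp in p["components"]:
            cw = _synth_component(comp, sr, stim.level)
            start = int(round(comp["onset_s"] * sr))
            seg = cw[: max(n - start, 0)]
            wave[start : start + len(seg)] += seg
        if p["direction"] == "reversed":
            wave = wave[::-1].copy()
        return _calibrate(wave, stim.level)

    if stim.category == "decomposition":
        if p["role"] == "component":
            comp = p["component"]
            m = int(round(stim.duration * sr))
            cw = _synth_component(comp, sr, stim.level)
            out = np.zeros(m)
            out[: min(len(cw), m)] = cw[:m]
            return out
        # reconstruction: sample-wise sum of its component waveforms at the
        # stored onsets (no recalibration, preserving the identity)
        if catalog is None:
            raise ValueError("reconstruction synthesis requires the catalog")
        wave = np.zeros(n)
        for sid, onset in p["component_onsets"]:
            comp_stim = catalog[sid]
            cw = synthesize(comp_stim)
            start = int(round(onset * sr))
            if start >= n:
                continue
            seg = cw[: n - start]
            wave[start : start + len(seg)] += seg
        wave *= 10.0 ** (p.get("level_offset_db", 0.0) / 20.0)
        if p.get("direction") == "reversed":
            wave = wave[::-1].copy()
        return wave

    raise ValueError(f"unknown category {stim.category!r}")


def write_wav(path, wave: np.ndarray, sample_rate: float) -> None:
    """Write a float32 WAV file (pressure samples, Pa)."""
    from scipy.io import wavfile

    wavfile.write(path, int(sample_rate), wave.astype(np.float32))
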