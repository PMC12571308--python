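"""Feature-level population tuning analyses on similarity matrices.

A similarity matrix summarizes how alike the population representations
of all sound pairs are; tuning analyses slice it along stimulus features:

* distance tuning curves — mean similarity versus feature distance
  (octaves of tone frequency, octaves of AM modulation frequency,
  octaves of noise bandwidth), the population analogue of a single-cell
  tuning curve width;
* matched-pair contrasts — similarity between sounds identical except
  for one feature (intensity, sweep/ramp direction, complex-sound
  identity or playback direction);
* summed-component comparisons — similarity between a compound sound's
  representation and the sum of its pure-tone components' representations,
  probing response linearity;
* salience profiles — normalized mean population response per category;
* region contrasts — paired Wilcoxon signed-rank tests between regions
  over identical pair sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .components import component_tone_ids
from .similarity import SimilarityMatrix, _split_halves, pearson, trial_vectors
from .preprocess import TrialTensor
from .stimuli import StimulusCatalog

__all__ = [
    "TuningCurve",
    "RegionContrast",
    "distance_tuning_curve",
    "contrast_similarity",
    "summed_component_similarity",
    "reconstruct_from_components",
    "salience_profile",
    "region_contrast",
    "CONTRASTS",
]

#: octave-distance snap tolerance for grouping grid distances
SNAP_OCTAVES = 0.05


@dataclass
class TuningCurve:
    """Mean similarity +/- SEM per feature-distance bin."""

    feature: str
    bins: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_pairs: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "feature": self.feature,
                "bin": self.bins,
                "mean": self.mean,
                "sem": self.sem,
                "n_pairs": self.n_pairs,
            }
        )


@dataclass
class RegionContrast:
    """Paired region comparison over identical sound-pair sets."""

    values_a: np.ndarray
    values_b: np.ndarray
    statistic: float
    p_value: float
    n_pairs: int


def _pair_values(matrix: SimilarityMatrix, pairs: list):
    vals = np.array([matrix[a, b] for a, b in pairs])
    ok = np.isfinite(vals)
    return vals[ok], [p for p, k in zip(pairs, ok) if k]


def _summarize(vals: np.ndarray):
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return mean, sem


# ---------------------------------------------------------------------------
# distance tuning curves
# ---------------------------------------------------------------------------


def _tone_pairs(catalog: StimulusCatalog, present: set):
    tones = [s for s in catalog.by_category("pure_tone") if s.sound_id in present]
    out = []
    for a, b in combinations(tones, 2):
        if a.level != b.level:
            continue
        d = abs(np.log2(a.params["freq_khz"]) - np.log2(b.params["freq_khz"]))
        out.append((a.sound_id, b.sound_id, d))
    return out


def _am_pairs(catalog: StimulusCatalog, present: set):
    ams = [s for s in catalog.by_category("am") if s.sound_id in present]
    out = []
    for a, b in combinations(ams, 2):
        if a.params["carrier_name"] != b.params["carrier_name"]:
            continue
        d = abs(np.log2(a.params["fm_hz"]) - np.log2(b.params["fm_hz"]))
        out.append((a.sound_id, b.sound_id, d))
    return out


def _bandwidth_pairs(catalog: StimulusCatalog, present: set):
    bands = [
        s
        for s in catalog.by_category("noise")
        if s.params.get("kind") == "band" and s.sound_id in present
    ]
    out = []
    for a, b in combinations(bands, 2):
        d = abs(a.params["bandwidth_octaves"] - b.params["bandwidth_octaves"])
        out.append((a.sound_id, b.sound_id, d))
    return out


_DISTANCE_FEATURES = {
    "tone_octave_distance": _tone_pairs,
    "am_logfreq_distance": _am_pairs,
    "noise_bandwidth_distance": _bandwidth_pairs,
}


def distance_tuning_curve(
    matrix: SimilarityMatrix,
    catalog: StimulusCatalog,
    feature: str,
    snap: float = SNAP_OCTAVES,
) -> TuningCurve:
    """Similarity versus feature distance, binned on the snapped grid.

    Grid distances are snapped to the nearest ``snap`` octave before
    grouping (floating-point grid arithmetic otherwise splits identical
    distances); each bin is labeled with the mean true distance of its
    pairs.  Undefined matrix entries are excluded.
    """
    if feature not in _DISTANCE_FEATURES:
        raise ValueError(f"unknown distance feature {feature!r}")
    present = set(matrix.sound_ids)
    pairs = _DISTANCE_FEATURES[feature](catalog, present)
    if not pairs:
        raise ValueError(f"no eligible pairs for feature {feature!r} in this matrix")
    groups: dict = {}
    for a, b, d in pairs:
        v = matrix[a, b]
        if not np.isfinite(v):
            continue
        key = round(d / snap)
        groups.setdefault(key, []).append((d, v))
    if not groups:
        raise ValueError(f"all pairs undefined for feature {feature!r}")
    keys = sorted(groups)
    bins, means, sems, ns = [], [], [], []
    for k in keys:
        ds, vs = zip(*groups[k])
        vs = np.asarray(vs)
        m, s = _summarize(vs)
        bins.append(float(np.mean(ds)))
        means.append(m)
        sems.append(s)
        ns.append(len(vs))
    return TuningCurve(
        feature=feature,
        bins=np.array(bins),
        mean=np.array(means),
        sem=np.array(sems),
        n_pairs=np.array(ns),
    )


# ---------------------------------------------------------------------------
# matched-pair contrasts
# ---------------------------------------------------------------------------


def _contrast_tone_intensity(catalog, present):
    """Same tone frequency, 50 vs 70 dB (14 pairs on the default catalog)."""
    tones = [s for s in catalog.by_category("pure_tone") if s.sound_id in present]
    by_freq: dict = {}
    for s in tones:
        by_freq.setdefault(s.params["freq_khz"], {})[s.level] = s.sound_id
    return [
        (d[50.0], d[70.0]) for f, d in sorted(by_freq.items()) if 50.0 in d and 70.0 in d
    ]


def _contrast_complex_intensity(catalog, present):
    """Same complex identity (forward), 50 vs 70 dB (15 pairs)."""
    cpx = [
        s
        for s in catalog.by_category("complex")
        if s.params["direction"] == "forward" and s.sound_id in present
    ]
    by_ident: dict = {}
    for s in cpx:
        by_ident.setdefault(s.params["identity"], {})[s.level] = s.sound_id
    return [
        (d[50.0], d[70.0]) for i, d in sorted(by_ident.items()) if 50.0 in d and 70.0 in d
    ]


def _contrast_complex_direction(catalog, present):
    """Forward vs time-reversed complex sound at 70 dB (15 pairs)."""
    cpx = [s for s in catalog.by_category("complex") if s.level == 70.0 and s.sound_id in present]
    by_ident: dict = {}
    for s in cpx:
        by_ident.setdefault(s.params["identity"], {})[s.params["direction"]] = s.sound_id
    return [
        (d["forward"], d["reversed"])
        for i, d in sorted(by_ident.items())
        if "forward" in d and "reversed" in d
    ]


def _contrast_complex_identity(catalog, present):
    """Different complex identities, forward at 70 dB (105 pairs)."""
    cpx = sorted(
        (
            s
            for s in catalog.by_category("complex")
            if s.level == 70.0 and s.params["direction"] == "forward" and s.sound_id in present
        ),
        key=lambda s: s.params["identity"],
    )
    return [(a.sound_id, b.sound_id) for a, b in combinations(cpx, 2)]


def _contrast_sweep_direction(catalog, present):
    """Time-symmetric up vs down 500-ms frequency sweeps (5 pairs)."""
    chirps = [
        s
        for s in catalog.by_category("chirp")
        if s.params["family"] == "range" and s.sound_id in present
    ]
    by_range: dict = {}
    for s in chirps:
        key = (s.params["f0_khz"], s.params["f1_khz"])
        by_range.setdefault(key, {})[s.params["direction"]] = s.sound_id
    return [
        (d["up"], d["down"]) for k, d in sorted(by_range.items()) if "up" in d and "down" in d
    ]


def _contrast_ramp_direction(catalog, present):
    """Up vs down intensity ramp at the same frequency (13 pairs)."""
    ramps = [s for s in catalog.by_category("ramp") if s.sound_id in present]
    by_freq: dict = {}
    for s in ramps:
        by_freq.setdefault(s.params["freq_khz"], {})[s.params["direction"]] = s.sound_id
    return [
        (d["up"], d["down"]) for f, d in sorted(by_freq.items()) if "up" in d and "down" in d
    ]


def _contrast_chord_within_pool(catalog, present):
    """All chord pairs built from the same frequency pool."""
    chords = [s for s in catalog.by_category("chord") if s.sound_id in present]
    by_pool: dict = {}
    for s in chords:
        by_pool.setdefault(s.params["pool"], []).append(s.sound_id)
    out = []
    for pool in sorted(by_pool):
        out.extend(combinations(sorted(by_pool[pool]), 2))
    return out


CONTRASTS = {
    "tone_intensity": _contrast_tone_intensity,
    "complex_intensity": _contrast_complex_intensity,
    "complex_direction": _contrast_complex_direction,
    "complex_identity": _contrast_complex_identity,
    "sweep_direction": _contrast_sweep_direction,
    "ramp_direction": _contrast_ramp_direction,
    "chord_within_pool": _contrast_chord_within_pool,
}


def contrast_pairs(catalog: StimulusCatalog, contrast: str, sound_ids=None) -> list:
    """Matched sound-id pairs for a named contrast (see :data:`CONTRASTS`)."""
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    present = set(sound_ids if sound_ids is not None else catalog.sound_ids)
    pairs = CONTRASTS[contrast](catalog, present)
    if not pairs:
        raise ValueError(f"contrast {contrast!r} matched zero pairs")
    return pairs


def contrast_similarity(
    matrix: SimilarityMatrix, catalog: StimulusCatalog, contrast: str
) -> dict:
    """Similarity values over a contrast's matched pairs, with mean +/- SEM."""
    pairs = contrast_pairs(catalog, contrast, matrix.sound_ids)
    vals, kept = _pair_values(matrix, pairs)
    if len(vals) == 0:
        raise ValueError(f"contrast {contrast!r}: all matched pairs undefined")
    mean, sem = _summarize(vals)
    return {
        "contrast": contrast,
        "pairs": kept,
        "values": vals,
        "mean": mean,
        "sem": sem,
        "n": len(vals),
        "n_matched": len(pairs),
    }


# ---------------------------------------------------------------------------
# summed-component (linearity) comparisons
# ---------------------------------------------------------------------------


def _half_average_sum(per_component, splits, code_is_spatial):
    """Sum of component half-average vectors, halves paired across components."""
    c = np.zeros(per_component[0].shape[1])
    d = np.zeros_like(c)
    for v, (h1, h2) in zip(per_component, splits):
        c += v[h1].mean(axis=0)
        d += v[h2].mean(axis=0)
    return c, d


def summed_component_similarity(
    tensor: TrialTensor,
    compound_sound,
    component_sounds=None,
    code: str = "spatial",
    n_resamples: int = 20,
    seed: int = 0,
    catalog: StimulusCatalog | None = None,
    durations: dict | None = None,
) -> float:
    """Noise-corrected similarity between a compound sound's representation
    and the summed representations of its components.

    Within each resample, every component's trials are half-split and the
    half-average vectors are summed element-wise across components (halves
    paired consistently); the split-half reliability of the summed
    construct comes from its own two half-vectors.  If
    ``component_sounds`` is omitted, components are resolved from the
    catalog's pure-tone grid.
    """
    if component_sounds is None:
        if catalog is None:
            raise ValueError("need component_sounds or a catalog to resolve them")
        component_sounds = component_tone_ids(catalog, compound_sound)
    if not component_sounds:
        raise ValueError("empty component list")
    missing = [c for c in component_sounds if c not in tensor.sound_ids]
    if missing:
        raise ValueError(f"components missing from tensor: {missing}")
    durations = durations or {}
    ic = (
        tensor.sound_ids.index(compound_sound)
        if isinstance(compound_sound, str)
        else int(compound_sound)
    )
    vc = trial_vectors(tensor, ic, code, durations.get(tensor.sound_ids[ic], 0.5))
    per_component = [
        trial_vectors(
            tensor,
            tensor.sound_ids.index(c),
            code,
            durations.get(c, 0.5),
        )
        for c in component_sounds
    ]
    rng = np.random.default_rng(seed)
    cross, rel_a, rel_s = [], [], []
    for _ in range(n_resamples):
        h1, h2 = _split_halves(len(vc), rng)
        a, b = vc[h1].mean(axis=0), vc[h2].mean(axis=0)
        splits = [_split_halves(len(v), rng) for v in per_component]
        c, d = _half_average_sum(per_component, splits, code == "spatial")
        terms = [pearson(a, c), pearson(a, d), pearson(b, c), pearson(b, d)]
        ra, rs = pearson(a, b), pearson(c, d)
        if np.any(np.isnan(terms)) or np.isnan(ra) or np.isnan(rs):
            continue
        cross.append(np.mean(terms))
        rel_a.append(ra)
        rel_s.append(rs)
    if not cross:
        return float("nan")
    mra, mrs = np.mean(rel_a), np.mean(rel_s)
    if mra <= 0 or mrs <= 0:
        return float("nan")
    return float(np.clip(np.mean(cross) / np.sqrt(mra * mrs), -1.0, 1.0))


def reconstruct_from_components(
    tensor: TrialTensor,
    complex_sound,
    components_with_onsets,
    code: str = "spatial",
    n_resamples: int = 20,
    seed: int = 0,
    durations: dict | None = None,
) -> float:
    """Similarity between a complex sound's representation and the response
    reconstructed from its components' responses shifted to their onsets.

    Each component's post-onset response time course is placed at its
    onset offset on the complex sound's bin grid (overlaps add); the
    spatial code time-averages after summation.  The comparison then runs
    as in :func:`summed_component_similarity`.
    """
    if not components_with_onsets:
        raise ValueError("empty component list")
    durations = durations or {}
    ic = (
        tensor.sound_ids.index(complex_sound)
        if isinstance(complex_sound, str)
        else int(complex_sound)
    )
    dur_c = durations.get(tensor.sound_ids[ic], 0.5)
    t = tensor.times
    window_mask = (t >= 0) & (t < dur_c + 0.1)
    n_win = int(window_mask.sum())
    onset_bin0 = int(np.argmax(window_mask))

    # per-component trial responses on the shifted common grid
    shifted = []
    for sid, onset in components_with_onsets:
        if sid not in tensor.sound_ids:
            raise ValueError(f"component {sid!r} missing from tensor")
        i = tensor.sound_ids.index(sid)
        dur_k = durations.get(sid, 0.5)
        mask_k = (t >= 0) & (t < dur_k + 0.1)
        v = tensor.values[:, i, :, :][:, :, mask_k]  # (U, R, Tk)
        shift = int(round(onset / tensor.bin_width))
        U, R, Tk = v.shape
        grid = np.zeros((U, R, n_win))
        hi = min(shift + Tk, n_win)
        if hi > shift >= 0:
            grid[:, :, shift:hi] = v[:, :, : hi - shift]
        shifted.append(grid)

    vc = trial_vectors(tensor, ic, code, dur_c)

    def code_vec(grid_half):  # (U, n_win) -> code vector
        if code == "spatial":
            return grid_half.mean(axis=-1)
        return grid_half.reshape(-1)

    rng = np.random.default_rng(seed)
    cross, rel_a, rel_s = [], [], []
    for _ in range(n_resamples):
        h1, h2 = _split_halves(vc.shape[0], rng)
        a, b = vc[h1].mean(axis=0), vc[h2].mean(axis=0)
        c = np.zeros(tensor.n_units if code == "spatial" else tensor.n_units * n_win)
        d = np.zeros_like(c)
        for grid in shifted:
            g1, g2 = _split_halves(grid.shape[1], rng)
            c += code_vec(grid[:, g1].mean(axis=1))
            d += code_vec(grid[:, g2].mean(axis=1))
        terms = [pearson(a, c), pearson(a, d), pearson(b, c), pearson(b, d)]
        ra, rs = pearson(a, b), pearson(c, d)
        if np.any(np.isnan(terms)) or np.isnan(ra) or np.isnan(rs):
            continue
        cross.append(np.mean(terms))
        rel_a.append(ra)
        rel_s.append(rs)
    if not cross:
        return float("nan")
    mra, mrs = np.mean(rel_a), np.mean(rel_s)
    if mra <= 0 or mrs <= 0:
        return float("nan")
    return float(np.clip(np.mean(cross) / np.sqrt(mra * mrs), -1.0, 1.0))


# ---------------------------------------------------------------------------
# salience and region statistics
# ---------------------------------------------------------------------------


def salience_profile(
    tensor: TrialTensor,
    catalog: StimulusCatalog,
    reference_category: str = "complex",
    reference_level: float = 70.0,
    durations: dict | None = None,
) -> dict:
    """Mean population response per category, doubly normalized.

    Each unit's trial- and window-averaged responses are divided by that
    unit's maximum across sounds (units with a nonpositive maximum are
    excluded); category means are then divided by the mean over the
    reference category at the reference level, which maps to 1.
    """
    durations = durations or {}
    S = tensor.n_sounds
    resp = np.stack(
        [
            trial_vectors(tensor, s, "spatial", durations.get(tensor.sound_ids[s], 0.5)).mean(
                axis=0
            )
            for s in range(S)
        ],
        axis=1,
    )  # (U, S)
    unit_max = resp.max(axis=1)
    keep = unit_max > 0
    n_excluded = int((~keep).sum())
    norm = resp[keep] / unit_max[keep, None]

    cats = {}
    ref_cols = []
    for s, sid in enumerate(tensor.sound_ids):
        stim = catalog[sid]
        cats.setdefault(stim.category, []).append(s)
        if stim.category == reference_category and stim.level == reference_level:
            ref_cols.append(s)
    if not ref_cols:
        raise ValueError(
            f"reference category {reference_category!r} at {reference_level} dB absent"
        )
    ref_mean = norm[:, ref_cols].mean()
    profile = {
        cat: float(norm[:, cols].mean() / ref_mean) for cat, cols in sorted(cats.items())
    }
    return {"profile": profile, "n_units": int(keep.sum()), "n_excluded": n_excluded}


def region_contrast(values_a, values_b) -> RegionContrast:
    """Paired Wilcoxon signed-rank test between two regions' similarity
    values over the identical sound-pair set.  Undefined entries are
    removed pairwise."""
    from scipy import stats

    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired value sets must share length")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 2:
        raise ValueError("need at least 2 defined pairs")
    diff = a - b
    if np.all(diff == 0):
        return RegionContrast(a, b, statistic=0.0, p_value=1.0, n_pairs=len(a))
    res = stats.wilcoxon(a, b, zero_method="zsplit")
    return RegionContrast(
        a, b, statistic=float(res.statistic), p_value=float(res.pvalue), n_pairs=len(a)
    )
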