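"""Noise-corrected Pearson similarity between population representations.

The raw Pearson correlation between trial-averaged population vectors is
biased toward 0 by trial-to-trial variability: residual noise in each
average inflates the denominator.  The split-half noise-corrected
estimator removes this attenuation.  For sounds ``s`` and ``s'`` the
trials of each sound are split into two random halves whose averages give
vectors ``a, b`` (sound s) and ``c, d`` (sound s').  Then

    rho_hat = mean[ r(a,c), r(a,d), r(b,c), r(b,d) ]
              / sqrt( r(a,b) * r(c,d) )

where ``r`` is the plain Pearson correlation.  The numerator's noise
attenuation is exactly the geometric mean of the two split-half
reliabilities in the denominator, so the ratio is asymptotically unbiased
as the number of units grows.  Splits are redrawn ``n_resamples`` times
(default 20); cross terms and reliabilities are averaged separately
across resamples before taking the ratio, which is more stable than
averaging per-resample ratios.  Estimates are clipped to [-1, 1]; when a
mean reliability is not positive the value is undefined (marked NaN and
excluded from downstream averages) rather than clipped, since clipping a
noise-dominated ratio would fabricate +/-1.

Two population codes are supported: ``spatial`` (time-averaged response
per unit, dimension N_units) and ``spatiotemporal`` (all time bins
concatenated, dimension N_units x N_bins).  Both use the window from
sound onset to 100 ms after sound offset; spatio-temporal vectors are
binned at 5 ms (ephys) or 43.5 ms (imaging).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import TrialTensor, _rebin

__all__ = [
    "pearson",
    "noise_corrected_similarity",
    "naive_similarity",
    "rsa_matrix",
    "mean_similarity",
    "SimilarityMatrix",
    "trial_vectors",
]

#: spatio-temporal bin width per modality (s)
ST_BIN = {"ephys": 0.005, "imaging": 0.0435}

#: analysis window extends this far past sound offset (s)
POST_OFFSET = 0.1


def pearson(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation; NaN (undefined) if either vector has zero variance."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must share length")
    if u.size < 2:
        raise ValueError("vectors must have length >= 2")
    uc = u - u.mean()
    vc = v - v.mean()
    nu = np.sqrt(uc @ uc)
    nv = np.sqrt(vc @ vc)
    if nu == 0 or nv == 0:
        return float("nan")
    return float(np.clip((uc @ vc) / (nu * nv), -1.0, 1.0))


def _window_mask(tensor: TrialTensor, duration: float) -> np.ndarray:
    t = tensor.times
    return (t >= 0) & (t < duration + POST_OFFSET)


def trial_vectors(
    tensor: TrialTensor,
    sound_index: int,
    code: str = "spatial",
    duration: float = 0.5,
) -> np.ndarray:
    """Per-trial population vectors for one sound, shape (R, D).

    ``spatial``: each unit's response time-averaged over the analysis
    window (sound onset to 100 ms after offset).  ``spatiotemporal``:
    window bins at the modality's spatio-temporal bin width, concatenated
    across units.
    """
    mask = _window_mask(tensor, duration)
    v = tensor.values[:, sound_index, :, :][:, :, mask]  # (U, R, T)
    if code == "spatial":
        return v.mean(axis=-1).T  # (R, U)
    if code == "spatiotemporal":
        v = _rebin(v, tensor.bin_width, ST_BIN[tensor.modality])
        U, R, T = v.shape
        return v.transpose(1, 0, 2).reshape(R, U * T)
    raise ValueError(f"unknown code {code!r}")


def _split_halves(R: int, rng: np.random.Generator):
    """Random partition of R trials into two halves (odd: extra trial
    randomly assigned)."""
    perm = rng.permutation(R)
    half = R // 2 + (rng.integers(2) if R % 2 else 0)
    return perm[:half], perm[half:]


def noise_corrected_similarity(
    tensor: TrialTensor,
    sound_a,
    sound_b,
    code: str = "spatial",
    n_resamples: int = 20,
    seed: int = 0,
    durations: dict | None = None,
) -> float:
    """Noise-corrected similarity between two sounds' representations.

    ``sound_a``/``sound_b`` are sound ids or indices.  Requires at least
    4 trials.  Returns NaN (undefined) when the representations are noise
    dominated (mean split-half reliability <= 0).
    """
    ia = tensor.sound_ids.index(sound_a) if isinstance(sound_a, str) else int(sound_a)
    ib = tensor.sound_ids.index(sound_b) if isinstance(sound_b, str) else int(sound_b)
    if tensor.n_trials < 4:
        raise ValueError("need at least 4 trials for split-half estimation")
    durations = durations or {}
    va = trial_vectors(tensor, ia, code, durations.get(tensor.sound_ids[ia], 0.5))
    vb = trial_vectors(tensor, ib, code, durations.get(tensor.sound_ids[ib], 0.5))
    rng = np.random.default_rng(seed)
    cross, rel_a, rel_b = [], [], []
    for _ in range(n_resamples):
        ha1, ha2 = _split_halves(len(va), rng)
        hb1, hb2 = _split_halves(len(vb), rng)
        a, b = va[ha1].mean(axis=0), va[ha2].mean(axis=0)
        c, d = vb[hb1].mean(axis=0), vb[hb2].mean(axis=0)
        terms = [pearson(a, c), pearson(a, d), pearson(b, c), pearson(b, d)]
        ra, rb = pearson(a, b), pearson(c, d)
        # zero-variance half-averages invalidate this resample's terms
        if np.any(np.isnan(terms)) or np.isnan(ra) or np.isnan(rb):
            continue
        cross.append(np.mean(terms))
        rel_a.append(ra)
        rel_b.append(rb)
    if not cross:
        return float("nan")
    mean_rel_a, mean_rel_b = np.mean(rel_a), np.mean(rel_b)
    if mean_rel_a <= 0 or mean_rel_b <= 0:
        return float("nan")
    est = np.mean(cross) / np.sqrt(mean_rel_a * mean_rel_b)
    return float(np.clip(est, -1.0, 1.0))


def naive_similarity(
    tensor: TrialTensor,
    sound_a,
    sound_b,
    code: str = "spatial",
    durations: dict | None = None,
) -> float:
    """Plain Pearson correlation of trial-averaged vectors (no noise correction)."""
    ia = tensor.sound_ids.index(sound_a) if isinstance(sound_a, str) else int(sound_a)
    ib = tensor.sound_ids.index(sound_b) if isinstance(sound_b, str) else int(sound_b)
    durations = durations or {}
    va = trial_vectors(tensor, ia, code, durations.get(tensor.sound_ids[ia], 0.5))
    vb = trial_vectors(tensor, ib, code, durations.get(tensor.sound_ids[ib], 0.5))
    return pearson(va.mean(axis=0), vb.mean(axis=0))


@dataclass
class SimilarityMatrix:
    """Symmetric sounds x sounds noise-corrected similarity matrix.

    Undefined entries (noise-dominated representations) are NaN; the
    ``defined`` property masks them.
    """

    values: np.ndarray
    sound_ids: list
    code: str = "spatial"
    n_resamples: int = 20
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("finite similarities must lie in [-1, 1]")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)

    def __getitem__(self, pair):
        a, b = pair
        ia = self.sound_ids.index(a) if isinstance(a, str) else a
        ib = self.sound_ids.index(b) if isinstance(b, str) else b
        return self.values[ia, ib]

    def submatrix(self, sound_ids: list) -> "SimilarityMatrix":
        idx = [self.sound_ids.index(s) for s in sound_ids]
        return SimilarityMatrix(
            values=self.values[np.ix_(idx, idx)],
            sound_ids=list(sound_ids),
            code=self.code,
            n_resamples=self.n_resamples,
            seed=self.seed,
            meta=dict(self.meta),
        )

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            h5.create_dataset("values", data=self.values)
            h5.create_dataset(
                "sound_ids", data=np.array(self.sound_ids, dtype=h5py.string_dtype())
            )
            h5.attrs["code"] = self.code
            h5.attrs["n_resamples"] = self.n_resamples
            h5.attrs["seed"] = self.seed
            for k, v in self.meta.items():
                h5.attrs[f"meta_{k}"] = v

    @classmethod
    def load(cls, path) -> "SimilarityMatrix":
        import h5py

        with h5py.File(path, "r") as h5:
            meta = {
                k[5:]: h5.attrs[k] for k in h5.attrs if k.startswith("meta_")
            }
            return cls(
                values=h5["values"][...],
                sound_ids=[s.decode() for s in h5["sound_ids"][...]],
                code=str(h5.attrs["code"]),
                n_resamples=int(h5.attrs["n_resamples"]),
                seed=int(h5.attrs["seed"]),
                meta=meta,
            )

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.sound_ids, columns=self.sound_ids).to_csv(path)


def _standardize_rows(M: np.ndarray):
    """Row-center and row-normalize; returns (standardized, valid mask)."""
    c = M - M.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(c, axis=1)
    valid = norms > 0
    c[valid] /= norms[valid, None]
    c[~valid] = 0.0
    return c, valid


def rsa_matrix(
    tensor: TrialTensor,
    code: str = "spatial",
    n_resamples: int = 20,
    seed: int = 0,
    durations: dict | None = None,
    sound_ids: list | None = None,
) -> SimilarityMatrix:
    """Full noise-corrected similarity matrix over all sound pairs.

    Per resample, two independent half-splits are drawn for every sound
    (one used in the row role, one in the column role), the half-average
    vectors are row-standardized, and all pairwise cross-half correlations
    are obtained as matrix products.  Cross terms and reliabilities are
    averaged across resamples separately, the matrix is symmetrized, and
    the ratio is clipped to [-1, 1].  Diagonal entries compare two
    independent splits of the same trials, so they approach 1 within
    resampling noise for reliable populations.
    """
    durations = durations or {}
    if sound_ids is None:
        sound_ids = list(tensor.sound_ids)
    idx = [tensor.sound_ids.index(s) for s in sound_ids]
    S = len(idx)
    per_sound = [
        trial_vectors(tensor, i, code, durations.get(tensor.sound_ids[i], 0.5)) for i in idx
    ]
    D = per_sound[0].shape[1]
    rng = np.random.default_rng(seed)

    cross_sum = np.zeros((S, S))
    cross_n = np.zeros((S, S))
    rel_sum = np.zeros(S)
    rel_n = np.zeros(S)

    for _ in range(n_resamples):
        A1 = np.empty((S, D))
        A2 = np.empty((S, D))
        B1 = np.empty((S, D))
        B2 = np.empty((S, D))
        for s, v in enumerate(per_sound):
            h1, h2 = _split_halves(len(v), rng)
            A1[s], A2[s] = v[h1].mean(axis=0), v[h2].mean(axis=0)
            h1, h2 = _split_halves(len(v), rng)
            B1[s], B2[s] = v[h1].mean(axis=0), v[h2].mean(axis=0)
        a1, va1 = _standardize_rows(A1)
        a2, va2 = _standardize_rows(A2)
        b1, vb1 = _standardize_rows(B1)
        b2, vb2 = _standardize_rows(B2)
        ok_a = va1 & va2
        ok_b = vb1 & vb2
        cross = 0.25 * (a1 @ b1.T + a1 @ b2.T + a2 @ b1.T + a2 @ b2.T)
        ok = np.outer(ok_a, ok_b)
        cross_sum += np.where(ok, cross, 0.0)
        cross_n += ok
        rel_res = np.einsum("sd,sd->s", a1, a2) + np.einsum("sd,sd->s", b1, b2)
        rel_cnt = ok_a.astype(float) + ok_b.astype(float)
        rel_sum += np.where(rel_cnt > 0, rel_res, 0.0)
        rel_n += rel_cnt

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_cross = np.where(cross_n > 0, cross_sum / np.maximum(cross_n, 1), np.nan)
        mean_rel = np.where(rel_n > 0, rel_sum / np.maximum(rel_n, 1), np.nan)
    mean_cross = 0.5 * (mean_cross + mean_cross.T)  # symmetrize
    denom = np.sqrt(np.outer(mean_rel, mean_rel))
    bad = ~(mean_rel > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        est = mean_cross / denom
    est[bad, :] = np.nan
    est[:, bad] = np.nan
    est = np.clip(est, -1.0, 1.0)
    return SimilarityMatrix(
        values=est,
        sound_ids=list(sound_ids),
        code=code,
        n_resamples=n_resamples,
        seed=seed,
        meta={"combination": "ratio_of_averages", "undefined_policy": "nan_excluded"},
    )


def mean_similarity(matrix: SimilarityMatrix, pair_subset=None):
    """Mean +/- SEM of similarity over unordered off-diagonal pairs.

    ``pair_subset``: optional iterable of (sound_id, sound_id) pairs;
    defaults to all off-diagonal pairs.  Undefined entries are excluded;
    returns ``(mean, sem, n)``.
    """
    if pair_subset is None:
        iu, ju = np.triu_indices(len(matrix.sound_ids), k=1)
        vals = matrix.values[iu, ju]
    else:
        pairs = list(pair_subset)
        if not pairs:
            raise ValueError("empty pair subset")
        vals = np.array([matrix[a, b] for a, b in pairs])
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no defined pairs to average")
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return mean, sem, int(vals.size)
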