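"""In-vivo style surface maps: myelin index and tonotopy by fMRI encoding.

The myelin index is the T1w/T2*w ratio within cortical gray matter, with
vessel-like extreme values removed by an adaptive upper-percentile threshold
and the survivors rescaled to [0, 100].

Tonotopy follows a linearized encoding approach: band energies of the sound
set (128 logarithmically spaced band-pass filters) are regressed onto each
vertex's sound responses with ridge regression; the center frequency of the
largest fitted weight defines the vertex's frequency preference.  Responses
are estimated per cross-validation fold with a two-step GLM: a 9-sample FIR
deconvolution yields each vertex's hemodynamic response on the training runs,
then per-sound betas are estimated with that response, separately for
training and test runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .volume import ScalarVolume

__all__ = [
    "adaptive_percentile_threshold",
    "myelin_index",
    "filterbank_centers",
    "cochlear_features",
    "estimate_hrf",
    "sound_responses",
    "noise_regressors",
    "EncodingModel",
    "ridge_encoding",
    "best_frequency_map",
]


# ---------------------------------------------------------------------------
# myelin

def adaptive_percentile_threshold(
    values: np.ndarray,
    p_start: float = 90.0,
    p_stop: float = 99.9,
    p_step: float = 0.1,
    c: float = 2.0,
    decel_run: int = 3,
    smooth_window: int = 5,
) -> float:
    """Upper cut-off from iterative deceleration of percentile differences.

    Scans upper percentiles p and their increments ``delta(p) = value(p+step)
    - value(p)``; the increments are moving-average smoothed (window
    `smooth_window`) because raw order-statistic gaps are negatively
    autocorrelated and would never show a sustained trend.  After the
    smoothed increments have decreased for `decel_run` consecutive steps,
    the first p with ``delta(p) < c * median(delta)`` defines the cut.
    Falls back to the last scanned percentile if the rule never fires.
    """
    ps = np.arange(p_start, p_stop + 1e-9, p_step)
    vals = np.percentile(values, ps)
    deltas = np.diff(vals)
    if smooth_window > 1 and len(deltas) >= smooth_window:
        kernel = np.ones(smooth_window) / smooth_window
        deltas = np.convolve(deltas, kernel, mode="same")
    med = np.median(deltas)
    run = 0
    for i in range(1, len(deltas)):
        run = run + 1 if deltas[i] <= deltas[i - 1] else 0
        if run >= decel_run and deltas[i] < c * med:
            return float(vals[i])
    return float(vals[-1])


def myelin_index(
    t1w: ScalarVolume,
    t2sw: ScalarVolume,
    gm_mask: ScalarVolume,
    threshold_kwargs: dict | None = None,
) -> ScalarVolume:
    """T1w/T2*w ratio in gray matter, outlier-trimmed and rescaled to [0, 100].

    Zeros in the T2*w image are excluded (count reported in a warning); voxels
    above the adaptive percentile threshold are removed; surviving values are
    min-max rescaled, which preserves their rank order.  Excluded voxels are
    returned as NaN.
    """
    if t1w.shape != t2sw.shape or t1w.shape != gm_mask.shape:
        raise ValueError("volumes are not co-registered (shape mismatch)")
    mask = gm_mask.data.astype(bool)
    if not mask.any():
        raise ValueError("empty gray matter mask")
    zeros = mask & (t2sw.data == 0)
    if zeros.any():
        warnings.warn(f"excluding {int(zeros.sum())} voxel(s) with zero T2*w signal")
        mask = mask & ~zeros
    ratio = np.full(t1w.shape, np.nan)
    ratio[mask] = t1w.data[mask] / t2sw.data[mask]
    vals = ratio[mask]
    if np.ptp(vals) == 0:
        warnings.warn("constant T1w/T2*w ratio: degenerate rescaling, all values set to 0")
        out = np.full(t1w.shape, np.nan)
        out[mask] = 0.0
        return t1w.with_data(out)
    cut = adaptive_percentile_threshold(vals, **(threshold_kwargs or {}))
    keep = mask & (ratio <= cut)
    if not keep.any():
        raise ValueError("no voxels survive the adaptive threshold")
    kept = ratio[keep]
    lo, hi = kept.min(), kept.max()
    out = np.full(t1w.shape, np.nan)
    if hi > lo:
        out[keep] = 100.0 * (ratio[keep] - lo) / (hi - lo)
    else:
        warnings.warn("degenerate post-threshold range: all values set to 0")
        out[keep] = 0.0
    return t1w.with_data(out)


# ---------------------------------------------------------------------------
# cochlear-like filterbank

def filterbank_centers(n_bands: int = 128, fmin: float = 180.0, fmax: float = 8000.0) -> np.ndarray:
    """Logarithmically spaced band center frequencies (Hz)."""
    return np.geomspace(fmin, fmax, n_bands)


def cochlear_features(
    sounds: list,
    fs: float,
    n_bands: int = 128,
    fmin: float = 180.0,
    fmax: float = 8000.0,
    order: int = 2,
    normalize: bool = True,
) -> np.ndarray:
    """Band energies of each sound through a log-spaced Butterworth filterbank.

    Band edges are the geometric means between neighboring centers
    (constant-Q); energy is the mean squared filter output, divided by the
    band's relative bandwidth when `normalize` is set (level normalization:
    white noise then gives flat band energies).  Silence yields a zero row.
    """
    if not (0 < fmin < fmax < fs / 2):
        raise ValueError("need 0 < fmin < fmax < Nyquist")
    centers = filterbank_centers(n_bands, fmin, fmax)
    ratio = centers[1] / centers[0]
    lo = centers / np.sqrt(ratio)
    hi = centers * np.sqrt(ratio)
    sos = [signal.butter(order, [l, h], btype="band", fs=fs, output="sos")
           for l, h in zip(lo, hi)]
    feats = np.zeros((len(sounds), n_bands))
    for i, snd in enumerate(sounds):
        x = np.asarray(snd, dtype=float)
        if x.ndim == 2:  # average channels
            x = x.mean(axis=1)
        if not x.any():
            continue
        for b in range(n_bands):
            y = signal.sosfilt(sos[b], x)
            e = float(np.mean(y ** 2))
            if normalize:
                e /= hi[b] - lo[b]  # energy per Hz: white noise comes out flat
            feats[i, b] = e
    return feats


# ---------------------------------------------------------------------------
# response estimation

def _fir_design(n_time: int, onset_vols, n_sticks: int) -> np.ndarray:
    X = np.zeros((n_time, n_sticks))
    for o in onset_vols:
        for k in range(n_sticks):
            if o + k < n_time:
                X[o + k, k] += 1.0
    return X


def _check_rank(X: np.ndarray, what: str) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        s = np.linalg.svd(X, compute_uv=False)
        bad = np.flatnonzero(s < s[0] * 1e-10) if len(s) else []
        raise ValueError(
            f"{what} design is rank deficient (rank {rank} < {X.shape[1]} columns; "
            f"near-null singular values at {list(bad)})")


def estimate_hrf(
    series: np.ndarray,
    onset_vols,
    n_sticks: int = 9,
    nuisance: np.ndarray | None = None,
) -> np.ndarray:
    """FIR deconvolution of the hemodynamic response (9 post-onset samples).

    `series` is time x vertices; all sounds share the FIR columns, so the
    estimate is each vertex's mean event response.  Exact on noiseless data
    with a full-rank design.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if series.shape[0] == 1:
        series = series.T
    X = _fir_design(len(series), onset_vols, n_sticks)
    cols = [X, np.ones((len(series), 1))]
    if nuisance is not None:
        cols.append(np.asarray(nuisance, dtype=float))
    Xf = np.hstack(cols)
    _check_rank(Xf, "FIR")
    beta, *_ = np.linalg.lstsq(Xf, series, rcond=None)
    return beta[:n_sticks]


def sound_responses(
    series: np.ndarray,
    hrf: np.ndarray,
    onsets,
    n_sounds: int,
    nuisance: np.ndarray | None = None,
) -> np.ndarray:
    """Per-sound response amplitudes with a per-vertex hemodynamic response.

    ``hrf`` is (n_sticks, n_vertices); each sound's predictor is its onset
    indicator convolved with the vertex's response, so the GLM is solved per
    vertex.  Returns betas (n_sounds, n_vertices).
    """
    series = np.asarray(series, dtype=float)
    hrf = np.atleast_2d(np.asarray(hrf, dtype=float))
    n_time, n_vert = series.shape
    n_sticks = hrf.shape[0]
    stick = np.zeros((n_time, n_sounds))
    for o, snd in onsets:
        stick[o, snd] += 1.0
    extra = [np.ones((n_time, 1))]
    if nuisance is not None:
        extra.append(np.asarray(nuisance, dtype=float))
    extra = np.hstack(extra)
    betas = np.zeros((n_sounds, n_vert))
    present = np.flatnonzero(stick.any(axis=0))
    kernel = np.zeros(n_sticks)
    for v in range(n_vert):
        kernel[:] = hrf[:, v]
        conv = signal.fftconvolve(stick[:, present], kernel[:, None], axes=0)[:n_time]
        X = np.hstack([conv, extra])
        if v == 0:
            _check_rank(X, "sound-response")
        b, *_ = np.linalg.lstsq(X, series[:, v], rcond=None)
        betas[present, v] = b[: len(present)]
    return betas


def noise_regressors(residuals: np.ndarray, k: int = 5) -> np.ndarray:
    """Top-k principal components of training-run residuals (time x k)."""
    r = residuals - residuals.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(r, full_matrices=False)
    return u[:, :k] * s[:k]


# ---------------------------------------------------------------------------
# ridge encoding

@dataclass
class EncodingModel:
    weights: np.ndarray               # bands x vertices
    penalties: np.ndarray             # chosen lambda per vertex
    best_band: np.ndarray             # argmax-weight band per vertex
    best_frequency: np.ndarray        # its center frequency (Hz)
    accuracy: np.ndarray              # mean test correlation per vertex


def _ridge_path(X: np.ndarray, Y: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Ridge solutions for every penalty via one SVD; (n_lambda, p, v)."""
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    UtY = U.T @ Y
    out = np.empty((len(lambdas), X.shape[1], Y.shape[1]))
    for i, lam in enumerate(lambdas):
        d = s / (s ** 2 + lam)
        out[i] = Vt.T @ (d[:, None] * UtY)
    return out


def ridge_encoding(
    features: np.ndarray,
    train_responses: list,
    test_responses: list,
    train_idx: list,
    test_idx: list,
    penalties=None,
    fmin: float = 180.0,
    fmax: float = 8000.0,
) -> EncodingModel:
    """Linearized encoding: ridge-fit band energies to responses per vertex.

    One (train_responses, test_responses, train_idx, test_idx) entry per
    cross-validation fold.  Features are standardized on the training sounds
    of each fold only.  The penalty is chosen per vertex by the test-fold
    prediction correlation averaged over folds (ties to the smaller penalty);
    final weights are the mean over folds of the training fits at the chosen
    penalty.  The best frequency is the center frequency of the largest
    weight (ties to the lowest band).
    """
    if penalties is None:
        penalties = np.logspace(-2, 4, 13)
    penalties = np.asarray(penalties, dtype=float)
    if penalties.size == 0:
        raise ValueError("empty penalty grid")
    features = np.asarray(features, dtype=float)
    n_folds = len(train_responses)
    n_bands = features.shape[1]
    n_vert = np.asarray(train_responses[0]).shape[1]
    acc = np.zeros((len(penalties), n_vert))
    fold_weights = np.zeros((n_folds, len(penalties), n_bands, n_vert))
    for f in range(n_folds):
        Xtr = features[np.asarray(train_idx[f])]
        Xte = features[np.asarray(test_idx[f])]
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xtr = (Xtr - mu) / sd
        Xte = (Xte - mu) / sd
        Ytr = np.asarray(train_responses[f], dtype=float)
        Yte = np.asarray(test_responses[f], dtype=float)
        W = _ridge_path(Xtr, Ytr - Ytr.mean(axis=0, keepdims=True), penalties)
        fold_weights[f] = W
        for i in range(len(penalties)):
            pred = Xte @ W[i]
            pc = pred - pred.mean(axis=0, keepdims=True)
            yc = Yte - Yte.mean(axis=0, keepdims=True)
            denom = np.sqrt((pc ** 2).sum(axis=0) * (yc ** 2).sum(axis=0))
            r = np.where(denom > 0, (pc * yc).sum(axis=0) / np.where(denom > 0, denom, 1.0), 0.0)
            acc[i] += r / n_folds
    best_pen = acc.argmax(axis=0)            # argmax returns first (smallest lambda) on ties
    weights = fold_weights.mean(axis=0)[best_pen, :, np.arange(n_vert)].T
    best_band = weights.argmax(axis=0)       # ties -> lowest band
    centers = filterbank_centers(n_bands, fmin, fmax)
    return EncodingModel(
        weights=weights,
        penalties=penalties[best_pen],
        best_band=best_band,
        best_frequency=centers[best_band],
        accuracy=acc[best_pen, np.arange(n_vert)],
    )


def best_frequency_map(model: EncodingModel, warp=None, mesh=None) -> np.ndarray:
    """Per-vertex preferred frequency, optionally transported through a warp."""
    bf = model.best_frequency
    if warp is not None:
        from .align import apply_warp
        bf = apply_warp(bf, warp, mesh)
    return bf


def plot_tonotopy(values: np.ndarray, ax=None):
    """Scatter/map helper: red (low frequency) to blue (high frequency)."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    sc = ax.scatter(np.arange(len(values)), values,
                    c=np.log(values), cmap="RdBu", s=8)
    ax.set_ylabel("best frequency (Hz)")
    ax.set_yscale("log")
    return sc
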