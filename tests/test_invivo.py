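"""Myelin-index construction and the tonotopy encoding chain."""

import numpy as np
import pytest

from temporalign import invivo as iv
from temporalign import synthdata as sd
from temporalign.volume import ScalarVolume, binary_mask


def _vol(data):
    return ScalarVolume(np.asarray(data, dtype=float))


class TestMyelinIndex:
    def _mask(self, shape):
        return binary_mask(np.ones(shape, bool))

    def test_constant_ratio_maps_to_zero_with_warning(self):
        t2 = _vol(np.full((4, 4, 4), 2.0))
        t1 = _vol(np.full((4, 4, 4), 4.0))
        with pytest.warns(UserWarning, match="constant"):
            out = iv.myelin_index(t1, t2, self._mask((4, 4, 4)))
        assert np.nanmax(np.abs(out.data)) == 0.0

    def test_minmax_rescaling_formula(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        t1 = _vol(np.tile(vals, (4, 4, 1)))
        t2 = _vol(np.ones((4, 4, 4)))
        out = iv.myelin_index(t1, t2, self._mask((4, 4, 4)),
                              threshold_kwargs={"p_stop": 99.9})
        got = np.unique(out.data[np.isfinite(out.data)])
        assert np.allclose(sorted(got), [0.0, 100 / 3, 200 / 3, 100.0], atol=0.01)

    def test_bounds_and_rank_order_with_planted_outliers(self):
        rng = np.random.default_rng(0)
        shape = (12, 12, 12)
        ratio = rng.uniform(1.0, 2.0, size=shape)
        flat = ratio.ravel()
        n_out = int(0.01 * flat.size)
        out_idx = rng.choice(flat.size, n_out, replace=False)
        flat[out_idx] *= 10.0  # vessel-like outliers
        t1 = _vol(flat.reshape(shape))
        t2 = _vol(np.ones(shape))
        out = iv.myelin_index(t1, t2, self._mask(shape))
        finite = np.isfinite(out.data)
        assert np.nanmin(out.data[finite]) >= 0.0
        assert np.nanmax(out.data[finite]) <= 100.0
        # planted outliers are all excluded
        assert not finite.ravel()[out_idx].any()
        # rank order preserved among survivors (monotone rescaling)
        surv_in = t1.data[finite]
        surv_out = out.data[finite]
        order = np.argsort(surv_in)
        assert (np.diff(surv_out[order]) >= 0).all()

    def test_zero_t2_voxels_excluded_with_count(self):
        t1 = _vol(np.ones((4, 4, 4)))
        t2d = np.ones((4, 4, 4))
        t2d[0, 0, 0] = 0.0
        with pytest.warns(UserWarning, match="1 voxel"):
            out = iv.myelin_index(t1, _vol(t2d), self._mask((4, 4, 4)))
        assert not np.isfinite(out.data[0, 0, 0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="co-registered"):
            iv.myelin_index(_vol(np.ones((4, 4, 4))), _vol(np.ones((5, 4, 4))),
                            self._mask((4, 4, 4)))


class TestCochlearFeatures:
    def test_pure_tone_peaks_at_its_band(self):
        centers = iv.filterbank_centers(128, 180, 8000)
        for k in (5, 64, 120):
            sounds, fs = sd.make_tone_sounds([centers[k]])
            feats = iv.cochlear_features(sounds, fs)
            assert feats[0].argmax() == k

    def test_silence_gives_zero_row(self):
        feats = iv.cochlear_features([np.zeros(4000)], 22050)
        assert (feats == 0).all()

    def test_white_noise_bands_flat_after_normalization(self):
        rng = np.random.default_rng(42)
        noise = rng.normal(size=220500)  # 10 s for stable band estimates
        feats = iv.cochlear_features([noise], 22050)[0]
        mid = feats[10:-10]  # edge bands clipped by the sampling band limits
        assert mid.max() / mid.min() < 1.2 / 0.8

    def test_invalid_band_range_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            iv.cochlear_features([np.zeros(100)], 16000, fmax=9000)


class TestEstimateHrf:
    def test_exact_recovery_isolated_events(self):
        kernel = np.array([0, 0.4, 1.0, 0.7, 0.3, 0.1, 0.0, -0.1, -0.05])
        series = np.zeros(200)
        onsets = [10, 40, 90, 150]
        for o in onsets:
            series[o:o + 9] += kernel
        est = iv.estimate_hrf(series, onsets)
        assert np.abs(est[:, 0] - kernel).max() < 1e-8

    def test_zero_series_gives_zero_hrf(self):
        est = iv.estimate_hrf(np.zeros((100, 3)), [5, 30, 60])
        assert np.allclose(est, 0.0)

    def test_overlapping_events_recovered(self):
        kernel = sd.canonical_hrf()
        rng = np.random.default_rng(1)
        onsets = sorted(rng.choice(np.arange(5, 180), size=30, replace=False).tolist())
        series = np.zeros(200)
        for o in onsets:
            end = min(o + 9, 200)
            series[o:end] += kernel[: end - o]
        est = iv.estimate_hrf(series, onsets)
        assert np.abs(est[:, 0] - kernel).max() < 1e-6

    def test_rank_deficiency_reported(self):
        with pytest.raises(ValueError, match="rank deficient"):
            # all onsets identical -> duplicate columns after the first
            iv.estimate_hrf(np.zeros(20), [])


class TestSoundResponses:
    def _setup(self, seed=2, noise=False):
        rng = np.random.default_rng(seed)
        n_sounds, n_vert, T = 10, 4, 160
        hrf = np.tile(sd.canonical_hrf()[:, None], (1, n_vert))
        betas = rng.normal(size=(n_sounds, n_vert))
        onsets = [(5 + 15 * i, i) for i in range(n_sounds)]
        series = np.zeros((T, n_vert))
        for o, snd in onsets:
            series[o:o + 9] += sd.canonical_hrf()[:, None] * betas[snd]
        return series, hrf, onsets, betas

    def test_forward_model_betas_recovered(self):
        series, hrf, onsets, betas = self._setup()
        est = iv.sound_responses(series, hrf, onsets, 10)
        assert np.abs(est - betas).max() < 1e-6

    def test_zero_series_gives_zero_betas(self):
        _, hrf, onsets, _ = self._setup()
        est = iv.sound_responses(np.zeros((160, 4)), hrf, onsets, 10)
        assert np.allclose(est, 0.0)

    def test_orthogonal_nuisance_leaves_betas_unchanged(self):
        series, hrf, onsets, betas = self._setup()
        est0 = iv.sound_responses(series, hrf, onsets, 10)
        # build a nuisance column orthogonal to every predictor column
        stick = np.zeros((160, 10))
        for o, snd in onsets:
            stick[o, snd] = 1.0
        from scipy.signal import fftconvolve

        X = np.hstack([
            fftconvolve(stick, sd.canonical_hrf()[:, None])[:160],
            np.ones((160, 1)),
        ])
        rng = np.random.default_rng(3)
        nuis = rng.normal(size=160)
        nuis -= X @ np.linalg.lstsq(X, nuis, rcond=None)[0]
        est1 = iv.sound_responses(series, hrf, onsets, 10, nuisance=nuis[:, None])
        assert np.abs(est0 - est1).max() < 1e-8


class TestRidgeEncoding:
    def _folds(self, features, betas, rng):
        n = len(features)
        idx = rng.permutation(n)
        folds = np.array_split(idx, 4)
        tr_r, te_r, tr_i, te_i = [], [], [], []
        for f in range(4):
            test = np.sort(folds[f])
            train = np.sort(np.concatenate([folds[g] for g in range(4) if g != f]))
            tr_r.append(betas[train])
            te_r.append(betas[test])
            tr_i.append(train)
            te_i.append(test)
        return tr_r, te_r, tr_i, te_i

    def test_zero_penalty_matches_ols_and_sklearn(self):
        from sklearn.linear_model import Ridge

        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 10))
        W = rng.normal(size=(10, 3))
        Y = X @ W
        model = iv.ridge_encoding(X, *self._folds(X, Y, rng), penalties=[1e-12],
                                  fmin=100, fmax=1000)
        # reproduce one fold by hand with sklearn
        tr_r, te_r, tr_i, te_i = self._folds(X, Y, np.random.default_rng(4))
        Xtr = X[tr_i[0]]
        mu, sdv = Xtr.mean(0), Xtr.std(0)
        Xs = (Xtr - mu) / sdv
        Ytr = tr_r[0] - tr_r[0].mean(0)
        sk = Ridge(alpha=1e-12, fit_intercept=False).fit(Xs, Ytr)
        ols = np.linalg.lstsq(Xs, Ytr, rcond=None)[0]
        assert np.abs(sk.coef_.T - ols).max() < 1e-6
        assert model.weights.shape == (10, 3)

    def test_huge_penalty_shrinks_weights_to_zero(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 8))
        Y = rng.normal(size=(40, 2))
        model = iv.ridge_encoding(X, *self._folds(X, Y, rng), penalties=[1e12],
                                  fmin=100, fmax=1000)
        assert np.abs(model.weights).max() <= 1e-6

    def test_tie_breaks_to_lowest_band(self):
        model = iv.EncodingModel(
            weights=np.ones((8, 1)), penalties=np.array([1.0]),
            best_band=np.ones((8, 1)).argmax(axis=0),
            best_frequency=iv.filterbank_centers(8)[np.ones((8, 1)).argmax(axis=0)],
            accuracy=np.zeros(1))
        assert model.best_band[0] == 0
        assert model.best_frequency[0] == iv.filterbank_centers(8)[0]

    def test_empty_penalty_grid_rejected(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 4))
        Y = rng.normal(size=(20, 1))
        with pytest.raises(ValueError, match="empty penalty"):
            iv.ridge_encoding(X, *self._folds(X, Y, rng), penalties=[])

    def test_fold_hygiene_test_responses_cannot_touch_weights(self):
        """At a fixed penalty, corrupting test responses leaves weights bitwise equal."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 10))
        Y = X @ rng.normal(size=(10, 3)) + 0.1 * rng.normal(size=(60, 3))
        tr_r, te_r, tr_i, te_i = self._folds(X, Y, rng)
        m1 = iv.ridge_encoding(X, tr_r, te_r, tr_i, te_i, penalties=[1.0],
                               fmin=100, fmax=1000)
        garbage = [np.full_like(t, 1e6) for t in te_r]
        m2 = iv.ridge_encoding(X, tr_r, garbage, tr_i, te_i, penalties=[1.0],
                               fmin=100, fmax=1000)
        assert np.array_equal(m1.weights, m2.weights)


class TestBestFrequencyMap:
    def test_one_hot_top_band_gives_highest_center(self):
        w = np.zeros((128, 1))
        w[127, 0] = 1.0
        centers = iv.filterbank_centers(128)
        assert centers[w.argmax(axis=0)][0] == pytest.approx(centers[-1])

    def test_warp_transport(self):
        from temporalign import align as al
        from temporalign import sphere as sph

        mesh = sph.icosphere(2)
        model = iv.EncodingModel(
            weights=np.zeros((4, len(mesh.vertices))),
            penalties=np.zeros(len(mesh.vertices)),
            best_band=np.zeros(len(mesh.vertices), dtype=int),
            best_frequency=np.full(len(mesh.vertices), 440.0),
            accuracy=np.zeros(len(mesh.vertices)))
        out = iv.best_frequency_map(model, al.identity_warp(mesh), mesh)
        assert np.allclose(out, 440.0)
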