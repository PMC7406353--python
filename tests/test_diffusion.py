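"""Structure-tensor edge-enhancing diffusion: per-step oracles and invariants."""

import numpy as np
import pytest

from temporalign import diffusion as df
from temporalign.volume import ScalarVolume


def _vol(data):
    return ScalarVolume(np.asarray(data, dtype=float))


class TestGaussianSmooth:
    def test_constant_volume_is_preserved(self):
        out = df.gaussian_smooth(_vol(np.full((8, 8, 8), 7.0)), 1.5)
        assert np.allclose(out.data, 7.0)

    def test_sigma_zero_is_identity(self):
        rng = np.random.default_rng(0)
        v = _vol(rng.normal(size=(6, 6, 6)))
        out = df.gaussian_smooth(v, 0.0)
        assert np.array_equal(out.data, v.data)

    def test_interior_impulse_kernel_sums_to_one(self):
        data = np.zeros((15, 15, 15))
        data[7, 7, 7] = 1.0
        out = df.gaussian_smooth(_vol(data), 1.0)
        assert abs(out.data.sum() - 1.0) < 1e-6

    def test_nonfinite_input_rejected_with_count(self):
        data = np.zeros((5, 5, 5))
        data[0, 0, 0] = np.nan
        data[1, 1, 1] = np.inf
        with pytest.raises(ValueError, match="2 non-finite"):
            df.gaussian_smooth(_vol(data), 1.0)


class TestStructureTensor:
    def test_constant_volume_gives_zero_tensor(self):
        S = df.structure_tensor(_vol(np.full((5, 5, 5), 3.0)))
        assert np.allclose(S, 0.0)

    def test_linear_ramp_in_x(self):
        x = np.arange(5, dtype=float)
        v = np.broadcast_to(x[:, None, None], (5, 5, 5)).copy()
        S = df.structure_tensor(_vol(v))
        interior = S[1:-1]
        assert np.allclose(interior[..., 0, 0], 1.0)
        expected = np.zeros((3, 3))
        expected[0, 0] = 1.0
        assert np.allclose(interior - expected, 0.0, atol=1e-12)

    def test_matches_bruteforce_outer_product(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(5, 5, 5))
        S = df.structure_tensor(_vol(v))
        for i in range(1, 4):
            for j in range(1, 4):
                for k in range(1, 4):
                    g = np.array([
                        (v[i + 1, j, k] - v[i - 1, j, k]) / 2,
                        (v[i, j + 1, k] - v[i, j - 1, k]) / 2,
                        (v[i, j, k + 1] - v[i, j, k - 1]) / 2,
                    ])
                    assert np.allclose(S[i, j, k], np.outer(g, g), atol=1e-12)

    def test_thin_grid_rejected(self):
        with pytest.raises(ValueError, match="thinner than 3"):
            df.structure_tensor(_vol(np.zeros((2, 5, 5))))


class TestEigendecompose:
    def test_diagonal_tensor_sorted_descending(self):
        T = np.diag([1.0, 2.0, 3.0])[None, None, None]
        eig = df.eigendecompose(T)
        assert np.allclose(eig.values[0, 0, 0], [3, 2, 1])

    def test_zero_tensor(self):
        eig = df.eigendecompose(np.zeros((2, 2, 2, 3, 3)))
        assert np.allclose(eig.values, 0.0)

    def test_eigenvalues_match_characteristic_polynomial(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(3, 3))
        T = (A @ A.T)[None, None, None]
        eig = df.eigendecompose(T)
        roots = np.sort(np.roots(np.poly(A @ A.T)))[::-1]
        assert np.allclose(eig.values[0, 0, 0], roots.real, atol=1e-8)

    def test_reconstruction(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(4, 4, 4, 3, 3))
        T = np.einsum("...ij,...kj->...ik", A, A)
        eig = df.eigendecompose(T)
        rec = np.einsum("...k,...ik,...jk->...ij", eig.values, eig.vectors, eig.vectors)
        assert np.allclose(rec, T, atol=1e-8)

    def test_asymmetric_rejected(self):
        T = np.zeros((1, 1, 1, 3, 3))
        T[..., 0, 1] = 1.0
        with pytest.raises(ValueError, match="asymmetric"):
            df.eigendecompose(T)


class TestSurfelWeight:
    def test_pure_surfel(self):
        eig = df.EigenSystem(np.array([[[[1.0, 0.0, 0.0]]]]), np.eye(3)[None, None, None])
        f = df.surfel_weight(eig, normalize=False)
        assert f.intensity[0, 0, 0] == 1.0
        assert f.range[0, 0, 0] == 1.0
        assert f.weight[0, 0, 0] == 0.0

    def test_mixed_tensor(self):
        eig = df.EigenSystem(np.array([[[[0.5, 0.25, 0.25]]]]), np.eye(3)[None, None, None])
        f = df.surfel_weight(eig, normalize=False)
        assert np.isclose(f.intensity[0, 0, 0], 1.0)
        assert np.isclose(f.range[0, 0, 0], 0.25)
        assert np.isclose(f.weight[0, 0, 0], 0.25)

    def test_degenerate_voxel_is_zeroed(self):
        eig = df.EigenSystem(np.zeros((1, 1, 1, 3)), np.eye(3)[None, None, None])
        f = df.surfel_weight(eig, normalize=False)
        assert f.range[0, 0, 0] == 0.0
        assert f.weight[0, 0, 0] == 0.0

    def test_negative_eigenvalues_rejected(self):
        eig = df.EigenSystem(np.array([[[[1.0, 0.0, -0.5]]]]), np.eye(3)[None, None, None])
        with pytest.raises(ValueError, match="negative eigenvalues"):
            df.surfel_weight(eig)


class TestDiffusionTensor:
    def _eig(self, shape=(4, 4, 4)):
        rng = np.random.default_rng(4)
        A = rng.normal(size=shape + (3, 3))
        S = np.einsum("...ij,...kj->...ik", A, A)
        return df.eigendecompose(S)

    def test_zero_weight_gives_zero_field(self):
        eig = self._eig()
        feats = df.SurfelFeatures(np.zeros((4, 4, 4)), np.zeros((4, 4, 4)), np.zeros((4, 4, 4)))
        D = df.diffusion_tensor(eig, feats, 1.0)
        assert np.allclose(D, 0.0)

    def test_rho_zero_is_identity(self):
        eig = self._eig()
        W = np.random.default_rng(5).random((4, 4, 4))
        feats = df.SurfelFeatures(W, W, W)
        D0 = df.diffusion_tensor(eig, feats, 0.0)
        D1 = df.diffusion_tensor(eig, feats, 0.0)
        assert np.array_equal(D0, D1)

    def test_impulse_spreads_like_scalar_smoothing(self):
        """Each unique tensor component smooths exactly as a scalar impulse."""
        shape = (9, 9, 9)
        eig = df.EigenSystem(
            np.zeros(shape + (3,)),
            np.broadcast_to(np.eye(3), shape + (3, 3)).copy(),
        )
        W = np.zeros(shape)
        W[4, 4, 4] = 1.0
        feats = df.SurfelFeatures(W, W, W)
        D = df.diffusion_tensor(eig, feats, 1.0)
        ref = df.gaussian_smooth(_vol(W), 1.0).data
        for i in range(3):
            assert np.allclose(D[..., i, i], ref, atol=1e-12)
        assert np.allclose(D[..., 0, 1], 0.0)

    def test_negative_rho_rejected(self):
        eig = self._eig()
        feats = df.SurfelFeatures(np.ones((4, 4, 4)), np.ones((4, 4, 4)), np.ones((4, 4, 4)))
        with pytest.raises(ValueError):
            df.diffusion_tensor(eig, feats, -1.0)


def _oracle_flux_update(v, D):
    """Straight-line stencil implementation of flux + divergence (zero-flux)."""
    n = v.shape
    g = np.zeros(n + (3,))
    vp = np.pad(v, 1, mode="edge")
    for i in range(n[0]):
        for j in range(n[1]):
            for k in range(n[2]):
                I, J, K = i + 1, j + 1, k + 1
                g[i, j, k] = [
                    (vp[I + 1, J, K] - vp[I - 1, J, K]) / 2,
                    (vp[I, J + 1, K] - vp[I, J - 1, K]) / 2,
                    (vp[I, J, K + 1] - vp[I, J, K - 1]) / 2,
                ]
    f = np.einsum("...ij,...j->...i", D, g)
    div = np.zeros(n)
    for ax in range(3):
        fa = f[..., ax]
        pad = [(0, 0)] * 3
        pad[ax] = (1, 1)
        fp = np.pad(fa, pad, mode="edge")
        # zero-flux: ghost fluxes are negated edge fluxes
        sl_lo = [slice(None)] * 3
        sl_lo[ax] = 0
        sl_hi = [slice(None)] * 3
        sl_hi[ax] = -1
        fp[tuple(sl_lo)] = -fa[tuple(sl_lo)]
        fp[tuple(sl_hi)] = -fa[tuple(sl_hi)]
        up = np.take(fp, range(2, fp.shape[ax]), axis=ax)
        dn = np.take(fp, range(0, fp.shape[ax] - 2), axis=ax)
        div += (up - dn) / 2.0
    return v + div


class TestFluxUpdate:
    def test_zero_tensor_is_identity(self):
        rng = np.random.default_rng(6)
        v = _vol(rng.normal(size=(6, 6, 6)))
        out = df.flux_update(v, np.zeros((6, 6, 6, 3, 3)))
        assert np.allclose(out.data, v.data)

    def test_total_intensity_conserved(self):
        rng = np.random.default_rng(7)
        v = _vol(rng.normal(10, 3, size=(7, 7, 7)))
        A = rng.normal(size=(7, 7, 7, 3, 3))
        D = np.einsum("...ij,...kj->...ik", A, A)
        out = df.flux_update(v, D)
        assert abs(out.data.sum() - v.data.sum()) < 1e-6 * abs(v.data.sum())

    def test_matches_bruteforce_stencil_oracle(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=(7, 7, 7))
        A = rng.normal(size=(7, 7, 7, 3, 3))
        D = np.einsum("...ij,...kj->...ik", A, A)
        out = df.flux_update(_vol(v), D)
        assert np.allclose(out.data, _oracle_flux_update(v, D), atol=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            df.flux_update(_vol(np.zeros((5, 5, 5))), np.zeros((4, 4, 4, 3, 3)))


class TestEnhance:
    def test_zero_iterations_is_identity(self):
        rng = np.random.default_rng(9)
        v = _vol(rng.normal(size=(6, 6, 6)))
        out = df.enhance(v, df.FilterParams(n_iter=0))
        assert np.array_equal(out.data, v.data)

    def test_constant_is_fixed_point_over_40_iterations(self):
        v = _vol(np.full((10, 10, 10), 42.0))
        out = df.enhance(v, df.FilterParams(n_iter=40))
        assert np.abs(out.data - 42.0).max() < 1e-6

    def test_conservation_every_iteration(self):
        rng = np.random.default_rng(10)
        v = _vol(rng.normal(80, 10, size=(10, 10, 10)))
        total = v.data.sum()
        cur = v
        for _ in range(5):
            cur = df.enhance(cur, df.FilterParams(n_iter=1))
            assert abs(cur.data.sum() - total) < 1e-6 * abs(total)

    def test_one_iteration_matches_straightline_reimplementation(self):
        """Full pipeline step equals an independently coded steps-1-to-9 pass."""
        from scipy import ndimage

        rng = np.random.default_rng(11)
        v = rng.normal(80, 10, size=(9, 9, 9))
        out = df.enhance(_vol(v), df.FilterParams(n_iter=1))

        smoothed = ndimage.gaussian_filter(v, 1.0, mode="reflect")
        g = np.zeros((9, 9, 9, 3))
        vp = np.pad(smoothed, 1, mode="edge")
        for i in range(9):
            for j in range(9):
                for k in range(9):
                    I, J, K = i + 1, j + 1, k + 1
                    g[i, j, k] = [
                        (vp[I + 1, J, K] - vp[I - 1, J, K]) / 2,
                        (vp[I, J + 1, K] - vp[I, J - 1, K]) / 2,
                        (vp[I, J, K + 1] - vp[I, J, K - 1]) / 2,
                    ]
        energy = (g ** 2).sum(axis=-1)
        scale = np.percentile(energy[energy > 0], 90.0)
        lam = np.clip(energy / scale, 0.0, 1.0)
        W = np.abs(1.0 - lam)  # rank-1 tensors: range == 1
        W[energy < 1e-12 * scale] = 0.0
        Wh = ndimage.gaussian_filter(W, 1.0, mode="reflect")
        D = Wh[..., None, None] * np.eye(3)
        expected = _oracle_flux_update_from_gradient(v, D, g)
        assert np.allclose(out.data, expected, atol=1e-10)

    def test_divergence_guard_names_iteration(self):
        v = _vol(np.full((5, 5, 5), 1e11))
        v.data[2, 2, 2] = -1e11
        # huge dynamic range cannot diverge under this scheme, so force the
        # guard by injecting an absurd seed value instead
        v.data *= 1e5
        with pytest.raises(RuntimeError, match="iteration"):
            df.enhance(v, df.FilterParams(n_iter=3))


def _oracle_flux_update_from_gradient(v, D, g):
    f = np.einsum("...ij,...j->...i", D, g)
    div = np.zeros(v.shape)
    for ax in range(3):
        fa = f[..., ax]
        pad = [(0, 0)] * 3
        pad[ax] = (1, 1)
        fp = np.pad(fa, pad, mode="edge")
        sl_lo = [slice(None)] * 3
        sl_lo[ax] = 0
        sl_hi = [slice(None)] * 3
        sl_hi[ax] = -1
        fp[tuple(sl_lo)] = -fa[tuple(sl_lo)]
        fp[tuple(sl_hi)] = -fa[tuple(sl_hi)]
        up = np.take(fp, range(2, fp.shape[ax]), axis=ax)
        dn = np.take(fp, range(0, fp.shape[ax] - 2), axis=ax)
        div += (up - dn) / 2.0
    return v + div
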