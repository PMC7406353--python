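"""Edge-enhancing anisotropic diffusion driven by the structure tensor.

The filter sharpens tissue boundaries in anatomical MRI volumes before
histogram-based segmentation.  Each iteration:

1. smooth the image with a Gaussian of width ``sigma`` (spatial regularization),
2. take the central-difference gradient,
3. form the structure tensor ``S = g g^T`` per voxel,
4. eigendecompose ``S`` (eigenvalues sorted descending),
5. derive per-voxel surfel features: ``intensity = l1+l2+l3``,
   ``range = (l1-l3)/intensity`` and the diffusivity weight
   ``W = |(|range-0.5|+0.5) - intensity|``, which is large in structureless
   regions and near zero around strong sheet-like (surfel) boundaries,
6. assemble a diffusion tensor from the weighted eigenvector frame,
   ``D = W * sum_k e_k e_k^T``,
7. smooth ``D`` component-wise with a Gaussian of width ``rho``,
8. compute the flux ``f = D_hat . grad(v_hat)`` from the smoothed image's
   gradient (the same gradient that built the tensor),
9. update ``v <- v + div(f)`` with zero-flux boundaries,
10. repeat for ``n_iter`` iterations (default 40).

Intensity is rescaled by a robust upper percentile of the gradient energy
and clipped to [0, 1] before step 5, making ``W`` invariant to acquisition
gain and saturating the strong-edge population at zero diffusivity.  Because
the flux then falls with gradient energy above the saturation knee,
iteration actively steepens partial-volume boundaries while flattening
tissue interiors.  Discrete zero-flux boundaries make every iteration
conserve total intensity exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .volume import ScalarVolume

log = logging.getLogger(__name__)

__all__ = [
    "FilterParams",
    "gaussian_smooth",
    "central_gradient",
    "structure_tensor",
    "eigendecompose",
    "surfel_weight",
    "diffusion_tensor",
    "flux_update",
    "enhance",
]


@dataclass
class FilterParams:
    """Parameters of the edge-enhancing diffusion filter.

    sigma, rho are Gaussian standard deviations in voxels; ``n_iter`` explicit
    update steps are applied.  ``eps_degenerate`` (relative to the maximum
    ``intensity``) marks voxels treated as structureless.
    """

    sigma: float = 1.0
    rho: float = 1.0
    n_iter: int = 40
    eps_degenerate: float = 1e-12
    boundary: str = "reflect"

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.rho < 0:
            raise ValueError("sigma and rho must be non-negative")
        if self.n_iter < 0:
            raise ValueError("n_iter must be non-negative")


class EigenSystem(NamedTuple):
    """Per-voxel eigenvalues (descending) and orthonormal eigenvectors.

    ``values[..., k]`` is the k-th eigenvalue, ``vectors[..., :, k]`` the
    matching eigenvector.
    """

    values: np.ndarray
    vectors: np.ndarray


class SurfelFeatures(NamedTuple):
    """Per-voxel tensor-shape features (intensity, range, diffusivity W)."""

    intensity: np.ndarray
    range: np.ndarray
    weight: np.ndarray


def gaussian_smooth(vol: ScalarVolume, sigma: float) -> ScalarVolume:
    """Gaussian smoothing with std `sigma` in voxels; sigma=0 is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    vol.require_finite("input volume")
    if sigma == 0:
        return vol.with_data(vol.data.copy())
    out = ndimage.gaussian_filter(vol.data.astype(float), sigma, mode="reflect")
    return vol.with_data(out)


def _pad_edge(a: np.ndarray, axis: int) -> np.ndarray:
    width = [(0, 0)] * a.ndim
    width[axis] = (1, 1)
    return np.pad(a, width, mode="edge")


def central_gradient(data: np.ndarray, spacing) -> np.ndarray:
    """Central-difference gradient in physical units; shape (..., 3).

    Edge voxels use replicated (Neumann) ghost values, i.e. one-sided
    half-weight differences.
    """
    if any(s < 3 for s in data.shape):
        raise ValueError(
            f"grid {data.shape} thinner than 3 voxels: central differences undefined"
        )
    spacing = np.asarray(spacing, dtype=float)
    g = np.empty(data.shape + (3,), dtype=float)
    for ax in range(3):
        padded = _pad_edge(data, ax)
        up = np.take(padded, range(2, padded.shape[ax]), axis=ax)
        down = np.take(padded, range(0, padded.shape[ax] - 2), axis=ax)
        g[..., ax] = (up - down) / (2.0 * spacing[ax])
    return g


def structure_tensor(vol: ScalarVolume) -> np.ndarray:
    """Per-voxel outer product of the central-difference gradient; (..., 3, 3)."""
    vol.require_finite("input volume")
    g = central_gradient(vol.data.astype(float), vol.spacing)
    return g[..., :, np.newaxis] * g[..., np.newaxis, :]


def eigendecompose(tensors: np.ndarray, sym_tol: float = 1e-10) -> EigenSystem:
    """Eigendecomposition of a symmetric tensor field, eigenvalues descending."""
    tensors = np.asarray(tensors, dtype=float)
    asym = np.abs(tensors - np.swapaxes(tensors, -1, -2)).max()
    if asym > sym_tol:
        raise ValueError(f"tensor field asymmetric: max |S - S^T| = {asym:g}")
    vals, vecs = np.linalg.eigh(tensors)
    # eigh sorts ascending; flip to descending
    vals = vals[..., ::-1]
    vecs = vecs[..., ::-1]
    return EigenSystem(vals, vecs)


def surfel_weight(
    eig: EigenSystem,
    eps_degenerate: float = 1e-12,
    normalize: bool = True,
    percentile: float = 90.0,
) -> SurfelFeatures:
    """Surfel-enhancing diffusivity from sorted eigenvalues.

    ``W = |(|range - 0.5| + 0.5) - intensity|`` is small at strong sheet-like
    (surfel) structure and large in structureless regions, so strong
    boundaries are preserved while the rest diffuses.  With ``normalize`` the
    intensity is rescaled by its `percentile`-th positive value and clipped to
    [0, 1]: the whole strong-edge population then saturates at zero
    diffusivity rather than only the single largest gradient, which is what
    makes boundary contrast grow rather than erode under iteration.
    ``eps_degenerate`` (relative to the normalization constant) marks
    structureless voxels, where ``range = W = 0``.
    """
    vals = np.asarray(eig.values, dtype=float)
    if vals[..., -1].min() < -1e-8 * max(1.0, np.abs(vals).max()):
        raise ValueError("negative eigenvalues beyond tolerance")
    vals = np.clip(vals, 0.0, None)
    raw = vals.sum(axis=-1)
    if normalize:
        pos = raw[raw > 0]
        scale = float(np.percentile(pos, percentile)) if pos.size else 1.0
        scale = scale if scale > 0 else 1.0
        intensity = np.clip(raw / scale, 0.0, 1.0)
    else:
        scale = 1.0
        intensity = raw
    ok = raw >= eps_degenerate * scale
    rng = np.zeros_like(raw)
    np.divide(vals[..., 0] - vals[..., 2], raw, out=rng, where=ok)
    rng = np.clip(rng, 0.0, 1.0)
    weight = np.abs((np.abs(rng - 0.5) + 0.5) - intensity)
    weight[~ok] = 0.0
    rng[~ok] = 0.0
    return SurfelFeatures(intensity, rng, weight)


def diffusion_tensor(
    eig: EigenSystem,
    feats: SurfelFeatures,
    rho: float,
) -> np.ndarray:
    """Diffusion tensor field from the weighted eigenvector frame, smoothed.

    The scalar weight multiplies the (orthonormal, hence identity-summing)
    eigenvector frame: ``D = W * sum_k e_k e_k^T = W * I``.  Diffusivity is
    therefore near zero everywhere around strong surfels — the boundary is
    preserved both across and along — and close to 1 in structureless tissue.
    Because the weight falls with gradient energy, the resulting flux is
    non-monotone in the gradient, which actively steepens partial-volume
    boundaries (Perona-Malik-type enhancement) instead of merely preserving
    them.  The result is Gaussian-smoothed with std ``rho`` (voxels) per
    unique component; rho=0 returns D unchanged.
    """
    if rho < 0:
        raise ValueError("rho must be non-negative")
    W = feats.weight
    vecs = eig.vectors
    mu = np.broadcast_to(W[..., None], W.shape + (3,))
    # D = W * sum_k e_k e_k^T  (== W * I up to round-off)
    D = np.einsum("...k,...ik,...jk->...ij", mu, vecs, vecs)
    if rho == 0:
        return D
    out = np.empty_like(D)
    for i in range(3):
        for j in range(i, 3):
            sm = ndimage.gaussian_filter(D[..., i, j], rho, mode="reflect")
            out[..., i, j] = sm
            out[..., j, i] = sm
    return out


def _divergence_zero_flux(flux: np.ndarray, spacing) -> np.ndarray:
    """Central-difference divergence with zero-flux (odd-reflected) boundaries.

    Ghost fluxes are the negated edge fluxes, which makes the discrete
    divergence sum to exactly zero over the grid (discrete divergence theorem).
    """
    spacing = np.asarray(spacing, dtype=float)
    div = np.zeros(flux.shape[:-1])
    for ax in range(3):
        f = flux[..., ax]
        first = np.take(f, [0], axis=ax)
        last = np.take(f, [f.shape[ax] - 1], axis=ax)
        padded = np.concatenate([-first, f, -last], axis=ax)
        up = np.take(padded, range(2, padded.shape[ax]), axis=ax)
        down = np.take(padded, range(0, padded.shape[ax] - 2), axis=ax)
        div += (up - down) / (2.0 * spacing[ax])
    return div


def flux_update(
    vol: ScalarVolume,
    D_hat: np.ndarray,
    boundary: str = "reflect",
    gradient_of: ScalarVolume | None = None,
) -> ScalarVolume:
    """One explicit update ``v <- v + div(D_hat . grad)`` (unit step).

    The flux gradient is taken from `gradient_of` when given (the full filter
    passes the pre-smoothed image here, which is also what keeps the unit
    explicit step stable) and from `vol` itself otherwise.  With the
    zero-flux boundary scheme the grid-total intensity is conserved exactly.
    """
    D_hat = np.asarray(D_hat, dtype=float)
    if D_hat.shape != vol.data.shape + (3, 3):
        raise ValueError(
            f"tensor field shape {D_hat.shape} does not match volume {vol.data.shape}"
        )
    src = vol if gradient_of is None else gradient_of
    if src.data.shape != vol.data.shape:
        raise ValueError("gradient source shape does not match volume")
    g = central_gradient(src.data.astype(float), vol.spacing)
    flux = np.einsum("...ij,...j->...i", D_hat, g)
    div = _divergence_zero_flux(flux, vol.spacing)
    return vol.with_data(vol.data + div)


def enhance(
    vol: ScalarVolume,
    params: FilterParams | None = None,
    progress: bool = False,
) -> ScalarVolume:
    """Run the full edge-enhancing diffusion filter for ``params.n_iter`` steps."""
    if params is None:
        params = FilterParams()
    vol.require_finite("input volume")
    out = vol.copy()
    out.data = out.data.astype(float)
    for it in range(params.n_iter):
        smoothed = gaussian_smooth(out, params.sigma)
        S = structure_tensor(smoothed)
        eig = eigendecompose(S)
        feats = surfel_weight(eig, params.eps_degenerate)
        D_hat = diffusion_tensor(eig, feats, params.rho)
        out = flux_update(out, D_hat, params.boundary, gradient_of=smoothed)
        peak = np.abs(out.data).max()
        if peak > 1e12:
            raise RuntimeError(
                f"intensity diverged (|v| = {peak:g}) at iteration {it + 1}"
            )
        if progress:
            log.info(
                "iter %d: total=%.6g min=%.6g max=%.6g",
                it + 1, out.data.sum(), out.data.min(), out.data.max(),
            )
    return out
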