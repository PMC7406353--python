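"""3D scalar volumes with world-space geometry.

A :class:`ScalarVolume` is the container every voxel-level stage of the
pipeline operates on: a 3D intensity grid together with its voxel size and a
NIfTI-style 4x4 voxel-to-world affine.  Binary masks reuse the same container
with boolean data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass
class ScalarVolume:
    """A 3D scalar grid with voxel spacing (mm) and a voxel-to-world affine.

    Parameters
    ----------
    data
        3D array of intensities (any real dtype).
    affine
        4x4 voxel-to-world transform.  Defaults to identity.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(self.spacing > 0):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def spacing(self) -> np.ndarray:
        """Voxel size per axis (mm), derived from the affine."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def require_finite(self, what: str = "volume") -> None:
        bad = ~np.isfinite(self.data)
        if bad.any():
            raise ValueError(
                f"{what} contains {int(bad.sum())} non-finite voxel(s)"
            )

    def with_data(self, data: np.ndarray) -> "ScalarVolume":
        """New volume sharing this volume's geometry."""
        return ScalarVolume(np.asarray(data), self.affine.copy())

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.data.copy(), self.affine.copy())


def load_nifti(path) -> ScalarVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return ScalarVolume(data, img.affine)


def save_nifti(vol: ScalarVolume, path) -> None:
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))


def binary_mask(data: np.ndarray, affine: np.ndarray | None = None) -> ScalarVolume:
    """Wrap a boolean grid as a volume (values coerced to {0,1})."""
    vol = ScalarVolume(
        np.asarray(data).astype(bool),
        np.eye(4) if affine is None else affine,
    )
    return vol


def upsample(vol: ScalarVolume, new_spacing: float) -> ScalarVolume:
    """Trilinear resampling to an isotropic grid of `new_spacing` mm.

    Optional pre-step before diffusion filtering of coarse acquisitions.
    """
    factors = vol.spacing / float(new_spacing)
    out = ndimage.zoom(vol.data.astype(float), factors, order=1, mode="nearest")
    new_affine = vol.affine.copy()
    new_affine[:3, :3] = vol.affine[:3, :3] / factors[np.newaxis, :]
    return ScalarVolume(out, new_affine)
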