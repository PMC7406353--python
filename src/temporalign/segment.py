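"""Initial white-matter segmentation from joint intensity/gradient histograms.

A 2D histogram over (intensity, gradient magnitude) separates tissue classes:
white matter forms a high-intensity, low-gradient mode; the white/gray
interface occupies high-gradient bins.  A serializable region (box or polygon)
in histogram space selects the voxels of a class, replacing the interactive
selection of typical histogram tools with a reproducible one.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as MplPath

from .diffusion import central_gradient
from .volume import ScalarVolume

__all__ = ["JointHistogram", "HistogramRegion", "joint_histogram", "mask_from_region"]


@dataclass
class JointHistogram:
    """2D counts over intensity (axis 0) and gradient-magnitude (axis 1) bins."""

    counts: np.ndarray
    intensity_edges: np.ndarray
    gradmag_edges: np.ndarray

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# intensity_edges," + ",".join(f"{e:.10g}" for e in self.intensity_edges) + "\n")
            fh.write("# gradmag_edges," + ",".join(f"{e:.10g}" for e in self.gradmag_edges) + "\n")
            np.savetxt(fh, self.counts, fmt="%d", delimiter=",")

    @classmethod
    def from_csv(cls, path) -> "JointHistogram":
        with open(path) as fh:
            ie = np.array(fh.readline().split(",")[1:], dtype=float)
            ge = np.array(fh.readline().split(",")[1:], dtype=float)
            counts = np.loadtxt(fh, delimiter=",")
        return cls(np.atleast_2d(counts), ie, ge)


@dataclass
class HistogramRegion:
    """A box or polygon in (intensity, gradient-magnitude) space.

    A box is given by ``intensity=(lo, hi)`` and ``gradmag=(lo, hi)``;
    alternatively ``polygon`` is an (n, 2) vertex list in the same space.
    """

    intensity: tuple | None = None
    gradmag: tuple | None = None
    polygon: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.polygon is not None:
            self.polygon = np.asarray(self.polygon, dtype=float)
            if self.polygon.ndim != 2 or self.polygon.shape[0] < 3:
                raise ValueError("polygon needs at least 3 (intensity, gradmag) vertices")
            return
        if self.intensity is None or self.gradmag is None:
            raise ValueError("region needs either a polygon or both box ranges")
        if self.intensity[0] >= self.intensity[1] or self.gradmag[0] >= self.gradmag[1]:
            raise ValueError("degenerate region: ranges must have positive extent")

    def contains(self, intensity: np.ndarray, gradmag: np.ndarray) -> np.ndarray:
        if self.polygon is not None:
            pts = np.column_stack([intensity.ravel(), gradmag.ravel()])
            inside = MplPath(self.polygon).contains_points(pts)
            return inside.reshape(intensity.shape)
        return (
            (intensity >= self.intensity[0]) & (intensity <= self.intensity[1])
            & (gradmag >= self.gradmag[0]) & (gradmag <= self.gradmag[1])
        )

    def to_json(self, path) -> None:
        obj = {
            "intensity": list(self.intensity) if self.intensity else None,
            "gradmag": list(self.gradmag) if self.gradmag else None,
            "polygon": self.polygon.tolist() if self.polygon is not None else None,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "HistogramRegion":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            intensity=tuple(obj["intensity"]) if obj.get("intensity") else None,
            gradmag=tuple(obj["gradmag"]) if obj.get("gradmag") else None,
            polygon=obj.get("polygon"),
        )


def _gradmag(vol: ScalarVolume) -> np.ndarray:
    g = central_gradient(vol.data.astype(float), vol.spacing)
    return np.sqrt((g ** 2).sum(axis=-1))


def _edges(values: np.ndarray, n_bins: int, robust: bool) -> np.ndarray:
    if robust:
        lo, hi = np.percentile(values, [0.5, 99.5])
    else:
        lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        hi = lo + max(abs(lo), 1.0) * 1e-6
    return np.linspace(lo, hi, n_bins + 1)


def joint_histogram(
    vol: ScalarVolume,
    n_bins_intensity: int = 100,
    n_bins_gradmag: int = 100,
    mask: ScalarVolume | None = None,
    robust: bool = True,
) -> JointHistogram:
    """Joint intensity/gradient-magnitude histogram over in-mask voxels.

    Bin edges are linear between the 0.5th and 99.5th percentiles (robust
    default); out-of-range voxels are clipped into the edge bins so the counts
    conserve the voxel total.
    """
    if n_bins_intensity < 2 or n_bins_gradmag < 2:
        raise ValueError("need at least 2 bins per axis")
    inten = vol.data.astype(float)
    gm = _gradmag(vol)
    sel = np.ones(vol.shape, bool) if mask is None else mask.data.astype(bool)
    iv, gv = inten[sel], gm[sel]
    ie = _edges(iv, n_bins_intensity, robust)
    ge = _edges(gv, n_bins_gradmag, robust)
    ii = np.clip(np.searchsorted(ie, iv, side="right") - 1, 0, n_bins_intensity - 1)
    gi = np.clip(np.searchsorted(ge, gv, side="right") - 1, 0, n_bins_gradmag - 1)
    counts = np.zeros((n_bins_intensity, n_bins_gradmag), dtype=np.int64)
    np.add.at(counts, (ii, gi), 1)
    return JointHistogram(counts, ie, ge)


def mask_from_region(
    vol: ScalarVolume,
    region: HistogramRegion,
    mask: ScalarVolume | None = None,
) -> ScalarVolume:
    """Binary mask of voxels whose (intensity, gradmag) pair lies in `region`."""
    inten = vol.data.astype(float)
    gm = _gradmag(vol)
    inside = region.contains(inten, gm)
    if mask is not None:
        inside &= mask.data.astype(bool)
    if not inside.any():
        warnings.warn("histogram region selects no voxels: empty mask")
    return ScalarVolume(inside, vol.affine.copy())
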