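"""Seeded synthetic data with ground truth for every pipeline stage.

Three generators emulate the statistical structure of the study data so the
whole pipeline runs without downloads:

* :func:`make_volume_phantom` — a folded two-tissue volume (white matter 100,
  gray matter 60, additive Gaussian noise) with an analytically known
  interface, for the diffusion filter and histogram segmentation.
* :func:`make_cohort` — a cohort of spheres sharing one template curvature
  pattern (band-limited background plus gyral/sulcal ridges along the four
  temporal landmarks), each subject deformed by a known smooth spherical
  field plus an along-ridge slide and a small global rotation.  Area labels
  co-vary with the landmark strips; the planted correspondence is stored, so
  perfect alignment implies perfect label overlap by construction.
* :func:`make_sound_experiment` — band-energy features of natural-sound-like
  stimuli, one-hot frequency tuning per vertex, and fMRI-like time series
  with the study's 168-sound / 24-run / 4-fold cross-validation layout.

Everything is deterministic under the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from . import sphere as sph
from .align import landmark_to_map
from .volume import ScalarVolume

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "SoundExperimentSpec",
    "make_volume_phantom",
    "make_cohort",
    "make_sound_experiment",
    "make_tone_sounds",
    "canonical_hrf",
]

AREA_NAMES = ("Te1.0", "Te1.1", "Te1.2", "Te2.1", "Te2.2", "Te3", "STS1", "STS2")


# ---------------------------------------------------------------------------
# folded two-tissue volume phantom

@dataclass
class PhantomSpec:
    shape: tuple = (48, 48, 48)
    wm_mean: float = 100.0
    gm_mean: float = 60.0
    noise_sd: float = 10.0
    fold_wavelength: float = 16.0
    fold_amplitude: float = 5.0
    psf_sigma: float = 2.0            # acquisition point-spread blur, voxels
    seed: int = 0


def make_volume_phantom(spec: PhantomSpec):
    """Folded two-tissue volume with exact truth masks.

    The white matter occupies ``z < z0(x, y)`` with a sinusoidally folded
    interface.  ``psf_sigma`` blurs the tissue image before noise, emulating
    the partial-volume transition of coarse acquisitions resampled to a finer
    grid (the study filtered 1 mm data upsampled to 0.5 mm, i.e. interfaces
    spanning about two voxels); set it to 0 for an ideal hard-edge phantom.
    Returns ``(volume, wm_mask, interface_mask, normals)`` where `normals`
    holds the analytic unit interface normal per voxel.
    """
    nx, ny, nz = spec.shape
    if spec.fold_amplitude >= nz / 2 - 2:
        raise ValueError("fold amplitude exceeds the grid")
    rng = np.random.default_rng(spec.seed)
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    k = 2 * np.pi / spec.fold_wavelength
    z0 = nz / 2 + spec.fold_amplitude * np.sin(k * x[:, :, 0]) * np.cos(k * y[:, :, 0])
    wm = z < z0[:, :, None]
    data = np.where(wm, spec.wm_mean, spec.gm_mean).astype(float)
    if spec.psf_sigma > 0:
        from scipy import ndimage as _ndi

        data = _ndi.gaussian_filter(data, spec.psf_sigma, mode="nearest")
    if spec.noise_sd > 0:
        data += rng.normal(0, spec.noise_sd, size=spec.shape)
    interface = np.abs(z - z0[:, :, None]) <= 1.0
    # gradient of F = z - z0(x, y)
    dz0x = spec.fold_amplitude * k * np.cos(k * x[:, :, 0]) * np.cos(k * y[:, :, 0])
    dz0y = -spec.fold_amplitude * k * np.sin(k * x[:, :, 0]) * np.sin(k * y[:, :, 0])
    normals = np.stack(
        [-np.broadcast_to(dz0x[:, :, None], spec.shape),
         -np.broadcast_to(dz0y[:, :, None], spec.shape),
         np.ones(spec.shape)], axis=-1)
    normals = normals / np.linalg.norm(normals, axis=-1, keepdims=True)
    return (
        ScalarVolume(data),
        ScalarVolume(wm),
        ScalarVolume(interface),
        normals,
    )


# ---------------------------------------------------------------------------
# spherical cohort

@dataclass
class CohortSpec:
    n_subjects: int = 10
    level: int = 4
    background_smooth: int = 30
    ridge_width: float = 0.06         # radians
    hg_band: float = 0.10             # half-width of the Heschl label band
    ridge_amplitudes: dict = field(default_factory=lambda: {
        "aHG": -1.2, "STG": -3.0, "STS": 3.0, "MTG": -3.0})
    deform_amplitude: float = 0.10    # radians, ~ one ridge width
    deform_smooth: int = 60
    n_deform_fields: int = 6
    slide_amplitude: float = 0.12     # along-aHG slide (radians)
    max_rotation_deg: float = 10.0
    curvature_noise_sd: float = 0.05
    seed: int = 0


def _arc_points(lat: float, s0: float, s1: float, n: int = 80) -> np.ndarray:
    """Points along a constant-latitude arc, angles in radians."""
    s = np.linspace(s0, s1, n)
    return np.column_stack([
        np.cos(lat) * np.cos(s), np.cos(lat) * np.sin(s), np.full(n, np.sin(lat))])


def _oblique_arc(p0: np.ndarray, p1: np.ndarray, n: int = 60) -> np.ndarray:
    """Great-circle arc between two unit points."""
    t = np.linspace(0, 1, n)
    omega = np.arccos(np.clip(p0 @ p1, -1, 1))
    if omega < 1e-9:
        raise ValueError("degenerate arc")
    a = np.sin((1 - t) * omega) / np.sin(omega)
    b = np.sin(t * omega) / np.sin(omega)
    return a[:, None] * p0 + b[:, None] * p1


def _angular_dist_to_curve(V: np.ndarray, curve: np.ndarray) -> np.ndarray:
    dots = np.clip(V @ curve.T, -1, 1)
    return np.arccos(dots.max(axis=1))


def _along_coordinate(V: np.ndarray, curve: np.ndarray) -> np.ndarray:
    """Normalized position in [0, 1] of each vertex's nearest curve point."""
    dots = np.clip(V @ curve.T, -1, 1)
    idx = dots.argmax(axis=1)
    return idx / (len(curve) - 1)


def _landmark_curves() -> dict:
    lat = {"STG": 0.0, "STS": -0.18, "MTG": -0.36}
    curves = {name: _arc_points(lat[name], -0.6, 0.6) for name in lat}
    p0 = sph.normalize_rows(_arc_points(0.34, -0.05, -0.05, 2))[0]
    p1 = sph.normalize_rows(_arc_points(0.06, 0.28, 0.28, 2))[0]
    curves["aHG"] = _oblique_arc(p0, p1)
    return curves


def _template_curvature(mesh, curves, spec, rng):
    V = np.asarray(mesh.vertices, dtype=float)
    A = sph.averaging_matrix(len(V), np.asarray(mesh.faces))
    bg = sph.smooth_map(rng.normal(size=len(V)), A, spec.background_smooth)
    bg = (bg - bg.mean()) / bg.std()
    curv = bg.copy()
    for name, curve in curves.items():
        d = _angular_dist_to_curve(V, curve)
        curv += spec.ridge_amplitudes[name] * np.exp(-0.5 * (d / spec.ridge_width) ** 2)
    return curv


def _template_labels(V, curves, spec) -> np.ndarray:
    d_hg = _angular_dist_to_curve(V, curves["aHG"])
    d_stg = _angular_dist_to_curve(V, curves["STG"])
    d_sts = _angular_dist_to_curve(V, curves["STS"])
    along_hg = _along_coordinate(V, curves["aHG"])
    along_sts = _along_coordinate(V, curves["STS"])
    labels = np.full(len(V), "none", dtype=object)
    sel = d_hg <= spec.hg_band
    labels[sel & (along_hg < 1 / 3)] = "Te1.1"
    labels[sel & (along_hg >= 1 / 3) & (along_hg < 2 / 3)] = "Te1.0"
    labels[sel & (along_hg >= 2 / 3)] = "Te1.2"
    free = labels == "none"
    ring1 = free & (d_hg > spec.hg_band) & (d_hg <= spec.hg_band + 0.07)
    labels[ring1] = "Te2.1"
    free = labels == "none"
    ring2 = free & (d_hg > spec.hg_band + 0.07) & (d_hg <= spec.hg_band + 0.14)
    labels[ring2] = "Te2.2"
    free = labels == "none"
    labels[free & (d_stg <= 0.08)] = "Te3"
    free = labels == "none"
    sts = free & (d_sts <= 0.08)
    labels[sts & (along_sts < 0.5)] = "STS1"
    labels[sts & (along_sts >= 0.5)] = "STS2"
    return labels.astype(str)


def _smooth_tangent_field(mesh, A, spec, rng) -> np.ndarray:
    V = np.asarray(mesh.vertices, dtype=float)
    total = np.zeros_like(V)
    for _ in range(spec.n_deform_fields):
        f = rng.normal(size=V.shape)
        f = sph.smooth_map(f, A, spec.deform_smooth)
        total += f
    total -= (total * V).sum(axis=1, keepdims=True) * V
    rms = np.sqrt((total ** 2).sum(axis=1).mean())
    if rms > 0:
        total *= spec.deform_amplitude / rms
    return total


def _displace(V: np.ndarray, disp: np.ndarray) -> np.ndarray:
    return sph.normalize_rows(V + disp)


def _invert_deformation(targets, V, disp, sampler, n_iter=40):
    """Solve normalize(x + d(x)) = target for x by fixed-point iteration."""
    x = targets.copy()
    for _ in range(n_iter):
        fx = _displace(x, sampler.interpolate(disp, x))
        x = sph.normalize_rows(x - (fx - targets))
    return x


@dataclass
class Cohort:
    mesh: trimesh.Trimesh
    level: int
    template_curvature: np.ndarray
    template_labels: np.ndarray
    template_landmark_paths: dict
    template_landmark_maps: dict
    subjects: list
    spec: CohortSpec


def make_cohort(spec: CohortSpec | None = None) -> Cohort:
    """Generate the deformed-sphere cohort with stored true correspondences.

    Each subject dict holds: ``curvature``, ``labels``, ``landmark_paths``,
    ``landmark_maps`` (unsmoothed indicators), ``rotation`` (planted global
    rotation), ``true_warp`` (template vertex -> subject-sphere position; the
    inverse of the planted deformation composed with the rotation) and
    ``forward_positions`` (subject vertex -> template-sphere position, at
    which sampling the template reproduces the subject map exactly).
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    mesh = sph.icosphere(spec.level)
    V = np.asarray(mesh.vertices, dtype=float)
    F = np.asarray(mesh.faces)
    A = sph.averaging_matrix(len(V), F)
    sampler = sph.SphereSampler(V, F)
    curves = _landmark_curves()
    t_curv = _template_curvature(mesh, curves, spec, rng)
    t_labels = _template_labels(V, curves, spec)
    t_paths, t_maps = {}, {}
    for name, curve in curves.items():
        anchors = sampler.nearest_vertex(curve[:: max(1, len(curve) // 12)])
        anchors = [a for i, a in enumerate(anchors) if i == 0 or a != anchors[i - 1]]
        path, indicator = landmark_to_map(mesh, anchors)
        t_paths[name] = path
        t_maps[name] = indicator

    # along-aHG unit tangent field for the slide component
    hg = curves["aHG"]
    hg_dir = np.gradient(hg, axis=0)
    d_hg = _angular_dist_to_curve(V, hg)
    nearest_pt = np.clip(V @ hg.T, -1, 1).argmax(axis=1)
    slide_dir = hg_dir[nearest_pt]
    slide_dir -= (slide_dir * V).sum(axis=1, keepdims=True) * V
    slide_dir = sph.normalize_rows(slide_dir)
    slide_env = np.exp(-0.5 * (d_hg / (2 * spec.hg_band)) ** 2)

    subjects = []
    for s in range(spec.n_subjects):
        disp = _smooth_tangent_field(mesh, A, spec, rng)
        slide = rng.normal(0, spec.slide_amplitude)
        disp = disp + slide * slide_env[:, None] * slide_dir
        disp -= (disp * V).sum(axis=1, keepdims=True) * V
        axis = sph.normalize_rows(rng.normal(size=3)[None])[0]
        angle = np.deg2rad(rng.uniform(0, spec.max_rotation_deg))
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        Rm = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)

        rotated = V @ Rm.T                      # R_s v_i
        forward = _displace(rotated, sampler.interpolate(disp, rotated))
        curv = sampler.interpolate(t_curv, forward)
        if spec.curvature_noise_sd > 0:
            curv = curv + rng.normal(0, spec.curvature_noise_sd, size=len(V))
        labels = t_labels[sampler.nearest_vertex(forward)]
        inv = _invert_deformation(V, V, disp, sampler)
        true_warp = inv @ Rm                    # rows: R_s^T inv_i
        # landmarks transported into subject space
        s_paths, s_maps = {}, {}
        for name in curves:
            pts = true_warp[t_paths[name]]
            anchors = sampler.nearest_vertex(pts[:: max(1, len(pts) // 12)])
            anchors = [a for i, a in enumerate(anchors) if i == 0 or a != anchors[i - 1]]
            if len(anchors) < 2:
                anchors = list(anchors) + [int(sampler.nearest_vertex(pts[-1:])[0])]
            path, indicator = landmark_to_map(mesh, anchors)
            s_paths[name] = path
            s_maps[name] = indicator
        subjects.append({
            "curvature": curv,
            "labels": labels,
            "landmark_paths": s_paths,
            "landmark_maps": s_maps,
            "rotation": Rm,
            "true_warp": true_warp,
            "forward_positions": forward,
        })
    return Cohort(mesh, spec.level, t_curv, t_labels, t_paths, t_maps, subjects, spec)


# ---------------------------------------------------------------------------
# sound-encoding experiment

@dataclass
class SoundExperimentSpec:
    n_sounds: int = 168
    n_runs: int = 24
    n_folds: int = 4
    n_vertices: int = 100
    n_bands: int = 128
    snr: float = 2.0
    tr: float = 2.6                   # volume time, seconds
    onset_spacing: int = 12           # volumes between sound onsets
    first_onset: int = 4
    hrf_length: int = 9
    feature_bump_sd: float = 1.5      # bands
    feature_noise: float = 0.02
    seed: int = 0


def canonical_hrf(n_samples: int = 9, tr: float = 2.6) -> np.ndarray:
    """Double-gamma hemodynamic response sampled at the volume time."""
    from scipy.stats import gamma as gamma_dist

    t = np.arange(n_samples) * tr
    # SPM-style double gamma: peak ~5 s, undershoot ~15 s
    h = gamma_dist.pdf(t, 6) - 1 / 6.0 * gamma_dist.pdf(t, 16)
    m = np.abs(h).max()
    return h / (m if m > 0 else 1.0)


def make_tone_sounds(freqs, fs: int = 22050, duration: float = 0.5):
    """Pure-tone waveforms (one per frequency) for filterbank checks."""
    t = np.arange(int(fs * duration)) / fs
    return [np.sin(2 * np.pi * f * t) for f in np.asarray(freqs, dtype=float)], fs


@dataclass
class SoundExperiment:
    features: np.ndarray              # sounds x bands
    series: np.ndarray                # time x vertices
    run_slices: list                  # per-run slice into the time axis
    onsets: list                      # per run: list of (volume_index, sound_index)
    folds: list                       # per fold: list of test-run indices
    true_bands: np.ndarray            # per-vertex tuned band index
    true_weights: np.ndarray          # bands x vertices (one-hot)
    true_betas: np.ndarray            # sounds x vertices
    hrf: np.ndarray
    spec: SoundExperimentSpec

    def fold_sounds(self, fold: int):
        """(train_sound_idx, test_sound_idx) for one cross-validation split."""
        test_runs = set(self.folds[fold])
        train, test = [], []
        for r, ons in enumerate(self.onsets):
            dest = test if r in test_runs else train
            dest.extend(snd for _, snd in ons)
        return np.array(sorted(train)), np.array(sorted(test))


def make_sound_experiment(spec: SoundExperimentSpec | None = None) -> SoundExperiment:
    """Simulate the natural-sound fMRI experiment with known tuning.

    Responses follow ``beta = features @ true_weights``; time series are the
    onset-convolved betas plus white noise at the stated amplitude SNR
    (``snr = inf`` gives noiseless series).  Sounds are distributed over runs
    so each 4-fold split has 126 training and 42 testing sounds.
    """
    spec = spec or SoundExperimentSpec()
    if not (spec.snr > 0):
        raise ValueError("snr must be positive (use numpy.inf for noiseless)")
    if spec.n_sounds % spec.n_runs:
        raise ValueError("n_sounds must be divisible by n_runs")
    rng = np.random.default_rng(spec.seed)
    sounds_per_run = spec.n_sounds // spec.n_runs

    # band-energy features: localized spectral bump per sound, full band coverage
    centers = np.concatenate([
        rng.permutation(spec.n_bands),
        rng.integers(0, spec.n_bands, size=spec.n_sounds - spec.n_bands),
    ]) if spec.n_sounds >= spec.n_bands else rng.integers(0, spec.n_bands, spec.n_sounds)
    band_axis = np.arange(spec.n_bands)
    features = np.exp(-0.5 * ((band_axis[None, :] - centers[:, None]) / spec.feature_bump_sd) ** 2)
    features += spec.feature_noise * rng.random((spec.n_sounds, spec.n_bands))

    # one-hot tuning covering the band axis
    true_bands = np.linspace(0, spec.n_bands - 1, spec.n_vertices).round().astype(int)
    true_bands = rng.permutation(true_bands)
    true_weights = np.zeros((spec.n_bands, spec.n_vertices))
    true_weights[true_bands, np.arange(spec.n_vertices)] = 1.0
    true_betas = features @ true_weights

    hrf = canonical_hrf(spec.hrf_length, spec.tr)
    run_len = spec.first_onset + spec.onset_spacing * sounds_per_run + spec.hrf_length
    sound_order = rng.permutation(spec.n_sounds)
    onsets, run_slices = [], []
    series = []
    t0 = 0
    for r in range(spec.n_runs):
        sounds = sound_order[r * sounds_per_run:(r + 1) * sounds_per_run]
        vols = spec.first_onset + spec.onset_spacing * np.arange(sounds_per_run)
        onsets.append(list(zip(vols.tolist(), sounds.tolist())))
        sig = np.zeros((run_len, spec.n_vertices))
        for v0, snd in zip(vols, sounds):
            sig[v0:v0 + spec.hrf_length] += hrf[:, None] * true_betas[snd][None, :]
        series.append(sig)
        run_slices.append(slice(t0, t0 + run_len))
        t0 += run_len
    series = np.vstack(series)
    if np.isfinite(spec.snr):
        sd = series.std(axis=0, keepdims=True)
        noise_sd = np.where(sd > 0, sd / spec.snr, 0.0)
        series = series + rng.normal(size=series.shape) * noise_sd

    runs = np.arange(spec.n_runs)
    per_fold = spec.n_runs // spec.n_folds
    folds = [runs[f * per_fold:(f + 1) * per_fold].tolist() for f in range(spec.n_folds)]
    return SoundExperiment(features, series, run_slices, onsets, folds,
                           true_bands, true_weights, true_betas, hrf, spec)
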