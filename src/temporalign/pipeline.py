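"""End-to-end comparison of the three alignment methods on a cohort.

Runs spherical rigid alignment, CBA, and CBA+ on a cohort of curvature maps
with landmark indicators and area labels (typically from
:func:`temporalign.synthdata.make_cohort`), transports the labels into
template space with each method's warps, and computes the evaluation
statistics: mean pairwise curvature correlation, group-map sharpness,
landmark-support DICE, and the leave-one-out DICE table per area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import align as al
from . import atlas as at
from . import sphere as sph

__all__ = ["MethodResult", "ComparisonResult", "run_alignment_comparison",
           "run_encoding_experiment"]

HG_AREAS = ("Te1.0", "Te1.1", "Te1.2")


@dataclass
class MethodResult:
    name: str
    warps: list                      # full warp per subject (template -> subject sphere)
    warped_curvature: list
    label_maps: list                 # labels in template space
    mean_pairwise_corr: float
    sharpness: float
    landmark_dice: float
    loo_dice: pd.DataFrame

    @property
    def mean_loo_dice(self) -> float:
        return float(self.loo_dice["Mean"].mean())


@dataclass
class ComparisonResult:
    rigid: MethodResult
    cba: MethodResult
    cba_plus: MethodResult

    def method(self, name: str) -> MethodResult:
        return {"rigid": self.rigid, "cba": self.cba, "cba+": self.cba_plus}[name]


def _pairwise_corr(maps: list) -> float:
    M = np.asarray(maps)
    C = np.corrcoef(M)
    iu = np.triu_indices(len(maps), k=1)
    return float(C[iu].mean())


def _sharpness(warped_curv: list) -> float:
    """Variance of the mean binarized curvature: 1 when all subjects agree."""
    binar = np.where(np.asarray(warped_curv) >= 0, 1.0, -1.0)
    return float(binar.mean(axis=0).var())


def _landmark_dice(label_maps: list, areas=HG_AREAS) -> float:
    """Mean pairwise DICE of the landmark-adjacent area support."""
    supports = [np.isin(m, areas) for m in label_maps]
    vals = [at.dice(supports[i], supports[j])
            for i in range(len(supports)) for j in range(i + 1, len(supports))]
    return float(np.mean(vals))


def _evaluate(name, warps, subjects, mesh, sampler, min_overlap) -> MethodResult:
    curv = [al.apply_warp(s["curvature"], w, mesh, sampler=sampler)
            for s, w in zip(subjects, warps)]
    labels = [al.apply_warp(s["labels"], w, mesh, kind="categorical", sampler=sampler)
              for s, w in zip(subjects, warps)]
    loo = at.loo_dice(labels, min_overlap=min_overlap)
    return MethodResult(
        name=name,
        warps=warps,
        warped_curvature=curv,
        label_maps=labels,
        mean_pairwise_corr=_pairwise_corr(curv),
        sharpness=_sharpness(curv),
        landmark_dice=_landmark_dice(labels),
        loo_dice=loo,
    )


def run_alignment_comparison(
    cohort,
    schedule: al.AlignmentSchedule | None = None,
    min_overlap: int = 4,
    seed: int = 0,
    verbose: bool = False,
) -> ComparisonResult:
    """Align a cohort with rigid, CBA and CBA+, and evaluate each method.

    Rigid runs in two passes (first against subject 0, then against the mean
    of the first-pass aligned maps); both nonlinear methods start from the
    rigid-aligned maps and compose their warps with the rigid rotations.
    """
    schedule = schedule or al.AlignmentSchedule()
    mesh = cohort.mesh
    V = np.asarray(mesh.vertices, dtype=float)
    F = np.asarray(mesh.faces)
    sampler = sph.SphereSampler(V, F)
    subjects = cohort.subjects
    n = len(subjects)

    # --- rigid stage (two passes of group alignment)
    curvs = [s["curvature"] for s in subjects]
    target = curvs[0]
    rotations = [al.rigid_spherical_align(c, target, mesh, seed=seed + i, sampler=sampler)
                 for i, c in enumerate(curvs)]
    aligned = [al.apply_warp(c, al.warp_from_rotation(R, mesh), mesh, sampler=sampler)
               for c, R in zip(curvs, rotations)]
    target = np.mean(aligned, axis=0)
    rotations = [al.rigid_spherical_align(c, target, mesh, seed=seed + n + i, sampler=sampler)
                 for i, c in enumerate(curvs)]
    rigid_warps = [al.warp_from_rotation(R, mesh) for R in rotations]
    rigid_curvs = [al.apply_warp(c, w, mesh, sampler=sampler)
                   for c, w in zip(curvs, rigid_warps)]
    rigid_lms = [
        {name: al.apply_warp(s["landmark_maps"][name], w, mesh, sampler=sampler)
         for name in s["landmark_maps"]}
        for s, w in zip(subjects, rigid_warps)
    ]

    # --- nonlinear stages on the rigid-aligned maps
    cba_warps, _ = al.cba(rigid_curvs, mesh, schedule, verbose=verbose)
    cbap_warps, _ = al.cba_plus(rigid_curvs, rigid_lms, mesh, schedule, verbose=verbose)
    cba_full = [al.compose_rotation(w, R) for w, R in zip(cba_warps, rotations)]
    cbap_full = [al.compose_rotation(w, R) for w, R in zip(cbap_warps, rotations)]

    return ComparisonResult(
        rigid=_evaluate("rigid", rigid_warps, subjects, mesh, sampler, min_overlap),
        cba=_evaluate("cba", cba_full, subjects, mesh, sampler, min_overlap),
        cba_plus=_evaluate("cba+", cbap_full, subjects, mesh, sampler, min_overlap),
    )


def run_encoding_experiment(experiment, penalties=None, n_noise_regressors: int = 5):
    """Two-step GLM plus ridge encoding on a simulated natural-sound session.

    Per cross-validation fold: concatenate the training runs, estimate each
    vertex's hemodynamic response by FIR deconvolution, derive noise
    regressors from the training residuals of a sound-only model, then
    estimate per-sound betas separately for training and test runs with the
    vertex's response.  The ridge stage selects the penalty per vertex by
    test-fold prediction accuracy.  Returns the fitted encoding model.
    """
    from . import invivo as iv

    ex = experiment
    tr_resp, te_resp, tr_idx, te_idx = [], [], [], []
    for f in range(len(ex.folds)):
        test_runs = set(ex.folds[f])

        def _concat(runs):
            segs, ons, off = [], [], 0
            for r in runs:
                sl = ex.run_slices[r]
                segs.append(ex.series[sl])
                ons.extend((off + o, s) for o, s in ex.onsets[r])
                off += sl.stop - sl.start
            return np.vstack(segs), ons

        train_runs = [r for r in range(len(ex.run_slices)) if r not in test_runs]
        Ytr, ons_tr = _concat(train_runs)
        Yte, ons_te = _concat(sorted(test_runs))
        hrf = iv.estimate_hrf(Ytr, [o for o, _ in ons_tr], n_sticks=len(ex.hrf))
        nuis = None
        if n_noise_regressors:
            betas0 = iv.sound_responses(Ytr, hrf, ons_tr, ex.features.shape[0])
            resid = Ytr.copy()
            stick = np.zeros((len(Ytr), ex.features.shape[0]))
            for o, s in ons_tr:
                stick[o, s] = 1.0
            from scipy.signal import fftconvolve

            for v in range(Ytr.shape[1]):
                conv = fftconvolve(stick, hrf[:, v][:, None])[: len(Ytr)]
                resid[:, v] -= conv @ betas0[:, v]
            nuis = iv.noise_regressors(resid, k=n_noise_regressors)
        btr = iv.sound_responses(Ytr, hrf, ons_tr, ex.features.shape[0], nuisance=nuis)
        bte = iv.sound_responses(Yte, hrf, ons_te, ex.features.shape[0])
        tri, tei = ex.fold_sounds(f)
        tr_resp.append(btr[tri])
        te_resp.append(bte[tei])
        tr_idx.append(tri)
        te_idx.append(tei)
    return iv.ridge_encoding(ex.features, tr_resp, te_resp, tr_idx, te_idx,
                             penalties=penalties)
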