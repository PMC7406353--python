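"""Spherical inter-subject alignment: rigid, curvature-driven (CBA), and
curvature plus anatomical-landmark priors (CBA+).

All subjects live on the same standard icosphere and carry a curvature map
(and, for CBA+, smoothed indicator maps of the four temporal landmarks: the
anterior Heschl's gyrus, the superior temporal gyrus and sulcus, and the
middle temporal gyrus).  Rigid alignment finds the rotation minimizing
curvature mismatch.  The nonlinear stages move a per-vertex warp (target
positions on the subject sphere) down the gradient of

    cost = mean_v (c_s(w(v)) - t(v))^2
         + w_lm * mean_lm mean_v (m_s,lm(w(v)) - t_lm(v))^2
         + lambda_reg * mean_e ((|w_i - w_j| - L0_ij) / L0_ij)^2

over a four-level coarse-to-fine schedule (strongly to slightly smoothed
maps).  The group template ``t`` is refreshed from the currently warped
subjects at each level boundary (dynamic group averaging).  Steps that do not
lower the cost, or that flip a spherical triangle, are rejected with a halved
step size, so the recorded cost is non-increasing and warps stay
diffeomorphic at every level's end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import sparse
from scipy.optimize import minimize
from scipy.sparse.csgraph import dijkstra
from scipy.spatial.transform import Rotation as R

from . import sphere as sph
from .surface import count_flipped_faces

__all__ = [
    "AlignmentSchedule",
    "GroupTemplate",
    "landmark_to_map",
    "rigid_spherical_align",
    "rotate_map",
    "warp_from_rotation",
    "compose_rotation",
    "identity_warp",
    "apply_warp",
    "cba",
    "cba_plus",
    "group_average",
]

LANDMARK_NAMES = ("aHG", "STG", "STS", "MTG")


@dataclass
class AlignmentSchedule:
    """Coarse-to-fine schedule: one entry per level, smoothing strictly decreasing."""

    curv_smooth: tuple = (120, 60, 20, 5)
    landmark_smooth: tuple = (120, 60, 20, 5)
    iterations: tuple = (200, 200, 150, 100)
    step_scale: tuple = (0.1, 0.05, 0.025, 0.0125)  # in mean edge lengths
    landmark_weight: float = 1.0
    lambda_reg: float = 1.0

    def __post_init__(self) -> None:
        n = len(self.curv_smooth)
        if not (len(self.landmark_smooth) == len(self.iterations) == len(self.step_scale) == n):
            raise ValueError("schedule fields must have equal length")
        if not all(a > b for a, b in zip(self.curv_smooth[:-1], self.curv_smooth[1:])):
            raise ValueError("curvature smoothing must be strictly decreasing across levels")

    @property
    def n_levels(self) -> int:
        return len(self.curv_smooth)


@dataclass
class GroupTemplate:
    """Group-average curvature (and optionally folded coordinates) on the standard mesh."""

    curvature: np.ndarray
    coords: np.ndarray | None = None
    landmarks: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# landmarks

def landmark_to_map(mesh: trimesh.Trimesh, anchors, smooth_steps: int = 0):
    """Geodesic polyline through ordered anchor vertices and its indicator map.

    The path concatenates shortest edge-paths (edge weights: chord lengths on
    the sphere) between consecutive anchors.  The indicator is 1 on path
    vertices and 0 elsewhere, optionally smoothed by neighbor averaging.
    Returns ``(path_vertex_indices, map)``.
    """
    anchors = [int(a) for a in anchors]
    n = len(mesh.vertices)
    if len(anchors) < 2 or len(set(anchors)) < 2:
        raise ValueError("need at least 2 distinct anchor vertices")
    if any(a < 0 or a >= n for a in anchors):
        raise ValueError("anchor vertex index outside mesh")
    V = np.asarray(mesh.vertices, dtype=float)
    edges = sph.mesh_edges(np.asarray(mesh.faces))
    w = np.linalg.norm(V[edges[:, 0]] - V[edges[:, 1]], axis=1)
    g = sparse.coo_matrix(
        (np.r_[w, w], (np.r_[edges[:, 0], edges[:, 1]], np.r_[edges[:, 1], edges[:, 0]])),
        shape=(n, n),
    ).tocsr()
    path = [anchors[0]]
    for a, b in zip(anchors[:-1], anchors[1:]):
        _, pred = dijkstra(g, indices=a, return_predecessors=True)
        if pred[b] < 0 and a != b:
            raise ValueError(f"no path between anchors {a} and {b}")
        seg = [b]
        while seg[-1] != a:
            seg.append(int(pred[seg[-1]]))
        path.extend(reversed(seg[:-1]))
    indicator = np.zeros(n)
    indicator[path] = 1.0
    if smooth_steps:
        A = sph.averaging_matrix(n, np.asarray(mesh.faces))
        indicator = sph.smooth_map(indicator, A, smooth_steps)
    return np.array(path, dtype=np.int64), indicator


# ---------------------------------------------------------------------------
# rigid stage

def rotate_map(values: np.ndarray, rotation: np.ndarray, sampler: sph.SphereSampler,
               query: np.ndarray) -> np.ndarray:
    """Map values of the rotated sphere: sample source at R^T v."""
    return sampler.interpolate(np.asarray(values, dtype=float), query @ rotation)


def rigid_spherical_align(
    src_curv: np.ndarray,
    tgt_curv: np.ndarray,
    mesh: trimesh.Trimesh,
    n_candidates: int = 1200,
    n_subsample: int = 600,
    seed: int = 0,
    sampler: sph.SphereSampler | None = None,
) -> np.ndarray:
    """Rotation minimizing the mean squared curvature difference.

    Seeded quasi-uniform candidates over SO(3) (nearest-vertex cost on a
    vertex subsample) are refined by Nelder-Mead on the rotation vector with
    the full barycentric cost.  Constant maps return the identity with a
    warning.  The returned R satisfies: rotated source map = src(R^T v).
    """
    src = np.asarray(src_curv, dtype=float)
    tgt = np.asarray(tgt_curv, dtype=float)
    if src.std() == 0 or tgt.std() == 0:
        warnings.warn("constant curvature map: no signal, returning identity rotation")
        return np.eye(3)
    V = np.asarray(mesh.vertices, dtype=float)
    if sampler is None:
        sampler = sph.SphereSampler(V, np.asarray(mesh.faces))
    rng = np.random.default_rng(seed)
    cands = R.random(n_candidates, random_state=rng)
    mats = np.concatenate([np.eye(3)[None], cands.as_matrix()])
    sub = rng.choice(len(V), size=min(n_subsample, len(V)), replace=False)
    qs = V[sub]
    best, best_cost = np.eye(3), np.inf
    for M in mats:
        idx = sampler.nearest_vertex(qs @ M)
        cost = np.mean((src[idx] - tgt[sub]) ** 2)
        if cost < best_cost:
            best, best_cost = M, cost

    refine_sub = rng.choice(len(V), size=min(4 * n_subsample, len(V)), replace=False)

    def refine_cost(rotvec):
        M = R.from_rotvec(rotvec).as_matrix()
        vals = sampler.interpolate(src, V[refine_sub] @ M)
        return np.mean((vals - tgt[refine_sub]) ** 2)

    x0 = R.from_matrix(best).as_rotvec()
    res = minimize(refine_cost, x0, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 250})
    if refine_cost(res.x) <= refine_cost(x0):
        best = R.from_rotvec(res.x).as_matrix()
    id_cost = np.mean((src - tgt) ** 2)
    if np.mean((sampler.interpolate(src, V @ best) - tgt) ** 2) > id_cost:
        best = np.eye(3)
    return best


def identity_warp(mesh: trimesh.Trimesh) -> np.ndarray:
    return np.asarray(mesh.vertices, dtype=float).copy()


def warp_from_rotation(rotation: np.ndarray, mesh: trimesh.Trimesh) -> np.ndarray:
    """Per-vertex warp equivalent to sampling the source at R^T v."""
    return np.asarray(mesh.vertices, dtype=float) @ np.asarray(rotation)


def compose_rotation(warp: np.ndarray, rotation: np.ndarray) -> np.ndarray:
    """Compose a nonlinear warp (on rigid-aligned maps) with the rigid rotation."""
    return np.asarray(warp) @ np.asarray(rotation)


def apply_warp(
    values: np.ndarray,
    warp: np.ndarray,
    mesh: trimesh.Trimesh,
    kind: str = "scalar",
    sampler: sph.SphereSampler | None = None,
) -> np.ndarray:
    """Transport a per-vertex map through a warp.

    Scalars are barycentrically interpolated at the warped positions;
    categorical labels take the nearest source vertex's label.
    """
    warp = np.asarray(warp, dtype=float)
    norms = np.linalg.norm(warp, axis=1)
    if np.abs(norms - 1).max() > 1e-4:
        raise ValueError("warp positions are not unit vectors")
    if sampler is None:
        sampler = sph.SphereSampler(np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.faces))
    values = np.asarray(values)
    if kind == "categorical":
        return values[sampler.nearest_vertex(warp)]
    return sampler.interpolate(values.astype(float), warp)


# ---------------------------------------------------------------------------
# nonlinear stage

def _tangential_gradient(V: np.ndarray, edges: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Per-vertex tangential gradient by one-ring least squares."""
    n = len(V)
    M = np.zeros((n, 3, 3))
    b = np.zeros((n, 3))
    for a, c in ((edges[:, 0], edges[:, 1]), (edges[:, 1], edges[:, 0])):
        d = V[c] - V[a]
        # project into the tangent plane at a
        d = d - (d * V[a]).sum(axis=1, keepdims=True) * V[a]
        dv = values[c] - values[a]
        np.add.at(M, a, d[:, :, None] * d[:, None, :])
        np.add.at(b, a, dv[:, None] * d)
    M += 1e-12 * np.eye(3)
    g = np.linalg.solve(M, b[..., None])[..., 0]
    g = g - (g * V).sum(axis=1, keepdims=True) * V
    return g


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


class _SphereContext:
    """Cached mesh structures shared by the nonlinear alignment."""

    def __init__(self, mesh: trimesh.Trimesh):
        self.mesh = mesh
        self.V = np.asarray(mesh.vertices, dtype=float)
        self.F = np.asarray(mesh.faces)
        self.A = sph.averaging_matrix(len(self.V), self.F)
        self.edges = sph.mesh_edges(self.F)
        self.rest = np.linalg.norm(self.V[self.edges[:, 0]] - self.V[self.edges[:, 1]], axis=1)
        self.mean_edge = float(self.rest.mean())
        self.sampler = sph.SphereSampler(self.V, self.F)


def _reg_cost_grad(w: np.ndarray, ctx: _SphereContext, lam: float):
    e0, e1 = ctx.edges[:, 0], ctx.edges[:, 1]
    d = w[e0] - w[e1]
    ell = np.linalg.norm(d, axis=1)
    rel = (ell - ctx.rest) / ctx.rest
    cost = lam * np.mean(rel ** 2)
    coef = (2.0 * lam / len(ctx.edges)) * rel / (ctx.rest * np.maximum(ell, 1e-12))
    g = np.zeros_like(w)
    np.add.at(g, e0, coef[:, None] * d)
    np.add.at(g, e1, -coef[:, None] * d)
    return cost, g


def _nonlinear_align(
    curvs: list,
    ctx: _SphereContext,
    schedule: AlignmentSchedule,
    landmark_maps: list | None = None,
    init_warps: list | None = None,
    verbose: bool = False,
):
    """Shared implementation of CBA and CBA+ (landmark term active iff maps given)."""
    n_sub = len(curvs)
    n_v = len(ctx.V)
    w_lm = schedule.landmark_weight if landmark_maps is not None else 0.0
    use_lm = landmark_maps is not None and w_lm > 0
    warps = ([w.copy() for w in init_warps] if init_warps
             else [identity_warp(ctx.mesh) for _ in range(n_sub)])
    history = []

    for level in range(schedule.n_levels):
        # level-smoothed, variance-normalized maps
        cs = [_zscore(sph.smooth_map(c, ctx.A, schedule.curv_smooth[level])) for c in curvs]
        grads = [_tangential_gradient(ctx.V, ctx.edges, c) for c in cs]
        if use_lm:
            lms, lm_grads = [], []
            for maps in landmark_maps:
                sm = {}
                gm = {}
                for name, m in maps.items():
                    m2 = sph.smooth_map(m, ctx.A, schedule.landmark_smooth[level])
                    sd = m2.std()
                    m2 = m2 / (sd if sd > 0 else 1.0)
                    sm[name] = m2
                    gm[name] = _tangential_gradient(ctx.V, ctx.edges, m2)
                lms.append(sm)
                lm_grads.append(gm)
            lm_names = list(landmark_maps[0].keys())

        # dynamic group averaging: template from currently-warped subjects
        located = [ctx.sampler.locate(w) for w in warps]
        warped = [ctx.sampler.interpolate_located(cs[s], *located[s]) for s in range(n_sub)]
        template = np.mean(warped, axis=0)
        if use_lm:
            lm_template = {
                name: np.mean(
                    [ctx.sampler.interpolate_located(lms[s][name], *located[s])
                     for s in range(n_sub)], axis=0)
                for name in lm_names
            }

        step0 = schedule.step_scale[level] * ctx.mean_edge
        level_costs = []
        for s in range(n_sub):
            w = warps[s]
            face, bw = located[s]

            def data_cost(face_, bw_):
                r = ctx.sampler.interpolate_located(cs[s], face_, bw_) - template
                c = np.mean(r ** 2)
                if use_lm:
                    for name in lm_names:
                        rl = ctx.sampler.interpolate_located(lms[s][name], face_, bw_) - lm_template[name]
                        c += w_lm * np.mean(rl ** 2) / len(lm_names)
                return c

            reg_c, _ = _reg_cost_grad(w, ctx, schedule.lambda_reg)
            cost = data_cost(face, bw) + reg_c
            step = step0
            costs = [cost]
            stall = 0
            for _ in range(schedule.iterations[level]):
                r = ctx.sampler.interpolate_located(cs[s], face, bw) - template
                G = ctx.sampler.interpolate_located(grads[s], face, bw)
                g = (2.0 / n_v) * r[:, None] * G
                if use_lm:
                    for name in lm_names:
                        rl = ctx.sampler.interpolate_located(lms[s][name], face, bw) - lm_template[name]
                        Gl = ctx.sampler.interpolate_located(lm_grads[s][name], face, bw)
                        g += (2.0 * w_lm / (n_v * len(lm_names))) * rl[:, None] * Gl
                reg_c, reg_g = _reg_cost_grad(w, ctx, schedule.lambda_reg)
                g = g + reg_g
                g = g - (g * w).sum(axis=1, keepdims=True) * w
                gmax = np.linalg.norm(g, axis=1).max()
                if gmax <= 0:
                    break
                g = g / gmax  # step then measures the largest vertex displacement
                accepted = False
                for _try in range(8):
                    w_try = sph.normalize_rows(w - step * g)
                    face_t, bw_t = ctx.sampler.locate(w_try, hint=face)
                    c_try = data_cost(face_t, bw_t) + _reg_cost_grad(w_try, ctx, schedule.lambda_reg)[0]
                    if c_try < cost and count_flipped_faces(w_try, ctx.F) == 0:
                        w, face, bw, cost = w_try, face_t, bw_t, c_try
                        step = min(step * 1.2, 4 * step0)
                        accepted = True
                        break
                    step *= 0.5
                costs.append(cost)
                if not accepted:
                    stall += 1
                    if stall >= 3:
                        break
                elif len(costs) > 11 and costs[-11] - costs[-1] < 1e-7 * max(costs[0], 1e-12):
                    break
            warps[s] = w
            located[s] = (face, bw)
            level_costs.append(costs)
            if verbose:
                print(f"level {level} subject {s}: cost {costs[0]:.5f} -> {costs[-1]:.5f}")
        history.append(level_costs)

    # final template on the least-smoothed maps
    final_cs = [_zscore(sph.smooth_map(c, ctx.A, schedule.curv_smooth[-1])) for c in curvs]
    warped = [apply_warp(final_cs[s], warps[s], ctx.mesh, sampler=ctx.sampler) for s in range(n_sub)]
    template = GroupTemplate(curvature=np.mean(warped, axis=0))
    return warps, template, history


def cba(
    curvs: list,
    mesh: trimesh.Trimesh,
    schedule: AlignmentSchedule | None = None,
    init_warps: list | None = None,
    verbose: bool = False,
):
    """Curvature-based alignment of rigid-pre-aligned subjects.

    Returns ``(warps, group_template)``; each warp gives, per template vertex,
    the position on the subject sphere whose map value it takes.
    """
    if len(curvs) < 2:
        raise ValueError("need at least 2 subjects to align")
    schedule = schedule or AlignmentSchedule()
    ctx = _SphereContext(mesh)
    warps, template, history = _nonlinear_align(
        curvs, ctx, schedule, None, init_warps, verbose)
    cba.last_history = history
    return warps, template


def cba_plus(
    curvs: list,
    landmark_maps: list,
    mesh: trimesh.Trimesh,
    schedule: AlignmentSchedule | None = None,
    init_warps: list | None = None,
    verbose: bool = False,
):
    """CBA with anatomical-landmark priors added to the matching cost.

    `landmark_maps` holds one dict per subject mapping landmark name to its
    per-vertex indicator map; every subject must provide every landmark.
    With ``schedule.landmark_weight == 0`` the result equals :func:`cba`.
    """
    if len(curvs) < 2:
        raise ValueError("need at least 2 subjects to align")
    if len(landmark_maps) != len(curvs):
        raise ValueError("one landmark-map dict per subject required")
    names = set(landmark_maps[0].keys())
    for s, maps in enumerate(landmark_maps):
        missing = names - set(maps.keys())
        for name in names:
            if name not in maps:
                raise ValueError(f"subject {s} is missing landmark '{name}'")
        if set(maps.keys()) != names:
            extra = set(maps.keys()) - names
            raise ValueError(f"subject {s} has unexpected landmark(s) {sorted(extra)}")
    schedule = schedule or AlignmentSchedule()
    ctx = _SphereContext(mesh)
    warps, template, history = _nonlinear_align(
        curvs, ctx, schedule, landmark_maps, init_warps, verbose)
    cba_plus.last_history = history
    return warps, template


def group_average(
    maps_or_coords: list,
    warps: list,
    mesh: trimesh.Trimesh,
    kind: str = "scalar",
) -> np.ndarray:
    """Per-vertex mean of per-subject maps (or 3D coordinates) after warping."""
    if len(maps_or_coords) != len(warps):
        raise ValueError(
            f"{len(maps_or_coords)} maps but {len(warps)} warps: subject counts differ")
    sampler = sph.SphereSampler(np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.faces))
    out = [apply_warp(m, w, mesh, kind=kind, sampler=sampler)
           for m, w in zip(maps_or_coords, warps)]
    return np.mean(out, axis=0)
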