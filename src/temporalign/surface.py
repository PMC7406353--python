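"""Cortical surface reconstruction and spherical standardization.

Meshes are extracted from binary segmentations with marching cubes, checked
for spherical topology (Euler characteristic 2 — the acceptance rule for
every surface), decimated, equipped with a smoothed mean-curvature map
(sulci positive, gyri negative), inflated to the unit sphere, and resampled
onto the standard icosphere so that all subjects share a vertex basis.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from . import sphere as sph
from .decimate import decimate  # re-exported
from .volume import ScalarVolume

__all__ = [
    "extract_mesh",
    "decimate",
    "euler_characteristic",
    "vertex_curvature",
    "inflate_to_sphere",
    "resample_to_standard",
    "count_flipped_faces",
]


def extract_mesh(mask: ScalarVolume) -> trimesh.Trimesh:
    """Closed triangle mesh at the 0.5 iso-level of a binary mask.

    The mask is zero-padded by one voxel so surfaces close at volume borders;
    vertices are mapped to world mm through the mask affine.  The foreground
    must be one connected component.
    """
    data = mask.data.astype(bool)
    if not data.any():
        raise ValueError("empty mask: nothing to extract")
    labels, n_comp = ndimage.label(data)
    if n_comp > 1:
        sizes = ndimage.sum_labels(data, labels, index=range(1, n_comp + 1))
        raise ValueError(
            f"mask has {n_comp} connected components (sizes {sorted(map(int, sizes), reverse=True)}); "
            "expected exactly one"
        )
    padded = np.pad(data, 1).astype(float)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    verts = verts - 1.0  # undo padding
    hom = np.column_stack([verts, np.ones(len(verts))])
    world = (mask.affine @ hom.T).T[:, :3]
    mesh = trimesh.Trimesh(vertices=world, faces=faces, process=False)
    if mesh.volume < 0:  # ensure outward orientation
        mesh.invert()
    return mesh


def euler_characteristic(mesh: trimesh.Trimesh) -> int:
    """V - E + F with E from unique undirected edges (2 for genus-0)."""
    V = len(mesh.vertices)
    F = len(mesh.faces)
    E = len(sph.mesh_edges(np.asarray(mesh.faces)))
    return V - E + F


def vertex_curvature(
    mesh: trimesh.Trimesh, smoothing_steps: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed signed curvature map and its binarization.

    The umbrella estimator projects the displacement toward the one-ring mean
    onto the outward vertex normal: convex (gyral) vertices come out negative,
    concave (sulcal) vertices positive.  `smoothing_steps` rounds of neighbor
    averaging regularize the map; binarization thresholds at 0 into {-1, +1}.
    """
    V = np.asarray(mesh.vertices, dtype=float)
    F = np.asarray(mesh.faces)
    A = sph.averaging_matrix(len(V), F)
    delta = A @ V - V
    normals = np.asarray(mesh.vertex_normals, dtype=float)
    curv = (delta * normals).sum(axis=1)
    curv = sph.smooth_map(curv, A, smoothing_steps)
    binar = np.where(curv >= 0, 1, -1)
    return curv, binar


def count_flipped_faces(vertices: np.ndarray, faces: np.ndarray) -> int:
    """Spherical triangles whose orientation is inward (det[a,b,c] <= 0)."""
    tri = np.asarray(vertices)[np.asarray(faces)]
    det = np.einsum("fi,fi->f", tri[:, 0], np.cross(tri[:, 1], tri[:, 2]))
    return int((det <= 0).sum())


def inflate_to_sphere(mesh: trimesh.Trimesh, n_steps: int = 500) -> trimesh.Trimesh:
    """Inflate a genus-0 mesh to the unit sphere.

    Iterative Laplacian smoothing with centroid re-centering and per-step
    projection to the unit sphere; vertex order (and hence any per-vertex map)
    is preserved.  Extra rounds run if any spherical triangle is still flipped.
    """
    chi = euler_characteristic(mesh)
    if chi != 2:
        raise ValueError(f"mesh is not genus-0 (Euler characteristic {chi}); cannot inflate")
    V = np.asarray(mesh.vertices, dtype=float).copy()
    F = np.asarray(mesh.faces)
    A = sph.averaging_matrix(len(V), F)
    V = V - V.mean(axis=0)
    V = sph.normalize_rows(V)
    for rounds in range(3):
        for _ in range(n_steps):
            V = 0.5 * V + 0.5 * (A @ V)
            V = V - V.mean(axis=0)
            V = sph.normalize_rows(V)
        if count_flipped_faces(V, F) == 0:
            break
    out = trimesh.Trimesh(vertices=V, faces=F.copy(), process=False)
    if out.volume < 0:
        raise RuntimeError("inflation inverted the surface orientation")
    return out


def resample_to_standard(
    sphere_mesh: trimesh.Trimesh,
    maps: dict | None = None,
    level: int = 7,
    categorical: set | None = None,
):
    """Transport per-vertex maps from a subject sphere onto the standard icosphere.

    Scalar maps are barycentrically interpolated inside the containing source
    triangle; maps named in `categorical` take the label of the nearest source
    vertex.  Returns ``(icosphere_mesh, resampled_maps, fallback_count)``.
    """
    V = np.asarray(sphere_mesh.vertices, dtype=float)
    radii = np.linalg.norm(V, axis=1)
    if np.abs(radii - 1).max() > 1e-4:
        raise ValueError("source mesh vertices are not on the unit sphere")
    std = sph.icosphere(level)
    sampler = sph.SphereSampler(V, np.asarray(sphere_mesh.faces))
    out: dict = {}
    categorical = categorical or set()
    q = np.asarray(std.vertices, dtype=float)
    face, w = sampler.locate(q)
    nearest = sampler.nearest_vertex(q)
    for name, values in (maps or {}).items():
        values = np.asarray(values)
        if len(values) != len(V):
            raise ValueError(f"map '{name}' length {len(values)} != vertex count {len(V)}")
        if name in categorical:
            out[name] = values[nearest]
        else:
            out[name] = sampler.interpolate_located(values.astype(float), face, w)
    return std, out, sampler.fallback_count
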