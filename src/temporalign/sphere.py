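"""Spherical mesh primitives: standard icospheres, neighbor smoothing, and
barycentric sampling of per-vertex maps at arbitrary directions.

The standard mesh is the recursively subdivided icosahedron; level ``L`` has
``10 * 4**L + 2`` vertices (level 7: 163842, the registration-grade density).
:class:`SphereSampler` locates unit directions inside spherical triangles by
central (gnomonic) projection and returns barycentric weights, the primitive
behind map resampling, warp application, and the registration cost.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy import sparse
from scipy.spatial import cKDTree

__all__ = [
    "icosphere",
    "icosphere_vertex_count",
    "normalize_rows",
    "mesh_edges",
    "averaging_matrix",
    "smooth_map",
    "SphereSampler",
]


def icosphere_vertex_count(level: int) -> int:
    return 10 * 4 ** level + 2


def icosphere(level: int) -> trimesh.Trimesh:
    """Standard unit icosphere at the given subdivision level."""
    if level < 0:
        raise ValueError("level must be non-negative")
    mesh = trimesh.creation.icosphere(subdivisions=level, radius=1.0)
    assert len(mesh.vertices) == icosphere_vertex_count(level)
    return trimesh.Trimesh(
        vertices=normalize_rows(np.asarray(mesh.vertices, dtype=float)),
        faces=np.asarray(mesh.faces),
        process=False,
    )


def normalize_rows(x: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(x, axis=-1, keepdims=True)
    return x / np.where(n == 0, 1.0, n)


def mesh_edges(faces: np.ndarray) -> np.ndarray:
    """Unique undirected edges (m, 2) of a triangle list."""
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e.sort(axis=1)
    return np.unique(e, axis=0)


def averaging_matrix(n_vertices: int, faces: np.ndarray) -> sparse.csr_matrix:
    """Row-stochastic one-ring neighbor averaging operator."""
    edges = mesh_edges(np.asarray(faces))
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    A = sparse.coo_matrix((np.ones(len(i)), (i, j)), shape=(n_vertices, n_vertices)).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    if (deg == 0).any():
        raise ValueError("mesh has isolated vertices")
    inv = sparse.diags(1.0 / deg)
    return (inv @ A).tocsr()


def smooth_map(values: np.ndarray, A: sparse.csr_matrix, steps: int) -> np.ndarray:
    """`steps` rounds of neighbor averaging (contracts variance; keeps constants)."""
    out = np.asarray(values, dtype=float).copy()
    for _ in range(steps):
        out = A @ out
    return out


class SphereSampler:
    """Barycentric sampling of per-vertex data on a spherical triangulation.

    Queries are unit directions; each is located in the spherical triangle
    containing it (central projection: solve ``[a b c] x = q``, all ``x >= 0``)
    via the faces incident to its nearest vertices.  Directions that hit no
    triangle numerically fall back to the nearest vertex; the count is kept in
    ``fallback_count``.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.vertices = normalize_rows(np.asarray(vertices, dtype=float))
        self.faces = np.asarray(faces, dtype=np.int64)
        self.tree = cKDTree(self.vertices)
        n = len(self.vertices)
        # padded vertex -> incident faces table
        counts = np.zeros(n, dtype=int)
        for k in range(3):
            np.add.at(counts, self.faces[:, k], 1)
        maxdeg = int(counts.max())
        table = np.zeros((n, maxdeg), dtype=np.int64)
        fill = np.zeros(n, dtype=int)
        for fi, tri in enumerate(self.faces):
            for v in tri:
                table[v, fill[v]] = fi
                fill[v] += 1
        # pad unused slots with the first incident face (harmless duplicates)
        for v in range(n):
            table[v, fill[v]:] = table[v, 0]
        self.vertex_faces = table
        self.fallback_count = 0

    def _candidate_weights(self, q: np.ndarray, cand: np.ndarray):
        """Barycentric weights of q in each candidate face; (nq, c, 3)."""
        tri = self.vertices[self.faces[cand]]          # (nq, c, 3 verts, 3)
        A = np.swapaxes(tri, -1, -2)                   # columns are vertices
        b = np.broadcast_to(q[:, None, :], cand.shape + (3,))
        x = np.linalg.solve(A, b[..., None])[..., 0]
        s = x.sum(axis=-1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = x / np.where(s == 0, 1.0, s)
        return w

    def locate(self, query: np.ndarray, tol: float = 1e-9, hint: np.ndarray | None = None):
        """Containing face and barycentric weights for each unit direction.

        Returns ``(face_index, weights)`` with shapes (nq,), (nq, 3).  `hint`
        may give a likely containing face per query (e.g. from a previous
        nearby call); queries still inside their hint skip the search.
        """
        q = normalize_rows(np.atleast_2d(np.asarray(query, dtype=float)))
        if hint is not None:
            face = np.asarray(hint, dtype=np.int64).copy()
            w = self._candidate_weights(q, face[:, None])[:, 0]
            miss = w.min(axis=-1) < -tol
            if miss.any():
                f2, w2 = self.locate(q[miss], tol=tol)
                face[miss] = f2
                w[miss] = w2
            w = np.clip(w, 0.0, None)
            w /= w.sum(axis=-1, keepdims=True)
            return face, w
        _, nearest = self.tree.query(q, k=1)
        cand = self.vertex_faces[nearest]              # (nq, c)
        w = self._candidate_weights(q, cand)
        score = w.min(axis=-1)
        best = score.argmax(axis=-1)
        rows = np.arange(len(q))
        face = cand[rows, best]
        weights = w[rows, best]
        bad = score[rows, best] < -tol
        if bad.any():
            # widen the search to the faces of the 6 nearest vertices
            _, knn = self.tree.query(q[bad], k=min(6, len(self.vertices)))
            cand2 = self.vertex_faces[knn].reshape(len(knn), -1)
            w2 = self._candidate_weights(q[bad], cand2)
            score2 = w2.min(axis=-1)
            best2 = score2.argmax(axis=-1)
            rows2 = np.arange(len(cand2))
            face[bad] = cand2[rows2, best2]
            weights[bad] = w2[rows2, best2]
            still = np.flatnonzero(bad)[score2[rows2, best2] < -1e-6]
            if len(still):
                # nearest-vertex fallback
                self.fallback_count += len(still)
                nv = nearest[still]
                f = self.vertex_faces[nv, 0]
                face[still] = f
                wfall = np.zeros((len(still), 3))
                for k, (fi, v) in enumerate(zip(f, nv)):
                    wfall[k, list(self.faces[fi]).index(v)] = 1.0
                weights[still] = wfall
        weights = np.clip(weights, 0.0, None)
        weights /= weights.sum(axis=-1, keepdims=True)
        return face, weights

    def interpolate(self, values: np.ndarray, query: np.ndarray) -> np.ndarray:
        """Barycentric interpolation of per-vertex scalar(s) at unit directions."""
        face, w = self.locate(query)
        return self.interpolate_located(values, face, w)

    def interpolate_located(self, values: np.ndarray, face: np.ndarray, w: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        corner = values[self.faces[face]]              # (nq, 3[, k])
        if corner.ndim == 3:
            return np.einsum("qc,qck->qk", w, corner)
        return (w * corner).sum(axis=-1)

    def nearest_vertex(self, query: np.ndarray) -> np.ndarray:
        q = normalize_rows(np.atleast_2d(np.asarray(query, dtype=float)))
        _, idx = self.tree.query(q, k=1)
        return idx
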