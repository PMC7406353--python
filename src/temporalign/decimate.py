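"""Topology-preserving mesh decimation by quadric edge collapse.

Edges are collapsed to their midpoint in ascending order of a cost that
combines the quadric (plane-distance) error with the squared edge length; the
length term drives the result toward approximately equal edge lengths.  Each
collapse is guarded by the edge link condition (manifoldness) and a normal
flip check, so the Euler characteristic is preserved.
"""

from __future__ import annotations

import heapq

import numpy as np
import trimesh

__all__ = ["decimate"]


def _vertex_quadrics(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    tri = vertices[faces]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    n = n / np.where(norm == 0, 1.0, norm)
    d = -(n * tri[:, 0]).sum(axis=1)
    p = np.hstack([n, d[:, None]])                    # plane coefficients
    K = p[:, :, None] * p[:, None, :]                 # (F, 4, 4)
    Q = np.zeros((len(vertices), 4, 4))
    for k in range(3):
        np.add.at(Q, faces[:, k], K)
    return Q


def _quadric_error(Q: np.ndarray, pos: np.ndarray) -> float:
    h = np.append(pos, 1.0)
    return float(h @ Q @ h)


def decimate(mesh: trimesh.Trimesh, target_vertices: int) -> trimesh.Trimesh:
    """Collapse edges until the vertex count reaches `target_vertices`.

    Returns the input unchanged if it already has no more than the target.
    Raises if no further collapse can be performed without breaking
    manifoldness before the target is reached.
    """
    if target_vertices < 4:
        raise ValueError("target must be at least 4 vertices")
    V = np.asarray(mesh.vertices, dtype=float).copy()
    F = np.asarray(mesh.faces, dtype=np.int64)
    n = len(V)
    if n <= target_vertices:
        return trimesh.Trimesh(vertices=V, faces=F.copy(), process=False)

    quadrics = _vertex_quadrics(V, F)
    faces = {i: list(tri) for i, tri in enumerate(F)}
    vfaces = {v: set() for v in range(n)}
    for fi, tri in faces.items():
        for v in tri:
            vfaces[v].add(fi)
    alive = np.ones(n, dtype=bool)
    version = np.zeros(n, dtype=np.int64)

    def neighbors(v):
        out = set()
        for fi in vfaces[v]:
            out.update(faces[fi])
        out.discard(v)
        return out

    def edge_cost(u, v):
        mid = 0.5 * (V[u] + V[v])
        q = _quadric_error(quadrics[u] + quadrics[v], mid)
        length2 = float(((V[u] - V[v]) ** 2).sum())
        return length2 + q, mid

    heap = []
    seen = set()
    for fi, tri in faces.items():
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            key = (min(a, b), max(a, b))
            if key not in seen:
                seen.add(key)
                c, _ = edge_cost(*key)
                heapq.heappush(heap, (c, key[0], key[1], 0, 0))

    n_alive = n
    while n_alive > target_vertices and heap:
        cost, u, v, vu, vv = heapq.heappop(heap)
        if not (alive[u] and alive[v]) or vu != version[u] or vv != version[v]:
            continue
        shared = vfaces[u] & vfaces[v]
        if len(shared) != 2:
            continue
        # link condition: common neighbors must be exactly the two apexes
        apex = set()
        for fi in shared:
            apex.update(faces[fi])
        apex -= {u, v}
        if neighbors(u) & neighbors(v) != apex:
            continue
        mid = 0.5 * (V[u] + V[v])
        # normal flip guard on surviving incident faces
        flip = False
        for fi in (vfaces[u] | vfaces[v]) - shared:
            tri = faces[fi]
            old = [V[w] for w in tri]
            new = [mid if w in (u, v) else V[w] for w in tri]
            n_old = np.cross(old[1] - old[0], old[2] - old[0])
            n_new = np.cross(new[1] - new[0], new[2] - new[0])
            if np.dot(n_old, n_new) <= 0:
                flip = True
                break
        if flip:
            continue
        # collapse v into u at the midpoint
        V[u] = mid
        quadrics[u] = quadrics[u] + quadrics[v]
        for fi in shared:
            for w in faces[fi]:
                vfaces[w].discard(fi)
            del faces[fi]
        for fi in list(vfaces[v]):
            tri = faces[fi]
            faces[fi] = [u if w == v else w for w in tri]
            vfaces[u].add(fi)
            vfaces[v].discard(fi)
        alive[v] = False
        version[u] += 1
        n_alive -= 1
        for w in neighbors(u):
            c, _ = edge_cost(u, w)
            heapq.heappush(heap, (c, min(u, w), max(u, w), version[min(u, w)], version[max(u, w)]))

    if n_alive > target_vertices:
        raise RuntimeError(
            f"decimation stalled at {n_alive} vertices (target {target_vertices}): "
            "no collapse preserves manifoldness"
        )
    # compact
    keep = np.flatnonzero(alive)
    remap = -np.ones(n, dtype=np.int64)
    remap[keep] = np.arange(len(keep))
    new_faces = np.array([[remap[w] for w in tri] for tri in faces.values()], dtype=np.int64)
    out = trimesh.Trimesh(vertices=V[keep], faces=new_faces, process=False)
    return _tangential_relax(out, rounds=20)


def _tangential_relax(mesh: trimesh.Trimesh, rounds: int) -> trimesh.Trimesh:
    """Equalize edge lengths by tangential Laplacian relaxation.

    Vertices move toward their one-ring centroid, with the motion projected
    into the local tangent plane so the shape is preserved.  Rounds that
    would flip a face normal are rolled back vertex-wise.
    """
    V = np.asarray(mesh.vertices, dtype=float).copy()
    F = np.asarray(mesh.faces)
    e = np.vstack([F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]])
    e.sort(axis=1)
    e = np.unique(e, axis=0)
    deg = np.zeros(len(V))
    np.add.at(deg, e[:, 0], 1)
    np.add.at(deg, e[:, 1], 1)
    for _ in range(rounds):
        normals = trimesh.Trimesh(vertices=V, faces=F, process=False).vertex_normals
        centroid = np.zeros_like(V)
        np.add.at(centroid, e[:, 0], V[e[:, 1]])
        np.add.at(centroid, e[:, 1], V[e[:, 0]])
        centroid /= deg[:, None]
        d = 0.5 * (centroid - V)
        d -= (d * normals).sum(axis=1, keepdims=True) * normals
        V_new = V + d
        tri = V_new[F]
        n_new = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        tri0 = V[F]
        n_old = np.cross(tri0[:, 1] - tri0[:, 0], tri0[:, 2] - tri0[:, 0])
        bad_faces = (n_new * n_old).sum(axis=1) <= 0
        if bad_faces.any():
            frozen = np.unique(F[bad_faces])
            V_new[frozen] = V[frozen]
        V = V_new
    return trimesh.Trimesh(vertices=V, faces=F, process=False)
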