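"""File round-trips for meshes, per-vertex maps, warps and landmarks.

Surfaces are read/written as GIfTI (via nibabel) or plain OBJ; per-vertex
scalar maps as GIfTI functional files or two-column CSV
(``vertex_index,value``); warps as per-vertex unit-vector CSV tables;
landmark polylines as JSON ``{name, anchor_vertices, path_vertices}``.
Vertex indices are 0-based everywhere.
"""

from __future__ import annotations

import json

import nibabel as nib
import numpy as np
import trimesh


def save_gifti_mesh(mesh: trimesh.Trimesh, path) -> None:
    img = nib.gifti.GiftiImage(darrays=[
        nib.gifti.GiftiDataArray(
            np.asarray(mesh.vertices, dtype=np.float32), intent="NIFTI_INTENT_POINTSET"),
        nib.gifti.GiftiDataArray(
            np.asarray(mesh.faces, dtype=np.int32), intent="NIFTI_INTENT_TRIANGLE"),
    ])
    nib.save(img, str(path))


def load_gifti_mesh(path) -> trimesh.Trimesh:
    img = nib.load(str(path))
    verts = faces = None
    for arr in img.darrays:
        if arr.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
            verts = np.asarray(arr.data, dtype=float)
        elif arr.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
            faces = np.asarray(arr.data, dtype=np.int64)
    if verts is None or faces is None:
        raise ValueError(f"{path}: GIfTI file lacks POINTSET/TRIANGLE arrays")
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def save_obj_mesh(mesh: trimesh.Trimesh, path) -> None:
    mesh.export(str(path), file_type="obj")


def load_obj_mesh(path) -> trimesh.Trimesh:
    m = trimesh.load(str(path), file_type="obj", process=False)
    return trimesh.Trimesh(vertices=np.asarray(m.vertices), faces=np.asarray(m.faces),
                           process=False)


def save_gifti_map(values: np.ndarray, path) -> None:
    img = nib.gifti.GiftiImage(darrays=[
        nib.gifti.GiftiDataArray(np.asarray(values, dtype=np.float32),
                                 intent="NIFTI_INTENT_SHAPE")])
    nib.save(img, str(path))


def load_gifti_map(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.darrays[0].data, dtype=float)


def save_map_csv(values: np.ndarray, path) -> None:
    values = np.asarray(values)
    with open(path, "w") as fh:
        fh.write("vertex_index,value\n")
        for i, v in enumerate(values):
            fh.write(f"{i},{v}\n")


def load_map_csv(path, dtype=float) -> np.ndarray:
    idx, vals = [], []
    with open(path) as fh:
        next(fh)
        for line in fh:
            i, v = line.rstrip("\n").split(",", 1)
            idx.append(int(i))
            vals.append(v)
    out = np.empty(len(vals), dtype=object if dtype is str else dtype)
    for i, v in zip(idx, vals):
        out[i] = v if dtype is str else dtype(v)
    return out.astype(str) if dtype is str else out


def save_warp_csv(warp: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(warp, dtype=float), delimiter=",",
               header="x,y,z", comments="")


def load_warp_csv(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", skiprows=1)


def save_landmark_json(name: str, anchors, path_vertices, path) -> None:
    with open(path, "w") as fh:
        json.dump({
            "name": name,
            "anchor_vertices": [int(a) for a in anchors],
            "path_vertices": [int(p) for p in path_vertices],
        }, fh, indent=1)


def load_landmark_json(path) -> dict:
    with open(path) as fh:
        obj = json.load(fh)
    return {
        "name": obj["name"],
        "anchor_vertices": np.asarray(obj["anchor_vertices"], dtype=np.int64),
        "path_vertices": np.asarray(obj["path_vertices"], dtype=np.int64),
    }
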