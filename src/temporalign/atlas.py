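"""Probabilistic surface atlas construction and overlap evaluation.

After alignment, each subject contributes a categorical area-label map on the
standard mesh.  The probabilistic atlas counts, per vertex and area, how many
subjects label that vertex; overlap histograms summarize the counts per area;
leave-one-subject-out DICE quantifies how well an atlas built from N-1
subjects (vertices labeled by at least `min_overlap` of them) predicts the
held-out subject's area.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "BACKGROUND",
    "probabilistic_map",
    "overlap_histogram",
    "dice",
    "loo_dice",
]

BACKGROUND = "none"


def _check_same_mesh(labels: list) -> int:
    sizes = {len(np.asarray(m)) for m in labels}
    if len(sizes) != 1:
        raise ValueError(f"label maps live on different meshes (lengths {sorted(sizes)})")
    return sizes.pop()


def _areas(labels: list) -> list:
    out = set()
    for m in labels:
        out.update(np.unique(np.asarray(m)))
    out.discard(BACKGROUND)
    return sorted(out)


def probabilistic_map(labels: list) -> dict:
    """Per-area, per-vertex count of subjects labeling the vertex with that area.

    Returns ``{area: counts}`` with integer counts in [0, N].
    """
    if len(labels) < 1:
        raise ValueError("need at least one label map")
    n_v = _check_same_mesh(labels)
    atlas = {}
    for area in _areas(labels):
        counts = np.zeros(n_v, dtype=np.int64)
        for m in labels:
            counts += np.asarray(m) == area
        atlas[area] = counts
    return atlas


def overlap_histogram(atlas: dict, area: str, n_subjects: int):
    """Frequencies of overlap levels 1..N for one area, normalized to sum 1.

    The denominator is the number of vertices with count >= 1 (the union
    support of the area).  Also returns the left-skew statistic: mass at
    level 1 minus mass at level N.
    """
    if area not in atlas:
        raise ValueError(f"area '{area}' absent from the atlas")
    counts = np.asarray(atlas[area])
    support = counts >= 1
    if not support.any():
        raise ValueError(f"area '{area}' labels no vertex in any subject")
    levels = np.arange(1, n_subjects + 1)
    freq = np.array([(counts == k).sum() for k in levels], dtype=float)
    freq /= support.sum()
    left_skew = freq[0] - freq[-1]
    return levels, freq, left_skew


def dice(a, b) -> float:
    """DICE overlap 2|A∩B| / (|A|+|B|) of two vertex sets (bool masks or index sets)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.dtype == bool and b.dtype == bool:
        if len(a) != len(b):
            raise ValueError("boolean masks live on different meshes")
        inter = np.logical_and(a, b).sum()
        na, nb = a.sum(), b.sum()
    else:
        sa, sb = set(np.asarray(a).ravel().tolist()), set(np.asarray(b).ravel().tolist())
        inter = len(sa & sb)
        na, nb = len(sa), len(sb)
    if na + nb == 0:
        warnings.warn("DICE of two empty sets: defined as 0")
        return 0.0
    return 2.0 * inter / (na + nb)


def loo_dice(labels: list, min_overlap: int = 4, subject_names: list | None = None) -> pd.DataFrame:
    """Leave-one-subject-out DICE table (areas x subjects, plus Mean/Std. Dev.).

    For each left-out subject, the per-area atlas region is the set of
    vertices labeled by at least `min_overlap` of the remaining N-1 subjects;
    the cell is the DICE between that region and the left-out subject's area.
    An area absent from the training subjects scores 0 (with a warning).
    """
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if not (1 <= min_overlap <= n - 1):
        raise ValueError(f"min_overlap must be in [1, {n - 1}]")
    _check_same_mesh(labels)
    labels = [np.asarray(m) for m in labels]
    areas = _areas(labels)
    names = subject_names or [f"sub-{i + 1:02d}" for i in range(n)]
    table = pd.DataFrame(index=areas, columns=names, dtype=float)
    for i in range(n):
        train = [labels[j] for j in range(n) if j != i]
        atlas = probabilistic_map(train)
        for area in areas:
            region = atlas.get(area, np.zeros(len(labels[i]), dtype=np.int64)) >= min_overlap
            subj = labels[i] == area
            if not region.any():
                warnings.warn(
                    f"area '{area}' has no atlas support at min_overlap={min_overlap} "
                    f"when leaving out {names[i]}")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table.loc[area, names[i]] = dice(region, subj)
    table["Mean"] = table[names].mean(axis=1)
    table["Std. Dev."] = table[names].std(axis=1, ddof=0)
    return table
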