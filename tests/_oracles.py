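"""Independent brute-force oracles used to cross-check the texture code.

These deliberately use naive O(N^2) pairwise / per-voxel loops and share no
code with the package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_nglcm(levels: np.ndarray, mask: np.ndarray, n_bins: int,
                distance: int = 1) -> np.ndarray:
    """Co-occurrence matrix by looping over all ordered voxel pairs."""
    counts = np.zeros((n_bins, n_bins))
    idx = list(zip(*np.nonzero(mask)))
    inside = set(idx)
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for (x, y, z) in idx:
        for (dx, dy, dz) in offsets:
            nb = (x + distance * dx, y + distance * dy, z + distance * dz)
            if nb in inside:
                counts[levels[x, y, z] - 1, levels[nb] - 1] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def brute_nglcm_features(p: np.ndarray) -> dict:
    nb = p.shape[0]
    uni = ent = dis = hom = idm = 0.0
    for i in range(nb):
        for j in range(nb):
            v = p[i, j]
            uni += v * v
            if v > 0:
                ent -= v * math.log2(v)
            d = abs(i - j)
            dis += v * d
            hom += v / (1 + d)
            idm += v / (1 + d * d)
    return {"uniformity": uni, "entropy_bits": ent, "dissimilarity": dis,
            "homogeneity": hom, "inverse_difference_moment": idm}


def brute_ngtdm(levels: np.ndarray, mask: np.ndarray,
                n_bins: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-voxel 26-neighborhood difference table by explicit looping."""
    s = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    n = 0
    shape = levels.shape
    for (x, y, z) in zip(*np.nonzero(mask)):
        nbr = []
        for dx, dy, dz in itertools.product((-1, 0, 1), repeat=3):
            if (dx, dy, dz) == (0, 0, 0):
                continue
            xx, yy, zz = x + dx, y + dy, z + dz
            if 0 <= xx < shape[0] and 0 <= yy < shape[1] and 0 <= zz < shape[2]:
                if mask[xx, yy, zz]:
                    nbr.append(levels[xx, yy, zz])
        if not nbr:
            continue
        n += 1
        lev = levels[x, y, z]
        s[lev - 1] += abs(lev - sum(nbr) / len(nbr))
        counts[lev - 1] += 1
    p_i = counts / n if n else counts
    return s, p_i, n


def brute_ngtdm_features(s: np.ndarray, p_i: np.ndarray, n: int,
                         eps: float = 1e-6) -> dict:
    occ = [i for i in range(len(p_i)) if p_i[i] > 0]
    ng = len(occ)
    coars = 1.0 / (eps + sum(p_i[i] * s[i] for i in occ))
    if ng < 2:
        return {"coarseness": coars, "contrast": None, "busyness": None,
                "complexity": None}
    contrast = (
        sum(p_i[i] * p_i[j] * ((i - j) ** 2) for i in occ for j in occ)
        / (ng * (ng - 1))
    ) * (sum(s) / n)
    denom = sum(
        abs((i + 1) * p_i[i] - (j + 1) * p_i[j]) for i in occ for j in occ if i != j
    )
    busy = sum(p_i[i] * s[i] for i in occ) / denom if denom > 0 else None
    comp = sum(
        abs(i - j) * (p_i[i] * s[i] + p_i[j] * s[j]) / (p_i[i] + p_i[j])
        for i in occ for j in occ if i != j
    ) / n
    return {"coarseness": coars, "contrast": contrast, "busyness": busy,
            "complexity": comp}


def flood_fill_components(mask: np.ndarray) -> list[set]:
    """26-connected components by explicit BFS flood fill."""
    shape = mask.shape
    seen = set()
    comps = []
    for start in zip(*np.nonzero(mask)):
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        seen.add(start)
        while stack:
            x, y, z = stack.pop()
            for dx, dy, dz in itertools.product((-1, 0, 1), repeat=3):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                nb = (x + dx, y + dy, z + dz)
                if (
                    0 <= nb[0] < shape[0] and 0 <= nb[1] < shape[1]
                    and 0 <= nb[2] < shape[2] and mask[nb] and nb not in seen
                ):
                    seen.add(nb)
                    comp.add(nb)
                    stack.append(nb)
        comps.append(comp)
    return comps
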