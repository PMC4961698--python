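"""Independent brute-force oracles for the test suite.

Everything here is written as literally as possible — plain Python
loops over voxels, offsets and block members — and shares no code with
the package's vote kernel.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np


def voxelized_sphere_count(shape, center, radius) -> int:
    """Count voxels inside a sphere by exhaustive grid scan."""
    n = 0
    cx, cy, cz = center
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= radius**2:
                    n += 1
    return n


def trimmed_mean(values, center, trim_fraction=0.25) -> float:
    """Mean of the values closest to `center`, dropping the far fraction."""
    values = np.sort(np.asarray(values, dtype=float))
    order = np.argsort(np.abs(values - center), kind="stable")
    n_keep = max(1, int(np.ceil((1 - trim_fraction) * values.size)))
    return float(values[order[:n_keep]].mean())


def _ss(p: np.ndarray, q: np.ndarray) -> float:
    mp, mq = p.mean(), q.mean()
    vp, vq = p.var(), q.var()
    mterm = 1.0 if mp * mp + mq * mq == 0 else 2 * mp * mq / (mp * mp + mq * mq)
    sterm = 1.0 if vp + vq == 0 else 2 * math.sqrt(vp) * math.sqrt(vq) / (vp + vq)
    return mterm * sterm


def _cropped_pair(subj, timg, c, j, pr):
    """Identically-cropped patch pair around subject voxel c / template voxel j."""
    shape = subj.shape
    lo = [max(-pr, -c[a], -j[a]) for a in range(3)]
    hi = [min(pr, shape[a] - 1 - c[a], shape[a] - 1 - j[a]) for a in range(3)]
    sp = tuple(slice(c[a] + lo[a], c[a] + hi[a] + 1) for a in range(3))
    sq = tuple(slice(j[a] + lo[a], j[a] + hi[a] + 1) for a in range(3))
    return subj[sp].astype(float), timg[sq].astype(float)


def brute_force_votes(
    subj,
    timgs,
    tlabs,
    mask,
    *,
    patch_size=3,
    search_radius=4,
    block_size=1,
    lam=0.15,
    eps=1e-4,
    th=0.9,
    sigma_d=math.sqrt(2.0),
    voxel_size=(1.0, 1.0, 1.0),
    normalize_blocks=False,
):
    """Literal triple-loop block-wise non-local label fusion.

    Returns (votes, labels): votes has shape (L, *grid), normalized per
    voxel after summing over all overlapping blocks; labels is the
    sorted union of template labels. With block_size == 1 this is the
    plain voxel-wise weighted label vote.
    """
    subj = np.asarray(subj, dtype=float)
    shape = subj.shape
    S = len(timgs)
    labels = np.unique(np.concatenate([np.unique(t) for t in tlabs]))
    lab_index = {int(k): i for i, k in enumerate(labels)}
    pr, sr, br = patch_size // 2, search_radius, block_size // 2
    acc = np.zeros((labels.size,) + shape)

    for c in np.argwhere(np.asarray(mask, dtype=bool)):
        c = tuple(int(v) for v in c)
        cands = []
        for s in range(S):
            for off in product(range(-sr, sr + 1), repeat=3):
                j = tuple(c[a] + off[a] for a in range(3))
                if not all(0 <= j[a] < shape[a] for a in range(3)):
                    continue
                p, q = _cropped_pair(subj, np.asarray(timgs[s], dtype=float), c, j, pr)
                ssd = float(((p - q) ** 2).sum())
                cands.append((s, j, off, ssd, _ss(p, q)))
        if not cands:
            continue
        h2 = lam * min(cd[3] for cd in cands) + eps
        weights = []
        for s, j, off, ssd, ss in cands:
            if ss > th:
                d2 = sum((off[a] * voxel_size[a]) ** 2 for a in range(3))
                w = math.exp(-d2 / (2 * sigma_d**2)) * math.exp(-ssd / h2)
            else:
                w = 0.0
            weights.append(w)
        total = sum(weights)
        if total <= 0:
            continue
        for (s, j, off, ssd, ss), w in zip(cands, weights):
            if w <= 0:
                continue
            val = w / total if normalize_blocks else w
            for b in product(range(-br, br + 1), repeat=3):
                t = tuple(c[a] + b[a] for a in range(3))
                u = tuple(j[a] + b[a] for a in range(3))
                if all(0 <= t[a] < shape[a] for a in range(3)) and all(
                    0 <= u[a] < shape[a] for a in range(3)
                ):
                    acc[lab_index[int(tlabs[s][u])]][t] += val

    tot = acc.sum(axis=0)
    voted = tot > 0
    acc[:, voted] /= tot[voted]
    return acc, labels
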