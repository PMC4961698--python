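"""Compiled inner loops for block-wise non-local vote accumulation.

The kernel walks every masked block center, compares the subject patch
against every template patch in the search volume (cropping both
patches identically at grid borders), gates on structural similarity,
converts squared distances to weights with the adaptive bandwidth, and
scatters each weight onto the whole label block around the matched
template voxel. Normalization happens in the caller.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["blockwise_vote_kernel"]


@njit(cache=True)
def blockwise_vote_kernel(
    subj,  # (nx, ny, nz) float64
    timgs,  # (S, nx, ny, nz) float64
    tlabs,  # (S, nx, ny, nz) int32 — contiguous label indices
    centers,  # (K, 3) int64 — masked block centers
    patch_r,  # int
    search_r,  # int
    block_r,  # int
    lam,  # float
    eps,  # float
    th,  # float
    swt,  # (2*search_r+1,)*3 float64 — spatial weight per offset
    normalize_blocks,  # bool: divide each block's votes by its weight sum
    votes,  # (L, nx, ny, nz) float64 — accumulated in place
):
    nx, ny, nz = subj.shape
    S = timgs.shape[0]
    W = 2 * search_r + 1
    ncand = S * W * W * W
    ssd = np.empty(ncand)
    ssv = np.empty(ncand)
    wts = np.empty(ncand)
    valid = np.zeros(ncand, np.uint8)

    for c in range(centers.shape[0]):
        zx = centers[c, 0]
        zy = centers[c, 1]
        zz = centers[c, 2]

        # Pass 1: patch stats (SSD + structural similarity) per candidate.
        idx = 0
        minssd = 1.0e300
        anyvalid = False
        for s in range(S):
            for ox in range(-search_r, search_r + 1):
                jx = zx + ox
                for oy in range(-search_r, search_r + 1):
                    jy = zy + oy
                    for oz in range(-search_r, search_r + 1):
                        jz = zz + oz
                        if (
                            jx < 0
                            or jx >= nx
                            or jy < 0
                            or jy >= ny
                            or jz < 0
                            or jz >= nz
                        ):
                            valid[idx] = 0
                            idx += 1
                            continue
                        # identical cropping for both patches
                        xlo = -patch_r
                        if zx + xlo < 0:
                            xlo = -zx
                        if jx + xlo < 0:
                            xlo = -jx
                        xhi = patch_r
                        if zx + xhi > nx - 1:
                            xhi = nx - 1 - zx
                        if jx + xhi > nx - 1:
                            xhi = nx - 1 - jx
                        ylo = -patch_r
                        if zy + ylo < 0:
                            ylo = -zy
                        if jy + ylo < 0:
                            ylo = -jy
                        yhi = patch_r
                        if zy + yhi > ny - 1:
                            yhi = ny - 1 - zy
                        if jy + yhi > ny - 1:
                            yhi = ny - 1 - jy
                        zlo = -patch_r
                        if zz + zlo < 0:
                            zlo = -zz
                        if jz + zlo < 0:
                            zlo = -jz
                        zhi = patch_r
                        if zz + zhi > nz - 1:
                            zhi = nz - 1 - zz
                        if jz + zhi > nz - 1:
                            zhi = nz - 1 - jz

                        n = 0
                        sp = 0.0
                        sq = 0.0
                        spp = 0.0
                        sqq = 0.0
                        sd = 0.0
                        for ux in range(xlo, xhi + 1):
                            ax = zx + ux
                            bx = jx + ux
                            for uy in range(ylo, yhi + 1):
                                ay = zy + uy
                                by = jy + uy
                                for uz in range(zlo, zhi + 1):
                                    p = subj[ax, ay, zz + uz]
                                    q = timgs[s, bx, by, jz + uz]
                                    sp += p
                                    sq += q
                                    spp += p * p
                                    sqq += q * q
                                    d = p - q
                                    sd += d * d
                                    n += 1
                        mp = sp / n
                        mq = sq / n
                        vp = spp / n - mp * mp
                        if vp < 0.0:
                            vp = 0.0
                        vq = sqq / n - mq * mq
                        if vq < 0.0:
                            vq = 0.0
                        den_m = mp * mp + mq * mq
                        if den_m == 0.0:
                            mterm = 1.0
                        else:
                            mterm = 2.0 * mp * mq / den_m
                        den_s = vp + vq
                        if den_s == 0.0:
                            sterm = 1.0
                        else:
                            sterm = 2.0 * np.sqrt(vp) * np.sqrt(vq) / den_s
                        ssd[idx] = sd
                        ssv[idx] = mterm * sterm
                        valid[idx] = 1
                        anyvalid = True
                        if sd < minssd:
                            minssd = sd
                        idx += 1
        if not anyvalid:
            continue
        h2 = lam * minssd + eps

        # Pass 2: weights, gated on structural similarity.
        idx = 0
        bsum = 0.0
        for s in range(S):
            for ox in range(-search_r, search_r + 1):
                for oy in range(-search_r, search_r + 1):
                    for oz in range(-search_r, search_r + 1):
                        w = 0.0
                        if valid[idx] == 1 and ssv[idx] > th:
                            w = swt[ox + search_r, oy + search_r, oz + search_r] * np.exp(
                                -ssd[idx] / h2
                            )
                        wts[idx] = w
                        bsum += w
                        idx += 1
        if bsum <= 0.0:
            continue
        scale = 1.0 / bsum if normalize_blocks else 1.0

        # Pass 3: scatter onto label blocks (cropped to the grid).
        idx = 0
        for s in range(S):
            for ox in range(-search_r, search_r + 1):
                jx = zx + ox
                for oy in range(-search_r, search_r + 1):
                    jy = zy + oy
                    for oz in range(-search_r, search_r + 1):
                        jz = zz + oz
                        w = wts[idx]
                        idx += 1
                        if w <= 0.0:
                            continue
                        ws = w * scale
                        for bx in range(-block_r, block_r + 1):
                            tx = zx + bx
                            ux = jx + bx
                            if tx < 0 or tx >= nx or ux < 0 or ux >= nx:
                                continue
                            for by in range(-block_r, block_r + 1):
                                ty = zy + by
                                uy = jy + by
                                if ty < 0 or ty >= ny or uy < 0 or uy >= ny:
                                    continue
                                for bz in range(-block_r, block_r + 1):
                                    tz = zz + bz
                                    uz = jz + bz
                                    if tz < 0 or tz >= nz or uz < 0 or uz >= nz:
                                        continue
                                    lab = tlabs[s, ux, uy, uz]
                                    votes[lab, tx, ty, tz] += ws
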