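"""Multi-atlas non-local patch-based label fusion.

Pipeline: rank the library by masked intensity similarity and keep the
best N templates; compare the subject patch around every masked voxel
with every template patch inside a cubic search volume; convert patch
distances to weights with an adaptive bandwidth plus a spatial
proximity term, gated by a structural-similarity threshold; cast each
weight onto a whole block of template labels; sum the overlapping block
votes per voxel (overcomplete aggregation); fuse vote maps from two
patch scales; and pick the most-voted label per voxel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import binary_dilation

from ._kernels import blockwise_vote_kernel
from .core import (
    AtlasLibrary,
    EmptyMaskError,
    GridMismatchError,
    LabelSetError,
    Volume,
    as_binary_mask,
)

log = logging.getLogger(__name__)

__all__ = [
    "FusionParams",
    "Patch",
    "VoteMap",
    "extract_patch",
    "structural_similarity",
    "adaptive_h2",
    "patch_weight",
    "select_templates",
    "structure_region_mask",
    "blockwise_vote",
    "multiscale_fuse",
    "decide_labels",
    "segment",
]


def _require_odd(name: str, value: int) -> None:
    if value < 1 or value % 2 == 0:
        raise ValueError(f"{name} must be a positive odd integer, got {value}")


@dataclass(frozen=True)
class FusionParams:
    """All fusion constants, defaulting to the tuned operating point."""

    n_templates: int = 25
    patch_size_1: int = 3
    patch_size_2: int = 5
    search_radius: int = 4  # half-width: 4 -> 9x9x9 search volume
    block_size: int = 3
    lam: float = 0.15
    epsilon: float = 1e-4
    sigma_d: float = math.sqrt(2.0)  # mm
    ss_threshold: float = 0.9
    scale_weights: tuple[float, float] = (0.5, 0.5)
    normalize_blocks: bool = False  # alternative: normalize per block before summing

    def __post_init__(self) -> None:
        if self.n_templates < 1:
            raise ValueError("n_templates must be >= 1")
        _require_odd("patch_size_1", self.patch_size_1)
        _require_odd("patch_size_2", self.patch_size_2)
        _require_odd("block_size", self.block_size)
        if self.search_radius < 0:
            raise ValueError("search_radius must be >= 0")
        if self.lam <= 0 or self.epsilon <= 0 or self.sigma_d <= 0:
            raise ValueError("lam, epsilon and sigma_d must be > 0")
        if not 0 <= self.ss_threshold <= 1:
            raise ValueError("ss_threshold must be in [0, 1]")
        w1, w2 = self.scale_weights
        if w1 < 0 or w2 < 0 or abs(w1 + w2 - 1.0) > 1e-12:
            raise ValueError("scale_weights must be nonnegative and sum to 1")

    def with_(self, **kwargs) -> "FusionParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Patch:
    """Cube of intensities centred on a voxel (possibly border-cropped)."""

    data: np.ndarray
    center: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    cropped: bool = False

    def center_mm(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float) * np.asarray(self.voxel_size)


def extract_patch(volume: Volume, center, size: int) -> Patch:
    """Extract the cube of edge ``size`` around ``center``, cropped to the grid."""
    _require_odd("patch size", size)
    r = size // 2
    cx, cy, cz = (int(c) for c in center)
    shape = volume.shape
    for axis, c in enumerate((cx, cy, cz)):
        if not 0 <= c < shape[axis]:
            raise IndexError(f"patch center {center} outside grid {shape}")
    sl = tuple(
        slice(max(0, c - r), min(shape[a], c + r + 1)) for a, c in enumerate((cx, cy, cz))
    )
    data = volume.data[sl]
    cropped = data.shape != (size, size, size)
    return Patch(np.asarray(data, dtype=float), (cx, cy, cz), volume.voxel_size, cropped)


def _patch_array(p) -> np.ndarray:
    return p.data if isinstance(p, Patch) else np.asarray(p, dtype=float)


def structural_similarity(p, q) -> float:
    """Luminance-contrast structural similarity between two patches.

    ss = (2 mu_p mu_q / (mu_p^2 + mu_q^2)) * (2 s_p s_q / (s_p^2 + s_q^2)).
    Equals 1 for identical non-constant patches. Degenerate rule: when
    both patches are constant the contrast term is taken as 1 (so two
    equal constants give ss = 1); when both means are 0 the luminance
    term is taken as 1.
    """
    a = _patch_array(p)
    b = _patch_array(q)
    if a.shape != b.shape:
        raise ValueError(f"patch shapes differ: {a.shape} vs {b.shape}")
    mp, mq = a.mean(), b.mean()
    vp, vq = a.var(), b.var()
    den_m = mp * mp + mq * mq
    mterm = 1.0 if den_m == 0 else 2.0 * mp * mq / den_m
    den_s = vp + vq
    sterm = 1.0 if den_s == 0 else 2.0 * math.sqrt(vp) * math.sqrt(vq) / den_s
    return float(mterm * sterm)


def adaptive_h2(
    subject: Volume,
    center,
    selected: AtlasLibrary,
    patch_size: int,
    search_radius: int,
    lam: float = 0.15,
    epsilon: float = 1e-4,
) -> float:
    """Adaptive bandwidth: lam * (min candidate patch SSD) + epsilon."""
    if len(selected) == 0:
        raise ValueError("no templates to search")
    p = extract_patch(subject, center, patch_size)
    r = patch_size // 2
    cx, cy, cz = p.center
    shape = subject.shape
    best = None
    for t in selected:
        for ox in range(-search_radius, search_radius + 1):
            for oy in range(-search_radius, search_radius + 1):
                for oz in range(-search_radius, search_radius + 1):
                    j = (cx + ox, cy + oy, cz + oz)
                    if not all(0 <= j[a] < shape[a] for a in range(3)):
                        continue
                    # identical cropping for both patches
                    lo = [max(-r, -p.center[a], -j[a]) for a in range(3)]
                    hi = [
                        min(r, shape[a] - 1 - p.center[a], shape[a] - 1 - j[a])
                        for a in range(3)
                    ]
                    sl_p = tuple(
                        slice(p.center[a] + lo[a], p.center[a] + hi[a] + 1) for a in range(3)
                    )
                    sl_q = tuple(slice(j[a] + lo[a], j[a] + hi[a] + 1) for a in range(3))
                    d = subject.data[sl_p].astype(float) - t.intensity.data[sl_q]
                    ssd = float(np.sum(d * d))
                    if best is None or ssd < best:
                        best = ssd
    if best is None:
        raise ValueError("search volume contains no candidate patches")
    return lam * best + epsilon


def patch_weight(p: Patch, q: Patch, h2: float, params: FusionParams) -> float:
    """Spatially-weighted patch similarity, gated on structural similarity."""
    if h2 <= 0:
        raise ValueError(f"h2 must be > 0, got {h2}")
    ss = structural_similarity(p, q)
    if ss <= params.ss_threshold:
        return 0.0
    diff = _patch_array(p) - _patch_array(q)
    ssd = float(np.sum(diff * diff))
    d2 = float(np.sum((p.center_mm() - q.center_mm()) ** 2))
    return math.exp(-d2 / (2.0 * params.sigma_d**2)) * math.exp(-ssd / h2)


def select_templates(
    subject: Volume, library: AtlasLibrary, region_mask, n: int
) -> AtlasLibrary:
    """Keep the N templates with the smallest masked intensity SSD.

    Deterministic: ties break toward the lower library index.
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    if n < 1:
        raise ValueError("n must be >= 1")
    m = as_binary_mask(region_mask)
    if not m.any():
        raise EmptyMaskError("region mask is empty")
    sub = np.asarray(subject.data, dtype=float)[m]
    ssds = np.empty(len(library))
    for i, t in enumerate(library):
        if t.intensity.shape != subject.shape:
            raise GridMismatchError(
                f"template {t.name!r} grid {t.intensity.shape} != subject {subject.shape}"
            )
        d = sub - np.asarray(t.intensity.data, dtype=float)[m]
        ssds[i] = np.dot(d, d)
    order = np.argsort(ssds, kind="stable")[: min(n, len(library))]
    return library.subset(list(order))


def structure_region_mask(
    library: AtlasLibrary, structure_labels=None, dilate: int = 4
) -> np.ndarray:
    """Union of the structures' labels across templates, dilated.

    ``structure_labels=None`` takes all non-background (non-zero) labels.
    Dilation uses a cube of half-width ``dilate`` (matching the cubic
    search volume).
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    mask = np.zeros(library[0].labels.shape, dtype=bool)
    for t in library:
        lab = t.labels.data
        if structure_labels is None:
            mask |= lab != 0
        else:
            mask |= np.isin(lab, np.asarray(list(structure_labels)))
    if dilate > 0 and mask.any():
        mask = binary_dilation(mask, structure=np.ones((2 * dilate + 1,) * 3, dtype=bool))
    return mask


@dataclass
class VoteMap:
    """Per-voxel accumulated normalized votes over a sorted label set."""

    votes: np.ndarray  # (L, nx, ny, nz), normalized where voted
    labels: np.ndarray  # (L,) sorted label ids
    mask: np.ndarray  # (nx, ny, nz) bool — region the vote was computed for
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def voted(self) -> np.ndarray:
        return self.votes.sum(axis=0) > 0

    def check_normalized(self, tol: float = 1e-6) -> bool:
        tot = self.votes.sum(axis=0)
        voted = tot > 0
        return bool(np.all(np.abs(tot[voted] - 1.0) <= tol))


def _stack_templates(selected: AtlasLibrary, subject: Volume):
    selected.validate_common_grid()
    for t in selected:
        if t.intensity.shape != subject.shape:
            raise GridMismatchError(
                f"template {t.name!r} grid {t.intensity.shape} != subject {subject.shape}"
            )
    timgs = np.stack([np.ascontiguousarray(t.intensity.data, dtype=np.float64) for t in selected])
    labels = selected.label_set()
    tlabs = np.stack(
        [
            np.searchsorted(labels, t.labels.data).astype(np.int32)
            for t in selected
        ]
    )
    return timgs, tlabs, labels


def _spatial_weight_table(search_radius: int, voxel_size, sigma_d: float) -> np.ndarray:
    r = search_radius
    off = np.arange(-r, r + 1, dtype=float)
    vx, vy, vz = voxel_size
    d2 = (
        (off[:, None, None] * vx) ** 2
        + (off[None, :, None] * vy) ** 2
        + (off[None, None, :] * vz) ** 2
    )
    return np.exp(-d2 / (2.0 * sigma_d**2))


def blockwise_vote(
    subject: Volume,
    selected: AtlasLibrary,
    region_mask,
    patch_size: int,
    params: FusionParams,
) -> VoteMap:
    """Accumulate block-wise overcomplete votes over the region mask.

    Every masked voxel acts as a block center. With ``block_size == 1``
    this degenerates to plain voxel-wise non-local label fusion.
    Voxels where every candidate was similarity-gated receive a uniform
    vote over the labels observed in their search volume (logged).
    """
    _require_odd("patch_size", patch_size)
    mask = as_binary_mask(region_mask)
    if mask.shape != subject.shape:
        raise ValueError("region mask and subject shapes differ")
    if not mask.any():
        raise EmptyMaskError("region mask is empty")
    if len(selected) == 0:
        raise ValueError("no templates selected")

    timgs, tlabs, labels = _stack_templates(selected, subject)
    subj = np.ascontiguousarray(subject.data, dtype=np.float64)
    centers = np.argwhere(mask).astype(np.int64)
    swt = _spatial_weight_table(params.search_radius, subject.voxel_size, params.sigma_d)
    votes = np.zeros((labels.size,) + subject.shape, dtype=np.float64)

    blockwise_vote_kernel(
        subj,
        timgs,
        tlabs,
        centers,
        patch_size // 2,
        params.search_radius,
        params.block_size // 2,
        float(params.lam),
        float(params.epsilon),
        float(params.ss_threshold),
        swt,
        bool(params.normalize_blocks),
        votes,
    )

    tot = votes.sum(axis=0)
    # Fallback for fully-gated voxels: uniform over labels seen in the
    # search volume.
    dead = mask & (tot <= 0)
    n_dead = int(dead.sum())
    if n_dead:
        log.warning(
            "blockwise_vote: %d masked voxel(s) had all weights gated out; "
            "falling back to a uniform vote over locally observed labels",
            n_dead,
        )
        r = params.search_radius
        shape = subject.shape
        for x, y, z in np.argwhere(dead):
            sl = (
                slice(None),
                slice(max(0, x - r), min(shape[0], x + r + 1)),
                slice(max(0, y - r), min(shape[1], y + r + 1)),
                slice(max(0, z - r), min(shape[2], z + r + 1)),
            )
            seen = np.unique(tlabs[sl])
            votes[seen, x, y, z] = 1.0 / seen.size
        tot = votes.sum(axis=0)

    voted = tot > 0
    votes[:, voted] /= tot[voted]
    return VoteMap(votes, labels, mask, subject.voxel_size)


def multiscale_fuse(v1: VoteMap, v2: VoteMap, weights=(0.5, 0.5)) -> VoteMap:
    """Late fusion of two vote maps: w1*v1 + w2*v2, renormalized per voxel."""
    if not np.array_equal(v1.labels, v2.labels):
        raise LabelSetError(
            f"label sets differ: {v1.labels.tolist()} vs {v2.labels.tolist()}"
        )
    if v1.votes.shape != v2.votes.shape:
        raise GridMismatchError("vote map grids differ")
    w1, w2 = weights
    if w1 < 0 or w2 < 0:
        raise ValueError("fusion weights must be nonnegative")
    fused = w1 * v1.votes + w2 * v2.votes
    tot = fused.sum(axis=0)
    voted = tot > 0
    fused[:, voted] /= tot[voted]
    return VoteMap(fused, v1.labels.copy(), v1.mask | v2.mask, v1.voxel_size)


def decide_labels(votes: VoteMap, background: int = 0) -> Volume:
    """Most-voted label per voxel; exact ties go to the smallest label id.

    Voxels without any vote (or outside the vote map's mask) get the
    background label.
    """
    if votes.votes.shape[0] == 0:
        raise ValueError("vote map has an empty label set")
    out = np.full(votes.votes.shape[1:], background, dtype=np.int32)
    sel = votes.voted & votes.mask
    # np.argmax returns the first maximizer; labels are sorted ascending,
    # so ties break toward the smallest label id.
    winners = votes.labels[np.argmax(votes.votes[:, sel], axis=0)]
    out[sel] = winners
    return Volume(out, votes.voxel_size)


def segment(
    subject: Volume,
    library: AtlasLibrary,
    region_mask,
    params: FusionParams = FusionParams(),
) -> Volume:
    """Full fusion: template selection, two patch scales, late fusion, argmax.

    The subject is assumed intensity-normalized onto the library's scale.
    """
    mask = as_binary_mask(region_mask)
    if not mask.any():
        raise EmptyMaskError("region mask is empty")
    selected = select_templates(subject, library, mask, params.n_templates)
    v1 = blockwise_vote(subject, selected, mask, params.patch_size_1, params)
    v2 = blockwise_vote(subject, selected, mask, params.patch_size_2, params)
    fused = multiscale_fuse(v1, v2, params.scale_weights)
    return decide_labels(fused)
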