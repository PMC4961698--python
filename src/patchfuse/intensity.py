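"""Robust tissue-mean estimation and piecewise-linear intensity mapping.

The estimator clusters masked intensities into three classes (CSF-, GM-
and WM-like), trims the voxels farthest from each class center — a
surrogate for excluding partial-volume voxels — and iterates trimmed-mean
updates to a fixed point. The mapping then pins the estimated means to
standard targets (defaults 50/150/250) with a continuous monotone
piecewise-linear transfer function anchored at 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DegenerateIntensityError, EmptyMaskError, Volume, as_binary_mask

__all__ = [
    "TissueMeans",
    "NormalizationTargets",
    "tms_estimate_means",
    "piecewise_linear_map",
]


@dataclass(frozen=True)
class TissueMeans:
    mu_csf: float
    mu_gm: float
    mu_wm: float

    def __post_init__(self) -> None:
        vals = (self.mu_csf, self.mu_gm, self.mu_wm)
        if not all(np.isfinite(vals)):
            raise ValueError(f"tissue means must be finite, got {vals}")
        if not (0 <= self.mu_csf < self.mu_gm < self.mu_wm):
            raise ValueError(f"tissue means must satisfy 0 <= csf < gm < wm, got {vals}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.mu_csf, self.mu_gm, self.mu_wm)


@dataclass(frozen=True)
class NormalizationTargets:
    target_csf: float = 50.0
    target_gm: float = 150.0
    target_wm: float = 250.0

    def __post_init__(self) -> None:
        if not (0 < self.target_csf < self.target_gm < self.target_wm):
            raise ValueError("targets must be strictly increasing and positive")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.target_csf, self.target_gm, self.target_wm)


def _trimmed_mean(values: np.ndarray, center: float, trim_fraction: float) -> float:
    """Mean of the (1 - trim_fraction) share of values closest to center."""
    n = values.size
    n_keep = max(1, int(np.ceil((1.0 - trim_fraction) * n)))
    if n_keep >= n:
        return float(values.mean())
    order = np.argsort(np.abs(values - center), kind="stable")
    return float(values[order[:n_keep]].mean())


def tms_estimate_means(
    image: Volume,
    mask,
    *,
    trim_fraction: float = 0.25,
    tol: float = 1e-3,
    max_iter: int = 100,
) -> TissueMeans:
    """Estimate CSF/GM/WM mean intensities inside a mask.

    Iterates: (a) assign each voxel to the nearest of three current
    means, (b) within each class drop the ``trim_fraction`` of voxels
    farthest from the class center, (c) recompute each mean as the
    trimmed mean; until the largest mean shift falls below ``tol``.

    Initialization uses the 10th/50th/90th percentiles of masked
    intensities; if those coincide (heavily unbalanced classes) it falls
    back to even spacing between the 1st and 99th percentiles.
    """
    if not 0 <= trim_fraction < 1:
        raise ValueError("trim_fraction must be in [0, 1)")
    m = as_binary_mask(mask)
    if m.shape != image.shape:
        raise ValueError("mask and image shapes differ")
    vals = np.asarray(image.data)[m].astype(float)
    if vals.size == 0:
        raise EmptyMaskError("mask selects no voxels")
    if not np.all(np.isfinite(vals)):
        raise ValueError("image contains non-finite values inside the mask")
    if np.ptp(vals) == 0:
        raise DegenerateIntensityError(
            "degenerate histogram: all masked voxels share one intensity"
        )

    means = np.percentile(vals, [10.0, 50.0, 90.0])
    if not (means[0] < means[1] < means[2]):
        lo, hi = np.percentile(vals, [1.0, 99.0])
        if lo == hi:
            lo, hi = vals.min(), vals.max()
        means = lo + np.array([0.1, 0.5, 0.9]) * (hi - lo)

    for _ in range(max_iter):
        d = np.abs(vals[:, None] - means[None, :])
        assign = np.argmin(d, axis=1)
        new = means.copy()
        for k in range(3):
            cls = vals[assign == k]
            if cls.size:
                new[k] = _trimmed_mean(cls, means[k], trim_fraction)
        shift = np.max(np.abs(new - means))
        means = new
        if shift < tol:
            break

    means = np.sort(means)
    if not (means[0] < means[1] < means[2]):
        raise DegenerateIntensityError(
            f"fewer than 3 distinguishable intensity modes (means converged to {means})"
        )
    return TissueMeans(*means)


def piecewise_linear_map(
    image: Volume,
    means: TissueMeans,
    targets: NormalizationTargets = NormalizationTargets(),
) -> Volume:
    """Map intensities so the tissue means land on the targets.

    Breakpoints: 0 -> 0, mu_csf -> target_csf, mu_gm -> target_gm,
    mu_wm -> target_wm; above mu_wm the last segment's slope continues;
    output is clipped at 0 below. The mapping is continuous and
    monotone non-decreasing.
    """
    xp = np.array([0.0, means.mu_csf, means.mu_gm, means.mu_wm])
    fp = np.array([0.0, *targets.as_tuple()])
    if means.mu_csf == 0.0:  # degenerate first anchor: drop the duplicate
        xp, fp = xp[1:], fp[1:]
    x = np.asarray(image.data, dtype=float)
    out = np.interp(x, xp, fp)
    slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
    above = x > xp[-1]
    if np.any(above):
        out = np.where(above, fp[-1] + slope * (x - xp[-1]), out)
    np.clip(out, 0.0, None, out=out)
    return image.with_data(out)
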