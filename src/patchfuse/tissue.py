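"""Intensity-driven tissue classification inside the intracranial mask.

Each voxel's intensity is decomposed into fractions of the two adjacent
tissue classes by linear mixing between the estimated class means, with
hard saturation below the CSF mean and above the WM mean. The crisp
segmentation is the per-voxel argmax of the fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EmptyMaskError, Volume, as_binary_mask
from .intensity import TissueMeans

__all__ = ["PVCMaps", "classify_tissues", "tissue_volumes", "CRISP_CSF", "CRISP_GM", "CRISP_WM"]

CRISP_CSF, CRISP_GM, CRISP_WM = 1, 2, 3


@dataclass(frozen=True)
class PVCMaps:
    """Partial-volume fractions per tissue; zero outside the ICC mask."""

    csf: Volume
    gm: Volume
    wm: Volume
    icc_mask: np.ndarray

    def __post_init__(self) -> None:
        for v in (self.csf, self.gm, self.wm):
            if v.shape != self.icc_mask.shape:
                raise ValueError("PVC maps and ICC mask must share a grid")

    def stacked(self) -> np.ndarray:
        return np.stack([self.csf.data, self.gm.data, self.wm.data])


def classify_tissues(
    image: Volume, icc_mask, means: TissueMeans
) -> tuple[PVCMaps, Volume]:
    """Compute tissue fractions and a crisp CSF/GM/WM labeling.

    Mixing model: intensity I with mu_a < I < mu_b for adjacent class
    means gets fraction (I - mu_a) / (mu_b - mu_a) of the brighter
    tissue and the complement of the darker one; I <= mu_csf is pure
    CSF and I >= mu_wm pure WM. Crisp ties (fraction exactly 0.5) go to
    the lower-intensity tissue.
    """
    mask = as_binary_mask(icc_mask)
    if mask.shape != image.shape:
        raise ValueError("ICC mask and image shapes differ")
    if not mask.any():
        raise EmptyMaskError("ICC mask is empty")
    mu_c, mu_g, mu_w = means.as_tuple()

    intens = np.asarray(image.data, dtype=float)
    csf = np.zeros(image.shape)
    gm = np.zeros(image.shape)
    wm = np.zeros(image.shape)

    low = mask & (intens <= mu_c)
    csf[low] = 1.0
    mid1 = mask & (intens > mu_c) & (intens <= mu_g)
    f = (intens[mid1] - mu_c) / (mu_g - mu_c)
    gm[mid1] = f
    csf[mid1] = 1.0 - f
    mid2 = mask & (intens > mu_g) & (intens < mu_w)
    f = (intens[mid2] - mu_g) / (mu_w - mu_g)
    wm[mid2] = f
    gm[mid2] = 1.0 - f
    high = mask & (intens >= mu_w)
    wm[high] = 1.0

    # argmax over (csf, gm, wm); first maximizer = lower-intensity tissue
    fractions = np.stack([csf, gm, wm])
    crisp = np.zeros(image.shape, dtype=np.int32)
    crisp[mask] = np.argmax(fractions[:, mask], axis=0) + 1

    vs = image.voxel_size
    pvc = PVCMaps(Volume(csf, vs), Volume(gm, vs), Volume(wm, vs), mask)
    return pvc, Volume(crisp, vs)


def tissue_volumes(pvc: PVCMaps, voxel_volume: float | None = None) -> dict[str, float]:
    """Integrate fractions into per-tissue volumes in cm^3."""
    if voxel_volume is None:
        voxel_volume = pvc.csf.voxel_volume
    if voxel_volume <= 0:
        raise ValueError("voxel_volume must be > 0")
    return {
        "csf": float(pvc.csf.data.sum() * voxel_volume / 1000.0),
        "gm": float(pvc.gm.data.sum() * voxel_volume / 1000.0),
        "wm": float(pvc.wm.data.sum() * voxel_volume / 1000.0),
    }
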