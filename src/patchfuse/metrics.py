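"""Segmentation evaluation and volumetry reporting.

Overlap and reproducibility statistics (Dice, percent volume
difference/overlap referenced to the mean of the two segmentations),
signed left/right asymmetry ratios, and per-structure volume tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .core import GridMismatchError, Volume, as_binary_mask

__all__ = [
    "StructureInfo",
    "StructureDict",
    "VolumetryReport",
    "dice",
    "pvd",
    "pvo",
    "asymmetry_ratio",
    "structure_volumes",
]


def _counts(a, b) -> tuple[int, int, int]:
    ma, mb = as_binary_mask(a), as_binary_mask(b)
    if ma.shape != mb.shape:
        raise GridMismatchError(f"grids differ: {ma.shape} vs {mb.shape}")
    return int(ma.sum()), int(mb.sum()), int((ma & mb).sum())


def dice(a, b) -> float:
    """Dice's kappa 2|A∩B|/(|A|+|B|); 1 when both masks are empty."""
    na, nb, ni = _counts(a, b)
    if na + nb == 0:
        return 1.0
    return 2.0 * ni / (na + nb)


def pvd(c1, c2) -> float:
    """Percent volume difference, referenced to the mean of both masks."""
    n1, n2, _ = _counts(c1, c2)
    if n1 + n2 == 0:
        raise ValueError("both segmentations are empty")
    return 100.0 * 2.0 * abs(n1 - n2) / (n1 + n2)


def pvo(c1, c2) -> float:
    """Percent volume overlap: exactly 100 * Dice, referenced to the mean."""
    n1, n2, _ = _counts(c1, c2)
    if n1 + n2 == 0:
        raise ValueError("both segmentations are empty")
    return 100.0 * dice(c1, c2)


def asymmetry_ratio(vol_left: float, vol_right: float) -> float:
    """Signed percent asymmetry, referenced to the mean of both sides."""
    if vol_left < 0 or vol_right < 0:
        raise ValueError("volumes must be nonnegative")
    total = vol_left + vol_right
    if total == 0:
        raise ValueError("both volumes are zero")
    return 100.0 * (vol_left - vol_right) / (total / 2.0)


@dataclass(frozen=True)
class StructureInfo:
    name: str
    hemisphere: str = "midline"  # left | right | midline
    pair: Optional[int] = None  # label id of the contralateral structure

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right", "midline"):
            raise ValueError(f"bad hemisphere tag {self.hemisphere!r}")


class StructureDict(dict):
    """Mapping label id -> StructureInfo with symmetric-pairing checks."""

    def __init__(self, mapping: Mapping[int, StructureInfo]):
        super().__init__({int(k): v for k, v in mapping.items()})
        self.validate()

    def validate(self) -> None:
        for lab, info in self.items():
            if info.pair is not None:
                other = self.get(info.pair)
                if other is None or other.pair != lab:
                    raise ValueError(f"pairing is not symmetric for label {lab}")
                if {info.hemisphere, other.hemisphere} != {"left", "right"}:
                    raise ValueError(
                        f"paired labels {lab}/{info.pair} must tag opposite hemispheres"
                    )

    def swap_table(self) -> dict[int, int]:
        """Left<->right label exchange map for mirror augmentation."""
        return {lab: info.pair for lab, info in self.items() if info.pair is not None}

    @classmethod
    def from_json(cls, path) -> "StructureDict":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            {
                int(k): StructureInfo(
                    v["name"], v.get("hemisphere", "midline"), v.get("pair")
                )
                for k, v in raw.items()
            }
        )


@dataclass
class VolumetryReport:
    """Per-structure volumes, ICC shares and asymmetry ratios."""

    rows: list[dict] = field(default_factory=list)
    icc_cm3: float = 0.0
    tissue_cm3: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=["name", "label", "volume_cm3", "pct_icc", "asymmetry_pct"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None):
        payload = {
            "icc_cm3": self.icc_cm3,
            "tissue_cm3": self.tissue_cm3,
            "structures": self.rows,
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return payload


def structure_volumes(
    labels: Volume,
    structures: StructureDict,
    voxel_volume: float | None = None,
    icc_cm3: float | None = None,
    background: int = 0,
) -> VolumetryReport:
    """Tabulate per-structure volumes, % of ICC and asymmetry ratios.

    Every non-background label present in the volume must appear in the
    structure dictionary. Volumes absent from the segmentation are
    reported as 0 (their pair's asymmetry still uses both sides).
    """
    if voxel_volume is None:
        voxel_volume = labels.voxel_volume
    present = np.unique(labels.data)
    unknown = [int(k) for k in present if k != background and int(k) not in structures]
    if unknown:
        raise ValueError(f"labels {unknown} missing from the structure dictionary")

    counts = {
        int(lab): int(np.count_nonzero(labels.data == lab)) for lab in structures
    }
    vols = {lab: counts[lab] * voxel_volume / 1000.0 for lab in counts}
    if icc_cm3 is None:
        icc_cm3 = float(
            np.count_nonzero(labels.data != background) * voxel_volume / 1000.0
        )

    rows = []
    for lab in sorted(structures):
        info = structures[lab]
        vol = vols[lab]
        asym = None
        if info.pair is not None:
            left, right = (
                (vol, vols[info.pair]) if info.hemisphere == "left" else (vols[info.pair], vol)
            )
            if left + right > 0:
                asym = asymmetry_ratio(left, right)
        rows.append(
            {
                "name": info.name,
                "label": lab,
                "volume_cm3": vol,
                "pct_icc": 100.0 * vol / icc_cm3 if icc_cm3 > 0 else 0.0,
                "asymmetry_pct": asym,
            }
        )
    return VolumetryReport(rows=rows, icc_cm3=icc_cm3)
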