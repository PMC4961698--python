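"""Core volume containers shared by every stage of the toolkit.

Volumes are plain numpy arrays plus voxel geometry. All algorithms assume
the inputs are already co-registered on a common isotropic-or-not grid;
no resampling between spaces happens here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Volume",
    "Template",
    "AtlasLibrary",
    "GridMismatchError",
    "EmptyMaskError",
    "DegenerateIntensityError",
    "LateralityError",
    "StructureBoundsError",
    "LabelSetError",
    "as_binary_mask",
]


class GridMismatchError(ValueError):
    """Two volumes expected on the same grid are not."""


class EmptyMaskError(ValueError):
    """An operation received an empty region mask."""


class DegenerateIntensityError(ValueError):
    """Intensity histogram has too few distinguishable modes."""


class LateralityError(ValueError):
    """Lateralized labels present without a left/right swap table."""


class StructureBoundsError(ValueError):
    """A phantom primitive or deformation exceeds the grid."""


class LabelSetError(ValueError):
    """Label sets of two vote maps / volumes do not match."""


@dataclass(frozen=True)
class Volume:
    """A 3D scalar or integer grid with voxel dimensions in mm.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values. Intensities are floats; labels are integers.
    voxel_size : tuple of 3 floats
        Edge length of a voxel along each axis, in mm.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={arr.ndim}")
        object.__setattr__(self, "data", arr)
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")
        object.__setattr__(self, "voxel_size", vs)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    def same_grid(self, other: "Volume") -> bool:
        return self.shape == other.shape and np.allclose(self.voxel_size, other.voxel_size)

    def with_data(self, data: np.ndarray) -> "Volume":
        return Volume(data, self.voxel_size)


@dataclass(frozen=True)
class Template:
    """A co-registered (intensity, label) pair from a template library."""

    intensity: Volume
    labels: Volume
    name: str = ""

    def __post_init__(self) -> None:
        if not self.intensity.same_grid(self.labels):
            raise GridMismatchError(
                f"template {self.name!r}: intensity and label grids differ "
                f"({self.intensity.shape} vs {self.labels.shape})"
            )
        if not np.issubdtype(self.labels.data.dtype, np.integer):
            raise TypeError("label volume must have an integer dtype")


@dataclass
class AtlasLibrary:
    """Ordered collection of co-registered templates."""

    templates: list[Template] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.templates)

    def __iter__(self) -> Iterator[Template]:
        return iter(self.templates)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return AtlasLibrary(self.templates[i])
        return self.templates[i]

    def subset(self, indices: Sequence[int]) -> "AtlasLibrary":
        return AtlasLibrary([self.templates[i] for i in indices])

    def validate_common_grid(self) -> None:
        """Raise GridMismatchError naming the first offending template."""
        if not self.templates:
            return
        ref = self.templates[0].intensity
        for t in self.templates:
            if not t.intensity.same_grid(ref):
                raise GridMismatchError(
                    f"template {t.name!r} is on grid {t.intensity.shape}, "
                    f"expected {ref.shape}"
                )

    def label_set(self) -> np.ndarray:
        """Sorted union of labels across all templates."""
        if not self.templates:
            return np.array([], dtype=np.int64)
        labs = [np.unique(t.labels.data) for t in self.templates]
        return np.unique(np.concatenate(labs)).astype(np.int64)


def as_binary_mask(mask) -> np.ndarray:
    """Coerce a Volume or array to a boolean array."""
    if isinstance(mask, Volume):
        mask = mask.data
    return np.asarray(mask).astype(bool)
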