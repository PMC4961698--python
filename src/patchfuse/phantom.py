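"""Seeded synthetic phantoms and deformed template libraries.

Generates intensity/label volume pairs with tissue-like class means,
Gaussian noise and optional smooth multiplicative bias fields, plus
libraries of smoothly deformed variants of a base pair. Everything is
driven by integer seeds so fixtures are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .core import (
    AtlasLibrary,
    LateralityError,
    StructureBoundsError,
    Template,
    Volume,
)

__all__ = [
    "Primitive",
    "BiasFieldSpec",
    "PhantomSpec",
    "DeformSpec",
    "make_phantom",
    "make_library",
    "flip_augment",
]


@dataclass(frozen=True)
class Primitive:
    """A geometric structure painted into the phantom.

    ``kind`` is one of ``sphere``, ``ellipsoid`` or ``box``. ``center``
    and ``radii`` are in voxel units (a sphere takes a scalar radius).
    """

    label: int
    kind: str
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    mean: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "ellipsoid", "box"):
            raise ValueError(f"unknown primitive kind {self.kind!r}")
        if any(r <= 0 for r in self.radii):
            raise ValueError(f"primitive {self.name or self.label}: radii must be > 0")


def sphere(label: int, center, radius: float, mean: float, name: str = "") -> Primitive:
    """Convenience constructor for a spherical primitive."""
    return Primitive(label, "sphere", tuple(center), (radius, radius, radius), mean, name)


@dataclass(frozen=True)
class BiasFieldSpec:
    """Smooth multiplicative confound: separable low-order polynomial.

    ``amplitude`` is the maximal fractional deviation from unity, e.g.
    0.2 yields a field in [0.8, 1.2].
    """

    order: int = 2
    amplitude: float = 0.2

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("bias order must be >= 1")
        if not 0 <= self.amplitude < 1:
            raise ValueError("bias amplitude must be in [0, 1)")


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int]
    structures: Sequence[Primitive]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_label: int = 0
    background_mean: float = 0.0
    noise_sigma: float = 0.0
    bias_field: Optional[BiasFieldSpec] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        labels = [p.label for p in self.structures] + [self.background_label]
        if len(set(labels)) != len(labels):
            raise ValueError("structure labels must be distinct (and differ from background)")
        if any(p.label < 0 for p in self.structures) or self.background_label < 0:
            raise ValueError("labels must be non-negative")


@dataclass(frozen=True)
class DeformSpec:
    """Random smooth deformations standing in for inter-subject anatomy."""

    n_templates: int
    displacement_amplitude: float = 2.0  # mm, max |component|
    displacement_smoothness: float = 8.0  # mm, Gaussian kernel width
    per_template_noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_templates < 1:
            raise ValueError("n_templates must be >= 1")
        if self.displacement_amplitude < 0:
            raise ValueError("displacement_amplitude must be >= 0")
        if self.displacement_smoothness <= 0:
            raise ValueError("displacement_smoothness must be > 0")
        if self.per_template_noise_sigma < 0:
            raise ValueError("per_template_noise_sigma must be >= 0")


def _primitive_mask(prim: Primitive, shape: tuple[int, int, int]) -> np.ndarray:
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cx, cy, cz = prim.center
    rx, ry, rz = prim.radii
    if prim.kind == "box":
        return (
            (np.abs(grids[0] - cx) <= rx)
            & (np.abs(grids[1] - cy) <= ry)
            & (np.abs(grids[2] - cz) <= rz)
        )
    # sphere / ellipsoid
    return (
        ((grids[0] - cx) / rx) ** 2
        + ((grids[1] - cy) / ry) ** 2
        + ((grids[2] - cz) / rz) ** 2
    ) <= 1.0


def _check_bounds(prim: Primitive, shape: tuple[int, int, int]) -> None:
    for axis in range(3):
        lo = prim.center[axis] - prim.radii[axis]
        hi = prim.center[axis] + prim.radii[axis]
        if lo < 0 or hi > shape[axis] - 1:
            raise StructureBoundsError(
                f"structure {prim.name or prim.label!r} exceeds grid along axis "
                f"{axis}: extent [{lo:.1f}, {hi:.1f}] vs [0, {shape[axis] - 1}]"
            )


def _bias_field(spec: BiasFieldSpec, shape, rng: np.random.Generator) -> np.ndarray:
    # Separable polynomial in normalized coordinates, scaled to +-amplitude.
    field = np.ones(shape)
    axes = []
    for n in shape:
        x = np.linspace(-1.0, 1.0, n)
        coefs = rng.standard_normal(spec.order + 1)
        coefs[0] = 0.0  # constant absorbed by the final normalization
        axes.append(np.polynomial.polynomial.polyval(x, coefs))
    field = (
        axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :]
    )
    peak = np.max(np.abs(field))
    if peak > 0:
        field = field / peak * spec.amplitude
    return 1.0 + field


def make_phantom(spec: PhantomSpec) -> tuple[Volume, Volume]:
    """Build a (intensity, label) pair from a phantom specification.

    Labels are painted in order, later structures overwriting earlier
    ones where they overlap. Intensity equals the per-label class mean,
    multiplied by the bias field if present, plus Gaussian noise.
    """
    shape = tuple(int(s) for s in spec.grid_shape)
    labels = np.full(shape, spec.background_label, dtype=np.int32)
    intensity = np.full(shape, float(spec.background_mean))
    for prim in spec.structures:
        _check_bounds(prim, shape)
        m = _primitive_mask(prim, shape)
        labels[m] = prim.label
        intensity[m] = prim.mean
    rng = np.random.default_rng(spec.seed)
    if spec.bias_field is not None:
        intensity = intensity * _bias_field(spec.bias_field, shape, rng)
    if spec.noise_sigma > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sigma, shape)
    vs = spec.voxel_size
    return Volume(intensity, vs), Volume(labels, vs)


def _smooth_displacement(
    shape, amplitude_mm: float, smoothness_mm: float, voxel_size, rng: np.random.Generator
) -> np.ndarray:
    """(3, nx, ny, nz) displacement in voxel units, max |component| = amplitude."""
    disp = np.empty((3,) + tuple(shape))
    for axis in range(3):
        noise = rng.standard_normal(shape)
        sigma_vox = [smoothness_mm / v for v in voxel_size]
        f = gaussian_filter(noise, sigma=sigma_vox, mode="reflect")
        peak = np.max(np.abs(f))
        if peak == 0:
            disp[axis] = 0.0
        else:
            disp[axis] = f / peak * (amplitude_mm / voxel_size[axis])
    return disp


def _warp(data: np.ndarray, disp: np.ndarray, order: int) -> np.ndarray:
    shape = data.shape
    coords = np.mgrid[: shape[0], : shape[1], : shape[2]].astype(float)
    coords = coords + disp
    out = map_coordinates(data, coords, order=order, mode="nearest")
    return out


def make_library(
    base_intensity: Volume, base_labels: Volume, deform: DeformSpec
) -> AtlasLibrary:
    """Generate ``n_templates`` smoothly deformed variants of a base pair.

    The same displacement field warps intensity (linear resampling) and
    labels (nearest-neighbour), so each pair stays mutually consistent.
    Per-template Gaussian noise is added after warping.
    """
    if not base_intensity.same_grid(base_labels):
        raise ValueError("base intensity and label volumes must share a grid")
    shape = base_intensity.shape
    vs = base_intensity.voxel_size

    # Conservative static bound: a structure within `margin` voxels of the
    # border could be pushed off the grid by the requested amplitude.
    fg = np.argwhere(base_labels.data != 0)
    if fg.size:
        margin = np.inf
        for axis in range(3):
            margin = min(margin, fg[:, axis].min(), shape[axis] - 1 - fg[:, axis].max())
        amp_vox = max(deform.displacement_amplitude / v for v in vs)
        if amp_vox > margin:
            raise StructureBoundsError(
                f"displacement amplitude {deform.displacement_amplitude} mm "
                f"(~{amp_vox:.1f} vox) exceeds the {margin:.0f}-voxel margin "
                "between labeled structures and the grid border"
            )

    rng = np.random.default_rng(deform.seed)
    templates = []
    for t in range(deform.n_templates):
        if deform.displacement_amplitude > 0:
            disp = _smooth_displacement(
                shape, deform.displacement_amplitude, deform.displacement_smoothness, vs, rng
            )
            img = _warp(base_intensity.data, disp, order=1)
            lab = _warp(base_labels.data, disp, order=0)
        else:
            img = base_intensity.data.copy()
            lab = base_labels.data.copy()
        if deform.per_template_noise_sigma > 0:
            img = img + rng.normal(0.0, deform.per_template_noise_sigma, shape)
        templates.append(
            Template(Volume(img, vs), Volume(lab.astype(base_labels.data.dtype), vs), name=f"tpl{t:03d}")
        )
    return AtlasLibrary(templates)


def flip_augment(
    library: AtlasLibrary,
    axis: int = 0,
    swap_table: Optional[Mapping[int, int]] = None,
    lateralized_labels: Iterable[int] = (),
) -> AtlasLibrary:
    """Double a library by mirroring every template across one axis.

    Returns originals followed by mirrored copies. Mirrored label maps
    have lateralized labels exchanged via ``swap_table`` (which must be
    symmetric). ``lateralized_labels`` declares which labels need the
    swap; a declared label missing from the table raises LateralityError.
    """
    if len(library) == 0:
        raise ValueError("cannot flip-augment an empty library")
    if not 0 <= axis <= 2:
        raise ValueError(f"axis must be 0..2, got {axis}")
    swap = dict(swap_table or {})
    for a, b in list(swap.items()):
        if swap.get(b) != a:
            raise LateralityError(f"swap table is not symmetric at {a}<->{b}")
    lateral = set(lateralized_labels)
    missing = lateral - set(swap)
    if missing:
        raise LateralityError(
            f"lateralized labels {sorted(missing)} present but not in the swap table"
        )

    mirrored = []
    for t in library:
        img = np.flip(t.intensity.data, axis=axis).copy()
        lab = np.flip(t.labels.data, axis=axis).copy()
        if swap:
            out = lab.copy()
            for a, b in swap.items():
                out[lab == a] = b
            lab = out
        mirrored.append(
            Template(
                Volume(img, t.intensity.voxel_size),
                Volume(lab, t.labels.voxel_size),
                name=f"{t.name}~flip",
            )
        )
    return AtlasLibrary(list(library.templates) + mirrored)
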