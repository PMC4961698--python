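"""NIfTI-1 volume I/O and library manifests."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import AtlasLibrary, Template, Volume

__all__ = [
    "load_volume",
    "load_labels",
    "save_volume",
    "load_library",
    "save_library",
    "write_manifest",
]


def load_volume(path) -> Volume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    zooms = img.header.get_zooms()[:3]
    return Volume(data, tuple(float(z) for z in zooms))


def load_labels(path) -> Volume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded):
            raise ValueError(f"{path}: label volume holds non-integer values")
        data = rounded
    zooms = img.header.get_zooms()[:3]
    return Volume(data.astype(np.int32), tuple(float(z) for z in zooms))


def save_volume(vol: Volume, path) -> None:
    affine = np.diag(list(vol.voxel_size) + [1.0])
    data = vol.data
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int32)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def load_library(manifest_path) -> AtlasLibrary:
    """Read a YAML/JSON manifest listing (intensity, labels) path pairs.

    Relative paths resolve against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        if manifest_path.suffix in (".yaml", ".yml"):
            manifest = yaml.safe_load(fh)
        else:
            manifest = json.load(fh)
    base = manifest_path.parent
    templates = []
    for i, entry in enumerate(manifest["templates"]):
        ipath = base / entry["intensity"]
        lpath = base / entry["labels"]
        for p in (ipath, lpath):
            if not p.exists():
                raise FileNotFoundError(f"manifest entry {i}: missing file {p}")
        templates.append(
            Template(load_volume(ipath), load_labels(lpath), name=entry.get("name", f"tpl{i:03d}"))
        )
    lib = AtlasLibrary(templates)
    lib.validate_common_grid()
    return lib


def save_library(library: AtlasLibrary, out_dir, manifest_name: str = "library.json") -> Path:
    """Write every template as NIfTI pairs plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, t in enumerate(library):
        name = t.name or f"tpl{i:03d}"
        ifile, lfile = f"{name}_t1.nii", f"{name}_lab.nii"
        save_volume(t.intensity, out_dir / ifile)
        save_volume(t.labels, out_dir / lfile)
        entries.append({"name": name, "intensity": ifile, "labels": lfile})
    manifest = out_dir / manifest_name
    with open(manifest, "w") as fh:
        json.dump({"templates": entries}, fh, indent=2)
    return manifest


def write_manifest(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
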