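"""File I/O: volumes (MetaImage / NIfTI), projections (TIFF + JSON sidecar).

Volumes are stored with spacing and origin in the header so they open in any
standard medical-image viewer.  Projection stacks are float32 multi-page TIFF
files with a ``.json`` sidecar holding the full scan geometry.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile

from .geometry import ProjectionSet, ScanGeometry, Volume, VolumeGrid

__all__ = [
    "read_volume",
    "write_volume",
    "read_projections",
    "write_projections",
    "save_gaussians",
    "load_gaussians",
]

_VOLUME_SUFFIXES = (".mha", ".mhd", ".nii", ".nii.gz")


def _check_volume_path(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _VOLUME_SUFFIXES):
        raise ValueError(
            f"unsupported volume format {path.suffix!r}; supported: {_VOLUME_SUFFIXES}"
        )


def read_volume(path) -> Volume:
    """Read a volume from MetaImage (.mha/.mhd) or NIfTI (.nii/.nii.gz)."""
    path = Path(path)
    _check_volume_path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"cannot parse {path}: empty file")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # corrupt header etc.
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    # SimpleITK arrays come back (z, y, x); our convention is (x, y, z).
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = tuple(img.GetSpacing())
    origin = tuple(img.GetOrigin())
    grid = VolumeGrid(*values.shape, spacing=spacing, origin=origin)
    return Volume(grid, values)


def write_volume(volume: Volume, path) -> None:
    """Write a volume losslessly (values, spacing, origin) to .mha or .nii.gz."""
    path = Path(path)
    _check_volume_path(path)
    if not np.all(np.isfinite(volume.values)):
        raise ValueError("refusing to write non-finite voxel values")
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(volume.grid.spacing))
    img.SetOrigin(tuple(volume.grid.origin))
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        sitk.WriteImage(img, str(path), useCompression=True)
    except RuntimeError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_projections(pset: ProjectionSet, path) -> None:
    """Write frames as float32 multi-page TIFF plus a JSON geometry sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), pset.frames.astype(np.float32))
    with open(_sidecar_path(path), "w") as fh:
        json.dump(pset.geometry.to_dict(), fh, indent=1)


def read_projections(path) -> ProjectionSet:
    """Read a projection stack and its geometry sidecar; validates consistency."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing geometry sidecar {sidecar}")
    with open(sidecar) as fh:
        geometry = ScanGeometry.from_dict(json.load(fh))
    frames = tifffile.imread(str(path))
    if frames.ndim == 2:
        frames = frames[None]
    return ProjectionSet(geometry, frames)


def save_gaussians(gset, path) -> None:
    """Serialize a Gaussian set to an .npz container with named arrays."""
    np.savez(
        path,
        positions=gset.positions,
        densities=gset.densities,
        scales=gset.scales,
        quaternions=gset.quaternions,
    )


def load_gaussians(path):
    from .gaussians import GaussianSet

    with np.load(path) as data:
        return GaussianSet(
            positions=data["positions"],
            densities=data["densities"],
            scales=data["scales"],
            quaternions=data["quaternions"],
        )
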