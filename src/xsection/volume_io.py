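"""Read/write segmentation and intensity volumes with mm spacing metadata.

Supported formats: NRRD (attached or detached header), NIfTI-1
(.nii / .nii.gz), and ordered stacks of single-plane TIFF files. Readers
permute file-native axis orderings into the package's (x, y, z) convention
and normalize all spacings to millimetres; axis-aligned flips/permutations
in orientation metadata are honored, anything oblique is rejected with an
instruction to resample first.
"""

from __future__ import annotations

import glob as _glob
import logging
import os
from pathlib import Path
from typing import Optional, Sequence, Union

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import tifffile

from .types import SegmentMask, VoxelVolume

log = logging.getLogger(__name__)

PathLike = Union[str, os.PathLike]

_NIFTI_UNIT_TO_MM = {"unknown": 1.0, "meter": 1000.0, "mm": 1.0, "micron": 1e-3}


class VolumeIOError(IOError):
    pass


def _check_axis_aligned(direction: np.ndarray, path: PathLike) -> np.ndarray:
    """Validate a 3x3 direction-cosine matrix as a signed permutation.

    Returns the rounded signed permutation matrix. Oblique orientations
    would silently shear per-slice metrics, so they are refused outright.
    """
    rounded = np.round(direction)
    if not np.allclose(direction, rounded, atol=1e-3) or not np.array_equal(
        np.abs(rounded).sum(axis=0), np.ones(3)
    ) or not np.array_equal(np.abs(rounded).sum(axis=1), np.ones(3)):
        raise VolumeIOError(
            f"{path}: volume orientation is oblique (direction cosines "
            f"{direction.tolist()}); resample the volume to an axis-aligned "
            "grid before analysis"
        )
    return rounded.astype(int)


def _apply_permutation(
    values: np.ndarray, spacing: Sequence[float], perm_signed: np.ndarray
) -> tuple[np.ndarray, tuple, tuple]:
    """Reorder/flip grid axes so grid axis i is world axis i (x, y, z)."""
    # column j of perm_signed: world direction of grid axis j
    world_of_grid = np.abs(perm_signed).argmax(axis=0)
    flips = [int(perm_signed[world_of_grid[j], j]) < 0 for j in range(3)]
    for j, flip in enumerate(flips):
        if flip:
            values = np.flip(values, axis=j)
    order = np.argsort(world_of_grid)
    values = np.transpose(values, order)
    spacing = tuple(float(spacing[j]) for j in order)
    names = tuple("xyz"[world_of_grid[j]] for j in order)
    return values, spacing, names


def _read_sitk(path: PathLike) -> VoxelVolume:
    try:
        image = sitk.ReadImage(os.fspath(path))
    except RuntimeError as exc:
        raise VolumeIOError(f"cannot read volume {path}: {exc}") from exc
    if image.GetDimension() != 3:
        raise VolumeIOError(f"{path}: expected 3D data, got {image.GetDimension()}D")
    direction = np.asarray(image.GetDirection()).reshape(3, 3)
    perm = _check_axis_aligned(direction, path)
    # GetArrayFromImage is (z, y, x); transpose to ITK's native (x, y, z)
    values = np.transpose(sitk.GetArrayFromImage(image), (2, 1, 0))
    values, spacing, names = _apply_permutation(values, image.GetSpacing(), perm)
    return VoxelVolume(values=values, spacing=spacing, axis_names=names)


def _read_nifti(path: PathLike) -> VoxelVolume:
    try:
        img = nib.load(os.fspath(path))
    except Exception as exc:
        raise VolumeIOError(f"cannot read volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeIOError(f"{path}: expected 3D data, got {data.ndim}D")
    affine = img.affine
    zooms = img.header.get_zooms()[:3]
    unit = img.header.get_xyzt_units()[0]
    scale = _NIFTI_UNIT_TO_MM.get(unit, 1.0)
    if unit not in ("mm", "unknown"):
        log.info("%s: converting NIfTI spatial units %r to mm", path, unit)
    direction = affine[:3, :3] / np.asarray(zooms)[None, :]
    perm = _check_axis_aligned(direction, path)
    values, spacing, names = _apply_permutation(
        data, [z * scale for z in zooms], perm
    )
    return VoxelVolume(values=values, spacing=spacing, axis_names=names)


def _read_tiff_stack(paths: Sequence[PathLike]) -> VoxelVolume:
    planes = []
    for p in paths:
        try:
            plane = tifffile.imread(os.fspath(p))
        except Exception as exc:
            raise VolumeIOError(f"cannot read TIFF {p}: {exc}") from exc
        if plane.ndim != 2:
            raise VolumeIOError(f"{p}: expected a single-plane 2D TIFF")
        planes.append(plane)
    if len({p.shape for p in planes}) != 1:
        raise VolumeIOError("TIFF planes disagree in shape")
    # plane rows/cols -> (y, x); stack axis -> z
    values = np.stack(planes, axis=-1).transpose(1, 0, 2)
    log.warning(
        "TIFF stack carries no physical spacing metadata; assuming 1 mm voxels"
    )
    return VoxelVolume(values=values, spacing=(1.0, 1.0, 1.0))


def read_volume(
    path: Union[PathLike, Sequence[PathLike]], format_hint: Optional[str] = None
) -> VoxelVolume:
    """Read a 3D volume, normalizing axes to (x, y, z) and spacing to mm.

    ``path`` may be one NRRD/NIfTI file, a directory of TIFF planes
    (sorted by name), a glob pattern, or an explicit ordered list of TIFF
    files. Integer voxel values are preserved bit-exactly. TIFF stacks
    without spacing metadata default to 1 mm isotropic with a warning.
    """
    if isinstance(path, (list, tuple)):
        return _read_tiff_stack(path)
    p = Path(path)
    if "*" in str(p):
        matches = sorted(_glob.glob(str(p)))
        if not matches:
            raise VolumeIOError(f"no files match pattern {p}")
        return _read_tiff_stack(matches)
    if p.is_dir():
        tiffs = sorted(
            q for q in p.iterdir() if q.suffix.lower() in (".tif", ".tiff")
        )
        if not tiffs:
            raise VolumeIOError(f"directory {p} contains no TIFF planes")
        return _read_tiff_stack(tiffs)
    if not p.exists():
        raise VolumeIOError(f"no such file: {p}")
    suffixes = "".join(p.suffixes).lower()
    fmt = (format_hint or "").lower()
    if fmt == "nifti" or suffixes.endswith((".nii", ".nii.gz")):
        return _read_nifti(p)
    if fmt == "nrrd" or suffixes.endswith((".nrrd", ".nhdr")):
        return _read_sitk(p)
    if suffixes.endswith((".tif", ".tiff")):
        raise VolumeIOError(
            f"{p} is a single TIFF plane; pass a directory, glob, or explicit "
            "ordered list of planes so the stacking order is unambiguous"
        )
    return _read_sitk(p)  # let ITK sniff anything else


def write_volume(volume: VoxelVolume, path: PathLike, format: Optional[str] = None) -> None:
    """Write a volume as NRRD or NIfTI-1 (chosen by extension or ``format``)."""
    p = Path(path)
    fmt = (format or "").lower()
    suffixes = "".join(p.suffixes).lower()
    is_nifti = fmt == "nifti" or suffixes.endswith((".nii", ".nii.gz"))
    values = np.asarray(volume.values)
    if values.dtype == bool:
        values = values.astype(np.uint8)
    volume = VoxelVolume(values=values, spacing=volume.spacing, axis_names=volume.axis_names)
    try:
        if is_nifti:
            affine = np.diag(list(volume.spacing) + [1.0])
            img = nib.Nifti1Image(np.asarray(volume.values), affine)
            img.header.set_xyzt_units(xyz="mm")
            nib.save(img, os.fspath(p))
        else:
            image = sitk.GetImageFromArray(
                np.ascontiguousarray(np.transpose(volume.values, (2, 1, 0)))
            )
            image.SetSpacing(tuple(float(s) for s in volume.spacing))
            sitk.WriteImage(image, os.fspath(p))
    except (RuntimeError, OSError) as exc:
        raise VolumeIOError(f"cannot write volume to {p}: {exc}") from exc


def extract_mask(volume: VoxelVolume, label: int) -> SegmentMask:
    """Binary mask of voxels equal to ``label``, spacing copied.

    Raises ``ValueError`` listing the labels actually present when the
    requested one is absent.
    """
    voxels = volume.values == label
    if not voxels.any():
        present = np.unique(volume.values)
        raise ValueError(
            f"label {label} not present in volume; labels found: "
            f"{present[:20].tolist()}"
        )
    return SegmentMask(voxels=voxels, spacing=volume.spacing, label_value=int(label))
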