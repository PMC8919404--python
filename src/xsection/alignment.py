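"""Orient a structure so its long axis coincides with the slicing axis.

Automatic alignment follows the segment's 3D moments of inertia: the long
axis is the direction of largest spatial spread of foreground voxel
centers, i.e. the axis about which the (unweighted) moment of inertia is
smallest. Explicit Euler rotations are applied in the fixed order
x-then-y-then-z about the foreground centroid unless another center is
given. Masks are resampled with nearest-neighbor interpolation so labels
stay binary; intensity volumes ride along with linear interpolation.
"""

from __future__ import annotations

import logging
import math
from typing import List, Optional, Tuple, Union

import numpy as np
from scipy import ndimage

from .types import RotationSpec, SegmentMask, SliceSection, VoxelVolume

log = logging.getLogger(__name__)

_AXIS_IDS = {"x": 0, "y": 1, "z": 2, 0: 0, 1: 1, 2: 2}

# eigenvalue gap below which spreads count as tied (fraction of the largest)
_DEGENERACY_RTOL = 1e-9


def _foreground_coords_mm(mask: SegmentMask) -> np.ndarray:
    idx = np.argwhere(mask.voxels).astype(float)
    return idx * np.asarray(mask.spacing)[None, :]


def inertia_axes_3d(
    mask: SegmentMask, slicing_axis: Union[int, str] = "z"
) -> Tuple[np.ndarray, np.ndarray]:
    """Principal-axis rotation from the segment's moments of inertia.

    Returns ``(R, extents)`` where ``R`` is a proper rotation (3x3,
    det = +1) mapping physical coordinates so that the long axis (largest
    coordinate spread, smallest moment of inertia) lands on the slicing
    axis and the shortest axis on the first remaining grid axis;
    ``extents`` are the RMS spreads (mm) about the centroid sorted to match
    the output axes. Eigenvector signs are fixed by requiring a
    non-negative projection onto the original slicing axis (ties broken on
    the next axes), so the result is deterministic. A fully degenerate
    segment (e.g. a cube) returns the identity; a collinear segment keeps
    the collinear direction as the long axis.
    """
    mask.require_nonempty()
    axis = _AXIS_IDS[slicing_axis]
    coords = _foreground_coords_mm(mask)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    evals, evecs = np.linalg.eigh(cov)  # ascending: small spread first
    if evals[-1] <= _DEGENERACY_RTOL or (evals[-1] - evals[0]) <= _DEGENERACY_RTOL * evals[-1]:
        return np.eye(3), np.sqrt(np.maximum(evals, 0.0))
    # destination order: long axis -> slicing axis, others fill remaining
    # grid axes in ascending-spread order
    rest = [a for a in range(3) if a != axis]
    dest_cols = np.empty((3, 3))
    dest_cols[:, axis] = evecs[:, 2]
    dest_cols[:, rest[0]] = evecs[:, 0]
    dest_cols[:, rest[1]] = evecs[:, 1]
    extents = np.empty(3)
    extents[axis] = math.sqrt(max(evals[2], 0.0))
    extents[rest[0]] = math.sqrt(max(evals[0], 0.0))
    extents[rest[1]] = math.sqrt(max(evals[1], 0.0))
    # deterministic signs: non-negative projection on the slicing axis,
    # ties resolved on the following axes
    probe_order = [axis] + rest
    for col in (axis, rest[1]):
        v = dest_cols[:, col]
        for p in probe_order:
            if abs(v[p]) > 1e-12:
                if v[p] < 0:
                    dest_cols[:, col] = -v
                break
    # third column from the other two keeps det = +1 and stays an eigenvector
    dest_cols[:, rest[0]] = np.cross(
        dest_cols[:, rest[1]], dest_cols[:, axis]
    ) * (1 if (rest[1], axis) in ((0, 1), (1, 2), (2, 0)) else -1)
    rotation = dest_cols.T  # maps eigenvector for column j onto grid axis j
    return rotation, extents


def _euler_matrix(angles_deg: Tuple[float, float, float]) -> np.ndarray:
    """Fixed-order rotation: about x, then y, then z (extrinsic)."""
    ax, ay, az = (math.radians(a) for a in angles_deg)
    cx, sx = math.cos(ax), math.sin(ax)
    cy, sy = math.cos(ay), math.sin(ay)
    cz, sz = math.cos(az), math.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _resample(
    values: np.ndarray,
    spacing: Tuple[float, float, float],
    rotation: np.ndarray,
    center_mm: np.ndarray,
    order: int,
) -> np.ndarray:
    """Rotate a grid about ``center_mm`` in physical space, expanding extent.

    The output grid keeps the input spacing; its origin is chosen so the
    rotated bounding box of the full input grid fits without clipping.
    """
    spacing_arr = np.asarray(spacing, dtype=float)
    shape = np.asarray(values.shape, dtype=float)
    corners_idx = np.array(
        [[i, j, k] for i in (0, shape[0] - 1) for j in (0, shape[1] - 1) for k in (0, shape[2] - 1)]
    )
    corners_mm = corners_idx * spacing_arr
    rotated = (rotation @ (corners_mm - center_mm).T).T + center_mm
    lo = rotated.min(axis=0)
    hi = rotated.max(axis=0)
    out_shape = np.ceil((hi - lo) / spacing_arr).astype(int) + 3
    origin = lo - spacing_arr  # one-voxel margin
    # output index -> physical -> inverse-rotate -> input index
    r_inv = rotation.T
    matrix = (r_inv * spacing_arr[None, :]) / spacing_arr[:, None]
    offset = (r_inv @ (origin - center_mm) + center_mm) / spacing_arr
    return ndimage.affine_transform(
        values.astype(float),
        matrix=matrix,
        offset=offset,
        output_shape=tuple(out_shape),
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=order > 1,
    )


def apply_rotation(
    mask: SegmentMask,
    spec: RotationSpec,
    intensity: Optional[VoxelVolume] = None,
    slicing_axis: Union[int, str] = "z",
) -> Union[SegmentMask, Tuple[SegmentMask, VoxelVolume]]:
    """Rotate a mask (and optionally its intensity volume) per ``spec``.

    mode 'none' returns the inputs unchanged; 'principal_inertia' computes
    the alignment rotation from :func:`inertia_axes_3d`; 'euler' applies the
    user angles. Output grids are expanded so no foreground voxel is
    clipped and spacing is preserved. Returns the mask alone, or a
    ``(mask, intensity)`` pair when an intensity volume is supplied.
    """
    mask.require_nonempty()
    if spec.mode == "none":
        return (mask, intensity) if intensity is not None else mask
    if spec.mode == "principal_inertia":
        rotation, _ = inertia_axes_3d(mask, slicing_axis)
    else:
        rotation = _euler_matrix(spec.euler_angles_deg)
    spacing_arr = np.asarray(mask.spacing, dtype=float)
    if spec.center is not None:
        center_mm = np.asarray(spec.center, dtype=float)
    else:
        center_mm = _foreground_coords_mm(mask).mean(axis=0)
    rotated = _resample(mask.voxels.astype(float), mask.spacing, rotation, center_mm, order=0)
    out_mask = SegmentMask(
        voxels=rotated >= 0.5, spacing=mask.spacing, label_value=mask.label_value
    )
    if intensity is None:
        return out_mask
    if intensity.values.shape != mask.voxels.shape:
        raise ValueError("intensity volume must share the mask's grid")
    rot_int = _resample(
        np.asarray(intensity.values, dtype=float),
        intensity.spacing,
        rotation,
        center_mm,
        order=1,
    )
    return out_mask, VoxelVolume(
        values=rot_int, spacing=intensity.spacing, axis_names=intensity.axis_names
    )


def slice_stack(
    mask: SegmentMask,
    intensity: Optional[VoxelVolume] = None,
    axis: Union[int, str] = "z",
) -> List[SliceSection]:
    """Cut the mask into ordered 2D sections along a grid axis.

    One section per plane from the first to the last plane containing
    foreground (inclusive); interior planes with no foreground are emitted
    as empty sections so indices stay aligned. Each section carries its
    in-plane spacings and a percent-length position: 0% at the first
    occupied plane, 100% at the last (a single-plane structure is 0%).
    """
    mask.require_nonempty()
    if axis not in _AXIS_IDS:
        raise ValueError(f"invalid slicing axis {axis!r}; use x, y, z or 0..2")
    ax = _AXIS_IDS[axis]
    if intensity is not None and intensity.values.shape != mask.voxels.shape:
        raise ValueError("intensity volume must share the mask's grid")
    occupied = np.any(mask.voxels, axis=tuple(a for a in range(3) if a != ax))
    planes = np.nonzero(occupied)[0]
    first, last = int(planes[0]), int(planes[-1])
    in_plane = [a for a in range(3) if a != ax]
    spacing2d = (mask.spacing[in_plane[0]], mask.spacing[in_plane[1]])
    sections: List[SliceSection] = []
    for i in range(first, last + 1):
        pixels = np.take(mask.voxels, i, axis=ax)
        inten = (
            np.take(np.asarray(intensity.values, dtype=float), i, axis=ax)
            if intensity is not None
            else None
        )
        pct = 0.0 if last == first else 100.0 * (i - first) / (last - first)
        section = SliceSection(
            pixels=pixels,
            pixel_spacing=spacing2d,
            intensity=inten,
            plane_index=i,
            percent_length=pct,
        )
        if section.is_empty:
            log.warning("plane %d inside the occupied range is empty", i)
        sections.append(section)
    return sections
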