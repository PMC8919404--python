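"""Shared domain types.

All physical lengths are millimetres; areas mm^2, section moduli mm^3,
second/polar moments mm^4. Grid axes are ordered (x, y, z) and the default
slicing axis is z; within a slice the first array axis is the horizontal
(+x) direction and the second the vertical (+y) direction, with angles
measured in degrees counterclockwise from horizontal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

AXIS_NAMES = ("x", "y", "z")


class EmptySectionError(ValueError):
    """Raised when a geometric operation is asked for an empty cross-section."""


def _check_spacing(spacing: Tuple[float, float, float]) -> Tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(not math.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive numbers, got {spacing!r}")
    return spacing


@dataclass
class VoxelVolume:
    """A 3D scalar grid (intensities or integer labels) with mm spacing.

    ``values[i, j, k]`` sits at physical position ``(i*sx, j*sy, k*sz)``
    (voxel centers). ``axis_names`` records which anatomical/file axis each
    grid axis came from after readers permute into the (x, y, z) convention.
    """

    values: np.ndarray
    spacing: Tuple[float, float, float]
    axis_names: Tuple[str, str, str] = AXIS_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.values.ndim}D")
        if min(self.values.shape) < 1:
            raise ValueError("every grid axis must have extent >= 1")
        self.spacing = _check_spacing(self.spacing)
        self.axis_names = tuple(self.axis_names)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape


@dataclass
class SegmentMask:
    """A binary foreground mask extracted from a labeled volume."""

    voxels: np.ndarray
    spacing: Tuple[float, float, float]
    label_value: int = 1

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"mask must be 3D, got {self.voxels.ndim}D")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    def require_nonempty(self) -> None:
        if not self.voxels.any():
            raise EmptySectionError("segment mask contains no foreground voxels")


@dataclass
class SliceSection:
    """One 2D cross-section: binary pixels plus optional co-registered intensity.

    ``pixels[i, j]`` is the material at in-plane position
    ``(i*px, j*py)``; ``percent_length`` places the slice along the occupied
    extent of the structure (0 at the first occupied plane, 100 at the last).
    """

    pixels: np.ndarray
    pixel_spacing: Tuple[float, float]
    intensity: Optional[np.ndarray] = None
    plane_index: int = 0
    percent_length: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("section pixels must be 2D")
        px, py = (float(s) for s in self.pixel_spacing)
        if px <= 0 or py <= 0:
            raise ValueError("pixel spacings must be positive")
        self.pixel_spacing = (px, py)
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=float)
            if self.intensity.shape != self.pixels.shape:
                raise ValueError("intensity grid must match pixel grid shape")

    @property
    def is_empty(self) -> bool:
        return not self.pixels.any()

    def require_nonempty(self) -> None:
        if self.is_empty:
            raise EmptySectionError(
                f"slice {self.plane_index} contains no foreground pixels"
            )


@dataclass
class InertiaTensor2D:
    """Centroidal area-moment tensor of one cross-section.

    Ixx is the second moment about the horizontal centroidal axis
    (integral of y^2 dA), Iyy about the vertical axis (x^2 dA), and Ixy the
    product moment (x*y dA); centroid in mm from the slice origin.
    """

    Ixx: float
    Iyy: float
    Ixy: float
    centroid: Tuple[float, float]
    area: float

    def __post_init__(self) -> None:
        if self.Ixx < 0 or self.Iyy < 0:
            raise ValueError("diagonal moments must be non-negative")
        det = self.Ixx * self.Iyy - self.Ixy**2
        if det < -1e-9 * max(self.Ixx * self.Iyy, 1.0):
            raise ValueError("inertia tensor must be positive semidefinite")


@dataclass
class SectionProperties:
    """Every per-slice metric, raw (unnormalized)."""

    plane_index: int
    percent_length: float
    CSA: float
    centroid: Tuple[float, float]
    Ixx: float
    Iyy: float
    Ixy: float
    I_about_minor_axis: float  # maximum centroidal second moment
    I_about_major_axis: float  # minimum centroidal second moment
    theta_principal: float  # deg CCW from horizontal of the minimum-I axis
    Z_minor_axis: float
    Z_major_axis: float
    J: float
    feret_max: float
    perimeter: float
    TCSA: float
    compactness: float
    mean_brightness: float = math.nan
    I_NA: float = math.nan  # about the user neutral axis, when requested
    Z_NA: float = math.nan
    neutral_axis_deg: Optional[float] = None
    is_empty: bool = False

    @classmethod
    def empty(cls, plane_index: int, percent_length: float) -> "SectionProperties":
        nan = math.nan
        return cls(
            plane_index=plane_index,
            percent_length=percent_length,
            CSA=nan,
            centroid=(nan, nan),
            Ixx=nan,
            Iyy=nan,
            Ixy=nan,
            I_about_minor_axis=nan,
            I_about_major_axis=nan,
            theta_principal=nan,
            Z_minor_axis=nan,
            Z_major_axis=nan,
            J=nan,
            feret_max=nan,
            perimeter=nan,
            TCSA=nan,
            compactness=nan,
            is_empty=True,
        )


@dataclass
class NormalizedProperties:
    """Length- and material-normalized variants for one slice.

    Length normalization reduces each quantity to a dimensionless linear
    measure via its root (CSA^1/2, Z^1/3, I and J^1/4) divided by structure
    length; material normalization is the ratio to a solid circle of equal
    cross-sectional area.
    """

    I_minor_lennorm: float = math.nan
    I_major_lennorm: float = math.nan
    I_NA_lennorm: float = math.nan
    Z_minor_lennorm: float = math.nan
    Z_major_lennorm: float = math.nan
    Z_NA_lennorm: float = math.nan
    J_lennorm: float = math.nan
    CSA_lennorm: float = math.nan
    I_minor_matnorm: float = math.nan
    I_major_matnorm: float = math.nan
    I_NA_matnorm: float = math.nan
    Z_minor_matnorm: float = math.nan
    Z_major_matnorm: float = math.nan
    Z_NA_matnorm: float = math.nan
    J_matnorm: float = math.nan
    compactness: float = math.nan


@dataclass
class RotationSpec:
    """How to orient the structure before slicing.

    mode 'none' leaves the grid as-is, 'principal_inertia' aligns the long
    axis (from the 3D moments of inertia of the foreground) with the slicing
    axis, and 'euler' applies fixed-order x-then-y-then-z rotations about
    ``center`` (default: foreground centroid).
    """

    mode: str = "none"
    euler_angles_deg: Optional[Tuple[float, float, float]] = None
    center: Optional[Tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if self.mode not in ("none", "principal_inertia", "euler"):
            raise ValueError(f"unknown rotation mode {self.mode!r}")
        if self.mode == "euler":
            if self.euler_angles_deg is None:
                raise ValueError("mode='euler' requires euler_angles_deg")
            angles = tuple(float(a) for a in self.euler_angles_deg)
            if len(angles) != 3 or any(not math.isfinite(a) for a in angles):
                raise ValueError("euler_angles_deg must be three finite degrees")
            self.euler_angles_deg = angles


@dataclass
class BeamReport:
    """Whole-structure slenderness check for the no-shear beam assumption."""

    length_L: float
    min_max_feret: float
    aspect_ratio: float
    shear_warning: bool
    trim_fraction: float = 0.05
    n_trimmed_per_end: int = 0


@dataclass
class DeflectionCase:
    """Euler-Bernoulli point-load deflection of a prismatic beam.

    configuration 'cantilever_end_load': delta = F L^3 / (3 E I);
    'simply_supported_midpoint': delta = F L^3 / (48 E I). The
    small-deflection assumption holds when delta < 10% of L.
    """

    F: float
    L: float
    E: float
    I: float
    configuration: str
    delta: float = math.nan
    small_deflection_ok: bool = False
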