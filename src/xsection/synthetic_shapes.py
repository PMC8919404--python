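"""Rasterized canonical beams with known closed-form section properties.

Every other module is testable against these fixtures without any external
data: a shape is rasterized on a voxel grid (a voxel is foreground iff its
center lies inside the continuous solid, matching the binary pixel model
of the geometry engine) and its continuum ground truth travels with it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple, Union

import numpy as np

from .types import SegmentMask, VoxelVolume

KINDS = (
    "cylinder",
    "tube",
    "box",
    "elliptical_beam",
    "i_beam",
    "oblique_cylinder",
    "dumbbell",
)

MAX_GRID_VOXELS = 250_000_000


@dataclass
class ShapeSpec:
    """A canonical beam to rasterize.

    dimensions (mm) by kind:
      cylinder: r; tube: ro, ri (ri < ro); box: w, h;
      elliptical_beam: a, b (semi-axes along x and y);
      i_beam: w, h, flange_t, web_t; oblique_cylinder: r, tilt_deg
      (axis tilted about y, in the x-z plane); dumbbell: r, gap
      (two coaxial cylinders separated by ``gap`` of empty planes).
    ``length`` is the extent along the beam axis, ``pitch`` the voxel size
    (scalar isotropic or a 3-tuple), ``intensity_fill`` an optional
    constant or 'z_gradient' for a co-registered intensity volume, and
    ``jitter`` shifts the shape off lattice-symmetric positions by a
    seeded sub-voxel amount.
    """

    kind: str
    dimensions: Dict[str, float]
    length: float
    pitch: Union[float, Tuple[float, float, float]] = 1.0
    intensity_fill: Optional[Union[float, str]] = None
    jitter: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r}; expected one of {KINDS}")
        if self.length <= 0:
            raise ValueError("length must be positive")
        if any(v <= 0 for v in self.dimensions.values()):
            raise ValueError("all shape dimensions must be positive")
        if self.kind == "tube" and self.dimensions["ri"] >= self.dimensions["ro"]:
            raise ValueError("tube requires ri < ro")
        if isinstance(self.pitch, (int, float)):
            self.pitch = (float(self.pitch),) * 3
        else:
            self.pitch = tuple(float(p) for p in self.pitch)
        if any(p <= 0 for p in self.pitch):
            raise ValueError("pitch must be positive")

    @property
    def spacing(self) -> Tuple[float, float, float]:
        return self.pitch


def _inplane_halfextent(spec: ShapeSpec) -> Tuple[float, float]:
    d = spec.dimensions
    if spec.kind in ("cylinder", "dumbbell"):
        return d["r"], d["r"]
    if spec.kind == "tube":
        return d["ro"], d["ro"]
    if spec.kind == "box":
        return d["w"] / 2, d["h"] / 2
    if spec.kind == "elliptical_beam":
        return d["a"], d["b"]
    if spec.kind == "i_beam":
        return d["w"] / 2, d["h"] / 2
    if spec.kind == "oblique_cylinder":
        t = math.radians(d["tilt_deg"])
        # axis in the x-z plane: x footprint grows with the tilted run
        return d["r"] / abs(math.cos(t)) + spec.length / 2 * abs(math.sin(t)), d["r"]
    raise AssertionError(spec.kind)


def _inside(spec: ShapeSpec, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Membership test in centered coordinates (z = 0 at mid-length)."""
    d = spec.dimensions
    half_l = spec.length / 2
    along = np.abs(z) <= half_l
    if spec.kind == "cylinder":
        return along & (x**2 + y**2 <= d["r"] ** 2)
    if spec.kind == "tube":
        r2 = x**2 + y**2
        return along & (r2 > d["ri"] ** 2) & (r2 <= d["ro"] ** 2)
    if spec.kind == "box":
        return along & (np.abs(x) <= d["w"] / 2) & (np.abs(y) <= d["h"] / 2)
    if spec.kind == "elliptical_beam":
        return along & ((x / d["a"]) ** 2 + (y / d["b"]) ** 2 <= 1.0)
    if spec.kind == "i_beam":
        nw = (d["w"] - d["web_t"]) / 2
        nh = d["h"] - 2 * d["flange_t"]
        outer = (np.abs(x) <= d["w"] / 2) & (np.abs(y) <= d["h"] / 2)
        notch = (np.abs(x) > d["web_t"] / 2) & (np.abs(y) < nh / 2)
        return along & outer & ~notch
    if spec.kind == "oblique_cylinder":
        t = math.radians(d["tilt_deg"])
        ux, uz = math.sin(t), math.cos(t)
        s = x * ux + z * uz
        rad2 = (x - s * ux) ** 2 + y**2 + (z - s * uz) ** 2
        return (np.abs(s) <= half_l) & (rad2 <= d["r"] ** 2)
    if spec.kind == "dumbbell":
        seg = (spec.length - d["gap"]) / 2
        if seg <= 0:
            raise ValueError("dumbbell gap must be smaller than length")
        in_seg = (np.abs(z) <= half_l) & (np.abs(z) > d["gap"] / 2)
        return in_seg & (x**2 + y**2 <= d["r"] ** 2)
    raise AssertionError(spec.kind)


def rasterize(spec: ShapeSpec) -> Tuple[SegmentMask, Optional[VoxelVolume]]:
    """Voxelize a shape; returns the mask and the optional intensity volume.

    Deterministic for a given spec and seed. The grid is sized to the
    shape plus a two-voxel margin; an error suggests a coarser pitch when
    that grid would be unreasonably large.
    """
    px, py, pz = spec.spacing
    hx, hy = _inplane_halfextent(spec)
    if spec.kind == "oblique_cylinder":
        t = math.radians(spec.dimensions["tilt_deg"])
        hz = spec.length / 2 * abs(math.cos(t)) + spec.dimensions["r"] / abs(math.cos(t))
    else:
        hz = spec.length / 2
    # even extents + half-pixel-offset lattice: voxel centers never land
    # exactly on a shape boundary that is a multiple of the pitch, so e.g.
    # a box with pitch-multiple sides rasterizes to its exact area
    nx = int(math.ceil(2 * hx / px)) + 6
    ny = int(math.ceil(2 * hy / py)) + 6
    nz = int(math.ceil(2 * hz / pz)) + 6
    nx += nx % 2
    ny += ny % 2
    nz += nz % 2
    if nx * ny * nz > MAX_GRID_VOXELS:
        raise ValueError(
            f"shape would need a {nx}x{ny}x{nz} grid "
            f"({nx * ny * nz:.2e} voxels); use a coarser pitch"
        )
    offset = np.zeros(3)
    if spec.jitter:
        rng = np.random.default_rng(spec.seed)
        offset = rng.uniform(-0.5, 0.5, size=3) * np.array([px, py, pz])
    x = (np.arange(nx) + 0.5 - nx / 2) * px - offset[0]
    y = (np.arange(ny) + 0.5 - ny / 2) * py - offset[1]
    z = (np.arange(nz) + 0.5 - nz / 2) * pz - offset[2]
    xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")
    voxels = _inside(spec, xx, yy, zz)
    mask = SegmentMask(voxels=voxels, spacing=spec.spacing)
    intensity = None
    if spec.intensity_fill is not None:
        if spec.intensity_fill == "z_gradient":
            vals = np.broadcast_to(
                100.0 * (np.arange(nz) / max(nz - 1, 1))[None, None, :], voxels.shape
            ).copy()
        else:
            vals = np.full(voxels.shape, float(spec.intensity_fill))
        vals[~voxels] = 0.0
        intensity = VoxelVolume(values=vals, spacing=spec.spacing)
    return mask, intensity


def _ellipse_perimeter(a: float, b: float) -> float:
    """Ramanujan's second approximation (sub-ppm for moderate aspect ratios)."""
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))


def closed_form_properties(spec: ShapeSpec) -> Dict[str, float]:
    """Continuum ground truth for the cross-section of a shape.

    Keys: CSA, Ixx (about horizontal), Iyy, I_minor (max principal),
    I_major (min principal), Z_horizontal, J, perimeter, feret_max, TCSA,
    compactness, plus kind-specific extras. The I-beam values come from
    composite-rectangle summation (outer rectangle minus the two notches
    with their parallel-axis transfers), which independently exercises the
    additivity of the per-pixel summation. The dumbbell has no single
    closed form (its interior slices are empty) and raises ValueError.
    """
    d = spec.dimensions
    k = spec.kind
    if k in ("cylinder", "oblique_cylinder", "dumbbell"):
        if k == "dumbbell":
            raise ValueError("dumbbell has no whole-shape closed form")
        r = d["r"]
        csa = math.pi * r**2
        ixx = math.pi * r**4 / 4
        out = dict(
            CSA=csa, Ixx=ixx, Iyy=ixx, I_minor=ixx, I_major=ixx,
            Z_horizontal=math.pi * r**3 / 4, J=2 * ixx,
            perimeter=2 * math.pi * r, feret_max=2 * r, TCSA=csa, compactness=1.0,
        )
        if k == "oblique_cylinder":
            t = math.radians(d["tilt_deg"])
            out["tilt_deg"] = d["tilt_deg"]
            out["axis_direction"] = (math.sin(t), 0.0, math.cos(t))
            # a z-slice through the tilted shaft is an ellipse stretched in x
            a, b = r / math.cos(t), r
            out.update(
                slice_CSA=math.pi * a * b,
                slice_Ixx=math.pi * a * b**3 / 4,
                slice_Iyy=math.pi * a**3 * b / 4,
            )
        return out
    if k == "tube":
        ro, ri = d["ro"], d["ri"]
        csa = math.pi * (ro**2 - ri**2)
        ixx = math.pi * (ro**4 - ri**4) / 4
        return dict(
            CSA=csa, Ixx=ixx, Iyy=ixx, I_minor=ixx, I_major=ixx,
            Z_horizontal=ixx / ro, J=2 * ixx,
            perimeter=2 * math.pi * (ro + ri), feret_max=2 * ro,
            TCSA=math.pi * ro**2, compactness=(ro**2 - ri**2) / ro**2,
        )
    if k == "box":
        w, h = d["w"], d["h"]
        ixx = w * h**3 / 12
        iyy = h * w**3 / 12
        return dict(
            CSA=w * h, Ixx=ixx, Iyy=iyy,
            I_minor=max(ixx, iyy), I_major=min(ixx, iyy),
            Z_horizontal=w * h**2 / 6, J=ixx + iyy,
            perimeter=2 * (w + h), feret_max=math.hypot(w, h),
            TCSA=w * h, compactness=1.0,
        )
    if k == "elliptical_beam":
        a, b = d["a"], d["b"]
        csa = math.pi * a * b
        ixx = math.pi * a * b**3 / 4
        iyy = math.pi * a**3 * b / 4
        return dict(
            CSA=csa, Ixx=ixx, Iyy=iyy,
            I_minor=max(ixx, iyy), I_major=min(ixx, iyy),
            Z_horizontal=ixx / b, J=ixx + iyy,
            perimeter=_ellipse_perimeter(a, b), feret_max=2 * max(a, b),
            TCSA=csa, compactness=1.0,
        )
    if k == "i_beam":
        w, h, tf, tw = d["w"], d["h"], d["flange_t"], d["web_t"]
        nw = (w - tw) / 2
        nh = h - 2 * tf
        # composite rectangles: outer minus the two notches
        csa = w * h - 2 * nw * nh
        ixx = w * h**3 / 12 - 2 * (nw * nh**3 / 12)
        dx = tw / 2 + nw / 2  # notch centroid offset from the section centroid
        iyy = h * w**3 / 12 - 2 * (nh * nw**3 / 12 + nh * nw * dx**2)
        return dict(
            CSA=csa, Ixx=ixx, Iyy=iyy,
            I_minor=max(ixx, iyy), I_major=min(ixx, iyy),
            Z_horizontal=ixx / (h / 2), J=ixx + iyy,
            perimeter=2 * (w + h) + 4 * nw, feret_max=math.hypot(w, h),
            TCSA=csa, compactness=1.0,
        )
    raise ValueError(f"no closed form for kind {k!r}")
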