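# Methods

## Model and scope

`xsection` treats a segmented 3D structure as a prismatic beam sampled
plane by plane along a grid axis. All quantities are classical area
properties of the 2D cross-sections; the material is assumed homogeneous,
isotropic and linearly elastic wherever beam-theory quantities (section
modulus, deflection) are interpreted mechanically. Two standing
restrictions follow from that model:

- every neutral axis passes through the section centroid (appropriate for
  beams that are not end-loaded; end loading shifts the neutral axis
  toward the tensile side and is out of scope);
- moments are unweighted by voxel intensity. Density-weighted moments
  would require calibrated grayscale (phantom-standardized CT), which
  most public scan repositories cannot provide; mean pixel brightness is
  reported per slice so users can judge heterogeneity, but it never
  enters the moments.

## The pixel model

A foreground pixel with spacing (px, py) is a solid px×py rectangle
centered on its lattice point. The centroidal tensor is the exact sum of
each rectangle's own moment (px·py³/12 about horizontal, px³·py/12 about
vertical, zero product term) plus the parallel-axis transfer A·D² to the
area centroid. Because each pixel's own product moment vanishes, the
second moment about a centroidal axis at angle θ follows exactly from the
tensor rotation

I(θ) = Ixx cos²θ + Iyy sin²θ − 2 Ixy sinθ cosθ,

and this equality against direct per-pixel re-summation (to 1e−9
relative) is a standing test. The model makes single-pixel and
coarse-grid sections principled rather than special cases, and supports
anisotropic in-plane spacing without resampling.

Principal moments are the eigenvalues of the 2×2 tensor. Following the
field's convention for bending resistance, the **minor** principal axis
carries the *maximum* I and the **major** axis the minimum;
`theta_principal` is the angle of the minimum-I (major) axis in
(−90°, 90°], counterclockwise from the slice horizontal. Isotropic
tensors (|Ixx−Iyy| and |Ixy| below 1e−12·J) tie-break to θ = 0.

## Numerical choices

- **Section modulus distance.** Z = I(θ)/c with c the largest
  perpendicular distance from the axis to a foreground *pixel center*.
  The pixel-corner alternative would systematically lengthen c by up to a
  half-diagonal; the center convention is used consistently and a section
  lying entirely on the axis (c = 0) reports a null with a warning rather
  than an infinite modulus.
- **Feret diameter** is the maximum pairwise distance between *corner*
  points of foreground pixels (reduced to per-column extremes, then the
  convex hull), so a single pixel measures its diagonal √(px²+py²). On
  smooth shapes the rasterized polygon genuinely extends up to a
  half-diagonal beyond the continuum outline, so the measured Feret
  converges to the continuum value from above at O(pitch).
- **Perimeter** is the total length of the sub-pixel 0.5-level
  marching-squares isocontour over all boundaries, outer and inner. The
  mask is pre-smoothed with a 1-pixel Gaussian before contouring: on raw
  binary data the isocontour is restricted to axis-parallel and 45°
  segments and overestimates smooth boundaries by about 5% (measured on
  a radius-100-pixel disc), while the smoothed isocontour tracks the same
  disc to ~0.6%. Shapes too thin to survive smoothing (e.g. one-pixel
  lines) fall back to the raw binary contour.
- **Vacuities** (for TCSA and compactness) are background components not
  connected to the slice border under 4-connectivity, the standard dual
  of 8-connected foreground; a notch open to the border is not a vacuity.
- **Multiple islands** in a slice are all included by default; the
  `largest_island` option restricts to the biggest 8-connected component
  for fragmented or noisy segmentations.
- **Empty planes** inside the occupied range produce all-null rows that
  stay in the table (keeping plane indexing aligned) but are excluded
  from plots and from the Feret minimum.

## Alignment

Automatic alignment diagonalizes the covariance of foreground voxel
center coordinates (mm). The long axis is the direction of largest
coordinate spread — equivalently the axis of smallest moment of inertia —
and is mapped onto the slicing axis; the remaining axes take the other
two principal directions in ascending-spread order. Determinism: each
eigenvector's sign is fixed by requiring a non-negative projection onto
the original slicing axis (ties fall through to the next axes), the third
column is the cross product of the other two (so det = +1 always), and a
fully degenerate segment (a cube) returns the identity. Recovery of
deliberately tilted rasterized shafts is accurate to well under the 2°
tolerance the tests assert at the pitches used (beam length ≥ 40 voxel
pitches).

Explicit rotations use the fixed order x-then-y-then-z (extrinsic),
about the foreground centroid unless a center is given; no universal
Euler convention exists across imaging tools, so one documented order is
the contract. Masks are resampled with nearest-neighbor interpolation
(labels stay binary), intensity volumes with linear interpolation under
the same transform; the output grid is expanded so no foreground voxel is
clipped and spacing is never changed. Lattice-preserving 90° rotations
about a lattice-centered centroid conserve the voxel count exactly;
generic rotations conserve foreground volume to well under 2% round trip
at the fixture pitches used.

Percent length of plane i is 100·(i − i_first)/(i_last − i_first) over
the occupied range, 0% for a single-plane structure.

## Normalization

Length normalization divides the k-th root of a property by the
structure length L (k = 2 for CSA, 3 for Z, 4 for I and J), making the
result invariant under isometric scaling. L defaults to the occupied
extent along the slicing axis (slice count × slice spacing) — the one
length the data itself defines — and can be overridden with an anatomical
length when the user has one. Material normalization divides by the same
property of a solid circle of equal area: with r = √(CSA/π),
I_circle = CSA²/4π, J_circle = CSA²/2π, Z_circle = CSA^3/2 / 4√π. No
cross-section-size-only normalization is offered: no single size proxy
(width, area, perimeter) is defensible across highly variable section
shapes.

## Beam checks

The aspect ratio is L divided by the smallest per-slice maximum Feret
diameter after dropping floor(0.05·n) occupied slices from each end
(0 for stacks under 20 slices — floor keeps short stacks usable); a ratio
strictly under 10 raises the shear warning (a boundary ratio of exactly
10 passes, per the "under 10" rule). Deflections are δ = FL³/(cEI) with
c = 3 (cantilever, end point load) or 48 (simply supported, midpoint
load); the small-deflection flag is strict δ < 0.10·L. Trimming counts
slices, not physical length, so anisotropic slice spacing does not skew
the trim.

## Synthetic shapes

The generator rasterizes canonical beams by testing voxel *centers*
against the continuous solid — deliberately the same inside rule as the
engine's pixel model, so fixture and engine discretization errors are
commensurate. The lattice is half-pixel offset with even extents, so
boundaries that are whole multiples of the pitch never pass exactly
through voxel centers; a box with pitch-multiple sides rasterizes to its
exact continuum area, and boundary-equality float artifacts are avoided.
Optional seeded sub-voxel jitter breaks this lattice registration for
convergence studies. The I-beam's ground truth is computed by
composite-rectangle summation (outer rectangle minus the two notch
rectangles with their parallel-axis transfers), which doubles as an
independent check of the engine's additivity.

What the fixtures do *not* emulate: partial-volume gray levels at
boundaries, segmentation noise, curved beam axes, and intensity
heterogeneity of real tissue. Passing the oracle suites therefore
demonstrates correctness of the geometry engine on exactly-known shapes,
not robustness to segmentation error — on real data the dominant error
source is the segmentation itself.

## Problem sizes and tolerances

Test fixtures use pitches of 1/50 to 1/100 of the smallest in-plane
feature, where every closed-form comparison lands within 1% (2% for
perimeter and in-plane-rotated fixtures); identities (J = Ixx + Iyy,
parallel-axis, tensor-vs-summation) are asserted at 1e−9 relative or
better since they are arithmetic, not discretization, statements.
Alignment fixtures use shafts of 40 mm at 0.5 mm pitch. NIfTI stores
spacings as 32-bit floats; round-trip tests that require bit-exact
spacing use float32-representable values, and spacing should generally be
treated as accurate to float32 precision when moving through NIfTI.

## File formats

NRRD is read and written through SimpleITK, NIfTI-1 through nibabel
(honoring the header's spatial units and converting to mm), TIFF stacks
through tifffile (no spacing metadata: 1 mm assumed with a warning).
Readers normalize axis order to (x, y, z) and undo axis flips recorded in
orientation metadata; genuinely oblique direction matrices are rejected
with an instruction to resample, because slicing an oblique grid
axis-aligned would silently corrupt every per-slice metric. Plain
labelmap volumes are the supported segmentation dialect; multi-segment
overlapping-label containers are out of scope.
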