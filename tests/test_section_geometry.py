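"""Math-core tests: moments, principal axes, modulus, Feret, perimeter, vacuities.

The independent oracle throughout is a direct per-pixel summation of the
parallel-axis decomposition about an axis at an arbitrary angle, written
with none of the tensor machinery under test.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import xsection as xs
from xsection import EmptySectionError, SliceSection
from conftest import random_section

# ---------------------------------------------------------------- oracle


def direct_summation_I(section: SliceSection, angle_deg: float, through=None) -> float:
    """Brute-force second moment about an axis at ``angle_deg``.

    The axis passes through the centroid unless ``through`` (x, y) mm is
    given. Each pixel contributes its own rotated-rectangle moment plus
    area times squared perpendicular distance.
    """
    px, py = section.pixel_spacing
    ii, jj = np.nonzero(section.pixels)
    x, y = ii * px, jj * py
    if through is None:
        through = (x.mean(), y.mean())
    t = math.radians(angle_deg)
    s, c = math.sin(t), math.cos(t)
    d = -(x - through[0]) * s + (y - through[1]) * c
    own = (px * py**3 / 12) * c * c + (px**3 * py / 12) * s * s
    return float(len(x) * own + (px * py) * np.dot(d, d))


# ---------------------------------------------------------------- tensor


def test_single_pixel_tensor():
    """One unit pixel is a 1x1 mm rectangle: I = 1/12 about both axes."""
    sec = SliceSection(np.ones((1, 1), bool), (1.0, 1.0))
    t = xs.inertia_tensor(sec)
    assert t.Ixx == pytest.approx(1 / 12)
    assert t.Iyy == pytest.approx(1 / 12)
    assert t.Ixy == 0.0
    assert t.area == pytest.approx(1.0)


@pytest.mark.parametrize(
    "fixture, Ixx_true, rtol",
    [("rect_section", 10 * 20**3 / 12, 0.005), ("cylinder_section", math.pi * 10**4 / 4, 0.005)],
)
def test_tensor_closed_forms(fixture, Ixx_true, rtol, request):
    sec = request.getfixturevalue(fixture)
    t = xs.inertia_tensor(sec)
    assert t.Ixx == pytest.approx(Ixx_true, rel=rtol)
    assert abs(t.Ixy) < rtol * t.Ixx


def test_empty_section_raises():
    sec = SliceSection(np.zeros((4, 4), bool), (1.0, 1.0))
    with pytest.raises(EmptySectionError):
        xs.inertia_tensor(sec)


def test_anisotropic_pixels_match_oracle():
    """Non-square pixels go through the same rectangle model."""
    rng = np.random.default_rng(7)
    sec = random_section(rng)
    t = xs.inertia_tensor(sec)
    assert t.Ixx == pytest.approx(direct_summation_I(sec, 0.0), rel=1e-12)
    assert t.Iyy == pytest.approx(direct_summation_I(sec, 90.0), rel=1e-12)


# ------------------------------------------------- rotation equivalence


def test_axis_identities():
    rng = np.random.default_rng(1)
    sec = random_section(rng)
    t = xs.inertia_tensor(sec)
    assert xs.second_moment_about_axis(t, 0.0) == t.Ixx
    assert xs.second_moment_about_axis(t, 90.0) == pytest.approx(t.Iyy, rel=1e-15)


def test_tensor_rotation_equals_direct_summation():
    """I(theta) from the tensor equals brute-force pixel summation, 1e-9 rel."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        sec = random_section(rng)
        t = xs.inertia_tensor(sec)
        theta = float(rng.uniform(-180, 180))
        assert xs.second_moment_about_axis(t, theta) == pytest.approx(
            direct_summation_I(sec, theta), rel=1e-9
        )


def test_parallel_axis_theorem_exact():
    """I about an offset axis = I_centroidal + CSA d^2, to arithmetic precision."""
    rng = np.random.default_rng(3)
    for _ in range(20):
        sec = random_section(rng)
        t = xs.inertia_tensor(sec)
        theta = float(rng.uniform(0, 180))
        q = (t.centroid[0] + rng.uniform(-5, 5), t.centroid[1] + rng.uniform(-5, 5))
        tr = math.radians(theta)
        d = -(t.centroid[0] - q[0]) * math.sin(tr) + (t.centroid[1] - q[1]) * math.cos(tr)
        expected = xs.second_moment_about_axis(t, theta) + t.area * d * d
        assert direct_summation_I(sec, theta, through=q) == pytest.approx(
            expected, rel=1e-12
        )


@given(theta=st.floats(-360, 360), seed=st.integers(0, 2**16))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_bounds_and_polar_identity(theta, seed):
    """I_major <= I(theta) <= I_minor and J = Ixx + Iyy for arbitrary sections."""
    sec = random_section(np.random.default_rng(seed), max_side=15)
    t = xs.inertia_tensor(sec)
    _, i_minor, i_major = xs.principal_axes(t)
    i_theta = xs.second_moment_about_axis(t, theta)
    tol = 1e-9 * max(i_minor, 1e-30)
    assert i_major - tol <= i_theta <= i_minor + tol
    assert xs.polar_moment(t) == t.Ixx + t.Iyy


# ---------------------------------------------------- principal axes


def test_principal_axes_rectangle(rect_section):
    """Tall rectangle: max I about horizontal, min about vertical (theta=90)."""
    theta, i_minor, i_major = xs.principal_axes(xs.inertia_tensor(rect_section))
    assert theta == pytest.approx(90.0)
    assert i_minor == pytest.approx(10 * 20**3 / 12, rel=0.005)
    assert i_major == pytest.approx(20 * 10**3 / 12, rel=0.005)


def test_principal_axes_isotropy_tiebreak(cylinder_section):
    theta, i_minor, i_major = xs.principal_axes(xs.inertia_tensor(cylinder_section))
    assert i_minor == pytest.approx(i_major, rel=0.01)
    # near-isotropic sections keep a small, well-defined angle or the 0 tie-break
    assert -90 < theta <= 90


def test_principal_values_rotation_invariant():
    """An in-plane rotated rectangle keeps its principal moments and angle."""
    angle = 30.0
    n = 400
    pitch = 0.05
    c, s = math.cos(math.radians(angle)), math.sin(math.radians(angle))
    coords = (np.arange(n) + 0.5 - n / 2) * pitch
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    u = c * xx + s * yy
    v = -s * xx + c * yy
    sec = SliceSection((np.abs(u) <= 5) & (np.abs(v) <= 2.5), (pitch, pitch))
    theta, i_minor, i_major = xs.principal_axes(xs.inertia_tensor(sec))
    # w=10 along u, h=5 along v: max I about the u axis at `angle`
    assert i_minor == pytest.approx(5 * 10**3 / 12, rel=0.01)
    assert i_major == pytest.approx(10 * 5**3 / 12, rel=0.01)
    assert theta == pytest.approx(angle, abs=1.0)


# ------------------------------------------------- modulus, J, Feret


def test_section_modulus_closed_forms(rect_section, cylinder_section):
    t = xs.inertia_tensor(rect_section)
    assert xs.section_modulus(rect_section, t, 0.0) == pytest.approx(
        10 * 20**2 / 6, rel=0.01
    )
    t = xs.inertia_tensor(cylinder_section)
    assert xs.section_modulus(cylinder_section, t, 30.0) == pytest.approx(
        math.pi * 10**3 / 4, rel=0.01
    )


def test_section_modulus_degenerate_is_nan():
    """All material on the axis: no lever arm, modulus undefined."""
    sec = SliceSection(np.ones((1, 1), bool), (1.0, 1.0))
    z = xs.section_modulus(sec, xs.inertia_tensor(sec), 0.0)
    assert math.isnan(z)


def test_polar_moment_tube(tube_section):
    assert xs.polar_moment(xs.inertia_tensor(tube_section)) == pytest.approx(
        math.pi * (10**4 - 8**4) / 2, rel=0.01
    )


def test_feret_rectangle_and_single_pixel(rect_section):
    assert xs.feret_max(rect_section) == pytest.approx(
        math.hypot(10, 20), abs=2 * 0.1
    )
    one = SliceSection(np.ones((1, 1), bool), (1.0, 1.0))
    assert xs.feret_max(one) == pytest.approx(math.sqrt(2))


def test_feret_circle(cylinder_section):
    assert xs.feret_max(cylinder_section) == pytest.approx(20.0, abs=2 * 0.1)


# ------------------------------------------------- perimeter, brightness


def test_perimeter_closed_forms(rect_section, cylinder_section, tube_section):
    assert xs.perimeter(rect_section) == pytest.approx(60.0, rel=0.02)
    assert xs.perimeter(cylinder_section) == pytest.approx(2 * math.pi * 10, rel=0.02)
    assert xs.perimeter(tube_section) == pytest.approx(
        2 * math.pi * (10 + 8), rel=0.02
    )


def test_perimeter_thin_structure_fallback():
    """A 1-pixel-wide line survives smoothing via the binary fallback."""
    sec = SliceSection(np.ones((1, 20), bool), (1.0, 1.0))
    assert xs.perimeter(sec) > 0


def test_mean_brightness_masks_background():
    pixels = np.zeros((4, 4), bool)
    pixels[:2] = True
    intensity = np.full((4, 4), 500.0)
    intensity[:2] = np.array([0.0, 0.0, 200.0, 200.0])  # rows: half 0, half 200
    sec = SliceSection(pixels, (1.0, 1.0), intensity=intensity)
    assert xs.mean_brightness(sec) == pytest.approx(100.0)
    assert math.isnan(xs.mean_brightness(SliceSection(pixels, (1.0, 1.0))))


# ------------------------------------------------- vacuities, compactness


def test_tube_vacuity_and_compactness(tube_section):
    tcsa = xs.total_area_with_vacuities(tube_section)
    t = xs.inertia_tensor(tube_section)
    assert tcsa == pytest.approx(math.pi * 10**2, rel=0.01)
    assert t.area == pytest.approx(math.pi * (10**2 - 8**2), rel=0.01)
    assert xs.compactness(t.area, tcsa) == pytest.approx(0.36, rel=0.01)


def test_open_notch_is_not_a_vacuity():
    """A C-shape's border-connected gap adds nothing to the total area."""
    pixels = np.ones((10, 10), bool)
    pixels[3:7, 3:] = False  # notch reaching the border
    sec = SliceSection(pixels, (1.0, 1.0))
    assert xs.total_area_with_vacuities(sec) == pytest.approx(float(pixels.sum()))


def test_compactness_requires_positive_tcsa():
    with pytest.raises(ValueError):
        xs.compactness(1.0, 0.0)


# ------------------------------------------------- aggregate record


def test_compute_section_properties_record(tube_section):
    props = xs.compute_section_properties(tube_section, neutral_axis_deg=45.0)
    assert props.J == props.Ixx + props.Iyy
    assert props.I_about_major_axis <= props.I_NA <= props.I_about_minor_axis
    assert 0 < props.compactness <= 1
    assert props.CSA <= props.TCSA
    assert props.neutral_axis_deg == 45.0


def test_empty_slice_yields_null_record():
    sec = SliceSection(np.zeros((4, 4), bool), (1.0, 1.0), plane_index=3)
    props = xs.compute_section_properties(sec)
    assert props.is_empty and math.isnan(props.CSA) and props.plane_index == 3


def test_largest_island_option():
    pixels = np.zeros((20, 20), bool)
    pixels[1:11, 1:11] = True  # 100-pixel island
    pixels[15:17, 15:17] = True  # 4-pixel island
    sec = SliceSection(pixels, (1.0, 1.0))
    assert xs.compute_section_properties(sec).CSA == pytest.approx(104.0)
    assert xs.compute_section_properties(
        sec, largest_island_only=True
    ).CSA == pytest.approx(100.0)
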