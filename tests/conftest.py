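import numpy as np
import pytest

from xsection import ShapeSpec, SliceSection, rasterize, slice_stack


def make_section(spec: ShapeSpec) -> SliceSection:
    """Mid-length cross-section of a rasterized shape."""
    mask, intensity = rasterize(spec)
    sections = slice_stack(mask, intensity)
    return sections[len(sections) // 2]


def random_section(rng: np.random.Generator, max_side: int = 30) -> SliceSection:
    """A random small blob section (guaranteed non-empty)."""
    nx = int(rng.integers(3, max_side + 1))
    ny = int(rng.integers(3, max_side + 1))
    pixels = rng.random((nx, ny)) < rng.uniform(0.2, 0.8)
    if not pixels.any():
        pixels[nx // 2, ny // 2] = True
    px, py = rng.uniform(0.05, 2.0, size=2)
    return SliceSection(pixels=pixels, pixel_spacing=(float(px), float(py)))


@pytest.fixture(scope="session")
def cylinder_section():
    return make_section(ShapeSpec("cylinder", {"r": 10.0}, length=1.0, pitch=0.1))


@pytest.fixture(scope="session")
def tube_section():
    return make_section(ShapeSpec("tube", {"ro": 10.0, "ri": 8.0}, length=1.0, pitch=0.1))


@pytest.fixture(scope="session")
def rect_section():
    # 10 mm wide x 20 mm tall
    return make_section(ShapeSpec("box", {"w": 10.0, "h": 20.0}, length=1.0, pitch=0.1))
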