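"""Length and material normalization of cross-sectional properties.

Length normalization reduces a property with units mm^k to a dimensionless
linear measure: the k-th root divided by the length of the whole structure
(k = 2 for CSA, 3 for section modulus, 4 for second and polar moments).
Material normalization divides a property by the same property of a solid
circle with equal cross-sectional area, isolating how the material is
*arranged* rather than how much there is: values above 1 mean the section
out-performs a solid circular beam of the same material budget.
"""

from __future__ import annotations

import math
from typing import Optional

from .types import NormalizedProperties, SectionProperties

_ROOT_FOR_KIND = {"CSA": 2, "Z": 3, "I": 4, "J": 4}


def length_normalize(value: float, root_order: int, L: float) -> float:
    """value^(1/root_order) / L; root_order 2 for areas, 3 for moduli, 4 for moments."""
    if root_order not in (2, 3, 4):
        raise ValueError(f"root_order must be 2, 3 or 4, got {root_order}")
    if L <= 0:
        raise ValueError("structure length must be positive")
    if math.isnan(value):
        return math.nan
    if value < 0:
        raise ValueError("cannot length-normalize a negative property value")
    return value ** (1.0 / root_order) / L


def circle_equivalent(kind: str, CSA: float) -> float:
    """The property of a solid circle whose area equals ``CSA``.

    With radius r = sqrt(CSA/pi): I = pi r^4 / 4 = CSA^2/(4 pi),
    J = CSA^2/(2 pi), Z = I / r = CSA^(3/2)/(4 sqrt(pi)).
    """
    if CSA <= 0:
        raise ValueError("CSA must be positive")
    if kind == "I":
        return CSA**2 / (4.0 * math.pi)
    if kind == "J":
        return CSA**2 / (2.0 * math.pi)
    if kind == "Z":
        return CSA**1.5 / (4.0 * math.sqrt(math.pi))
    raise ValueError(f"unknown kind {kind!r}; expected 'I', 'Z' or 'J'")


def material_normalize(value: float, kind: str, CSA: float) -> float:
    """Ratio of ``value`` to the same property of an equal-area solid circle."""
    if math.isnan(value):
        return math.nan
    return value / circle_equivalent(kind, CSA)


def normalize_section(
    props: SectionProperties,
    L: float,
    *,
    length: bool = True,
    material: bool = True,
) -> NormalizedProperties:
    """Normalized record for one slice (NaN-filled for empty slices)."""
    out = NormalizedProperties(compactness=props.compactness)
    if props.is_empty:
        return out
    if length:
        out.I_minor_lennorm = length_normalize(props.I_about_minor_axis, 4, L)
        out.I_major_lennorm = length_normalize(props.I_about_major_axis, 4, L)
        out.J_lennorm = length_normalize(props.J, 4, L)
        out.CSA_lennorm = length_normalize(props.CSA, 2, L)
        out.Z_minor_lennorm = length_normalize(props.Z_minor_axis, 3, L)
        out.Z_major_lennorm = length_normalize(props.Z_major_axis, 3, L)
        if not math.isnan(props.I_NA):
            out.I_NA_lennorm = length_normalize(props.I_NA, 4, L)
            out.Z_NA_lennorm = length_normalize(props.Z_NA, 3, L)
    if material:
        out.I_minor_matnorm = material_normalize(props.I_about_minor_axis, "I", props.CSA)
        out.I_major_matnorm = material_normalize(props.I_about_major_axis, "I", props.CSA)
        out.J_matnorm = material_normalize(props.J, "J", props.CSA)
        out.Z_minor_matnorm = material_normalize(props.Z_minor_axis, "Z", props.CSA)
        out.Z_major_matnorm = material_normalize(props.Z_major_axis, "Z", props.CSA)
        if not math.isnan(props.I_NA):
            out.I_NA_matnorm = material_normalize(props.I_NA, "I", props.CSA)
            out.Z_NA_matnorm = material_normalize(props.Z_NA, "Z", props.CSA)
    return out
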