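"""Euler-Bernoulli deflection and beam-assumption validity checks.

Classical beam theory assumes small deflections (under 10% of beam
length) and negligible shear, which empirically requires a length to
width ratio of at least 10. The deflection of a prismatic beam under a
point load is delta = F L^3 / (c E I) with a configuration-dependent
scalar c: 3 for a cantilever loaded at the free end, 48 for a simply
supported beam loaded at midspan.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

from .types import BeamReport, DeflectionCase, SectionProperties

log = logging.getLogger(__name__)

_COEFFICIENTS = {
    "cantilever_end_load": 3.0,
    "simply_supported_midpoint": 48.0,
}

SHEAR_ASPECT_THRESHOLD = 10.0
SMALL_DEFLECTION_FRACTION = 0.10
TRIM_FRACTION = 0.05


def deflection(
    F: float, L: float, E: float, I: float, configuration: str
) -> DeflectionCase:
    """Point-load deflection delta = F L^3 / (c E I).

    F in N, L in mm, E in N/mm^2, I in mm^4 give delta in mm.
    ``small_deflection_ok`` is True when delta < 10% of L (strict).
    """
    if configuration not in _COEFFICIENTS:
        raise ValueError(
            f"unknown configuration {configuration!r}; expected one of "
            f"{sorted(_COEFFICIENTS)}"
        )
    if F < 0:
        raise ValueError("load F must be non-negative")
    if L <= 0 or E <= 0 or I <= 0:
        raise ValueError("L, E and I must be positive")
    delta = F * L**3 / (_COEFFICIENTS[configuration] * E * I)
    return DeflectionCase(
        F=F,
        L=L,
        E=E,
        I=I,
        configuration=configuration,
        delta=delta,
        small_deflection_ok=delta < SMALL_DEFLECTION_FRACTION * L,
    )


def beam_check(sections: Sequence[SectionProperties], L: float) -> BeamReport:
    """Slenderness check for the no-shear assumption.

    The structure width is the smallest per-slice maximum Feret diameter
    after dropping floor(5% of occupied slices) from each end (flared
    epiphyses would otherwise never drive the minimum anyway, but the ends
    themselves are noisy). A length-to-width ratio strictly under 10
    raises the shear warning.
    """
    occupied = [s for s in sections if not s.is_empty and not math.isnan(s.feret_max)]
    if not occupied:
        raise ValueError("beam check requires at least one non-empty section")
    if L <= 0:
        raise ValueError("structure length must be positive")
    n = len(occupied)
    trim = int(math.floor(TRIM_FRACTION * n))
    kept = occupied[trim : n - trim] if trim > 0 else occupied
    min_max_feret = min(s.feret_max for s in kept)
    aspect = L / min_max_feret
    warn = aspect < SHEAR_ASPECT_THRESHOLD
    if warn:
        log.warning(
            "length/width ratio %.2f is under %.0f: the no-shear assumption "
            "of Euler-Bernoulli beam theory may not be met",
            aspect,
            SHEAR_ASPECT_THRESHOLD,
        )
    return BeamReport(
        length_L=L,
        min_max_feret=min_max_feret,
        aspect_ratio=aspect,
        shear_warning=warn,
        trim_fraction=TRIM_FRACTION,
        n_trimmed_per_end=trim,
    )
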