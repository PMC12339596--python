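"""Number-to-mass conversion for optical particle counter size bins (ALT algorithm).

Dual-channel optical particle monitors report *cumulative* number
concentrations — particles per deciliter at or above a set of optical size
thresholds (0.3, 0.5, 1.0, 2.5, 5.0, 10.0 µm).  The ALT estimator converts
the three size categories below 2.5 µm into a PM2.5 mass concentration:

    PM2.5_ALT = CF * (k1*N1 + k2*N2 + k3*N3)

where N1..N3 are the category counts (differences of adjacent cumulative
counts), k1..k3 are per-particle masses computed from the geometric-mean
diameter of each category assuming spherical particles of unit density, and
CF is a dimensionless calibration factor (3 by default; 3.4 in later
literature).  The estimator is independent of the vendor's proprietary mass
outputs, is linear and homogeneous in the counts, and has a lower limit of
detection than the proprietary algorithms.

The coefficients are derived at import time from the bin edges rather than
hard-coded; a regression test pins them to their published 8-decimal values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_BIN_EDGES",
    "DEFAULT_CF",
    "DEFAULT_DENSITY",
    "AltCoefficients",
    "SizeBinCounts",
    "derive_coefficient",
    "alt_mass",
    "alt_mass_from_counts",
    "alt_channel_pair",
]

#: Lower edges of the three PM2.5 size categories plus the 2.5 µm upper edge.
DEFAULT_BIN_EDGES: tuple[float, ...] = (0.3, 0.5, 1.0, 2.5)

#: Default calibration factor (the original ALT-CF3 choice).
DEFAULT_CF: float = 3.0

#: Assumed particle density, g/cm³.
DEFAULT_DENSITY: float = 1.0

# Unit bookkeeping for derive_coefficient: diameters are in µm so the sphere
# volume is in µm³ = 1e-12 cm³; times density (g/cm³) gives grams = 1e6 µg,
# i.e. a factor 1e-6 µg per particle.  Number concentrations are per dL and
# 1 m³ = 1e4 dL, so mass concentration per (#/dL) carries a further 1e4.
_UNIT_FACTOR = 1e-6 * 1e4  # = 1e-2


def derive_coefficient(d_lo: float, d_hi: float, density: float = DEFAULT_DENSITY) -> float:
    """Per-particle mass coefficient for one size category.

    Particles in the category [d_lo, d_hi) µm are treated as spheres whose
    diameter is the geometric mean of the category boundaries.  The returned
    coefficient converts a category number concentration in particles/dL into
    a mass concentration in µg/m³.

    Parameters
    ----------
    d_lo, d_hi:
        Category boundaries in µm, 0 < d_lo < d_hi.
    density:
        Particle density in g/cm³ (> 0).
    """
    if not (0 < d_lo < d_hi):
        raise ValueError(f"require 0 < d_lo < d_hi, got ({d_lo}, {d_hi})")
    if density <= 0:
        raise ValueError(f"density must be positive, got {density}")
    d = math.sqrt(d_lo * d_hi)
    return (math.pi / 6.0) * d**3 * density * _UNIT_FACTOR


@dataclass(frozen=True)
class AltCoefficients:
    """Coefficients of the ALT mass estimator.

    k1, k2, k3 are µg/m³ contributed per (particle/dL) in the 0.3–0.5,
    0.5–1.0 and 1.0–2.5 µm categories; ``cf`` is the dimensionless
    calibration factor and ``density`` the assumed particle density in g/cm³.
    """

    k1: float
    k2: float
    k3: float
    cf: float = DEFAULT_CF
    density: float = DEFAULT_DENSITY
    bin_edges: tuple[float, ...] = field(default=DEFAULT_BIN_EDGES)

    def __post_init__(self) -> None:
        if not (self.k1 < self.k2 < self.k3):
            raise ValueError("coefficients must increase with particle size")

    @classmethod
    def from_bin_edges(
        cls,
        edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
        density: float = DEFAULT_DENSITY,
        cf: float = DEFAULT_CF,
    ) -> "AltCoefficients":
        if len(edges) != 4:
            raise ValueError("need 4 bin edges for the 3 PM2.5 size categories")
        k1, k2, k3 = (
            derive_coefficient(lo, hi, density) for lo, hi in zip(edges, edges[1:])
        )
        return cls(k1=k1, k2=k2, k3=k3, cf=cf, density=density, bin_edges=tuple(edges))

    def with_cf(self, cf: float) -> "AltCoefficients":
        return AltCoefficients(self.k1, self.k2, self.k3, cf, self.density, self.bin_edges)


#: Module-level default coefficient set (CF = 3, density 1 g/cm³).
DEFAULT_COEFFICIENTS = AltCoefficients.from_bin_edges()


@dataclass(frozen=True)
class SizeBinCounts:
    """Cumulative number concentrations (particles/dL) at the size thresholds.

    ``c03`` is the count at/above 0.3 µm and so on; cumulative counts must be
    nonincreasing with threshold.  The derived category counts N1–N3 are the
    differences of adjacent cumulative counts.
    """

    c03: float
    c05: float
    c10: float
    c25: float
    c50: float | None = None
    c100: float | None = None

    def __post_init__(self) -> None:
        seq = [self.c03, self.c05, self.c10, self.c25]
        for extra in (self.c50, self.c100):
            if extra is not None:
                seq.append(extra)
        if any(v < 0 for v in seq):
            raise ValueError("cumulative counts must be nonnegative")
        if any(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError("cumulative counts must be nonincreasing with threshold")

    @property
    def n1(self) -> float:
        return self.c03 - self.c05

    @property
    def n2(self) -> float:
        return self.c05 - self.c10

    @property
    def n3(self) -> float:
        return self.c10 - self.c25


def alt_mass_from_counts(
    c03,
    c05,
    c10,
    c25,
    coeffs: AltCoefficients = DEFAULT_COEFFICIENTS,
    *,
    clamp_negative: bool = False,
):
    """Vectorized ALT mass from cumulative counts (array-likes or scalars).

    Category counts that come out negative (violated monotonicity) raise by
    default; with ``clamp_negative`` they are clamped to zero instead.
    Missing inputs (NaN) propagate to a missing result.
    """
    c03, c05, c10, c25 = (np.asarray(c, dtype=float) for c in (c03, c05, c10, c25))
    n1, n2, n3 = c03 - c05, c05 - c10, c10 - c25
    cats = np.stack(np.broadcast_arrays(n1, n2, n3))
    finite = np.isfinite(cats)
    if np.any(cats[finite] < 0):
        if clamp_negative:
            cats = np.where(finite & (cats < 0), 0.0, cats)
        else:
            raise ValueError("cumulative counts are not nonincreasing (negative category count)")
    n1, n2, n3 = cats
    mass = coeffs.cf * (coeffs.k1 * n1 + coeffs.k2 * n2 + coeffs.k3 * n3)
    return mass if mass.ndim else float(mass)


def alt_mass(
    bins: SizeBinCounts,
    coeffs: AltCoefficients = DEFAULT_COEFFICIENTS,
    *,
    clamp_negative: bool = False,
) -> float:
    """PM2.5 mass concentration (µg/m³) of one set of size-bin counts."""
    return alt_mass_from_counts(
        bins.c03, bins.c05, bins.c10, bins.c25, coeffs, clamp_negative=clamp_negative
    )


def alt_channel_pair(
    bins_a: SizeBinCounts | None,
    bins_b: SizeBinCounts | None,
    coeffs: AltCoefficients = DEFAULT_COEFFICIENTS,
) -> tuple[float, float, float]:
    """Per-channel ALT masses and their mean for a dual-channel monitor.

    A missing channel yields NaN for that channel and for the mean (the mean
    of the two channels is only defined when both report).
    """
    if bins_a is None and bins_b is None:
        raise ValueError("at least one channel must be present")
    alt_a = alt_mass(bins_a, coeffs) if bins_a is not None else math.nan
    alt_b = alt_mass(bins_b, coeffs) if bins_b is not None else math.nan
    mean = (alt_a + alt_b) / 2.0  # NaN-propagating on a missing channel
    return alt_a, alt_b, mean
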