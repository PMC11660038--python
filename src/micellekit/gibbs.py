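"""Gibbs adsorption-isotherm analysis of the pre-CMC surface-tension slope.

For a nonionic treatment (Gibbs prefactor n = 1) the surface excess is

    Gamma = -(1/RT) * d(gamma)/d(ln c)        [mol m^-2]

and the area per molecule at the air-water interface follows as
A = 1/(N_A * Gamma), reported in A^2.  Combining A with the micelle core
surface area a_mic = 4*pi*R^2 gives a surface-packing estimate of the
micelle association number p = a_mic / A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.constants import N_A, R as GAS_CONSTANT

__all__ = [
    "GibbsAnalysis",
    "SurfaceAssociation",
    "surface_excess",
    "area_per_molecule",
    "surface_association_number",
    "gibbs_pipeline",
]

_M2_TO_A2 = 1e20  # m^2 -> A^2


def surface_excess(slope: float, T: float, log_base: str = "ln") -> float:
    """Surface excess Gamma = -slope/(R*T) in mol m^-2.

    Parameters
    ----------
    slope : float
        Pre-CMC slope d(gamma)/d(log c) in N m^-1 per unit log concentration.
        Negative for a surface-active solute.
    T : float
        Temperature in K.
    log_base : {"ln", "log10"}
        Basis of the supplied slope.  A per-decade slope is converted to the
        natural-log basis by 1/ln(10) before applying the isotherm.

    Notes
    -----
    A positive slope (surface-inactive solute) yields a negative Gamma,
    which is returned as-is so callers can flag it.
    """
    if not math.isfinite(slope):
        raise ValueError("slope must be finite")
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    if log_base == "log10":
        slope = slope / math.log(10.0)
    elif log_base != "ln":
        raise ValueError(f"log_base must be 'ln' or 'log10', got {log_base!r}")
    return -slope / (GAS_CONSTANT * T)


def area_per_molecule(gamma_excess: float) -> float:
    """Area per molecule A = 1/(N_A * Gamma), reported in A^2."""
    if gamma_excess <= 0:
        raise ValueError("surface excess must be positive for an area")
    return _M2_TO_A2 / (N_A * gamma_excess)


def surface_association_number(radius: float, area: float) -> int:
    """p = round(4*pi*R^2 / A): molecules tiling the micelle core surface.

    ``radius`` is the micelle core radius in A, ``area`` the interfacial
    area per molecule in A^2 (assumed transferable to the micelle surface).
    """
    if radius <= 0 or area <= 0:
        raise ValueError("radius and area must be positive")
    return int(round(4.0 * math.pi * radius**2 / area))


@dataclass(frozen=True)
class GibbsAnalysis:
    """Full record of one Gibbs-isotherm evaluation."""

    slope: float  # N m^-1 per unit ln c
    temperature: float  # K
    surface_excess: float  # mol m^-2
    area_per_molecule: float  # A^2
    surface_inactive: bool  # True when slope >= 0 (Gamma <= 0)


@dataclass(frozen=True)
class SurfaceAssociation:
    """Micelle association number from surface packing."""

    radius: float  # A
    a_mic: float  # A^2, = 4 pi R^2
    p_surface: int


def gibbs_pipeline(
    slope: float,
    T: float = 293.0,
    radius: float | None = None,
    log_base: str = "ln",
) -> tuple[GibbsAnalysis, SurfaceAssociation | None]:
    """slope -> Gamma -> A (-> p if a core radius is given)."""
    gam = surface_excess(slope, T, log_base=log_base)
    if gam <= 0:
        analysis = GibbsAnalysis(slope, T, gam, float("nan"), True)
        return analysis, None
    area = area_per_molecule(gam)
    analysis = GibbsAnalysis(slope, T, gam, area, False)
    assoc = None
    if radius is not None:
        assoc = SurfaceAssociation(
            radius=radius,
            a_mic=4.0 * math.pi * radius**2,
            p_surface=surface_association_number(radius, area),
        )
    return analysis, assoc
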