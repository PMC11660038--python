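"""Model-independent micelle molar mass from absolute forward scattering.

On an absolute intensity scale (cm^-1) the zero-angle scattering of a
dilute particle solution is

    I(0) = c * M_mic * r_0^2 * v_p^2 * (rho_l - rho_0)^2 / N_A

so the micelle molar mass follows directly from a measured I(0):

    M_mic = I(0) * N_A / (c * r_0^2 * v_p^2 * drho^2)

with c the micelle mass concentration (g cm^-3), r_0 the classical (Thomson)
electron radius in cm, v_p the partial specific volume (cm^3 g^-1) and the
electron-density contrast drho in e cm^-3.  The association number is then
p = M_mic / M_mol.

The contrast model is tail-only: the scattering contrast is taken between
the lipid (alkyl) tail and water, with the tail electron density from the
Tanford chain volume v_l = 27.4 + 26.9 n (A^3, n = chain carbons excluding
the terminal CH3).  Electron densities are carried at the conventional
1e-3 e A^-3 quoting precision by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from scipy.constants import N_A

__all__ = [
    "CLASSICAL_ELECTRON_RADIUS_CM",
    "WATER_ELECTRON_DENSITY",
    "ContrastModel",
    "ForwardScatterResult",
    "tanford_volume",
    "electron_density",
    "micelle_molar_mass",
    "association_number",
    "forward_scatter_pipeline",
]

CLASSICAL_ELECTRON_RADIUS_CM = 0.28179e-12  # cm per electron
WATER_ELECTRON_DENSITY = 0.333  # e A^-3

_A3_TO_CM3 = 1e-24  # A^3 -> cm^3 (so e A^-3 -> e cm^-3 multiplies by 1e24)


def tanford_volume(n: int) -> float:
    """Tanford volume of an alkyl chain, v_l = 27.4 + 26.9 n, in A^3.

    ``n`` counts the chain carbons excluding the terminal CH3 group
    (n = 15 for a C16 palmitoyl tail).
    """
    if n < 0:
        raise ValueError("carbon count must be non-negative")
    return 27.4 + 26.9 * n


def electron_density(n_electrons: float, volume: float) -> float:
    """Electron density n_e / V in e A^-3 (full precision; round for quoting)."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    return n_electrons / volume


@dataclass(frozen=True)
class ContrastModel:
    """Tail/solvent electron-density contrast for forward-scattering analysis.

    Attributes
    ----------
    n_carbons : int
        Chain carbons excluding the terminal CH3 (15 for C16).
    v_l : float
        Tanford chain volume, A^3.
    n_electrons_tail : float
        Electrons in the tail volume (129 for a C16 tail).
    rho_l : float
        Tail electron density, e A^-3.
    rho_0 : float
        Solvent electron density, e A^-3 (water: 0.333).
    v_p : float
        Partial specific volume, cm^3 g^-1.
    r_0 : float
        Classical electron radius, cm.
    """

    n_carbons: int
    v_l: float
    n_electrons_tail: float
    rho_l: float
    rho_0: float = WATER_ELECTRON_DENSITY
    v_p: float = 1.15
    r_0: float = CLASSICAL_ELECTRON_RADIUS_CM

    @classmethod
    def from_tail(
        cls,
        n_carbons: int = 15,
        n_electrons_tail: float = 129.0,
        rho_solvent: float = WATER_ELECTRON_DENSITY,
        v_p: float = 1.15,
        rho_decimals: int | None = 3,
    ) -> "ContrastModel":
        """Build the contrast from the Tanford tail volume.

        ``rho_decimals`` rounds the derived tail electron density to the
        stated number of decimals (default 3, the precision at which
        electron densities are conventionally quoted and combined);
        pass None to keep full precision.
        """
        v_l = tanford_volume(n_carbons)
        rho_l = electron_density(n_electrons_tail, v_l)
        if rho_decimals is not None:
            rho_l = round(rho_l, rho_decimals)
        return cls(
            n_carbons=n_carbons,
            v_l=v_l,
            n_electrons_tail=n_electrons_tail,
            rho_l=rho_l,
            rho_0=rho_solvent,
            v_p=v_p,
        )

    @property
    def delta_rho(self) -> float:
        """Contrast rho_l - rho_0 in e A^-3."""
        return self.rho_l - self.rho_0

    @property
    def delta_rho_cm(self) -> float:
        """Contrast in e cm^-3."""
        return self.delta_rho / _A3_TO_CM3

    def with_(self, **kw) -> "ContrastModel":
        return replace(self, **kw)


@dataclass(frozen=True)
class ForwardScatterResult:
    """I(0) -> micelle molar mass -> association number."""

    I0: float  # cm^-1
    c_mic: float  # g cm^-3
    M_mic: float  # g mol^-1
    M_mol: float  # g mol^-1
    p: int


def micelle_molar_mass(I0: float, c_mic: float, contrast: ContrastModel) -> float:
    """Micelle molar mass from absolute forward scattering, g mol^-1.

    M_mic = I0 * N_A / (c_mic * r_0^2 * v_p^2 * drho^2), drho in e cm^-3.
    """
    if I0 < 0:
        raise ValueError("forward intensity must be non-negative")
    if c_mic <= 0:
        raise ValueError("micelle concentration must be positive")
    drho = contrast.delta_rho_cm
    if drho == 0:
        raise ValueError("no contrast: tail and solvent electron densities match")
    return I0 * N_A / (c_mic * contrast.r_0**2 * contrast.v_p**2 * drho**2)


def association_number(M_mic: float, M_mol: float) -> int:
    """p = round(M_mic / M_mol), molecules per micelle."""
    if M_mic <= 0 or M_mol <= 0:
        raise ValueError("molar masses must be positive")
    return int(round(M_mic / M_mol))


def forward_scatter_pipeline(
    I0: float,
    c_mic: float,
    M_mol: float,
    contrast: ContrastModel | None = None,
) -> ForwardScatterResult:
    """Full I(0) -> M_mic -> p chain with the default C16/water contrast."""
    if contrast is None:
        contrast = ContrastModel.from_tail()
    M_mic = micelle_molar_mass(I0, c_mic, contrast)
    p = association_number(M_mic, M_mol) if M_mic > 0 else 0
    return ForwardScatterResult(I0=I0, c_mic=c_mic, M_mic=M_mic, M_mol=M_mol, p=p)
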