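"""Conversions between persistence length, filament and membrane bending
rigidity, and honeycomb-foam scaling for the network moduli.

A semi-flexible filament of persistence length ``L_p`` has bending rigidity
``kappa_pol = L_p * k_B T``.  For a hollow, thin-walled membrane tube of
outer radius ``R`` the same persistence length instead reflects the
two-dimensional membrane bending modulus through

    L_p = 2 * kappa_mem * pi * R / (k_B T)

so ``kappa_mem`` (in units of kT) is ``L_p / (2 pi R)``.  Treating the
tubular network as a hexagonal honeycomb foam of strut thickness ``2r`` and
branch spacing ``L`` gives the scaling of the network moduli relative to
the single-tubule modulus ``E``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from .constants import K_B, DEFAULT_TEMPERATURE, thermal_energy

__all__ = [
    "TubuleMechanics",
    "NetworkModuli",
    "kappa_pol_from_lp",
    "lp_from_kappa_pol",
    "kappa_mem_from_lp",
    "lp_from_kappa_mem",
    "honeycomb_moduli",
    "tubule_mechanics",
]


@dataclass
class TubuleMechanics:
    """Mechanical summary of a single tubule."""

    L_p_um: float
    R_nm: float
    temperature_K: float
    kappa_pol_Jm: float
    kappa_mem_kT: float
    kappa_mem_J: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class NetworkModuli:
    """Honeycomb-foam moduli of the tubular network relative to the
    single-tubule Young's modulus E."""

    thickness_2r_nm: float
    branch_spacing_L_um: float
    ratio_Ein_E: float
    ratio_Gin_E: float
    ratio_Eout_E: float

    def to_dict(self) -> dict:
        return asdict(self)


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value}")


def kappa_pol_from_lp(L_p_um: float, temperature_K: float = DEFAULT_TEMPERATURE) -> float:
    """Filament bending rigidity kappa_pol = L_p * k_B T  [J m]."""
    _require_positive(L_p_um=L_p_um, temperature_K=temperature_K)
    return L_p_um * 1e-6 * K_B * temperature_K


def lp_from_kappa_pol(kappa_pol_Jm: float, temperature_K: float = DEFAULT_TEMPERATURE) -> float:
    """Inverse of :func:`kappa_pol_from_lp`; returns L_p in um."""
    _require_positive(kappa_pol_Jm=kappa_pol_Jm, temperature_K=temperature_K)
    return kappa_pol_Jm / (K_B * temperature_K) * 1e6


def kappa_mem_from_lp(
    L_p_um: float, R_nm: float, temperature_K: float = DEFAULT_TEMPERATURE
) -> tuple[float, float]:
    """Membrane bending rigidity of a thin hollow tube.

    Returns ``(kappa_mem in kT units, kappa_mem in joules)`` from
    ``kappa_mem / kT = L_p / (2 pi R)``.
    """
    _require_positive(L_p_um=L_p_um, R_nm=R_nm, temperature_K=temperature_K)
    kappa_kT = (L_p_um * 1e-6) / (2.0 * math.pi * R_nm * 1e-9)
    return kappa_kT, kappa_kT * thermal_energy(temperature_K)


def lp_from_kappa_mem(kappa_mem_kT: float, R_nm: float) -> float:
    """Persistence length [um] of a tube with membrane rigidity
    ``kappa_mem_kT`` (in kT units) and outer radius R [nm]."""
    _require_positive(kappa_mem_kT=kappa_mem_kT, R_nm=R_nm)
    return 2.0 * math.pi * R_nm * 1e-9 * kappa_mem_kT * 1e6


def honeycomb_moduli(thickness_2r_nm: float, branch_spacing_L_um: float) -> NetworkModuli:
    """Network moduli ratios for a hexagonal honeycomb of slender struts.

    In-plane Young's modulus scales as (2r/L)^3, in-plane shear as
    0.25 (2r/L)^3, out-of-plane Young's modulus as (2r/L)^1.
    """
    _require_positive(
        thickness_2r_nm=thickness_2r_nm, branch_spacing_L_um=branch_spacing_L_um
    )
    ratio = (thickness_2r_nm * 1e-9) / (branch_spacing_L_um * 1e-6)
    if ratio <= 1 + 1e-12:
        ratio = min(ratio, 1.0)
    else:
        raise ValueError(
            f"tubule thickness 2r={thickness_2r_nm} nm exceeds branch spacing "
            f"L={branch_spacing_L_um} um; the slender-strut scaling does not apply"
        )
    return NetworkModuli(
        thickness_2r_nm=thickness_2r_nm,
        branch_spacing_L_um=branch_spacing_L_um,
        ratio_Ein_E=ratio**3,
        ratio_Gin_E=0.25 * ratio**3,
        ratio_Eout_E=ratio,
    )


def tubule_mechanics(
    L_p_um: float, R_nm: float, temperature_K: float = DEFAULT_TEMPERATURE
) -> TubuleMechanics:
    """Full mechanical summary from measured L_p and R."""
    kappa_kT, kappa_J = kappa_mem_from_lp(L_p_um, R_nm, temperature_K)
    return TubuleMechanics(
        L_p_um=L_p_um,
        R_nm=R_nm,
        temperature_K=temperature_K,
        kappa_pol_Jm=kappa_pol_from_lp(L_p_um, temperature_K),
        kappa_mem_kT=kappa_kT,
        kappa_mem_J=kappa_J,
    )
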