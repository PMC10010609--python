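"""Physical laws of the bathing solution and xylem sap.

Internal unit system: m, s, MPa, mol m⁻³, m³ s⁻¹, K. PEG mass
concentrations are in kg l⁻¹ (numerically equal to g PEG per g water in
the osmotic calibration below). Viscosities are in mPa s, with pure
water at 1 mPa s as the reference; axial conductances quoted "at
reference viscosity" correspond to sap with µ = 1 mPa s.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "R_GAS",
    "CE_CONTROL_MOL_M3",
    "rt_mpa",
    "peg_viscosity",
    "peg_water_potential",
    "peg_osmotic_pressure",
    "vant_hoff_term",
    "capillary_conductance",
    "BathSolution",
]

#: Universal gas constant, J mol⁻¹ K⁻¹.
R_GAS = 8.314

#: Lumped solute concentration of the control hydroponic solution,
#: mol m⁻³, derived from its measured water potential of −0.034 MPa at
#: 298 K (0.034 / RT).  The nutrient mix is treated as a single
#: Van't Hoff solute.
CE_CONTROL_MOL_M3 = 13.72

# Viscosity law fitted on PEG 8000 data between 100 and 200 g/l with the
# pure-water point (1 mPa s) anchored at w = 0:  µ = −17.4 + 18.4·exp(w/0.279)
_MU_A = -17.4
_MU_B = 18.4
_MU_W0 = 0.279
_MU_VALID_MAX = 0.25  # kg/l; beyond the fitted range, extrapolation

# PEG 8000 osmotic calibration (Michel 1983): Ψ in bar as a function of
# C = g PEG / g water and temperature in °C.
_PSI_T_COEF = 1.29
_PSI_C2_COEF = -140.0
_PSI_C1_COEF = -4.0


def rt_mpa(T: float = 298.0) -> float:
    """RT in MPa per (mol m⁻³); 2.4776e-3 at 298 K."""
    return R_GAS * T * 1e-6


def _viscosity_raw(w_peg):
    # range-check-free evaluation for solver hot loops
    return _MU_A + _MU_B * np.exp(np.asarray(w_peg, dtype=float) / _MU_W0)


def peg_viscosity(w_peg):
    """Dynamic viscosity (mPa s) of a PEG 8000 solution.

    Parameters
    ----------
    w_peg : float or array
        PEG mass concentration in kg l⁻¹. Valid up to 0.25 kg l⁻¹
        (fitted range plus the anchored water point); larger values
        extrapolate with a warning.
    """
    w = np.asarray(w_peg, dtype=float)
    if np.any(w < 0):
        raise ValueError("PEG concentration must be non-negative")
    if np.any(w > _MU_VALID_MAX):
        warnings.warn(
            "PEG concentration beyond the fitted viscosity range "
            f"(> {_MU_VALID_MAX} kg/l); extrapolating",
            stacklevel=2,
        )
    mu = _MU_A + _MU_B * np.exp(w / _MU_W0)
    return float(mu) if np.isscalar(w_peg) else mu


def peg_water_potential(w_peg, T: float = 298.0):
    """Water potential Ψ_peg (MPa, ≤ 0) of a PEG 8000 solution.

    Empirical quadratic-in-concentration, linear-in-temperature law for
    PEG 8000, with the concentration expressed as mass of PEG per mass
    of water (numerically taken equal to ``w_peg`` in kg l⁻¹). Anchors:
    Ψ(0) = 0 and Ψ(0.150, 25 °C) = −0.302 MPa.
    """
    w = np.asarray(w_peg, dtype=float)
    if np.any(w < 0):
        raise ValueError("PEG concentration must be non-negative")
    t_c = T - 273.15
    psi_bar = (_PSI_T_COEF * t_c + _PSI_C2_COEF) * w * w + _PSI_C1_COEF * w
    psi = 0.1 * psi_bar  # bar -> MPa
    return float(psi) if np.isscalar(w_peg) else psi


def peg_osmotic_pressure(w_peg, T: float = 298.0):
    """Osmotic pressure π_peg = −Ψ_peg (MPa, ≥ 0)."""
    return -peg_water_potential(w_peg, T)


def vant_hoff_term(C_diff, sigma: float, T: float = 298.0):
    """Osmotic pressure term σ·RT·ΔC in MPa (ΔC in mol m⁻³)."""
    if not 0.0 <= sigma <= 1.0:
        raise ValueError(f"reflection coefficient must be in [0, 1], got {sigma}")
    return sigma * rt_mpa(T) * np.asarray(C_diff, dtype=float)[()]


def capillary_conductance(r, mu: float = 1.0):
    """Hagen–Poiseuille conductance πr⁴/(8µ) of a cylindrical capillary.

    ``r`` in m, ``mu`` in mPa s; returns m⁴ MPa⁻¹ s⁻¹ (so that µ = 1
    mPa s yields the reference conductance, and K scales as 1/µ).
    """
    r = np.asarray(r, dtype=float)[()]
    if np.any(np.asarray(r) <= 0) or mu <= 0:
        raise ValueError("radius and viscosity must be positive")
    return np.pi * r**4 / (8.0 * mu * 1e-9)


@dataclass
class BathSolution:
    """External medium state around the root.

    Attributes
    ----------
    Pe : float
        Relative hydrostatic pressure of the bathing solution, MPa
        (0 = atmospheric).
    Ce : float
        Lumped solute concentration, mol m⁻³.
    w_peg : float
        PEG 8000 mass concentration, kg l⁻¹.
    T : float
        Temperature, K.
    """

    Pe: float = 0.0
    Ce: float = CE_CONTROL_MOL_M3
    w_peg: float = 0.0
    T: float = 298.0

    def __post_init__(self):
        if self.Ce < 0 or self.w_peg < 0:
            raise ValueError("concentrations must be non-negative")

    @property
    def pi_peg_ext(self) -> float:
        """PEG contribution to the bath osmotic pressure, MPa (≥ 0)."""
        return float(peg_osmotic_pressure(self.w_peg, self.T))

    @property
    def mu_ext(self) -> float:
        """Bath dynamic viscosity, mPa s."""
        return float(peg_viscosity(self.w_peg))

    @property
    def water_potential(self) -> float:
        """Total bath water potential Ψ = Ψ_peg − RT·Ce + Pe, MPa."""
        return self.Pe + float(peg_water_potential(self.w_peg, self.T)) - rt_mpa(self.T) * self.Ce

    def replace(self, **kw) -> "BathSolution":
        from dataclasses import replace as _rep

        return _rep(self, **kw)
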