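"""Analytic two-compartment (Fiscus-type) root model.

The whole root is reduced to one semi-permeable barrier of area S_tot
separating the bath from a well-mixed xylem compartment held at the
basal (atmospheric, relative 0) pressure. The same water and solute
closure as the tree model then admits a closed form:

    Jv   = k·S_tot·(Pe − π_peg_ext − σRT(Ce − C))
    Jv·C = S_tot·(Js* − Ps·(C − Ce))

which reduces to a quadratic in C − Ce. The branch with C ≥ 0 and
continuous, non-decreasing Jv(Pe) is selected. This model is the exact
solution of a one-REV tree with negligible axial resistance, which
makes it the primary oracle for the numerical solver; it is also the
reference point for quantifying how much the compartment idealization
biases fitted parameters on realistic architectures.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .media import BathSolution
from .solver import M3_PER_S_TO_UL_PER_S, TransportParams

__all__ = ["OsmometerModel", "osmometer_steady_state", "osmometer_curve", "fit_osmometer", "compare_with_rsa"]


@dataclass
class OsmometerModel:
    """Two-compartment root: total membrane area plus transport params."""

    S_tot: float  # m²
    params: TransportParams = field(default_factory=TransportParams)
    bath: BathSolution = field(default_factory=BathSolution)

    def __post_init__(self):
        if self.S_tot <= 0:
            raise ValueError("S_tot must be > 0")


def osmometer_steady_state(m: OsmometerModel, Pe: float):
    """Closed-form steady state (Jv in m³ s⁻¹, C in mol m⁻³) at bath
    pressure ``Pe`` (MPa, relative).

    Solves the quadratic in D = C − Ce:
    ``a·D² + b·D + c = 0`` with ``a = A·σRT``, ``b = A·Pe* + A·σRT·Ce +
    S·Ps``, ``c = A·Pe*·Ce − S·Js*`` where ``A = k·S`` and ``Pe* = Pe −
    π_peg_ext``. The larger root is the physical branch (continuous in
    Pe, C ≥ 0); at the zero-flow point it gives exactly D = Js*/Ps and
    Pe* = −σRT·Js*/Ps.
    """
    p, bath = m.params, m.bath
    S = m.S_tot
    A = p.k * S
    srt = p.sigma * p.rt
    pe_star = Pe - bath.pi_peg_ext
    a = A * srt
    b = A * pe_star + A * srt * bath.Ce + S * p.Ps
    c = A * pe_star * bath.Ce - S * p.Js_star
    if a == 0.0:  # sigma = 0: no osmotic coupling, linear balance
        if b == 0.0:
            raise ValueError("degenerate osmometer balance (k·Pe* and Ps both zero)")
        D = -c / b
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0:
            raise ValueError("no real steady state for these parameters")
        sq = np.sqrt(disc)
        # larger root, in a cancellation-safe form
        D = (-b + sq) / (2.0 * a) if b <= 0 else (2.0 * c) / (-b - sq)
    C = bath.Ce + D
    if C < 0:
        raise ValueError("no steady state with non-negative concentration")
    Jv = A * (pe_star + srt * D)
    return float(Jv), float(C)


def osmometer_curve(m: OsmometerModel, pressures) -> np.ndarray:
    """Jv(Pe) over a pressure grid, in µl s⁻¹."""
    return np.array(
        [osmometer_steady_state(m, Pe)[0] * M3_PER_S_TO_UL_PER_S for Pe in np.asarray(pressures, dtype=float)]
    )


def fit_osmometer(
    pressures,
    Jv_ul,
    S_tot: float,
    bath: BathSolution,
    first_guess: TransportParams | None = None,
) -> TransportParams:
    """Least-squares fit of (k, Js*, Ps) of a two-compartment root to a
    Jv(Pe) series (µl s⁻¹), with σ and S_tot held fixed."""
    p0 = first_guess or TransportParams()
    x0 = np.log10([p0.k, p0.Js_star, p0.Ps])

    def make(x):
        k, js, ps = 10.0 ** x
        return OsmometerModel(S_tot, p0.replace(k=k, Js_star=js, Ps=ps), bath)

    def resid(x):
        return osmometer_curve(make(x), pressures) - np.asarray(Jv_ul, dtype=float)

    sol = least_squares(resid, x0, method="lm", xtol=1e-12, ftol=1e-12)
    k, js, ps = 10.0 ** sol.x
    return p0.replace(k=k, Js_star=js, Ps=ps)


def compare_with_rsa(
    g,
    params: TransportParams,
    bath: BathSolution,
    pressure_grid,
    gradient_pressure: float = 0.1,
    **solver_opts,
):
    """Fit the two-compartment model to tree-model Jv(Pe) data and
    report the parameter bias of the compartment idealization.

    ``S_tot`` is the tree's total REV lateral surface. Also reports the
    basal-to-tip xylem solute concentration difference of the tree
    solution, evaluated at a representative overpressure
    (``gradient_pressure``, the heat-map condition), divided by the
    primary length — the homogeneity metric: near-zero gradients mean
    the two models coincide.
    """
    from .solver import solve_steady_state

    pressures = np.asarray(pressure_grid, dtype=float)
    Jv = [
        solve_steady_state(g, params, bath.replace(Pe=float(Pe)), **solver_opts).Jv_base_ul
        for Pe in pressures
    ]
    state0 = solve_steady_state(g, params, bath.replace(Pe=gradient_pressure), **solver_opts)
    S_tot = g.total_surface
    fitted = fit_osmometer(pressures, Jv, S_tot, bath, first_guess=params)

    primary = g.order == 0
    dtt = g.dist_to_tip[primary]
    C_prim = state0.C[primary]
    c_base = C_prim[np.argmax(dtt)]  # largest distance to tip = basal end
    c_tip = C_prim[np.argmin(dtt)]
    grad = (c_tip - c_base) / g.primary_axis_length  # mol m⁻⁴, > 0: sap
    # is most concentrated at the tip and diluted toward the base

    return {
        "fitted": fitted,
        "rel_dev": {
            "k": fitted.k / params.k - 1.0,
            "Js_star": fitted.Js_star / params.Js_star - 1.0,
            "Ps": fitted.Ps / params.Ps - 1.0,
        },
        "concentration_gradient_mol_m4": float(grad),
        "S_tot_m2": float(S_tot),
        "Jv_ul": np.array(Jv),
    }
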