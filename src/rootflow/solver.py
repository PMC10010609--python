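"""Coupled steady-state water / solute / PEG transport on a REV tree.

Model closure, per representative elementary volume (REV):

* radial water influx across the peripheral tissues
  ``j = k·(Pe − P − π_peg_ext + π_peg − σ·RT·(Ce − C))·S`` — PEG is
  non-permeant radially, so its osmotic terms carry reflection
  coefficient 1 (not σ);
* axial Hagen–Poiseuille sap flow ``J = K(µ)·ΔP/l`` along the xylem,
  with the axial conductance profile K quoted at reference viscosity
  1 mPa s and scaled by the local sap viscosity µ(C_peg);
* radial solute flux ``j_s = (Js* − Ps·(C − Ce))·S`` (active pumping
  minus passive leak) and axial advection ``J·C``; PEG is advected
  (``J·C_peg``) but enters only through open cut faces.

Boundary conditions: Dirichlet P = 0 (relative, atmospheric) at the
basal face feeding the pressure-chamber seal; sealed apices (zero axial
flow); Dirichlet P = Pe with advective exchange of bath composition at
every open cut face.

The tree topology makes both linear sub-problems solvable exactly in
O(n) by leaf-to-root elimination: a symmetric system for pressure, and
an M-matrix system (donor-cell advection plus a weak axial dispersion
that anchors near-stagnant regions) for the concentrations, which
guarantees non-negativity. The two are alternated in a damped Picard
fixed-point loop (the osmosis–advection feedback makes the coupled
problem nonlinear).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .architecture import REVGraph
from .media import (
    BathSolution,
    _viscosity_raw,
    peg_osmotic_pressure,
    peg_viscosity,
    rt_mpa,
)

__all__ = [
    "TransportParams",
    "PressureSolution",
    "SolveState",
    "SolverError",
    "ConvergenceError",
    "UnboundedAccumulationError",
    "M3_PER_S_TO_UL_PER_S",
    "radial_water_flux",
    "radial_solute_flux",
    "axial_conductance_at",
    "solve_pressure",
    "solve_advection",
    "solve_steady_state",
    "balance_residuals",
]

M3_PER_S_TO_UL_PER_S = 1e9


class SolverError(RuntimeError):
    pass


class ConvergenceError(SolverError):
    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history or []


class UnboundedAccumulationError(SolverError):
    """Raised when a zero-throughflow REV with active uptake and no leak
    admits no steady state (solute would accumulate indefinitely)."""


@dataclass
class TransportParams:
    """Unknowns of the inverse problem plus physical constants.

    k : radial hydraulic conductivity, m s⁻¹ MPa⁻¹ (uniform).
    K_knots : piecewise-linear axial conductance profile, ordered
        ``(distance_to_tip [m], K [m⁴ MPa⁻¹ s⁻¹ at µ = 1 mPa s])``
        knots, clamped constant beyond the end knots.
    sigma : effective reflection coefficient of the lumped solute.
    Js_star : active solute uptake rate, mol m⁻² s⁻¹ (uniform).
    Ps : radial solute permeability (leak), m s⁻¹ (uniform).
    T : temperature, K.
    """

    k: float = 1e-7
    K_knots: Sequence[tuple[float, float]] = ((0.0, 1e-12), (0.1, 1e-10))
    sigma: float = 0.85
    Js_star: float = 1e-7
    Ps: float = 1e-9
    T: float = 298.0

    def __post_init__(self):
        knots = [(float(x), float(K)) for x, K in self.K_knots]
        if not knots:
            raise ValueError("K_knots must be non-empty")
        xs = [x for x, _ in knots]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ValueError("K_knots must be strictly increasing in distance")
        if self.k <= 0 or any(K <= 0 for _, K in knots):
            raise ValueError("conductances must be > 0")
        if self.Js_star < 0 or self.Ps < 0:
            raise ValueError("solute parameters must be >= 0")
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError("sigma must be in [0, 1]")
        self.K_knots = tuple(knots)
        self._kx = np.array(xs)
        self._kv = np.array([K for _, K in knots])

    def axial_K(self, dist_to_tip):
        """Reference-viscosity axial conductance at given distances to tip."""
        return np.interp(np.asarray(dist_to_tip, dtype=float), self._kx, self._kv)

    @property
    def rt(self) -> float:
        return rt_mpa(self.T)

    def replace(self, **kw) -> "TransportParams":
        return replace(self, **kw)


def axial_conductance_at(rev_dist_to_tip, params: TransportParams, mu_local=1.0):
    """Axial conductance (m⁴ MPa⁻¹ s⁻¹) at a distance to tip, for sap of
    viscosity ``mu_local`` (mPa s; reference 1)."""
    return params.axial_K(rev_dist_to_tip) / mu_local


def radial_water_flux(S, P, C, params: TransportParams, bath: BathSolution, pi_peg_in=0.0):
    """Radial water influx j (m³ s⁻¹) across a lateral surface S (m²).

    ``j = k·(Pe − P − π_peg_ext + π_peg_in − σRT(Ce − C))·S``; positive
    = influx. The PEG osmotic terms are not scaled by σ (PEG does not
    cross the radial barrier).
    """
    drive = (
        bath.Pe
        - np.asarray(P, dtype=float)
        - bath.pi_peg_ext
        + pi_peg_in
        - params.sigma * params.rt * (bath.Ce - np.asarray(C, dtype=float))
    )
    return params.k * drive * S


def radial_solute_flux(S, C, params: TransportParams, bath: BathSolution):
    """Radial solute influx j_s (mol s⁻¹): active uptake minus leak,
    ``(Js* − Ps·(C − Ce))·S``."""
    return (params.Js_star - params.Ps * (np.asarray(C, dtype=float) - bath.Ce)) * S


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _tree_pressure_kernel(parent, g_edge, diag, rhs):
    """Exact solve of the SPD tree system by leaf-to-root elimination.

    Node equation: diag[i]·P[i] − g_edge[i]·P[parent[i]] −
    Σ_children g_edge[c]·P[c] = rhs[i]; children always carry larger
    indices than their parent.
    """
    n = parent.shape[0]
    d = diag.copy()
    b = rhs.copy()
    for i in range(n - 1, 0, -1):
        p = parent[i]
        f = g_edge[i] / d[i]
        d[p] -= f * g_edge[i]
        b[p] += f * b[i]
    P = np.empty(n)
    P[0] = b[0] / d[0]
    for i in range(1, n):
        P[i] = (b[i] + g_edge[i] * P[parent[i]]) / d[i]
    return P


@njit(cache=True)
def _tree_linear_kernel(parent, diag, upper, lower, rhs, default):
    """Exact solve of a tree-structured linear system with nonsymmetric
    edge couplings (upwind advection + symmetric dispersion).

    Row i: diag[i]·C[i] + upper[i]·C[parent[i]] + Σ_children
    lower[c]·C[c] = rhs[i]. Off-diagonals are ≤ 0 and the system is an
    M-matrix, so elimination pivots stay positive and the solution is
    non-negative for non-negative rhs. A fully decoupled row
    (diag = 0) with positive rhs has no steady state → error flag 1;
    with zero rhs it takes the default concentration.
    """
    n = parent.shape[0]
    d = diag.copy()
    r = rhs.copy()
    for i in range(n - 1, 0, -1):
        if d[i] > 0.0 and lower[i] != 0.0:
            p = parent[i]
            f = lower[i] / d[i]
            d[p] -= f * upper[i]
            r[p] -= f * r[i]
    C = np.empty(n)
    if d[0] > 0.0:
        C[0] = r[0] / d[0]
    elif r[0] > 0.0:
        return C, 1
    else:
        C[0] = default[0]
    for i in range(1, n):
        if d[i] > 0.0:
            C[i] = (r[i] - upper[i] * C[parent[i]]) / d[i]
        elif r[i] > 0.0:
            return C, 1
        else:
            C[i] = default[i]
    return C, 0


# ---------------------------------------------------------------------------
# pressure / advection wrappers
# ---------------------------------------------------------------------------


@dataclass
class PressureSolution:
    """Pressure field and flows for fixed concentration fields.

    P : xylem relative pressure per REV, MPa.
    J : axial flow from each REV toward its parent, m³ s⁻¹ (0 at the
        basal REV whose outflow is ``Jv_base``).
    Jv_base : basal outflow through the chamber seal, m³ s⁻¹.
    Q_face : bath→xylem flow through each open cut face, m³ s⁻¹.
    j : radial water influx per REV, m³ s⁻¹.
    """

    P: np.ndarray
    J: np.ndarray
    Jv_base: float
    Q_face: np.ndarray
    j: np.ndarray


def _drive_term(g, params, bath, C, pi_peg_in, solute_transport, osmotic_offset, include_peg):
    drive = np.full(g.n_revs, bath.Pe)
    if include_peg:
        drive += pi_peg_in - bath.pi_peg_ext
    if solute_transport:
        drive -= params.sigma * params.rt * (bath.Ce - C)
    else:
        drive -= osmotic_offset
    return drive


def solve_pressure(
    g: REVGraph,
    params: TransportParams,
    bath: BathSolution,
    C=None,
    C_peg=None,
    mu=None,
    *,
    solute_transport: bool = True,
    osmotic_offset: float = 0.0,
    include_peg: bool = True,
) -> PressureSolution:
    """Solve the linear pressure system for fixed concentration fields.

    Every REV mass balance (axial in + radial in = axial out) is
    satisfied to machine precision by the exact tree elimination.
    """
    n = g.n_revs
    C = np.full(n, bath.Ce) if C is None else np.asarray(C, dtype=float)
    C_peg = np.zeros(n) if C_peg is None else np.asarray(C_peg, dtype=float)
    if mu is None:
        mu = peg_viscosity(C_peg) if np.any(C_peg > 0) else np.ones(n)
    pi_in = peg_osmotic_pressure(C_peg, bath.T) if include_peg else np.zeros(n)

    Keff = params.axial_K(g.dist_to_tip) / mu
    ghalf = 2.0 * Keff / g.length
    parent = g.parent
    g_edge = np.zeros(n)
    if n > 1:
        gp = ghalf[parent[1:]]
        g_edge[1:] = ghalf[1:] * gp / (ghalf[1:] + gp)
    basal = g.basal_rev
    g_base = ghalf[basal]
    g_face = np.where(g.is_cut_face, ghalf, 0.0)

    kS = params.k * g.surface
    diag = kS + g_face + g_edge
    diag += np.bincount(parent[1:], weights=g_edge[1:], minlength=n)
    diag[basal] += g_base
    drive = _drive_term(g, params, bath, C, pi_in, solute_transport, osmotic_offset, include_peg)
    rhs = kS * drive + g_face * bath.Pe

    P = _tree_pressure_kernel(parent, g_edge, diag, rhs)
    J = np.zeros(n)
    if n > 1:
        J[1:] = g_edge[1:] * (P[1:] - P[parent[1:]])
    Jv_base = float(g_base * P[basal])
    Q_face = g_face * (bath.Pe - P)
    j = kS * (drive - P)
    return PressureSolution(P=P, J=J, Jv_base=Jv_base, Q_face=Q_face, j=j)


def _dispersion_conductance(g: REVGraph, J, Jv_base, Q_face, eta: float) -> np.ndarray:
    """Per-edge axial dispersion conductance (m³ s⁻¹): ``eta`` times the
    dominant flow magnitude. Emulates xylem molecular
    diffusion/dispersion; negligible against through-flow (Péclet
    ~1/eta) but it anchors the concentration of near-stagnant regions,
    making the advection solution continuous in the flow field."""
    scale = max(
        float(np.max(np.abs(J))),
        abs(Jv_base),
        float(np.max(np.abs(Q_face))),
    )
    D = np.full(J.shape[0], eta * scale)
    D[0] = 0.0
    return D


def _advection_system(g, flows, D, leak, src, face_conc):
    """Assemble diag/upper/lower/rhs of the steady advection balance."""
    n = g.n_revs
    J = flows.J
    Jp = np.maximum(J, 0.0)  # flow toward parent
    Jm = np.maximum(-J, 0.0)  # flow from parent
    Qf = flows.Q_face
    diag = Jp + D + leak + np.maximum(-Qf, 0.0)
    diag += np.bincount(g.parent[1:], weights=(Jm + D)[1:], minlength=n)
    upper = -(Jm + D)
    lower = -(Jp + D)
    rhs = src + np.maximum(Qf, 0.0) * face_conc
    return diag, upper, lower, rhs


def solve_advection(
    g: REVGraph,
    flows: PressureSolution,
    params: TransportParams,
    bath: BathSolution,
    *,
    include_peg: bool = True,
    basal_inflow_composition: Optional[float] = None,
    axial_dispersion: float = 1e-3,
    pseudo_step: Optional[tuple] = None,
):
    """Steady-state upwind advection balance for the solute and PEG
    concentration fields, given a fixed flow field.

    Solved exactly (M-matrix tree elimination, concentrations stay
    ≥ 0) with donor-cell advective fluxes plus a weak axial dispersion
    (``axial_dispersion`` × the dominant flow). Under reversed basal
    flow the re-entering fluid carries the basal REV's own
    concentrations (zero-gradient) unless
    ``basal_inflow_composition`` fixes the solute concentration.

    ``pseudo_step = (dt, C_prev, Cpeg_prev, volume)`` adds an implicit
    pseudo-transient storage term V/dt·(C − C_prev) used by the outer
    continuation; the fixed point is independent of dt, so the
    converged solution is the true steady state.

    Returns ``(C, C_peg)``; raises
    :class:`UnboundedAccumulationError` when a zero-throughflow REV has
    positive uptake and no leak (the physical argument for a nonzero
    solute permeability Ps).
    """
    n = g.n_revs
    basal = g.basal_rev
    D = _dispersion_conductance(g, flows.J, flows.Jv_base, flows.Q_face, axial_dispersion)
    S = g.surface
    src = (params.Js_star + params.Ps * bath.Ce) * S
    leak = params.Ps * S
    diag, upper, lower, rhs = _advection_system(g, flows, D, leak, src, bath.Ce)
    if flows.Jv_base > 0:
        diag[basal] += flows.Jv_base
    elif flows.Jv_base < 0 and basal_inflow_composition is not None:
        rhs[basal] += -flows.Jv_base * float(basal_inflow_composition)
    peg_active = include_peg and (bath.w_peg > 0 and bool(np.any(g.is_cut_face)))
    if peg_active:
        zeros = np.zeros(n)
        diag_p, upper_p, lower_p, rhs_p = _advection_system(
            g, flows, D, zeros, zeros, bath.w_peg
        )
        if flows.Jv_base > 0:
            diag_p[basal] += flows.Jv_base
    if pseudo_step is not None:
        dt, C_prev, Cpeg_prev, volume = pseudo_step
        cap = volume / dt
        diag += cap
        rhs += cap * C_prev
        if peg_active:
            diag_p += cap
            rhs_p += cap * Cpeg_prev
    C, flag = _tree_linear_kernel(
        g.parent, diag, upper, lower, rhs, np.full(n, bath.Ce)
    )
    if flag:
        raise UnboundedAccumulationError(
            "a REV with no outflow receives a positive solute source "
            "(Js* > 0 with Ps = 0): no steady state exists"
        )
    if peg_active:
        C_peg, flag_p = _tree_linear_kernel(
            g.parent, diag_p, upper_p, lower_p, rhs_p, np.zeros(n)
        )
        if flag_p:
            raise UnboundedAccumulationError(
                "PEG accumulates in a REV with inflow but no outflow"
            )
    else:
        C_peg = np.zeros(n)
    return C, C_peg


# ---------------------------------------------------------------------------
# coupled fixed point
# ---------------------------------------------------------------------------


@dataclass
class SolveState:
    """Converged steady-state fields on a REVGraph."""

    P: np.ndarray
    C: np.ndarray
    C_peg: np.ndarray
    J: np.ndarray
    j: np.ndarray
    j_s: np.ndarray
    Q_face: np.ndarray
    Jv_base: float  # m³ s⁻¹, positive = outflow at the base
    converged: bool
    iterations: int
    axial_dispersion: float = 1e-3
    final_dt: float = np.inf  # last pseudo-step of the continuation
    residual_history: list = field(default_factory=list, repr=False)

    @property
    def Jv_base_ul(self) -> float:
        """Basal outflow in µl s⁻¹ (the unit of the experimental figures)."""
        return self.Jv_base * M3_PER_S_TO_UL_PER_S

    def to_frame(self, g: REVGraph) -> "pd.DataFrame":  # noqa: F821
        import pandas as pd

        return pd.DataFrame(
            {
                "rev_id": np.arange(g.n_revs),
                "distance_to_tip_m": g.dist_to_tip,
                "order": g.order,
                "P_MPa": self.P,
                "C_mol_m3": self.C,
                "C_peg_kg_l": self.C_peg,
                "j_m3_s": self.j,
                "J_m3_s": self.J,
            }
        )


def solve_steady_state(
    g: REVGraph,
    params: TransportParams,
    bath: BathSolution,
    *,
    tol: float = 1e-8,
    damping: float = 1.0,
    max_iter: int = 1500,
    C0=None,
    Cpeg0=None,
    solute_transport: bool = True,
    osmotic_offset: float = 0.0,
    include_peg: bool = True,
    viscosity_coupling: bool = True,
    basal_inflow_composition: Optional[float] = None,
    axial_dispersion: float = 1e-3,
    dt0: Optional[float] = None,
    strict: bool = True,
) -> SolveState:
    """Picard alternation of the pressure and advection solves,
    stabilized by pseudo-transient continuation.

    Each outer iteration solves the linear pressure system for the
    current concentrations, then takes one implicit pseudo-time step of
    the advection balance (whose fixed point is the exact steady state
    for any step size); the pseudo step grows while the iteration
    contracts and backs off when the osmosis–advection–viscosity
    feedback destabilizes the alternation. ``damping`` optionally
    under-relaxes the concentration update on top of the implicit step.

    Iterates until the maximum relative change of (P, C, C_peg, Jv)
    drops below ``tol`` (default 1e-8; conservation-critical analyses
    may tighten it) and the steady advection balance agrees, or
    ``max_iter`` is reached. ``osmotic_offset`` replaces the σRT(Ce−C)
    term by a constant when ``solute_transport=False`` (pure-hydraulic
    mode). ``viscosity_coupling=False`` freezes sap viscosity at
    1 mPa s (the neglect whose bias on fitted K the cut-and-flow
    analysis exposes). Raises :class:`ConvergenceError` if not
    converged and ``strict``.
    """
    n = g.n_revs
    if C0 is not None:
        C = np.array(C0, dtype=float)
    elif solute_transport and params.Js_star > 0 and params.Ps > 0:
        # start from the zero-flow solute ceiling Ce + Js*/Ps: dilution
        # relaxes it downward smoothly, whereas starting from Ce lets
        # transient radial efflux drag PEG deep into intact laterals
        C = np.full(n, bath.Ce + params.Js_star / params.Ps)
    else:
        C = np.full(n, bath.Ce)
    C_peg = np.zeros(n) if Cpeg0 is None else np.array(Cpeg0, dtype=float)
    peg_active = include_peg and bath.w_peg > 0 and bool(np.any(g.is_cut_face))
    if not solute_transport and not peg_active:
        # fully linear: one exact solve
        flows = solve_pressure(
            g, params, bath, C, C_peg,
            solute_transport=False, osmotic_offset=osmotic_offset,
            include_peg=include_peg,
        )
        j_s = np.zeros(n)
        return SolveState(
            P=flows.P, C=C, C_peg=C_peg, J=flows.J, j=flows.j, j_s=j_s,
            Q_face=flows.Q_face, Jv_base=flows.Jv_base,
            converged=True, iterations=1, axial_dispersion=axial_dispersion,
        )

    history = []
    P_prev = None
    Jv_prev = None
    converged = False
    adv_kw = dict(
        include_peg=peg_active,
        basal_inflow_composition=basal_inflow_composition,
        axial_dispersion=axial_dispersion,
    )
    flux_floor = params.k * g.total_surface * 1e-3  # MPa-scale flux unit
    # pseudo-transient continuation: the advection solve carries an
    # implicit storage term V/dt·(C − C_prev) whose fixed point is the
    # true steady state for any dt. The pseudo step is adapted by
    # switched evolution relaxation on the steady balance residual
    # (which is dt-independent and decreases along the pseudo march);
    # steps that sharply worsen it are rejected and retried smaller.
    volume = 0.25 * np.pi * g.diameter**2 * g.length
    # transient excursions are kept inside the laws' sane ranges; the
    # caps are far above any converged value and only shape the path
    cap_C = 100.0 * (bath.Ce + (params.Js_star / params.Ps if params.Ps > 0 else 0.0) + 1.0)
    cap_peg = max(2.0 * bath.w_peg, 0.25)
    mu_of = lambda w: _viscosity_raw(np.minimum(w, 0.5))  # noqa: E731
    parent_safe = np.maximum(g.parent, 0)

    def steady_residual(flows):
        """Max relative residual of the steady advection balances at the
        current concentration fields and flows."""
        D = _dispersion_conductance(g, flows.J, flows.Jv_base, flows.Q_face, axial_dispersion)
        S = g.surface
        worst = 0.0
        fields = []
        if solute_transport:
            fields.append((C, (params.Js_star + params.Ps * bath.Ce) * S, params.Ps * S, bath.Ce))
        if peg_active:
            fields.append((C_peg, np.zeros(n), np.zeros(n), bath.w_peg))
        for X, src, leak, face_conc in fields:
            diag, upper, lower, rhs = _advection_system(g, flows, D, leak, src, face_conc)
            if flows.Jv_base > 0:
                diag[g.basal_rev] += flows.Jv_base
            R = diag * X + upper * X[parent_safe] - rhs  # upper[basal] = 0
            R += np.bincount(g.parent[1:], weights=(lower * X)[1:], minlength=n)
            scale = max(float(np.max(np.abs(diag * X))), float(np.max(np.abs(rhs))), 1e-300)
            worst = max(worst, float(np.max(np.abs(R))) / scale)
        return worst

    dt = np.inf
    err_prev = None
    flows = None
    C_bak = Cpeg_bak = None
    err_best = np.inf
    best = None  # (C, C_peg, dt) at the lowest residual seen
    restarts = 0
    aitken_prev = None
    for it in range(1, max_iter + 1):
        mu = mu_of(C_peg) if (viscosity_coupling and peg_active) else np.ones(n)
        flows = solve_pressure(
            g, params, bath, C, C_peg, mu,
            solute_transport=solute_transport, osmotic_offset=osmotic_offset,
            include_peg=include_peg,
        )
        flux_scale = max(
            float(np.max(np.abs(flows.J))),
            abs(flows.Jv_base), flux_floor, 1e-30,
        )
        if it == 1:
            # ~one residence time, unless a previous solve's step is given
            dt_init = float(np.median(volume)) / flux_scale
            dt = dt0 if dt0 else dt_init
        err_res = steady_residual(flows)
        err_obs = 0.0
        if P_prev is not None:
            err_obs = float(np.max(np.abs(flows.P - P_prev))) / max(float(np.max(np.abs(flows.P))), 1e-6)
            err_obs = max(err_obs, abs(flows.Jv_base - Jv_prev) / flux_scale)
        err = max(err_res, err_obs)
        history.append(err)
        if it > 1 and err <= tol:
            converged = True
            break
        if err_res < err_best:
            err_best = err_res
            best = (C.copy(), C_peg.copy(), dt)
        elif best is not None and err_res > 30.0 * max(err_best, tol) and restarts < 25:
            # the iteration wandered off to a worse attractor: restart
            # from the best fields seen with a much smaller pseudo step
            restarts += 1
            C, C_peg, dt_best = best
            C, C_peg = C.copy(), C_peg.copy()
            # fall back to (at most) the residence scale: a carried-over
            # or overgrown pseudo step can be many orders too large
            dt = max(min(dt_best * 0.2, dt_init) / 2**restarts, 1e-9)
            err_prev = None
            C_bak = Cpeg_bak = None
            continue
        if err_prev is not None and err_res > 100.0 * max(err_prev, tol) and C_bak is not None:
            # the last step destabilized the alternation: revert it and
            # retry with a smaller pseudo step
            C, C_peg = C_bak, Cpeg_bak
            C_bak = Cpeg_bak = None
            dt = max(dt * 0.25, 1e-9)
            continue
        C_new, Cpeg_new = solve_advection(
            g, flows, params, bath, pseudo_step=(dt, C, C_peg, volume), **adv_kw
        )
        if not solute_transport:
            C_new = C
        if params.Ps == 0.0 and params.Js_star > 0.0 and float(np.max(C_new)) > cap_C:
            raise UnboundedAccumulationError(
                "solute accumulates without bound (Js* > 0 with Ps = 0 "
                "in a zero-throughflow region): no steady state exists"
            )
        np.minimum(C_new, cap_C, out=C_new)
        np.minimum(Cpeg_new, cap_peg, out=Cpeg_new)
        P_prev = flows.P
        Jv_prev = flows.Jv_base
        C_bak, Cpeg_bak = C, C_peg
        C = C + damping * (C_new - C)
        C_peg = C_peg + damping * (Cpeg_new - C_peg)
        # Aitken extrapolation of the dominant error mode: osmotically
        # coupled low-flow regions can relax with a contraction factor
        # very close to 1, which a plain alternation crawls through
        if it % 8 == 0 and aitken_prev is not None:
            d1 = np.concatenate([C - aitken_prev[0], C_peg - aitken_prev[1]])
            d0 = aitken_prev[2]
            if d0 is not None:
                num = float(d1 @ d0)
                den = float(d0 @ d0)
                lam = num / den if den > 0 else 0.0
                if 0.3 < lam < 0.999:
                    boost = lam / (1.0 - lam)
                    C = np.maximum(C + boost * d1[:n], 0.0)
                    C_peg = np.maximum(C_peg + boost * d1[n:], 0.0)
                    np.minimum(C, cap_C, out=C)
                    np.minimum(C_peg, cap_peg, out=C_peg)
            aitken_prev = (C.copy(), C_peg.copy(), d1)
        elif it % 8 == 0 or aitken_prev is None:
            aitken_prev = (C.copy(), C_peg.copy(), None)
        if err_prev is not None:
            # grow the pseudo step while the balance residual does not
            # worsen (a flat residual just means a slow march), back
            # off when the alternation starts to destabilize
            if err_res <= 1.02 * err_prev:
                dt = min(dt * 1.4, 1e18)
            elif err_res > 1.5 * err_prev:
                dt = max(dt * 0.5, 1e-9)
        err_prev = err_res

    if not converged and strict:
        raise ConvergenceError(
            f"steady state not reached in {max_iter} iterations "
            f"(last residual {history[-1]:.3e})",
            history=history,
        )
    mu = mu_of(C_peg) if (viscosity_coupling and peg_active) else np.ones(n)
    flows = solve_pressure(
        g, params, bath, C, C_peg, mu,
        solute_transport=solute_transport, osmotic_offset=osmotic_offset,
        include_peg=include_peg,
    )
    if np.any(C < 0) or np.any(C_peg < 0):
        raise SolverError("negative concentration: upwind scheme violated")
    j_s = radial_solute_flux(g.surface, C, params, bath) if solute_transport else np.zeros(n)
    return SolveState(
        P=flows.P, C=C, C_peg=C_peg, J=flows.J, j=flows.j, j_s=j_s,
        Q_face=flows.Q_face, Jv_base=flows.Jv_base,
        converged=converged, iterations=it, axial_dispersion=axial_dispersion,
        final_dt=dt, residual_history=history,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def balance_residuals(g: REVGraph, state: SolveState, params: TransportParams, bath: BathSolution):
    """Per-REV and global water/solute balance residuals of a state.

    Returns a dict with per-REV residual arrays (m³ s⁻¹ / mol s⁻¹),
    the global water closure ``Σj + Σ Q_face − Jv_base`` and the global
    solute closure ``Σ j_s + Σ face advection − basal export``, plus
    the flux scales to normalise them.
    """
    n = g.n_revs
    parent = g.parent
    basal = g.basal_rev
    J, Jv, Qf = state.J, state.Jv_base, state.Q_face

    water = state.j + Qf - J
    water += np.bincount(parent[1:], weights=J[1:], minlength=n)
    water[basal] -= Jv

    # solute: upwind advective transport plus weak axial dispersion
    D = _dispersion_conductance(g, J, Jv, Qf, state.axial_dispersion)
    adv_up = np.where(J > 0, state.C, state.C[np.maximum(parent, 0)])
    edge_s = J * adv_up  # solute flow toward parent along each edge
    edge_s = edge_s + D * (state.C - state.C[np.maximum(parent, 0)])
    edge_s[basal] = 0.0
    solute = state.j_s - edge_s
    solute += np.bincount(parent[1:], weights=edge_s[1:], minlength=n)
    face_s = np.where(Qf > 0, Qf * bath.Ce, Qf * state.C)
    solute += face_s
    basal_export = Jv * state.C[basal] if Jv > 0 else 0.0
    solute[basal] -= basal_export

    scale_w = max(np.max(np.abs(state.j)), np.max(np.abs(J)), abs(Jv), 1e-30)
    scale_s = max(np.max(np.abs(edge_s)), np.max(np.abs(state.j_s)), abs(basal_export), 1e-30)
    return {
        "water": water,
        "solute": solute,
        "water_global": float(state.j.sum() + Qf.sum() - Jv),
        "solute_global": float(state.j_s.sum() + face_s.sum() - basal_export),
        "water_scale": float(scale_w),
        "solute_scale": float(scale_s),
    }
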