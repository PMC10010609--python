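"""Inverse estimation of transport parameters from protocol curves.

The unknowns are the uniform radial conductivity k, the piecewise-linear
axial conductance profile K (one knot per cut, abscissae at the blade
positions), and the uniform solute parameters Js* and Ps. They are
estimated by minimizing the objective F = Σ(Jv_data − Jv_model)²
(µl² s⁻²) pooled over the Jv(P) and cut-and-flow points, with a staged
local workflow (global optimizers are unreliable on this landscape):

1. {K knots, k} on the cut-and-flow data with solute transport off and
   the osmotic term frozen at a constant offset estimated from the
   Jv(P) intercept (bounded Gauss–Newton least squares);
2. {k, Js*, Ps} on the Jv(P) data with K fixed (SLSQP);
3. joint refinement of all parameters on both series by bounded
   trust-region least squares with numerical Jacobians.

All positive parameters are optimized in log10 space, which enforces
positivity without explicit constraints and makes the finite-difference
Jacobians well scaled across the decades the conductances span. The objective is re-evaluated
on the full model after each stage and the best parameter set is kept,
so F decreases (weakly) across stages.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize, minimize_scalar

from .architecture import REVGraph
from .protocols import CutFlowSimulator, ExperimentSeries, simulate_jvp
from .solver import SolverError, TransportParams

__all__ = [
    "FitConfig",
    "FitResult",
    "make_k_profile",
    "default_first_guess",
    "objective",
    "fit",
    "fit_pure_hydraulic",
    "sensitivity_scan",
    "parameter_band",
]

MAX_KNOTS = 9  # up to nine cuts per plant -> at most 12 free parameters
PENALTY_F = 1e6  # µl² s⁻², returned when the forward solve fails


def make_k_profile(cut_positions: Sequence[float], K_values: Sequence[float]):
    """Build K knots from cut abscissae (m, distance to tip) and values."""
    x = [float(v) for v in cut_positions]
    K = [float(v) for v in K_values]
    if len(x) != len(K):
        raise ValueError("cut_positions and K_values must have the same length")
    if len(set(x)) != len(x):
        raise ValueError("duplicate knot abscissae")
    if any(b <= a for a, b in zip(x, x[1:])):
        raise ValueError("knot abscissae must be increasing")
    if len(x) > MAX_KNOTS:
        raise ValueError(f"at most {MAX_KNOTS} K knots are supported")
    return tuple(zip(x, K))


def default_first_guess(
    cut_positions: Sequence[float],
    step_position: float = 0.1,
    K_min: float = 1e-12,
    K_max: float = 1e-10,
    sigma: float = 0.85,
) -> TransportParams:
    """First guesses for the staged fit: a step axial-conductance
    profile (K_min below ~0.1 m from the tip, K_max above), k = 1e-7
    m MPa⁻¹ s⁻¹, Js* = 1e-7 mol m⁻² s⁻¹ and Ps = 1e-9 m s⁻¹."""
    xs = sorted(float(v) for v in cut_positions)
    Kv = [K_min if x < step_position else K_max for x in xs]
    return TransportParams(
        k=1e-7, K_knots=make_k_profile(xs, Kv), sigma=sigma, Js_star=1e-7, Ps=1e-9
    )


@dataclass
class FitConfig:
    """Stage budgets, bounds and solver settings of the inversion."""

    first_guess: Optional[TransportParams] = None
    #: log10 bounds per parameter kind
    log_bounds: dict = field(
        default_factory=lambda: {
            "k": (-10.0, -4.0),
            "K": (-14.0, -7.0),
            "Js_star": (-11.0, -4.0),
            "Ps": (-13.0, -6.0),
        }
    )
    stages: tuple = (1, 2, 3)  # ordered subset of the staged workflow
    stage1_maxfev: int = 400
    stage2_maxiter: int = 60
    stage3_maxfev: int = 500
    linear_part_threshold: float = 0.1  # MPa; Jv(P) is ~linear above
    solver_opts: dict = field(default_factory=lambda: {"tol": 1e-8})


@dataclass
class FitResult:
    """Fitted parameters with objective value and diagnostics."""

    params: TransportParams
    F: float  # µl² s⁻²
    r2: float
    residuals: dict
    stage_trace: list
    n_evals: int = 0

    def to_dict(self) -> dict:
        p = self.params
        return {
            "k_m_per_MPa_s": p.k,
            "K_knots": [[x, K] for x, K in p.K_knots],
            "sigma": p.sigma,
            "Js_star_mol_m2_s": p.Js_star,
            "Ps_m_s": p.Ps,
            "F_ul2_s2": self.F,
            "R2": self.r2,
            "stage_trace": self.stage_trace,
        }


class _Forward:
    """Forward model over both protocols with cut graphs precomputed."""

    def __init__(self, g, jvp_series, cutflow_series, solver_opts):
        self.g = g
        self.jvp = jvp_series
        self.cutflow = cutflow_series
        self.opts = dict(solver_opts)
        self.n_evals = 0
        self.cf_sim = None
        self._jvp_warm = None  # warm start across optimizer evaluations
        if cutflow_series is not None:
            cuts = [x for x in cutflow_series.x if x > 0]
            self.cf_sim = CutFlowSimulator(
                g, cuts, cutflow_series.operating_pressure, cutflow_series.bath
            )

    def jvp_model(self, params, **extra) -> np.ndarray:
        from .solver import solve_steady_state

        if extra:  # non-default solver mode: no warm-start cache
            return simulate_jvp(
                self.g, params, self.jvp.bath, self.jvp.x, **self.opts, **extra
            ).Jv
        if self._jvp_warm is None:
            self._jvp_warm = {}
        Jv = np.empty(len(self.jvp.x))
        for i, Pe in enumerate(self.jvp.x):
            init = self._jvp_warm.get(i)
            kw = dict(self.opts)
            if init is not None:
                kw["C0"], kw["Cpeg0"], kw["dt0"] = init
            bath_i = self.jvp.bath.replace(Pe=float(Pe))
            try:
                st = solve_steady_state(self.g, params, bath_i, **kw)
            except SolverError:
                if init is None:
                    raise
                # stale warm start (parameters moved too far): retry cold
                st = solve_steady_state(self.g, params, bath_i, **self.opts)
            Jv[i] = st.Jv_base_ul
            self._jvp_warm[i] = (st.C, st.C_peg, st.final_dt)
        return Jv

    def cutflow_model(self, params, **extra) -> np.ndarray:
        return self.cf_sim.simulate(params, warm_start=not extra, **self.opts, **extra).Jv

    def residuals(self, params, use_jvp=True, use_cutflow=True, **extra):
        res = []
        if use_jvp and self.jvp is not None:
            res.append(self.jvp_model(params, **extra) - self.jvp.Jv)
        if use_cutflow and self.cf_sim is not None:
            res.append(self.cutflow_model(params, **extra) - self.cutflow.Jv)
        return np.concatenate(res) if res else np.empty(0)

    def F(self, params, **kw) -> float:
        self.n_evals += 1
        try:
            r = self.residuals(params, **kw)
        except SolverError as exc:
            warnings.warn(f"forward solve failed ({exc}); penalizing", stacklevel=2)
            return PENALTY_F
        return float(np.sum(r * r))


def objective(
    params: TransportParams,
    g: REVGraph,
    jvp_series: Optional[ExperimentSeries],
    cutflow_series: Optional[ExperimentSeries],
    **solver_opts,
) -> float:
    """Sum of squared flow errors (µl² s⁻²) over both protocols.

    Solver failures at any point return a large penalty instead of
    raising, which keeps derivative-free optimizers alive.
    """
    opts = {"tol": 1e-8}
    opts.update(solver_opts)
    return _Forward(g, jvp_series, cutflow_series, opts).F(params)


def _estimate_p0(jvp_series, threshold):
    """Pressure-axis intercept of the linear part of Jv(P)."""
    if jvp_series is None:
        return 0.0
    mask = jvp_series.x >= threshold
    if mask.sum() < 2:
        mask = np.ones(len(jvp_series.x), dtype=bool)
    slope, icept = np.polyfit(jvp_series.x[mask], jvp_series.Jv[mask], 1)
    if slope <= 0:
        return 0.0
    return float(-icept / slope)


def _pooled_r2(measured, modeled):
    measured = np.concatenate(measured)
    modeled = np.concatenate(modeled)
    ss_res = np.sum((measured - modeled) ** 2)
    ss_tot = np.sum((measured - measured.mean()) ** 2)
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else -np.inf


def fit(
    g: REVGraph,
    jvp_series: Optional[ExperimentSeries],
    cutflow_series: Optional[ExperimentSeries],
    config: Optional[FitConfig] = None,
) -> FitResult:
    """Three-stage inversion of both protocol series (see module docs).

    Either series may be omitted (degraded single-series mode, with a
    warning); the corresponding stage is skipped.
    """
    cfg = config or FitConfig()
    if jvp_series is None and cutflow_series is None:
        raise ValueError("at least one experiment series is required")
    if jvp_series is None or cutflow_series is None:
        warnings.warn("single-series fit: parameter resolution is degraded", stacklevel=2)

    fwd = _Forward(g, jvp_series, cutflow_series, cfg.solver_opts)
    if cfg.first_guess is not None:
        p = cfg.first_guess
    else:
        cuts = [x for x in cutflow_series.x if x > 0] if cutflow_series is not None else [0.05, 0.15]
        p = default_first_guess(cuts)
    lb, ub = cfg.log_bounds["K"]
    knot_x = [x for x, _ in p.K_knots]
    trace = []

    def record(stage, params):
        F = fwd.F(params)
        trace.append({"stage": stage, "F": F, "k": params.k, "Js_star": params.Js_star, "Ps": params.Ps})
        return F

    best_p, best_F = p, record("first_guess", p)

    # -- stage 1: {K, k} on cut-and-flow, pure hydraulic -------------
    if cutflow_series is not None and 1 in cfg.stages:
        p0_offset = _estimate_p0(jvp_series, cfg.linear_part_threshold)
        offset = p0_offset - cutflow_series.bath.pi_peg_ext  # PEG term modeled explicitly

        n1 = len(cutflow_series.x)

        def r_stage1(theta):
            fwd.n_evals += 1
            params = p.replace(
                K_knots=make_k_profile(knot_x, 10.0 ** np.asarray(theta[:-1])),
                k=10.0 ** theta[-1],
            )
            try:
                return fwd.residuals(
                    params, use_jvp=False,
                    solute_transport=False, osmotic_offset=offset,
                )
            except SolverError as exc:
                warnings.warn(f"forward solve failed ({exc}); penalizing", stacklevel=2)
                return np.full(n1, np.sqrt(PENALTY_F / n1))

        theta0 = np.log10([K for _, K in p.K_knots] + [p.k])
        lo1 = [cfg.log_bounds["K"][0]] * len(knot_x) + [cfg.log_bounds["k"][0]]
        hi1 = [cfg.log_bounds["K"][1]] * len(knot_x) + [cfg.log_bounds["k"][1]]
        res1 = least_squares(
            r_stage1, np.clip(theta0, lo1, hi1), bounds=(lo1, hi1), method="trf",
            diff_step=1e-4, xtol=1e-10, ftol=1e-12, gtol=1e-12,
            max_nfev=cfg.stage1_maxfev,
        )
        theta1 = res1.x
        p = p.replace(
            K_knots=make_k_profile(knot_x, 10.0 ** theta1[:-1]), k=10.0 ** theta1[-1]
        )
        F = record("stage1_cutflow_hydraulic", p)
        if F <= best_F:
            best_p, best_F = p, F
        else:
            p = best_p

    # -- stage 2: {k, Js*, Ps} on Jv(P), K fixed ----------------------
    if jvp_series is not None and 2 in cfg.stages:

        def f_stage2(theta):
            k, js, ps = 10.0 ** np.asarray(theta)
            return fwd.F(p.replace(k=k, Js_star=js, Ps=ps), use_cutflow=False)

        theta0 = np.log10([p.k, p.Js_star, p.Ps])
        bounds = [cfg.log_bounds["k"], cfg.log_bounds["Js_star"], cfg.log_bounds["Ps"]]
        res2 = minimize(
            f_stage2, theta0, method="SLSQP", bounds=bounds,
            options={"maxiter": cfg.stage2_maxiter, "ftol": 1e-12},
        )
        k, js, ps = 10.0 ** res2.x
        cand = p.replace(k=k, Js_star=js, Ps=ps)
        F = record("stage2_jvp_solute", cand)
        if F <= best_F:
            best_p, best_F = cand, F
        p = best_p

    # -- stage 3: joint refinement of everything ----------------------
    nK = len(knot_x)
    if 3 not in cfg.stages:
        res3 = None

    def unpack3(theta):
        return p.replace(
            K_knots=make_k_profile(knot_x, 10.0 ** np.asarray(theta[:nK])),
            k=10.0 ** theta[nK],
            Js_star=10.0 ** theta[nK + 1],
            Ps=10.0 ** theta[nK + 2],
        )

    def r_stage3(theta):
        fwd.n_evals += 1
        try:
            return fwd.residuals(unpack3(theta))
        except SolverError as exc:
            warnings.warn(f"forward solve failed ({exc}); penalizing", stacklevel=2)
            return np.full(n_points, np.sqrt(PENALTY_F / n_points))

    n_points = (len(jvp_series.x) if jvp_series is not None else 0) + (
        len(cutflow_series.x) if cutflow_series is not None else 0
    )
    if 3 in cfg.stages:
        theta0 = np.log10([K for _, K in p.K_knots] + [p.k, p.Js_star, p.Ps])
        lo = [cfg.log_bounds["K"][0]] * nK + [cfg.log_bounds["k"][0], cfg.log_bounds["Js_star"][0], cfg.log_bounds["Ps"][0]]
        hi = [cfg.log_bounds["K"][1]] * nK + [cfg.log_bounds["k"][1], cfg.log_bounds["Js_star"][1], cfg.log_bounds["Ps"][1]]
        res3 = least_squares(
            r_stage3, np.clip(theta0, lo, hi), bounds=(lo, hi), method="trf",
            diff_step=1e-4, xtol=1e-10, ftol=1e-12, gtol=1e-12,
            max_nfev=cfg.stage3_maxfev,
        )
        cand = unpack3(res3.x)
        F = record("stage3_joint", cand)
        if F <= best_F:
            best_p, best_F = cand, F

    measured, modeled, residuals = [], [], {}
    if jvp_series is not None:
        m = fwd.jvp_model(best_p)
        measured.append(jvp_series.Jv)
        modeled.append(m)
        residuals["jvp"] = m - jvp_series.Jv
    if cutflow_series is not None:
        m = fwd.cutflow_model(best_p)
        measured.append(cutflow_series.Jv)
        modeled.append(m)
        residuals["cutflow"] = m - cutflow_series.Jv
    return FitResult(
        params=best_p, F=best_F, r2=_pooled_r2(measured, modeled),
        residuals=residuals, stage_trace=trace, n_evals=fwd.n_evals,
    )


def fit_pure_hydraulic(
    g: REVGraph,
    jvp_series: Optional[ExperimentSeries],
    cutflow_series: Optional[ExperimentSeries],
    config: Optional[FitConfig] = None,
) -> tuple[FitResult, float]:
    """Fit {K, k, P0} of a purely hydraulic model, j = k(Pe − P − P0)S.

    The osmotic driving force is frozen at the constant pressure offset
    P0 and solute transport is removed; only the linear part of Jv(P)
    (Pe above ``config.linear_part_threshold``) is used, as in classical
    linear-regression treatments. Exposes the bias of neglecting solute
    transport relative to the coupled fit; returns ``(result, P0)``.
    """
    cfg = config or FitConfig()
    if jvp_series is not None:
        mask = jvp_series.x >= cfg.linear_part_threshold
        jvp_lin = ExperimentSeries(
            kind="jvp", x=jvp_series.x[mask], Jv=jvp_series.Jv[mask],
            bath=jvp_series.bath,
        ) if mask.sum() >= 4 else jvp_series
    else:
        jvp_lin = None
    fwd = _Forward(g, jvp_lin, cutflow_series, cfg.solver_opts)
    if cfg.first_guess is not None:
        p = cfg.first_guess
    else:
        cuts = [x for x in cutflow_series.x if x > 0] if cutflow_series is not None else [0.05, 0.15]
        p = default_first_guess(cuts)
    knot_x = [x for x, _ in p.K_knots]
    nK = len(knot_x)
    pi_ext = (jvp_lin or cutflow_series).bath.pi_peg_ext
    P0_guess = _estimate_p0(jvp_lin, cfg.linear_part_threshold)

    def unpack(theta):
        params = p.replace(
            K_knots=make_k_profile(knot_x, 10.0 ** np.asarray(theta[:nK])),
            k=10.0 ** theta[nK],
            Js_star=0.0, Ps=0.0,
        )
        return params, theta[nK + 1]

    n_pts = (len(jvp_lin.x) if jvp_lin is not None else 0) + (
        len(cutflow_series.x) if cutflow_series is not None else 0
    )

    def r(theta):
        fwd.n_evals += 1
        params, P0 = unpack(theta)
        try:
            return fwd.residuals(
                params, solute_transport=False, osmotic_offset=P0 - pi_ext,
            )
        except SolverError as exc:
            warnings.warn(f"forward solve failed ({exc}); penalizing", stacklevel=2)
            return np.full(n_pts, np.sqrt(PENALTY_F / n_pts))

    theta0 = np.concatenate([np.log10([K for _, K in p.K_knots] + [p.k]), [P0_guess]])
    nK1 = len(knot_x)
    lo = [cfg.log_bounds["K"][0]] * nK1 + [cfg.log_bounds["k"][0], -2.0]
    hi = [cfg.log_bounds["K"][1]] * nK1 + [cfg.log_bounds["k"][1], 2.0]
    res = least_squares(
        r, np.clip(theta0, lo, hi), bounds=(lo, hi), method="trf",
        diff_step=1e-4, xtol=1e-10, ftol=1e-12, gtol=1e-12,
        max_nfev=cfg.stage3_maxfev + cfg.stage1_maxfev,
    )
    best_p, P0 = unpack(res.x)
    extra = {"solute_transport": False, "osmotic_offset": P0 - pi_ext}
    measured, modeled, residuals = [], [], {}
    if jvp_lin is not None:
        m = fwd.jvp_model(best_p, **extra)
        measured.append(jvp_lin.Jv)
        modeled.append(m)
        residuals["jvp"] = m - jvp_lin.Jv
    if cutflow_series is not None:
        m = fwd.cutflow_model(best_p, **extra)
        measured.append(cutflow_series.Jv)
        modeled.append(m)
        residuals["cutflow"] = m - cutflow_series.Jv
    result = FitResult(
        params=best_p, F=float(np.sum(np.atleast_1d(res.fun) ** 2)), r2=_pooled_r2(measured, modeled),
        residuals=residuals,
        stage_trace=[{"stage": "pure_hydraulic", "F": float(np.sum(np.atleast_1d(res.fun) ** 2)), "P0": float(P0)}],
        n_evals=fwd.n_evals,
    )
    return result, float(P0)


def sensitivity_scan(
    g: REVGraph,
    jvp_series: ExperimentSeries,
    params_best: TransportParams,
    scan: dict,
    config: Optional[FitConfig] = None,
) -> pd.DataFrame:
    """Re-fit k on the Jv(P) data over a grid of frozen parameter values.

    ``scan`` maps parameter names (``Js_star``, ``Ps``, ``sigma``) to
    value sequences; the scan runs over their Cartesian product. Each
    row reports the scanned values, the re-fitted k and the objective
    F — the basis of the ±10 % robustness bands for k.
    """
    cfg = config or FitConfig()
    fwd = _Forward(g, jvp_series, None, cfg.solver_opts)
    names = list(scan)
    lo, hi = cfg.log_bounds["k"]
    rows = []
    for values in itertools.product(*(scan[n] for n in names)):
        frozen = params_best.replace(**dict(zip(names, map(float, values))))

        def f(logk):
            return fwd.F(frozen.replace(k=10.0 ** logk))

        res = minimize_scalar(
            f, bounds=(max(np.log10(params_best.k) - 2, lo), min(np.log10(params_best.k) + 2, hi)),
            method="bounded", options={"xatol": 1e-4},
        )
        row = dict(zip(names, map(float, values)))
        row["k_fit"] = 10.0 ** res.x
        row["F"] = float(res.fun)
        rows.append(row)
    return pd.DataFrame(rows)


def parameter_band(table: pd.DataFrame, column: str, k0: float, rel_change: float = 0.1):
    """Multiplicative range of ``column`` over which the re-fitted k
    stays within ``rel_change`` of k0; returns (min, max) of the
    retained values."""
    ok = table[np.abs(table["k_fit"] / k0 - 1.0) <= rel_change]
    if ok.empty:
        return (np.nan, np.nan)
    return float(ok[column].min()), float(ok[column].max())
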