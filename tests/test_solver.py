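"""Tree transport solver: flux closures, exact linear solves against an
independent nodal-analysis oracle, conservation, coupled steady states."""
import numpy as np
import pytest

from rootflow import (
    BathSolution,
    TransportParams,
    UnboundedAccumulationError,
    axial_conductance_at,
    balance_residuals,
    discretize,
    generate_synthetic_rsa,
    radial_solute_flux,
    radial_water_flux,
    solve_advection,
    solve_pressure,
    solve_steady_state,
)
from rootflow.solver import PressureSolution


class TestFluxClosures:
    def test_radial_water_flux_value(self):
        S = np.pi * 1.05e-3 * 1e-3
        params = TransportParams(k=1e-7, sigma=0.85)
        bath = BathSolution(Pe=0.1, Ce=0.0)
        # Pe - P = 0.1, C - Ce = 40 -> osmotic term adds 0.08424 MPa
        j = radial_water_flux(S, P=0.0, C=40.0, params=params, bath=bath)
        assert j == pytest.approx(6.078e-14, rel=1e-3)

    def test_radial_water_flux_zero_gradients(self):
        j = radial_water_flux(1e-6, P=0.0, C=13.72, params=TransportParams(), bath=BathSolution(Pe=0.0))
        assert j == pytest.approx(0.0, abs=1e-30)

    def test_peg_reverses_influx(self):
        # external PEG osmotic pull beats the 0.18424 MPa inward drive
        S = np.pi * 1.05e-3 * 1e-3
        params = TransportParams(k=1e-7, sigma=0.85)
        bath = BathSolution(Pe=0.1, Ce=0.0, w_peg=0.150, T=298.15)
        j = radial_water_flux(S, P=0.0, C=40.0, params=params, bath=bath)
        assert j < 0.0

    def test_radial_solute_flux(self):
        S = np.pi * 1.05e-3 * 1e-3
        params = TransportParams(Js_star=1e-7, Ps=1e-9)
        bath = BathSolution(Ce=10.0)
        assert radial_solute_flux(S, C=10.0, params=params, bath=bath) == pytest.approx(1e-7 * S)
        assert radial_solute_flux(S, C=110.0, params=params, bath=bath) == pytest.approx(0.0, abs=1e-25)
        assert radial_solute_flux(S, C=60.0, params=params, bath=bath) == pytest.approx(1.649e-13, rel=1e-3)

    def test_axial_conductance_interpolation(self):
        params = TransportParams(K_knots=((0.0, 1e-12), (0.1, 1e-10)))
        assert axial_conductance_at(0.05, params) == pytest.approx(5.05e-11)
        assert axial_conductance_at(0.2, params) == pytest.approx(1e-10)  # clamped
        assert axial_conductance_at(0.05, params, mu_local=14.0) == pytest.approx(5.05e-11 / 14.0)


def _nodal_analysis_oracle(g, params, bath):
    """Independent dense solve of the hydrostatic resistor network:
    radial conductance k*S from each REV to the bath (at Pe), axial
    half-resistances in series along edges, basal node grounded."""
    n = g.n_revs
    K = params.axial_K(g.dist_to_tip)
    ghalf = 2.0 * K / g.length
    kS = params.k * g.surface
    A = np.zeros((n, n))
    b = np.zeros(n)
    for i in range(n):
        A[i, i] += kS[i]
        b[i] += kS[i] * bath.Pe
        p = g.parent[i]
        if p >= 0:
            ge = 1.0 / (1.0 / ghalf[i] + 1.0 / ghalf[p])
            A[i, i] += ge
            A[p, p] += ge
            A[i, p] -= ge
            A[p, i] -= ge
        else:
            A[i, i] += ghalf[i]  # to the grounded chamber
        if g.is_cut_face[i]:
            A[i, i] += ghalf[i]
            b[i] += ghalf[i] * bath.Pe
    P = np.linalg.solve(A, b)
    Jv = ghalf[g.basal_rev] * P[g.basal_rev]
    return P, Jv


class TestPressureSolve:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_electrical_analogue(self, seed):
        rs = generate_synthetic_rsa(0.05, 60.0, lateral_length_law=(0.012, 0.004), seed=seed)
        g = discretize(rs, 1e-3)
        assert g.n_revs <= 100
        params = TransportParams(k=1e-7, Js_star=0.0, Ps=0.0)
        bath = BathSolution(Pe=0.25, Ce=0.0)
        sol = solve_pressure(g, params, bath, C=np.zeros(g.n_revs), C_peg=np.zeros(g.n_revs))
        P_ref, Jv_ref = _nodal_analysis_oracle(g, params, bath)
        assert np.allclose(sol.P, P_ref, rtol=1e-10, atol=1e-15)
        assert sol.Jv_base == pytest.approx(Jv_ref, rel=1e-10)

    def test_analogue_with_cut_faces(self):
        rs = generate_synthetic_rsa(0.06, 60.0, lateral_length_law=(0.02, 0.005), seed=9)
        g = discretize(rs, 1e-3).cut_at_distance(0.02)
        params = TransportParams(k=1e-7, Js_star=0.0, Ps=0.0)
        bath = BathSolution(Pe=0.2, Ce=0.0)
        sol = solve_pressure(g, params, bath, C=np.zeros(g.n_revs), C_peg=np.zeros(g.n_revs))
        P_ref, Jv_ref = _nodal_analysis_oracle(g, params, bath)
        assert np.allclose(sol.P, P_ref, rtol=1e-10, atol=1e-15)
        assert sol.Jv_base == pytest.approx(Jv_ref, rel=1e-10)

    def test_equilibrium_is_flowless(self, small_graph):
        bath = BathSolution(Pe=0.0)
        sol = solve_pressure(small_graph, TransportParams(), bath,
                             C=np.full(small_graph.n_revs, bath.Ce),
                             C_peg=np.zeros(small_graph.n_revs))
        assert np.allclose(sol.P, 0.0, atol=1e-15)
        assert np.allclose(sol.J, 0.0, atol=1e-25)
        assert sol.Jv_base == pytest.approx(0.0, abs=1e-25)

    def test_linearity_in_conductances(self, small_graph):
        bath = BathSolution(Pe=0.3, Ce=0.0)
        p1 = TransportParams(k=1e-7, Js_star=0.0, Ps=0.0)
        p2 = TransportParams(
            k=2e-7, K_knots=tuple((x, 2 * K) for x, K in p1.K_knots), Js_star=0.0, Ps=0.0
        )
        C = np.zeros(small_graph.n_revs)
        Z = np.zeros(small_graph.n_revs)
        jv1 = solve_pressure(small_graph, p1, bath, C, Z).Jv_base
        jv2 = solve_pressure(small_graph, p2, bath, C, Z).Jv_base
        assert jv2 == pytest.approx(2 * jv1, rel=1e-12)

    def test_per_rev_balance_machine_exact(self, small_graph):
        params = TransportParams()
        bath = BathSolution(Pe=0.2)
        sol = solve_pressure(small_graph, params, bath,
                             C=np.full(small_graph.n_revs, 50.0),
                             C_peg=np.zeros(small_graph.n_revs))
        n = small_graph.n_revs
        bal = sol.j + sol.Q_face - sol.J
        bal += np.bincount(small_graph.parent[1:], weights=sol.J[1:], minlength=n)
        bal[small_graph.basal_rev] -= sol.Jv_base
        scale = max(np.max(np.abs(sol.j)), np.max(np.abs(sol.J)), abs(sol.Jv_base))
        assert np.max(np.abs(bal)) / scale < 1e-12


class TestAdvection:
    def test_single_rev_dilution_balance(self, one_rev_graph):
        # one REV with face inflow J at bath composition and no leak:
        # C = Ce + Js*.S/J
        g = one_rev_graph
        params = TransportParams(Js_star=1e-7, Ps=0.0)
        bath = BathSolution(Ce=10.0)
        J = 2e-12
        flows = PressureSolution(
            P=np.zeros(1), J=np.zeros(1), Jv_base=J,
            Q_face=np.array([J]), j=np.zeros(1),
        )
        C, C_peg = solve_advection(g, flows, params, bath)
        S = g.surface[0]
        assert C[0] == pytest.approx(10.0 + 1e-7 * S / J, rel=1e-12)
        assert C_peg[0] == 0.0

    def test_zero_flow_ceiling(self, one_rev_graph, huge_axial_params):
        # at the zero-flow pressure the xylem sits at C - Ce = Js*/Ps
        p = huge_axial_params
        Pe0 = -p.sigma * p.rt * p.Js_star / p.Ps
        st = solve_steady_state(one_rev_graph, p, BathSolution(Pe=Pe0), tol=1e-13, max_iter=3000)
        assert st.C[0] - 13.72 == pytest.approx(p.Js_star / p.Ps, rel=1e-8)
        assert abs(st.Jv_base) < 1e-22

    def test_unbounded_accumulation_without_leak(self, one_rev_graph, huge_axial_params):
        # no leak, no osmotic coupling, no pressure drive: the pumped
        # solutes have nowhere to go
        params = huge_axial_params.replace(Ps=0.0, sigma=0.0)
        with pytest.raises(UnboundedAccumulationError):
            solve_steady_state(one_rev_graph, params, BathSolution(Pe=0.0))


class TestSteadyState:
    def test_exudation_and_negative_flux_regimes(self, reference_graph):
        st = solve_steady_state(reference_graph, TransportParams(), BathSolution(Pe=0.0), tol=1e-10)
        assert st.converged and st.Jv_base > 0  # spontaneous exudation
        peg = solve_steady_state(
            reference_graph, TransportParams(k=1e-8), BathSolution(Pe=0.0, w_peg=0.150), tol=1e-10
        )
        assert peg.converged and peg.Jv_base < 0  # reverse flow under water deficit

    def test_concentrations_nonnegative(self, reference_graph):
        g = reference_graph.cut_at_distance(0.1)
        st = solve_steady_state(
            g, TransportParams(k=1e-8), BathSolution(Pe=0.3, w_peg=0.150), tol=1e-10
        )
        assert np.all(st.C >= 0)
        assert np.all(st.C_peg >= 0)
        assert st.C_peg.max() <= 0.151  # no more concentrated than the bath here

    def test_jv_monotone_in_pressure(self, small_graph):
        jv = [
            solve_steady_state(small_graph, TransportParams(), BathSolution(Pe=pe), tol=1e-10).Jv_base
            for pe in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
        ]
        assert np.all(np.diff(jv) > 0)

    def test_grid_refinement_convergence(self, small_rs):
        params = TransportParams()
        bath = BathSolution(Pe=0.2)
        jv = [
            solve_steady_state(discretize(small_rs, h), params, bath, tol=1e-10).Jv_base
            for h in (1e-3, 0.5e-3)
        ]
        assert abs(jv[1] / jv[0] - 1) < 0.01

    def test_warm_start_agrees_with_cold(self, small_graph):
        params = TransportParams()
        cold = solve_steady_state(small_graph, params, BathSolution(Pe=0.25), tol=1e-11)
        other = solve_steady_state(small_graph, params, BathSolution(Pe=0.15), tol=1e-11)
        warm = solve_steady_state(
            small_graph, params, BathSolution(Pe=0.25), tol=1e-11,
            C0=other.C, Cpeg0=other.C_peg, dt0=other.final_dt,
        )
        assert warm.Jv_base == pytest.approx(cold.Jv_base, rel=1e-8)

    def test_per_rev_export(self, small_graph):
        st = solve_steady_state(small_graph, TransportParams(), BathSolution(Pe=0.1), tol=1e-10)
        df = st.to_frame(small_graph)
        assert list(df.columns) == [
            "rev_id", "distance_to_tip_m", "order", "P_MPa", "C_mol_m3", "C_peg_kg_l", "j_m3_s", "J_m3_s",
        ]
        assert len(df) == small_graph.n_revs


class TestConservation:
    @pytest.mark.parametrize("seed", range(3))
    def test_water_and_solute_balances(self, seed):
        rs = generate_synthetic_rsa(0.12, 60.0, lateral_length_law=(0.03, 0.01), seed=seed)
        g = discretize(rs, 1e-3)
        params = TransportParams()
        bath = BathSolution(Pe=0.15)
        st = solve_steady_state(g, params, bath, tol=1e-12, max_iter=4000)
        res = balance_residuals(g, st, params, bath)
        assert np.max(np.abs(res["water"])) / res["water_scale"] < 1e-10
        assert np.max(np.abs(res["solute"])) / res["solute_scale"] < 1e-10
        assert abs(res["water_global"]) / res["water_scale"] < 1e-10
        assert abs(res["solute_global"]) / res["solute_scale"] < 1e-10
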