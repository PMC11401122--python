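"""Physics of the coupled pressure/concentration solver.

Covers the constitutive pieces (Van't Hoff, exudation sources), exactness on
trivial equilibria, the physiological flow structure (direction, magnitudes,
albumin accumulation), conservation closure, axis regularity, comparative
statics, and agreement with the independent one-dimensional far-field
solution.
"""

import numpy as np
import pytest

import macuflow as mf
from macuflow.mesh import build_ring_mesh
from macuflow.parameters import MMHG, ParameterError
from macuflow.transport import fluid_budget, solute_budget


class TestConstitutive:
    def test_osmotic_pressure_values(self, params):
        assert mf.osmotic_pressure(0.0, params) == 0.0
        assert mf.osmotic_pressure(0.011, params) == pytest.approx(28.3, rel=0.01)
        pi_c = mf.osmotic_pressure(0.053, params)
        assert pi_c == pytest.approx(136.6, rel=0.01)
        assert (pi_c - mf.osmotic_pressure(0.011, params)) == pytest.approx(108.2, rel=0.01)
        with pytest.raises(ParameterError):
            mf.osmotic_pressure(-1e-3, params)

    def test_fluid_source_cases(self, params):
        nm = mf.Numerics()
        off = mf.Scenario(af_fraction=0.0)
        on = mf.Scenario(af_fraction=1.0)
        h = params.h_0
        # physiological: identically zero
        assert mf.fluid_source(1.5e-3, 0.9 * h, 0.0, h, params, off, nm) == 0.0
        # zero driving difference
        assert mf.fluid_source(1.5e-3, 0.9 * h, params.p_a, h, params, on, nm) == 0.0
        # inside the ring at zero tissue pressure: q = alpha p_a
        q = mf.fluid_source(1.5e-3, 0.9 * h, 0.0, h, params, on, nm)
        assert q == pytest.approx(nm.af_amplitude(params) * params.p_a, rel=1e-12)
        # deformation invariance of the leak rate: q scales as h0/h
        q2 = mf.fluid_source(1.5e-3, 1.8 * h, 0.0, 2 * h, params, on, nm)
        assert q2 == pytest.approx(q / 2, rel=1e-12)

    def test_solute_source_is_a_times_fluid_source(self, params):
        nm = mf.Numerics()
        on = mf.Scenario(af_fraction=1.0)
        pts = [(1.5e-3, 0.9 * params.h_0), (1.7e-3, 0.95 * params.h_0)]
        for r, z in pts:
            q = mf.fluid_source(r, z, 10.0, params.h_0, params, on, nm)
            qa = mf.solute_source(r, z, 10.0, params.h_0, params, on, nm)
            assert qa == pytest.approx(params.a * q, rel=1e-12)
        off = mf.Scenario(af_fraction=1.0, albumin_on=False)
        assert mf.solute_source(1.5e-3, 0.9 * params.h_0, 0.0, params.h_0,
                                params, off, nm) == 0.0


class TestTrivialEquilibrium:
    def test_no_driving_forces_gives_uniform_rest_state(self):
        """Equal reservoirs, no pumping, no sources: p = p_v, u = 0, c = c_v,
        reached in at most two Picard sweeps."""
        params = mf.load_parameters({"Q_RPE": 1e-30, "c_c": 0.011})
        nm = mf.Numerics(dr_inner=8e-5, dr_ring=1e-4, nz=8)
        sc = mf.Scenario(af_fraction=0.0)
        K = mf.build_conductivity_field(params, 60.0, nm)
        mesh = mf.build_mesh(params, nm)
        st = mf.coupled_solve(mesh, K, params, sc, nm)
        assert st.iterations <= 2
        assert np.max(np.abs(st.p - params.p_v)) < 1e-8
        assert np.max(st.speed) < 1e-16
        assert np.max(np.abs(st.c - params.c_v)) < 1e-12

    def test_uniform_pressure_gives_zero_velocity(self, params, kfield, numerics):
        mesh = mf.build_mesh(params, numerics)
        from macuflow.transport import compute_velocity, conductivity_elements
        u = compute_velocity(mesh, conductivity_elements(mesh, kfield),
                             np.full(mesh.nodes.shape[0], 7.0))
        assert np.max(np.abs(u)) < 1e-20


class TestPhysiological:
    def test_trans_retinal_pressure_drop_below_1mmHg(self, phys_state):
        P = phys_state.p.reshape(-1, phys_state.mesh.zeta.size)
        assert np.max(P.max(axis=1) - P.min(axis=1)) < 1.0 * MMHG

    def test_flow_exits_through_rpe_everywhere(self, params, phys_state):
        Pi = params.RT * phys_state.c
        outflux = (params.Gamma_RPE * ((phys_state.p - params.p_c)
                                       - params.sigma * (Pi - params.RT * params.c_c))
                   + params.Q_RPE)
        rpe_nodes = np.arange(phys_state.mesh.nr) * phys_state.mesh.zeta.size
        assert np.all(outflux[rpe_nodes] > 0)

    def test_albumin_accumulates_toward_rpe_far_field(self, phys_state):
        C = phys_state.c.reshape(-1, phys_state.mesh.zeta.size)
        far = phys_state.mesh.r_array > 3e-3
        assert np.all(C[far, 0] > C[far, -1])

    def test_speed_peaks_in_the_macular_high_conductivity_region(self, params, phys_state):
        cen = phys_state.mesh.centroid
        inner = phys_state.speed[cen[:, 0] <= params.L_1].max()
        outer = phys_state.speed[cen[:, 0] > params.L_1 + 2e-4].max()
        assert inner > 2 * outer
        # an order of magnitude above the distal one-dimensional drift
        far = phys_state.speed[cen[:, 0] > 6e-3].max()
        assert inner > 8 * far

    def test_axis_regularity(self, phys_state):
        """Zero radial pressure gradient at r = 0 to discretization accuracy."""
        P = phys_state.p.reshape(-1, phys_state.mesh.zeta.size)
        r = phys_state.mesh.r_array
        dpdr_axis = (P[1] - P[0]) / (r[1] - r[0])
        scale = np.max(np.abs(P)) / phys_state.mesh.h_profile[0]
        assert np.max(np.abs(dpdr_axis)) < 2e-2 * scale

    def test_balances_and_peclet_reported(self, phys_state):
        assert abs(phys_state.fluid_balance) < 1e-8
        assert abs(phys_state.solute_balance) < 1e-6
        assert 0 < phys_state.peclet < 1.5
        assert phys_state.c.min() > 0        # no undershoot at mild Peclet


class TestConservation:
    def test_pathological_budgets_close(self, params, numerics, base_edema):
        sc = mf.Scenario(af_fraction=1.0, albumin_on=True, deformable=True)
        fb = fluid_budget(base_edema.state, params, sc, numerics)
        sb = solute_budget(base_edema.state, params, sc, numerics)
        assert abs(fb["residual"]) < 1e-8
        assert abs(sb["residual"]) < 1e-6
        # albumin leaves only through the ILM and matches the leak exactly
        assert sb["out_ilm"] == pytest.approx(sb["source"], rel=1e-6)


class TestFarFieldOracle:
    def test_two_dimensional_solver_matches_column_solution(self, params):
        """On an r-independent configuration the FEM solution must agree
        with the independently coded two-point boundary-value solution."""
        nm = mf.Numerics()
        K = mf.build_conductivity_field(params, 60.0, nm)
        mesh = build_ring_mesh(params, 0.95 * params.L, params.L, 4, 400)
        st = mf.coupled_solve(mesh, K, params, mf.Scenario(af_fraction=0.0), nm)
        v, p_of_z, c_of_z = mf.far_field_column(
            params, lambda z: K(np.full_like(z, params.L), z, params.h_0))
        nzp = mesh.zeta.size
        i = mesh.nr - 1
        z = mesh.nodes[i * nzp:(i + 1) * nzp, 1]
        p_err = np.max(np.abs(st.column(i, st.p) - p_of_z(z))) / np.max(np.abs(p_of_z(z)))
        c_err = np.max(np.abs(st.column(i, st.c) - c_of_z(z))) / params.c_v
        assert p_err < 1e-4
        assert c_err < 1e-4
        # the physiological drift is retina -> choroid (downward)
        assert v < 0
        assert abs(v) == pytest.approx(1.06e-8, rel=0.05)


class TestComparativeStatics:
    def test_stronger_pumping_lowers_tissue_pressure(self, params):
        K_of_z = lambda z: np.full_like(z, params.Gamma_ret * params.h_0)
        v1, p1, _ = mf.far_field_column(params, K_of_z, q_rpe_multiplier=1.0)
        v2, p2, _ = mf.far_field_column(params, K_of_z, q_rpe_multiplier=2.0)
        assert p2(0.0) < p1(0.0) and p2(params.h_0) < p1(params.h_0)

    def test_higher_choroidal_albumin_increases_rpe_flux(self, params):
        K_of_z = lambda z: np.full_like(z, params.Gamma_ret * params.h_0)
        v1, _, _ = mf.far_field_column(params, K_of_z)
        richer = params.replace(c_c=2 * params.c_c)
        v2, _, _ = mf.far_field_column(richer, K_of_z)
        assert -v2 > -v1      # outflux toward the choroid grows

    def test_statics_hold_in_two_dimensions(self, params, numerics, kfield, phys_state):
        pumped = mf.coupled_solve(mf.build_mesh(params, numerics), kfield, params,
                                  mf.Scenario(af_fraction=0.0, q_rpe_multiplier=2.0),
                                  numerics)
        assert pumped.p.mean() < phys_state.p.mean()


class TestPicard:
    def test_tolerance_halving_self_consistency(self, params, kfield):
        nm = mf.Numerics(dr_inner=8e-5, dr_ring=1.2e-4, nz=12)
        mesh = mf.build_mesh(params, nm)
        sc = mf.Scenario(af_fraction=1.0)
        loose = mf.coupled_solve(mesh, kfield, params, sc, nm, tol=1e-6)
        tight = mf.coupled_solve(mesh, kfield, params, sc, nm, tol=5e-7)
        rel = np.linalg.norm(tight.c - loose.c) / np.linalg.norm(tight.c)
        assert rel < 1e-6

    def test_nonconvergence_reports_history(self, params, kfield):
        nm = mf.Numerics(dr_inner=8e-5, dr_ring=1.2e-4, nz=12)
        mesh = mf.build_mesh(params, nm)
        with pytest.raises(RuntimeError, match="residual history"):
            mf.coupled_solve(mesh, kfield, params, mf.Scenario(af_fraction=1.0),
                             nm, tol=1e-13, max_iter=3)
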