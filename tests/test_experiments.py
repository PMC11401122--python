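"""Scenario metrics, sweeps and the mesh-invariance study."""

import numpy as np
import pytest

import macuflow as mf
from macuflow import experiments as ex
from macuflow.parameters import MMHG, ParameterError


class TestMeanFoveolarPressure:
    def _fake_state(self, params, numerics, value, h=None):
        mesh = mf.build_mesh(params, numerics, h=h)
        n = mesh.nodes.shape[0]
        return mf.SolutionState(mesh=mesh, p=np.full(n, value),
                                c=np.full(n, params.c_v),
                                u=np.zeros((mesh.tris.shape[0], 2)),
                                h=mesh.h_profile)

    def test_zero_and_constant_fields(self, params, coarse_numerics):
        st0 = self._fake_state(params, coarse_numerics, 0.0)
        assert ex.mean_foveolar_pressure(st0, params, coarse_numerics) == 0.0
        stc = self._fake_state(params, coarse_numerics, 3.7 * MMHG)
        assert ex.mean_foveolar_pressure(stc, params, coarse_numerics) == pytest.approx(3.7)

    def test_constant_field_unaffected_by_deformation(self, params, coarse_numerics):
        bump = lambda r: params.h_0 * (1 + np.exp(-(r / 5e-4) ** 2))
        std = self._fake_state(params, coarse_numerics, 2.0 * MMHG, h=bump)
        assert ex.mean_foveolar_pressure(std, params, coarse_numerics) == pytest.approx(2.0)


class TestPhysiologicalScenario:
    def test_flow_and_velocity_structure(self, params, phys_result):
        m = phys_result.metrics
        assert m["trans_retinal_dp_mmHg"] < 1.0
        assert 1e-8 < m["max_speed_fovea"] < 1e-6
        assert m["max_speed"] == pytest.approx(m["max_speed_fovea"], rel=1e-9)

    def test_far_field_becomes_radially_uniform(self, phys_result):
        """The macular disturbance decays: radial variation is a few per cent
        at 2 mm and essentially gone by 6 mm."""
        st = phys_result.state
        P = st.p.reshape(st.mesh.nr, st.mesh.zeta.size)
        var = np.max(np.abs(P - P[-1]), axis=1) / np.max(np.abs(P[-1]))
        r = st.mesh.r_array
        assert var[np.searchsorted(r, 2e-3)] < 0.10
        assert var[np.searchsorted(r, 4e-3)] < 0.02
        assert var[np.searchsorted(r, 6e-3)] < 0.005

    def test_reference_independence_of_pathology_parameters(self, params, numerics,
                                                            phys_result):
        """Physiological metrics do not depend on A_f; moving the exudation
        ring only re-anchors the mesh (small discretization shift)."""
        m0 = phys_result.metrics
        other = ex.run_physiological(params.replace(A_f=5 * params.A_f), numerics)
        assert other.metrics["trans_retinal_dp_mmHg"] == pytest.approx(
            m0["trans_retinal_dp_mmHg"], rel=1e-12)
        moved = ex.run_physiological(params.replace(L_e1=1.4e-3, L_e2=1.9e-3),
                                     numerics)
        assert moved.metrics["trans_retinal_dp_mmHg"] == pytest.approx(
            m0["trans_retinal_dp_mmHg"], rel=1e-2)

    def test_determinism(self, params, coarse_numerics):
        a = ex.run_physiological(params, coarse_numerics)
        b = ex.run_physiological(params, coarse_numerics)
        for key in ("trans_retinal_dp_mmHg", "max_speed", "peak_c"):
            assert a.metrics[key] == pytest.approx(b.metrics[key], rel=1e-10)


class TestPathologicalScenario:
    def test_headline_structure(self, params, base_edema):
        m = base_edema.metrics
        assert m["max_thickening"] == pytest.approx(2.0, abs=0.15)
        assert m["thickening_at_r0"] == m["max_thickening"]
        assert m["max_excess_p_mmHg"] > 0
        assert m["peak_c"] < 0.53          # below the plasma ceiling
        # albumin peaks adjacent to the exudation ring
        st = base_edema.state
        i = int(np.argmax(st.c))
        r_peak = st.mesh.nodes[i, 0]
        assert 1.0e-3 < r_peak < 2.2e-3

    def test_fluid_drawn_from_vitreous_at_the_exudation_site(self, params, base_edema):
        """Osmotic suction pulls vitreal fluid inward across the ILM above
        the ring, while the RPE keeps draining toward the choroid."""
        from macuflow import fem
        from macuflow.transport import _boundary_elements
        st = base_edema.state
        ilm_elems = _boundary_elements(st.mesh, "ilm")
        n_ilm = fem.edge_normals(st.mesh, "ilm")
        u_n = np.einsum("ed,ed->e", st.u[ilm_elems], n_ilm)
        e_mid = st.mesh.nodes[st.mesh.edges["ilm"]].mean(axis=1)
        ring = (e_mid[:, 0] > params.L_e1) & (e_mid[:, 0] < params.L_e2)
        assert np.min(u_n[ring]) < 0       # inflow somewhere over the ring
        Pi = params.RT * st.c
        out_rpe = (params.Gamma_RPE * ((st.p - params.p_c)
                                       - params.sigma * (Pi - params.RT * params.c_c))
                   + params.Q_RPE)
        rpe_nodes = np.arange(st.mesh.nr) * st.mesh.zeta.size
        assert np.all(out_rpe[rpe_nodes] > 0)

    def test_rejects_zero_amplitude(self, params, coarse_numerics):
        with pytest.raises(ParameterError):
            ex.run_pathological(params, coarse_numerics, af_fraction=0.0)


@pytest.fixture(scope="module")
def af_table(params, numerics):
    return ex.sweep_exudation(params, fractions=(0.05, 0.5, 1.0),
                              numerics=numerics)


class TestSweeps:
    def test_pressure_monotone_in_amplitude(self, af_table):
        for ratio in (1.0, 60.0):
            sub = af_table[af_table.hc_ratio == ratio]
            assert np.all(np.diff(sub.mean_foveolar_p_mmHg) > 0)

    def test_layering_mitigates_the_pressure_rise(self, af_table):
        one = af_table[af_table.hc_ratio == 1.0].set_index("af_fraction")
        three = af_table[af_table.hc_ratio == 60.0].set_index("af_fraction")
        gain1 = one.mean_foveolar_p_mmHg[1.0] - one.mean_foveolar_p_mmHg[0.05]
        gain3 = three.mean_foveolar_p_mmHg[1.0] - three.mean_foveolar_p_mmHg[0.05]
        assert gain3 < gain1

    def test_continuity_toward_the_physiological_mean(self, af_table, phys_result):
        p_phys = phys_result.metrics["mean_foveolar_p_mmHg"]
        three = af_table[af_table.hc_ratio == 60.0].set_index("af_fraction")
        gap_small = three.mean_foveolar_p_mmHg[0.05] - p_phys
        gap_large = three.mean_foveolar_p_mmHg[1.0] - p_phys
        assert 0 < gap_small < 0.2 * gap_large

    def test_ratio_sweep_protects_the_fovea(self, params, numerics, af_table):
        """Strong layer contrast lowers the foveolar pressure: the curve
        decreases from ratio 10 upward and the net 1 -> 100 change is a
        decrease (a small bump exists at low ratios, where the more
        conductive outer layers transmit the ring pressure inward)."""
        df = ex.sweep_hc_ratio(params, ratios=(1.0, 10.0, 60.0, 100.0),
                               albumin_settings=(True,), numerics=numerics)
        p = df.mean_foveolar_p_mmHg.values
        assert np.all(np.diff(p[1:]) < 0)  # monotone beyond ratio 10
        assert p[-1] < p[0]                # net protective effect
        # ratio 1 reproduces the single-layer amplitude-sweep point
        one = af_table[(af_table.hc_ratio == 1.0) & (af_table.af_fraction == 1.0)]
        assert p[0] == pytest.approx(one.mean_foveolar_p_mmHg.iloc[0], rel=1e-10)
        with pytest.raises(ParameterError):
            ex.sweep_hc_ratio(params, ratios=(0.5,), numerics=numerics)


def test_albumin_switch_isolates_the_osmotic_drive(params, numerics, base_edema):
    """Switching off the albumin source collapses the excess pressure:
    osmosis, not mechanical leak pressure, drives the edema."""
    rec = ex.albumin_switch_experiment(params, numerics, base=base_edema)
    assert rec["dp_with_albumin_mmHg"] == base_edema.metrics["max_excess_p_mmHg"]
    assert rec["dp_with_albumin_mmHg"] > 5 * rec["dp_without_albumin_mmHg"]
    assert rec["dp_without_albumin_mmHg"] > 0


class TestRpePumping:
    def test_identity_multiplier_changes_nothing(self, params, numerics, base_edema):
        rec = ex.rpe_pumping_sensitivity(params, 1.0, numerics, base=base_edema)
        assert rec["percent_reduction"] == pytest.approx(0.0, abs=1e-6)

    def test_weaker_pumping_raises_pressure(self, params, numerics, base_edema):
        rec = ex.rpe_pumping_sensitivity(params, 0.5, numerics, base=base_edema)
        assert rec["percent_reduction"] < 0

    def test_rejects_nonpositive_multiplier(self, params, numerics, base_edema):
        with pytest.raises(ParameterError):
            ex.rpe_pumping_sensitivity(params, 0.0, numerics, base=base_edema)


class TestMeshStudy:
    def test_single_mesh_request_rejected(self, params, numerics):
        with pytest.raises(ParameterError):
            ex.mesh_convergence_study(params, numerics, n_meshes=1)
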