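"""Scripted scenarios: physiological baseline, edema case, parameter sweeps.

Each scenario returns a ``ScenarioResult`` carrying the scalar metrics the
study tracks (mean foveolar pressure, peak Darcy speed, peak albumin
concentration, maximum excess pressure against the physiological reference,
maximum thickening ratio) plus the underlying solution state(s).

Pressure metrics for the sweeps are computed on the rigid domain: the
exudation source carries the h_0/h factor, so its strength is
deformation-invariant, and the foveolar pressure was found insensitive to
the deformation; the headline edema scenario itself runs the full
fluid-structure loop.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fem
from .deformation import FsiResult, calibrate_beta, fsi_solve, reference_state
from .geometry import build_conductivity_field
from .mesh import build_mesh
from .parameters import MMHG, ModelParameters, Numerics, ParameterError, Scenario
from .transport import SolutionState, coupled_solve


@dataclass
class ScenarioResult:
    """Scalar metrics and the underlying fields of one scenario run."""

    name: str
    inputs: dict
    metrics: dict
    state: SolutionState
    reference: SolutionState | None = None
    fsi: FsiResult | None = None
    tables: dict = field(default_factory=dict)
    exports: list = field(default_factory=list)


# ---------------------------------------------------------------------- #
# Metric helpers
# ---------------------------------------------------------------------- #

def mean_foveolar_pressure(state: SolutionState, params: ModelParameters,
                           numerics: Numerics | None = None) -> float:
    """Volume-averaged pressure over the foveolar column (mm Hg).

    The average uses the axisymmetric r-weighted measure over
    {r <= R_f, 0 <= z <= h(r)} with R_f = L_f by default.
    """
    nm = numerics or Numerics()
    R_f = nm.foveola_avg_radius if nm.foveola_avg_radius is not None else params.L_f
    mask = state.mesh.centroid[:, 0] <= R_f
    rq = fem._elem_r_mid(state.mesh)
    pq = state.p[state.mesh.tris] @ fem._MID.T
    w = (state.mesh.area[:, None] / 3.0 * rq)[mask]
    num = float(np.sum(w * pq[mask]))
    den = float(np.sum(w))
    return num / den / MMHG


def trans_retinal_dp(state: SolutionState) -> float:
    """Max over radius of the through-thickness pressure difference (mm Hg)."""
    P = state.p.reshape(-1, state.mesh.zeta.size)
    return float(np.max(P.max(axis=1) - P.min(axis=1))) / MMHG


def max_speed_within(state: SolutionState, radius: float) -> float:
    mask = state.mesh.centroid[:, 0] <= radius
    return float(state.speed[mask].max())


def excess_pressure_max(state: SolutionState, reference: SolutionState) -> float:
    """Max of p - p_ref at matched (r, zeta) grid points (mm Hg)."""
    return float(np.max(state.p - reference.p)) / MMHG


def interp_structured(state: SolutionState, fieldvec: np.ndarray,
                      r: float, zeta: float) -> float:
    """Bilinear interpolation of a nodal field at (r, z/h) on the tensor grid."""
    mesh = state.mesh
    F = fieldvec.reshape(mesh.nr, mesh.zeta.size)
    col = np.array([np.interp(zeta, mesh.zeta, F[i]) for i in range(mesh.nr)])
    return float(np.interp(r, mesh.r_array, col))


def _common_metrics(state: SolutionState, params: ModelParameters,
                    numerics: Numerics) -> dict:
    return {
        "mean_foveolar_p_mmHg": mean_foveolar_pressure(state, params, numerics),
        "trans_retinal_dp_mmHg": trans_retinal_dp(state),
        "max_speed": float(state.speed.max()),
        "max_speed_foveola": max_speed_within(state, params.L_f),
        "max_speed_fovea": max_speed_within(state, params.L_1),
        "peak_c": float(state.c.max()),
        "min_c": float(state.c.min()),
        "peclet": state.peclet,
        "fluid_balance": state.fluid_balance,
        "solute_balance": state.solute_balance,
        "picard_iterations": state.iterations,
    }


# ---------------------------------------------------------------------- #
# Scenarios
# ---------------------------------------------------------------------- #

def run_physiological(params: ModelParameters,
                      numerics: Numerics | None = None,
                      hc_ratio: float = 60.0) -> ScenarioResult:
    """Physiological baseline: rigid domain, no exudation (A_f = 0)."""
    nm = numerics or Numerics()
    sc = Scenario(name="physiological", af_fraction=0.0, hc_ratio=hc_ratio)
    K = build_conductivity_field(params, hc_ratio, nm)
    mesh = build_mesh(params, nm)
    t0 = time.time()
    st = coupled_solve(mesh, K, params, sc, nm)
    m = _common_metrics(st, params, nm)
    # radial flatness of the far field: relative variation beyond 2 mm
    P = st.p.reshape(mesh.nr, mesh.zeta.size)
    far = mesh.r_array >= 2e-3
    m["far_field_radial_variation"] = float(
        np.max(np.abs(P[far] - P[-1])) / np.max(np.abs(P[-1])))
    m["runtime_s"] = time.time() - t0
    return ScenarioResult("physiological", {"hc_ratio": hc_ratio}, m, st)


def run_pathological(params: ModelParameters,
                     numerics: Numerics | None = None,
                     af_fraction: float = 1.0,
                     hc_ratio: float = 60.0,
                     albumin_on: bool = True,
                     q_rpe_multiplier: float = 1.0,
                     beta: float | None = None,
                     reference: SolutionState | None = None) -> ScenarioResult:
    """Edema case: full fluid-structure solve at the given exudation level."""
    if af_fraction <= 0:
        raise ParameterError("the pathological scenario requires af_fraction > 0")
    nm = numerics or Numerics()
    sc = Scenario(name="pathological", af_fraction=af_fraction,
                  hc_ratio=hc_ratio, albumin_on=albumin_on,
                  q_rpe_multiplier=q_rpe_multiplier, deformable=True, beta=beta)
    K = build_conductivity_field(params, hc_ratio, nm)
    t0 = time.time()
    ref = reference if reference is not None else reference_state(params, K, nm)
    res = fsi_solve(params, K, sc, nm, beta=beta, reference=ref)
    st = res.state
    m = _common_metrics(st, params, nm)
    th = res.thickening
    r = ref.mesh.r_array
    m["max_excess_p_mmHg"] = excess_pressure_max(st, ref)
    m["max_thickening"] = float(th.max())
    m["thickening_at_r0"] = float(th[0])
    m["thickening_at_Le2"] = float(np.interp(params.L_e2, r, th))
    # lateral half-width of the bump: radius where the thickening excess
    # first falls to half its maximum
    excess = th - 1.0
    if excess.max() > 0:
        half = 0.5 * excess.max()
        above = np.nonzero(excess >= half)[0]
        m["lateral_half_width"] = float(r[above[-1]])
    else:
        m["lateral_half_width"] = 0.0
    m["beta"] = res.beta
    m["outer_iterations"] = res.outer_iterations
    m["runtime_s"] = time.time() - t0
    return ScenarioResult(
        "pathological",
        {"af_fraction": af_fraction, "hc_ratio": hc_ratio,
         "albumin_on": albumin_on, "q_rpe_multiplier": q_rpe_multiplier},
        m, st, reference=ref, fsi=res)


def sweep_exudation(params: ModelParameters,
                    fractions=None,
                    layerings=(1.0, 60.0),
                    numerics: Numerics | None = None) -> pd.DataFrame:
    """Mean foveolar pressure vs. exudation amplitude, 1- vs 3-layer retina.

    ``fractions`` span 10%-250% of the baseline A_f by default; the 1-layer
    curve uses a conductivity ratio of 1 at the same overall retinal HC.
    """
    nm = numerics or Numerics()
    if fractions is None:
        fractions = np.linspace(0.1, 2.5, 9)
    rows = []
    for ratio in layerings:
        K = build_conductivity_field(params, ratio, nm)
        mesh = build_mesh(params, nm)
        for f in fractions:
            sc = Scenario(name="sweep", af_fraction=float(f), hc_ratio=ratio)
            st = coupled_solve(mesh, K, params, sc, nm)
            rows.append({"af_fraction": float(f), "hc_ratio": float(ratio),
                         "mean_foveolar_p_mmHg": mean_foveolar_pressure(st, params, nm),
                         "peak_c": float(st.c.max())})
    return pd.DataFrame(rows)


def sweep_hc_ratio(params: ModelParameters,
                   ratios=(1.0, 10.0, 60.0, 100.0),
                   albumin_settings=(True, False),
                   af_fraction: float = 1.0,
                   numerics: Numerics | None = None) -> pd.DataFrame:
    """Mean foveolar pressure vs. the layer conductivity ratio K(1)/K(2).

    The overall retinal conductivity is held fixed while the ratio varies;
    ratio 1 is the homogeneous single-layer retina.
    """
    nm = numerics or Numerics()
    rows = []
    for ratio in ratios:
        if ratio < 1:
            raise ParameterError("hc_ratio sweep requires ratios >= 1")
        K = build_conductivity_field(params, ratio, nm)
        mesh = build_mesh(params, nm)
        for alb in albumin_settings:
            sc = Scenario(name="sweep", af_fraction=af_fraction,
                          hc_ratio=ratio, albumin_on=alb)
            st = coupled_solve(mesh, K, params, sc, nm)
            rows.append({"hc_ratio": float(ratio), "albumin_on": bool(alb),
                         "af_fraction": af_fraction,
                         "mean_foveolar_p_mmHg": mean_foveolar_pressure(st, params, nm)})
    return pd.DataFrame(rows)


def rpe_pumping_sensitivity(params: ModelParameters, multiplier: float = 3.5,
                            numerics: Numerics | None = None,
                            base: ScenarioResult | None = None) -> dict:
    """Percent reduction of peak excess pressure under stronger RPE pumping.

    Reruns the baseline edema case with Q_RPE scaled by ``multiplier`` and
    reports 100 * (1 - dp_max_new / dp_max_base).
    """
    if multiplier <= 0:
        raise ParameterError("pumping multiplier must be > 0")
    nm = numerics or Numerics()
    if base is None:
        base = run_pathological(params, nm)
    scaled = run_pathological(params, nm, q_rpe_multiplier=multiplier,
                              beta=base.metrics["beta"], reference=base.reference)
    dp0 = base.metrics["max_excess_p_mmHg"]
    dp1 = scaled.metrics["max_excess_p_mmHg"]
    return {"multiplier": multiplier,
            "dp_base_mmHg": dp0, "dp_scaled_mmHg": dp1,
            "percent_reduction": 100.0 * (1.0 - dp1 / dp0)}


def albumin_switch_experiment(params: ModelParameters,
                              numerics: Numerics | None = None,
                              base: ScenarioResult | None = None) -> dict:
    """Peak excess pressure with and without albumin leakage (mm Hg).

    Isolates the osmotic contribution: the fluid source stays at baseline
    while the albumin source A_a is switched off in the second run.
    """
    nm = numerics or Numerics()
    if base is None:
        base = run_pathological(params, nm, albumin_on=True)
    no_alb = run_pathological(params, nm, albumin_on=False,
                              beta=base.metrics["beta"], reference=base.reference)
    return {"dp_with_albumin_mmHg": base.metrics["max_excess_p_mmHg"],
            "dp_without_albumin_mmHg": no_alb.metrics["max_excess_p_mmHg"]}


# ---------------------------------------------------------------------- #
# Mesh-invariance study
# ---------------------------------------------------------------------- #

#: probe locations (r, z/h): foveola centre, foveola edge, exudation ring,
#: deep parafovea, far field
PROBES = ((0.0, 0.5), (0.17e-3, 0.5), (1.58e-3, 0.83), (3e-3, 0.17), (6e-3, 0.5))


def mesh_convergence_study(params: ModelParameters,
                           numerics: Numerics | None = None,
                           n_meshes: int = 8, growth: float = 0.10,
                           hc_ratio: float = 60.0) -> dict:
    """Pressure/concentration at five probes across a sequence of meshes.

    Mesh k has ~(1+growth)^k times the elements of the production mesh
    (k = 0); the study passes if the production values deviate < 1% from the
    most refined mesh at every probe.
    """
    if n_meshes < 2:
        raise ParameterError("a mesh study needs at least two meshes")
    nm = numerics or Numerics()
    K = build_conductivity_field(params, hc_ratio, nm)
    sc = Scenario(name="mesh-study", af_fraction=0.0, hc_ratio=hc_ratio)
    rows = []
    for k in range(n_meshes):
        refine = (1.0 + growth) ** (k / 2.0)   # elements scale ~ refine^2
        mesh = build_mesh(params, nm, refine=refine)
        st = coupled_solve(mesh, K, params, sc, nm)
        rec = {"mesh": k, "n_elements": mesh.tris.shape[0]}
        for j, (r, zeta) in enumerate(PROBES):
            rec[f"p{j}"] = interp_structured(st, st.p, r, zeta)
            rec[f"c{j}"] = interp_structured(st, st.c, r, zeta)
        rows.append(rec)
    df = pd.DataFrame(rows)
    finest = df.iloc[-1]
    prod = df.iloc[0]
    devs = {}
    for j in range(len(PROBES)):
        devs[f"p{j}"] = abs(prod[f"p{j}"] - finest[f"p{j}"]) / max(abs(finest[f"p{j}"]), 1e-30)
        devs[f"c{j}"] = abs(prod[f"c{j}"] - finest[f"c{j}"]) / max(abs(finest[f"c{j}"]), 1e-30)
    return {"table": df, "deviations": devs,
            "max_deviation": max(devs.values()),
            "passed": max(devs.values()) < 0.01}
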