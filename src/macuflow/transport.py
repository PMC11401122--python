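"""Coupled steady Darcy-pressure / albumin transport solver.

Model summary (axisymmetric, steady state):

* Darcy flow:            u = -K grad p,   div(K grad p) + q = 0
* exudation source:      q = A_f (p_a - p) (h0/h) F_r(r) F_z(z)
* albumin transport:     div(u c) - div(D grad c) - q_a = 0,  q_a = a q
* membrane water flux (Starling, outward-positive with n the outward normal):
      RPE (z=0):  u.n = Gamma_RPE [(p - p_c) - sigma (Pi - Pi_c)] + Q_RPE
      ILM (z=h):  u.n = Gamma_ILM [(p - p_v) - sigma (Pi - Pi_v)]
* membrane solute flux (Kedem-Katchalsky):
      RPE: (u c - D grad c).n = 0      (tight junctions block albumin)
      ILM: (u c - D grad c).n = omega R T (c - c_v)
                                + (c + c_v)/2 (1 - sigma) u.n
* Pi = R T c (Van't Hoff), symmetry at r = 0, no flux at r = L.

The two fields are coupled through the osmotic boundary terms (p depends on
c) and through advection and the pressure-dependent sources (c depends on p);
a damped Picard iteration alternates the two linear solves.  Because q is
linear in p it is assembled implicitly into the pressure operator.

Sign conventions are the physical ones (flux positive out of the tissue;
active pumping pushes water toward the choroid); every boundary term is
unit-tested against the physiological retina-to-choroid direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import brentq

from . import fem
from .geometry import ConductivityField, exudation_indicator
from .mesh import Mesh2D
from .parameters import ModelParameters, Numerics, ParameterError, Scenario


# ---------------------------------------------------------------------- #
# Pointwise constitutive pieces
# ---------------------------------------------------------------------- #

def osmotic_pressure(c, params: ModelParameters):
    """Van't Hoff osmotic pressure Pi = R T c (Pa)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ParameterError("osmotic pressure requires c >= 0")
    out = params.RT * c
    return out if out.ndim else float(out)


def fluid_source(r, z, p, h, params: ModelParameters, scenario: Scenario,
                 numerics: Numerics | None = None):
    """Volumetric exudation source q (1/s) at a point."""
    nm = numerics or Numerics()
    alpha = nm.af_amplitude(params, scenario.af_fraction)
    F = exudation_indicator(r, z, h, params, nm)
    out = alpha * (params.p_a - np.asarray(p, dtype=float)) * (params.h_0 / np.asarray(h, dtype=float)) * F
    return out if np.ndim(out) else float(out)


def solute_source(r, z, p, h, params: ModelParameters, scenario: Scenario,
                  numerics: Numerics | None = None):
    """Albumin source q_a = a * q (mol/m^3/s); zero when albumin is off."""
    a = params.a if scenario.albumin_on else 0.0
    return a * fluid_source(r, z, p, h, params, scenario, numerics)


# ---------------------------------------------------------------------- #
# Solution container
# ---------------------------------------------------------------------- #

@dataclass
class SolutionState:
    """Converged fields on one mesh plus convergence metadata."""

    mesh: Mesh2D
    p: np.ndarray                 # nodal pressure (Pa)
    c: np.ndarray                 # nodal albumin concentration (mol/m^3)
    u: np.ndarray                 # elementwise Darcy velocity (M, 2) (m/s)
    h: np.ndarray                 # thickness profile on the radial grid (m)
    iterations: int = 0
    converged: bool = True
    residual_history: list = field(default_factory=list)
    fluid_balance: float = np.nan    # relative closure of the water budget
    solute_balance: float = np.nan   # relative closure of the albumin budget
    peclet: float = np.nan           # max cell Peclet number
    meta: dict = field(default_factory=dict)

    @property
    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.u, axis=1)

    def osmotic(self, params: ModelParameters) -> np.ndarray:
        return params.RT * self.c

    def column(self, i: int, fieldvec: np.ndarray) -> np.ndarray:
        """Values of a nodal field along radial station i (bottom to top)."""
        nzp = self.mesh.zeta.size
        return fieldvec[i * nzp:(i + 1) * nzp]


# ---------------------------------------------------------------------- #
# Assembly helpers
# ---------------------------------------------------------------------- #

def _quad_points(mesh: Mesh2D):
    """(r, z) of the 3 midpoint quadrature nodes per element, each (M, 3)."""
    rv = mesh.nodes[mesh.tris, 0]
    zv = mesh.nodes[mesh.tris, 1]
    return rv @ fem._MID.T, zv @ fem._MID.T


def source_weight(mesh: Mesh2D, params: ModelParameters,
                  numerics: Numerics) -> np.ndarray:
    """(h0/h) F_r F_z at the element quadrature nodes, (M, 3)."""
    rq, zq = _quad_points(mesh)
    hq = np.interp(rq, mesh.r_array, mesh.h_profile)
    F = exudation_indicator(rq, zq, hq, params, numerics)
    return (params.h_0 / hq) * F


def conductivity_elements(mesh: Mesh2D, K: ConductivityField) -> np.ndarray:
    """Conductivity at element centroids (piecewise-constant field)."""
    rc, zc = mesh.centroid[:, 0], mesh.centroid[:, 1]
    hc = np.interp(rc, mesh.r_array, mesh.h_profile)
    return K(rc, zc, hc)


def _boundary_elements(mesh: Mesh2D, tag: str) -> np.ndarray:
    """Element adjacent to each tagged boundary edge."""
    lut = {}
    t = mesh.tris
    for k in range(3):
        a, b = t[:, k], t[:, (k + 1) % 3]
        key = np.minimum(a, b).astype(np.int64) * mesh.nodes.shape[0] + np.maximum(a, b)
        for idx, kk in enumerate(key):
            lut.setdefault(kk, idx)
    e = mesh.edges[tag]
    key = np.minimum(e[:, 0], e[:, 1]).astype(np.int64) * mesh.nodes.shape[0] + np.maximum(e[:, 0], e[:, 1])
    return np.array([lut[k] for k in key], dtype=np.int64)


# ---------------------------------------------------------------------- #
# Linear sub-solves
# ---------------------------------------------------------------------- #

class PressureOperator:
    """Factorized pressure operator; the matrix is fixed on a given mesh,
    only the osmotic right-hand side changes across Picard iterations."""

    def __init__(self, mesh: Mesh2D, K_elem: np.ndarray,
                 params: ModelParameters, scenario: Scenario,
                 numerics: Numerics):
        self.mesh, self.params, self.scenario, self.numerics = mesh, params, scenario, numerics
        self.K_elem = K_elem
        self.w_q = source_weight(mesh, params, numerics)
        self.alpha = numerics.af_amplitude(params, scenario.af_fraction)
        self.q_eff = params.Q_RPE * scenario.q_rpe_multiplier

        A = fem.assemble_stiffness(mesh, K_elem)
        A = A + fem.assemble_boundary_mass(mesh, "rpe", params.Gamma_RPE)
        A = A + fem.assemble_boundary_mass(mesh, "ilm", params.Gamma_ILM)
        if self.alpha > 0:
            A = A + fem.assemble_volume_mass(mesh, self.alpha * self.w_q)
        self.lu = spla.splu(A.tocsc())
        self._A = A

    def rhs(self, c: np.ndarray) -> np.ndarray:
        p_, sc = self.params, self.scenario
        Pi = p_.RT * c
        g_rpe = (p_.Gamma_RPE * p_.p_c - self.q_eff
                 + p_.sigma * p_.Gamma_RPE * (Pi - p_.RT * p_.c_c))
        g_ilm = (p_.Gamma_ILM * p_.p_v
                 + p_.sigma * p_.Gamma_ILM * (Pi - p_.RT * p_.c_v))
        b = fem.assemble_boundary_load(self.mesh, "rpe", g_rpe)
        b += fem.assemble_boundary_load(self.mesh, "ilm", g_ilm)
        if self.alpha > 0:
            b += fem.assemble_load(self.mesh, self.alpha * self.w_q * p_.p_a)
        return b

    def solve(self, c: np.ndarray) -> np.ndarray:
        return self.lu.solve(self.rhs(c))


def compute_velocity(mesh: Mesh2D, K_elem: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Elementwise Darcy velocity u = -K grad p, (M, 2)."""
    gradp = np.einsum("eid,ei->ed", mesh.grad, p[mesh.tris])
    return -K_elem[:, None] * gradp


def solve_concentration(mesh: Mesh2D, u_elem: np.ndarray, p: np.ndarray,
                        params: ModelParameters, scenario: Scenario,
                        numerics: Numerics,
                        w_q: np.ndarray | None = None,
                        ilm_elems: np.ndarray | None = None) -> np.ndarray:
    """One linear advection-diffusion solve for given velocity and pressure."""
    nm = numerics
    if w_q is None:
        w_q = source_weight(mesh, params, nm)
    if ilm_elems is None:
        ilm_elems = _boundary_elements(mesh, "ilm")

    D_el = np.full(mesh.tris.shape[0], params.D)
    if nm.stabilization:
        h_el = np.sqrt(2.0 * mesh.area)
        D_el = D_el + 0.5 * np.linalg.norm(u_elem, axis=1) * h_el

    A = fem.assemble_stiffness(mesh, D_el) + fem.assemble_advection(mesh, u_elem)

    n_ilm = fem.edge_normals(mesh, "ilm")
    u_n = np.einsum("ed,ed->e", u_elem[ilm_elems], n_ilm)       # per ILM edge
    omRT = params.omega * params.RT
    coef = omRT + 0.5 * (1.0 - params.sigma) * u_n
    A = A + fem.assemble_boundary_mass(mesh, "ilm", coef)

    b = fem.assemble_boundary_load(
        mesh, "ilm", omRT * params.c_v - 0.5 * params.c_v * (1.0 - params.sigma) * u_n)

    a_eff = params.a if scenario.albumin_on else 0.0
    alpha = nm.af_amplitude(params, scenario.af_fraction)
    if a_eff > 0 and alpha > 0:
        p_mid = p[mesh.tris] @ fem._MID.T
        q_a = a_eff * alpha * w_q * (params.p_a - p_mid)
        b += fem.assemble_load(mesh, q_a)

    return spla.spsolve(A.tocsc(), b)


# ---------------------------------------------------------------------- #
# Budgets and diagnostics
# ---------------------------------------------------------------------- #

def fluid_budget(state: SolutionState, params: ModelParameters,
                 scenario: Scenario, numerics: Numerics) -> dict[str, float]:
    """Water budget: boundary outflux vs. volumetric source (m^3/s per rad)."""
    mesh, p, c = state.mesh, state.p, state.c
    Pi = params.RT * c
    q_eff = params.Q_RPE * scenario.q_rpe_multiplier
    f_rpe = (params.Gamma_RPE * ((p - params.p_c) - params.sigma * (Pi - params.RT * params.c_c))
             + q_eff)
    f_ilm = params.Gamma_ILM * ((p - params.p_v) - params.sigma * (Pi - params.RT * params.c_v))
    out_rpe = fem.boundary_integral(mesh, "rpe", f_rpe)
    out_ilm = fem.boundary_integral(mesh, "ilm", f_ilm)

    w_q = source_weight(mesh, params, numerics)
    alpha = numerics.af_amplitude(params, scenario.af_fraction)
    p_mid = p[mesh.tris] @ fem._MID.T
    src = fem.volume_integral_quad(mesh, alpha * w_q * (params.p_a - p_mid))

    scale = max(abs(out_rpe), abs(out_ilm), abs(src), 1e-30)
    return {"out_rpe": out_rpe, "out_ilm": out_ilm, "source": src,
            "residual": (out_rpe + out_ilm - src) / scale}


def solute_budget(state: SolutionState, params: ModelParameters,
                  scenario: Scenario, numerics: Numerics) -> dict[str, float]:
    """Albumin budget: ILM efflux vs. volumetric source (mol/s per rad)."""
    mesh, p, c = state.mesh, state.p, state.c
    ilm_elems = _boundary_elements(mesh, "ilm")
    n_ilm = fem.edge_normals(mesh, "ilm")
    u_n = np.einsum("ed,ed->e", state.u[ilm_elems], n_ilm)
    c_g = fem.boundary_gauss_values(mesh, "ilm", c)             # (E, 2)
    flux_g = (params.omega * params.RT * (c_g - params.c_v)
              + 0.5 * (c_g + params.c_v) * (1.0 - params.sigma) * u_n[:, None])
    out_ilm = fem.boundary_integral(mesh, "ilm", flux_g)

    a_eff = params.a if scenario.albumin_on else 0.0
    alpha = numerics.af_amplitude(params, scenario.af_fraction)
    w_q = source_weight(mesh, params, numerics)
    p_mid = p[mesh.tris] @ fem._MID.T
    src = fem.volume_integral_quad(mesh, a_eff * alpha * w_q * (params.p_a - p_mid))

    # capacity scale: diffusive ILM throughput at the vitreal concentration,
    # keeps the relative residual meaningful when the source is zero
    capacity = params.omega * params.RT * params.c_v * fem.boundary_integral(
        mesh, "ilm", lambda r, z: np.ones_like(r))
    scale = max(abs(out_ilm), abs(src), capacity)
    return {"out_ilm": out_ilm, "source": src,
            "residual": (out_ilm - src) / scale}


def cell_peclet(mesh: Mesh2D, u_elem: np.ndarray, D: float) -> float:
    h_el = np.sqrt(2.0 * mesh.area)
    return float(np.max(np.linalg.norm(u_elem, axis=1) * h_el / D))


# ---------------------------------------------------------------------- #
# Coupled fixed point
# ---------------------------------------------------------------------- #

def coupled_solve(mesh: Mesh2D, K: ConductivityField | np.ndarray,
                  params: ModelParameters, scenario: Scenario,
                  numerics: Numerics | None = None,
                  c0: np.ndarray | None = None,
                  tol: float | None = None,
                  max_iter: int | None = None) -> SolutionState:
    """Damped Picard iteration between the pressure and concentration solves.

    Converges when the relative L2 change of both fields falls below ``tol``.
    Raises ``RuntimeError`` with the residual history on non-convergence.
    """
    nm = numerics or Numerics()
    tol = nm.picard_tol if tol is None else tol
    max_iter = nm.picard_max if max_iter is None else max_iter
    if tol <= 0:
        raise ParameterError("picard tolerance must be > 0")

    K_elem = conductivity_elements(mesh, K) if isinstance(K, ConductivityField) else np.asarray(K)
    op = PressureOperator(mesh, K_elem, params, scenario, nm)
    ilm_elems = _boundary_elements(mesh, "ilm")

    n = mesh.nodes.shape[0]
    c = np.full(n, params.c_v) if c0 is None else c0.copy()
    p = np.zeros(n)
    history = []
    converged = False
    relax = nm.relax
    stall = 0
    it = 0
    for it in range(1, max_iter + 1):
        p_new = op.solve(c)
        u = compute_velocity(mesh, K_elem, p_new)
        c_new = solve_concentration(mesh, u, p_new, params, scenario, nm,
                                    w_q=op.w_q, ilm_elems=ilm_elems)
        dp = np.linalg.norm(p_new - p) / max(np.linalg.norm(p_new), 1.0)
        dc = np.linalg.norm(c_new - c) / max(np.linalg.norm(c_new), 1e-12)
        history.append(max(dp, dc))
        p = p_new
        c = c + relax * (c_new - c)
        if history[-1] < tol:
            c = c_new
            converged = True
            break
        # safeguard: if the damped fixed point is not contracting, damp harder
        if it > 4 and history[-1] > 0.98 * history[-2]:
            stall += 1
            if stall >= 3 and relax > 0.05:
                relax *= 0.5
                stall = 0
        else:
            stall = 0
    if not converged:
        raise RuntimeError(
            f"Picard iteration did not converge in {max_iter} iterations; "
            f"residual history tail: {history[-5:]}")

    if c.min() < -0.01 * params.c_v:
        raise RuntimeError(
            f"concentration undershoot {c.min():.3e} mol/m^3 beyond tolerance; "
            "refine the mesh or enable streamline-diffusion stabilization")
    u = compute_velocity(mesh, K_elem, p)
    state = SolutionState(mesh=mesh, p=p, c=c, u=u, h=mesh.h_profile.copy(),
                          iterations=it, converged=True,
                          residual_history=history)
    state.peclet = cell_peclet(mesh, u, params.D)
    state.fluid_balance = fluid_budget(state, params, scenario, nm)["residual"]
    state.solute_balance = solute_budget(state, params, scenario, nm)["residual"]
    state.meta["K_elem"] = K_elem
    return state


# ---------------------------------------------------------------------- #
# Independent one-dimensional far-field oracle
# ---------------------------------------------------------------------- #

def far_field_column(params: ModelParameters, K_of_z: Callable[[np.ndarray], np.ndarray],
                     h: float | None = None, q_rpe_multiplier: float = 1.0,
                     n_quad: int = 20001):
    """Semi-analytic 1D column solution far from the macula (no exudation).

    Vertical Darcy flow with a constant velocity v (positive upward), the
    exact exponential albumin profile c(z) = c_v exp(v (z - h)/D) implied by
    zero RPE solute flux, and the two Starling membrane conditions reduce to
    one scalar nonlinear equation for v, solved by bracketing.

    Returns ``(v, p_of_z, c_of_z)`` with the two profiles as callables.
    This path shares no code with the finite-element solver and serves as an
    independent oracle for it.
    """
    pr = params
    hh = pr.h_0 if h is None else float(h)
    z = np.linspace(0.0, hh, n_quad)
    invK = 1.0 / np.asarray(K_of_z(z), dtype=float)
    # cumulative hydraulic resistance from z to h
    cum = np.concatenate([[0.0], np.cumsum((invK[1:] + invK[:-1]) * 0.5 * np.diff(z))])
    R_total = cum[-1]
    R_from_top = R_total - cum
    q_eff = pr.Q_RPE * q_rpe_multiplier

    def residual(v: float) -> float:
        c0 = pr.c_v * np.exp(-v * hh / pr.D)
        p_top = pr.p_v + v / pr.Gamma_ILM  # Pi(h) = Pi_v exactly
        p_bot = p_top + v * R_total        # p' = -v/K inside the tissue
        out_rpe = (pr.Gamma_RPE * ((p_bot - pr.p_c)
                                   - pr.sigma * pr.RT * (c0 - pr.c_c)) + q_eff)
        return (-v) - out_rpe

    v = brentq(residual, -1e-4, 1e-4, xtol=1e-22, rtol=1e-15)

    def p_of_z(zq):
        p_top = pr.p_v + v / pr.Gamma_ILM
        return p_top + v * np.interp(zq, z, R_from_top)

    def c_of_z(zq):
        return pr.c_v * np.exp(v * (np.asarray(zq, dtype=float) - hh) / pr.D)

    return v, p_of_z, c_of_z
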