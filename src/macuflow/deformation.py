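"""Fluid-structure coupling: excess pressure -> thickness profile.

The retinal parenchyma is modelled as a bed of independent axial springs
(a Winkler foundation) whose areal stiffness is proportional to the local
Müller-cell density: k(r) = beta * n(r) * kappa_c, with kappa_c = E pi d_c^2/4
the axial stiffness of a single cell and beta a dimensionless calibration
factor.  The excess of the depth-averaged tissue pressure over the
physiological reference state loads the springs; the local engineering
strain epsilon = dp/k thickens the column, h(r) = h_0 (1 + epsilon).

beta is calibrated once, at the baseline exudation amplitude, so that the
maximum thickening ratio is ~2 (doubling of the foveal thickness), matching
the clinical picture the model is built around.  The closure is isolated
behind ``thickness_update`` so an alternative (e.g. a nonlinear spring) can
replace it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .geometry import ConductivityField, muller_density
from .mesh import build_mesh
from .parameters import ModelParameters, Numerics, ParameterError, Scenario
from .transport import SolutionState, coupled_solve


def muller_stiffness(E: float, d_c: float) -> float:
    """Axial force per unit strain of one cylindrical Müller cell: E pi d_c^2/4."""
    if E <= 0 or d_c <= 0:
        raise ParameterError("E and d_c must be > 0")
    return E * np.pi * d_c**2 / 4.0


@dataclass
class StiffnessProfile:
    """Winkler foundation modulus k(r) = beta * n(r) * kappa_c (Pa per unit strain)."""

    params: ModelParameters
    beta: float
    w_r: float = 50e-6

    def density(self, r):
        return muller_density(r, self.params, self.w_r)

    def __call__(self, r):
        return self.beta * self.density(r) * self.params.kappa_c


def excess_pressure_profile(state: SolutionState, reference: SolutionState,
                            numerics: Numerics | None = None) -> np.ndarray:
    """Depth-averaged excess pressure dp(r) >= 0 against the reference state.

    Both states must live on the same structured (r, zeta) grid; columns are
    compared at matching fractional depth, so the deformed state maps onto
    the rigid reference column by column.
    """
    nm = numerics or Numerics()
    if (state.mesh.r_array.size != reference.mesh.r_array.size
            or not np.allclose(state.mesh.r_array, reference.mesh.r_array)
            or state.mesh.zeta.size != reference.mesh.zeta.size):
        raise ParameterError("states live on incompatible radial grids")
    nzp = state.mesh.zeta.size
    P = state.p.reshape(-1, nzp)
    P0 = reference.p.reshape(-1, nzp)
    if nm.depth_average == "mid":
        dp = (P - P0)[:, nzp // 2]
    else:
        dp = np.trapezoid(P - P0, state.mesh.zeta, axis=1)
    return np.clip(dp, 0.0, None)


def _smooth_radial(r: np.ndarray, f: np.ndarray, width: float) -> np.ndarray:
    """C1 smoothing of a radial profile by a compact half-cosine kernel."""
    if width <= 0:
        return f
    ru = np.arange(r[0], r[-1] + width / 8.0, width / 8.0)
    fu = np.interp(ru, r, f)
    m = int(round(8))
    t = np.arange(-m, m + 1) / m
    ker = np.cos(0.5 * np.pi * t) ** 2
    ker /= ker.sum()
    fpad = np.pad(fu, m, mode="edge")
    fs = np.convolve(fpad, ker, mode="valid")
    return np.interp(r, ru, fs)


def thickness_update(dp_r: np.ndarray, stiffness: StiffnessProfile,
                     r: np.ndarray, h_prev: np.ndarray,
                     relax: float = 0.5,
                     numerics: Numerics | None = None) -> np.ndarray:
    """New thickness profile from the spring law, blended and smoothed.

    epsilon(r) = dp(r)/k(r); the target h_0 (1 + epsilon) is blended with the
    previous profile by ``relax`` and radially smoothed so h is C1.
    """
    nm = numerics or Numerics()
    if np.any(dp_r < 0):
        raise ParameterError("excess pressure must be clipped at zero")
    if not 0.0 < relax <= 1.0:
        raise ParameterError("relaxation factor must lie in (0, 1]")
    h_0 = stiffness.params.h_0
    eps = dp_r / stiffness(r)
    if np.max(eps) > nm.strain_cap:
        raise RuntimeError(
            f"strain {np.max(eps):.2f} exceeds the cap {nm.strain_cap}; "
            "re-calibrate beta or reduce the exudation amplitude")
    h_target = h_0 * (1.0 + eps)
    h_new = h_prev + relax * (h_target - h_prev)
    h_new = _smooth_radial(r, h_new, nm.h_smooth_width)
    return np.maximum(h_new, 0.2 * h_0)


@dataclass
class FsiResult:
    state: SolutionState
    reference: SolutionState
    beta: float
    h: np.ndarray
    outer_iterations: int
    h_history: list

    @property
    def thickening(self) -> np.ndarray:
        return self.h / self.reference.mesh.h_profile


def reference_state(params: ModelParameters, K: ConductivityField,
                    numerics: Numerics | None = None) -> SolutionState:
    """Converged physiological solution on the rigid domain (A_f = 0)."""
    nm = numerics or Numerics()
    mesh = build_mesh(params, nm)
    sc = Scenario(name="physiological", af_fraction=0.0)
    return coupled_solve(mesh, K, params, sc, nm)


def calibrate_beta(params: ModelParameters, K: ConductivityField,
                   scenario: Scenario, numerics: Numerics | None = None,
                   reference: SolutionState | None = None,
                   target_ratio: float = 2.0) -> float:
    """Choose beta so the rigid-domain excess pressure would thicken the most
    compliant column to ``target_ratio`` * h_0 (strain target_ratio - 1).

    The subsequent fluid-structure loop changes the pressure field only
    weakly (the source amplitude is deformation-invariant by construction),
    so the converged maximum thickening stays close to the target.
    """
    nm = numerics or Numerics()
    ref = reference if reference is not None else reference_state(params, K, nm)
    st = coupled_solve(ref.mesh, K, params, scenario, nm)
    dp = excess_pressure_profile(st, ref, nm)
    base = StiffnessProfile(params, beta=1.0, w_r=nm.w_r)
    eps_unit = dp / base(ref.mesh.r_array)     # strain at beta = 1
    return float(np.max(eps_unit) / (target_ratio - 1.0))


def fsi_solve(params: ModelParameters, K: ConductivityField,
              scenario: Scenario, numerics: Numerics | None = None,
              beta: float | None = None,
              reference: SolutionState | None = None,
              tol: float | None = None, max_outer: int | None = None) -> FsiResult:
    """Outer fixed point: transport solve -> excess pressure -> new h(r).

    The mesh is rebuilt (z mapped to the new thickness) every outer
    iteration; the exudation source carries the h_0/h factor, so the leakage
    rate is independent of the deformation.  Converges when the maximum
    relative change of h falls below ``tol``.
    """
    nm = numerics or Numerics()
    tol = nm.outer_tol if tol is None else tol
    max_outer = nm.outer_max if max_outer is None else max_outer
    ref = reference if reference is not None else reference_state(params, K, nm)
    if beta is None:
        beta = scenario.beta
    if beta is None:
        beta = calibrate_beta(params, K, scenario, nm, reference=ref)
    stiff = StiffnessProfile(params, beta=beta, w_r=nm.w_r)

    r = ref.mesh.r_array
    h = np.full(r.size, params.h_0)
    h_history = [h.copy()]
    state = None
    c_prev = None
    for outer in range(1, max_outer + 1):
        mesh = build_mesh(params, nm, h=h)
        state = coupled_solve(mesh, K, params, scenario, nm, c0=c_prev)
        c_prev = state.c
        if scenario.af_fraction == 0.0:
            return FsiResult(state, ref, beta, h, outer, h_history)
        dp = excess_pressure_profile(state, ref, nm)
        h_new = thickness_update(dp, stiff, r, h, relax=nm.outer_relax, numerics=nm)
        change = np.max(np.abs(h_new - h)) / params.h_0
        h = h_new
        h_history.append(h.copy())
        if change < tol:
            return FsiResult(state, ref, beta, h, outer, h_history)
    raise RuntimeError(
        f"fluid-structure loop did not converge in {max_outer} iterations; "
        f"last max relative h-changes: "
        f"{[float(np.max(np.abs(h_history[i+1]-h_history[i]))/params.h_0) for i in range(max(0,len(h_history)-4), len(h_history)-1)]}")
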