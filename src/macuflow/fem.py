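"""P1 finite-element assembly for the axisymmetric weak forms.

All volume integrals carry the cylindrical measure r dr dz (the constant 2*pi
factor is dropped consistently from both sides of every equation and from all
reported balances).  Volume quadrature is the degree-2 edge-midpoint rule,
which integrates the products of two hat functions with the linear weight r
to the accuracy needed here and makes discrete conservation statements exact
by construction.  Boundary integrals use 2-point Gauss on each tagged edge.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import scipy.sparse as sp

from .mesh import Mesh2D

# barycentric coordinates of the three edge midpoints
_MID = np.array([[0.5, 0.5, 0.0],
                 [0.0, 0.5, 0.5],
                 [0.5, 0.0, 0.5]])

# 2-point Gauss on [0, 1]
_GP = np.array([0.5 - 0.5 / np.sqrt(3.0), 0.5 + 0.5 / np.sqrt(3.0)])
_GW = np.array([0.5, 0.5])


def _elem_r_mid(mesh: Mesh2D) -> np.ndarray:
    """Radius at the three midpoint quadrature nodes of every element, (M, 3)."""
    rv = mesh.nodes[mesh.tris, 0]           # (M, 3) vertex radii
    return rv @ _MID.T


def assemble_stiffness(mesh: Mesh2D, K_elem: np.ndarray) -> sp.csr_matrix:
    """∫ K grad(u).grad(v) r dA with piecewise-constant K."""
    g = mesh.grad                            # (M, 3, 2)
    rbar = mesh.centroid[:, 0]
    coef = K_elem * mesh.area * rbar         # exact: grads constant, ∫r dA = A r̄
    ke = np.einsum("e,eid,ejd->eij", coef, g, g)
    return _scatter(mesh, ke)


def _coef_at_mid(mesh: Mesh2D, coef) -> np.ndarray:
    """Coefficient at the midpoint quadrature nodes: accepts a scalar, an
    elementwise array (M,) or per-quadrature values (M, 3)."""
    c = np.asarray(coef, dtype=float)
    if c.ndim == 2:
        return c
    if c.ndim == 1:
        return c[:, None] * np.ones((1, 3))
    return float(c) * np.ones((mesh.tris.shape[0], 3))


def assemble_volume_mass(mesh: Mesh2D, coef) -> sp.csr_matrix:
    """∫ c u v r dA; coefficient per element or per quadrature point."""
    rq = _elem_r_mid(mesh)                   # (M, 3)
    cq = _coef_at_mid(mesh, coef)
    w = (mesh.area / 3.0)[:, None] * rq * cq          # (M, 3) quadrature weights
    ke = np.einsum("eq,qi,qj->eij", w, _MID, _MID)
    return _scatter(mesh, ke)


def assemble_advection(mesh: Mesh2D, u_elem: np.ndarray) -> sp.csr_matrix:
    """A_ij = -∫ (u . grad phi_i) phi_j r dA  (conservative advection, test i)."""
    udotg = np.einsum("ed,eid->ei", u_elem, mesh.grad)     # (M, 3)
    rq = _elem_r_mid(mesh)
    w = (mesh.area / 3.0)[:, None] * rq
    phi_int = np.einsum("eq,qj->ej", w, _MID)              # ∫ phi_j r dA
    ke = -np.einsum("ei,ej->eij", udotg, phi_int)
    return _scatter(mesh, ke)


def assemble_load(mesh: Mesh2D, f) -> np.ndarray:
    """∫ f phi_i r dA; f per element or per quadrature point."""
    rq = _elem_r_mid(mesh)
    fq = _coef_at_mid(mesh, f)
    w = (mesh.area / 3.0)[:, None] * rq * fq
    fe = np.einsum("eq,qi->ei", w, _MID)
    out = np.zeros(mesh.nodes.shape[0])
    np.add.at(out, mesh.tris, fe)
    return out


def assemble_load_nodal(mesh: Mesh2D, f_nodes: np.ndarray) -> np.ndarray:
    """∫ f phi_i r dA with P1-interpolated nodal f."""
    fq = f_nodes[mesh.tris] @ _MID.T         # (M, 3) values at midpoints
    rq = _elem_r_mid(mesh)
    w = (mesh.area / 3.0)[:, None] * rq * fq
    fe = np.einsum("eq,qi->ei", w, _MID)
    out = np.zeros(mesh.nodes.shape[0])
    np.add.at(out, mesh.tris, fe)
    return out


def _scatter(mesh: Mesh2D, ke: np.ndarray) -> sp.csr_matrix:
    t = mesh.tris
    rows = np.repeat(t, 3, axis=1).ravel()
    cols = np.tile(t, (1, 3)).ravel()
    n = mesh.nodes.shape[0]
    return sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()


# ---------------------------------------------------------------------- #
# Boundary (edge) integrals
# ---------------------------------------------------------------------- #

def _edge_quadrature(mesh: Mesh2D, tag: str):
    e = mesh.edges[tag]
    p0, p1 = mesh.nodes[e[:, 0]], mesh.nodes[e[:, 1]]
    L = np.linalg.norm(p1 - p0, axis=1)                    # (E,)
    pts = p0[:, None, :] + _GP[None, :, None] * (p1 - p0)[:, None, :]  # (E, 2, 2)
    wq = L[:, None] * _GW[None, :] * pts[:, :, 0]          # ds * r weight (E, 2)
    phi = np.stack([1.0 - _GP, _GP], axis=1)               # (2 gauss, 2 nodes)
    return e, pts, wq, phi


def edge_normals(mesh: Mesh2D, tag: str) -> np.ndarray:
    """Outward unit normals of the tagged boundary edges, (E, 2)."""
    e = mesh.edges[tag]
    t = mesh.nodes[e[:, 1]] - mesh.nodes[e[:, 0]]
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    if tag in ("ilm", "axis"):      # domain lies to the right of the tangent
        return np.column_stack([-t[:, 1], t[:, 0]])
    return np.column_stack([t[:, 1], -t[:, 0]])           # rpe, far


def assemble_boundary_mass(mesh: Mesh2D, tag: str, coef) -> sp.csr_matrix:
    """∮ c u v r ds on the tagged boundary.

    ``coef``: scalar, callable c(r, z), per-edge (E,) or per-Gauss (E, 2).
    """
    e, pts, wq, phi = _edge_quadrature(mesh, tag)
    if callable(coef):
        c = coef(pts[:, :, 0], pts[:, :, 1])
    else:
        c = np.asarray(coef, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
    w = wq * c                                            # (E, 2)
    ke = np.einsum("eq,qi,qj->eij", w, phi, phi)
    rows = np.repeat(e, 2, axis=1).ravel()
    cols = np.tile(e, (1, 2)).ravel()
    n = mesh.nodes.shape[0]
    return sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def assemble_boundary_load(mesh: Mesh2D, tag: str, g) -> np.ndarray:
    """∮ g phi_i r ds; ``g`` scalar, callable g(r, z), or nodal array."""
    e, pts, wq, phi = _edge_quadrature(mesh, tag)
    if callable(g):
        gq = g(pts[:, :, 0], pts[:, :, 1])
    elif np.ndim(g) == 2:
        gq = np.asarray(g, dtype=float)                    # per-Gauss (E, 2)
    elif np.ndim(g) == 1 and np.size(g) == mesh.nodes.shape[0]:
        gq = g[e] @ phi.T                                  # P1 interpolation
    elif np.ndim(g) == 1:
        gq = np.asarray(g, dtype=float)[:, None]           # per-edge (E,)
    else:
        gq = g
    fe = np.einsum("eq,qi->ei", wq * gq, phi)
    out = np.zeros(mesh.nodes.shape[0])
    np.add.at(out, e, fe)
    return out


def boundary_integral(mesh: Mesh2D, tag: str, values) -> float:
    """∮ f r ds over the tagged boundary.

    ``values``: callable f(r, z), nodal array (N,), or per-Gauss array (E, 2).
    """
    e, pts, wq, phi = _edge_quadrature(mesh, tag)
    if callable(values):
        fq = values(pts[:, :, 0], pts[:, :, 1])
    elif np.ndim(values) == 2:
        fq = np.asarray(values, dtype=float)
    else:
        fq = values[e] @ phi.T
    return float(np.sum(wq * fq))


def boundary_gauss_values(mesh: Mesh2D, tag: str, nodal: np.ndarray) -> np.ndarray:
    """Nodal field interpolated at the 2-point Gauss nodes of tagged edges, (E, 2)."""
    e, pts, wq, phi = _edge_quadrature(mesh, tag)
    return nodal[e] @ phi.T


def volume_integral_quad(mesh: Mesh2D, fq: np.ndarray) -> float:
    """∫ f r dA of values given at the midpoint quadrature nodes, (M, 3)."""
    rq = _elem_r_mid(mesh)
    return float(np.sum(mesh.area[:, None] / 3.0 * rq * fq))


def volume_integral(mesh: Mesh2D, values) -> float:
    """∫ f r dA of an elementwise (M,) or nodal (N,) field."""
    vals = np.asarray(values)
    rq = _elem_r_mid(mesh)
    if vals.size == mesh.tris.shape[0]:
        return float(np.sum(vals * mesh.area / 3.0 * rq.sum(axis=1)))
    fq = vals[mesh.tris] @ _MID.T
    return float(np.sum(mesh.area[:, None] / 3.0 * rq * fq))


def l2_error(mesh: Mesh2D, vec: np.ndarray, exact: Callable) -> float:
    """r-weighted L2 error of a nodal field against a callable exact(r, z)."""
    rq = _elem_r_mid(mesh)
    zq = mesh.nodes[mesh.tris, 1] @ _MID.T
    uq = vec[mesh.tris] @ _MID.T
    diff2 = (uq - exact(rq, zq)) ** 2
    return float(np.sqrt(np.sum(mesh.area[:, None] / 3.0 * rq * diff2)))
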