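"""Structured axisymmetric triangulation of {0 <= r <= L, 0 <= z <= h(r)}.

The mesh is a tensor grid in (r, zeta) with zeta = z/h(r) in [0, 1], split
into triangles; vertical node columns follow the (possibly deformed)
thickness profile, so remeshing after a deformation update is just a
re-mapping of the z coordinates.  Boundary edges are tagged
``rpe`` (z = 0), ``ilm`` (z = h(r)), ``axis`` (r = 0) and ``far`` (r = L).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .parameters import ModelParameters, Numerics


def radial_grid(params: ModelParameters, numerics: Numerics,
                refine: float = 1.0) -> np.ndarray:
    """Radial node positions: anchored at the region/ring radii, uniformly
    fine in the macula and geometrically coarsening toward the far field.

    ``refine`` > 1 refines all spacings by that factor (mesh studies).
    """
    p, nm = params, numerics
    anchors = [0.0, p.L_f, p.L_1, p.L_e1, p.L_e2, nm.r_fine]
    spacing = [nm.dr_inner, nm.dr_inner, nm.dr_ring, nm.dr_ring, nm.dr_ring]
    pieces = []
    for (a, b), dr in zip(zip(anchors[:-1], anchors[1:]), spacing):
        n = max(2, int(np.ceil((b - a) / (dr / refine))) + 1)
        pieces.append(np.linspace(a, b, n)[:-1])
    # geometric growth from r_fine to L
    r = nm.r_fine
    dr = nm.dr_ring / refine
    tail = [r]
    while r < p.L:
        dr = min(dr * nm.growth, nm.dr_max / refine)
        r = min(r + dr, p.L)
        tail.append(r)
    if p.L - tail[-2] < 0.3 * (tail[-1] - tail[-2]):  # avoid a sliver at L
        tail.pop(-2)
    return np.concatenate(pieces + [np.asarray(tail)])


@dataclass
class Mesh2D:
    """Conforming P1 triangulation with structured (r, zeta) metadata."""

    nodes: np.ndarray                 # (N, 2) columns r, z
    tris: np.ndarray                  # (M, 3) int
    edges: dict[str, np.ndarray]      # tag -> (n_edges, 2) node pairs
    r_array: np.ndarray               # radial stations (nr,)
    zeta: np.ndarray                  # vertical fractions (nz+1,)
    h_profile: np.ndarray             # thickness at each radial station (nr,)

    # geometric caches, filled by ``prepare``
    area: np.ndarray = field(default=None, repr=False)
    grad: np.ndarray = field(default=None, repr=False)     # (M, 3, 2)
    centroid: np.ndarray = field(default=None, repr=False)  # (M, 2)

    @property
    def nr(self) -> int:
        return self.r_array.size

    @property
    def nz(self) -> int:
        return self.zeta.size - 1

    def node_index(self, i: int, j: int) -> int:
        """Structured index: radial station i, vertical level j."""
        return i * self.zeta.size + j

    def prepare(self) -> "Mesh2D":
        xy = self.nodes
        t = self.tris
        v0, v1, v2 = xy[t[:, 0]], xy[t[:, 1]], xy[t[:, 2]]
        d1, d2 = v1 - v0, v2 - v0
        det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
        if np.any(det <= 0):
            raise ValueError("mesh contains inverted or degenerate triangles")
        self.area = 0.5 * det
        # gradients of the three hat functions on each triangle
        g = np.empty((t.shape[0], 3, 2))
        g[:, 0, 0] = (v1[:, 1] - v2[:, 1]) / det
        g[:, 0, 1] = (v2[:, 0] - v1[:, 0]) / det
        g[:, 1, 0] = (v2[:, 1] - v0[:, 1]) / det
        g[:, 1, 1] = (v0[:, 0] - v2[:, 0]) / det
        g[:, 2, 0] = (v0[:, 1] - v1[:, 1]) / det
        g[:, 2, 1] = (v1[:, 0] - v0[:, 0]) / det
        self.grad = g
        self.centroid = (v0 + v1 + v2) / 3.0
        return self

    def quality(self) -> dict[str, float]:
        e0 = np.linalg.norm(self.nodes[self.tris[:, 1]] - self.nodes[self.tris[:, 0]], axis=1)
        e1 = np.linalg.norm(self.nodes[self.tris[:, 2]] - self.nodes[self.tris[:, 1]], axis=1)
        e2 = np.linalg.norm(self.nodes[self.tris[:, 0]] - self.nodes[self.tris[:, 2]], axis=1)
        hmax = np.maximum(np.maximum(e0, e1), e2)
        return {
            "n_nodes": self.nodes.shape[0],
            "n_tris": self.tris.shape[0],
            "min_area": float(self.area.min()),
            "max_aspect": float((hmax**2 / (2.0 * self.area)).max()),
        }


def build_mesh(params: ModelParameters, numerics: Numerics,
               h: Callable[[np.ndarray], np.ndarray] | np.ndarray | float | None = None,
               refine: float = 1.0, nz: int | None = None) -> Mesh2D:
    """Build the structured triangulation for a given thickness profile.

    ``h`` may be None (undeformed, h_0), a scalar, an array on the radial
    grid, or a callable h(r).
    """
    r = radial_grid(params, numerics, refine)
    nzz = nz if nz is not None else max(3, int(round(numerics.nz * refine)))
    zeta = np.linspace(0.0, 1.0, nzz + 1)

    return _assemble(r, zeta, _thickness_on_grid(r, h, params.h_0))


def build_ring_mesh(params: ModelParameters, r0: float, r1: float,
                    nr: int, nz: int, h=None) -> Mesh2D:
    """Annular column mesh {r0 <= r <= r1}; used for effectively
    one-dimensional configurations (far-field verification)."""
    r = np.linspace(r0, r1, nr + 1)
    zeta = np.linspace(0.0, 1.0, nz + 1)
    return _assemble(r, zeta, _thickness_on_grid(r, h, params.h_0))


def _thickness_on_grid(r: np.ndarray, h, h_0: float) -> np.ndarray:
    if h is None:
        return np.full(r.size, h_0)
    if callable(h):
        return np.asarray(h(r), dtype=float)
    if np.ndim(h) == 0:
        return np.full(r.size, float(h))
    h_r = np.asarray(h, dtype=float)
    if h_r.size != r.size:
        raise ValueError("thickness array does not match the radial grid")
    return h_r


def _assemble(r: np.ndarray, zeta: np.ndarray, h_r: np.ndarray) -> Mesh2D:
    R = np.repeat(r, zeta.size)
    Z = (h_r[:, None] * zeta[None, :]).ravel()
    nodes = np.column_stack([R, Z])

    nr, nzp = r.size, zeta.size
    tris = []
    for i in range(nr - 1):
        for j in range(nzp - 1):
            a = i * nzp + j
            b = (i + 1) * nzp + j
            if (i + j) % 2 == 0:  # union-jack split avoids directional bias
                tris.append((a, b, b + 1))
                tris.append((a, b + 1, a + 1))
            else:
                tris.append((a, b, a + 1))
                tris.append((b, b + 1, a + 1))
    tris = np.asarray(tris, dtype=np.int64)

    bottom = np.array([[i * nzp, (i + 1) * nzp] for i in range(nr - 1)])
    top = np.array([[i * nzp + nzp - 1, (i + 1) * nzp + nzp - 1] for i in range(nr - 1)])
    axis = np.array([[j, j + 1] for j in range(nzp - 1)])
    far = np.array([[(nr - 1) * nzp + j, (nr - 1) * nzp + j + 1] for j in range(nzp - 1)])
    edges = {"rpe": bottom, "ilm": top, "axis": axis, "far": far}

    return Mesh2D(nodes=nodes, tris=tris, edges=edges,
                  r_array=r, zeta=zeta, h_profile=h_r).prepare()
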