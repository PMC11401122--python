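"""Domain partition, smoothed indicator functions and the conductivity map.

The macular domain is the axisymmetric slab {0 <= r <= L, 0 <= z <= h(r)}
with the RPE at z = 0 and the ILM at z = h.  Radially it splits into
foveola (r < L_f), fovea (L_f < r < L_1) and parafovea; vertically the
parafovea splits into three equal layers whose middle one — where Müller
cells are inclined and tightly packed — is far less conductive.

All step functions are smoothed with a compact-support half-cosine ramp so
that region values are attained exactly away from the (narrow) transition
zones.  Vertical blending of the conductivity is done in resistivity (1/K),
which makes the through-thickness series composite of the parafoveal column
equal the prescribed overall retinal conductivity exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ModelParameters, Numerics, ParameterError


# ---------------------------------------------------------------------- #
# Smoothed steps
# ---------------------------------------------------------------------- #

def smoothed_step(x, x0: float, w: float):
    """C1 monotone ramp: 0 for x <= x0-w, 1 for x >= x0+w, 1/2 at x0.

    ``w`` is the half-width of the transition.  Vectorized in ``x``.
    """
    if np.any(np.asarray(w) <= 0):
        raise ParameterError("smoothing width w must be > 0")
    t = np.clip((np.asarray(x, dtype=float) - x0) / w, -1.0, 1.0)
    out = 0.5 * (1.0 + np.sin(0.5 * np.pi * t))
    return out if out.ndim else float(out)


def smoothed_box(x, x_lo: float, x_hi: float, w: float):
    """Smoothed double step: ~1 inside [x_lo, x_hi], ~0 outside."""
    return smoothed_step(x, x_lo, w) * (1.0 - smoothed_step(x, x_hi, w))


# ---------------------------------------------------------------------- #
# Region partition
# ---------------------------------------------------------------------- #

@dataclass(frozen=True)
class RegionPartition:
    """Radial regions {foveola, fovea, parafovea} and axial layers {1,2,3}.

    Layer 1 is the outer (RPE-side) layer, layer 3 the inner (ILM-side) one.
    Layer interfaces sit at fixed fractions of the local thickness so that
    they follow the deformed profile h(r).
    """

    L_f: float
    L_1: float
    L: float
    f_1: float  # d_1 / h_0
    f_2: float  # (d_1 + d_2) / h_0
    w_r: float
    w_z_frac: float

    @classmethod
    def from_params(cls, params: ModelParameters, numerics: Numerics | None = None) -> "RegionPartition":
        nm = numerics or Numerics()
        return cls(
            L_f=params.L_f, L_1=params.L_1, L=params.L,
            f_1=params.d_1 / params.h_0,
            f_2=(params.d_1 + params.d_2) / params.h_0,
            w_r=nm.w_r, w_z_frac=nm.w_z_frac,
        )

    def radial_labels(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        lab = np.full(r.shape, "parafovea", dtype=object)
        lab[r < self.L_1] = "fovea"
        lab[r < self.L_f] = "foveola"
        return lab

    def layer_labels(self, z, h) -> np.ndarray:
        zeta = np.asarray(z, dtype=float) / np.asarray(h, dtype=float)
        lab = np.full(np.shape(zeta), 3, dtype=int)
        lab[zeta < self.f_2] = 2
        lab[zeta < self.f_1] = 1
        return lab


# ---------------------------------------------------------------------- #
# Exudation indicator
# ---------------------------------------------------------------------- #

def exudation_indicator(r, z, h, params: ModelParameters,
                        numerics: Numerics | None = None):
    """Smoothed indicator F_r(r) * F_z(z) of the exudation region.

    F_r is one on the ring L_e1 <= r <= L_e2, F_z is one on the innermost
    (ILM-side) layer z >= (d_1 + d_2) h / h_0; both ramp smoothly to zero.
    The layer bound scales with the local thickness h, as does the axial
    smoothing width.
    """
    nm = numerics or Numerics()
    r = np.asarray(r, dtype=float)
    z = np.asarray(z, dtype=float)
    h = np.asarray(h, dtype=float)
    f2 = (params.d_1 + params.d_2) / params.h_0
    w_z = nm.w_z_frac * h
    Fr = smoothed_box(r, params.L_e1, params.L_e2, nm.w_r)
    Fz = smoothed_step(z, f2 * h, w_z)
    out = Fr * Fz
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------- #
# Layer conductivities and the conductivity field
# ---------------------------------------------------------------------- #

def layer_conductivities(gamma_ret: float, ratio: float,
                         h_0: float = 320e-6) -> tuple[float, float, float]:
    """Layer conductivities (K1, K2, K3) from the overall retinal HC.

    The three layers have equal thickness h_0/3, K1 = K3 = ratio * K2, and
    their series (harmonic) composite equals ``gamma_ret``:
    [(d/K1) + (d/K2) + (d/K3)]^-1 = gamma_ret with d = h_0/3.
    """
    if gamma_ret <= 0:
        raise ParameterError("overall retinal conductivity must be > 0")
    if ratio < 1:
        raise ParameterError("hc_ratio must be >= 1 (middle layer is the less permeable)")
    d = h_0 / 3.0
    # d*(1/K1 + ratio/K1 + 1/K1) = 1/gamma_ret
    K1 = gamma_ret * d * (2.0 + ratio)
    K2 = K1 / ratio
    return K1, K2, K1


@dataclass
class ConductivityField:
    """Piecewise-smooth scalar hydraulic conductivity K(r, z) (m^2/s/Pa).

    Foveola column: uniform C_f.  Fovea column: uniform straight-cell value
    K1 (overridable).  Parafoveal column: layered K1/K2/K1 blended in
    resistivity across layer interfaces that follow the local thickness.
    Radial transitions are blended in log K over the half-width ``w_r``.
    """

    params: ModelParameters
    ratio: float
    K1: float
    K2: float
    K_fovea: float
    w_r: float
    w_z_frac: float

    def __call__(self, r, z, h=None):
        p = self.params
        r = np.asarray(r, dtype=float)
        z = np.asarray(z, dtype=float)
        hh = np.full_like(r, p.h_0) if h is None else np.broadcast_to(
            np.asarray(h, dtype=float), r.shape).copy()

        w_z = self.w_z_frac * hh
        f1 = p.d_1 / p.h_0
        f2 = (p.d_1 + p.d_2) / p.h_0
        # vertical profile in the parafovea: blend resistivity 1/K
        s_lo = smoothed_step(z, f1 * hh, w_z)      # 0 in layer 1, 1 above
        s_hi = smoothed_step(z, f2 * hh, w_z)      # 0 below layer 3, 1 in it
        mid = s_lo * (1.0 - s_hi)                  # 1 inside the middle layer
        inv_K_para = (1.0 - mid) / self.K1 + mid / self.K2
        K_para = 1.0 / inv_K_para

        g1 = smoothed_step(r, p.L_f, self.w_r)     # foveola -> fovea
        g2 = smoothed_step(r, p.L_1, self.w_r)     # fovea -> parafovea
        logK = ((1.0 - g1) * np.log(p.C_f)
                + g1 * ((1.0 - g2) * np.log(self.K_fovea) + g2 * np.log(K_para)))
        out = np.exp(logK)
        return out if out.ndim else float(out)

    def column_composite(self, r: float, h: float | None = None, n: int = 4001) -> float:
        """Through-thickness harmonic composite [∫ dz/K]^-1 at radius r (m/s/Pa)."""
        p = self.params
        hh = p.h_0 if h is None else float(h)
        z = np.linspace(0.0, hh, n)
        invK = 1.0 / self(np.full_like(z, r), z, hh)
        return 1.0 / np.trapezoid(invK, z)


def build_conductivity_field(params: ModelParameters, ratio: float = 60.0,
                             numerics: Numerics | None = None,
                             K_fovea: float | None = None) -> ConductivityField:
    """Assemble the conductivity map from the overall retinal HC and a ratio.

    ``K_fovea`` defaults to the straight-cell (outer-layer) parafoveal value:
    cells in the fovea are straight and their density is intermediate.
    """
    nm = numerics or Numerics()
    K1, K2, _ = layer_conductivities(params.Gamma_ret, ratio, params.h_0)
    return ConductivityField(
        params=params, ratio=ratio, K1=K1, K2=K2,
        K_fovea=K1 if K_fovea is None else K_fovea,
        w_r=nm.w_r, w_z_frac=nm.w_z_frac,
    )


# ---------------------------------------------------------------------- #
# Müller-cell density profile (used by the deformation closure)
# ---------------------------------------------------------------------- #

def muller_density(r, params: ModelParameters, w_r: float = 50e-6):
    """Müller-cell density n(r) (cells/m^2), log-blended across regions."""
    p = params
    r = np.asarray(r, dtype=float)
    g1 = smoothed_step(r, p.L_f, w_r)
    g2 = smoothed_step(r, p.L_1, w_r)
    logn = ((1.0 - g1) * np.log(p.n_foveola)
            + g1 * ((1.0 - g2) * np.log(p.n_fovea) + g2 * np.log(p.n_parafovea)))
    out = np.exp(logn)
    return out if out.ndim else float(out)
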