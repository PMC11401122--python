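"""Model parameters, scenario settings and numerical settings.

All quantities are stored in SI units (Pa, m, s, mol, K).  Pressures that are
conventionally quoted in mm Hg (capillary, choroidal and vitreal pressures,
and all reported pressure metrics) are converted once at the configuration
boundary; ``MMHG`` is the single conversion constant used everywhere.

The registry covers every symbol of the transport model: reservoir
concentrations and pressures, membrane conductivities, Müller-cell geometry,
densities and stiffness, the exudation-source amplitudes and ring radii, and
the domain geometry.  Defaults are the published baseline of the model.
"""

from __future__ import annotations

import dataclasses
import io as _io
import math
from dataclasses import dataclass, field, fields
from typing import Any, Mapping

MMHG = 133.322  # Pa per mm Hg


class ParameterError(ValueError):
    """Raised when a configuration document contains an invalid entry."""


#: name -> (symbol, units, provenance) for the exportable registry.
PARAMETER_INFO: dict[str, tuple[str, str, str]] = {
    "T": ("T", "K", "body temperature, 37 C"),
    "R": ("R", "J/mol/K", "universal gas constant"),
    "c_c": ("c_c", "mol/m^3", "albumin concentration in the choroid"),
    "c_v": ("c_v", "mol/m^3", "albumin concentration in the vitreous"),
    "D": ("D", "m^2/s", "albumin diffusivity in free solution"),
    "E": ("E", "Pa", "Müller-cell elastic modulus"),
    "C_f": ("C_f", "m^2/s/Pa", "foveolar hydraulic conductivity (assumed)"),
    "Gamma_RPE": ("Γ_RPE", "m/s/Pa", "RPE membrane hydraulic conductivity"),
    "Gamma_ILM": ("Γ_ILM", "m/s/Pa", "ILM membrane hydraulic conductivity"),
    "Gamma_ret": ("Γ_ret", "m/s/Pa", "overall retinal hydraulic conductivity"),
    "L": ("L", "m", "domain radius (far-field cutoff, assumed)"),
    "n_foveola": ("n_foveola", "cells/m^2", "Müller-cell density, foveola"),
    "n_fovea": ("n_fovea", "cells/m^2", "Müller-cell density, fovea"),
    "n_parafovea": ("n_parafovea", "cells/m^2", "Müller-cell density, parafovea"),
    "d_c": ("d_c", "m", "Müller-cell diameter"),
    "omega": ("ω", "s·mol/kg/m", "ILM solute permittivity (derived)"),
    "p_a": ("p_a", "Pa", "arterial capillary pressure (25 mm Hg)"),
    "p_c": ("p_c", "Pa", "choroidal interstitial pressure (reference 0)"),
    "p_v": ("p_v", "Pa", "vitreal interstitial pressure (reference 0)"),
    "L_1": ("L_1", "m", "fovea radius"),
    "L_f": ("L_f", "m", "foveola radius"),
    "Q_RPE": ("Q_RPE", "m/s", "RPE active pumping velocity"),
    "sigma": ("σ", "-", "Staverman reflection coefficient (assumed)"),
    "kappa_c": ("κ_c", "N", "single Müller-cell stiffness (derived, E π d_c²/4)"),
    "d_m": ("d_m", "m", "vitreous cortex + ILM thickness (informational)"),
    "h_0": ("h_0", "m", "undeformed retinal thickness"),
    "d_1": ("d_1", "m", "outer (RPE-side) layer thickness"),
    "d_2": ("d_2", "m", "middle layer thickness"),
    "d_3": ("d_3", "m", "inner (ILM-side) layer thickness"),
    "A_f": ("A_f", "1/s/Pa (nominal)", "fluid exudation amplitude (assumed)"),
    "a": ("a", "mol/m^3", "A_a/A_f ratio (assumed, plasma ceiling 0.53)"),
    "L_e1": ("L_e1", "m", "inner exudation-ring radius"),
    "L_e2": ("L_e2", "m", "outer exudation-ring radius"),
    "FAZ_area": ("FAZ", "m^2", "foveal avascular zone area (informational)"),
}


@dataclass(frozen=True)
class ModelParameters:
    """Complete registry of the model constants (SI units)."""

    T: float = 310.0
    R: float = 8.314
    c_c: float = 0.053
    c_v: float = 0.011
    D: float = 6.1e-11
    E: float = 250.0
    C_f: float = 1e-9
    Gamma_RPE: float = 1.16e-11
    Gamma_ILM: float = 1e-9
    Gamma_ret: float = 2.54e-10
    L: float = 0.008
    n_foveola: float = 500e6
    n_fovea: float = 10_000e6
    n_parafovea: float = 27_000e6
    d_c: float = 5e-6
    omega: float = 1.97e-11
    p_a: float = 25.0 * MMHG
    p_c: float = 0.0
    p_v: float = 0.0
    L_1: float = 0.75e-3
    L_f: float = 0.17e-3
    Q_RPE: float = 1e-8
    sigma: float = 1.0
    kappa_c: float = 4.9e-9
    d_m: float = 120e-6
    h_0: float = 320e-6
    d_1: float = 320e-6 / 3
    d_2: float = 320e-6 / 3
    d_3: float = 320e-6 / 3
    A_f: float = 1.15e-4
    a: float = 0.5
    L_e1: float = 1.33e-3
    L_e2: float = 1.83e-3
    FAZ_area: float = 0.289e-6

    # ------------------------------------------------------------------ #
    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        may_be_zero = {"p_c", "p_v", "A_f"}
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ParameterError(f"parameter {f.name!r} is not a finite number")
            if f.name in may_be_zero:
                if v < 0:
                    raise ParameterError(f"parameter {f.name!r} must be >= 0")
            elif v <= 0:
                raise ParameterError(f"parameter {f.name!r} must be > 0")
        if not 0.0 <= self.sigma <= 1.0:
            raise ParameterError("parameter 'sigma' must lie in [0, 1]")
        if abs(self.d_1 + self.d_2 + self.d_3 - self.h_0) > 1e-9 * self.h_0:
            raise ParameterError("layer thicknesses d_1 + d_2 + d_3 must equal h_0")
        if not self.L_e1 < self.L_e2 < self.L:
            raise ParameterError("exudation radii must satisfy L_e1 < L_e2 < L")
        if not self.L_f < self.L_1 < self.L_e1:
            raise ParameterError("region radii must satisfy L_f < L_1 < L_e1")

    # ------------------------------------------------------------------ #
    @property
    def RT(self) -> float:
        """R*T (Pa per mol/m^3), the Van't Hoff factor."""
        return self.R * self.T

    @property
    def p_a_mmHg(self) -> float:
        return self.p_a / MMHG

    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any]) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ParameterError(f"unknown parameter key(s): {sorted(unknown)}")
        base = {f.name: f.default for f in fields(cls)}
        base.update({k: float(v) for k, v in doc.items()})
        # keep the layer partition consistent when only h_0 is overridden
        if "h_0" in doc and not {"d_1", "d_2", "d_3"} & set(doc):
            base["d_1"] = base["d_2"] = base["d_3"] = base["h_0"] / 3.0
        return cls(**base)

    def to_csv(self) -> str:
        """Registry as CSV text: name, symbol, value, units, provenance."""
        buf = _io.StringIO()
        buf.write("name,symbol,value,units,provenance\n")
        for f in fields(self):
            sym, units, prov = PARAMETER_INFO[f.name]
            buf.write(f"{f.name},{sym},{getattr(self, f.name)!r},{units},\"{prov}\"\n")
        return buf.getvalue()


def load_parameters(config: Mapping[str, Any] | None = None) -> ModelParameters:
    """Build a validated parameter registry from a key/value document.

    Absent keys take the baseline defaults; pressures given under keys ending
    in ``_mmHg`` are converted to Pa.  Unknown keys and non-positive values
    are rejected with the offending key named.
    """
    doc = dict(config or {})
    for key in list(doc):
        if key.endswith("_mmHg"):
            doc[key[:-5]] = float(doc.pop(key)) * MMHG
    return ModelParameters.from_dict(doc)


# ---------------------------------------------------------------------- #
# Scenario and numerical settings
# ---------------------------------------------------------------------- #

@dataclass
class Scenario:
    """Case settings: exudation amplitude, layering and pumping multipliers.

    ``af_fraction`` scales the baseline exudation amplitude A_f (0 for the
    physiological case, 1 for baseline edema).  ``hc_ratio`` is the
    outer/middle layer conductivity ratio K(1)/K(2) at fixed overall retinal
    conductivity.  ``albumin_on`` switches the solute source A_a = a*A_f on or
    off independently of the fluid source.
    """

    name: str = "physiological"
    af_fraction: float = 0.0
    hc_ratio: float = 60.0
    q_rpe_multiplier: float = 1.0
    albumin_on: bool = True
    deformable: bool = False
    beta: float | None = None  # Winkler calibration factor; None = calibrate

    def validate(self) -> None:
        if self.af_fraction < 0:
            raise ParameterError("scenario key 'af_fraction' must be >= 0")
        if self.hc_ratio < 1:
            raise ParameterError("scenario key 'hc_ratio' must be >= 1")
        if self.q_rpe_multiplier <= 0:
            raise ParameterError("scenario key 'q_rpe_multiplier' must be > 0")


@dataclass
class Numerics:
    """Mesh resolution, smoothing widths, tolerances and unit conventions."""

    # smoothing half-widths of the region/layer indicator steps
    w_r: float = 50e-6          # radial (m)
    w_z_frac: float = 1.0 / 30.0  # axial, as a fraction of h_0

    # mesh: uniform spacing up to r_fine, then geometric growth to L
    dr_inner: float = 2.5e-5    # spacing for r < L_1 (m)
    dr_ring: float = 3.0e-5     # spacing for L_1 < r < r_fine (m)
    r_fine: float = 2.6e-3      # end of the uniformly refined region (m)
    growth: float = 1.09        # geometric growth factor beyond r_fine
    dr_max: float = 1.2e-4      # cap on the far-field radial spacing (m)
    nz: int = 36                # vertical element count

    # Picard fixed point (pressure <-> concentration)
    picard_tol: float = 1e-9
    picard_max: int = 200
    relax: float = 0.3

    # fluid-structure outer loop
    outer_tol: float = 1e-3
    outer_max: int = 50
    outer_relax: float = 0.5
    strain_cap: float = 3.0
    h_smooth_width: float = 1.5e-4  # radial smoothing of the thickness profile

    # conventions / switches
    af_convention: str = "mmHg"   # "mmHg": A_f is per (s*mmHg); "si": per (s*Pa)
    stabilization: bool = False   # streamline diffusion (off: cell Peclet is mild)
    foveola_avg_radius: float | None = None  # None -> L_f
    depth_average: str = "mean"   # excess-pressure reduction: "mean" | "mid"

    def validate(self) -> None:
        if self.af_convention not in ("mmHg", "si"):
            raise ParameterError("numerics key 'af_convention' must be 'mmHg' or 'si'")
        if self.w_r <= 0 or self.w_z_frac <= 0:
            raise ParameterError("smoothing widths must be > 0")
        if self.nz < 3:
            raise ParameterError("numerics key 'nz' must be >= 3")

    def af_amplitude(self, params: ModelParameters, fraction: float = 1.0) -> float:
        """Internal SI exudation amplitude (1/s/Pa) for a given A_f fraction."""
        scale = 1.0 / MMHG if self.af_convention == "mmHg" else 1.0
        return params.A_f * fraction * scale


def scenario_from_dict(doc: Mapping[str, Any] | None) -> Scenario:
    doc = dict(doc or {})
    known = {f.name for f in fields(Scenario)}
    unknown = set(doc) - known
    if unknown:
        raise ParameterError(f"unknown scenario key(s): {sorted(unknown)}")
    sc = Scenario(**doc)
    sc.validate()
    return sc


def numerics_from_dict(doc: Mapping[str, Any] | None) -> Numerics:
    doc = dict(doc or {})
    known = {f.name for f in fields(Numerics)}
    unknown = set(doc) - known
    if unknown:
        raise ParameterError(f"unknown numerics key(s): {sorted(unknown)}")
    for key in ("nz", "picard_max", "outer_max"):
        if key in doc:
            doc[key] = int(doc[key])
    nm = Numerics(**doc)
    nm.validate()
    return nm
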