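"""Configuration reading, result writers and the run manifest.

The canonical configuration dialect is TOML with three sections:

    [parameters]   # overrides of the baseline model constants (SI; *_mmHg ok)
    [scenario]     # af_fraction, hc_ratio, albumin_on, q_rpe_multiplier, ...
    [numerics]     # mesh resolution, tolerances, smoothing widths, switches

Fields export to legacy ASCII VTK (unstructured grid) and CSV profiles;
scalar metrics append to a JSON-lines record; every run writes a manifest
(parameter echo, configuration hash, output inventory) last, so a complete
manifest marks a complete run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__ as _version
from .mesh import Mesh2D
from .parameters import (ModelParameters, Numerics, Scenario, load_parameters,
                         numerics_from_dict, scenario_from_dict)
from .transport import SolutionState


def read_config(path: str | Path | None) -> tuple[ModelParameters, Scenario, Numerics]:
    """Parse a TOML configuration file; a missing path yields all defaults."""
    doc = {}
    if path is not None:
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
    params = load_parameters(doc.get("parameters"))
    scenario = scenario_from_dict(doc.get("scenario"))
    numerics = numerics_from_dict(doc.get("numerics"))
    return params, scenario, numerics


def config_hash(params: ModelParameters, scenario: Scenario,
                numerics: Numerics) -> str:
    """Stable hash of the full configuration (key order independent)."""
    blob = json.dumps({
        "parameters": params.to_dict(),
        "scenario": dataclasses.asdict(scenario),
        "numerics": dataclasses.asdict(numerics),
    }, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Inventory of one scenario run; written last, after all outputs."""

    scenario: str
    config_hash: str
    parameters: dict
    scenario_settings: dict
    numerics: dict
    version: str = _version
    started: str = ""
    finished: str = ""
    status: str = "running"
    outputs: list = field(default_factory=list)

    @classmethod
    def start(cls, name: str, params: ModelParameters, scenario: Scenario,
              numerics: Numerics) -> "RunManifest":
        return cls(scenario=name,
                   config_hash=config_hash(params, scenario, numerics),
                   parameters=params.to_dict(),
                   scenario_settings=dataclasses.asdict(scenario),
                   numerics=dataclasses.asdict(numerics),
                   started=time.strftime("%Y-%m-%dT%H:%M:%S"))

    def add(self, path: str | Path) -> Path:
        self.outputs.append(str(path))
        return Path(path)

    def finish(self, out_dir: str | Path, status: str = "completed") -> Path:
        self.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        self.status = status
        missing = [p for p in self.outputs if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"manifest lists missing outputs: {missing}")
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        return path


# ---------------------------------------------------------------------- #
# Writers
# ---------------------------------------------------------------------- #

def append_metrics(path: str | Path, record: dict) -> Path:
    """Append one JSON-lines metrics record."""
    path = Path(path)
    clean = {k: (float(v) if isinstance(v, (np.floating, np.integer)) else v)
             for k, v in record.items()}
    with open(path, "a") as fh:
        fh.write(json.dumps(clean) + "\n")
    return path


def write_vtk(path: str | Path, mesh: Mesh2D, point_data: dict[str, np.ndarray]) -> Path:
    """Legacy ASCII VTK unstructured grid with nodal scalar/vector data."""
    path = Path(path)
    n = mesh.nodes.shape[0]
    m = mesh.tris.shape[0]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nmacuflow fields\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {n} double\n")
        for r, z in mesh.nodes:
            fh.write(f"{r:.10e} {z:.10e} 0.0\n")
        fh.write(f"\nCELLS {m} {4 * m}\n")
        for t in mesh.tris:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        fh.write(f"\nCELL_TYPES {m}\n")
        fh.write("\n".join(["5"] * m) + "\n")
        fh.write(f"\nPOINT_DATA {n}\n")
        for name, vals in point_data.items():
            vals = np.asarray(vals)
            if vals.ndim == 1:
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.10e}" for v in vals) + "\n")
            else:
                fh.write(f"VECTORS {name} double\n")
                for row in vals:
                    fh.write(f"{row[0]:.10e} {row[1]:.10e} 0.0\n")
    return path


def nodal_velocity(mesh: Mesh2D, u_elem: np.ndarray) -> np.ndarray:
    """Area-weighted nodal average of the elementwise Darcy velocity."""
    out = np.zeros_like(mesh.nodes)
    wsum = np.zeros(mesh.nodes.shape[0])
    w = mesh.area
    for k in range(3):
        np.add.at(out, mesh.tris[:, k], u_elem * w[:, None])
        np.add.at(wsum, mesh.tris[:, k], w)
    return out / wsum[:, None]


def write_state_vtk(path: str | Path, state: SolutionState) -> Path:
    u_nod = nodal_velocity(state.mesh, state.u)
    return write_vtk(path, state.mesh, {
        "pressure": state.p,
        "concentration": state.c,
        "speed": np.linalg.norm(u_nod, axis=1),
        "velocity": u_nod,
    })


def write_column_profiles(path: str | Path, state: SolutionState,
                          radii=(0.0, 1.58e-3, 3e-3)) -> Path:
    """CSV of p(z) and c(z) at selected radii (nearest radial stations)."""
    import pandas as pd

    mesh = state.mesh
    rows = []
    for r in radii:
        i = int(np.argmin(np.abs(mesh.r_array - r)))
        nzp = mesh.zeta.size
        z = mesh.nodes[i * nzp:(i + 1) * nzp, 1]
        for zz, pp, cc in zip(z, state.column(i, state.p), state.column(i, state.c)):
            rows.append({"r": mesh.r_array[i], "z": zz, "p": pp, "c": cc})
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def write_thickness_profile(path: str | Path, r: np.ndarray, h: np.ndarray,
                            h_0: float) -> Path:
    import pandas as pd

    pd.DataFrame({"r": r, "h": h, "h_ratio": h / h_0}).to_csv(path, index=False)
    return Path(path)


def write_parameters_csv(path: str | Path, params: ModelParameters) -> Path:
    Path(path).write_text(params.to_csv())
    return Path(path)
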