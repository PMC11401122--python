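"""Shared fixtures: the expensive solves are session-scoped and reused."""

from __future__ import annotations

import numpy as np
import pytest

import macuflow as mf
from macuflow import experiments as ex

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, derandomize=True,
                              max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def params() -> mf.ModelParameters:
    return mf.load_parameters()


@pytest.fixture(scope="session")
def numerics() -> mf.Numerics:
    return mf.Numerics()


@pytest.fixture(scope="session")
def kfield(params, numerics):
    return mf.build_conductivity_field(params, 60.0, numerics)


@pytest.fixture(scope="session")
def phys_result(params, numerics) -> ex.ScenarioResult:
    """Converged physiological baseline scenario (rigid domain)."""
    return ex.run_physiological(params, numerics)


@pytest.fixture(scope="session")
def phys_state(phys_result):
    return phys_result.state


@pytest.fixture(scope="session")
def base_edema(params, numerics) -> ex.ScenarioResult:
    """Baseline pathological scenario: full fluid-structure solve."""
    return ex.run_pathological(params, numerics)


@pytest.fixture(scope="session")
def edema_no_albumin(params, numerics, base_edema) -> ex.ScenarioResult:
    """Baseline fluid exudation with the albumin source switched off."""
    return ex.run_pathological(params, numerics, albumin_on=False,
                               beta=base_edema.metrics["beta"],
                               reference=base_edema.reference)


@pytest.fixture(scope="session")
def coarse_numerics() -> mf.Numerics:
    """Cheap mesh for smoke tests that only exercise plumbing."""
    return mf.Numerics(dr_inner=8e-5, dr_ring=1e-4, nz=10, picard_tol=1e-7)
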