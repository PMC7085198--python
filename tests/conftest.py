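"""Shared fixtures.

The full microcirculation-load (ML) and pressure-load (PL) transient runs
and the steady analytic benchmarks are expensive, so they are computed once
per session and shared between the solver tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from stenoflow import (CarreauParams, FluidParams, PorousParams,
                       SimulationConfig, StenosisGeometry, build_waveform,
                       run_simulation)


def default_ml_setup():
    geom = StenosisGeometry(L_porous=0.2e-3)
    cfg = SimulationConfig(outlet_mode="ML")
    return geom, CarreauParams(), FluidParams(), PorousParams(), build_waveform(), cfg


def default_pl_setup():
    geom = StenosisGeometry()
    cfg = SimulationConfig(outlet_mode="PL")
    return geom, CarreauParams(), FluidParams(), None, build_waveform(), cfg


@pytest.fixture(scope="session")
def ml_history():
    """Full 3-cycle microcirculation-load run at reference defaults."""
    return run_simulation(*default_ml_setup())


@pytest.fixture(scope="session")
def pl_history():
    """Full 3-cycle pressure-load run at reference defaults."""
    return run_simulation(*default_pl_setup())


@pytest.fixture(scope="session")
def poiseuille_check():
    from stenoflow.validate import check_poiseuille
    return check_poiseuille()


@pytest.fixture(scope="session")
def slug_check():
    from stenoflow.validate import check_porous_slug
    return check_porous_slug()
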