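"""Shared fixtures.

The coupled-run fixtures are session-scoped because each one is a full
clot-flow-lysis simulation; several acceptance checks read different
aspects of the same run.
"""

from __future__ import annotations

import numpy as np
import pytest

from fibroflow.analytic import LysisParams1D
from fibroflow.config import RunConfig
from fibroflow.lattice import UnitSystem


@pytest.fixture(scope="session")
def units() -> UnitSystem:
    return UnitSystem(dx=2e-5, dt=2e-4, nu=1e-6)


@pytest.fixture
def baseline_params() -> LysisParams1D:
    """Reference in-vitro-like 1D parameters (fibrin 2.4 mg/ml clot)."""
    return LysisParams1D(
        F0=2.4, Fstar=0.2, Fbar0=1e-5, k1=12.5, u_f=5e-6,
        Delta=5e-3 / 100, L=5e-3,
    )


def mini_config(**clot_kw) -> RunConfig:
    """A small, fast coupled-run config for behavioural tests (not the
    desk-scale study conditions): short clot, strong kinetics."""
    from fibroflow.config import DomainBlock

    cfg = RunConfig()
    cfg.domain = DomainBlock(ny=12, nx=24, inlet_lumen=3, clot_len=8)
    cfg.physical.k1 = 4000.0
    cfg.outputs.sample_period_s = 10.0
    cfg.stop.t_max_s = 3e4
    for k, v in clot_kw.items():
        setattr(cfg.clot, k, v)
    return cfg


@pytest.fixture(scope="session")
def frontcheck_run():
    """The homogeneous front-comparison study run (shared across tests)."""
    from fibroflow.studies import frontcheck_config
    from fibroflow.transport import run_lysis

    return run_lysis(frontcheck_config(seed=20260))


@pytest.fixture(scope="session")
def mini_run():
    """A completed small homogeneous run for observable/record tests."""
    from fibroflow.transport import run_lysis

    return run_lysis(mini_config(), seed_override=7)

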