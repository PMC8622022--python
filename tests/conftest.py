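"""Shared fixtures: reference parameters, grids, and the (expensive)
reference synchronization runs, computed once per session."""

import numpy as np
import pytest

import selkovsync as sv


@pytest.fixture(scope="session")
def ref_params() -> sv.KineticParams:
    """Kinetics and diffusivities of the reference experiments."""
    return sv.KineticParams(a=3.5, b=0.25, d1=0.01, d2=1.0)


@pytest.fixture(scope="session")
def grid_1d() -> sv.Grid:
    return sv.build_grid(1, 10.0, 51)


@pytest.fixture(scope="session")
def grid_2d() -> sv.Grid:
    return sv.build_grid(2, 10.0, 51)


@pytest.fixture(scope="session")
def ref_tcfg(ref_params, grid_1d) -> sv.TimeSteppingConfig:
    return sv.TimeSteppingConfig.from_cfl(
        ref_params, grid_1d, t_end=100.0, snapshot_interval=4.0
    )


@pytest.fixture(scope="session")
def ref_ics(grid_1d):
    return sv.ic_reference_drive(grid_1d), sv.ic_reference_response(grid_1d)


@pytest.fixture(scope="session")
def controlled_run(ref_params, ref_tcfg, ref_ics):
    """Reference drive-response run with K = 15: (snapshots, diagnostics)."""
    drive_ic, resp_ic = ref_ics
    gains = sv.ControlGains.from_K(15.0, ref_params)
    return sv.synchronize(drive_ic, resp_ic, ref_params, gains, ref_tcfg)


@pytest.fixture(scope="session")
def uncontrolled_run(ref_params, ref_tcfg, ref_ics):
    """Same pair with U == 0 (negative control)."""
    drive_ic, resp_ic = ref_ics
    return sv.synchronize(drive_ic, resp_ic, ref_params, None, ref_tcfg)
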