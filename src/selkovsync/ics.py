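"""Initial-condition fixtures for the reference experiments.

The 1D reference runs use sinusoidal perturbations around distinct
baselines for drive and response — the drive starts near the homogeneous
steady state (3.5, 0.28), the response far from it — so the controller
has a nontrivial error to remove.  For Turing-pattern runs a seeded
uniform random perturbation of the steady state is provided.

In 2D the sinusoidal fixtures default to the same expressions evaluated
in x only (constant in y); a separable ``sin(x)*sin(y)`` variant is
available via ``variant="xy"``.
"""

from __future__ import annotations

import numpy as np

from .grids import Grid, State
from .model import KineticParams, homogeneous_steady_state

__all__ = ["ic_reference_drive", "ic_reference_response", "ic_perturbed_steady"]


def _profile(grid: Grid, base1, amp1, base2, amp2, freq, variant):
    if grid.ndim == 1:
        (x,) = grid.coords()
        s = np.sin(freq * x)
    else:
        x, y = grid.coords()
        if variant == "xy":
            s = np.sin(freq * x) * np.sin(freq * y)
        elif variant == "x":
            s = np.sin(freq * x)
        else:
            raise ValueError(f"unknown 2D variant {variant!r} (use 'x' or 'xy')")
    return State(grid=grid, u1=base1 + amp1 * s, u2=base2 + amp2 * s, time=0.0)


def ic_reference_drive(grid: Grid, variant: str = "x") -> State:
    """Drive initial condition ``(3.5 + 0.1 sin x, 0.28 + 0.1 sin x)``.

    The baseline is the homogeneous steady state for (a, b) = (3.5, 0.25).
    """
    return _profile(grid, 3.5, 0.1, 0.28, 0.1, 1.0, variant)


def ic_reference_response(grid: Grid, variant: str = "x") -> State:
    """Response initial condition ``(1 + 0.5 sin 0.2x, 0.6 + 0.5 sin 0.2x)``."""
    return _profile(grid, 1.0, 0.5, 0.6, 0.5, 0.2, variant)


def ic_perturbed_steady(
    params: KineticParams, grid: Grid, amplitude: float, seed: int
) -> State:
    """Steady state with a seeded uniform relative perturbation.

    Each field is multiplied by ``1 + amplitude * U(-1, 1)`` nodewise;
    the same seed always reproduces the same fields.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    ss = homogeneous_steady_state(params)
    rng = np.random.default_rng(seed)
    u1 = ss.u1_star * (1.0 + amplitude * rng.uniform(-1.0, 1.0, grid.shape))
    u2 = ss.u2_star * (1.0 + amplitude * rng.uniform(-1.0, 1.0, grid.shape))
    return State(grid=grid, u1=u1, u2=u2, time=0.0)
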