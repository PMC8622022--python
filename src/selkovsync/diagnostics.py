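"""Synchronization diagnostics: norms, the Lyapunov functional, monitors.

The synchronization error is ``e = (v1 - u1, v2 - u2)``; convergence is
measured in the spatial L2 norm ``||e||_L2 = sqrt(int_Omega (e1^2 + e2^2))``
and certified by monotone decrease of the Lyapunov functional
``V(t) = 1/2 * int_Omega (e1^2 + e2^2) = 1/2 * ||e||^2``.

All integrals use the trapezoidal rule on the vertex grid, consistent
with the second-order spatial stencil.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .grids import Grid, State

__all__ = [
    "DiagnosticsSeries",
    "MonotonicityReport",
    "BoundednessReport",
    "l2_norm",
    "lyapunov_v",
    "check_monotone_decrease",
    "convergence_time",
    "boundedness_report",
]


def l2_norm(e1: np.ndarray, e2: np.ndarray, grid: Grid) -> float:
    """Spatial L2 norm of the error pair: sqrt(int (e1^2 + e2^2) dx)."""
    grid._check_shape(np.asarray(e1))
    grid._check_shape(np.asarray(e2))
    w = grid.quad_weights()
    return float(np.sqrt(np.sum(w * (e1 * e1 + e2 * e2))))


def lyapunov_v(e1: np.ndarray, e2: np.ndarray, grid: Grid) -> float:
    """Lyapunov functional V = 1/2 * int (e1^2 + e2^2) dx (same quadrature)."""
    w = grid.quad_weights()
    grid._check_shape(np.asarray(e1))
    grid._check_shape(np.asarray(e2))
    return float(0.5 * np.sum(w * (e1 * e1 + e2 * e2)))


@dataclass
class DiagnosticsSeries:
    """Per-snapshot time series of synchronization diagnostics.

    Satisfies the definitional identity ``lyapunov_v == 0.5 * l2_error**2``
    at every time point.
    """

    times: np.ndarray
    l2_error: np.ndarray
    lyapunov_v: np.ndarray
    sup_u1: np.ndarray
    sup_u2: np.ndarray
    sup_v1: np.ndarray
    sup_v2: np.ndarray
    min_fields: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("l2_error", "lyapunov_v", "sup_u1", "sup_u2",
                     "sup_v1", "sup_v2", "min_fields"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != n:
                raise ValueError(f"series '{name}' length {len(arr)} != {n}")
            setattr(self, name, arr)
        self.times = np.asarray(self.times, dtype=float)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "l2_error": self.l2_error,
                "lyapunov_v": self.lyapunov_v,
                "sup_u1": self.sup_u1,
                "sup_u2": self.sup_u2,
                "sup_v1": self.sup_v1,
                "sup_v2": self.sup_v2,
                "min_fields": self.min_fields,
            }
        )

    def write_csv(self, path) -> None:
        """Delimited-text table, one row per snapshot, 9 significant digits."""
        self.to_frame().to_csv(path, index=False, float_format="%.9g")


@dataclass(frozen=True)
class MonotonicityReport:
    passed: bool
    first_violation_index: Optional[int]
    max_relative_increase: float


def check_monotone_decrease(
    series: DiagnosticsSeries, tol: float = 1e-8
) -> MonotonicityReport:
    """Check V(t_{k+1}) <= V(t_k) * (1 + tol) for consecutive snapshots.

    The relative tolerance (default 1e-8) absorbs floating-point noise
    once V has collapsed toward zero.  Returns the index of the first
    violating transition, if any.
    """
    v = series.lyapunov_v
    if len(v) == 0:
        raise ValueError("empty diagnostics series")
    first = None
    max_inc = 0.0
    for k in range(len(v) - 1):
        allowed = v[k] * (1.0 + tol)
        if v[k + 1] > allowed:
            if first is None:
                first = k + 1
        if v[k] > 0:
            max_inc = max(max_inc, (v[k + 1] - v[k]) / v[k])
    return MonotonicityReport(
        passed=first is None,
        first_violation_index=first,
        max_relative_increase=max_inc,
    )


def convergence_time(
    series: DiagnosticsSeries, threshold_ratio: float
) -> Optional[float]:
    """Earliest snapshot time with l2_error <= threshold_ratio * l2_error(0).

    Returns None if the threshold is never reached; returns 0.0 by
    convention when the initial error is already zero.
    """
    if not 0 < threshold_ratio < 1:
        raise ValueError("threshold_ratio must be in (0, 1)")
    e0 = series.l2_error[0]
    if e0 == 0:
        return 0.0
    hit = np.nonzero(series.l2_error <= threshold_ratio * e0)[0]
    if hit.size == 0:
        return None
    return float(series.times[hit[0]])


@dataclass(frozen=True)
class BoundednessReport:
    """Global field bounds over a run; the continuum solution is known to
    stay in [0, M], so negative minima flag discretization error."""

    min_u1: float
    max_u1: float
    min_u2: float
    max_u2: float
    has_negative: bool
    has_nonfinite: bool
    cap_exceeded: Optional[bool]

    @property
    def overall_max(self) -> float:
        return max(self.max_u1, self.max_u2)


def boundedness_report(
    snapshots: Sequence[State], M_cap: Optional[float] = None
) -> BoundednessReport:
    """Min/max of each field over a run, with positivity and cap flags."""
    if len(snapshots) == 0:
        raise ValueError("need at least one snapshot")
    u1s = [s.u1 for s in snapshots]
    u2s = [s.u2 for s in snapshots]
    nonfinite = not all(np.all(np.isfinite(u)) for u in u1s + u2s)
    min_u1 = float(np.nanmin([np.nanmin(u) for u in u1s]))
    max_u1 = float(np.nanmax([np.nanmax(u) for u in u1s]))
    min_u2 = float(np.nanmin([np.nanmin(u) for u in u2s]))
    max_u2 = float(np.nanmax([np.nanmax(u) for u in u2s]))
    overall_max = max(max_u1, max_u2)
    return BoundednessReport(
        min_u1=min_u1,
        max_u1=max_u1,
        min_u2=min_u2,
        max_u2=max_u2,
        has_negative=min(min_u1, min_u2) < 0,
        has_nonfinite=nonfinite,
        cap_exceeded=None if M_cap is None else overall_max > M_cap,
    )
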