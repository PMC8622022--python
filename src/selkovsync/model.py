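"""Selkov glycolysis kinetics and linear stability analysis.

The Selkov model is a minimal two-species description of glycolytic
oscillations: ``u1`` is the substrate (e.g. ADP) and ``u2`` the product
(e.g. F6P), coupled through the cubic autocatalytic term ``u1**2 * u2``.
With diffusion the model reads::

    du1/dt = d1 * lap(u1) + f(u1, u2),   f = b*u2 - u1 + u1**2 * u2
    du2/dt = d2 * lap(u2) + g(u1, u2),   g = a - b*u2 - u1**2 * u2

where ``a`` is the constant substrate-injection rate and ``b`` a linear
kinetic rate.  The kinetics are autonomous: time never enters the
right-hand side.

A structural identity used throughout the package (and as a test oracle)
is ``f + g = a - u1``: the autocatalytic and linear exchange terms cancel
in the sum, leaving only injection minus removal of the substrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KineticParams",
    "SteadyState",
    "StabilityReport",
    "selkov_rhs",
    "homogeneous_steady_state",
    "jacobian_at",
    "neumann_wavenumbers",
    "turing_analysis",
]


@dataclass(frozen=True)
class KineticParams:
    """Kinetic and transport constants of the Selkov reaction-diffusion model.

    Parameters
    ----------
    a : float
        Substrate-injection rate (concentration / time), > 0.
    b : float
        Linear kinetic rate (1 / time), > 0.
    d1, d2 : float
        Diffusion coefficients of the substrate and product
        (length**2 / time), > 0.
    """

    a: float
    b: float
    d1: float
    d2: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "d1", "d2"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(
                    f"KineticParams.{name} must be finite and > 0, got {value!r}"
                )


@dataclass(frozen=True)
class SteadyState:
    """Spatially homogeneous steady state (u1*, u2*) of the kinetics."""

    u1_star: float
    u2_star: float

    def as_array(self) -> np.ndarray:
        return np.array([self.u1_star, self.u2_star])


def selkov_rhs(u1, u2, params: KineticParams):
    """Evaluate the Selkov kinetics elementwise.

    Returns ``(f, g)`` with ``f = b*u2 - u1 + u1**2*u2`` and
    ``g = a - b*u2 - u1**2*u2``.  Inputs may be scalars or arrays of a
    common shape.

    Raises
    ------
    ValueError
        If the fields differ in shape or contain non-finite entries.
    """
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    if u1.shape != u2.shape:
        raise ValueError(f"field shapes differ: {u1.shape} vs {u2.shape}")
    if not (np.all(np.isfinite(u1)) and np.all(np.isfinite(u2))):
        raise ValueError("non-finite values in concentration fields")
    cubic = u1 * u1 * u2
    f = params.b * u2 - u1 + cubic
    g = params.a - params.b * u2 - cubic
    return f, g


def homogeneous_steady_state(params: KineticParams) -> SteadyState:
    """Closed-form homogeneous steady state ``(a, a / (b + a**2))``.

    Adding ``f = 0`` and ``g = 0`` gives ``a - u1 = 0``, so ``u1* = a``;
    substituting into ``g = 0`` yields ``u2* = a / (b + a**2)``.  The
    denominator is always positive.
    """
    a, b = params.a, params.b
    return SteadyState(u1_star=a, u2_star=a / (b + a * a))


def jacobian_at(params: KineticParams, point: SteadyState) -> np.ndarray:
    """Jacobian of the kinetics ``(f, g)`` with respect to ``(u1, u2)``.

    Returns ``[[-1 + 2*u1*u2, b + u1**2], [-2*u1*u2, -b - u1**2]]``
    evaluated at ``point``.  Note the column sums: the first column sums
    to -1 and the second to 0, a direct consequence of ``f + g = a - u1``.
    """
    u1, u2 = point.u1_star, point.u2_star
    if not (np.isfinite(u1) and np.isfinite(u2)):
        raise ValueError("steady-state point must be finite")
    b = params.b
    return np.array(
        [
            [-1.0 + 2.0 * u1 * u2, b + u1 * u1],
            [-2.0 * u1 * u2, -b - u1 * u1],
        ]
    )


@dataclass(frozen=True)
class StabilityReport:
    """Linear stability of the homogeneous steady state, with dispersion.

    ``dispersion`` holds ``(k**2, max Re eigenvalue of J - k**2 diag(d1, d2))``
    pairs; a positive growth rate at some ``k**2 > 0`` while the
    diffusion-free system is stable signals a Turing (diffusion-driven)
    instability, the mechanism behind the spatial patterns this model forms
    when ``d1 << d2``.
    """

    steady_state: SteadyState
    jacobian: np.ndarray
    trace: float
    determinant: float
    homogeneous_stable: bool
    turing_unstable: bool
    dispersion: np.ndarray = field(repr=False)  # shape (n, 2): k^2, growth rate

    @property
    def max_growth_rate(self) -> float:
        return float(self.dispersion[:, 1].max())

    def to_table(self):
        """Dispersion relation as a two-column DataFrame (k^2, growth_rate)."""
        import pandas as pd

        return pd.DataFrame(self.dispersion, columns=["k_squared", "growth_rate"])

    def summary(self) -> dict:
        """Structured summary record (plain scalars, serialisable)."""
        i = int(np.argmax(self.dispersion[:, 1]))
        return {
            "u1_star": self.steady_state.u1_star,
            "u2_star": self.steady_state.u2_star,
            "trace": self.trace,
            "determinant": self.determinant,
            "homogeneous_stable": self.homogeneous_stable,
            "turing_unstable": self.turing_unstable,
            "max_growth_rate": float(self.dispersion[i, 1]),
            "k_squared_at_max": float(self.dispersion[i, 0]),
        }


def neumann_wavenumbers(extent: float = 10.0, n_modes: int = 64) -> np.ndarray:
    """Squared wavenumbers ``(m*pi/L)**2`` for m = 0..n_modes.

    These are the admissible cosine modes of the zero-flux (Neumann)
    Laplacian on an interval of length ``extent``; they are the natural
    sampling grid for the dispersion relation on a bounded domain.
    """
    if extent <= 0 or n_modes < 1:
        raise ValueError("extent must be > 0 and n_modes >= 1")
    m = np.arange(n_modes + 1, dtype=float)
    return (m * np.pi / extent) ** 2


def turing_analysis(params: KineticParams, wavenumber_grid=None) -> StabilityReport:
    """Linear (Turing) stability analysis of the homogeneous steady state.

    For each squared wavenumber ``k2`` in ``wavenumber_grid`` the growth
    rate is the largest real part of the eigenvalues of
    ``J - k2 * diag(d1, d2)``.  ``turing_unstable`` is set when the
    diffusion-free system is stable (trace < 0, det > 0) yet some
    ``k2 > 0`` has a positive growth rate.

    Parameters
    ----------
    wavenumber_grid : array-like of float, optional
        Nonnegative, sorted k^2 values.  Defaults to the Neumann modes
        ``(m*pi/10)**2`` for m = 0..64 (domain [0, 10]).
    """
    if wavenumber_grid is None:
        wavenumber_grid = neumann_wavenumbers()
    k2 = np.asarray(wavenumber_grid, dtype=float)
    if k2.size == 0:
        raise ValueError("wavenumber grid must be nonempty")
    if np.any(k2 < 0) or np.any(np.diff(k2) < 0):
        raise ValueError("wavenumber grid must be nonnegative and sorted")

    ss = homogeneous_steady_state(params)
    J = jacobian_at(params, ss)
    trace = float(np.trace(J))
    det = float(np.linalg.det(J))
    stable = trace < 0 and det > 0

    D = np.diag([params.d1, params.d2])
    growth = np.empty_like(k2)
    for i, k in enumerate(k2):
        growth[i] = np.linalg.eigvals(J - k * D).real.max()

    turing = bool(stable and np.any((k2 > 0) & (growth > 0)))
    return StabilityReport(
        steady_state=ss,
        jacobian=J,
        trace=trace,
        determinant=det,
        homogeneous_stable=stable,
        turing_unstable=turing,
        dispersion=np.column_stack([k2, growth]),
    )
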