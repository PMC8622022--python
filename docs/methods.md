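# Methods

## Model

The package simulates the two-species Selkov glycolysis kinetics with
diffusion,

    ∂u₁/∂t = d₁ Δu₁ + b u₂ − u₁ + u₁² u₂
    ∂u₂/∂t = d₂ Δu₂ + a − b u₂ − u₁² u₂

on Ω = [0, L] or [0, L]², with zero-flux Neumann boundaries and
nonnegative bounded initial data. The kinetics are autonomous (no explicit
time dependence). Two structural facts are used as oracles throughout:
f + g = a − u₁ exactly (the exchange terms cancel), and the homogeneous
steady state is (u₁*, u₂*) = (a, a/(b+a²)), obtained by adding f = 0 and
g = 0 and solving. The continuum solution is known to stay nonnegative and
uniformly bounded; the solver treats a negative sample as a
discretization-accuracy signal (flagged, never clipped).

## Synchronization scheme

A response copy (v₁, v₂) of the same PDE is forced by a linear full-state
feedback on the error e = (v₁−u₁, v₂−u₂):

    U₁ = −(2K − 1) e₁ − b e₂,    U₂ = −(2K − b) e₂.

These coefficients are defined as *the unique linear feedback that turns
the open-loop error system*

    ∂e₁/∂t = d₁Δe₁ + b e₂ − e₁ + (v₁²v₂ − u₁²u₂) + U₁
    ∂e₂/∂t = d₂Δe₂ − b e₂ − (v₁²v₂ − u₁²u₂) + U₂

*into uniform −2K damping on both components* — the object the Lyapunov
argument actually uses. This identity (b e₂ − e₁ + U₁ = −2K e₁ and
−b e₂ + U₂ = −2K e₂) is the defining contract of `control_law` and is
asserted to near machine precision in the tests. The coefficients are
exposed as overrides on `ControlGains` so alternative sign conventions can
be explored; any override whose closed-loop damping is ≥ 2K preserves the
stability argument.

The gain must dominate the Lipschitz constant of the cubic coupling:
whenever u₁ ≤ K₁, u₂ ≤ K₂, v₁ ≤ K₃ hold pointwise,
|v₁²v₂ − u₁²u₂| ≤ K(|e₁|+|e₂|) with K = max{K₃², K₂(K₁+K₃)}. The Lyapunov
functional V = ½∫(e₁²+e₂²) then satisfies dV/dt < 0 away from synchrony.
The package offers a two-stage gain pipeline — run the uncontrolled pair,
take sup-norms of u₁, u₂, v₁ over all snapshots, inflate by a safety
margin (default 1.2, a hedge against the finite snapshot sampling of the
sup), and apply the max formula — plus a direct user-supplied-K path used
by the reference experiment (K = 15). `verify_lipschitz_bound` re-checks the
pointwise inequality along any run and reports the worst ratio.

## Discretization

* **Grid.** Vertex-centered, uniform, nodes on the boundary; L = 10 with
  51 nodes per axis gives dx = 0.2. 2D uses the same extent and spacing
  per axis.
* **Laplacian.** 3-point (1D) / 5-point (2D) central stencil; Neumann
  boundaries by ghost-node mirroring (ghost = first interior value), which
  is second-order accurate including the boundary rows. Verified by
  manufactured Neumann eigenfunctions (error ratio ≈ 4 under dx halving)
  and by the discrete divergence theorem (trapezoid-weighted Laplacian
  sums exactly to zero, hence exact mass conservation under pure
  diffusion).
* **Quadrature.** Trapezoidal rule on the vertex grid for all spatial
  integrals (L² norm, Lyapunov V, mass) — second order, consistent with
  the stencil.
* **Time stepping.** Explicit forward Euler. Stability requires
  dt·|λ| < 2 for every right-hand-side rate, so the step is chosen from a
  *budget* rather than the diffusion-only CFL:
  dt = s·2/(λ_diff + λ_kin [+ λ_ctl]) with safety s = 0.9,
  λ_diff = 4·ndim·max(d₁,d₂)/dx², λ_kin = b + a² (the product's linear
  decay rate at the steady state, the stiffest kinetic rate), and, for
  controlled runs, λ_ctl = 2K + K (closed-loop damping plus the Lipschitz
  bound of the cubic coupling). The diffusion-only choice
  dt = 0.9·dx²/(2·ndim·d_max) leaves no margin for the kinetic rate: at
  the reference parameters it puts the Nyquist mode of u₂ just outside the
  stability disc (dt·(λ_diff+λ_kin) ≈ 2.03) and visibly corrupts the
  product field, and the controlled run overflows. With the budget,
  dt = 0.016 for the 1D reference grid (0.0114 when K = 15 is active).
  `stable_dt` still reports the classical diffusive limit for reference.
  Deliberately oversized steps are not rejected up front: integration
  detects non-finite fields and raises a blow-up error naming the time
  reached (and, for coupled runs, the subsystem).
* **Snapshots.** Stored every `snapshot_interval` time units (the
  reference runs use 4, matching the plotting stride of the original
  experiments; it cannot be the Euler dt, which is three orders of
  magnitude smaller), with steps shortened to land on snapshot times and
  t_end exactly. Shortening only reduces dt, so it never endangers
  stability.
* **Control timing.** The feedback is evaluated explicitly from the error
  at the current time level, consistent with the explicit scheme; drive
  and response advance with the same dt.

## Reference experiments

1D: Ω = [0, 10], dx = 0.2 (51 nodes), t ∈ [0, 100], parameters
(d₁, d₂, a, b) = (0.01, 1, 3.5, 0.25), drive IC
(3.5 + 0.1 sin x, 0.28 + 0.1 sin x), response IC
(1 + 0.5 sin 0.2x, 0.6 + 0.5 sin 0.2x), K = 15. The controlled run
collapses the L² error from 7.20 to exactly zero (the response fields
become bitwise equal to the drive under the strong contraction) within the
first snapshot interval; V is non-increasing across all snapshots. The
uncontrolled pair retains more than 10% of its initial error at t = 100
and never reaches the 10⁻³ threshold. An auto-gain sweep over
(a, b) ∈ [1, 4] × [0.1, 1] synchronizes everywhere with monotone V.

2D: the original 2D experiments do not state their domain, grid or initial
data (only snapshot times t = 0, 1, 3), so the 2D defaults here are a
design choice: [0, 10]² at the same spacing, sinusoidal fixtures evaluated
in x (with an optional sin x · sin y variant), and a seeded uniform ±5%
perturbation of the steady state for pattern runs.

## Pattern-formation timing

At the reference parameters the steady state is Turing unstable — the
dispersion relation (largest real eigenvalue of J − k² diag(d₁,d₂),
sampled on the Neumann modes k = mπ/L, m = 0…64) is positive on
k² ∈ [19.6, 63.9] — but the *maximal* growth rate is only λ_max ≈ 0.096.
A white-noise perturbation therefore first *loses* variance (all modes
outside the narrow unstable band decay quickly; measured u₁ variance ratio
≈ 0.46 at t = 3) and needs t ≈ 40–50 for 10-fold variance growth
(measured ratio ≈ 115 at t = 50, pattern saturation beyond). Any visible
structure at t ≤ 3 in this regime is a transient of far-from-steady
initial data, not a developed Turing pattern. The acceptance checks assert
the t = 3 variance ratio at face value, so that check documents this
timing fact rather than passing.

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| a | conc/time | 3.5 | reference injection rate; sets u₁* = a |
| b | 1/time | 0.25 | reference linear rate; u₂* = a/(b+a²) = 0.28 |
| d₁, d₂ | length²/time | 0.01, 1 | ratio 1:100 puts the system in the Turing regime |
| K | 1/time | 15 (or `auto`) | closed-loop damping −2K; must dominate the cubic coupling's Lipschitz constant (≈ 12.3 for the reference sups) |
| bound margin | — | 1.2 | inflation of sampled sups in the auto-gain pipeline |
| cfl_safety | — | 0.9 | fraction of the explicit stability budget actually used |
| snapshot interval | time | 4 | diagnostic/plotting stride |
| monotonicity tol | — | 1e−8 (relative) | absorbs floating-point noise in V near zero |

## What the synthetic inputs do and do not show

All inputs are synthetic by construction (the model has no external data):
sinusoidal IC fixtures and seeded uniform perturbations. They exercise
smooth, resolved initial data on a fixed moderate grid. They do not probe
rough or near-singular data, large-domain mode competition, parameter
regimes outside the sampled (a, b) box, or the behaviour of the explicit
scheme near its stability boundary — passing tests certify the scheme and
the control law under the stated study conditions, not beyond them.

## Known limitations

* Explicit Euler only; no IMEX or adaptive stepping, so stiff parameter
  choices (large a², large K) shrink dt via the budget rather than
  switching scheme.
* First-order accuracy in time; spatial order two. The synchronization
  conclusions are robust to this (the error decay is exponential with
  rate ≫ discretization error), but trajectory details at coarse dt are
  not.
* The theoretical decay-rate constant implied by the Lyapunov inequality
  is not estimated; only monotone decrease and the final-to-initial error
  ratio are asserted.
* No bifurcation continuation or limit-cycle analysis of the
  diffusion-free kinetics.
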