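# selkovsync

Simulation and synchronization of the Selkov glycolysis reaction-diffusion
model.

## The problem

The Selkov model is a minimal two-species description of glycolytic
oscillations — substrate u₁ and product u₂ coupled through cubic
autocatalysis — extended here with diffusion on a bounded domain Ω with
zero-flux (homogeneous Neumann) boundaries:

    ∂u₁/∂t = d₁ Δu₁ + f(u₁, u₂),    f = b u₂ − u₁ + u₁² u₂
    ∂u₂/∂t = d₂ Δu₂ + g(u₁, u₂),    g = a − b u₂ − u₁² u₂

with positive constants a (substrate injection), b (linear kinetic rate)
and diffusivities d₁, d₂. With d₁ ≪ d₂ the homogeneous steady state
(u₁*, u₂*) = (a, a/(b+a²)) is kinetically stable but diffusion-driven
(Turing) unstable, so spatial patterns form.

The package addresses the *drive-response synchronization* problem: make a
second, controlled copy of the system (the response, fields v₁, v₂, control
inputs U₁, U₂) converge to the trajectory of the autonomous drive system,
whatever their initial conditions. The pointwise synchronization error is
e = (v₁ − u₁, v₂ − u₂), and the linear full-state control law

    U₁ = −(2K − 1) e₁ − b e₂,    U₂ = −(2K − b) e₂

turns the error dynamics into a uniformly damped system
∂eᵢ/∂t = dᵢ Δeᵢ − 2K eᵢ ± (v₁²v₂ − u₁²u₂). Whenever the gain K dominates
the Lipschitz constant of the cubic coupling — guaranteed by
K = max{K₃², K₂(K₁+K₃)} for sup bounds u₁ ≤ K₁, u₂ ≤ K₂, v₁ ≤ K₃ — the
Lyapunov functional V(t) = ½∫_Ω (e₁² + e₂²) decreases monotonically and the
L² error converges to zero. The package implements the solver, the control
law, the bound-estimation gain pipeline and the diagnostics that verify all
of this numerically, in one and two spatial dimensions.

Intended users: researchers in nonlinear dynamics and systems biology who
want a reproducible reference implementation of PDE synchronization by
linear feedback, with the stability bookkeeping (CFL budgets, quadrature,
Lyapunov monitoring) done carefully.

## Worked example

```python
import selkovsync as sv

params = sv.KineticParams(a=3.5, b=0.25, d1=0.01, d2=1.0)
grid = sv.build_grid(ndim=1, extent=10.0, n_points=51)      # dx = 0.2
tcfg = sv.TimeSteppingConfig.from_cfl(params, grid, t_end=100.0,
                                      snapshot_interval=4.0)

drive_ic = sv.ic_reference_drive(grid)       # (3.5 + 0.1 sin x, 0.28 + 0.1 sin x)
resp_ic = sv.ic_reference_response(grid)     # (1 + 0.5 sin 0.2x, 0.6 + 0.5 sin 0.2x)
gains = sv.ControlGains.from_K(15.0, params)

snaps, series = sv.synchronize(drive_ic, resp_ic, params, gains, tcfg)
print(f"dt = {tcfg.dt:.4f}")
print(f"initial L2 error = {series.l2_error[0]:.4f}")
print(f"final L2 error   = {series.l2_error[-1]:.3e}")
print(f"V monotone non-increasing: {sv.check_monotone_decrease(series).passed}")
print(f"time to 0.001 x initial error: t = {sv.convergence_time(series, 1e-3)}")

report = sv.turing_analysis(params)
print(f"Turing unstable: {report.turing_unstable}, "
      f"max growth rate = {report.max_growth_rate:.4f}")
```

prints

```
dt = 0.0160
initial L2 error = 7.1965
final L2 error   = 0.000e+00
V monotone non-increasing: True
time to 0.001 x initial error: t = 4.0
Turing unstable: True, max growth rate = 0.0957
```

The initial L² error 7.20 measures how far apart the two initial fields
are over Ω = [0, 10]. With gain K = 15 the damping rate −2K = −30 collapses
the error within the first snapshot interval — by t = 4 the response fields
are bitwise equal to the drive fields, so the error is exactly zero from
then on — and the Lyapunov functional never increases. The same parameters
are diffusion-driven unstable (fastest dispersion growth rate ≈ 0.096 at
k² ≈ 36), which is why the drive system itself develops a spatial pattern
while remaining perfectly tracked by the response.

The same run from a shell:

```sh
selkovsync make-config ref.yaml
selkovsync synchronize -c ref.yaml
```

```
grid: 1D, extent 10.0, 51 points/axis (dx = 0.2)
dt = 0.016, CFL ratio dt/dt_max = 0.800
K = 15; initial L2 error 7.1965, final 0
time to 0.001 x initial error: 4
diagnostics written to out/diagnostics.csv
```

`selkovsync simulate` integrates a single system, `selkovsync stability`
writes the dispersion relation, and setting `K: auto` in the config runs
the two-stage gain pipeline (uncontrolled run → sup-bound estimation →
Lipschitz-dominating K).

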