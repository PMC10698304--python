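# Methods

This note documents the models implemented in `aerowalk`, the choices made
where the design was genuinely open, and what the shipped test conditions
do and do not demonstrate.

## Discrete-phase model

Each particle integrates the linear-drag force balance
`du_p/dt = f/τ_p (u_f − u_p) + g(ρ_p − ρ_f)/ρ_p` with
`τ_p = ρ_p d_p²/(18 μ)`. The drag factor uses the Morsi–Alexander
piecewise smooth-sphere coefficients (`particle_dynamics.MORSI_ALEXANDER_COEFFS`,
`C_D = a_1 + a_2/Re_p + a_3/Re_p²`). The law is quoted valid for
`Re_p ≤ 100`; the tracker evaluates it beyond that with a warning, and the
published band constants carry sub-percent seams at the range joins (so
`f(Re_p)` is monotone only to ≈0.7%).

Because the fluid velocity seen by a particle is frozen over one tracking
substep, the balance is linear there and is advanced with its exact
exponential solution (which is simultaneously the correct implicit update
near hydrodynamic equilibrium, `τ_p ≪ Δt`). The scalar integrator
(`particle_dynamics.advance`) wraps this in step-doubling with at most 20
halvings against a 1e-6 relative local error, covering the weak
nonlinearity of `f(Re_p)`; the batch tracker (`tracking.track`) applies
the same update over two half-steps with the drag factor refreshed, which
meets the same tolerance at the step sizes the tracker selects.

Brownian motion, lift, particle rotation, two-way coupling, hygroscopic
growth, and electrostatics are all out of scope by design; the model is
aimed at the micrometer range where turbulent dispersion and impaction
dominate.

## Eddy interaction model and its modifications

The DRW holds a Gaussian vector **G** for the eddy lifetime `t_e = 2T_l`,
`T_l = c_l/(0.09 ω)` with `c_l = 0.15` by default. Interactions end at
`min(remaining lifetime, t_cross)` with the logarithmic crossing-time
formula; the crossing time is evaluated once at eddy birth. A zero-length
eddy (k = 0) is treated as never crossed and never constrains the
timestep, which makes dispersion-off runs bit-identical to runs in a k ≡ 0
field (a tested invariant).

Numerical conventions worth stating:

- **Wall units for the lifetime floor.** The floor is applied as
  `T_l⁺ = T_l u*²/ν ≥ 3` (the standard viscous time scaling); the floor is
  inactive wherever the friction velocity is zero (e.g. homogeneous-box
  diagnostics).
- **Gaussian draws** are untruncated standard normals. Each particle owns
  an independent stream spawned from (master seed, particle index), so
  changing the particle count never reshuffles existing trajectories.
- **Damped wall-normal component.** Below the regional y⁺ limit the
  wall-normal projection of the *same* **G** is reused in the damped form
  (no extra draw), keeping isotropic and damped variants comparable eddy
  by eddy. The damping acts in the local wall frame and is rotated back.
- **NW limit.** Within the NW distance the *total* instantaneous
  wall-normal fluid velocity used for drag is zeroed (mean plus
  fluctuation plus drift); a toggle (`nw_zero_mean=False`) restricts the
  zeroing to the fluctuating part. The NW limit is applied last, so it
  always wins over damping and drift.
- **Drift correction.** The accumulated mean fluctuation
  `Δū_i′ = σ (∂σ/∂x_i) Δt/(1+Stk)` pairs each velocity component with the
  matching gradient component, is reset at eddy birth, and — importantly —
  is incremented *before* the step's velocity is composed. Near walls the
  lifetime floor makes a whole eddy fit in one timestep; with a lagged
  update the correction would silently vanish exactly where it matters.
- **Timestep.** `Δt = min(remaining interaction time, ½·max(y, r_p)/|v_n|,
  flow-through/200)`, where `|v_n|` is the larger of the particle's and
  fluid's wall-normal speed. The wall-normal bound prevents skipping
  eddies or tunneling through the trap test; a particle deposits when its
  center-to-wall distance falls to its radius (interception-style), and
  overshoot past the wall is caught by the same test.

## Flow fields

Analytic duct fields supply the mean axial velocity as the 1/7th power law
matched to the bulk flow rate (`U_c = 60/49·U_bulk`), with the friction
velocity from the Blasius friction factor `f = 0.316 Re^{−1/4}`. The
benchmark pipe is defined by both a flow rate (86.36 L/min → U = 11.36 m/s)
and a nominal Re = 10,000 used in the friction factor, giving
u* = 0.714 m/s. Supported Re range for the closures: 4,000–50,000.

k and ω come from algebraic equilibrium closures (`AnalyticProfile`,
swappable): k⁺ rises as y⁺² in the viscous sublayer, peaks at ≈4.5 near
y⁺ ≈ 15, relaxes to the log-region plateau k⁺ ≈ 1/√C_μ ≈ 3.3, and decays
quadratically across the outer region to a configurable core level
(default k⁺ = 0.8, ≈4.5% turbulence intensity in the benchmark pipe).
ω blends the viscous-sublayer asymptote `6ν/(0.075 y²)` with the log form
`u*/(√0.09 κ y)`. The σ gradient for the drift correction is computed by
central differencing of σ = √(2k/3) with a step of
`min(10⁻³ D, 0.1 y)` so the probe never crosses the wall.

**These closures are a stand-in, not a reproduction, of a RANS solution.**
They exercise every code path of the EIM (the model consumes only k, ω,
y⁺), but absolute deposition levels are highly sensitive to the near-wall
k magnitude and its gradients. Two consequences observed in the shipped
benchmarks: the correlated y⁺ limit for the vertical pipe resolves to ≈7.4
(Re_cell,Vavg ≈ 723, an extrapolation beyond the correlation's calibrated
range of 150–400, which is permitted but logged); and the mid-size
(τ⁺ ≈ 1) pipe deposition is higher than laboratory S-curves, because the
DNS-like buffer-layer k peak drives wall-ward transport just above the
thin damped layer and the drift term adds a mean velocity up the σ
gradient. The S-curve acceptance test records this honestly: the fine
bins (≤2.5 µm) show zero deposition, the 3.6 µm bin does not meet the
"negligible" bound under these field conditions, and the coarse bins
saturate near 100%. A user supplying a CFD-exported field through the
gridded reader replaces exactly this weak link.

The curved-tube field sweeps the same profile along the bend centerline
with solid-body turning: impaction plus dispersion mechanics are
exercised, but Dean vortices are absent, so quantitative agreement with
bend experiments is not claimed.

The cell-centered vs interpolated sampling toggle (and the Table-style
node-interpolation feature column) affects gridded fields only; analytic
fields are exact closed forms, so both modes coincide there. The toggles
are still recorded in the run manifest for provenance. Gridded fields
estimate wall normals and σ gradients by local least-squares over the
8 nearest nodes, and default the friction velocity to the equilibrium
estimate `u* = C_μ^{1/4}√k` when no value is supplied.

## y⁺-limit correlation

`field_stats` implements the shell volume average (cells with y⁺ ≤ 100 by
default — enough to include the viscous and buffer layers while excluding
the core), the wall-distance cell Reynolds number `Re_i = y_i|u_i|ρ/μ`,
the linear correlation `y⁺_lim = max(0, 0.0122·Re − 1.4098)` and the
quadratic alternative `3.7964×10⁻⁵Re² − 8.7033×10⁻³Re + 1.2801`. Both are
floored at zero (the quadratic's printed minimum is positive, so its floor
is moot; it is kept for uniformity). Region partitioning is user-supplied:
the package does not segment geometry automatically. An exponential
regression variant quoted alongside these forms overflows as printed and
is deliberately not implemented.

## Benchmark cases and study conditions

The vertical-pipe case is D = 1.27 cm, L = 102 cm, 86.36 L/min
(nominal Re 10,000), bins {1.4, 2.5, 3.6, 5.3, 7.2, 10.1, 14.0} µm at
10,000 particles per bin by default, trap walls, gravity aligned with the
mean flow. The curved tube is D = 5.03 mm, bend ratio 5.7, 10-diameter
extensions, inlet 17.42 m/s (Re ≈ 6,000), 5,000 particles per bin, zero
gravity by default; its default bins (1.0–9.0 µm) span the
impaction-relevant Stokes range. Particle density is a required argument
with no silent default (the benchmark aerosols' densities are not part of
the case definition); tests and the acceptance script use 920 kg/m³
(olive-oil droplets of the classic vertical-pipe deposition experiment)
and 895 kg/m³ (oleic-acid aerosol of the classic bend experiment).

Injection draws positions uniformly over the inlet cross-section of
radius `R − d_p/2` — a particle center cannot sit within its own radius of
the wall, and without the cap a no-dispersion run would show spurious
instant deposition. Initial velocities are axial at the local 1/7th-law
magnitude. Each particle carries its bin's mass weight divided by the bin
count, so DE/DF are mass-based; explicit bin lists default to equal mass
weights, and a lognormal constructor (default MMAD 1.72 µm) builds
equal-mass quantile bins. Particles still suspended after 20 flow-through
times are reported separately and flag the run as failed rather than
being booked anywhere.

Test and acceptance runs use reduced problem sizes — typically 7×500 to
7×2,000 particles for pipe runs and 10⁴ tracers for the statistical
properties — chosen so the full suite completes in minutes while keeping
Monte-Carlo error well inside the asserted tolerances.

## Diagnostics

`diagnostics.taylor_dispersion` tracks inertia-free tracers through
synchronized eddies in homogeneous turbulence; the long-time mean squared
displacement per axis must grow as `2(2k/3)T_eff·t`, where the tests
compute `T_eff` from an independent brute-force simulation of the eddy
velocity autocorrelation (for this renewal process the triangular
autocorrelation gives `T_eff = t_e/2 = T_l`). `stationary_concentration_1d`
places tracers in a linear σ(x) gradient with specularly reflecting ends:
without the drift correction the stationary concentration follows ≈1/σ(x)
(the classic DRW over-concentration artifact); with it the histogram's
coefficient of variation drops by about a factor of three.

## Known limitations

- Analytic k/ω closures stand in for a CFD flow field; absolute deposition
  levels inherit their uncertainty (see above). The gridded reader is the
  documented path to full fidelity.
- The tracking loop requires a duct-like field (arc-length coordinates and
  an inlet frame); gridded fields currently support sampling, not the
  benchmark tracking loop.
- Presets without the eddy-lifetime floor run with physically tiny
  near-wall eddies and are correspondingly slow when dispersion is on.
- No continuous-random-walk variant; no wall roughness; no re-entrainment
  of deposited particles.
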