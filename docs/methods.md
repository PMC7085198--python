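# Methods

## The model

`stenoflow` simulates pulsatile blood flow through an idealized symmetric
coronary stenosis and computes fractional flow reserve (FFR), contrasting
two representations of what lies downstream of the epicardial vessel:

* **PL (pressure load)** — the conventional outflow boundary: a constant
  static pressure (3333 Pa ≈ 25 mmHg, a venular level) at the distal end.
* **ML (microcirculation load)** — the microvascular bed is carried inside
  the domain as a porous segment appended to the distal vessel; the far
  boundary behind the bed is at 0 Pa and the entire outlet impedance comes
  from the bed's Darcy drag.

The flow is laminar, incompressible and axisymmetric; walls are rigid and
no-slip. The domain and all boundary conditions are rotationally symmetric
and the Reynolds number stays in the laminar range (throat Re ≈ 400–700),
so the governing equations are solved in cylindrical (z, r) coordinates.
The reduction from a 3D mesh to an axisymmetric one is the main
cost-saving design decision of this package: it preserves the physics of a
symmetric stenosis while making a full pulsatile run a few minutes on one
CPU.

### Geometry

A piecewise-linear ("trapezoidal") radius profile: proximal straight
segment of radius r_p = 1.4 mm, linear taper over l_c = 1.5 mm to a throat
of radius r_s = 0.7 mm and length l_s = 1.2 mm, linear expansion over
l_d = 3 mm back to r_d = 1.4 mm, then a distal straight segment and
(ML only) the porous bed. Area stenosis AS = (r_p² − r_s²)/r_p² × 100 = 75%
for the reference radii.

The straight-segment lengths are not physically constrained by the
stenosis itself and are free parameters: defaults L_prox = L_dist = 14 mm
(five proximal diameters for inlet development; the distal run gives the
post-stenotic jet room before the outlet).

### Blood rheology

Carreau shear-thinning viscosity
μ(γ̇) = μ∞ + (μ0 − μ∞)[1 + (λγ̇)²]^((n−1)/2) with the standard literature
constants for whole blood: μ0 = 0.0560 Pa·s (zero-shear), μ∞ = 0.00345 Pa·s
(infinite-shear), λ = 3.313 s, n = 0.3568; density ρ = 1060 kg/m³. The
scalar shear rate is the second invariant γ̇ = √(2 D:D) of the axisymmetric
strain-rate tensor, including the hoop component u_r/r.

### Microcirculation bed

The bed is an isotropic porous medium with porosity φ = 0.5 and
representative microvessel diameter d = 100 µm, giving a Kozeny–Carman
permeability k = d²φ³/(180(1−φ)²) ≈ 2.78·10⁻¹¹ m². Within the bed the
momentum balance is the φ-weighted (physical-velocity) porous form whose
sink is (φ²η/k)u; with constant φ inside the zone, dividing by φ leaves
the ordinary Navier–Stokes equations plus a volumetric drag (φη/k)u, which
is what the solver assembles. Two consequences worth noting:

* The steady uniform-flow pressure gradient inside the bed is exactly
  φηu/k; this closed form is the porous oracle used in the tests.
* The pressure is continuous across the lumen/bed interface (the pressure
  term is φ∇p, not ∇(φp): the latter would imply a spurious pressure jump
  of order (1−φ)p at the interface). The small momentum-flux jump ρu²Δφ
  (~80 Pa here, ≈2% of the bed's drop) is neglected.

**η in the bed defaults to the constant μ∞**, not the local Carreau value.
Rationale: shear rates in 100 µm vessels are O(10³ s⁻¹), where blood is
effectively Newtonian at μ∞; and a shear-dependent η in a plug-flow slab is
numerically ill-posed — the interior shear tends to zero over a Brinkman
length √k/φ ≈ 10 µm, so the drag would flip between μ∞-like and μ0-like
(a factor 16) depending on how well that microscopic layer is resolved.
A `porous_eta: carreau` switch restores the shear-dependent option.

**Bed length.** The porous segment length L_porous is the one genuinely
free parameter of the ML configuration: the printed porous properties fix
the drag per unit length (φημ∞/k ≈ 1.7·10⁷ Pa/m per 0.28 m/s), so the bed's
total resistance — and with it the absolute coronary pressure level — is
set by its length. The default, L_porous = 0.2 mm, is chosen so that the
Darcy drop at the cycle-mean velocity puts the mean distal pressure near
the physiological ≈3.5 kPa (26 mmHg) operating point; note this is the same
pressure level the PL case imposes directly (3333 Pa). FFR is sensitive to
this choice (it → 1 as L_porous grows); the acceptance script writes an
FFR-vs-L_porous sensitivity table, and the test suite asserts the
monotonicity.

### Inlet waveform

Only four statistics of the coronary inlet velocity are prescribed: peak
0.46, mean 0.28, trough 0.13 m/s, period 0.8 s (heart rate 75/min). The
default synthesis is a C1 piecewise raised-cosine — a systolic dip to the
trough over a fraction f_s of the cycle followed by a diastolic hump to the
peak — whose junction level follows from the mean constraint in closed
form, so all three statistics are met exactly for every admissible triple.
f_s defaults to 0.35 and is moved inside its feasibility interval
(1 − 2β < f_s < 2 − 2β, β the normalized mean position) when needed. The
peak falls at (1 + f_s)/2 of the cycle — diastolic, as coronary flow is.
A two-harmonic Fourier template (`shape: fourier2`) is available. The
radial inlet shape is parabolic (fully developed) by default, normalized so
the cross-section mean equals the waveform value; a plug option exists.

### FFR

FFR = (P̃_d − P_v)/(P̃_a − P_v) with P̃ the time-averaged cross-section
pressures over the statistics cycle and P_v = 0. Probe planes default to
3 mm upstream of the converging-section start and 3 mm downstream of the
diverging-section end. Reports carry each plane's peak, trough,
fluctuation range (peak − trough) and fluctuation percent (range/peak ×
100 — the definition that reproduces all four percent cells printed in the
reference results table).

## Numerics

Finite-volume discretization on a body-fitted structured grid: radial
lines are fixed fractions of the local wall radius (geometric clustering
toward the wall, ratio 1.08); cell volumes and face areas carry the
cylindrical metric exactly (Simpson quadrature is exact for the
piecewise-linear wall, so the grid volume matches the analytic solid of
revolution to round-off at any resolution).

Axial resolution: base nz_per_mm = 4 with the converging/throat/diverging
block refined 2×; the long proximal/distal feeds grade geometrically
(ratio 1.15, capped at 4× the base spacing) away from the stenosis. When a
porous bed is present, the distal grading is two-sided so the cell size is
continuous across the bed interface — a large spacing jump there was found
to destabilize the pressure–velocity coupling. The bed itself always
receives at least 4 axial cells. Radial default nr = 32.

Time integration is implicit backward Euler at dt = 0.0032 s, 247 steps
per cycle, with a BDF2 option. Each step iterates SIMPLEC-type
pressure–velocity coupling (collocated variables, Rhie–Chow face fluxes)
with Picard updates of convection and viscosity until all scaled residuals
fall below 10⁻⁵ (momentum residuals normalized by Σ|a_P u_P|, continuity
by the mean inflow — the standard scaled-residual convention). Convection
is implicit first-order upwind plus a deferred central correction (blend
0.9) except on faces at the porous interface, which stay first-order;
diffusion uses over-relaxed non-orthogonal decomposition with explicit
cross terms; the variable-viscosity transpose-stress and hoop terms are
carried explicitly; the Darcy sink and hoop viscous terms are implicit.

Face pressures in the momentum equation are gradient-corrected from both
sides, and at the bed interface — where the Darcy sink makes ∂p/∂z
discontinuous — they are reconstructed from one-sided axial gradients,
which is exact for piecewise-linear pressure. With this treatment the
uniform-seepage solution (plug flow through a porous tube with slip walls)
is an exact discrete solution.

Linear systems are solved with SuperLU; within a time step the step-start
factorizations precondition BiCGStab on the freshly assembled systems.
Velocity under-relaxation 0.9; pressure-correction update relaxed by 0.7.
Runs start from rest at the outlet pressure; three cycles are simulated and
statistics come from the last (cycle-mean probe pressures change by <0.1%
between cycles 2 and 3). A replication mode (single cycle from rest)
mirrors the reference protocol. Everything is deterministic — there is no
randomness anywhere in the pipeline.

Grid convergence: the steady mean-flow FFR changes by ~0.002 between the
default grid and one uniform doubling of both resolutions (the acceptance
suite recomputes this), and the steady stenotic pressure drop at the mean
flow is ~840 Pa, close to the reference value.

## What the defaults reproduce (and what they do not)

With all defaults, the package's own transient runs give FFR ≈ 0.77–0.78
for the PL case and a strictly larger FFR for the ML case, with stenotic
pressure drops and fluctuation ranges in the neighbourhood of the reference
study's values. Exact agreement with a commercial 3D solver is not
expected: probe-plane placement, the unreported domain lengths and bed
length, and discretization all shift the third decimal of FFR. The
qualitative contrasts — microcirculation load raises FFR, damps
post-stenotic velocity, and passes the inlet pulsatility into much wider
pressure fluctuation ranges — are robust to those choices.

The synthetic inlet waveform honours only the four published statistics,
not the full measured trace morphology; conclusions that depend on
intra-cycle timing (e.g. instant of peak pressure) are therefore
template-dependent, while cycle statistics (means, extrema, FFR) are not.

## Degenerate inputs and guards

Non-positive lengths/radii, throat wider than the lumen, porosity outside
(0, 1), inadmissible waveform orderings, PL with a porous segment (or ML
without one), probes outside the domain and under-resolved grids all raise
typed configuration/domain errors. Convergence failure raises an error
naming the worst residual; NaN detection raises a divergence error.

## Known limitations

* Rigid walls: no fluid–structure interaction, so systolic–diastolic
  compliance effects are absent.
* Axisymmetric: bifurcations, curvature and non-axisymmetric jet
  instabilities (which appear at higher Reynolds numbers) are out of scope.
* The porous bed is homogeneous and isotropic with a single length scale;
  real microvascular beds are hierarchical and autoregulating.
* First-order time integration by default; the waveform statistics and
  cycle means are insensitive to this at 247 steps/cycle.
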