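# Methods

`fsgsim` simulates the mechanobiological state and evolution of an
intracranial aneurysm (IA) with a fluid-solid-growth (FSG) model: slow
growth-and-remodelling (G&R) laws, driven by wall-shear-stress (WSS)
metrics, evolve the composition and natural configuration of a
fiber-reinforced wall, which is re-equilibrated quasi-statically at
diastolic and systolic pressure after every G&R step.  This note records
the model, its assumptions, the parameter choices that are the package's
own, and what the idealized desk-scale setting does and does not show.

## Wall constitutive model

The wall is a two-layer (media, adventitia) nearly incompressible
composite.  Kinematics use the isochoric/volumetric split
`F = J^(1/3) F̄`, with modified invariants `Ī₁`, `Ī₂` and, per collagen
fiber family with reference direction `mⁱ`, the pseudo-invariant
`Ī₄ⁱ = mⁱ·C̄mⁱ` and fiber stretch `λ̄₄ⁱ = √Ī₄ⁱ`.

Per layer `L`, the strain energy is

```
Ψ_L = (m_{L,e} K_{L,e} + m_{L,sm} K_{L,sm}) (Ī₁ − 3)            isotropic matrix
    + m_{L,c} Σᵢ ∫ ψ̃(λ̄₄c) ρ_rec(λ̄₄r) dλ̄₄r                     collagen ensemble
    + κ/4 (I₃ − 1 − 2 ln √I₃)                                   volumetric
```

where the `m`'s are normalized mass densities (1 in healthy reference
tissue), the `K`'s stiffness-like constants in MPa, and `κ` the bulk
modulus.  Each collagen fiber is linear in the first Piola–Kirchhoff
sense once recruited, `ψ̃ = K_c/2 (λ̄₄c − 1)²` with fiber stretch
`λ̄₄c = λ̄₄/λ̄₄r` (floored at 1: a wavy, unrecruited fiber bears no load),
and the recruitment stretches `λ̄₄r` follow a triangular density with
parameters (min, mode, max).  Integrating the ensemble analytically gives
a four-branch piecewise expression for `∂Ψ/∂Ī₄`: zero below the
recruitment minimum, two log-polynomial toe branches while fibers are
progressively recruited, and an affine first Piola–Kirchhoff stress once
all fibers are recruited.  The branch constants (`c₁ … c₁₀` in
`mechanics.branch_coefficients`) were derived once by symbolic
integration and are validated in the test suite against adaptive
quadrature of the defining integral to 1e-8 relative tolerance.  Near the
recruitment minimum the closed form cancels to third order, so the
rising-branch moment integrals switch to series expansions below
`(v−a)/a < 1e-4` to keep full relative precision.

A degenerate distribution (min = mode = max) is treated as a
single-recruitment (Heaviside) family with its own analytic branch.

Stress is assembled as `S = 2 ∂Ψ/∂C` with the standard deviatoric
projector of the isochoric split, `Dev(A) = J^(-2/3)(A − (A:C)/3 C⁻¹)`,
applied to the matrix and fiber terms, and `S_vol = κ/2 (I₃−1) C⁻¹`.

**Bulk modulus.** Because the fiber law has constant stiffness once all
fibers are recruited, a bulk modulus can be chosen that keeps volumetric
changes small without locking; the default is `κ = 100 × K_c` per layer
(configurable).  The thick-shell runs here keep `|J − 1|` near 0.1%, well
inside the 2% near-incompressibility budget.

## Flow metrics

The WSS vector is the tangential traction `τ = ση − ((ση)·η)η`.  Over a
cardiac cycle `[0, T]` its tip traces a rosette at each wall point; the
wall shear stress aspect ratio (WSSAR) is the ratio of the smaller to the
larger peak-to-peak projection range along two orthogonal in-plane
principal directions: 0 for uni-directional flow, 1 for fully
bi-directional (rotating) flow.

The principal direction `η₁` maximizes `∫ τ·η dt` over a discretized
in-plane angle sweep (0.5° default; a 10× finer sweep agrees to within
one coarse step).  The signed integral vanishes identically for centred
rosettes (symmetric oscillation), so the default "auto" mode falls back
to maximizing the peak-to-peak projection range whenever the signed
integral is below 5% of the magnitude integral; an explicit
`|projection|`-integral variant is also selectable.  The range criterion
is exact for sample-aligned axes, which makes the uni-/bi-directional
limit cases exact: 0 and 1 to machine precision on the canonical 200
samples/cycle grid.  A zero-flow series returns WSSAR 0 with a
`degenerate` flag (no flow, no degradation signal); a rosette whose
objective is flat in the angle is flagged `isotropic`.

Two quadratic stimulus functions map flow metrics to a degradation signal
in [0, 1]:

* low-WSS law: 1 below `τ_L = 0.5 Pa`, 0 above `τ_C = 1 Pa`,
  `((τ_C − ‖τ‖)/(τ_C − τ_L))²` between;
* WSSAR law: 0 below `τ_C,AR = 0.7`, 1 above `τ_H,AR = 0.8`, quadratic
  between.  The WSSAR thresholds are dimensionless (the metric is a
  ratio).

Time integrals use the trapezoid rule on the sampled series and extrema
are sample extrema — no interpolation, matching CFD output cadence.

## Growth and remodelling laws

Explicit Euler at `dt = 0.02` year (refinement factor available; the
Euler trajectories converge at first order to the closed-form
exponentials, verified in tests).

1. **Degradation** `∂m/∂t = −F_X · D_max · m` with `D_max = 1.5 /yr`,
   applied to elastin, collagen and smooth-muscle masses alike in both
   layers; `F_X` is the scenario's stimulus (low-WSS or WSSAR —
   exclusive per run).
2. **Recruitment remodelling** drives the fiber-stretch distribution
   toward the attachment (homeostatic target) distribution at rate
   `α₀ = 10 /yr`, with the cross-pairing: the distribution's *minimum*
   recruitment stretch is driven by the mismatch of the *maximum* fiber
   stretch, and vice versa.  The stats are evaluated at whichever of the
   diastolic/systolic configurations maximizes the fiber stretch,
   pointwise per step.
3. **Collagen growth** `∂m_c/∂t = ε m_c (λ̄₄f − λ̄₄f,att)/λ̄₄f,att` at
   systole, with the fibroblast natural configuration identified with
   the maximally stretched collagen fibers.  The reference
   parameterization sets `ε = 0`, so this law is inert by default.
4. **Attachment adaptation** (stabilization): a discrete per-step map
   `att ← att + α_att (λ̄₄c − att)` per quantile, `α_att = 0.5`, applied
   only during the stabilization window.

**Clamping convention.** The stress law floors fiber stretches at 1
(compressed/wavy fibers bear no load).  The remodelling laws use the
*raw* ratio `λ̄₄/λ̄₄r`: the physiological parameter tables prescribe
attachment minima below 1 (the protective parent adventitia is configured
slack), and those targets are only meaningful for the unclamped ratio —
with clamping active in the remodelling laws the homeostatic fixed point
`λ̄₄r = λ̄₄/att` would not exist wherever `att < λ̄₄` is required to dip
below 1.  Recruitment stretches themselves are floored at 1 (with a
warning) and re-ordered after every update; a point whose attachment
target would need recruitment below 1 settles at this *constrained* fixed
point, which is stationary and counts as (constrained) mechanobiological
equilibrium.

## Idealized geometry and membrane equilibrium

The desk-scale stand-in for a 3-D FEM solve is a two-layer axisymmetric
surface parameterized by a meridian coordinate `s ∈ [0, 1]`, split into
*parent artery* (cylindrical), *neck* (blend band) and *dome*
(sphere-like) regions.  Default dimensions — the package's own choice, as
the source setting is patient-specific: parent lumen radius 2 mm, sac
bulge height 2 mm (an ~8 mm dome on a 4 mm-diameter vessel, a typical
detected IA), uniform thickness 0.15 mm (media) + 0.10 mm (adventitia).
These were fixed by requiring that the *detected aneurysm be mechanically
stable*: with a 4 mm bulge the homeostatic apex stretch approaches 2
(marginal), contradicting the stable-IA premise; with 2 mm it is ~1.10.

Material parameters interpolate linearly (componentwise, including the
stretch triples) between the parent and dome tables through the neck.
Fiber families sit at ±30° (media) and ±60° (adventitia) about the
circumferential direction in the parent; on the dome they follow the
principal curvature directions of the axisymmetric surface
(circumferential and meridional), with the same pair used as the
documented fallback at the umbilic apex; neck angles interpolate along
the shortest rotation.

Equilibrium per material point solves a blended Laplace system in the
in-plane stretch pair `(λ_θ, λ_m)`:

```
(N_θ + w N_m)/r = P        hoop/normal balance   (w: 0 cylinder → 1 sphere)
2 N_m / r       = P        meridional balance (closed cap / closed tube)
```

with stress resultants `N = Σ_L σ_L h_L` integrated through both layers
(`h_L = λ_r H_L`), `r = λ_θ R` the current local radius, and pressures in
Pa converted to the MPa stress scale internally.  The radial stretch
comes from a through-thickness condition: the default "thick" variant
solves `σ_rr = −P/2` (the thickness-averaged radial stress between the
loaded inner and free outer face) by an inner safeguarded 1-D
Newton/bisection — the radial residual is governed by the bulk penalty
and is orders of magnitude stiffer than the membrane residuals, and
nesting it removes that stiffness from the outer iteration; the
"membrane" variant enforces `J = 1` exactly with a per-layer plane-stress
reaction.  The outer 2-D Newton uses forward-difference Jacobians, a 10%
relative trust region on the stretch increments, and warm starts from the
previous configuration; all points advance simultaneously as vectorized
fields.  Tolerance: residual below 1e-8 of the applied pressure.

Assumptions worth keeping in mind: in-plane shear is neglected (the
deformation gradient is kept principal in the circumferential/meridional
frame — exact for the symmetric ±α parent pairs and the 0°/90° dome pair,
approximate in the neck, where non-symmetric interpolated pairs would
shear); the cut parent ends are represented by the cylindrical closed-tube
balance rather than a clamped boundary (no membrane analogue exists); the
reference configuration is the idealized unloaded geometry (no
pre-stressing problem).

## Hemodynamic surrogate

A reduced-order WSS source replaces the CFD solver.  The parent-artery
level is the Poiseuille estimate `τ = 4μQ/(πr³)` at the current parent
radius (blood: ρ = 1066 kg/m³, μ = 3.5×10⁻³ Pa·s, mean inflow
2.54×10⁻⁶ m³/s → ≈1.4 Pa at 2 mm).  Into the sac the magnitude decays as
`exp(−β · depth · r/r_parent)`; the *effective depth* grows with the
deformed radius, so enlargement lowers and widens the low-WSS region —
the feedback loop that localizes and sustains degradation.  The
oscillatory cross-direction ratio (which the WSSAR scenario consumes)
grows with the same effective depth and saturates at a ceiling.

Surrogate constants are the package's own, fixed once by the criterion
that the detected aneurysm be *marginally* destabilized at t = 0:

* `β = 0.15` puts the initial apex WSS at ≈0.9 Pa — just inside the
  degradation band;
* oscillation gain 0.35 puts the initial apex WSSAR at ≈0.73, just above
  its activation threshold;
* oscillation ceiling 0.75: perfect bidirectionality is an idealized
  limit that a deepening sac's still-directional recirculation does not
  reach; the ceiling also keeps the WSSAR stimulus off its maximum.

The rationale is a capacity argument (see Limitations): a pointwise
membrane saturates at roughly 3.5× the homeostatic wall tension, so a
point held at maximal stimulus for the full 2-year degradation window
(mass × 0.05) must pass a limit point.  Marginal onset with
feedback-driven ramp-up is the desk-scale configuration consistent with
both the stable-detection premise and subsequent enlargement.

Cardiac waveform: period 0.8 s, 200 samples per cycle (0.004 s; three
cycles = 600 samples), smooth two-harmonic pulse with configurable
amplitude ratios; means are exact by construction (mean outlet pressure
9752.285 Pa — the mean of the two printed steady outlet values; pressure
pulsatility ±20% of the mean, giving ≈8.39/11.70 kPa diastole/systole —
a physiological ~25 mmHg pulse around a 73 mmHg mean).  The sample grid
includes both period endpoints so periodic trapezoid integrals vanish to
machine precision.

## Simulation schedule

Three phases over 3 simulated years at dt = 0.02 yr (150 steps):

1. **Initial homeostasis** — fixed-point iteration alternating
   equilibrium (both pressures) and recruitment remodelling until the
   effective recruitment update falls below 1e-3 (relative).  The default
   sac converges in 27 iterations; the dome adventitia reaches its
   attachment triple (modal fiber stretch 1.05) exactly, constrained
   entries (see clamping) settle pinned at recruitment 1.
2. **Degradation** — steps 1–100 (2 years).  Flow metrics refresh every
   20 steps from the current deformed geometry.
3. **Stabilization** — steps 101–150 (1 year).  Attachment adaptation is
   active; the degradation stimulus is off in this window (with it on,
   masses keep decaying, stretches keep growing, and no equilibrium of
   the combined system exists — switching it off is what lets the
   remodelling-rate norm contract below 1e-3/yr, which it does here to
   ~1e-15/yr).  The resulting attachment field is spatially
   heterogeneous and elevated above the initial table values.

Checkpoints (HDF5) contain every evolving array including the cached flow
metrics, so a restarted run reproduces the remaining trajectory
bit-identically; the only stochastic element (fixture noise) is seeded
per point and per spec, never carried as hidden RNG state.

## Numerical choices and degenerate inputs

* Triangular density with min = mode or mode = max: the empty sub-branch
  drops out of the closed forms automatically; min = max uses the
  Heaviside branch.  The density itself reports a point mass as `inf` at
  the atom.
* Zero-pressure equilibrium returns identity stretches exactly.
* Zero sac height builds a plain cylinder labelled parent throughout; a
  zero neck fraction produces a hard parameter jump with a warning.
* Recruitment updates are floored at 1 and re-ordered
  (min ≤ mode ≤ max) after every step; attachment updates are re-ordered
  likewise.
* `D_max · dt < 1` is enforced so explicit Euler preserves mass
  positivity.

## What the synthetic setting shows — and does not

The generators emulate: prescribed-bidirectionality rosettes (elliptical
tip paths whose WSSAR equals the cross-amplitude ratio exactly),
pulsatile waveforms with exact means, and the monotone WSS-enlargement
feedback of a deepening sac.  They do not emulate: spatial WSS patterns
of real aneurysm CFD (impingement, vortex migration), non-Newtonian or
transitional flow, measurement noise structure, or patient geometry.
Passing tests therefore demonstrate the correctness of the constitutive
closed forms, the metric definitions, the G&R laws and their coupling —
not predictive validity for any real aneurysm.

## Known limitations

* **Pointwise statics.** Each material point carries its local Laplace
  load alone.  The affine ensemble stress times the thinning wall gives
  a *bounded* maximum tension (∝ collagen mass), so sustained maximal
  degradation must eventually pass a limit point — there is no spatial
  redistribution as in a 3-D FEM.  The simulator detects this honestly
  (equilibrium failure aborts with the saved trajectory); the default
  study conditions avoid it by marginal-onset feedback, which also means
  the simulated enlargement (≈8% apex radius growth under the low-WSS
  scenario, ≈25% under WSSAR) is more modest than patient-scale results.
* Dome attachment values: the parameter tables (used as defaults) and
  the narrative text disagree in one entry (1.0 vs 1.01 for the
  adventitial minimum); the tables win.
* The attachment "mean" of the parameter tables is identified with the
  triangular distribution's mode.
* No bending stiffness, contact, fluid-structure interaction, exponential
  fiber laws, fiber-angle dispersion, or active smooth-muscle tone.
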