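# Methods

This document describes the models and numerical methods implemented in
`cardiogrowth`: an anisotropic, stretch-driven volumetric growth model coupled
to a biventricular electromechanics simulator on synthetic idealized geometry.
Everything runs on plain `numpy`/`scipy`; the finite-element core is
implemented in the package itself.

Units: mm, ms, kPa (1 mmHg = 0.1333 kPa), days for the growth time scale.
Volumes are reported in ml (1 ml = 1000 mm³).

## 1. Geometry and microstructure

### Meshes (`cardiogrowth.geometry`, `cardiogrowth.mesh`)

Three structured tetrahedral presets are provided:

- `sphere_shell` — a truncated thick spherical shell (fast test geometry),
- `lv_ellipsoid` — a truncated thick-walled prolate ellipsoid (left ventricle),
- `biventricle` — the ellipsoidal LV plus a crescent-shaped right-ventricular
  free wall offset from the LV epicardium over an azimuthal sector. The
  unmeshed gap between the LV epicardium and the RV free wall is the RV
  cavity, open at the base.

All presets are built from a structured (transmural × longitudinal ×
circumferential) block decomposition; each hexahedral cell is split into
tetrahedra with consistent positive orientation. Cells carry region tags
(`LVFW`, `SEPTUM`, `RVFW`: the LV cells inside the RV sector are the septum)
and boundary facets carry surface tags (`lv_endo`, `rv_endo`, `epi`, `base`).
`biventricle(resolution=h)` selects subdivision counts so the typical edge
length is about `h` mm (smaller `h` = finer mesh).

The default LV endocardial semi-axes (`a_endo = 25.8`, `c_endo = 50` mm,
truncated at `z_base = 15` mm, wall 10 mm) are sized so the unloaded LV cavity
volume is 100 ml by the closed-form truncated-ellipsoid formula
(`truncated_ellipsoid_volume`); the crescent RV (4 mm wall) encloses a
comparable cavity.

Cavity volumes are measured with the divergence theorem on the closed
endocardial surface: the open basal rim is closed by a fan of triangles to a
fixed apex point on the base plane, and
`V = (1/3) ∮ x · n dA` is evaluated on the deformed surface. The same
expression, written in terms of the P2 displacement field, supplies the exact
volume constraint and its derivatives for the mechanics solver.

### Fiber architecture (`cardiogrowth.fibers`)

Myofiber orientation follows a rule-based description. For each quadrature
point a local wall coordinate system (transmural direction `e_t`, apicobasal
`e_l`, circumferential `e_c`) is computed from the level sets of a normalized
transmural coordinate `d ∈ [0, 1]` (0 = endocardium, 1 = epicardium). The
fiber angle rotates linearly across the wall,

    alpha(d) = 60° − 120° d ,

(+60° at the endocardium to −60° at the epicardium, as in standard
rule-based fiber models). `f0` is the fiber direction in the local tangent
plane, `s0` the outward transmural sheet direction, `n0 = f0 × s0`; the triad
is orthonormalized at every quadrature point. After a growth step the triad
is pushed forward through the elastic deformation and re-orthonormalized.

## 2. Electrophysiology (`cardiogrowth.ep`)

Action-potential propagation uses the two-variable Aliev–Panfilov model in a
monodomain reaction–diffusion equation for the normalized transmembrane
potential `phi` and recovery variable `r`:

    dphi/dt = div(D grad phi) + c phi (phi − alpha)(1 − phi) − r phi
    dr/dt   = (eps0 + mu1 r / (mu2 + phi)) (−r − c phi (phi − b − 1))

with a transversely isotropic conductivity `D = d_iso I + d_ani f0 ⊗ f0`
(conduction is faster along the fiber). The dimensionless model time is
mapped to milliseconds by a calibrated `time_scale`.

Discretization: linear (P1) finite elements with mass lumping,
operator-split forward-Euler reaction + implicit diffusion step (the
diffusion operator is factorized once with a sparse LU). A stimulus is a
small vertex set around the pacing site. Activation time `t_init` at each
vertex is the linearly interpolated crossing of `phi = 0.5` on the upstroke.
`d_iso`, `d_ani` and `time_scale` are calibrated so a septal (normal)
initiation activates the default biventricle in ≈ 80 ms and an LV-free-wall
pacing site prolongs total activation, reproducing the dyssynchrony of
single-site pacing.

The nodal activation map is interpolated to mechanics quadrature points and
enters the active-stress law as the local activation delay.

## 3. Solid mechanics (`cardiogrowth.mechanics`)

### Passive behavior

The myocardium is a transversely isotropic Fung-type (Guccione) hyperelastic
material, nearly incompressible. With Green–Lagrange strain `E` expressed in
the microstructural frame,

    W = C/2 (exp(Q) − 1),
    Q = b_f E_ff² + b_xx (E_ss² + E_nn² + E_sn² + E_ns²)
        + b_fs (E_fs² + E_sf² + E_fn² + E_nf²)

with defaults `C = 0.2` kPa, `b_f = 29.8`, `b_fs = 14.3`, `b_xx = 13.3`.
Incompressibility is imposed on the *elastic* volume change `J_e` with a
pressure field `p` (see §5).

### Active stress

Active contraction adds a rank-one second Piola–Kirchhoff stress along the
fiber,

    S_act = T(t_sa, l) / lambda_f² · f0 ⊗ f0 ,

where `t_sa = t − t_init` is the time since local activation and `l` the
current sarcomere length (`l = l_s0 · lambda_f` with slack length
`l_s0 = 1.85` µm). The twitch tension is

    T = (T_max/2) · Ca_factor(l) · (1 − cos omega(t_sa, l)),

where `Ca_factor` is a length-dependent calcium sensitivity term (zero at and
below the zero-tension length `l_0 = 1.58` µm, saturating for long
sarcomeres — the Frank–Starling effect) and `omega` is a piecewise phase
schedule: rise over `t_0 = 150` ms, relaxation over a length-dependent
duration `t_r = m·l + b_rel`, and zero outside the twitch. By construction
`T(t_sa ≤ 0) = 0` and `0 ≤ T ≤ T_max`.

`T_max = 260 kPa` is calibrated on the default coarse biventricle (quadratic
elements on a coarse structured mesh are effectively stiffer than the
continuum) to give physiological function: LV ejection fraction ≈ 46%, peak
LV pressure ≈ 155 mmHg at 8 mmHg filling.

## 4. Growth law (`cardiogrowth.growth`)

Growth follows the multiplicative split `F = F_e F_g` with a growth tensor
diagonal in the microstructural frame:

    F_g = theta_f f0⊗f0 + theta_s s0⊗s0 + theta_n n0⊗n0 .

The stimulus is the maximum *elastic* myofiber stretch over a beat,
`lambda_f,max`, measured from the end-diastolic configuration. Its deviation
from a local homeostatic set point `lambda_f,h` (recorded once from a
normally activated beat) drives all three multipliers:

    d theta_i / dt = k_i(theta_i) · (lambda_f,max − lambda_f,h)

with the rate-limiting function (forward branch for positive deviation,
reverse branch for negative)

    k_i = (1/tau_g,i)  · [(theta_max − theta_i)/(theta_max − theta_min)]^gamma   (growth)
    k_i = (1/tau_rg,i) · [(theta_i − theta_min)/(theta_max − theta_min)]^gamma   (reverse)

Bounds `theta ∈ [0.5, 2]`, `gamma = 1`. The default time constants are
anisotropic and asymmetric: the fiber direction grows fast and reverses
slowly (`tau_g = 3.8` d, `tau_rg = 9.6` d), the transverse directions the
opposite (`tau_g = 9.6` d, `tau_rg = 3.8` d). `GrowthParams.with_equal_rates()`
produces the symmetric-rate variant `tau_rg = tau_g` used for comparison.

For `gamma = 1` and a constant deviation `s` the law integrates in closed
form to an exponential approach toward the bound,

    theta(t) = theta_max − (theta_max − theta_0) · exp(−s t / (tau_g (theta_max − theta_min)))

(mirror image toward `theta_min` for reverse growth), giving the analytic
oracle `closed_form_theta` for the explicit-Euler integrator `evolve_growth`
and the half-life

    t_1/2 = tau ln 2 (theta_max − theta_min) / |s| .

## 5. Finite-element cardiac cycle (`cardiogrowth.fem`, `cardiogrowth.cycle`)

### Discretization

Total-Lagrangian quasi-static finite elasticity on Taylor–Hood tetrahedra:
quadratic (P2) displacement, linear (P1) pressure, 4-point quadrature. The
weak form of equilibrium with the growth-split constitutive law evaluates
`F_e = F F_g⁻¹`, the passive + active second Piola–Kirchhoff stress in the
grown intermediate configuration, and pulls back to the reference with
`det F_g` weighting.

Incompressibility of the elastic deformation is imposed with a *perturbed
Lagrangian*: the pressure unknown acts through `p_eff = p − kappa (J_e − 1)`
with penalty `kappa = 5·10³ kPa`, which regularizes the saddle point and
keeps `‖J_e − 1‖ ≤ 10⁻³` on converged solves.

Boundary conditions: cavity pressures act as follower loads on the deformed
endocardial surfaces (including the fan closure, so load and volume
measurement are consistent); weak Robin (spring) supports on the epicardium
(0.1 kPa/mm) and the basal plane (1 kPa/mm, normal direction) suppress
rigid-body motion. Springs were chosen over rigid-body Lagrange multipliers
because they also mimic pericardial/atrial tethering and keep the linear
system definite and uniformly sparse; the basal spring replaces the common
hard fixation of the base, which over-constrains coarse meshes.

Cavity volume constraints are imposed exactly with one Lagrange multiplier
per cavity; the multiplier is the (negative of the) cavity pressure, which
the solver reports. Pressure- and volume-driven phases therefore use one
code path.

### Newton solver

The nonlinear system is solved by a damped modified Newton method with an
analytic consistent tangent. The sparse Jacobian is symmetrically
equilibrated and factorized with SuperLU; the factorization is *reused*
across iterations and only refreshed when the residual reduction ratio
stalls (> 0.965) or every 25 iterations — for these strongly exponential
materials re-factorizing every iteration is slower in wall time. A
backtracking line search (up to 8 halvings) and a displacement-increment cap
guard the highly nonlinear regime. Cold starts ramp the load and continue
the penalty `kappa` geometrically from `kappa/64`, projecting the pressure
field consistently at each stage.

### Cardiac cycle

One beat couples the FE model to lumped hemodynamics per cavity
(`CirculationParams`):

1. **Passive filling** to the prescribed end-diastolic pressure (ramped);
   the end-diastolic state is the reference for the elastic myofiber-stretch
   stimulus.
2. **Isovolumic contraction**: volume-constrained solves as activation
   proceeds (`t_sa = t − t_init` per quadrature point), until the cavity
   pressure reaches the arterial valve-opening pressure.
3. **Ejection** against a 3-element Windkessel (characteristic resistance
   `R_c`, peripheral resistance `R_p`, arterial compliance `C_a`,
   backward-Euler update; diode valve). The FE volume constraint tracks the
   integrated outflow.
4. **Isovolumic relaxation and return** to the diastolic state.

Time step 5 ms; each active step uses a two-point linear extrapolation
predictor, falling back to the previous converged state, then to
activation-time sub-stepping within the step, and finally to a re-solve at
`kappa/64` with penalty continuation back to the full value — the last
rescue can traverse snap-through states (e.g. thin-wall buckling on strongly
remodeled geometries) where the full-penalty Newton stalls. `CycleRecord`
stores the PV loops, EDV/ESV/EF per cavity and
the per-quadrature-point `lambda_f,max` field (maximum over the beat of the
elastic fiber stretch measured from end-diastole), which is the growth
stimulus.

## 6. Time-scale separation and reference update (`cardiogrowth.remodeling`)

Growth (days–months) is split from the beat (milliseconds):

1. Run one beat with the current activation map → `lambda_f,max` field.
2. Integrate the growth ODE for `dt_days` (explicit Euler substeps, clamped
   at the bounds). The stimulus is cell-averaged first (an element-wise,
   DG0 field): sub-element roughness of the incompatible growth tensor
   carries no information at this discretization and destabilizes the
   equilibrium solve.
3. Solve the **growth equilibrium**: a traction-free elastic problem with the
   *incremental* growth tensor (current multipliers over those already
   absorbed in the reference). Large accumulated increments are applied as
   several successive equilibrium-and-adopt steps of at most 0.12 in
   log-multiplier per direction, with adaptive halving of the step size if a
   solve fails. Within each step the increment is ramped geometrically
   (`F_g^s`, `s → 1`) at reduced `kappa` and the penalty then continued to
   its full value. Because the problem is traction-free, a dedicated solver
   with only a token epicardial spring (0.01 kPa/mm, no basal spring) is
   used: it removes the rigid-body null space without resisting the grown
   shape (for a compatible `F_g = cI` the computed volume is exact to
   ~5·10⁻⁴).
4. **Adopt** the grown configuration as the new unloaded reference: vertices
   move by the converged displacement, the FE space is rebuilt and the fiber
   triads are pushed forward through `F_e` and re-orthonormalized. The small
   residual stress of the incompatible growth field is discarded — a standard
   approximation that keeps each cycle's reference state stress-free.

`GrowthRemodelingModel` owns mesh + fibers + solver + growth state and
exposes `beat` / `set_homeostatic` / `update`. The update cadence
(`update_days`) is the main cost knob: each update costs one beat plus one
growth-equilibrium solve.

## 7. Scenario driver (`cardiogrowth.scenario`, CLI)

`run_scenario` wires everything together: build the mesh, run a normally
activated baseline beat, record the homeostatic set point, then repeat
(paced beat → growth update) for the configured duration. Pacing sites are
selected on the LV endocardium by azimuth (septal ≈ 135°, LV free wall
≈ 315°) at a basal level. Outputs: `history.csv` (per-update wall
thickness, wall volume, cavity volume, mean multipliers, EDV/ESV/EF),
`pv_loops.csv`, `activation.json`, `provenance.csv` (per-parameter source
tags), `config.json`, and optionally a VTK file of the final reference mesh.

The `cardiogrowth` CLI exposes `mesh` (write a preset as VTK), `run`
(scenario from YAML), `growth-ode` (closed-form vs Euler table) and `report`
(summarize a run directory).

## 8. Verification summary

- Growth law: explicit Euler vs closed form (first-order convergence),
  half-life formula, bound clamping, equal-rate variant (unit tests +
  acceptance suite).
- Constitutive laws: `fung_stress_fiber` = central-difference gradient of the
  energy; analytic tangent = FD Jacobian of the stress; frame invariance;
  twitch bounds `T(t_sa=0) = 0`, `T ≤ T_max`.
- EP: resting-state invariance, full capture, conduction velocity ∝ √D,
  fiber anisotropy, monotone activation along a cable.
- FE: inflation volume–pressure duality (constraint multiplier recovers the
  inflation pressure), incompressibility `‖J_e − 1‖ ≤ 10⁻³`, hyperelastic
  unloading returns to the reference, cavity meter vs divergence-theorem
  volume, sphere-preset cavity volume within 1% of the closed form.
- Remodeling: compatible growth `F_g = cI` gives exact volume scaling `c³`;
  transverse growth thickens the wall; zero deviation is an identity update.

## 9. Known limitations

- Structured idealized geometry only (no image-based meshes); the RV crescent
  is attached alongside, not blended into, the LV epicardium.
- Quasi-static mechanics with a prescribed activation-to-tension schedule; no
  excitation–contraction feedback, no atria, no valves beyond diodes.
- Growth updates discard residual stress and re-solve activation on the grown
  geometry; very coarse update cadences make correspondingly large single
  increments.
- Coarse default meshes are tuned for turnaround, not mesh-converged
  hemodynamics; `T_max` is calibrated at the default resolution.
- On the idealized geometry the positively stimulated RV free wall thickens
  under chronic LV-free-wall pacing. The RV thinning reported for
  image-based geometries arises from redistribution of a near-constant RV
  wall volume over a dilating surface under fine (per-beat) update
  cadences; the synthetic crescent, whose RV cavity dilates strongly under
  the fixed-pressure filling protocol, does not reproduce it.
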