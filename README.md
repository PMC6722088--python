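# cardiogrowth

Anisotropic, myofiber-stretch-driven cardiac growth coupled to biventricular
electromechanics, on synthetic idealized geometry, in pure Python
(`numpy`/`scipy` only — the finite-element core is part of the package).

The model simulates chronic ventricular remodeling under mechanical
dyssynchrony (e.g. single-site LV free-wall pacing):

- **Electrophysiology** — monodomain Aliev–Panfilov action-potential
  propagation with fiber-anisotropic conduction produces an activation-time
  map for a chosen pacing site.
- **Cardiac cycle** — quasi-static total-Lagrangian finite elasticity
  (Taylor–Hood P2/P1 tetrahedra) with a Fung-type (Guccione) passive law,
  length-dependent active-stress twitch, exact cavity-volume constraints and
  3-element Windkessel afterloads runs one beat and records pressure–volume
  loops plus the growth stimulus: the per-point maximum elastic myofiber
  stretch λ<sub>f,max</sub> relative to end-diastole.
- **Growth** — the deviation of λ<sub>f,max</sub> from a homeostatic set
  point (recorded under normal activation) drives rate-limited growth
  multipliers (θ<sub>f</sub>, θ<sub>s</sub>, θ<sub>n</sub>) along the local
  fiber / sheet / sheet-normal directions, with asymmetric forward/reverse
  time constants. Between beats a traction-free growth-equilibrium solve
  bakes the accumulated growth into a new unloaded reference geometry.

See [docs/methods.md](docs/methods.md) for model equations, discretization
and numerical methods.

## Quick start

The growth law alone (milliseconds):

```python
import numpy as np
from cardiogrowth import GrowthParams, closed_form_theta, half_life

p = GrowthParams().s                     # transverse (wall-thickening) direction
print(half_life(p.tau_g, p.theta_max, p.theta_min, 0.06))   # 166.4 days
print(closed_form_theta(180.0, 0.06, p) - 1.0)              # 0.528 (53% growth)
```

One coupled beat on the default biventricle (a few minutes; see
[examples/single_beat.py](examples/single_beat.py) for the full script):

```python
from cardiogrowth import (biventricle, assign_fibers, MechanicsSolver,
                          MonodomainSolver, EPParams, CirculationParams,
                          activation_map, run_cycle)
from cardiogrowth.fem import FESpace
from cardiogrowth.scenario import pacing_site

mesh = biventricle()
space = FESpace(mesh)
frame = assign_fibers(mesh, space=space)
ep = MonodomainSolver(mesh, frame.cell_mean_f0(), EPParams())
state = ep.run(stim_center=pacing_site(mesh, azimuth_deg=135.0))  # septal
solver = MechanicsSolver(space, frame)
rec = run_cycle(solver, CirculationParams(), space.p_qp_values(state.t_init),
                fill_pressures={"LV": 8 * 0.1333, "RV": 4 * 0.1333})
print(rec.edv["LV"], rec.esv["LV"], rec.ejection_fraction("LV"))
```

On the default mesh this gives a total activation time of ≈ 83 ms, an LV
end-diastolic volume of ≈ 133 ml and an ejection fraction of ≈ 46%.

A full 6-month pacing-remodeling scenario
([examples/pacing_remodeling.py](examples/pacing_remodeling.py), ~25–30 min
on one CPU; the test suite runs the same scenario on a coarser mesh in about
half that):

```python
from cardiogrowth import ScenarioConfig, run_scenario
cfg = ScenarioConfig.from_dict({"duration_days": 180.0, "update_days": 90.0})
result = run_scenario(cfg, out_dir="out_pacing", progress=print)
print(result.history.to_dataframe())
```

LV free-wall pacing stretches the late-activated septum and right-ventricular
free wall above their set points (pre-systolic stretch) and unloads the
early-activated LV free wall, so over six months the septum thickens, the LV
free wall thins and the LV cavity dilates. On the idealized geometry the
positively stimulated RV free wall thickens as well; reproducing the RV
thinning reported for image-based geometries requires the geometric
redistribution of a near-constant RV wall volume that this synthetic crescent
does not exhibit.

## Command-line interface

```bash
cardiogrowth mesh --preset biventricle --out bv.vtk   # write a preset mesh (VTK)
cardiogrowth growth-ode --deviation 0.06 --out ode.csv
cardiogrowth run --config examples/scenario.yaml --out out_run
cardiogrowth report out_run
```

`run` writes `history.csv` (per-update wall thickness, cavity volumes, growth
multipliers, EDV/ESV/EF), `pv_loops.csv`, `activation.json`,
`provenance.csv` (per-parameter source tags) and `config.json`.

## Package layout

| Module | Contents |
| --- | --- |
| `cardiogrowth.mesh`, `.geometry` | tetrahedral mesh container, idealized presets (sphere shell, LV ellipsoid, biventricle), wall/cavity metrics |
| `cardiogrowth.fibers` | rule-based myofiber/sheet/normal triads (±60° helix) |
| `cardiogrowth.ep` | monodomain Aliev–Panfilov solver, activation maps |
| `cardiogrowth.mechanics` | Fung passive law, active twitch, growth-split stress |
| `cardiogrowth.fem`, `.cycle` | P2/P1 FE core, Newton solver, cavity constraints, Windkessel, `run_cycle` |
| `cardiogrowth.growth` | growth tensor, rate-limited ODE, closed-form oracle |
| `cardiogrowth.remodeling` | growth equilibrium, reference update, `GrowthRemodelingModel` |
| `cardiogrowth.scenario`, `.cli` | validated configuration, scenario driver, `cardiogrowth` CLI |

## Testing

```bash
python -m pytest            # full suite, including the coupled acceptance tests
python scripts/acceptance.py --seed 0 --out results/acceptance.json
```

The unit suite verifies each layer against independent oracles (analytic
growth solutions, finite-difference stress consistency, closed-form cavity
volumes, conduction-velocity scaling, volume–pressure duality); the
acceptance tests add the coupled directional properties of the 6-month
pacing scenario.
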