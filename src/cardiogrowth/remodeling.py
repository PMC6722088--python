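"""Long-time-scale growth and reverse remodeling of the reference geometry.

The coupled model separates time scales: a single cardiac cycle (ms) is
simulated with :mod:`cardiogrowth.cycle` to obtain the growth stimulus --
the per-point maximum elastic myofiber stretch lambda_f,max measured from
the end-diastolic configuration -- and the growth multipliers theta_i then
evolve over days by the rate-limited law of :mod:`cardiogrowth.growth`.

After each growth update the unloaded reference configuration is updated:

1. the incremental growth tensor F_g (the ratio of the current multipliers
   to those already absorbed into the reference) is applied and the
   traction-free *growth equilibrium* is solved -- an elastic problem whose
   only loading is the incompatibility of F_g itself,
2. the mesh vertices are moved by the converged displacement, producing the
   new (nearly stress-free) reference geometry; the small residual stresses
   of the incompatible growth field are discarded,
3. the microstructural triads are pushed forward through the elastic part
   of the deformation and re-orthonormalized.

:class:`GrowthRemodelingModel` bundles the mesh, fiber frame, mechanics
solver and growth state and exposes ``beat`` / ``set_homeostatic`` /
``update`` for scenario drivers; :class:`GrowthHistory` accumulates a
per-update table of wall and cavity metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cycle import (
    CirculationParams,
    CycleRecord,
    MechanicsSolver,
    MechSolution,
    NewtonError,
    run_cycle,
)
from .fem import FESpace
from .fibers import FiberFrame, assign_fibers
from .geometry import wall_metrics
from .growth import GrowthParams, GrowthState, evolve_growth, growth_tensor
from .mechanics import ActiveParams, PassiveParams
from .mesh import TetMesh

__all__ = [
    "growth_equilibrium",
    "adopt_reference",
    "set_homeostatic",
    "GrowthRemodelingModel",
    "GrowthHistory",
]


def _incremental_fg_fields(ratios, frame: FiberFrame):
    """F_g^{-1} and det F_g at quadrature points from per-direction ratios.

    ``ratios`` is a tuple of three arrays (r_f, r_s, r_n) broadcasting with
    the frame's ``(ne, nq)`` leading shape.  F_g is diagonal in the local
    orthonormal triad, so its inverse has reciprocal multipliers and its
    determinant is the product.
    """
    r_f, r_s, r_n = (np.asarray(r, dtype=float) for r in ratios)
    if np.any(r_f <= 0) or np.any(r_s <= 0) or np.any(r_n <= 0):
        raise ValueError("growth ratios must be positive")
    Fg_inv = growth_tensor(
        1.0 / r_f, 1.0 / r_s, 1.0 / r_n, frame.f0, frame.s0, frame.n0, check=False
    )
    det_Fg = r_f * r_s * r_n * np.ones(frame.f0.shape[:2])
    return Fg_inv, det_Fg


def growth_equilibrium(
    solver: MechanicsSolver,
    frame: FiberFrame,
    ratios,
    n_ramp: int = 4,
) -> tuple[MechSolution, np.ndarray, np.ndarray]:
    """Solve the traction-free equilibrium under an incremental growth tensor.

    ``ratios = (r_f, r_s, r_n)`` are the incremental growth multipliers
    relative to the current reference.  The only loading is growth itself, so
    the solve is continued along the geometric ramp ``r^s``, s in (0, 1]
    (with adaptive substepping), which keeps Newton in its convergence basin
    even for the large per-update increments of coarse growth cadences.

    Returns ``(solution, Fg_inv, det_Fg)`` at the full increment.
    """
    r_f, r_s, r_n = (np.asarray(r, dtype=float) for r in ratios)
    kappa_target = solver.kappa
    # the growth increment is ramped at a much-reduced quadrature penalty (a
    # small kappa regularizes the penalty-free pressure modes while keeping
    # Newton robust against the J_e jump each new F_g stage introduces) and
    # the full penalty is then continued geometrically at the full increment
    solver.kappa = kappa_target / 64.0
    solver._lu_cache = None
    try:
        sol = None
        s_done, step = 0.0, 1.0 / n_ramp
        while s_done < 1.0 - 1e-12:
            s = min(1.0, s_done + step)
            Fg_inv, det_Fg = _incremental_fg_fields((r_f**s, r_s**s, r_n**s), frame)
            try:
                # ramp stages only warm-start the penalty continuation, so a
                # loose tolerance suffices (the penalty-free pressure space
                # has near-singular modes that stall tight line searches)
                sol = solver.solve(sol, Fg_inv=Fg_inv, det_Fg=det_Fg, tol=1e-2)
                s_done = s
            except NewtonError:
                step *= 0.5
                if step < 1e-3:
                    raise
        Fg_inv, det_Fg = _incremental_fg_fields((r_f, r_s, r_n), frame)
        if kappa_target > 0.0:
            sol = solver.continue_kappa(
                sol,
                kappa_target,
                lambda guess: solver.solve(guess, Fg_inv=Fg_inv, det_Fg=det_Fg),
                state_fn=lambda s_: solver._state(
                    s_.u, s_.p, None, Fg_inv, det_Fg, want_tangent=False
                ),
                kappa_start=kappa_target / 64.0,
            )
    finally:
        solver.kappa = kappa_target
    return sol, Fg_inv, det_Fg


def adopt_reference(
    space: FESpace,
    frame: FiberFrame,
    solver: MechanicsSolver,
    sol: MechSolution,
    Fg_inv: np.ndarray,
    det_Fg: np.ndarray,
) -> tuple[TetMesh, FESpace, FiberFrame]:
    """Bake a converged growth equilibrium into a new reference configuration.

    Mesh vertices move by the converged displacement (straight tetrahedra are
    re-formed; quadratic midpoints are re-derived from the new vertices) and
    the fiber triads are pushed forward through the elastic deformation
    F_e = F F_g^{-1} and re-orthonormalized.  Residual stresses of the
    incompatible growth field are discarded.
    """
    mesh = space.mesh
    nv = mesh.n_vertices
    u_vert = sol.u[: 3 * nv].reshape(nv, 3)
    new_mesh = TetMesh(
        mesh.vertices + u_vert,
        mesh.cells.copy(),
        mesh.region_tags.copy(),
        boundary_facets=mesh.boundary_facets.copy(),
        facet_tags=None if mesh.facet_tags is None else mesh.facet_tags.copy(),
    )
    new_space = FESpace(new_mesh)
    st = solver._state(sol.u, sol.p, Fg_inv=Fg_inv, det_Fg=det_Fg, want_tangent=False)
    new_frame = frame.push_forward(st["Fe"])
    return new_mesh, new_space, new_frame


def cell_mean(field: np.ndarray) -> np.ndarray:
    """Element-wise (DG0) representation of a quadrature-point field.

    Growth stimuli are kept constant per element: sub-element variation of
    the (incompatible) growth tensor carries no physical information at this
    discretization and needlessly excites the pressure modes of the
    growth-equilibrium solve.
    """
    return np.broadcast_to(
        field.mean(axis=1, keepdims=True), field.shape
    ).copy()


def set_homeostatic(state: GrowthState, record: CycleRecord) -> GrowthState:
    """Record a beat's lambda_f,max field as the homeostatic set point."""
    state.lam_h = cell_mean(record.lam_f_max)
    return state


@dataclass
class GrowthHistory:
    """Per-update table of geometric and functional remodeling metrics."""

    rows: list = field(default_factory=list)

    def record(
        self,
        t_days: float,
        mesh: TetMesh,
        growth: GrowthState,
        record: CycleRecord | None = None,
        label: str = "",
    ) -> dict:
        wm = wall_metrics(mesh)
        row = {
            "t_days": float(t_days),
            "label": label,
            **{f"thickness_{r}": v for r, v in wm["thickness"].items()},
            **{f"wall_volume_{r}": v for r, v in wm["wall_volume"].items()},
            **{
                f"cavity_{c}": v for c, v in wm["cavity_volume"].items()
            },
            "theta_f_mean": float(growth.theta_f.mean()),
            "theta_s_mean": float(growth.theta_s.mean()),
            "theta_n_mean": float(growth.theta_n.mean()),
        }
        if record is not None:
            for c in record.edv:
                row[f"EDV_{c}"] = record.edv[c]
                row[f"ESV_{c}"] = record.esv[c]
                row[f"EF_{c}"] = record.ejection_fraction(c)
        self.rows.append(row)
        return row

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.rows)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


class GrowthRemodelingModel:
    """Mesh + fibers + mechanics solver + growth state, with reference updates.

    The model owns the *current* reference configuration.  ``beat`` runs one
    cardiac cycle on it; ``update`` advances the growth multipliers by
    ``dt_days`` under a given stimulus field, solves the growth equilibrium
    for the increment not yet absorbed in the reference, and adopts the grown
    geometry (rebuilding the FE space, fiber frame and solver).
    """

    def __init__(
        self,
        mesh: TetMesh,
        passive: PassiveParams | None = None,
        active: ActiveParams | None = None,
        growth_params: GrowthParams | None = None,
        circulation: CirculationParams | None = None,
        space: FESpace | None = None,
        frame: FiberFrame | None = None,
    ):
        self.mesh = mesh
        self.passive = passive or PassiveParams()
        self.active = active or ActiveParams()
        self.growth_params = growth_params or GrowthParams()
        self.circulation = circulation or CirculationParams()
        self.space = space or FESpace(mesh)
        self.frame = frame or assign_fibers(mesh, space=self.space)
        self.solver = MechanicsSolver(self.space, self.frame, self.passive, self.active)
        self.growth_solver = self._make_growth_solver()
        shape = self.frame.f0.shape[:2]
        self.growth = GrowthState.uniform(shape, self.growth_params)
        # cumulative multipliers already absorbed into the reference geometry
        self.theta_ref = tuple(np.ones(shape) for _ in range(3))
        self.t_days = 0.0
        self.jerr_last: float | None = None

    def _make_growth_solver(self) -> MechanicsSolver:
        """The growth equilibrium is traction-free, so only a very weak
        epicardial spring is kept (removing the rigid-body null space without
        measurably resisting the grown shape)."""
        return MechanicsSolver(
            self.space,
            self.frame,
            self.passive,
            self.active,
            k_spring_epi=0.01,
            include_base_spring=False,
        )

    # -- short time scale -----------------------------------------------------

    def beat(
        self,
        t_init_qp: np.ndarray | None,
        edv_targets: dict | None = None,
        fill_pressures: dict | None = None,
        **kw,
    ) -> CycleRecord:
        """One cardiac cycle on the current reference geometry."""
        return run_cycle(
            self.solver,
            self.circulation,
            t_init_qp,
            edv_targets=edv_targets,
            fill_pressures=fill_pressures,
            **kw,
        )

    def set_homeostatic(self, record: CycleRecord) -> None:
        set_homeostatic(self.growth, record)

    # -- long time scale ------------------------------------------------------

    def update(
        self,
        stimulus: np.ndarray,
        dt_days: float,
        n_substeps: int = 10,
        max_step_log: float = 0.12,
    ) -> None:
        """Advance growth by ``dt_days`` and adopt the grown reference.

        ``stimulus`` is the lambda_f,max field of the latest beat (per
        quadrature point); the deviation from the stored homeostatic set
        point drives all three growth multipliers.

        Large increments (coarse update cadences) are applied as several
        successive equilibrium-and-adopt geometry steps of at most
        ``max_step_log`` in log-multiplier per direction: the strongly
        incompatible single-shot increment is both harder to solve and a
        poorer approximation of the continuous growth path.  If an
        equilibrium solve fails, the per-step size is halved and the
        remaining increment retried (adaptive continuation).
        """
        self.growth = evolve_growth(
            self.growth, cell_mean(stimulus), self.growth_params, dt_days, n_substeps
        )
        ratios = (
            self.growth.theta_f / self.theta_ref[0],
            self.growth.theta_s / self.theta_ref[1],
            self.growth.theta_n / self.theta_ref[2],
        )
        remaining = tuple(r.copy() for r in ratios)
        step_log = max_step_log
        while True:
            log_max = max(float(np.abs(np.log(r)).max()) for r in remaining)
            if log_max < 1e-12:
                break
            k = max(1, int(np.ceil(log_max / step_log)))
            step_ratios = tuple(r ** (1.0 / k) for r in remaining)
            try:
                sol, Fg_inv, det_Fg = growth_equilibrium(
                    self.growth_solver, self.frame, step_ratios
                )
            except NewtonError:
                # the increment was too large for this (already remodeled)
                # geometry: halve the per-step size and retry
                step_log *= 0.5
                if step_log < max_step_log / 16.0:
                    raise
                continue
            self.jerr_last = self.growth_solver.incompressibility_error(
                sol, Fg_inv, det_Fg
            )
            self.mesh, self.space, self.frame = adopt_reference(
                self.space, self.frame, self.growth_solver, sol, Fg_inv, det_Fg
            )
            self.growth_solver = self._make_growth_solver()
            remaining = tuple(r / s for r, s in zip(remaining, step_ratios))
        self.solver = MechanicsSolver(self.space, self.frame, self.passive, self.active)
        self.theta_ref = tuple(t.copy() for t in self.growth.thetas())
        self.t_days += dt_days
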