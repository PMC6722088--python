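"""Monodomain Aliev-Panfilov electrophysiology and activation-time maps.

The action potential phi (dimensionless, resting 0, peak ~1) obeys the
monodomain reaction-diffusion system on the reference mesh

    dphi/dt = div(D grad phi) + f_phi(phi, r) + I_s,   dr/dt = f_r(phi, r),
    f_phi = c phi (phi - alpha)(1 - phi) - r phi,
    f_r   = (gamma + mu1 r / (mu2 + phi)) (-r - c phi (phi - b - 1)),

with conductivity D = d_iso I + d_ani f0 (x) f0 (faster along the myofiber
direction).  The kinetics are dimensionless; ``time_scale`` converts model
time to milliseconds.  phi lives on continuous P1 vertices, the recovery
variable r on cells (DG0).  Time stepping is IMEX: diffusion backward-Euler
with a lumped mass matrix (operator factorized once), reaction explicit.

The local activation time is t_init(X) = first time phi >= 0.9, linearly
interpolated between steps; it drives the active-contraction schedule of
the mechanics model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .mesh import TetMesh
from .fem import p1_stiffness, p1_lumped_mass

__all__ = ["EPParams", "EPState", "MonodomainSolver", "activation_map"]


@dataclass(frozen=True)
class EPParams:
    """Aliev-Panfilov constants and monodomain conductivities.

    ``d_iso``/``d_ani`` are in mm^2/ms; kinetics constants dimensionless;
    ``time_scale`` is ms of physical time per unit of model time.
    """

    c: float = 8.0
    alpha: float = 0.01
    b: float = 0.15
    gamma: float = 0.002
    mu1: float = 0.2
    mu2: float = 0.3
    d_iso: float = 1.45
    d_ani: float = 2.9
    time_scale: float = 12.9
    dt: float = 0.6  # ms
    stim_amplitude: float = 30.0  # added to f_phi inside the stimulus ball
    stim_duration: float = 2.0  # ms
    stim_radius: float = 6.0  # mm

    def __post_init__(self) -> None:
        if self.d_iso <= 0 or self.d_ani < 0:
            raise ValueError("require d_iso > 0 and d_ani >= 0")
        if not (0 < self.alpha < 1):
            raise ValueError("require 0 < alpha < 1")
        if self.dt <= 0 or self.time_scale <= 0:
            raise ValueError("dt and time_scale must be positive")


@dataclass
class EPState:
    phi: np.ndarray  # (n_vertices,)
    r: np.ndarray  # (n_cells,)
    t_init: np.ndarray  # (n_vertices,) ms, NaN where not yet activated
    time: float = 0.0  # ms

    @property
    def activated(self) -> np.ndarray:
        return ~np.isnan(self.t_init)


def _f_phi(phi, r, p: EPParams):
    return p.c * phi * (phi - p.alpha) * (1.0 - phi) - r * phi


def _f_r(phi, r, p: EPParams):
    eps = p.gamma + p.mu1 * r / (p.mu2 + phi)
    return eps * (-r - p.c * phi * (phi - p.b - 1.0))


class MonodomainSolver:
    """IMEX monodomain integrator on a labeled tet mesh."""

    def __init__(self, mesh: TetMesh, fiber_cell: np.ndarray | None, params: EPParams):
        self.mesh = mesh
        self.p = params
        ne = mesh.n_cells
        if fiber_cell is None or params.d_ani == 0.0:
            D = params.d_iso * np.broadcast_to(np.eye(3), (ne, 3, 3))
        else:
            f = np.asarray(fiber_cell, dtype=float)
            D = params.d_iso * np.eye(3)[None] + params.d_ani * (
                f[:, :, None] * f[:, None, :]
            )
        self.K = p1_stiffness(mesh, D)
        self.m = p1_lumped_mass(mesh)
        dt = params.dt
        A = sp.diags(self.m / dt) + self.K
        self._lu = splu(A.tocsc())
        # cell averages of phi: 1/4 sum over cell vertices
        self._cells = mesh.cells
        vol = mesh.cell_volumes()
        self._scatter_w = np.repeat(vol / 4.0, 4)

    def initial_state(self) -> EPState:
        return EPState(
            phi=np.zeros(self.mesh.n_vertices),
            r=np.zeros(self.mesh.n_cells),
            t_init=np.full(self.mesh.n_vertices, np.nan),
        )

    def _project_cell_to_vertices(self, fc: np.ndarray) -> np.ndarray:
        out = np.zeros(self.mesh.n_vertices)
        np.add.at(out, self._cells.ravel(), np.repeat(fc, 4) * self._scatter_w)
        return out / self.m

    def step(self, state: EPState, stim_mask: np.ndarray | None = None) -> EPState:
        """One IMEX step of ``dt`` ms.  ``stim_mask`` marks stimulated vertices."""
        p = self.p
        dt_model = p.dt / p.time_scale  # reaction advances in model time
        phi, r = state.phi, state.r
        phi_cell = phi[self._cells].mean(axis=1)
        r_new = r + dt_model * _f_r(phi_cell, r, p)
        react_cell = _f_phi(phi_cell, 0.0 * phi_cell, p)  # c phi(phi-a)(1-phi)
        # the -r phi coupling uses the cell-wise r (DG0)
        react_cell = react_cell - r * phi_cell
        react_v = self._project_cell_to_vertices(react_cell)
        rhs = self.m * (phi / p.dt + react_v / p.time_scale)
        if stim_mask is not None and stim_mask.any():
            rhs = rhs + self.m * stim_mask * (p.stim_amplitude / p.time_scale)
        phi_new = self._lu.solve(rhs)
        t_new = state.time + p.dt
        t_init = state.t_init.copy()
        cross = np.isnan(t_init) & (phi_new >= 0.9)
        if np.any(cross):
            # linear interpolation of the crossing time inside the step
            f0, f1 = phi[cross], phi_new[cross]
            frac = np.clip((0.9 - f0) / np.maximum(f1 - f0, 1e-12), 0.0, 1.0)
            t_init[cross] = state.time + frac * p.dt
        if np.any(np.abs(phi_new) > 10.0):
            raise RuntimeError("EP solver diverged (|phi| > 10)")
        return EPState(phi=phi_new, r=r_new, t_init=t_init, time=t_new)

    def stimulus_mask(self, center: np.ndarray, radius: float | None = None) -> np.ndarray:
        radius = radius if radius is not None else self.p.stim_radius
        d = np.linalg.norm(self.mesh.vertices - np.asarray(center), axis=1)
        mask = d <= radius
        if not mask.any():
            raise ValueError("stimulus ball contains no mesh vertices")
        return mask

    def run(
        self,
        stim_center: np.ndarray,
        t_end: float = 300.0,
        stop_when_activated: bool = True,
    ) -> EPState:
        """Propagate from a stimulus ball until ``t_end`` ms (or full capture)."""
        state = self.initial_state()
        mask = self.stimulus_mask(stim_center)
        n_steps = int(np.ceil(t_end / self.p.dt))
        for k in range(n_steps):
            stim = mask if state.time < self.p.stim_duration else None
            state = self.step(state, stim)
            if stop_when_activated and state.activated.all():
                break
        return state


def activation_map(state: EPState, warn_unactivated: bool = True) -> dict:
    """Summarize a solved EP state: t_init field and total activation time (ms)."""
    import warnings

    act = state.activated
    n_un = int((~act).sum())
    if n_un and warn_unactivated:
        warnings.warn(f"{n_un} vertices never reached the activation threshold")
    t = state.t_init[act]
    return {
        "t_init": state.t_init,
        "n_unactivated": n_un,
        "total_activation_time": float(t.max() - t.min()) if len(t) else float("nan"),
    }
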