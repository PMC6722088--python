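"""Quasi-static cardiac-cycle finite-element solver.

Solves the short-time-scale electromechanics equilibrium on the unloaded
reference mesh with Taylor-Hood (P2 displacement / P1 pressure) elements:

* total PK2 stress S = S_p(E_e, p) + S_a(t - t_init, l) from
  :mod:`cardiogrowth.mechanics`,
* local incompressibility J = det F_e = 1 via the pressure field,
* cavity terms either as prescribed endocardial pressures or as
  cavity-volume constraints whose Lagrange multipliers are the cavity
  pressures (both use the divergence-theorem volume and its exact gradient,
  including the follower-load Hessian for quadratic Newton convergence),
* Robin springs on the epicardial and basal surfaces (they also remove the
  rigid-body null space).

A full 750 ms beat is driven by :func:`run_cycle`: passive filling (pressure
ramp to prescribed end-diastolic volumes, or to prescribed filling
pressures), isovolumic contraction, ejection against a 3-element Windkessel
per cavity (terminated at the prescribed outflow cutoff), and isovolumic
relaxation.  The per-point maximum elastic myofiber stretch relative to the
end-diastolic configuration is recorded as the growth stimulus.

Units: mm, kPa, ms, ml.  An optional per-quadrature-point growth tensor
F_g enters through the multiplicative split F = F_e F_g (used by the
long-time-scale growth equilibrium; within a beat F_g = I because residual
stresses are removed when the reference geometry is updated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .fem import FESpace, CavityMeter
from .fibers import FiberFrame
from .mechanics import (
    ActiveParams,
    PassiveParams,
    active_tension,
    active_tension_dl,
    fung_stress_fiber,
    fung_tangent_fiber,
)

__all__ = [
    "WindkesselParams",
    "CirculationParams",
    "CycleRecord",
    "MechanicsSolver",
    "MechSolution",
    "windkessel_step",
    "run_cycle",
    "NewtonError",
]

KPA_PER_MMHG = 0.133322


@dataclass(frozen=True)
class WindkesselParams:
    """3-element Windkessel afterload (kPa, ms, ml)."""

    R_c: float  # characteristic resistance, kPa ms / ml
    R_p: float  # peripheral resistance, kPa ms / ml
    C_a: float  # arterial compliance, ml / kPa
    P_open: float  # valve opening (arterial diastolic) pressure, kPa
    P_fill: float  # pressure at which isovolumic relaxation ends, kPa

    def __post_init__(self) -> None:
        if min(self.R_c, self.R_p, self.C_a) <= 0:
            raise ValueError("Windkessel elements must be positive")


def _lv_default() -> WindkesselParams:
    return WindkesselParams(
        R_c=6.7, R_p=160.0, C_a=12.0,
        P_open=80.0 * KPA_PER_MMHG, P_fill=5.0 * KPA_PER_MMHG,
    )


def _rv_default() -> WindkesselParams:
    return WindkesselParams(
        R_c=3.0, R_p=25.0, C_a=35.0,
        P_open=18.0 * KPA_PER_MMHG, P_fill=2.0 * KPA_PER_MMHG,
    )


@dataclass(frozen=True)
class CirculationParams:
    lv: WindkesselParams = field(default_factory=_lv_default)
    rv: WindkesselParams = field(default_factory=_rv_default)
    cycle_duration: float = 750.0  # ms
    dt: float = 5.0  # mechanics time step, ms
    outflow_cutoff: float = 0.005 / 60000.0  # 0.005 ml/min in ml/ms


@dataclass
class MechSolution:
    """Converged state of one equilibrium solve."""

    u: np.ndarray  # (3*n_p2,)
    p: np.ndarray  # (n_vert,)
    cavity_pressures: dict  # name -> kPa
    n_iter: int = 0

    def copy(self) -> "MechSolution":
        return MechSolution(self.u.copy(), self.p.copy(), dict(self.cavity_pressures))


@dataclass
class CycleRecord:
    """PV time series and stimulus field for one beat."""

    time: np.ndarray
    volumes: dict  # name -> array (ml)
    pressures: dict  # name -> array (kPa)
    phases: dict  # name -> list[str]
    lam_f_max: np.ndarray  # (ne, nq) max elastic fiber stretch w.r.t. ED
    ed_pressures: dict  # name -> kPa
    edv: dict
    esv: dict
    u_ed: np.ndarray | None = None

    def ejection_fraction(self, name: str) -> float:
        return (self.edv[name] - self.esv[name]) / self.edv[name]

    def stroke_volume(self, name: str) -> float:
        return self.edv[name] - self.esv[name]


class NewtonError(RuntimeError):
    pass


class _ScaledLU:
    """Sparse LU with symmetric diagonal equilibration.

    The saddle-point tangent mixes displacement, pressure, and constraint
    scales; equilibrating by sqrt(|diag|) and factorizing in SuperLU's
    symmetric mode roughly halves fill-in and factorization time.
    """

    def __init__(self, J: sp.csc_matrix):
        d = np.sqrt(np.abs(J.diagonal()))
        d[d < 1e-8] = 1.0
        self._d = d
        Dinv = sp.diags(1.0 / d)
        try:
            self._lu = splu(
                (Dinv @ J @ Dinv).tocsc(),
                permc_spec="MMD_AT_PLUS_A",
                options={"SymmetricMode": True},
                diag_pivot_thresh=1e-3,
            )
        except RuntimeError as exc:
            raise NewtonError(f"linear solve failed: {exc}") from exc

    def solve(self, b: np.ndarray) -> np.ndarray:
        return self._lu.solve(b / self._d) / self._d


class MechanicsSolver:
    """Newton solver for the growth-coupled hyperelastic equilibrium."""

    def __init__(
        self,
        space: FESpace,
        frame: FiberFrame,
        passive: PassiveParams | None = None,
        active: ActiveParams | None = None,
        k_spring_epi: float = 0.1,  # kPa/mm
        k_spring_base: float = 1.0,  # kPa/mm
        include_base_spring: bool = True,
    ):
        passive = passive or PassiveParams()
        active = active or ActiveParams()
        self.space = space
        self.frame = frame
        self.passive = passive
        self.active = active
        mesh = space.mesh
        self.K_spring = k_spring_epi * space.surface_mass(mesh.facets_with_tag("epi"))
        if include_base_spring:
            self.K_spring = self.K_spring + k_spring_base * space.surface_mass(
                mesh.facets_with_tag("base")
            )
        self.cavities: dict[str, CavityMeter] = {}
        from .mesh import SURFACE_TAGS

        for name, tag in (("LV", "lv_endo"), ("RV", "rv_endo")):
            if mesh.facet_tags is not None and np.any(
                mesh.facet_tags == SURFACE_TAGS[tag]
            ):
                self.cavities[name] = CavityMeter(space, tag)
        # rotation matrices: rows are (f0, s0, n0) per quadrature point
        self.R = np.stack([frame.f0, frame.s0, frame.n0], axis=-2)
        self.f0 = frame.f0
        self._eye = np.eye(3)
        # effective volumetric penalty; solve_stepped ramps this from zero on
        # cold starts because the full penalty is too stiff for Newton far
        # from equilibrium
        self.kappa = passive.kappa
        self._lu_cache = None  # (n_constrained, lu) reused across solves
        # stale-tangent iterations cost only a backsolve plus a residual, so
        # the tangent is refactorized only once linear contraction per
        # iteration degrades beyond this ratio
        self.refactor_ratio = 0.965
        # cumulative work counters (diagnostics only)
        self.stats = {"solves": 0, "iterations": 0, "factorizations": 0,
                      "residual_evals": 0}

    # -- constitutive evaluation at quadrature points -------------------------

    def _state(self, u, p, t_sa=None, Fg_inv=None, det_Fg=None, want_tangent=True):
        sp_ = self.space
        gu = sp_.u_qp_gradients(u)  # (ne,nq,3,3)
        F = gu + self._eye
        if Fg_inv is not None:
            Fe = np.einsum("eqij,eqjk->eqik", F, Fg_inv)
        else:
            Fe = F
        C = np.einsum("eqji,eqjk->eqik", Fe, Fe)
        E = 0.5 * (C - self._eye)
        E_fib = np.einsum("eqia,eqab,eqjb->eqij", self.R, E, self.R)
        S_fib = fung_stress_fiber(E_fib, self.passive)
        S = np.einsum("eqia,eqij,eqjb->eqab", self.R, S_fib, self.R)

        Je = np.sqrt(np.linalg.det(C))
        Cinv = np.linalg.inv(C)
        # perturbed-Lagrangian effective pressure: multiplier + penalty part
        pq = sp_.p_qp_values(p) - self.kappa * (Je - 1.0)
        S = S - pq[..., None, None] * Je[..., None, None] * Cinv

        lam = None
        if t_sa is not None:
            fCf = np.einsum("eqi,eqij,eqj->eq", self.f0, C, self.f0)
            lam = np.sqrt(fCf)
            l = self.active.l_s0 * lam
            T = active_tension(t_sa, l, self.active)
            S = S + T[..., None, None] * self.f0[..., :, None] * self.f0[..., None, :]

        out = {"F": F, "Fe": Fe, "C": C, "S": S, "Je": Je, "Cinv": Cinv, "lam": lam}
        if not want_tangent:
            return out

        Ct = fung_tangent_fiber(E_fib, self.passive)
        Ct = np.einsum(
            "eqia,eqjb,eqkc,eqld,eqijkl->eqabcd", self.R, self.R, self.R, self.R, Ct,
            optimize=True,
        )
        # volumetric tangent dS_vol/dE
        JC = Je[..., None, None, None, None]
        pqx = pq[..., None, None, None, None]
        CiCi = Cinv[..., :, :, None, None] * Cinv[..., None, None, :, :]
        sym = 0.5 * (
            np.einsum("eqac,eqbd->eqabcd", Cinv, Cinv)
            + np.einsum("eqad,eqbc->eqabcd", Cinv, Cinv)
        )
        Ct = Ct + 2.0 * (-pqx) * (0.5 * JC * CiCi - JC * sym)
        # penalty part: d(-kappa(J-1)) / dE through the volumetric stress
        Ct = Ct + self.kappa * JC**2 * CiCi
        if t_sa is not None:
            l = self.active.l_s0 * lam
            dT = active_tension_dl(t_sa, l, self.active)
            coef = dT * self.active.l_s0**2 / np.maximum(l, 1e-9)
            ff = self.f0[..., :, None] * self.f0[..., None, :]
            Ct = Ct + coef[..., None, None, None, None] * (
                ff[..., :, :, None, None] * ff[..., None, None, :, :]
            )
        Ct = 0.5 * (Ct + np.swapaxes(Ct, -1, -2))  # minor symmetry in last pair
        out["Ct"] = Ct
        return out

    # -- residual and jacobian -------------------------------------------------

    def _pk1_ref(self, st, Fg_inv, det_Fg):
        P = np.einsum("eqik,eqkl->eqil", st["Fe"], st["S"])
        if Fg_inv is not None:
            P = det_Fg[..., None, None] * np.einsum("eqil,eqal->eqia", P, Fg_inv)
        return P

    def residual(self, u, p, cavity_pressures, t_sa=None, Fg_inv=None, det_Fg=None,
                 volume_targets=None, st=None):
        sp_ = self.space
        if st is None:
            st = self._state(u, p, t_sa, Fg_inv, det_Fg, want_tangent=False)
        P_ref = self._pk1_ref(st, Fg_inv, det_Fg)
        Ru = sp_.residual_u(P_ref) + self.K_spring @ u
        jfac = st["Je"] - 1.0
        if det_Fg is not None:
            jfac = jfac * det_Fg
        Rp = sp_.residual_p(jfac)
        Rc = []
        for name, meter in self.cavities.items():
            P_cav = cavity_pressures.get(name, 0.0)
            if P_cav != 0.0:
                Ru = Ru - P_cav * meter.gradient(u)
            if volume_targets is not None and name in volume_targets:
                Rc.append(meter.volume(u) - volume_targets[name])
        return Ru, Rp, np.array(Rc), st

    def _cavity_hessian(self, u, cavity_pressures):
        """- sum_c P_c d2V_c/du2 (follower-load tangent), sparse."""

        def skew(v):
            z = np.zeros(v.shape[:-1] + (3, 3))
            z[..., 0, 1] = -v[..., 2]
            z[..., 0, 2] = v[..., 1]
            z[..., 1, 0] = v[..., 2]
            z[..., 1, 2] = -v[..., 0]
            z[..., 2, 0] = -v[..., 1]
            z[..., 2, 1] = v[..., 0]
            return z

        rows, cols, vals = [], [], []
        for name, meter in self.cavities.items():
            P_cav = cavity_pressures.get(name, 0.0)
            if P_cav == 0.0:
                continue
            x = meter._coords(u)
            tris = meter.tris
            nreal = meter.n_real
            p0, p1, p2 = (x[tris[:, k]] for k in range(3))
            H = {
                (0, 1): -skew(p2) / 6.0,
                (0, 2): skew(p1) / 6.0,
                (1, 2): -skew(p0) / 6.0,
            }
            scale = meter.sign * P_cav  # mm^3 gradient scale
            for (a, b), Hab in H.items():
                for (i, j, M) in ((a, b, Hab), (b, a, np.swapaxes(Hab, -1, -2))):
                    ni, nj = tris[:, i], tris[:, j]
                    ok = (ni < nreal) & (nj < nreal)
                    if not ok.any():
                        continue
                    Mok = M[ok]
                    bi = 3 * ni[ok, None, None] + np.arange(3)[:, None]
                    bj = 3 * nj[ok, None, None] + np.arange(3)[None, :]
                    rows.append(np.broadcast_to(bi, Mok.shape).ravel())
                    cols.append(np.broadcast_to(bj, Mok.shape).ravel())
                    vals.append((-scale) * Mok.ravel())
        if not rows:
            return None
        return sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.space.n_udof, self.space.n_udof),
        ).tocsr()

    def jacobian(self, u, p, st, cavity_pressures, Fg_inv=None, det_Fg=None,
                 constrained=()):
        sp_ = self.space
        Fe, S, Ct, Cinv, Je = st["Fe"], st["S"], st["Ct"], st["Cinv"], st["Je"]
        if Fg_inv is None:
            Fg_inv = np.broadcast_to(self._eye, Fe.shape)
            det_Fg = np.ones(Fe.shape[:2])
        # geometric part: detFg * delta_ij (Fginv S Fginv)_{BA}
        GSG = np.einsum("eqbk,eqkl,eqal->eqba", Fg_inv, S, Fg_inv, optimize=True)
        # material part: detFg * Fe_iK Fginv_AL C_KLMN Fe_jM Fginv_BN
        T1 = np.einsum("eqik,eqklmn->eqilmn", Fe, Ct, optimize=True)
        T2 = np.einsum("eqal,eqilmn->eqiamn", Fg_inv, T1, optimize=True)
        T3 = np.einsum("eqjm,eqiamn->eqiajn", Fe, T2, optimize=True)
        A2 = np.einsum("eqbn,eqiajn->eqiajb", Fg_inv, T3, optimize=True)
        w = sp_.wdet * det_Fg
        G = sp_.grad_p2
        tmp = np.einsum("eqaA,eqiAjB->eqaijB", G, A2)
        Ke2 = np.einsum("eq,eqaijB,eqbB->eaibj", w, tmp, G)
        Kgeo = np.einsum("eq,eqaA,eqBA,eqbB->eab", w, G, GSG, G, optimize=True)
        Ke = Ke2 + Kgeo[:, :, None, :, None] * self._eye[None, None, :, None, :]
        K_uu = sp_.assemble_uu(Ke) + self.K_spring
        Hcav = self._cavity_hessian(u, cavity_pressures)
        if Hcav is not None:
            K_uu = K_uu + Hcav
        # dS/dp = -Je C^{-1}  =>  dP_ref/dp = -detFg Je F^{-T}
        FeinvT = np.swapaxes(np.linalg.inv(Fe), -1, -2)
        FinvT = np.einsum("eqik,eqak->eqia", FeinvT, Fg_inv)
        dPdp = -(det_Fg * Je)[..., None, None] * FinvT
        Kup_e = np.einsum(
            "eq,eqaA,eqiA,qc->eaic", sp_.wdet, G, dPdp, sp_.p1_vals, optimize=True
        )
        K_up = sp_.assemble_up(Kup_e)
        K_pu = (-K_up.T).tocsr()
        g_cols = [self.cavities[name].gradient(u) for name in constrained]
        return K_uu, K_up, K_pu, g_cols

    # -- Newton ---------------------------------------------------------------

    def solve(
        self,
        sol: MechSolution | None = None,
        pressures: dict | None = None,
        volume_targets: dict | None = None,
        t_sa=None,
        Fg_inv=None,
        det_Fg=None,
        tol: float = 1e-4,
        max_iter: int = 80,
    ) -> MechSolution:
        """Solve one equilibrium.

        ``pressures`` prescribes cavity pressures (kPa); ``volume_targets``
        (ml) turns those cavities into volume constraints whose multipliers
        are returned as the cavity pressures.
        """
        sp_ = self.space
        if sol is None:
            sol = MechSolution(
                np.zeros(sp_.n_udof), np.zeros(sp_.n_pdof),
                {k: 0.0 for k in self.cavities},
            )
        else:
            sol = sol.copy()
        pressures = dict(pressures or {})
        volume_targets = dict(volume_targets or {})
        constrained = [n for n in self.cavities if n in volume_targets]
        u, p = sol.u, sol.p
        P_mult = {n: sol.cavity_pressures.get(n, 0.0) for n in constrained}

        def _resnorm(uu, pp, Pm):
            self.stats["residual_evals"] += 1
            cav = {**pressures, **Pm}
            with np.errstate(over="ignore", invalid="ignore"):
                Ru, Rp, Rc, st0 = self.residual(
                    uu, pp, cav, t_sa, Fg_inv, det_Fg, volume_targets
                )
            vec = np.concatenate([Ru, Rp, Rc if len(Rc) else np.empty(0)])
            if not np.all(np.isfinite(vec)):
                return np.inf, None, None
            with np.errstate(over="ignore"):
                # an overflowing norm of a huge trial residual is simply a
                # rejected line-search step, not an error
                return float(np.linalg.norm(vec)), vec, cav

        res, rvec, cav_P = _resnorm(u, p, P_mult)
        if not np.isfinite(res):
            raise NewtonError("non-finite residual at the initial guess")
        nu, npd, nc = sp_.n_udof, sp_.n_pdof, len(constrained)

        self.stats["solves"] += 1

        def _factorize():
            self.stats["factorizations"] += 1
            st = self._state(u, p, t_sa, Fg_inv, det_Fg, want_tangent=True)
            K_uu, K_up, K_pu, g_cols = self.jacobian(
                u, p, st, cav_P, Fg_inv, det_Fg, constrained
            )
            top = [K_uu, K_up]
            if nc:
                top.append(sp.csr_matrix(-np.column_stack(g_cols)))
            rows = [sp.hstack(top)]
            rows.append(sp.hstack([K_pu, sp.csr_matrix((npd, npd + nc))]))
            if nc:
                # constraint row in ml to match the residual scale
                Gc = sp.csr_matrix(np.column_stack(g_cols) / CavityMeter.ML).T
                rows.append(sp.hstack([Gc, sp.csr_matrix((nc, npd + nc))]))
            J = sp.vstack(rows).tocsc()
            return _ScaledLU(J)

        # modified Newton: reuse the LU of the tangent from a previous solve
        # (or iteration) and refactorize only when convergence degrades
        lu = None
        if self._lu_cache is not None and self._lu_cache[0] == nc:
            lu = self._lu_cache[1]
        lu_fresh = False  # factorized at the current iterate?
        for it in range(max_iter):
            self.stats["iterations"] += 1
            if res < tol:
                self._lu_cache = (nc, lu) if lu is not None else None
                return MechSolution(u, p, cav_P, n_iter=it)
            if lu is None:
                lu = _factorize()
                lu_fresh = True
            dx = lu.solve(-rvec)
            if not np.all(np.isfinite(dx)):
                if lu_fresh:
                    raise NewtonError("non-finite Newton increment")
                lu, lu_fresh = None, False
                continue
            umax = np.abs(dx[:nu]).max() if nu else 0.0
            damp = 1.0 if umax < 5.0 else 5.0 / umax  # cap 5 mm per iteration
            # backtracking line search on the residual norm
            accepted = False
            for _ in range(8):
                u_t = u + damp * dx[:nu]
                p_t = p + damp * dx[nu : nu + npd]
                Pm_t = {
                    name: P_mult[name] + damp * dx[nu + npd + k]
                    for k, name in enumerate(constrained)
                }
                res_t, rvec_t, cav_t = _resnorm(u_t, p_t, Pm_t)
                if res_t < res or res_t < tol:
                    ratio = res_t / max(res, 1e-300)
                    u, p, P_mult, res, rvec, cav_P = u_t, p_t, Pm_t, res_t, rvec_t, cav_t
                    accepted = True
                    break
                damp *= 0.5
            if not accepted:
                if not lu_fresh:
                    lu, lu_fresh = None, False  # stale tangent: refactorize
                    continue
                raise NewtonError(
                    f"line search failed at iteration {it} (residual {res:.3e})"
                )
            # stale-tangent iterations cost only a backsolve and a residual
            # (an order of magnitude cheaper than a factorization), so
            # tolerate quite slow linear contraction before paying for a
            # refactorization at the new iterate
            if ratio > self.refactor_ratio or (it > 0 and it % 25 == 0):
                lu = None
            lu_fresh = False
        if res < tol:
            self._lu_cache = (nc, lu) if lu is not None else None
            return MechSolution(u, p, cav_P, n_iter=max_iter)
        raise NewtonError(
            f"Newton did not converge in {max_iter} iterations (residual {res:.3e})"
        )

    def solve_stepped(self, target_pressures, sol=None, n_steps=4, **kw):
        """Pressure ramp with adaptive substepping on Newton failure.

        On a cold start (``sol is None``) the volumetric penalty is ramped as
        well: the pressure ramp runs penalty-free (the Lagrange multiplier
        alone keeps the solve robust far from equilibrium), then the penalty
        is switched on in decades with warm restarts.
        """
        cold = sol is None
        kappa_target = self.kappa
        if cold and kappa_target > 0.0:
            self.kappa = 0.0
            self._lu_cache = None
        try:
            start = {
                k: (sol.cavity_pressures.get(k, 0.0) if sol is not None else 0.0)
                for k in target_pressures
            }
            frac = 0.0
            step = 1.0 / n_steps
            while frac < 1.0 - 1e-12:
                trial = min(1.0, frac + step)
                P = {
                    k: start[k] + (target_pressures[k] - start[k]) * trial
                    for k in target_pressures
                }
                try:
                    sol = self.solve(sol, pressures=P, **kw)
                    frac = trial
                except NewtonError:
                    step *= 0.5
                    if step < 1e-3:
                        raise
            if cold and kappa_target > 0.0:
                sol = self.continue_kappa(
                    sol,
                    kappa_target,
                    lambda guess: self.solve(
                        guess, pressures=dict(target_pressures), **kw
                    ),
                )
        finally:
            self.kappa = kappa_target
        return sol

    def continue_kappa(self, sol, kappa_target, resolve, state_fn=None,
                       kappa_start=0.0):
        """Raise the effective volumetric penalty to ``kappa_target`` in
        geometric stages starting from the penalty-free solution ``sol``.

        ``resolve(guess)`` must re-solve the equilibrium at the current
        ``self.kappa``; ``state_fn(sol)`` evaluates the constitutive state
        (defaults to the growth-free state).  Each stage projects the
        current J_e defect onto the pressure space so that the effective
        pressure p_eff = p - kappa (J_e - 1) stays continuous and the stage
        starts near equilibrium.  ``self.kappa`` is left at ``kappa_target``.
        """
        if state_fn is None:
            state_fn = lambda s: self._state(s.u, s.p, want_tangent=False)
        # lumped P1 mass for projecting quadrature fields onto p
        m_p = self.space.residual_p(np.ones_like(self.space.wdet))
        kap_done = kappa_start
        kap_next = max(kappa_target / 64.0, 2.0 * kappa_start)
        kap_next = min(kap_next, kappa_target)
        while kap_done < kappa_target:
            st = state_fn(sol)
            jdef = self.space.residual_p(st["Je"] - 1.0) / m_p
            guess = sol.copy()
            guess.p = sol.p + (kap_next - kap_done) * jdef
            self.kappa = kap_next
            try:
                sol = resolve(guess)
                kap_done = kap_next
                kap_next = min(kappa_target, 2.0 * kap_done)
            except NewtonError:
                trial = (
                    np.sqrt(kap_done * kap_next) if kap_done > 0.0 else kap_next / 10.0
                )
                if trial < 1e-8 * kappa_target or trial > 0.97 * kap_next:
                    raise
                kap_next = trial
        return sol

    def incompressibility_error(self, sol: MechSolution, Fg_inv=None, det_Fg=None) -> float:
        """Volume-weighted L2 norm of (J_e - 1)."""
        st = self._state(sol.u, sol.p, None, Fg_inv, det_Fg, want_tangent=False)
        w = self.space.wdet
        return float(np.sqrt(np.sum(w * (st["Je"] - 1.0) ** 2) / np.sum(w)))


def windkessel_step(P_cavity: float, P_art: float, wk: WindkesselParams, dt: float):
    """One backward-Euler step of the 3-element Windkessel.

    Returns ``(Q, P_art_new)`` with outflow Q in ml/ms, clipped at zero when
    the valve closes (cavity pressure below arterial pressure).
    """
    denom = 1.0 + dt / (wk.C_a * wk.R_c) + dt / (wk.C_a * wk.R_p)
    P_new = (P_art + dt * P_cavity / (wk.C_a * wk.R_c)) / denom
    Q = (P_cavity - P_new) / wk.R_c
    if Q < 0.0:
        P_new = P_art / (1.0 + dt / (wk.C_a * wk.R_p))
        Q = 0.0
    return Q, P_new


def _kappa_rescue(solver, sol_start, V, t_sa):
    """Final fallback for a failed active step: re-solve from the previous
    converged state with the volumetric penalty lowered to kappa/64 (the
    pressure multiplier alone keeps the solve well-behaved far from the
    solution branch) and continue the penalty back up.  This can traverse
    states where the full-penalty Newton stalls."""
    kappa_target = solver.kappa
    resolve = lambda g: solver.solve(g, volume_targets=dict(V), t_sa=t_sa)
    try:
        solver.kappa = kappa_target / 64.0
        solver._lu_cache = None
        sol = resolve(sol_start)
        if kappa_target > 0.0:
            sol = solver.continue_kappa(
                sol, kappa_target, resolve, kappa_start=kappa_target / 64.0
            )
    finally:
        solver.kappa = kappa_target
        solver._lu_cache = None
    return sol


def _substep_active(solver, sol_start, V, t, dt, t_init_qp):
    """Last-resort continuation for a failed active step: advance the
    activation time from the previous converged state in smaller increments
    (the active-tension rise over one dt can outrun the Newton radius on
    strongly remodeled geometries)."""
    for m in (4, 16):
        sol = sol_start
        try:
            for j in range(1, m + 1):
                t_j = t - dt + dt * j / m
                sol = solver.solve(
                    sol, volume_targets=dict(V), t_sa=t_j - t_init_qp
                )
            return sol
        except NewtonError:
            continue
    raise NewtonError("active step failed despite activation-time sub-stepping")


def run_cycle(
    solver: MechanicsSolver,
    circulation: CirculationParams,
    t_init_qp: np.ndarray | None,
    edv_targets: dict | None = None,
    fill_pressures: dict | None = None,
    record_displacement: bool = False,
) -> CycleRecord:
    """Simulate one full cardiac cycle and record PV data and lambda_f,max.

    Filling runs either to prescribed end-diastolic volumes (``edv_targets``,
    ml; pressure ramp followed by an exact volume-constrained solve) or to
    prescribed end-diastolic pressures (``fill_pressures``, kPa).  Then, with
    per-quadrature-point activation times ``t_init_qp`` (ms), the active
    phases are stepped at ``circulation.dt``: isovolumic contraction until
    the cavity pressure exceeds the arterial opening pressure, Windkessel
    ejection until the outflow drops below the cutoff, isovolumic relaxation
    until the filling-initiation pressure.
    """
    cavs = list(solver.cavities)
    wk = {"LV": circulation.lv, "RV": circulation.rv}

    # ---- passive filling ----------------------------------------------------
    if edv_targets is not None:
        ramp = {c: 0.3 * KPA_PER_MMHG for c in cavs}
        sol = solver.solve_stepped(dict(ramp), n_steps=2)
        for _ in range(80):
            vols = {c: solver.cavities[c].volume(sol.u) for c in cavs}
            if all(vols[c] >= edv_targets[c] - 1e-9 for c in cavs):
                break
            ramp = {
                c: ramp[c] * (1.3 if vols[c] < edv_targets[c] else 1.0) for c in cavs
            }
            sol = solver.solve_stepped(dict(ramp), sol=sol, n_steps=1)
        else:
            raise NewtonError("filling ramp failed to reach the target EDV")
        sol = solver.solve(sol, volume_targets=dict(edv_targets))
        ed_pressures = {c: sol.cavity_pressures[c] for c in cavs}
        V = dict(edv_targets)
    elif fill_pressures is not None:
        sol = solver.solve_stepped(dict(fill_pressures), n_steps=6)
        ed_pressures = dict(fill_pressures)
        V = {c: solver.cavities[c].volume(sol.u) for c in cavs}
    else:
        raise ValueError("provide edv_targets or fill_pressures")

    edv = dict(V)
    u_ed = sol.u.copy()
    st = solver._state(sol.u, sol.p, want_tangent=False)
    lam_ed = np.sqrt(np.einsum("eqi,eqij,eqj->eq", solver.f0, st["C"], solver.f0))
    lam_max = np.ones_like(lam_ed)

    times = [0.0]
    volumes = {c: [V[c]] for c in cavs}
    pressures = {c: [ed_pressures[c]] for c in cavs}
    phases = {c: ["ed"] for c in cavs}

    if t_init_qp is None:
        return CycleRecord(
            np.array(times), {c: np.array(v) for c, v in volumes.items()},
            {c: np.array(v) for c, v in pressures.items()},
            phases, lam_max, ed_pressures, edv, dict(V),
            u_ed if record_displacement else None,
        )

    # ---- active phases ------------------------------------------------------
    dt = circulation.dt
    phase = {c: "ivc" for c in cavs}
    P_art = {c: wk[c].P_open for c in cavs}
    esv = dict(V)
    t = 0.0
    n_steps = int(round(circulation.cycle_duration / dt))
    sol_prev = None
    for _ in range(n_steps):
        t += dt
        t_sa = t - t_init_qp
        # linear extrapolation of the previous two converged states as the
        # Newton predictor
        if sol_prev is not None:
            guess = sol.copy()
            guess.u = 2.0 * sol.u - sol_prev.u
            guess.p = 2.0 * sol.p - sol_prev.p
            guess.cavity_pressures = {
                c: 2.0 * sol.cavity_pressures[c] - sol_prev.cavity_pressures[c]
                for c in sol.cavity_pressures
            }
        else:
            guess = sol
        sol_prev = sol
        try:
            sol = solver.solve(guess, volume_targets=dict(V), t_sa=t_sa)
        except NewtonError:
            try:
                # fall back to the unextrapolated previous state
                sol = solver.solve(sol_prev, volume_targets=dict(V), t_sa=t_sa)
            except NewtonError:
                try:
                    sol = _substep_active(solver, sol_prev, V, t, dt, t_init_qp)
                except NewtonError:
                    sol = _kappa_rescue(solver, sol_prev, V, t_sa)
        P = {c: sol.cavity_pressures[c] for c in cavs}
        for c in cavs:
            if phase[c] == "ivc" and P[c] > wk[c].P_open:
                phase[c] = "eject"
            if phase[c] == "eject":
                Q, P_art[c] = windkessel_step(P[c], P_art[c], wk[c], dt)
                if Q < circulation.outflow_cutoff:
                    phase[c] = "ivr"
                else:
                    V[c] = V[c] - Q * dt
            elif phase[c] == "ivr" and P[c] <= wk[c].P_fill:
                phase[c] = "done"
            esv[c] = min(esv[c], V[c])
        C_now = solver._state(sol.u, sol.p, want_tangent=False)["C"]
        lam = np.sqrt(np.einsum("eqi,eqij,eqj->eq", solver.f0, C_now, solver.f0))
        np.maximum(lam_max, lam / lam_ed, out=lam_max)
        times.append(t)
        for c in cavs:
            volumes[c].append(V[c])
            pressures[c].append(P[c])
            phases[c].append(phase[c])
        if all(phase[c] == "done" for c in cavs):
            break

    return CycleRecord(
        np.array(times),
        {c: np.array(v) for c, v in volumes.items()},
        {c: np.array(v) for c, v in pressures.items()},
        phases,
        lam_max,
        ed_pressures,
        edv,
        esv,
        u_ed if record_displacement else None,
    )
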