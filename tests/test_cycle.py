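"""Windkessel afterload and quasi-static FE cycle-solver tests.

FE solves run on a small truncated spherical shell so the whole module
stays fast; full biventricular beats are exercised by the acceptance suite.
"""

import numpy as np
import pytest

from cardiogrowth.cycle import (
    CirculationParams,
    MechanicsSolver,
    WindkesselParams,
    run_cycle,
    windkessel_step,
)
from cardiogrowth.fem import FESpace
from cardiogrowth.fibers import assign_fibers
from cardiogrowth.geometry import cavity_volume_from_surface
from cardiogrowth.mechanics import ActiveParams, PassiveParams


@pytest.fixture(scope="module")
def shell_solver(shell_mesh):
    space = FESpace(shell_mesh)
    frame = assign_fibers(shell_mesh, space=space)
    return MechanicsSolver(space, frame, PassiveParams(), ActiveParams())


# ---------------------------------------------------------------------------
# Windkessel
# ---------------------------------------------------------------------------


def test_windkessel_dc_gain():
    """Holding the cavity pressure, the arterial pressure settles at the
    resistive divider value P R_p / (R_p + R_c)."""
    wk = WindkesselParams(R_c=6.7, R_p=160.0, C_a=12.0, P_open=10.0, P_fill=0.7)
    P_cav, P_art, dt = 16.0, 10.0, 5.0
    for _ in range(20000):
        Q, P_art = windkessel_step(P_cav, P_art, wk, dt)
    expect = P_cav * wk.R_p / (wk.R_p + wk.R_c)
    assert P_art == pytest.approx(expect, rel=1e-6)
    assert Q == pytest.approx(P_cav / (wk.R_p + wk.R_c), rel=1e-6)


def test_windkessel_diastolic_decay():
    """With the valve closed the arterial pressure decays on the R_p C_a
    time constant (backward-Euler discretization of the RC circuit)."""
    wk = WindkesselParams(R_c=6.7, R_p=160.0, C_a=12.0, P_open=10.0, P_fill=0.7)
    dt, P0 = 5.0, 12.0
    P = P0
    n = 100
    for _ in range(n):
        Q, P = windkessel_step(0.0, P, wk, dt)
        assert Q == 0.0
    expect = P0 / (1.0 + dt / (wk.R_p * wk.C_a)) ** n
    assert P == pytest.approx(expect, rel=1e-12)
    # and the discrete decay converges to exp(-t/RC) as dt -> 0
    t_end, rc = 500.0, wk.R_p * wk.C_a
    for dt_small in (1.0, 0.25):
        P = P0
        for _ in range(int(t_end / dt_small)):
            _, P = windkessel_step(0.0, P, wk, dt_small)
        assert P == pytest.approx(P0 * np.exp(-t_end / rc), rel=5e-2 * dt_small)


def test_windkessel_valve_rectifies():
    wk = WindkesselParams(R_c=1.0, R_p=10.0, C_a=1.0, P_open=1.0, P_fill=0.1)
    Q, _ = windkessel_step(0.5, 2.0, wk, 1.0)  # arterial above cavity
    assert Q == 0.0


# ---------------------------------------------------------------------------
# FE equilibrium on the shell
# ---------------------------------------------------------------------------


def test_inflation_volume_pressure_duality(shell_solver):
    """Inflating to a pressure and then constraining to the inflated volume
    must recover that pressure as the constraint multiplier."""
    P = 1.0  # kPa
    sol = shell_solver.solve_stepped({"LV": P}, n_steps=4)
    V = shell_solver.cavities["LV"].volume(sol.u)
    V0 = shell_solver.cavities["LV"].volume(np.zeros_like(sol.u))
    assert V > V0  # inflation grows the cavity
    sol2 = shell_solver.solve(sol, volume_targets={"LV": V})
    assert sol2.cavity_pressures["LV"] == pytest.approx(P, rel=5e-3)
    # volume constraint is satisfied tightly
    assert shell_solver.cavities["LV"].volume(sol2.u) == pytest.approx(V, abs=1e-4)


def test_inflation_incompressible(shell_solver):
    sol = shell_solver.solve_stepped({"LV": 1.0}, n_steps=4)
    assert shell_solver.incompressibility_error(sol) < 1e-3


def test_unloading_returns_to_reference(shell_solver):
    """Hyperelasticity: unloading the inflated shell recovers the reference."""
    sol = shell_solver.solve_stepped({"LV": 1.0}, n_steps=4)
    back = shell_solver.solve_stepped({"LV": 0.0}, sol=sol, n_steps=2)
    assert np.abs(back.u).max() < 1e-3  # mm


def test_cavity_meter_matches_divergence_volume(shell_mesh, shell_solver):
    V_meter = shell_solver.cavities["LV"].volume(
        np.zeros(shell_solver.space.n_udof)
    )
    V_direct = cavity_volume_from_surface(shell_mesh, "lv_endo")
    assert V_meter == pytest.approx(V_direct, rel=1e-12)


def test_active_contraction_raises_pressure(shell_solver):
    """At fixed volume, activating the fibers raises the cavity pressure."""
    P_fill = 0.5
    sol = shell_solver.solve_stepped({"LV": P_fill}, n_steps=3)
    V = shell_solver.cavities["LV"].volume(sol.u)
    t_sa = np.full(shell_solver.f0.shape[:2], 100.0)  # mid-upstroke everywhere
    sol_act = shell_solver.solve(sol, volume_targets={"LV": V}, t_sa=t_sa)
    assert sol_act.cavity_pressures["LV"] > 2.0 * P_fill


def test_run_cycle_passive_only(shell_solver):
    """Without an activation map run_cycle performs filling only."""
    circ = CirculationParams()
    rec = run_cycle(shell_solver, circ, None, fill_pressures={"LV": 1.0})
    assert rec.edv["LV"] == rec.esv["LV"]
    assert len(rec.time) == 1
    assert np.all(rec.lam_f_max == 1.0)
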