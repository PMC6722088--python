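"""Monodomain Aliev-Panfilov electrophysiology tests."""

import numpy as np
import pytest

from cardiogrowth.ep import EPParams, MonodomainSolver, activation_map


def _cable_cv(slab_mesh, params, fiber=None, probes=(20.0, 45.0)):
    """Conduction velocity (mm/ms) along the slab from two probe planes."""
    if fiber is not None:
        fiber = np.broadcast_to(fiber, (slab_mesh.n_cells, 3)).copy()
    solver = MonodomainSolver(slab_mesh, fiber, params)
    state = solver.run(np.array([0.0, 0.5, 0.5]), t_end=400.0)
    amap = activation_map(state)
    assert amap["n_unactivated"] == 0
    x = slab_mesh.vertices[:, 0]
    t = state.t_init
    times = []
    for xp in probes:
        sel = np.isclose(x, xp, atol=0.6)
        assert sel.any()
        times.append(t[sel].mean())
    return (probes[1] - probes[0]) / (times[1] - times[0])


def test_rest_state_is_invariant(slab_mesh):
    """Without a stimulus the resting state (phi = r = 0) is an equilibrium."""
    solver = MonodomainSolver(slab_mesh, None, EPParams())
    state = solver.initial_state()
    for _ in range(50):
        state = solver.step(state)
    assert np.allclose(state.phi, 0.0, atol=1e-12)
    assert np.allclose(state.r, 0.0, atol=1e-12)
    assert not state.activated.any()


def test_stimulus_triggers_full_capture(slab_mesh):
    solver = MonodomainSolver(slab_mesh, None, EPParams())
    state = solver.run(np.array([0.0, 0.5, 0.5]), t_end=400.0)
    assert state.activated.all()
    # upstroke overshoots towards phi ~ 1, never diverges
    assert state.phi.max() < 2.0


def test_cv_scales_with_sqrt_diffusivity(slab_mesh):
    base = EPParams(d_ani=0.0)
    fast = EPParams(d_ani=0.0, d_iso=4.0 * base.d_iso)
    cv1 = _cable_cv(slab_mesh, base)
    cv2 = _cable_cv(slab_mesh, fast)
    assert cv2 / cv1 == pytest.approx(2.0, rel=0.15)


def test_anisotropy_speeds_conduction_along_fiber(slab_mesh):
    iso = EPParams(d_ani=0.0)
    ani = EPParams()  # d_ani > 0
    cv_iso = _cable_cv(slab_mesh, iso)
    cv_along = _cable_cv(slab_mesh, ani, fiber=np.array([1.0, 0.0, 0.0]))
    cv_across = _cable_cv(slab_mesh, ani, fiber=np.array([0.0, 1.0, 0.0]))
    assert cv_along > 1.2 * cv_iso
    assert cv_across == pytest.approx(cv_iso, rel=0.05)


def test_activation_time_interpolated_monotone(slab_mesh):
    """Activation times grow monotonically with distance from the stimulus."""
    solver = MonodomainSolver(slab_mesh, None, EPParams(d_ani=0.0))
    state = solver.run(np.array([0.0, 0.5, 0.5]), t_end=400.0)
    x = slab_mesh.vertices[:, 0]
    order = np.argsort(x)
    t_sorted = state.t_init[order]
    # average over the 4 vertices per x-plane, then require monotone increase
    t_plane = t_sorted.reshape(-1, 4).mean(axis=1)
    assert np.all(np.diff(t_plane) > -1e-9)


def test_params_validation():
    with pytest.raises(ValueError):
        EPParams(d_iso=-1.0)
    with pytest.raises(ValueError):
        EPParams(alpha=1.5)
    with pytest.raises(ValueError):
        EPParams(dt=-0.1)


def test_stimulus_mask_requires_vertices(slab_mesh):
    solver = MonodomainSolver(slab_mesh, None, EPParams())
    with pytest.raises(ValueError):
        solver.stimulus_mask(np.array([1e4, 1e4, 1e4]), radius=1.0)
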