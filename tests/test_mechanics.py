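"""Constitutive-law unit tests: Fung passive stress, active twitch."""

import numpy as np
import pytest

from cardiogrowth.mechanics import (
    ActiveParams,
    PassiveParams,
    active_stress,
    active_tension,
    fung_stress_fiber,
    fung_tangent_fiber,
    omega_schedule,
    passive_stress,
    sarcomere_length,
    strain_energy,
    volumetric_stress,
)


def _random_strain(rng, scale=0.08):
    A = rng.standard_normal((3, 3)) * scale
    return 0.5 * (A + A.T)


def test_fung_stress_is_energy_gradient(rng):
    """dW/dE by central differences matches fung_stress_fiber to O(h^2)."""
    params = PassiveParams()
    E = _random_strain(rng)
    S = fung_stress_fiber(E, params)
    h = 1e-6
    fd = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            Ep, Em = E.copy(), E.copy()
            Ep[i, j] += h
            Em[i, j] -= h
            fd[i, j] = (strain_energy(Ep, params) - strain_energy(Em, params)) / (2 * h)
    assert np.allclose(S, fd, rtol=1e-6, atol=1e-9)


def test_fung_tangent_is_stress_jacobian(rng):
    params = PassiveParams()
    E = _random_strain(rng)
    Ct = fung_tangent_fiber(E, params)
    h = 1e-6
    for k in range(3):
        for l in range(3):
            Ep, Em = E.copy(), E.copy()
            Ep[k, l] += h
            Em[k, l] -= h
            fd = (fung_stress_fiber(Ep, params) - fung_stress_fiber(Em, params)) / (
                2 * h
            )
            assert np.allclose(Ct[..., k, l], fd, rtol=5e-5, atol=1e-8)


def test_passive_stress_frame_invariance(rng):
    """Rotating strain and frame together rotates the stress."""
    params = PassiveParams()
    E = _random_strain(rng)
    f0 = np.array([1.0, 0.0, 0.0])
    s0 = np.array([0.0, 1.0, 0.0])
    n0 = np.array([0.0, 0.0, 1.0])
    S = passive_stress(E, 0.3, params, f0, s0, n0)
    # random rotation
    A = rng.standard_normal((3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    E_rot = Q @ E @ Q.T
    S_rot = passive_stress(E_rot, 0.3, params, Q @ f0, Q @ s0, Q @ n0)
    assert np.allclose(S_rot, Q @ S @ Q.T, atol=1e-10)


def test_passive_stress_zero_strain_gives_hydrostatic():
    params = PassiveParams()
    eye = np.eye(3)
    S = passive_stress(np.zeros((3, 3)), 0.7, params, eye[0], eye[1], eye[2])
    assert np.allclose(S, -0.7 * np.eye(3))


def test_volumetric_stress_isochoric_zero():
    C = np.diag([4.0, 0.5, 0.5])  # det = 1
    S = volumetric_stress(C, 1.3)
    assert np.allclose(S, -1.3 * np.linalg.inv(C))


def test_omega_schedule_piecewise():
    p = ActiveParams()
    l = 1.9  # t_r = 1048*1.9 - 1600 = 391.2 ms
    t_r = p.relaxation_time(l)
    assert np.isclose(omega_schedule(0.0, l, p), 0.0)
    assert np.isclose(omega_schedule(p.t_0 / 2, l, p), np.pi / 2)
    assert np.isclose(omega_schedule(p.t_0, l, p), np.pi)
    assert np.isclose(omega_schedule(p.t_0 + t_r / 2, l, p), 1.5 * np.pi)
    assert omega_schedule(p.t_0 + t_r + 1.0, l, p) == 0.0
    assert omega_schedule(-5.0, l, p) == 0.0


def test_omega_schedule_rejects_bad_relaxation():
    p = ActiveParams()
    with pytest.raises(ValueError):
        omega_schedule(10.0, 1.6, ActiveParams(m=10.0, b_rel=-100.0))
    # below l_0 a nonpositive t_r is harmless (tension is zero anyway)
    w = omega_schedule(10.0, 1.2, ActiveParams(m=10.0, b_rel=-100.0))
    assert np.isfinite(w)


def test_active_tension_bounds_and_zeros():
    p = ActiveParams()
    t = np.linspace(-50.0, 900.0, 400)
    l = np.linspace(1.4, 2.3, 11)
    T = active_tension(t[:, None], l[None, :], p)
    assert np.all(T >= 0.0)
    assert np.all(T <= p.T_max + 1e-12)
    # zero at activation onset and before it
    assert np.all(active_tension(0.0, l, p) == 0.0)
    assert np.all(active_tension(-1.0, l, p) == 0.0)
    # zero at and below the zero-tension sarcomere length
    assert np.all(active_tension(t, p.l_0, p) == 0.0)
    assert np.all(active_tension(t, p.l_0 - 0.1, p) == 0.0)
    # peak near mid-twitch is strictly positive
    assert active_tension(p.t_0, 2.0, p) > 0.0


def test_active_tension_length_dependence():
    """Longer sarcomeres (within range) develop more tension (Frank-Starling)."""
    p = ActiveParams()
    T1 = active_tension(p.t_0, 1.8, p)
    T2 = active_tension(p.t_0, 2.1, p)
    assert T2 > T1 > 0


def test_active_stress_structure(rng):
    f0 = rng.standard_normal(3)
    f0 /= np.linalg.norm(f0)
    S = active_stress(12.0, f0)
    assert np.allclose(S, 12.0 * np.outer(f0, f0))
    with pytest.raises(ValueError):
        active_stress(-1.0, f0)


def test_sarcomere_length():
    C = np.diag([1.21, 1.0, 1.0])
    l = sarcomere_length(C, np.array([1.0, 0, 0]), 1.85)
    assert np.isclose(l, 1.85 * 1.1)
    with pytest.raises(ValueError):
        sarcomere_length(np.diag([-1.0, 1, 1]), np.array([1.0, 0, 0]), 1.85)


def test_passive_params_validation():
    with pytest.raises(ValueError):
        PassiveParams(C=-1.0)
    with pytest.warns(UserWarning):
        PassiveParams(b_f=10.0, b_xx=13.3)
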