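"""Growth-law unit tests against analytic oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiogrowth.growth import (
    DirectionGrowthParams,
    GrowthParams,
    GrowthState,
    closed_form_theta,
    evolve_growth,
    fiber_stretch,
    growth_tensor,
    half_life,
    rate_limiter,
)


def _frame(rng, n=6):
    f = rng.standard_normal((n, 3))
    f /= np.linalg.norm(f, axis=-1, keepdims=True)
    a = rng.standard_normal((n, 3))
    s = a - np.sum(a * f, axis=-1, keepdims=True) * f
    s /= np.linalg.norm(s, axis=-1, keepdims=True)
    return f, s, np.cross(f, s)


def test_growth_tensor_eigenstructure(rng):
    f, s, n = _frame(rng)
    tf, ts, tn = 1.3, 0.8, 1.1
    Fg = growth_tensor(tf, ts, tn, f, s, n)
    assert np.allclose(np.einsum("eij,ej->ei", Fg, f), tf * f)
    assert np.allclose(np.einsum("eij,ej->ei", Fg, s), ts * s)
    assert np.allclose(np.einsum("eij,ej->ei", Fg, n), tn * n)
    assert np.allclose(np.linalg.det(Fg), tf * ts * tn)
    # inverse by reciprocal multipliers
    Fg_inv = growth_tensor(1 / tf, 1 / ts, 1 / tn, f, s, n)
    assert np.allclose(np.einsum("eij,ejk->eik", Fg, Fg_inv), np.eye(3), atol=1e-12)


def test_growth_tensor_rejects_bad_frames(rng):
    f, s, n = _frame(rng)
    with pytest.raises(ValueError):
        growth_tensor(1.0, 1.0, 1.0, 2 * f, s, n)
    with pytest.raises(ValueError):
        growth_tensor(-0.5, 1.0, 1.0, f, s, n)


def test_fiber_stretch_simple():
    C = np.diag([4.0, 1.0, 1.0])
    assert np.isclose(fiber_stretch(C, np.array([1.0, 0, 0])), 2.0)
    with pytest.raises(ValueError):
        fiber_stretch(np.diag([-1.0, 1.0, 1.0]), np.array([1.0, 0, 0]))


def test_rate_limiter_branches_and_saturation():
    p = DirectionGrowthParams(tau_g=3.8, tau_rg=9.6)
    # forward branch at theta_max is zero; reverse branch at theta_min is zero
    assert rate_limiter(p.theta_max, +0.1, p) == 0.0
    assert rate_limiter(p.theta_min, -0.1, p) == 0.0
    # at theta_0 = 1 the rates equal the prescribed time constants' limiters
    k_fwd = rate_limiter(1.0, +0.1, p)
    k_rev = rate_limiter(1.0, -0.1, p)
    span = p.theta_max - p.theta_min
    assert np.isclose(k_fwd, (p.theta_max - 1.0) / span / p.tau_g)
    assert np.isclose(k_rev, (1.0 - p.theta_min) / span / p.tau_rg)


def test_closed_form_matches_euler_forward_and_reverse():
    p = DirectionGrowthParams(tau_g=3.8, tau_rg=9.6)
    params = GrowthParams(f=p, s=p, n=p)
    for dev in (0.06, -0.06):
        state = GrowthState.uniform((1,))
        state.lam_h = np.zeros(1)
        t, dt = 0.0, 0.25
        while t < 60.0 - 1e-9:
            state = evolve_growth(state, np.full(1, dev), params, dt, n_substeps=4)
            t += dt
        exact = closed_form_theta(60.0, dev, p)
        assert abs(state.theta_f[0] - exact) < 2e-4


def test_half_life_matches_closed_form():
    p = DirectionGrowthParams(tau_g=9.6, tau_rg=9.6)
    dev = 0.06
    t_half = half_life(p.tau_g, p.theta_max, p.theta_min, dev)
    th = closed_form_theta(t_half, dev, p)
    frac = (th - p.theta_0) / (p.theta_max - p.theta_0)
    assert np.isclose(frac, 0.5, atol=1e-12)


def test_equal_rates_variant():
    gp = GrowthParams()
    eq = gp.with_equal_rates()
    assert eq.f.tau_rg == eq.f.tau_g == gp.f.tau_g
    assert eq.s.tau_rg == eq.s.tau_g == gp.s.tau_g
    # original is untouched (frozen dataclasses)
    assert gp.f.tau_rg == 9.6 and gp.s.tau_rg == 3.8


def test_direction_param_validation():
    with pytest.raises(ValueError):
        DirectionGrowthParams(tau_g=-1.0, tau_rg=1.0)
    with pytest.raises(ValueError):
        DirectionGrowthParams(tau_g=1.0, tau_rg=1.0, theta_min=1.5)


@settings(max_examples=50, deadline=None)
@given(
    dev=st.floats(-0.3, 0.3),
    dt=st.floats(0.1, 30.0),
    theta0=st.floats(0.55, 1.95),
)
def test_theta_stays_in_bounds_and_moves_with_deviation(dev, dt, theta0):
    p = DirectionGrowthParams(tau_g=3.8, tau_rg=9.6, theta_0=theta0)
    params = GrowthParams(f=p, s=p, n=p)
    state = GrowthState(
        theta_f=np.full(1, theta0),
        theta_s=np.full(1, theta0),
        theta_n=np.full(1, theta0),
        lam_h=np.ones(1),
    )
    new = evolve_growth(state, np.full(1, 1.0 + dev), params, dt)
    th = new.theta_f[0]
    assert p.theta_min - 1e-12 <= th <= p.theta_max + 1e-12
    if dev > 0:
        assert th >= theta0 - 1e-12
    elif dev < 0:
        assert th <= theta0 + 1e-12
    else:
        assert th == theta0


def test_evolve_requires_set_point():
    state = GrowthState.uniform((2, 2))
    with pytest.raises(ValueError):
        evolve_growth(state, np.ones((2, 2)), GrowthParams(), 1.0)
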