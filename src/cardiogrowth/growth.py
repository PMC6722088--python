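"""Anisotropic volumetric growth constitutive model.

Growth is described by the multiplicative split F = F_e F_g with a growth
tensor diagonal in the local microstructural frame,

    F_g = theta_f f0 (x) f0 + theta_s s0 (x) s0 + theta_n n0 (x) n0 .

The scalar growth multipliers theta_i evolve by a rate-limited first-order
law driven by the deviation of the maximum elastic myofiber stretch
lambda_f (taken over one cardiac cycle, measured from the end-diastolic
configuration) from its local homeostatic set point lambda_f,h:

    d theta_i / dt = k_i(theta_i) * (lambda_f - lambda_f,h) ,

where the rate-limiting function k_i has separate forward and reverse
branches so growth and reverse growth proceed at different speeds and
saturate smoothly at prescribed bounds [theta_min, theta_max].

Default rate constants follow the calibrated values for chronic
left-ventricular free-wall pacing: the fiber direction grows forward fast
(tau_g = 3.8 d) and reverses slowly (tau_rg = 9.6 d), while the transverse
(sheet / sheet-normal) directions do the opposite.  With gamma = 1 and a
constant stimulus the law integrates in closed form to an exponential
approach toward a bound, which serves as the analytic oracle for the
explicit-Euler integrator used in the coupled simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DirectionGrowthParams",
    "GrowthParams",
    "GrowthState",
    "growth_tensor",
    "fiber_stretch",
    "rate_limiter",
    "evolve_growth",
    "closed_form_theta",
    "half_life",
]

DIRECTIONS = ("f", "s", "n")


@dataclass(frozen=True)
class DirectionGrowthParams:
    """Growth-law constants for one material direction.

    tau_g, tau_rg : forward / reverse growth time constants (days)
    gamma_g, gamma_rg : rate-limiter exponents (dimensionless)
    theta_min, theta_max : hard bounds on the growth multiplier
    theta_0 : initial multiplier (unloaded reference has theta = 1)
    """

    tau_g: float
    tau_rg: float
    gamma_g: float = 1.0
    gamma_rg: float = 1.0
    theta_min: float = 0.5
    theta_max: float = 2.0
    theta_0: float = 1.0

    def __post_init__(self) -> None:
        if not (self.tau_g > 0 and self.tau_rg > 0):
            raise ValueError("growth time constants must be positive")
        if self.gamma_g < 0 or self.gamma_rg < 0:
            raise ValueError("rate-limiter exponents must be nonnegative")
        if not (self.theta_min < self.theta_0 <= self.theta_max):
            raise ValueError(
                "require theta_min < theta_0 <= theta_max, got "
                f"{self.theta_min}, {self.theta_0}, {self.theta_max}"
            )


def _default_f() -> DirectionGrowthParams:
    return DirectionGrowthParams(tau_g=3.8, tau_rg=9.6)


def _default_transverse() -> DirectionGrowthParams:
    return DirectionGrowthParams(tau_g=9.6, tau_rg=3.8)


@dataclass(frozen=True)
class GrowthParams:
    """Per-direction growth constants (defaults: calibrated pacing values)."""

    f: DirectionGrowthParams = field(default_factory=_default_f)
    s: DirectionGrowthParams = field(default_factory=_default_transverse)
    n: DirectionGrowthParams = field(default_factory=_default_transverse)

    def direction(self, i: str) -> DirectionGrowthParams:
        if i not in DIRECTIONS:
            raise ValueError(f"unknown direction {i!r}")
        return getattr(self, i)

    def with_equal_rates(self) -> "GrowthParams":
        """Variant with tau_rg = tau_g in every direction (symmetric-rate model)."""
        return GrowthParams(
            f=replace(self.f, tau_rg=self.f.tau_g),
            s=replace(self.s, tau_rg=self.s.tau_g),
            n=replace(self.n, tau_rg=self.n.tau_g),
        )


@dataclass
class GrowthState:
    """Growth multipliers and homeostatic set point, one value per material point.

    Arrays share an arbitrary common shape (typically (n_cells, n_qp)).
    ``lam_h`` is the homeostatic maximum elastic myofiber stretch field,
    recorded from a normally activated beat.
    """

    theta_f: np.ndarray
    theta_s: np.ndarray
    theta_n: np.ndarray
    lam_h: np.ndarray | None = None

    @classmethod
    def uniform(cls, shape, params: GrowthParams | None = None) -> "GrowthState":
        params = params or GrowthParams()
        return cls(
            theta_f=np.full(shape, params.f.theta_0, dtype=float),
            theta_s=np.full(shape, params.s.theta_0, dtype=float),
            theta_n=np.full(shape, params.n.theta_0, dtype=float),
        )

    def thetas(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.theta_f, self.theta_s, self.theta_n

    def copy(self) -> "GrowthState":
        return GrowthState(
            self.theta_f.copy(),
            self.theta_s.copy(),
            self.theta_n.copy(),
            None if self.lam_h is None else self.lam_h.copy(),
        )

    def det_fg(self) -> np.ndarray:
        return self.theta_f * self.theta_s * self.theta_n


def _check_orthonormal(f0, s0, n0, tol: float = 1e-8) -> None:
    for v in (f0, s0, n0):
        nrm = np.linalg.norm(v, axis=-1)
        if not np.allclose(nrm, 1.0, atol=tol):
            raise ValueError("frame vectors must be unit length")
    if not np.allclose(np.sum(f0 * s0, axis=-1), 0.0, atol=tol):
        raise ValueError("frame not orthogonal (f0 . s0 != 0)")
    if not np.allclose(np.sum(f0 * n0, axis=-1), 0.0, atol=tol):
        raise ValueError("frame not orthogonal (f0 . n0 != 0)")
    if not np.allclose(np.sum(s0 * n0, axis=-1), 0.0, atol=tol):
        raise ValueError("frame not orthogonal (s0 . n0 != 0)")


def growth_tensor(theta_f, theta_s, theta_n, f0, s0, n0, check: bool = True) -> np.ndarray:
    """Assemble F_g = sum_i theta_i e_i (x) e_i over the microstructural frame.

    theta_* may be scalars or arrays broadcasting against the leading shape of
    the frame vectors (each ``(..., 3)``).  Returns ``(..., 3, 3)``.
    """
    f0 = np.asarray(f0, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    n0 = np.asarray(n0, dtype=float)
    if check:
        _check_orthonormal(f0, s0, n0)
    tf = np.asarray(theta_f, dtype=float)[..., None, None]
    ts = np.asarray(theta_s, dtype=float)[..., None, None]
    tn = np.asarray(theta_n, dtype=float)[..., None, None]
    if np.any(tf <= 0) or np.any(ts <= 0) or np.any(tn <= 0):
        raise ValueError("growth multipliers must be positive")
    return (
        tf * f0[..., :, None] * f0[..., None, :]
        + ts * s0[..., :, None] * s0[..., None, :]
        + tn * n0[..., :, None] * n0[..., None, :]
    )


def fiber_stretch(C, f0) -> np.ndarray:
    """Myofiber stretch lambda_f = sqrt(f0 . C f0).

    ``C`` is a right Cauchy-Green tensor ``(..., 3, 3)`` (typically measured
    with respect to the end-diastolic configuration) and ``f0`` the unit fiber
    direction in that configuration.
    """
    C = np.asarray(C, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    if not np.allclose(C, np.swapaxes(C, -1, -2), atol=1e-8 * max(1.0, np.abs(C).max())):
        raise ValueError("C must be symmetric")
    q = np.einsum("...i,...ij,...j->...", f0, C, f0)
    if np.any(q <= 0):
        raise ValueError("C is not positive definite along f0")
    return np.sqrt(q)


def rate_limiter(theta, deviation, p: DirectionGrowthParams) -> np.ndarray:
    """Rate-limiting function k_i(theta, s) in 1/day.

    Forward branch for ``deviation >= 0`` vanishes as theta -> theta_max;
    reverse branch vanishes as theta -> theta_min.
    """
    theta = np.asarray(theta, dtype=float)
    deviation = np.asarray(deviation, dtype=float)
    if np.any(theta < p.theta_min - 1e-12) or np.any(theta > p.theta_max + 1e-12):
        raise ValueError("theta outside [theta_min, theta_max]")
    span = p.theta_max - p.theta_min
    up = np.clip((p.theta_max - theta) / span, 0.0, 1.0)
    dn = np.clip((theta - p.theta_min) / span, 0.0, 1.0)
    k_fwd = up ** p.gamma_g / p.tau_g
    k_rev = dn ** p.gamma_rg / p.tau_rg
    return np.where(deviation >= 0.0, k_fwd, k_rev)


def _evolve_direction(theta, deviation, p: DirectionGrowthParams, dt_days, n_substeps):
    theta = np.array(theta, dtype=float, copy=True)
    h = dt_days / n_substeps
    for _ in range(n_substeps):
        k = rate_limiter(theta, deviation, p)
        theta += h * k * deviation
        np.clip(theta, p.theta_min, p.theta_max, out=theta)
    return theta


def evolve_growth(
    state: GrowthState,
    stimulus: np.ndarray,
    params: GrowthParams,
    dt_days: float,
    n_substeps: int = 10,
) -> GrowthState:
    """Advance the growth multipliers by ``dt_days`` of explicit-Euler substeps.

    ``stimulus`` is the maximum elastic myofiber stretch field lambda_f,max of
    the latest beat; the driving deviation is ``stimulus - state.lam_h``.  The
    same myofiber-stretch deviation drives all three directions.  Each substep
    clamps theta to its bounds, so the update is total (never raises on
    saturation).
    """
    if dt_days <= 0:
        raise ValueError("dt_days must be positive")
    if state.lam_h is None:
        raise ValueError("homeostatic set point lam_h is not set")
    dev = np.asarray(stimulus, dtype=float) - state.lam_h
    return GrowthState(
        theta_f=_evolve_direction(state.theta_f, dev, params.f, dt_days, n_substeps),
        theta_s=_evolve_direction(state.theta_s, dev, params.s, dt_days, n_substeps),
        theta_n=_evolve_direction(state.theta_n, dev, params.n, dt_days, n_substeps),
        lam_h=state.lam_h,
    )


def closed_form_theta(t_days, deviation: float, p: DirectionGrowthParams) -> np.ndarray:
    """Analytic theta(t) for gamma = 1 and a constant stimulus deviation.

    Forward (deviation > 0):
        theta(t) = theta_max - (theta_max - theta_0) exp(-s t / (tau_g (theta_max - theta_min)))
    Reverse is the mirror image toward theta_min with tau_rg.  Used as the
    independent oracle for :func:`evolve_growth`.
    """
    if p.gamma_g != 1.0 or p.gamma_rg != 1.0:
        raise ValueError("closed form requires gamma_g = gamma_rg = 1")
    t = np.asarray(t_days, dtype=float)
    span = p.theta_max - p.theta_min
    if deviation >= 0.0:
        rate = deviation / (p.tau_g * span)
        return p.theta_max - (p.theta_max - p.theta_0) * np.exp(-rate * t)
    rate = -deviation / (p.tau_rg * span)
    return p.theta_min + (p.theta_0 - p.theta_min) * np.exp(-rate * t)


def half_life(tau: float, theta_max: float, theta_min: float, deviation: float) -> float:
    """Half-life t_1/2 = tau ln(2) (theta_max - theta_min) / |deviation| (days).

    Time for theta to cover half the distance from theta_0 to the approached
    bound under a constant deviation, for gamma = 1.
    """
    if deviation == 0.0:
        raise ValueError("deviation must be nonzero")
    if tau <= 0 or theta_max <= theta_min:
        raise ValueError("invalid parameters")
    return tau * np.log(2.0) * (theta_max - theta_min) / abs(deviation)
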