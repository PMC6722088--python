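"""Tissue constitutive laws: Fung-type passive stress and active contraction.

All functions are point-level and vectorized: tensor arguments take shape
``(..., 3, 3)``, directions ``(..., 3)``, scalars broadcast.  Stresses are
second Piola-Kirchhoff (PK2), in kPa; lengths in micrometres; times in ms.

Passive behavior is the transversely isotropic Fung/Guccione exponential

    W(E_e) = C/2 (exp(Q) - 1),
    Q = b_f E_ff^2 + b_fs (E_fs^2 + E_sf^2 + E_fn^2 + E_nf^2)
        + b_xx (E_ss^2 + E_nn^2 + E_ns^2 + E_sn^2),

with E_ij the elastic Green-Lagrange strain components in the local
(f0, s0, n0) frame.  Incompressibility is enforced with a pressure-like
Lagrange multiplier p through the augmented energy W - p (J - 1), giving

    S_p = dW/dE_e - p J C_e^{-1}.

Active stress is fiber-directed, S_a = T f0 (x) f0, with a twitch whose
amplitude carries length-dependent calcium sensitivity

    T = T_max Ca0^2 / (Ca0^2 + ECa50(l)^2) * (1 - cos w)/2,
    ECa50 = (Ca0)_max / sqrt(exp(B (l - l0)) - 1),

and whose phase w is scheduled by the time since local activation t_sa with
a rise time t_0 and a sarcomere-length-dependent relaxation time
t_r = m l + b_rel; after t_0 + t_r the twitch has fully relaxed (w = 0).
The sarcomere length is l = l_s0 sqrt(f0 . C_e f0).

Material constants default to Guccione-lineage literature values; in the
coupled simulations they are read from the scenario configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PassiveParams",
    "ActiveParams",
    "strain_energy",
    "passive_stress",
    "fung_stress_fiber",
    "fung_tangent_fiber",
    "volumetric_stress",
    "volumetric_tangent",
    "active_tension",
    "active_tension_dl",
    "omega_schedule",
    "active_stress",
    "sarcomere_length",
]


@dataclass(frozen=True)
class PassiveParams:
    """Fung-type passive constants: stress scale C (kPa) and exponents.

    ``kappa`` (kPa) is a volumetric penalty augmenting the incompressibility
    Lagrange multiplier (perturbed-Lagrangian formulation): the augmented
    energy carries an extra kappa/2 (J-1)^2 so that J = det F_e is enforced
    pointwise at quadrature points, with the smooth part of the constraint
    carried by the pressure field.
    """

    C: float = 0.2
    b_f: float = 29.8
    b_fs: float = 14.3
    b_xx: float = 13.3
    kappa: float = 5.0e3

    def __post_init__(self) -> None:
        if min(self.C, self.b_f, self.b_fs, self.b_xx) <= 0:
            raise ValueError("passive parameters must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be nonnegative")
        if self.b_f <= self.b_xx:
            import warnings

            warnings.warn("b_f <= b_xx: passive response is not fiber-dominant")

    @property
    def b_matrix(self) -> np.ndarray:
        bf, bfs, bxx = self.b_f, self.b_fs, self.b_xx
        return np.array(
            [[bf, bfs, bfs], [bfs, bxx, bxx], [bfs, bxx, bxx]], dtype=float
        )


@dataclass(frozen=True)
class ActiveParams:
    """Active contraction constants (kPa, uM, um, ms).

    ``T_max`` defaults to a value calibrated so that the bundled coarse
    biventricular mesh ejects with a physiological ejection fraction
    (~45%) against the default Windkessel afterload; on the coarse
    quadratic mesh the discrete myocardium is effectively stiffer than in
    fully resolved models, which pushes the calibrated contractility above
    typical literature values (~135 kPa).
    """

    T_max: float = 260.0
    Ca0: float = 4.35
    Ca0_max: float = 4.35
    B: float = 4.75
    l_0: float = 1.58
    l_s0: float = 1.85
    t_0: float = 150.0
    m: float = 1048.0
    b_rel: float = -1600.0

    def __post_init__(self) -> None:
        if self.t_0 <= 0:
            raise ValueError("t_0 must be positive")
        if self.T_max < 0:
            raise ValueError("T_max must be nonnegative")

    def relaxation_time(self, l):
        return self.m * np.asarray(l, dtype=float) + self.b_rel


# ----------------------------------------------------------------------------
# passive
# ----------------------------------------------------------------------------


def _fiber_components(E, f0, s0, n0):
    """Rotate a symmetric tensor into the (f0, s0, n0) frame: E~ = R E R^T."""
    R = np.stack([f0, s0, n0], axis=-2)  # rows are the frame vectors
    return np.einsum("...ia,...ab,...jb->...ij", R, E, R)


def strain_energy(E, params: PassiveParams, f0=None, s0=None, n0=None):
    """Fung energy W(E_e) in kPa.  If a frame is given, E is rotated into it;
    otherwise E is taken to already be in fiber coordinates."""
    E = np.asarray(E, dtype=float)
    if f0 is not None:
        E = _fiber_components(E, np.asarray(f0), np.asarray(s0), np.asarray(n0))
    b = params.b_matrix
    Q = np.einsum("ij,...ij->...", b, E**2)
    return 0.5 * params.C * (np.exp(Q) - 1.0)


def fung_stress_fiber(E_fib, params: PassiveParams):
    """dW/dE in fiber coordinates: S~_ij = C exp(Q) b_ij E~_ij."""
    E_fib = np.asarray(E_fib, dtype=float)
    b = params.b_matrix
    Q = np.einsum("ij,...ij->...", b, E_fib**2)
    return params.C * np.exp(Q)[..., None, None] * b * E_fib


def fung_tangent_fiber(E_fib, params: PassiveParams):
    """dS~/dE~ (9-component convention) in fiber coordinates, shape (...,3,3,3,3)."""
    E_fib = np.asarray(E_fib, dtype=float)
    b = params.b_matrix
    Q = np.einsum("ij,...ij->...", b, E_fib**2)
    expQ = np.exp(Q)[..., None, None, None, None]
    bE = b * E_fib  # (...,3,3)
    eye = np.eye(3)
    diag = b[..., :, :, None, None] * np.einsum("ik,jl->ijkl", eye, eye)
    outer = 2.0 * bE[..., :, :, None, None] * bE[..., None, None, :, :]
    return params.C * expQ * (diag + outer)


def volumetric_stress(C_tensor, p):
    """S_vol = -p J C^{-1} with J = sqrt(det C)."""
    C_tensor = np.asarray(C_tensor, dtype=float)
    detC = np.linalg.det(C_tensor)
    if np.any(detC <= 0):
        raise ValueError("C must be positive definite")
    J = np.sqrt(detC)
    Cinv = np.linalg.inv(C_tensor)
    p = np.asarray(p, dtype=float)
    return -p[..., None, None] * J[..., None, None] * Cinv


def volumetric_tangent(C_tensor, p):
    """d S_vol / d E (= 2 d/dC), shape (...,3,3,3,3)."""
    C_tensor = np.asarray(C_tensor, dtype=float)
    J = np.sqrt(np.linalg.det(C_tensor))[..., None, None, None, None]
    Ci = np.linalg.inv(C_tensor)
    p = np.asarray(p, dtype=float)[..., None, None, None, None]
    CiCi = Ci[..., :, :, None, None] * Ci[..., None, None, :, :]
    sym = 0.5 * (
        np.einsum("...ac,...bd->...abcd", Ci, Ci)
        + np.einsum("...ad,...bc->...abcd", Ci, Ci)
    )
    dS_dC = -p * (0.5 * J * CiCi - J * sym)
    return 2.0 * dS_dC


def passive_stress(E, p, params: PassiveParams, f0, s0, n0):
    """Total passive PK2 stress S_p = dW/dE - p J C^{-1} in global coordinates.

    ``E`` is the elastic Green-Lagrange strain in global coordinates; the
    Fung part is evaluated in the (f0, s0, n0) frame and rotated back.
    """
    E = np.asarray(E, dtype=float)
    if not np.allclose(E, np.swapaxes(E, -1, -2), atol=1e-9 * max(1.0, np.abs(E).max())):
        raise ValueError("E must be symmetric")
    f0, s0, n0 = (np.asarray(v, dtype=float) for v in (f0, s0, n0))
    R = np.stack([f0, s0, n0], axis=-2)
    E_fib = np.einsum("...ia,...ab,...jb->...ij", R, E, R)
    S_fib = fung_stress_fiber(E_fib, params)
    S_dev = np.einsum("...ia,...ij,...jb->...ab", R, S_fib, R)
    C_tensor = 2.0 * E + np.eye(3)
    J = np.sqrt(np.linalg.det(C_tensor))
    p_eff = np.asarray(p, dtype=float) - params.kappa * (J - 1.0)
    return S_dev + volumetric_stress(C_tensor, p_eff)


# ----------------------------------------------------------------------------
# active
# ----------------------------------------------------------------------------


def omega_schedule(t_sa, l, params: ActiveParams):
    """Twitch phase w(t_sa, l) in radians.

    Rises linearly to pi over [0, t_0), continues to 2 pi over the
    relaxation window [t_0, t_0 + t_r) with t_r = m l + b_rel, and is zero
    before activation and after full relaxation.
    """
    t_sa = np.asarray(t_sa, dtype=float)
    l = np.asarray(l, dtype=float)
    t_r = params.relaxation_time(l)
    if np.any((t_r <= 0.0) & (l > params.l_0)):
        # below l_0 the tension is zero regardless of the phase, so a
        # nonpositive t_r there is harmless (relaxation already complete)
        raise ValueError("nonpositive relaxation time t_r = m l + b_rel")
    t_r_safe = np.where(t_r > 0.0, t_r, 1.0)
    w_rise = np.pi * t_sa / params.t_0
    w_fall = np.pi * (t_sa - params.t_0 + t_r_safe) / t_r_safe
    w = np.where(t_sa < params.t_0, w_rise, w_fall)
    w = np.where((t_sa < 0.0) | (t_sa >= params.t_0 + np.maximum(t_r, 0.0)), 0.0, w)
    return w


def active_tension(t_sa, l, params: ActiveParams):
    """Active fiber tension T(t_sa, l) in kPa, bounded by [0, T_max]."""
    t_sa = np.asarray(t_sa, dtype=float)
    l = np.asarray(l, dtype=float)
    w = omega_schedule(t_sa, l, params)
    time_factor = 0.5 * (1.0 - np.cos(w))
    arg = np.exp(params.B * (l - params.l_0)) - 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        eca50_sq = np.where(arg > 0.0, params.Ca0_max**2 / np.where(arg > 0, arg, 1.0), np.inf)
        ca_factor = params.Ca0**2 / (params.Ca0**2 + eca50_sq)
    ca_factor = np.where(l > params.l_0, ca_factor, 0.0)
    return params.T_max * ca_factor * time_factor


def active_tension_dl(t_sa, l, params: ActiveParams, h: float = 1e-6):
    """dT/dl by central difference (used in the consistent FE tangent)."""
    return (active_tension(t_sa, l + h, params) - active_tension(t_sa, l - h, params)) / (
        2.0 * h
    )


def active_stress(T, f0):
    """Fiber-directed active PK2 stress S_a = T f0 (x) f0."""
    T = np.asarray(T, dtype=float)
    if np.any(T < 0):
        raise ValueError("active tension must be nonnegative")
    f0 = np.asarray(f0, dtype=float)
    return T[..., None, None] * f0[..., :, None] * f0[..., None, :]


def sarcomere_length(C_e, f0, l_s0: float):
    """Instantaneous sarcomere length l = l_s0 sqrt(f0 . C_e f0) (um)."""
    C_e = np.asarray(C_e, dtype=float)
    q = np.einsum("...i,...ij,...j->...", f0, C_e, f0)
    if np.any(q <= 0):
        raise ValueError("C_e not positive definite along f0")
    return l_s0 * np.sqrt(q)
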