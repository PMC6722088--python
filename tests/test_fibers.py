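"""Rule-based fiber architecture tests."""

import numpy as np

from cardiogrowth.fibers import assign_fibers, transmural_coordinate


def test_frames_orthonormal(bv_frame):
    bv_frame.check_orthonormal(tol=1e-9)


def test_transmural_coordinate_range(bv_mesh):
    d = transmural_coordinate(bv_mesh)
    assert d.min() > -1e-9 and d.max() < 1.0 + 1e-9


def test_helix_angle_transmural_profile(bv_frame):
    """+60 deg near the endocardium, -60 near the epicardium, ~0 mid-wall."""
    d = bv_frame.transmural
    a = bv_frame.helix_angle
    assert a[d < 0.1].mean() > 40.0
    assert a[d > 0.9].mean() < -40.0
    mid = a[(d > 0.45) & (d < 0.55)]
    assert abs(mid.mean()) < 12.0
    # linear rule: angle = 60 - 120 d exactly
    assert np.allclose(a, 60.0 - 120.0 * d, atol=1e-9)


def test_fibers_mostly_in_wall_plane(bv_mesh, bv_frame):
    """f0 is orthogonal to the transmural sheet direction by construction,
    and s0 points outward across the wall (positive radial component)."""
    assert np.allclose(np.sum(bv_frame.f0 * bv_frame.s0, axis=-1), 0.0, atol=1e-12)
    cent = bv_mesh.vertices[bv_mesh.cells].mean(axis=1)
    radial = cent * np.array([1.0, 1.0, 0.0])
    radial /= np.maximum(np.linalg.norm(radial, axis=-1, keepdims=True), 1e-9)
    proj = np.einsum("eqi,ei->eq", bv_frame.s0, radial)
    # away from the apex cap the transmural direction is outward
    mask = cent[:, 2] > -35.0
    assert (proj[mask] > 0).mean() > 0.9


def test_push_forward_preserves_orthonormality(bv_frame, rng):
    ne, nq = bv_frame.f0.shape[:2]
    F = np.eye(3) + 0.1 * rng.standard_normal((ne, nq, 3, 3))
    new = bv_frame.push_forward(F)
    new.check_orthonormal(tol=1e-9)


def test_push_forward_identity(bv_frame):
    ne, nq = bv_frame.f0.shape[:2]
    F = np.broadcast_to(np.eye(3), (ne, nq, 3, 3)).copy()
    new = bv_frame.push_forward(F)
    assert np.allclose(new.f0, bv_frame.f0, atol=1e-12)
    assert np.allclose(new.s0, bv_frame.s0, atol=1e-12)
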