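"""Rule-based myofiber architecture (Laplace-Dirichlet construction).

Orthonormal microstructural triads (f0, s0, n0) are assigned at quadrature
points from harmonic coordinates solved on the mesh:

* a transmural coordinate d in [0, 1] (endocardium 0, epicardium 1); on
  biventricles the left wall and septum use the LV-endo-to-(RV-endo/epi)
  harmonic and the RV free wall its own rv-endo-to-epi harmonic, so the
  septal transmural direction runs LV-endo -> RV-endo,
* an apex-to-base harmonic coordinate whose gradient, orthogonalized
  against the transmural direction, gives the local longitudinal direction.

The helix angle varies linearly across the wall from ``endo_angle`` at the
endocardium to ``epi_angle`` at the epicardium (defaults +60/-60 degrees);
f0 is the circumferential direction rotated by the helix angle towards the
longitudinal one, s0 is transmural, n0 = f0 x s0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TetMesh, SURFACE_TAGS
from .fem import FESpace, p1_stiffness

__all__ = ["FiberFrame", "assign_fibers", "transmural_coordinate"]


@dataclass
class FiberFrame:
    """Per-quadrature-point orthonormal triads and helix angles (degrees)."""

    f0: np.ndarray  # (ne, nq, 3)
    s0: np.ndarray
    n0: np.ndarray
    helix_angle: np.ndarray  # (ne, nq)
    transmural: np.ndarray  # (ne, nq) coordinate d in [0, 1]

    def check_orthonormal(self, tol: float = 1e-10) -> None:
        for v in (self.f0, self.s0, self.n0):
            if not np.allclose(np.linalg.norm(v, axis=-1), 1.0, atol=tol):
                raise ValueError("fiber frame not unit length")
        if not np.allclose(np.sum(self.f0 * self.s0, axis=-1), 0.0, atol=tol):
            raise ValueError("fiber frame not orthogonal")
        if not np.allclose(np.cross(self.f0, self.s0), self.n0, atol=1e-8):
            raise ValueError("n0 != f0 x s0")

    def cell_mean_f0(self) -> np.ndarray:
        m = self.f0.mean(axis=1)
        return m / np.linalg.norm(m, axis=-1, keepdims=True)

    def push_forward(self, F: np.ndarray) -> "FiberFrame":
        """Carry the triads through a deformation: f ~ F f0 (renormalized),
        s re-orthogonalized from F s0, n = f x s.  Used when the reference
        geometry is updated after a growth step."""
        f = np.einsum("eqij,eqj->eqi", F, self.f0)
        f /= np.linalg.norm(f, axis=-1, keepdims=True)
        s = np.einsum("eqij,eqj->eqi", F, self.s0)
        s -= np.sum(s * f, axis=-1, keepdims=True) * f
        s /= np.linalg.norm(s, axis=-1, keepdims=True)
        n = np.cross(f, s)
        return FiberFrame(f, s, n, self.helix_angle.copy(), self.transmural.copy())


def _solve_dirichlet(mesh: TetMesh, node_values: list[tuple[np.ndarray, float]]):
    from scipy.sparse.linalg import spsolve

    K = p1_stiffness(mesh, 1.0)
    fixed = np.zeros(mesh.n_vertices, dtype=bool)
    vals = np.zeros(mesh.n_vertices)
    for nodes, value in node_values:
        fixed[nodes] = True
        vals[nodes] = value
    if not fixed.any():
        raise ValueError("no Dirichlet data")
    free = ~fixed
    rhs = -K[:, fixed] @ vals[fixed]
    sol = vals.copy()
    sol[free] = spsolve(K[free][:, free].tocsc(), rhs[free])
    if not np.all(np.isfinite(sol)):
        raise RuntimeError("harmonic solve failed (disconnected surfaces?)")
    return sol


def _tag_nodes(mesh: TetMesh, tag: str) -> np.ndarray:
    return np.unique(mesh.facets_with_tag(tag))


def transmural_coordinate(mesh: TetMesh) -> np.ndarray:
    """Vertex field d in [0,1], 0 at endocardium and 1 at epicardium.

    On biventricular meshes two harmonics are blended: LV wall and septum
    use lv_endo=0 with rv_endo and epi at 1; the RV free wall uses
    rv_endo=0, epi=1.  On single-cavity meshes a single harmonic is used.
    """
    has_rv = np.any(mesh.facet_tags == SURFACE_TAGS["rv_endo"])
    epi = _tag_nodes(mesh, "epi")
    lv_endo = _tag_nodes(mesh, "lv_endo")
    if not has_rv:
        return _solve_dirichlet(mesh, [(lv_endo, 0.0), (epi, 1.0)])
    rv_endo = _tag_nodes(mesh, "rv_endo")
    # assignment order matters where surfaces meet (welded attachment nodes):
    # the later entry wins, keeping each harmonic's own zero surface intact
    d_lv = _solve_dirichlet(mesh, [(rv_endo, 1.0), (epi, 1.0), (lv_endo, 0.0)])
    d_rv = _solve_dirichlet(mesh, [(lv_endo, 1.0), (epi, 1.0), (rv_endo, 0.0)])
    # choose per vertex by dominant adjacent region
    from .mesh import REGION_TAGS

    rv_cells = mesh.region_tags == REGION_TAGS["RVFW"]
    count_rv = np.zeros(mesh.n_vertices)
    count_all = np.zeros(mesh.n_vertices)
    np.add.at(count_rv, mesh.cells[rv_cells].ravel(), 1.0)
    np.add.at(count_all, mesh.cells.ravel(), 1.0)
    w = count_rv / count_all
    return (1 - w) * d_lv + w * d_rv


def _apex_base_coordinate(mesh: TetMesh) -> np.ndarray:
    base = _tag_nodes(mesh, "base")
    apex = np.array([np.argmin(mesh.vertices[:, 2])])
    return _solve_dirichlet(mesh, [(base, 1.0), (apex, 0.0)])


def assign_fibers(
    mesh: TetMesh,
    endo_angle: float = 60.0,
    epi_angle: float = -60.0,
    space: FESpace | None = None,
) -> FiberFrame:
    """Build per-quadrature-point fiber triads on a labeled mesh."""
    space = space or FESpace(mesh)
    d_vert = transmural_coordinate(mesh)
    ab_vert = _apex_base_coordinate(mesh)

    # P1 gradients are constant per cell
    v, c = mesh.vertices, mesh.cells
    X = v[c]
    jac = np.swapaxes(X[:, 1:] - X[:, :1], 1, 2)
    invJT = np.linalg.inv(jac).swapaxes(1, 2)
    dl = np.zeros((4, 3))
    dl[0] = -1.0
    dl[1, 0] = dl[2, 1] = dl[3, 2] = 1.0
    g = np.einsum("eij,aj->eai", invJT, dl)
    grad_d = np.einsum("eai,ea->ei", g, d_vert[c])
    grad_ab = np.einsum("eai,ea->ei", g, ab_vert[c])

    def _unit(x, fallback=None):
        n = np.linalg.norm(x, axis=-1, keepdims=True)
        bad = n[..., 0] < 1e-10
        if np.any(bad):
            if fallback is None:
                raise RuntimeError("degenerate direction in fiber construction")
            x = np.where(bad[..., None], fallback, x)
            n = np.linalg.norm(x, axis=-1, keepdims=True)
        return x / n

    # transmural, endo -> epi; isolated flat cells (e.g. at welded RV
    # attachment columns) fall back to the horizontal radial direction
    centroid = X.mean(axis=1)
    radial = centroid * np.array([1.0, 1.0, 0.0])
    nrm = np.linalg.norm(radial, axis=-1, keepdims=True)
    radial = np.where(nrm > 1e-9, radial / np.maximum(nrm, 1e-12), [1.0, 0.0, 0.0])
    e_t = _unit(grad_d, fallback=radial)
    e_l = grad_ab - np.sum(grad_ab * e_t, axis=-1, keepdims=True) * e_t
    # near the apex pole grad_ab ~ e_t; fall back to any orthogonal direction
    fb = np.cross(e_t, np.broadcast_to([1.0, 0.0, 0.0], e_t.shape))
    fb2 = np.cross(e_t, np.broadcast_to([0.0, 1.0, 0.0], e_t.shape))
    fb = np.where(
        (np.linalg.norm(fb, axis=-1, keepdims=True) < 1e-6), fb2, fb
    )
    e_l = _unit(e_l, fallback=fb)
    e_c = _unit(np.cross(e_l, e_t))

    # transmural coordinate at quadrature points
    d_qp = np.einsum("qa,ea->eq", space.p1_vals, d_vert[c])
    d_qp = np.clip(d_qp, 0.0, 1.0)
    alpha = np.deg2rad(endo_angle + d_qp * (epi_angle - endo_angle))

    f0 = (
        np.cos(alpha)[..., None] * e_c[:, None, :]
        + np.sin(alpha)[..., None] * e_l[:, None, :]
    )
    s0 = np.broadcast_to(e_t[:, None, :], f0.shape).copy()
    n0 = np.cross(f0, s0)
    frame = FiberFrame(
        f0=f0,
        s0=s0,
        n0=n0,
        helix_angle=np.rad2deg(alpha),
        transmural=d_qp,
    )
    frame.check_orthonormal(tol=1e-9)
    return frame
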