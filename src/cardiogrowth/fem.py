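"""Finite-element infrastructure on tetrahedral meshes.

Provides the Taylor-Hood pair used by the mechanics solvers (continuous
piecewise-quadratic displacement, continuous piecewise-linear pressure),
P1 scalar operators for the electrophysiology and harmonic-coordinate
solves, surface (Robin spring) matrices on quadratic facet traces, and the
divergence-theorem cavity-volume functional with its exact gradient.

Volume quadrature is the symmetric 4-point degree-2 rule (positive weights,
exact for the linearized P2 operator on straight tets); facet integrals use
a degree-4 triangle rule.  All assembly is vectorized over elements with
precomputed scatter indices.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .mesh import TetMesh

__all__ = ["FESpace", "CavityMeter", "solve_harmonic", "p1_stiffness", "p1_lumped_mass"]

# 4-point degree-2 tet rule (barycentric), weights sum to 1
_QA, _QB = 0.5854101966249685, 0.1381966011250105
TET_QP = np.array(
    [
        [_QA, _QB, _QB, _QB],
        [_QB, _QA, _QB, _QB],
        [_QB, _QB, _QA, _QB],
        [_QB, _QB, _QB, _QA],
    ]
)
TET_QW = np.full(4, 0.25)

# 6-point degree-4 triangle rule (barycentric), weights sum to 1
_TA1, _TB1 = 0.816847572980459, 0.091576213509771
_TA2, _TB2 = 0.108103018168070, 0.445948490915965
TRI_QP = np.array(
    [
        [_TA1, _TB1, _TB1],
        [_TB1, _TA1, _TB1],
        [_TB1, _TB1, _TA1],
        [_TA2, _TB2, _TB2],
        [_TB2, _TA2, _TB2],
        [_TB2, _TB2, _TA2],
    ]
)
TRI_QW = np.array(
    [0.109951743655322, 0.109951743655322, 0.109951743655322,
     0.223381589678011, 0.223381589678011, 0.223381589678011]
)

TET_EDGES = np.array([[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]])


def _p2_basis(lmb):
    """P2 basis values at barycentric coords lmb (..., 4) -> (..., 10)."""
    l = np.asarray(lmb)
    vert = l * (2 * l - 1)
    e = TET_EDGES
    edge = 4 * l[..., e[:, 0]] * l[..., e[:, 1]]
    return np.concatenate([vert, edge], axis=-1)


def _p2_grad_ref(lmb):
    """P2 gradients wrt (lmb1..lmb3) taking lmb0 = 1-sum: (..., 10, 3)."""
    l = np.asarray(lmb)
    n = l.shape[:-1]
    # dl_i/dxi_j with xi = (l1,l2,l3): dl0 = (-1,-1,-1), dl1=e1, ...
    dl = np.zeros((4, 3))
    dl[0] = -1.0
    dl[1, 0] = dl[2, 1] = dl[3, 2] = 1.0
    g = np.zeros(n + (10, 3))
    for i in range(4):
        g[..., i, :] = (4 * l[..., i : i + 1] - 1) * dl[i]
    for k, (i, j) in enumerate(TET_EDGES):
        g[..., 4 + k, :] = 4 * (l[..., i : i + 1] * dl[j] + l[..., j : j + 1] * dl[i])
    return g


class FESpace:
    """Taylor-Hood (P2 vector / P1 scalar) space on a :class:`TetMesh`."""

    def __init__(self, mesh: TetMesh):
        self.mesh = mesh
        v, c = mesh.vertices, mesh.cells
        self.n_vert = len(v)
        # global edge table
        pairs = c[:, TET_EDGES].reshape(-1, 2)
        pairs_sorted = np.sort(pairs, axis=1)
        uniq, inv = np.unique(pairs_sorted, axis=0, return_inverse=True)
        self.edges = uniq
        self.n_edge = len(uniq)
        self.n_p2 = self.n_vert + self.n_edge
        edge_ids = inv.reshape(len(c), 6) + self.n_vert
        self.cells_p2 = np.concatenate([c, edge_ids], axis=1)  # (ne, 10)
        self.p2_coords = np.vstack([v, 0.5 * (v[uniq[:, 0]] + v[uniq[:, 1]])])

        # geometry mapping (straight tets)
        X = v[c]
        self.jac = np.swapaxes(X[:, 1:] - X[:, :1], 1, 2)  # (ne,3,3), columns = edges
        self.detJ = np.linalg.det(self.jac)
        if np.any(self.detJ <= 0):
            raise ValueError("negative-Jacobian cell")
        self.invJT = np.linalg.inv(self.jac).swapaxes(1, 2)  # (ne,3,3): invJ^T
        self.cell_vol = self.detJ / 6.0

        self.nq = len(TET_QW)
        self.qw = TET_QW
        gref = _p2_grad_ref(TET_QP)  # (nq,10,3)
        # physical gradients: g_phys = invJ^T @ g_ref
        self.grad_p2 = np.einsum("eij,qaj->eqai", self.invJT, gref)
        self.p1_vals = TET_QP  # (nq,4) P1 basis = barycentric coords
        self.p2_vals = _p2_basis(TET_QP)  # (nq,10)
        dl = np.zeros((4, 3))
        dl[0] = -1.0
        dl[1, 0] = dl[2, 1] = dl[3, 2] = 1.0
        self.grad_p1 = np.einsum("eij,aj->eai", self.invJT, dl)  # (e,4,3)
        # quadrature point positions
        self.qpoints = np.einsum("qa,eai->eqi", TET_QP, X)
        self.wdet = self.qw[None, :] * self.cell_vol[:, None]  # (ne, nq)

        # scatter indices for the (u,u) and (u,p) blocks
        dofs_u = (3 * self.cells_p2[:, :, None] + np.arange(3)).reshape(-1, 30)
        self._rows_uu = np.repeat(dofs_u, 30, axis=1).ravel()
        self._cols_uu = np.tile(dofs_u, (1, 30)).ravel()
        dofs_p = self.mesh.cells
        self._rows_up = np.repeat(dofs_u, 4, axis=1).ravel()
        self._cols_up = np.tile(dofs_p, (1, 30)).ravel()
        self.n_udof = 3 * self.n_p2
        self.n_pdof = self.n_vert

    # -- interpolation --------------------------------------------------------

    def u_qp_gradients(self, u: np.ndarray) -> np.ndarray:
        """grad u at quadrature points: (ne, nq, 3, 3) from P2 dof vector."""
        ue = u.reshape(-1, 3)[self.cells_p2]  # (ne,10,3)
        return np.einsum("eqaj,eai->eqij", self.grad_p2, ue)

    def p_qp_values(self, p: np.ndarray) -> np.ndarray:
        pe = p[self.mesh.cells]  # (ne,4)
        return np.einsum("qa,ea->eq", self.p1_vals, pe)

    def scalar_p1_at_qp(self, f_vert: np.ndarray) -> np.ndarray:
        return self.p_qp_values(f_vert)

    # -- assembly -------------------------------------------------------------

    def assemble_uu(self, Ke: np.ndarray) -> sp.csr_matrix:
        """Ke: (ne, 10, 3, 10, 3) element matrices -> global (3n x 3n)."""
        vals = Ke.reshape(len(self.mesh.cells), 30, 30).ravel()
        A = sp.coo_matrix(
            (vals, (self._rows_uu, self._cols_uu)), shape=(self.n_udof, self.n_udof)
        )
        return A.tocsr()

    def assemble_up(self, Ke: np.ndarray) -> sp.csr_matrix:
        """Ke: (ne, 10, 3, 4) -> global (3n x nv)."""
        vals = Ke.reshape(len(self.mesh.cells), 30, 4).ravel()
        A = sp.coo_matrix(
            (vals, (self._rows_up, self._cols_up)), shape=(self.n_udof, self.n_pdof)
        )
        return A.tocsr()

    def residual_u(self, Pe: np.ndarray) -> np.ndarray:
        """Internal-force vector from per-qp PK1 stress Pe (ne, nq, 3, 3)."""
        re = np.einsum("eq,eqaj,eqij->eai", self.wdet, self.grad_p2, Pe)
        out = np.zeros(self.n_udof)
        np.add.at(out, (3 * self.cells_p2[:, :, None] + np.arange(3)).ravel(), re.ravel())
        return out

    def residual_p(self, fq: np.ndarray) -> np.ndarray:
        """Pressure-test residual from per-qp scalar fq (ne, nq)."""
        re = np.einsum("eq,qa->ea", self.wdet * fq, self.p1_vals)
        out = np.zeros(self.n_pdof)
        np.add.at(out, self.mesh.cells.ravel(), re.ravel())
        return out

    # -- surface --------------------------------------------------------------

    def facet_p2_nodes(self, facets: np.ndarray) -> np.ndarray:
        """(nf, 6) P2 node ids for each facet: 3 vertices + 3 edge midpoints."""
        edge_lookup = {tuple(e): i for i, e in enumerate(map(tuple, self.edges))}
        out = np.empty((len(facets), 6), dtype=np.int64)
        out[:, :3] = facets
        pairs = [(0, 1), (1, 2), (2, 0)]
        for k, (i, j) in enumerate(pairs):
            for n, f in enumerate(facets):
                key = (min(f[i], f[j]), max(f[i], f[j]))
                out[n, 3 + k] = self.n_vert + edge_lookup[key]
        return out

    def surface_mass(self, facets: np.ndarray) -> sp.csr_matrix:
        """Vector surface mass matrix  M_ab I3  over quadratic facet traces."""
        f6 = self.facet_p2_nodes(facets)
        v = self.mesh.vertices
        e1 = v[facets[:, 1]] - v[facets[:, 0]]
        e2 = v[facets[:, 2]] - v[facets[:, 0]]
        area2 = np.linalg.norm(np.cross(e1, e2), axis=1)  # 2*area
        l = TRI_QP
        # P2 triangle basis on 6 nodes (3 vertex + edge midpoints 01,12,20)
        N = np.concatenate(
            [
                l * (2 * l - 1),
                4
                * np.stack(
                    [l[:, 0] * l[:, 1], l[:, 1] * l[:, 2], l[:, 2] * l[:, 0]], axis=-1
                ),
            ],
            axis=-1,
        )  # (nqs, 6)
        Me = np.einsum("q,qa,qb->ab", TRI_QW, N, N)  # reference (6,6)
        Me = Me[None, :, :] * (area2 * 0.5)[:, None, None]
        dofs = (3 * f6[:, :, None] + np.arange(3)).reshape(-1, 18)
        rows = np.repeat(dofs, 18, axis=1).ravel()
        cols = np.tile(dofs, (1, 18)).ravel()
        vals = np.einsum("fab,ij->faibj", Me, np.eye(3)).reshape(len(facets), 18, 18)
        A = sp.coo_matrix(
            (vals.ravel(), (rows, cols)), shape=(self.n_udof, self.n_udof)
        )
        return A.tocsr()


class CavityMeter:
    """Cavity volume V(u) and exact gradient dV/du for one tagged cavity.

    The cavity surface is the tagged endocardial facet set closed by a fan
    over its basal ring from a fixed apex point; vertices displace with the
    P2 vertex dofs (linear surface trace).  Volumes in ml.
    """

    ML = 1000.0

    def __init__(self, space: FESpace, tag_name: str):
        self.space = space
        mesh = space.mesh
        tris, apex = mesh.closed_cavity_surface(tag_name)
        self.tris = tris
        self.apex = apex
        self.n_real = mesh.n_vertices
        ref = self._signed(np.zeros(space.n_udof))
        self.sign = 1.0 if ref >= 0 else -1.0

    def _coords(self, u: np.ndarray) -> np.ndarray:
        x = self.space.mesh.vertices + u.reshape(-1, 3)[: self.n_real]
        return np.vstack([x, self.apex[None, :]])

    def _signed(self, u: np.ndarray) -> float:
        x = self._coords(u)
        p0, p1, p2 = (x[self.tris[:, k]] for k in range(3))
        return float(np.einsum("ij,ij->", p0, np.cross(p1, p2)) / 6.0)

    def volume(self, u: np.ndarray) -> float:
        return self.sign * self._signed(u) / self.ML

    def gradient(self, u: np.ndarray) -> np.ndarray:
        """dV/du as a dense vector over all u dofs, in mm^3 per mm.

        The mm^3 scale makes ``P_cav * gradient`` a consistent nodal force
        (kPa * mm^2) in the virtual-work residual; divide by ``ML`` for the
        ml-based constraint row."""
        x = self._coords(u)
        p0, p1, p2 = (x[self.tris[:, k]] for k in range(3))
        g0 = np.cross(p1, p2) / 6.0
        g1 = np.cross(p2, p0) / 6.0
        g2 = np.cross(p0, p1) / 6.0
        out = np.zeros((len(x), 3))
        np.add.at(out, self.tris[:, 0], g0)
        np.add.at(out, self.tris[:, 1], g1)
        np.add.at(out, self.tris[:, 2], g2)
        full = np.zeros(self.space.n_udof)
        full.reshape(-1, 3)[: self.n_real] = out[:-1]
        return self.sign * full


# ----------------------------------------------------------------------------
# P1 scalar operators
# ----------------------------------------------------------------------------


def p1_stiffness(mesh: TetMesh, D_cell: np.ndarray) -> sp.csr_matrix:
    """Anisotropic stiffness  K_ab = sum_e (grad a . D_e grad b) V_e  on P1.

    ``D_cell`` is (ne, 3, 3) or a scalar (isotropic).
    """
    v, c = mesh.vertices, mesh.cells
    X = v[c]
    jac = np.swapaxes(X[:, 1:] - X[:, :1], 1, 2)
    detJ = np.linalg.det(jac)
    invJT = np.linalg.inv(jac).swapaxes(1, 2)
    dl = np.zeros((4, 3))
    dl[0] = -1.0
    dl[1, 0] = dl[2, 1] = dl[3, 2] = 1.0
    g = np.einsum("eij,aj->eai", invJT, dl)  # (ne,4,3)
    vol = detJ / 6.0
    if np.isscalar(D_cell) or np.ndim(D_cell) == 0:
        D = float(D_cell) * np.broadcast_to(np.eye(3), (len(c), 3, 3))
    else:
        D = np.asarray(D_cell)
    Ke = np.einsum("e,eai,eij,ebj->eab", vol, g, D, g)
    rows = np.repeat(c, 4, axis=1).ravel()
    cols = np.tile(c, (1, 4)).ravel()
    return sp.coo_matrix(
        (Ke.ravel(), (rows, cols)), shape=(len(v), len(v))
    ).tocsr()


def p1_lumped_mass(mesh: TetMesh) -> np.ndarray:
    """Row-summed (lumped) P1 mass vector: V_e/4 to each vertex."""
    vol = mesh.cell_volumes()
    m = np.zeros(mesh.n_vertices)
    np.add.at(m, mesh.cells.ravel(), np.repeat(vol / 4.0, 4))
    return m


def solve_harmonic(mesh: TetMesh, dirichlet: dict[str, float]) -> np.ndarray:
    """Solve Laplace's equation on P1 with Dirichlet data on tagged surfaces.

    ``dirichlet`` maps surface-tag names to boundary values.  Used for the
    transmural and apex-to-base coordinates of the rule-based fiber
    construction.  Raises if the constrained system is singular (e.g.
    disconnected surfaces missing from the tags).
    """
    K = p1_stiffness(mesh, 1.0).tolil()
    b = np.zeros(mesh.n_vertices)
    fixed = np.zeros(mesh.n_vertices, dtype=bool)
    vals = np.zeros(mesh.n_vertices)
    for tag, value in dirichlet.items():
        nodes = np.unique(mesh.facets_with_tag(tag))
        fixed[nodes] = True
        vals[nodes] = value
    if not np.any(fixed):
        raise ValueError("no Dirichlet surfaces found for harmonic solve")
    K = K.tocsr()
    free = ~fixed
    b = -K[:, fixed] @ vals[fixed]
    Kff = K[free][:, free]
    from scipy.sparse.linalg import spsolve

    sol = np.array(vals)
    try:
        sol[free] = spsolve(Kff.tocsc(), b[free])
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"harmonic solve failed: {exc}") from exc
    if not np.all(np.isfinite(sol)):
        raise RuntimeError("harmonic solve produced non-finite values")
    return sol
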