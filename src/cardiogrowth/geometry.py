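"""Synthetic unloaded ventricular geometry presets.

The generator produces structured tetrahedral meshes of idealized hearts in
the unloaded, stress-free reference configuration:

* ``sphere_shell`` — truncated spherical shell (closed-form volumes; used as
  the verification preset),
* ``lv_ellipsoid`` — single-LV truncated thick-walled ellipsoid,
* ``biventricle`` — truncated-ellipsoid LV with a crescent-shaped RV block
  welded conformally onto an azimuthal sector of the LV epicardium, leaving
  an unmeshed RV cavity gap between LV epicardium and RV free wall.

These are stand-ins sized to the ~100 ml LV end-diastolic-volume regime of
an adult human heart, not replicas of any patient anatomy.  Meshing is a
structured hexahedral grid in (transmural, longitudinal, circumferential)
parameter space split into tetrahedra with the Freudenthal (main-diagonal)
pattern, which is conforming across neighbouring cells; the hexahedra that
collapse at the apex pole are reduced to wedges automatically.

Lengths in mm, volumes returned in ml (1 ml = 1000 mm^3).
"""

from __future__ import annotations

import numpy as np

from .mesh import TetMesh, SURFACE_TAGS, REGION_TAGS

__all__ = [
    "sphere_shell",
    "lv_ellipsoid",
    "biventricle",
    "truncated_ellipsoid_volume",
    "wall_metrics",
    "cavity_volume_from_surface",
]

ML = 1000.0  # mm^3 per ml

# Freudenthal 6-tet split of a hex whose corners are ordered with bits
# (transmural, longitudinal, circumferential); all tets share diagonal 0-7.
_HEX_TETS = np.array(
    [[0, 1, 3, 7], [0, 3, 2, 7], [0, 2, 6, 7], [0, 6, 4, 7], [0, 4, 5, 7], [0, 5, 1, 7]]
)


def truncated_ellipsoid_volume(a: float, c: float, z_base: float) -> float:
    """Volume (ml) of the ellipsoid x^2/a^2 + y^2/a^2 + z^2/c^2 <= 1 below z = z_base."""
    if not (-c < z_base <= c):
        raise ValueError("base plane must intersect the ellipsoid")
    zb = z_base
    v = np.pi * a * a * ((zb + c) - (zb**3 + c**3) / (3.0 * c * c))
    return float(v) / ML


def _surface_point(a, c, mu, phi):
    mu, phi = np.broadcast_arrays(np.asarray(mu, dtype=float), np.asarray(phi, dtype=float))
    return np.stack(
        [a * np.sin(mu) * np.cos(phi), a * np.sin(mu) * np.sin(phi), c * np.cos(mu)],
        axis=-1,
    )


def _check_geom(a_endo, c_endo, wall, z_base):
    if wall <= 0:
        raise ValueError("wall thickness must be positive")
    if a_endo <= 0 or c_endo <= 0:
        raise ValueError("cavity semi-axes must be positive")
    if not (-c_endo < z_base < c_endo):
        raise ValueError("base truncation plane must cut the endocardial ellipsoid")


def _divisions_from_resolution(a_epi, c_epi, z_base, wall, resolution):
    """Map a target edge length (mm) to structured divisions."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    circ = 2 * np.pi * a_epi
    mu_b = np.arccos(np.clip(z_base / c_epi, -1.0, 1.0))
    arc = (np.pi - mu_b) * 0.5 * (a_epi + c_epi)
    n_c = max(8, int(np.ceil(circ / resolution)))
    n_l = max(4, int(np.ceil(arc / resolution)))
    n_t = max(2, int(np.ceil(wall / resolution)))
    return n_t, n_l, n_c


def _build_ventricle(
    a_endo,
    c_endo,
    wall,
    z_base,
    n_t,
    n_l,
    n_c,
    rv=None,
):
    """Structured LV shell, optionally with a welded RV block.

    ``rv`` is None or a dict with keys ``sector`` (azimuth interval, rad),
    ``gap_max`` (mm), ``wall`` (mm), ``n_t`` (transmural divisions),
    ``l0_frac`` (longitudinal fraction where the RV bottom sits).
    """
    a_epi, c_epi = a_endo + wall, c_endo + wall
    _check_geom(a_endo, c_endo, wall, z_base)
    if z_base >= c_epi:
        raise ValueError("base plane above the epicardial apex-to-base extent")

    phis = 2 * np.pi * np.arange(n_c) / n_c

    # ---- LV node layers -----------------------------------------------------
    nid = -np.ones((n_t + 1, n_l + 1, n_c), dtype=np.int64)
    coords: list[np.ndarray] = []
    layer_of: list[int] = []
    lpar: list[float] = []
    vpar: list[float] = []

    def add_node(xyz, t, l, v) -> int:
        coords.append(xyz)
        layer_of.append(t)
        lpar.append(l)
        vpar.append(v)
        return len(coords) - 1

    for t in range(n_t + 1):
        tau = t / n_t
        a_t = a_endo + tau * wall
        c_t = c_endo + tau * wall
        mu_b = np.arccos(np.clip(z_base / c_t, -1.0, 1.0))
        # apex pole: one node per layer
        apex = add_node(np.array([0.0, 0.0, -c_t]), t, 0.0, -1.0)
        nid[t, 0, :] = apex
        for l in range(1, n_l + 1):
            mu = np.pi - (np.pi - mu_b) * l / n_l
            pts = _surface_point(a_t, c_t, mu, phis)
            for v in range(n_c):
                nid[t, l, v] = add_node(pts[v], t, float(l), float(v))

    # ---- RV block -----------------------------------------------------------
    g_node = {}
    rv_layers = 0
    if rv is not None:
        phi0, phi1 = rv["sector"]
        if not (0.0 < phi0 < phi1 < 2 * np.pi):
            raise ValueError("RV sector must lie strictly inside (0, 2*pi)")
        v0 = int(np.ceil(phi0 * n_c / (2 * np.pi)))
        v1 = int(np.floor(phi1 * n_c / (2 * np.pi)))
        if v1 - v0 < 2:
            raise ValueError("RV sector too narrow for this circumferential resolution")
        l0 = max(1, int(round(rv["l0_frac"] * n_l)))
        if n_l - l0 < 2:
            raise ValueError("RV attachment requires at least 2 longitudinal cells")
        n_tr = rv["n_t"]
        gap_max, th_rv = rv["gap_max"], rv["wall"]
        if th_rv <= 0 or gap_max <= 0:
            raise ValueError("RV gap and wall thickness must be positive")
        rv_layers = n_tr + 1
        nid_rv = -np.ones((rv_layers, n_l + 1, n_c), dtype=np.int64)

        def g_of(l, v):
            if l < l0 or not (v0 <= v <= v1):
                return 0.0
            uv = (v - v0) / (v1 - v0)
            sl = np.sin(0.5 * np.pi * (l - l0) / (n_l - l0))
            return gap_max * np.sin(np.pi * uv) * sl

        for k in range(rv_layers):
            for l in range(l0, n_l + 1):
                for v in range(v0, v1 + 1):
                    g = g_of(l, v)
                    if k == 0 and g <= 1e-12:
                        nid_rv[k, l, v] = nid[n_t, l, v]  # weld to LV epicardium
                        g_node[nid[n_t, l, v]] = 0.0
                        continue
                    base_pt = coords[nid[n_t, l, v]]
                    d = np.array(
                        [
                            base_pt[0] / a_epi**2,
                            base_pt[1] / a_epi**2,
                            0.0 if l == n_l else base_pt[2] / c_epi**2,
                        ]
                    )
                    d /= np.linalg.norm(d)
                    offset = g + th_rv * k / n_tr
                    xyz = base_pt + d * offset
                    xyz[2] = min(xyz[2], z_base)
                    idx = add_node(xyz, n_t + 1 + k, float(l), float(v))
                    nid_rv[k, l, v] = idx
                    if k == 0:
                        g_node[idx] = g
        for v in range(v0, v1 + 1):
            g_node[nid[n_t, n_l, v]] = g_node.get(nid[n_t, n_l, v], g_of(n_l, v))
        for l in range(l0, n_l + 1):
            for v in range(v0, v1 + 1):
                g_node.setdefault(nid[n_t, l, v], g_of(l, v))

    coords = np.asarray(coords)
    layer_of = np.asarray(layer_of)

    # ---- cells --------------------------------------------------------------
    def hex_corners(t_lo, grid, l, v):
        vp = (v + 1) % n_c
        return [
            grid[t_lo, l, v],
            grid[t_lo + 1, l, v],
            grid[t_lo, l + 1, v],
            grid[t_lo + 1, l + 1, v],
            grid[t_lo, l, vp],
            grid[t_lo + 1, l, vp],
            grid[t_lo, l + 1, vp],
            grid[t_lo + 1, l + 1, vp],
        ]

    cells = []
    regions = []
    sector_cells = None
    if rv is not None:
        sector_cells = set()
        for v in range(v0, v1):
            sector_cells.add(v)

    for t in range(n_t):
        for l in range(n_l):
            for v in range(n_c):
                corners = hex_corners(t, nid, l, v)
                if rv is not None and v in sector_cells:
                    reg = REGION_TAGS["SEPTUM"]
                else:
                    reg = REGION_TAGS["LVFW"]
                for tet in _HEX_TETS:
                    conn = [corners[j] for j in tet]
                    if len(set(conn)) == 4:
                        cells.append(conn)
                        regions.append(reg)

    if rv is not None:
        for k in range(n_tr):
            for l in range(l0, n_l):
                for v in range(v0, v1):
                    vp = v + 1  # sector never wraps the seam
                    corners = [
                        nid_rv[k, l, v],
                        nid_rv[k + 1, l, v],
                        nid_rv[k, l + 1, v],
                        nid_rv[k + 1, l + 1, v],
                        nid_rv[k, l, vp],
                        nid_rv[k + 1, l, vp],
                        nid_rv[k, l + 1, vp],
                        nid_rv[k + 1, l + 1, vp],
                    ]
                    for tet in _HEX_TETS:
                        conn = [corners[j] for j in tet]
                        if len(set(conn)) == 4:
                            cells.append(conn)
                            regions.append(REGION_TAGS["RVFW"])

    cells = np.asarray(cells, dtype=np.int64)
    regions = np.asarray(regions, dtype=np.int64)

    # drop tets that are geometrically degenerate (collapsed RV taper)
    vol = np.linalg.det(coords[cells][:, 1:] - coords[cells][:, :1])
    keep = np.abs(vol) > 1e-9
    cells, regions = cells[keep], regions[keep]

    mesh = TetMesh(coords, cells, regions)

    # ---- facet tags ---------------------------------------------------------
    facets = mesh.boundary_facets
    tags = np.full(len(facets), SURFACE_TAGS["epi"], dtype=np.int64)
    fz = coords[facets][:, :, 2]
    layers = layer_of[facets]
    on_base = np.all(fz >= z_base - 1e-9, axis=1)
    tags[on_base] = SURFACE_TAGS["base"]
    tags[np.all(layers == 0, axis=1) & ~on_base] = SURFACE_TAGS["lv_endo"]
    if rv is not None:
        inner = np.all((layers == n_t) | (layers == n_t + 1), axis=1) & ~on_base
        gvals = np.array(
            [
                np.mean([g_node.get(i, 0.0) for i in f]) if flag else 0.0
                for f, flag in zip(facets, inner)
            ]
        )
        has_inner_layer = np.any(layers == n_t + 1, axis=1)
        cavity = inner & ((gvals > 1e-9) | has_inner_layer)
        tags[cavity] = SURFACE_TAGS["rv_endo"]
    mesh.facet_tags = tags
    mesh.validate()
    return mesh


# ----------------------------------------------------------------------------
# public presets
# ----------------------------------------------------------------------------


def sphere_shell(
    r_inner: float = 20.0,
    r_outer: float = 30.0,
    z_base: float = 0.0,
    n_t: int = 2,
    n_l: int = 8,
    n_c: int = 16,
    resolution: float | None = None,
) -> TetMesh:
    """Truncated spherical shell (single cavity, all cells tagged LVFW)."""
    wall = r_outer - r_inner
    if resolution is not None:
        n_t, n_l, n_c = _divisions_from_resolution(r_outer, r_outer, z_base, wall, resolution)
    return _build_ventricle(r_inner, r_inner, wall, z_base, n_t, n_l, n_c, rv=None)


def lv_ellipsoid(
    a_endo: float = 22.0,
    c_endo: float = 50.0,
    wall: float = 10.0,
    z_base: float = 15.0,
    n_t: int = 2,
    n_l: int = 8,
    n_c: int = 12,
    resolution: float | None = None,
) -> TetMesh:
    """Single-LV truncated thick-walled ellipsoid."""
    if resolution is not None:
        n_t, n_l, n_c = _divisions_from_resolution(
            a_endo + wall, c_endo + wall, z_base, wall, resolution
        )
    return _build_ventricle(a_endo, c_endo, wall, z_base, n_t, n_l, n_c, rv=None)


def biventricle(
    a_endo: float = 25.8,
    c_endo: float = 50.0,
    wall: float = 10.0,
    z_base: float = 15.0,
    rv_sector: tuple[float, float] = (np.pi * 0.28, np.pi * 1.22),
    rv_gap_max: float = 28.0,
    rv_wall: float = 4.0,
    rv_l0_frac: float = 0.3,
    n_t: int = 2,
    n_l: int = 8,
    n_c: int = 12,
    n_t_rv: int = 1,
    resolution: float | None = None,
) -> TetMesh:
    """Idealized biventricle: truncated-ellipsoid LV + crescent RV free wall.

    The RV free wall is offset from the LV epicardium over the azimuthal
    ``rv_sector``; the enclosed unmeshed gap is the RV cavity, open at the
    base.  LV cells inside the sector are tagged SEPTUM, outside LVFW; the
    RV block is RVFW.
    """
    if resolution is not None:
        n_t, n_l, n_c = _divisions_from_resolution(
            a_endo + wall, c_endo + wall, z_base, wall, resolution
        )
    rv = {
        "sector": rv_sector,
        "gap_max": rv_gap_max,
        "wall": rv_wall,
        "n_t": n_t_rv,
        "l0_frac": rv_l0_frac,
    }
    return _build_ventricle(a_endo, c_endo, wall, z_base, n_t, n_l, n_c, rv=rv)


# ----------------------------------------------------------------------------
# geometric metrics
# ----------------------------------------------------------------------------


def cavity_volume_from_surface(
    mesh: TetMesh, tag_name: str, displacement: np.ndarray | None = None
) -> float:
    """Cavity volume (ml) by the divergence theorem over the closed surface.

    The tagged cavity facets are closed by a triangle fan over the basal
    opening from a fixed apex point; the signed volume sign is fixed so the
    reference-configuration volume is positive.
    """
    tris, fan_apex = mesh.closed_cavity_surface(tag_name)
    x = np.vstack([mesh.deformed(displacement), fan_apex[None, :]])
    p0, p1, p2 = x[tris[:, 0]], x[tris[:, 1]], x[tris[:, 2]]
    signed = np.einsum("ij,ij->", p0, np.cross(p1, p2)) / 6.0
    x0 = np.vstack([mesh.vertices, fan_apex[None, :]])
    q0, q1, q2 = x0[tris[:, 0]], x0[tris[:, 1]], x0[tris[:, 2]]
    ref = np.einsum("ij,ij->", q0, np.cross(q1, q2)) / 6.0
    sign = 1.0 if ref >= 0 else -1.0
    return float(sign * signed) / ML


def _point_triangle_distance(points, tri_a, tri_b, tri_c):
    """Exact min distance from each point to a set of triangles (Ericson regions)."""
    d = np.empty(len(points))
    ab = tri_b - tri_a
    ac = tri_c - tri_a
    bc = tri_c - tri_b
    for i, p in enumerate(points):
        ap = p - tri_a
        bp = p - tri_b
        cp = p - tri_c
        d1 = np.einsum("ij,ij->i", ab, ap)
        d2 = np.einsum("ij,ij->i", ac, ap)
        d3 = np.einsum("ij,ij->i", ab, bp)
        d4 = np.einsum("ij,ij->i", ac, bp)
        d5 = np.einsum("ij,ij->i", ab, cp)
        d6 = np.einsum("ij,ij->i", ac, cp)
        va = d3 * d6 - d5 * d4
        vb = d5 * d2 - d1 * d6
        vc = d1 * d4 - d3 * d2
        with np.errstate(divide="ignore", invalid="ignore"):
            t_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
            t_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
            den_bc = (d4 - d3) + (d5 - d6)
            t_bc = np.where(den_bc != 0, (d4 - d3) / den_bc, 0.0)
            denom = va + vb + vc
            v_in = np.where(denom != 0, vb / denom, 0.0)
            w_in = np.where(denom != 0, vc / denom, 0.0)
        proj = tri_a + v_in[:, None] * ab + w_in[:, None] * ac
        proj = np.where((va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0),
                        (tri_b + t_bc[:, None] * bc).T, proj.T).T
        proj = np.where((vb <= 0) & (d2 >= 0) & (d6 <= 0),
                        (tri_a + t_ac[:, None] * ac).T, proj.T).T
        proj = np.where((vc <= 0) & (d1 >= 0) & (d3 <= 0),
                        (tri_a + t_ab[:, None] * ab).T, proj.T).T
        proj = np.where((d6 >= 0) & (d5 <= d6), tri_c.T, proj.T).T
        proj = np.where((d3 >= 0) & (d4 <= d3), tri_b.T, proj.T).T
        proj = np.where((d1 <= 0) & (d2 <= 0), tri_a.T, proj.T).T
        d[i] = np.sqrt(((p - proj) ** 2).sum(axis=1).min())
    return d


def _facet_cell_map(mesh: TetMesh):
    from .mesh import _TET_FACES

    faces = mesh.cells[:, _TET_FACES].reshape(-1, 3)
    owner = np.repeat(np.arange(mesh.n_cells), 4)
    key = {tuple(sorted(f)): c for f, c in zip(faces, owner)}
    return np.array([key[tuple(sorted(f))] for f in mesh.boundary_facets])


def wall_metrics(
    mesh: TetMesh,
    displacement: np.ndarray | None = None,
    band: float = 0.15,
) -> dict:
    """Regional wall thickness (mm), wall volume (ml) and cavity volumes (ml).

    Thickness is the mean distance from endocardial-side surface nodes in a
    mid-ventricular z-band to the opposing surface triangulation; wall volume
    is the sum of deformed cell volumes per region; cavity volumes use the
    divergence-theorem surface integral.  Regions with no mid-ventricular
    samples are reported as NaN with a warning.
    """
    import warnings

    x = mesh.deformed(displacement)
    vols = mesh.cell_volumes(displacement)

    out: dict = {"thickness": {}, "wall_volume": {}, "cavity_volume": {}}
    for name in REGION_TAGS:
        idx = mesh.region_cells(name)
        out["wall_volume"][name] = float(vols[idx].sum()) / ML if len(idx) else 0.0

    owner = _facet_cell_map(mesh)
    zref = mesh.vertices[:, 2]
    z_lo = zref.min() + (0.5 - band) * (zref.max() - zref.min())
    z_hi = zref.min() + (0.5 + band) * (zref.max() - zref.min())

    pairs = {
        "LVFW": ("lv_endo", "epi"),
        "SEPTUM": ("lv_endo", "rv_endo"),
        "RVFW": ("rv_endo", "epi"),
    }
    for region, (tag_in, tag_out) in pairs.items():
        cells_r = set(mesh.region_cells(region).tolist())
        if not cells_r:
            continue
        sel_in = (mesh.facet_tags == SURFACE_TAGS[tag_in]) & np.isin(
            owner, list(cells_r)
        )
        sel_out = (mesh.facet_tags == SURFACE_TAGS[tag_out]) & np.isin(
            owner, list(cells_r)
        )
        f_in = mesh.boundary_facets[sel_in]
        f_out = mesh.boundary_facets[sel_out]
        # drop opposing facets that touch the source surface (e.g. side faces
        # at the RV attachment) and sample nodes shared with the target
        nodes_in_all = np.unique(f_in)
        if len(f_out):
            shared = np.isin(f_out, nodes_in_all).any(axis=1)
            f_out = f_out[~shared]
        nodes_in = np.setdiff1d(nodes_in_all, np.unique(f_out))
        nodes_in = nodes_in[(zref[nodes_in] >= z_lo) & (zref[nodes_in] <= z_hi)]
        if len(nodes_in) == 0 or len(f_out) == 0:
            warnings.warn(f"region {region}: no mid-ventricular thickness samples")
            out["thickness"][region] = float("nan")
            continue
        dist = _point_triangle_distance(
            x[nodes_in], x[f_out[:, 0]], x[f_out[:, 1]], x[f_out[:, 2]]
        )
        out["thickness"][region] = float(dist.mean())

    for cav, tag in (("LV", "lv_endo"), ("RV", "rv_endo")):
        if np.any(mesh.facet_tags == SURFACE_TAGS[tag]):
            out["cavity_volume"][cav] = cavity_volume_from_surface(
                mesh, tag, displacement
            )
    return out
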