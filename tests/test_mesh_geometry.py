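"""Mesh container and idealized-geometry tests."""

import numpy as np
import pytest

from cardiogrowth.geometry import (
    biventricle,
    cavity_volume_from_surface,
    lv_ellipsoid,
    sphere_shell,
    truncated_ellipsoid_volume,
    wall_metrics,
)
from cardiogrowth.mesh import REGION_TAGS, SURFACE_TAGS, TetMesh


def test_mesh_invariants(bv_mesh):
    bv_mesh.validate()
    assert np.all(bv_mesh.cell_volumes() > 0)
    # every boundary facet tagged exactly once
    assert len(bv_mesh.facet_tags) == len(bv_mesh.boundary_facets)
    # all three regions and all four surfaces present
    assert set(np.unique(bv_mesh.region_tags)) == set(REGION_TAGS.values())
    assert set(np.unique(bv_mesh.facet_tags)) == set(SURFACE_TAGS.values())


def test_cell_orientation_fixup():
    verts = np.array(
        [[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]]
    )
    cells = np.array([[0, 2, 1, 3]])  # negatively oriented on purpose
    m = TetMesh(verts, cells, np.array([1]))
    assert np.isclose(m.cell_volumes()[0], 1.0 / 6.0)


def test_degenerate_cell_rejected():
    verts = np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0], [1.0, 1.0, 0]])
    with pytest.raises(ValueError):
        TetMesh(verts, np.array([[0, 1, 2, 3]]), np.array([1]))


def test_truncated_ellipsoid_volume_closed_forms():
    # full sphere: z_base -> c gives (4/3) pi r^3
    r = 10.0
    assert np.isclose(
        truncated_ellipsoid_volume(r, r, r), 4.0 / 3.0 * np.pi * r**3 / 1000.0
    )
    # hemisphere
    assert np.isclose(
        truncated_ellipsoid_volume(r, r, 0.0), 2.0 / 3.0 * np.pi * r**3 / 1000.0
    )


def test_mesh_cavity_volume_converges_to_analytic():
    exact = truncated_ellipsoid_volume(22.0, 50.0, 15.0)
    errs = []
    for res in (9.0, 4.5):  # target edge length in mm; smaller refines
        m = lv_ellipsoid(resolution=res)
        v = cavity_volume_from_surface(m, "lv_endo")
        errs.append(abs(v - exact) / exact)
    assert errs[1] < errs[0]  # refinement reduces the discretization deficit
    assert errs[1] < 0.03


def test_sphere_cavity_volume_closed_form():
    m = sphere_shell(n_l=16, n_c=32)
    v = cavity_volume_from_surface(m, "lv_endo")
    exact = 2.0 / 3.0 * np.pi * 20.0**3 / 1000.0
    assert abs(v - exact) / exact < 0.01


def test_cavity_volume_displacement_scaling(shell_mesh):
    """Uniform scaling of the geometry scales the cavity volume cubically."""
    v0 = cavity_volume_from_surface(shell_mesh, "lv_endo")
    scale = 1.1
    disp = (scale - 1.0) * shell_mesh.vertices
    v1 = cavity_volume_from_surface(shell_mesh, "lv_endo", displacement=disp)
    assert np.isclose(v1, scale**3 * v0, rtol=1e-12)


def test_wall_metrics_reference(bv_mesh):
    wm = wall_metrics(bv_mesh)
    # LVFW and septum share the prescribed 10 mm wall, RV free wall is 4 mm;
    # faceting makes the measured values slightly smaller
    assert 8.0 < wm["thickness"]["LVFW"] < 10.0
    assert 8.0 < wm["thickness"]["SEPTUM"] < 10.0
    assert 3.0 < wm["thickness"]["RVFW"] < 4.1
    assert wm["cavity_volume"]["LV"] > wm["cavity_volume"]["RV"] * 0.8
    assert all(v > 0 for v in wm["wall_volume"].values())


def test_wall_metrics_uniform_scaling(bv_mesh):
    wm0 = wall_metrics(bv_mesh)
    scale = 1.07
    wm1 = wall_metrics(bv_mesh, displacement=(scale - 1.0) * bv_mesh.vertices)
    for r in ("LVFW", "SEPTUM", "RVFW"):
        assert np.isclose(wm1["thickness"][r], scale * wm0["thickness"][r], rtol=5e-3)
    # nearly cubic: the basal closure fan apex is fixed in the reference
    # configuration, so the cap contribution does not scale exactly
    assert np.isclose(
        wm1["cavity_volume"]["LV"], scale**3 * wm0["cavity_volume"]["LV"], rtol=1e-2
    )


def test_biventricle_regions_are_azimuthal(bv_mesh):
    """Septal cells sit inside the RV sector, LVFW cells outside."""
    cent = bv_mesh.vertices[bv_mesh.cells].mean(axis=1)
    az = np.arctan2(cent[:, 1], cent[:, 0]) % (2 * np.pi)
    sept = bv_mesh.region_tags == REGION_TAGS["SEPTUM"]
    lvfw = bv_mesh.region_tags == REGION_TAGS["LVFW"]
    lo, hi = np.pi * 0.28, np.pi * 1.22
    assert np.all((az[sept] > lo - 0.3) & (az[sept] < hi + 0.3))
    assert not np.any((az[lvfw] > lo + 0.3) & (az[lvfw] < hi - 0.3))


def test_closed_cavity_surface_is_closed(bv_mesh):
    for tag in ("lv_endo", "rv_endo"):
        tris, _ = bv_mesh.closed_cavity_surface(tag)
        edges = np.concatenate(
            [tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]]
        )
        key = np.sort(edges, axis=1)
        _, counts = np.unique(key, axis=0, return_counts=True)
        assert np.all(counts == 2)  # watertight: every edge shared twice
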