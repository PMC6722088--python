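"""Labeled tetrahedral mesh container.

Holds vertices (mm), tet connectivity, per-cell region tags and tagged
boundary facets.  Conventions:

* surface tags: ``lv_endo=1, rv_endo=2, epi=3, base=4``
* region tags:  ``LVFW=1, SEPTUM=2, RVFW=3``

Every boundary facet carries exactly one surface tag; every cell one region
tag; cells are oriented so their signed volumes are positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TetMesh", "SURFACE_TAGS", "REGION_TAGS"]

SURFACE_TAGS = {"lv_endo": 1, "rv_endo": 2, "epi": 3, "base": 4}
REGION_TAGS = {"LVFW": 1, "SEPTUM": 2, "RVFW": 3}

# faces of a tet (0,1,2,3), each ordered so its normal points out of the cell
_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


@dataclass
class TetMesh:
    vertices: np.ndarray  # (nv, 3) float, mm
    cells: np.ndarray  # (ne, 4) int
    region_tags: np.ndarray  # (ne,) int
    boundary_facets: np.ndarray = field(default=None)  # (nb, 3) int, outward-oriented
    facet_tags: np.ndarray = field(default=None)  # (nb,) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.cells = np.asarray(self.cells, dtype=np.int64)
        self.region_tags = np.asarray(self.region_tags, dtype=np.int64)
        self._orient_cells()
        if self.boundary_facets is None:
            self.boundary_facets = self.extract_boundary()
        self.boundary_facets = np.asarray(self.boundary_facets, dtype=np.int64)
        if self.facet_tags is not None:
            self.facet_tags = np.asarray(self.facet_tags, dtype=np.int64)

    # -- construction helpers ------------------------------------------------

    def _orient_cells(self) -> None:
        v = self.vertices[self.cells]
        det = np.linalg.det(v[:, 1:] - v[:, :1])
        flip = det < 0
        if np.any(flip):
            c = self.cells[flip].copy()
            c[:, [2, 3]] = c[:, [3, 2]]
            self.cells[flip] = c
        scale = np.abs(self.vertices).max() or 1.0
        if np.any(np.abs(det) < 1e-12 * scale**3):
            raise ValueError("mesh contains degenerate (zero-volume) cells")

    def extract_boundary(self) -> np.ndarray:
        """Outward-oriented boundary triangles (faces owned by one cell only)."""
        faces = self.cells[:, _TET_FACES].reshape(-1, 3)
        key = np.sort(faces, axis=1)
        _, inv, counts = np.unique(
            key, axis=0, return_inverse=True, return_counts=True
        )
        return faces[counts[inv] == 1]

    # -- queries --------------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def deformed(self, displacement: np.ndarray | None) -> np.ndarray:
        if displacement is None:
            return self.vertices
        displacement = np.asarray(displacement, dtype=float)
        if displacement.shape != self.vertices.shape:
            raise ValueError("displacement must be a per-vertex 3-vector field")
        return self.vertices + displacement

    def cell_volumes(self, displacement: np.ndarray | None = None) -> np.ndarray:
        x = self.deformed(displacement)[self.cells]
        return np.abs(np.linalg.det(x[:, 1:] - x[:, :1])) / 6.0

    def total_volume(self, displacement: np.ndarray | None = None) -> float:
        return float(self.cell_volumes(displacement).sum())

    def region_cells(self, name: str) -> np.ndarray:
        return np.where(self.region_tags == REGION_TAGS[name])[0]

    def facets_with_tag(self, name: str) -> np.ndarray:
        if self.facet_tags is None:
            raise ValueError("mesh has no facet tags")
        return self.boundary_facets[self.facet_tags == SURFACE_TAGS[name]]

    def validate(self) -> None:
        """Check labeling invariants: one tag per facet/cell, positive volumes."""
        if self.facet_tags is None or len(self.facet_tags) != len(self.boundary_facets):
            raise ValueError("every boundary facet must carry exactly one surface tag")
        if not set(np.unique(self.facet_tags)).issubset(set(SURFACE_TAGS.values())):
            raise ValueError("unknown surface tag present")
        if not set(np.unique(self.region_tags)).issubset(set(REGION_TAGS.values())):
            raise ValueError("unknown region tag present")
        if np.any(self.cell_volumes() <= 0):
            raise ValueError("nonpositive cell volume")

    # -- surface-mesh utilities ----------------------------------------------

    def surface_ring(self, facets: np.ndarray) -> np.ndarray:
        """Boundary edge loop of an open facet patch (edges used once)."""
        edges = np.concatenate(
            [facets[:, [0, 1]], facets[:, [1, 2]], facets[:, [2, 0]]]
        )
        key = np.sort(edges, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        return edges[counts[inv] == 1]

    def closed_cavity_surface(self, tag_name: str) -> tuple[np.ndarray, np.ndarray]:
        """Cavity facets plus cap-fan triangles closing the basal opening.

        Returns ``(triangles, fan_apex)`` where ``triangles`` indexes mesh
        vertices and fan triangles use a virtual apex appended by the caller
        (index = n_vertices), placed at ``fan_apex`` (centroid of the basal
        ring in the reference configuration).
        """
        facets = self.facets_with_tag(tag_name)
        if len(facets) == 0:
            raise ValueError(f"no facets tagged {tag_name!r}")
        ring = self.surface_ring(facets)
        if len(ring) == 0:
            raise ValueError(f"cavity surface {tag_name!r} has no basal opening")
        apex = self.vertices[np.unique(ring)].mean(axis=0)
        nv = self.n_vertices
        fan = np.column_stack(
            [ring[:, 1], ring[:, 0], np.full(len(ring), nv, dtype=np.int64)]
        )
        return np.concatenate([facets, fan]), apex

    def write_vtk(
        self,
        path,
        point_data: dict[str, np.ndarray] | None = None,
        cell_data: dict[str, np.ndarray] | None = None,
    ) -> None:
        from .vtkio import write_vtk_unstructured

        cd = {"region": self.region_tags}
        if cell_data:
            cd.update(cell_data)
        write_vtk_unstructured(path, self.vertices, self.cells, point_data, cd)
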