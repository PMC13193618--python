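"""Heightmap -> watertight triangle solid.

A grid cell is emitted iff all 4 corner nodes are included by the mask.
The solid consists of a relief top (2 triangles per cell, fixed diagonal
split from the low-row/low-col corner to the high-row/high-col corner), a
flat bottom at z = 0 wound downward, and vertical walls along every cell
edge bordering an unemitted region or the grid border.

At a "pinch" node — where exactly the two diagonally opposite cells around
a node are emitted — the node's top and bottom vertices are duplicated per
fan of edge-connected cells, so every undirected edge of the output is
shared by exactly two facets even for adversarial masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MaskError, MeshValidationError
from .relief import HeightMap

__all__ = [
    "TriangleMesh",
    "WatertightReport",
    "heightmap_to_solid",
    "mesh_volume",
    "validate_watertight",
]

_DEGENERATE_AREA = 1e-12


@dataclass(frozen=True)
class TriangleMesh:
    """Indexed triangle soup: vertices in mm, counter-clockwise winding
    seen from outside (right-hand-rule normals point outward)."""

    vertices: np.ndarray = field(repr=False)  # (V, 3) float64
    triangles: np.ndarray = field(repr=False)  # (F, 3) int64

    def __post_init__(self):
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError(f"vertices must be (V, 3), got {self.vertices.shape}")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError(f"triangles must be (F, 3), got {self.triangles.shape}")
        if len(self.triangles) and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise ValueError("triangle indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def facet_corners(self) -> np.ndarray:
        """(F, 3, 3) array of triangle corner coordinates."""
        return self.vertices[self.triangles]

    def facet_normals(self) -> np.ndarray:
        """Unit right-hand-rule normals, one per facet."""
        c = self.facet_corners()
        n = np.cross(c[:, 1] - c[:, 0], c[:, 2] - c[:, 0])
        length = np.linalg.norm(n, axis=1, keepdims=True)
        length[length == 0] = 1.0
        return n / length

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)


@dataclass(frozen=True)
class WatertightReport:
    """Defect listing; an empty report certifies a printable closed manifold."""

    boundary_edges: list  # undirected edges with facet count 1
    nonmanifold_edges: list  # undirected edges with facet count > 2
    inconsistent_edges: list  # directed edges traversed twice in the same direction
    degenerate_facets: list  # facet indices with (near-)zero area

    @property
    def is_watertight(self) -> bool:
        return not (
            self.boundary_edges
            or self.nonmanifold_edges
            or self.inconsistent_edges
            or self.degenerate_facets
        )

    def summary(self) -> str:
        if self.is_watertight:
            return "watertight, consistently oriented"
        return (
            f"{len(self.boundary_edges)} boundary edge(s), "
            f"{len(self.nonmanifold_edges)} non-manifold edge(s), "
            f"{len(self.inconsistent_edges)} inconsistently wound edge(s), "
            f"{len(self.degenerate_facets)} degenerate facet(s)"
        )


# Cell slots around node (r, c), in rotational (cyclic) order.  Two slots
# adjacent in this cycle share a grid edge incident to the node.
_NW, _NE, _SE, _SW = 0, 1, 2, 3


def heightmap_to_solid(hm: HeightMap) -> TriangleMesh:
    """Triangulate a (possibly masked) heightmap into a closed solid."""
    mask = hm.mask
    cells = mask[:-1, :-1] & mask[1:, :-1] & mask[:-1, 1:] & mask[1:, 1:]
    if not cells.any():
        raise MaskError("no printable area: no fully included 2x2 node block")

    rows, cols = hm.rows, hm.cols
    # Padded cell grid: cp[r, c] == cell (r-1, c-1) emitted; False border.
    cp = np.zeros((rows + 1, cols + 1), dtype=bool)
    cp[1:rows, 1:cols] = cells

    # Incident cell slots per node, cyclic order NW, NE, SE, SW.
    nw = cp[0:rows, 0:cols]
    ne = cp[0:rows, 1 : cols + 1]
    se = cp[1 : rows + 1, 1 : cols + 1]
    sw = cp[1 : rows + 1, 0:cols]
    used = nw | ne | se | sw
    # Exactly-diagonal patterns need a second vertex fan.
    pinch_a = nw & se & ~ne & ~sw  # NW+SE emitted
    pinch_b = ne & sw & ~nw & ~se  # NE+SW emitted

    # Fan index per (node, slot): 0 everywhere except the second cell of a
    # diagonal pair.
    fan = np.zeros((rows, cols, 4), dtype=np.int8)
    fan[:, :, _SE][pinch_a] = 1
    fan[:, :, _SW][pinch_b] = 1

    n_fans = np.where(pinch_a | pinch_b, 2, 1)
    n_fans[~used] = 0

    # Vertex ids: per node, per fan, top then bottom.
    top_id = np.full((rows, cols, 2), -1, dtype=np.int64)
    bot_id = np.full((rows, cols, 2), -1, dtype=np.int64)
    xs = hm.x_coords
    ys = hm.y_coords

    verts: list[tuple[float, float, float]] = []
    rr, cc = np.nonzero(used)
    for r, c in zip(rr.tolist(), cc.tolist()):
        for f in range(n_fans[r, c]):
            top_id[r, c, f] = len(verts)
            verts.append((xs[c], ys[r], hm.z[r, c]))
            bot_id[r, c, f] = len(verts)
            verts.append((xs[c], ys[r], 0.0))

    def tv(r, c, slot):
        return top_id[r, c, fan[r, c, slot]]

    def bv(r, c, slot):
        return bot_id[r, c, fan[r, c, slot]]

    tris: list[tuple[int, int, int]] = []
    crr, ccc = np.nonzero(cells)
    for r, c in zip(crr.tolist(), ccc.tolist()):
        # Corner nodes of cell (r, c); the slot names which quadrant the
        # cell occupies around each corner node.
        ta = tv(r, c, _SE)          # node (r, c): top-left in xy
        tb = tv(r, c + 1, _SW)      # node (r, c+1): top-right
        tc = tv(r + 1, c + 1, _NW)  # node (r+1, c+1): bottom-right
        td = tv(r + 1, c, _NE)      # node (r+1, c): bottom-left
        ba = bv(r, c, _SE)
        bb = bv(r, c + 1, _SW)
        bc = bv(r + 1, c + 1, _NW)
        bd = bv(r + 1, c, _NE)

        # Top: split along the (r, c) -> (r+1, c+1) diagonal, CCW from +z.
        tris.append((ta, td, tc))
        tris.append((ta, tc, tb))
        # Bottom: mirrored winding, normals point down.
        tris.append((ba, bc, bd))
        tris.append((ba, bb, bc))

        # Walls where a neighbouring cell is absent.  Edge direction P->Q
        # follows the top face's CCW boundary (A->D->C->B->A).
        if not cp[r + 1, c]:  # west neighbour (r, c-1)
            tris.extend(_wall(ta, td, ba, bd))
        if not cp[r + 2, c + 1]:  # south neighbour (r+1, c)
            tris.extend(_wall(td, tc, bd, bc))
        if not cp[r + 1, c + 2]:  # east neighbour (r, c+1)
            tris.extend(_wall(tc, tb, bc, bb))
        if not cp[r, c + 1]:  # north neighbour (r-1, c)
            tris.extend(_wall(tb, ta, bb, ba))

    return TriangleMesh(
        np.asarray(verts, dtype=np.float64), np.asarray(tris, dtype=np.int64)
    )


def _wall(tp, tq, bp, bq):
    """Quad from top edge P->Q down to z=0, wound outward."""
    return [(tp, bp, bq), (tp, bq, tq)]


def _directed_edges(triangles: np.ndarray) -> np.ndarray:
    return np.concatenate(
        [triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]]
    )


def validate_watertight(mesh: TriangleMesh) -> WatertightReport:
    """Check closed-2-manifold and orientation invariants.

    An empty report means every undirected edge is shared by exactly two
    facets, adjacent facets are consistently wound, and no facet is
    degenerate.
    """
    tris = mesh.triangles
    if len(tris) == 0:
        return WatertightReport([], [], [], [])
    directed = _directed_edges(tris)
    undirected = np.sort(directed, axis=1)
    uniq, counts = np.unique(undirected, axis=0, return_counts=True)
    boundary = [tuple(e) for e in uniq[counts == 1]]
    nonmanifold = [tuple(e) for e in uniq[counts > 2]]

    duniq, dcounts = np.unique(directed, axis=0, return_counts=True)
    inconsistent = [tuple(e) for e in duniq[dcounts > 1]]

    c = mesh.facet_corners()
    areas = 0.5 * np.linalg.norm(
        np.cross(c[:, 1] - c[:, 0], c[:, 2] - c[:, 0]), axis=1
    )
    degenerate = np.nonzero(areas < _DEGENERATE_AREA)[0].tolist()

    return WatertightReport(boundary, nonmanifold, inconsistent, degenerate)


def mesh_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume in mm^3 via the signed-tetrahedron sum.

    Positive for an outward-oriented mesh; raises if the mesh is not
    watertight (the sum is meaningless on open meshes).
    """
    report = validate_watertight(mesh)
    if not report.is_watertight:
        raise MeshValidationError(f"mesh is not watertight: {report.summary()}")
    c = mesh.facet_corners()
    return float(np.einsum("ij,ij->", np.cross(c[:, 0], c[:, 1]), c[:, 2]) / 6.0)


def euler_characteristic(mesh: TriangleMesh) -> int:
    """V - E + F counting only vertices referenced by facets."""
    tris = mesh.triangles
    v = len(np.unique(tris))
    e = len(np.unique(np.sort(_directed_edges(tris), axis=1), axis=0))
    return v - e + len(tris)
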