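"""Structured tetrahedral meshing of labelled voxel volumes and mesh quality.

Each non-air voxel is split into the 6 path tetrahedra of the Kuhn/Freudenthal
decomposition around the main cube diagonal.  With the same diagonal
orientation in every voxel the decomposition is conforming: the two triangles
on any shared cube face coincide between neighbours.  The decomposition is
deterministic, volume-exact, and all its tetrahedra are non-obtuse, which gives
the assembled diffusion operator the M-matrix (discrete maximum principle)
property.

Quality is measured by the Joe-Liu volume index

    qvol = 12 * (3 * vol)^(2/3) / sum_{i<j} |l_ij|^2 ,

equal to 1 for the regular tetrahedron and tending to 0 for degenerate ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .phantom import TISSUE_LABELS, VoxelModel

__all__ = [
    "TetMesh",
    "MeshStatistics",
    "voxel_to_tetmesh",
    "joe_liu_quality",
    "mesh_statistics",
    "write_vtk",
]

_GM = TISSUE_LABELS["gm"]
_WM = TISSUE_LABELS["wm"]


@dataclass
class TetMesh:
    """Tetrahedral mesh with per-element tissue and per-node parcel labels."""

    nodes: np.ndarray  # (N, 3) mm
    elements: np.ndarray  # (M, 4) int32, positively oriented
    element_tissue: np.ndarray  # (M,) int8
    element_region: np.ndarray  # (M,) int32, 0 = non-brain
    node_region: np.ndarray  # (N,) int32, 0 = non-brain
    node_tissue: np.ndarray  # (N,) int8 majority tissue of incident voxels
    element_quality: np.ndarray = field(default=None)  # (M,) qvol

    def __post_init__(self) -> None:
        if self.element_quality is None:
            self.element_quality = joe_liu_quality(self.nodes[self.elements])

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_volumes(self) -> np.ndarray:
        if not hasattr(self, "_volumes"):
            self._volumes = _signed_volumes(self.nodes[self.elements])
        return self._volumes

    def nodal_volumes(self) -> np.ndarray:
        """Lumped nodal volumes: sum of V_e/4 over incident elements [mm^3]."""
        if not hasattr(self, "_nodal_volumes"):
            v = np.zeros(self.n_nodes)
            np.add.at(v, self.elements.ravel(), np.repeat(self.element_volumes() / 4.0, 4))
            self._nodal_volumes = v
        return self._nodal_volumes

    def faces(self) -> tuple:
        """(unique_faces, counts): sorted node triples and incidence counts."""
        el = self.elements
        tri = np.concatenate(
            [el[:, [0, 1, 2]], el[:, [0, 1, 3]], el[:, [0, 2, 3]], el[:, [1, 2, 3]]]
        )
        tri = np.sort(tri, axis=1)
        return np.unique(tri, axis=0, return_counts=True)

    def boundary_faces(self) -> np.ndarray:
        """Faces incident to exactly one element, as (F, 3) node triples."""
        faces, counts = self.faces()
        return faces[counts == 1]


def _signed_volumes(p: np.ndarray) -> np.ndarray:
    d = p[..., 1:, :] - p[..., :1, :]
    return np.linalg.det(d) / 6.0


# 6 path tetrahedra of the unit cube sharing diagonal c000 -> c111.
# Corner offsets indexed as bit pattern (dx, dy, dz).
def _kuhn_templates() -> np.ndarray:
    corners = {
        (dx, dy, dz): np.array([dx, dy, dz]) for dx in (0, 1) for dy in (0, 1) for dz in (0, 1)
    }
    tets = []
    for perm in permutations(range(3)):
        v = [np.zeros(3, dtype=int)]
        acc = np.zeros(3, dtype=int)
        for axis in perm:
            acc = acc.copy()
            acc[axis] = 1
            v.append(acc)
        tet = np.array([_corner_index(c) for c in v])
        # enforce positive orientation
        pts = np.array([list(corners[_corner_bits(i)]) for i in tet], dtype=float)
        if _signed_volumes(pts[None])[0] < 0:
            tet = tet[[0, 2, 1, 3]]
        tets.append(tet)
    return np.array(tets)


def _corner_index(c) -> int:
    return int(c[0]) * 4 + int(c[1]) * 2 + int(c[2])


def _corner_bits(i: int) -> tuple:
    return ((i >> 2) & 1, (i >> 1) & 1, i & 1)


_TEMPLATES = _kuhn_templates()  # (6, 4) indices into the 8 cube corners
_CORNER_OFFSETS = np.array([_corner_bits(i) for i in range(8)])  # (8, 3)


def voxel_to_tetmesh(model: VoxelModel) -> TetMesh:
    """Decompose every non-air voxel into 6 tetrahedra; merge shared nodes.

    Element tissue/region are inherited from the parent voxel.  Node region and
    node tissue are majority votes over the voxels incident to the node, ties
    broken by the smallest label id (nodes not touching any brain voxel get
    region 0).
    """
    nonair = model.labels != TISSUE_LABELS["air"]
    vox = np.argwhere(nonair)
    if len(vox) == 0:
        raise ValueError("voxel model has no tissue voxels")

    shape = np.asarray(model.shape)
    grid_shape = shape + 1

    # global corner ids of the 8 corners of each voxel
    corner_idx = vox[:, None, :] + _CORNER_OFFSETS[None, :, :]  # (V, 8, 3)
    corner_gid = np.ravel_multi_index(
        (corner_idx[..., 0], corner_idx[..., 1], corner_idx[..., 2]), grid_shape
    )  # (V, 8)

    used = np.unique(corner_gid)
    remap = np.full(int(np.prod(grid_shape)), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    local = remap[corner_gid]  # (V, 8)

    # node coordinates: corner (i,j,k) sits at origin + (i-1/2, j-1/2, k-1/2)*h
    ijk = np.stack(np.unravel_index(used, grid_shape), axis=1).astype(float)
    nodes = model.origin + (ijk - 0.5) * model.voxel_size

    elements = local[:, _TEMPLATES].reshape(-1, 4).astype(np.int32)  # (6V, 4)
    labels_v = model.labels[nonair]
    regions_v = model.regions[nonair]
    element_tissue = np.repeat(labels_v, 6).astype(np.int8)
    element_region = np.repeat(regions_v, 6).astype(np.int32)

    node_region = _majority_vote(corner_gid, regions_v, remap, len(used), brain_only=True)
    node_tissue = _majority_vote(
        corner_gid, labels_v.astype(np.int32), remap, len(used), brain_only=False
    ).astype(np.int8)

    return TetMesh(
        nodes=nodes,
        elements=elements,
        element_tissue=element_tissue,
        element_region=element_region,
        node_region=node_region,
        node_tissue=node_tissue,
    )


def _majority_vote(corner_gid, values, remap, n_nodes, brain_only):
    """Per-node majority over incident voxel values; ties -> smallest value."""
    vals = np.repeat(values, 8)
    nids = remap[corner_gid.ravel()]
    if brain_only:
        keep = vals > 0
        vals, nids = vals[keep], nids[keep]
    if len(vals) == 0:
        return np.zeros(n_nodes, dtype=np.int32)
    vmax = int(vals.max()) + 1
    key = nids.astype(np.int64) * vmax + vals
    uniq, counts = np.unique(key, return_counts=True)
    node = (uniq // vmax).astype(np.int64)
    val = (uniq % vmax).astype(np.int64)
    # order by (node, -count, value): stable pick of first row per node
    order = np.lexsort((val, -counts, node))
    node, val = node[order], val[order]
    first = np.ones(len(node), dtype=bool)
    first[1:] = node[1:] != node[:-1]
    out = np.zeros(n_nodes, dtype=np.int32)
    out[node[first]] = val[first]
    return out


def joe_liu_quality(points: np.ndarray) -> np.ndarray:
    """Joe-Liu volume quality index of tetrahedra given as (..., 4, 3) arrays.

    Returns values in [0, 1]; coincident/coplanar vertices give 0.  The index
    is invariant to uniform scaling and to any permutation of the vertices.
    """
    p = np.asarray(points, dtype=float)
    single = p.ndim == 2
    if single:
        p = p[None]
    vol = np.abs(_signed_volumes(p))
    ii, jj = np.triu_indices(4, k=1)
    edges = p[..., ii, :] - p[..., jj, :]
    l2 = np.sum(edges * edges, axis=-1).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(l2 > 0, 12.0 * np.cbrt(3.0 * vol) ** 2 / l2, 0.0)
    return float(q[0]) if single else q


@dataclass(frozen=True)
class MeshStatistics:
    n_nodes: int
    n_elements: int
    n_boundary_faces: int
    quality_mean: float
    quality_std: float
    fraction_above_0_7: float

    def __str__(self) -> str:
        return (
            f"nodes={self.n_nodes} elements={self.n_elements} "
            f"boundary_faces={self.n_boundary_faces} "
            f"qvol={self.quality_mean:.3f}+-{self.quality_std:.3f} "
            f"frac(qvol>0.7)={self.fraction_above_0_7:.3f}"
        )


def mesh_statistics(mesh: TetMesh) -> MeshStatistics:
    """Node/element/boundary-face counts and Joe-Liu quality summary."""
    q = mesh.element_quality
    return MeshStatistics(
        n_nodes=mesh.n_nodes,
        n_elements=mesh.n_elements,
        n_boundary_faces=len(mesh.boundary_faces()),
        quality_mean=float(q.mean()),
        quality_std=float(q.std()),
        fraction_above_0_7=float((q > 0.7).mean()),
    )


def write_vtk(mesh: TetMesh, path, point_data: dict | None = None) -> None:
    """Write the mesh (and optional per-node scalar fields) as legacy ASCII VTK."""
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nnirscc tetrahedral mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(f, mesh.nodes, fmt="%.6g")
        f.write(f"CELLS {mesh.n_elements} {mesh.n_elements * 5}\n")
        cells = np.column_stack([np.full(mesh.n_elements, 4), mesh.elements])
        np.savetxt(f, cells, fmt="%d")
        f.write(f"CELL_TYPES {mesh.n_elements}\n")
        np.savetxt(f, np.full(mesh.n_elements, 10), fmt="%d")
        f.write(f"CELL_DATA {mesh.n_elements}\n")
        f.write("SCALARS tissue int 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, mesh.element_tissue, fmt="%d")
        fields = {"region": mesh.node_region.astype(float)}
        if point_data:
            fields.update(point_data)
        f.write(f"POINT_DATA {mesh.n_nodes}\n")
        for name, values in fields.items():
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, np.asarray(values, dtype=float), fmt="%.8g")
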