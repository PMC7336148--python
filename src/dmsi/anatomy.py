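"""Cortical surface handling.

The source space for distributed source imaging is a triangulated cortical
mesh with one current dipole per vertex, oriented along the local surface
normal.  This module owns the mesh container, the vertex adjacency graph,
Euclidean distance fields to a reference region, and graph-constrained patch
growing (used both to define synthetic ground-truth foci and to parcellate
the cortex for the maximum-entropy solver).

All coordinates are in millimeters.  Distances are Euclidean (chord)
distances, not geodesic ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = [
    "CorticalMesh",
    "FocusRegion",
    "build_adjacency",
    "distance_to_region",
    "grow_patch",
    "save_surface_gifti",
    "load_surface_gifti",
    "save_surface_freesurfer",
    "load_surface_freesurfer",
    "save_region",
    "load_region",
]


class MeshError(ValueError):
    """Raised for malformed surface meshes."""


@dataclass
class CorticalMesh:
    """Triangulated cortical surface with per-vertex unit normals.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex positions in millimeters.
    faces : (m, 3) int array
        Vertex-index triples.
    normals : (n, 3) float array
        Unit dipole orientation per vertex (perpendicular to the surface).
    """

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.normals = np.asarray(self.normals, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be (m, 3)")
        if self.normals.shape != self.vertices.shape:
            raise MeshError("normals must match vertices in shape")
        n = len(self.vertices)
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= n:
            raise MeshError("face indices out of range")
        used = np.zeros(n, dtype=bool)
        used[self.faces.ravel()] = True
        if not used.all():
            raise MeshError("every vertex must belong to at least one face")
        norms = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise MeshError("vertex normals must have unit norm (tol 1e-9)")
        adj = build_adjacency(self)
        n_comp, _ = connected_components(adj, directed=False)
        if n_comp != 1:
            raise MeshError(f"mesh adjacency graph is disconnected ({n_comp} components)")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @classmethod
    def from_geometry(cls, vertices: np.ndarray, faces: np.ndarray) -> "CorticalMesh":
        """Build a mesh, computing outward area-weighted vertex normals.

        Face normals are accumulated per vertex with area weighting and each
        is oriented away from the vertex centroid; this is valid for the
        star-shaped surfaces used throughout (closed head-like meshes).
        """
        vertices = np.asarray(vertices, dtype=float)
        faces = np.asarray(faces, dtype=np.int64)
        centroid = vertices.mean(axis=0)
        v0, v1, v2 = (vertices[faces[:, k]] for k in range(3))
        fn = np.cross(v1 - v0, v2 - v0)  # area-weighted face normal
        # orient each face normal outward w.r.t. the centroid
        fc = (v0 + v1 + v2) / 3.0
        flip = np.einsum("ij,ij->i", fn, fc - centroid) < 0
        fn[flip] *= -1.0
        normals = np.zeros_like(vertices)
        for k in range(3):
            np.add.at(normals, faces[:, k], fn)
        lens = np.linalg.norm(normals, axis=1)
        if np.any(lens == 0):
            raise MeshError("degenerate vertex normal")
        normals /= lens[:, None]
        return cls(vertices, faces, normals)


@dataclass
class FocusRegion:
    """A connected set of mesh vertices serving as the reference region.

    In the clinical setting this is the epileptic focus delineated on the
    cortical surface; here it is either user supplied or grown synthetically
    with :func:`grow_patch`.
    """

    vertex_ids: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        ids = np.unique(np.asarray(self.vertex_ids, dtype=np.int64))
        if ids.size == 0:
            raise ValueError("FocusRegion must contain at least one vertex")
        self.vertex_ids = ids

    def __len__(self) -> int:
        return len(self.vertex_ids)

    def check(self, mesh: CorticalMesh) -> None:
        """Validate that the region is a connected subset of ``mesh``."""
        if self.vertex_ids.min() < 0 or self.vertex_ids.max() >= mesh.n_vertices:
            raise ValueError("region vertices outside mesh")
        adj = build_adjacency(mesh)
        sub = adj[np.ix_(self.vertex_ids, self.vertex_ids)]
        n_comp, _ = connected_components(sub, directed=False)
        if n_comp != 1:
            raise ValueError("region is not connected in the mesh adjacency graph")


def build_adjacency(mesh: CorticalMesh) -> sparse.csr_matrix:
    """Vertex adjacency from shared face edges, as a symmetric boolean CSR matrix.

    Raises
    ------
    MeshError
        If the mesh contains duplicate faces (same vertex triple in any
        order), which indicates a non-manifold surface.
    """
    faces = mesh.faces
    key = np.sort(faces, axis=1)
    if len(np.unique(key, axis=0)) != len(faces):
        raise MeshError("duplicate faces: non-manifold mesh rejected")
    i = faces[:, [0, 1, 2]].ravel()
    j = faces[:, [1, 2, 0]].ravel()
    n = mesh.n_vertices
    a = sparse.coo_matrix((np.ones(len(i), dtype=bool), (i, j)), shape=(n, n))
    a = (a + a.T).tocsr()
    a.setdiag(False)
    a.eliminate_zeros()
    a.data = np.ones_like(a.data, dtype=bool)
    return a


def neighbors(adj: sparse.csr_matrix, vertex: int) -> np.ndarray:
    """Neighbor indices of ``vertex`` in a CSR adjacency matrix."""
    return adj.indices[adj.indptr[vertex] : adj.indptr[vertex + 1]]


def distance_to_region(mesh: CorticalMesh, region: FocusRegion) -> np.ndarray:
    """Per-vertex minimum Euclidean distance (mm) to the region.

    ``d_i = min_{j in region} ||x_i - x_j||``; exactly zero for vertices in
    the region.
    """
    if len(region) == 0:  # pragma: no cover - FocusRegion forbids this
        raise ValueError("empty region")
    tree = cKDTree(mesh.vertices[region.vertex_ids])
    d, _ = tree.query(mesh.vertices)
    d[region.vertex_ids] = 0.0
    return d


def grow_patch(mesh: CorticalMesh, seed: int, radius_mm: float, label: str = "") -> FocusRegion:
    """Grow a connected cortical patch around ``seed``.

    Breadth-first search over the adjacency graph, accepting only vertices
    within ``radius_mm`` Euclidean distance of the seed: the result is the
    maximal connected set containing the seed that is reachable through
    accepted vertices.  A radius below the shortest incident edge returns the
    singleton ``{seed}``.
    """
    if not 0 <= seed < mesh.n_vertices:
        raise ValueError(f"seed {seed} outside mesh")
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    adj = build_adjacency(mesh)
    x0 = mesh.vertices[seed]
    within = np.linalg.norm(mesh.vertices - x0, axis=1) <= radius_mm
    accepted = {seed}
    frontier = [seed]
    while frontier:
        nxt = []
        for v in frontier:
            for u in neighbors(adj, v):
                if within[u] and u not in accepted:
                    accepted.add(int(u))
                    nxt.append(int(u))
        frontier = nxt
    return FocusRegion(np.fromiter(accepted, dtype=np.int64), label=label)


# ---------------------------------------------------------------------------
# surface / region I/O
# ---------------------------------------------------------------------------

def save_surface_gifti(mesh: CorticalMesh, path) -> None:
    """Write the surface as GIfTI (.surf.gii); units declared as mm."""
    import nibabel as nib

    meta = nib.gifti.GiftiMetaData()
    meta["units"] = "mm"
    pts = nib.gifti.GiftiDataArray(
        mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET", meta=meta
    )
    tri = nib.gifti.GiftiDataArray(
        mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
    )
    nib.save(nib.gifti.GiftiImage(darrays=[pts, tri]), str(path))


def load_surface_gifti(path) -> CorticalMesh:
    import nibabel as nib

    img = nib.load(str(path))
    vertices, faces = img.agg_data(("pointset", "triangle"))
    return CorticalMesh.from_geometry(np.asarray(vertices, float), np.asarray(faces))


def save_surface_freesurfer(mesh: CorticalMesh, path) -> None:
    import nibabel.freesurfer as fs

    fs.write_geometry(str(path), mesh.vertices, mesh.faces)


def load_surface_freesurfer(path) -> CorticalMesh:
    import nibabel.freesurfer as fs

    vertices, faces = fs.read_geometry(str(path))
    return CorticalMesh.from_geometry(np.asarray(vertices, float), np.asarray(faces))


def save_region(region: FocusRegion, path, mesh: CorticalMesh | None = None) -> None:
    """Write a region as a FreeSurfer .label file (needs ``mesh``) or as
    plain one-index-per-line text."""
    path = str(path)
    ids = region.vertex_ids
    if path.endswith(".label"):
        if mesh is None:
            raise ValueError("writing a FreeSurfer label requires the mesh")
        with open(path, "w") as fh:
            fh.write(f"#!ascii label {region.label}\n{len(ids)}\n")
            for i in ids:
                x, y, z = mesh.vertices[i]
                fh.write(f"{i} {x:.6f} {y:.6f} {z:.6f} 0.000000\n")
    else:
        np.savetxt(path, ids, fmt="%d")


def load_region(path, label: str = "") -> FocusRegion:
    path = str(path)
    if path.endswith(".label"):
        import nibabel.freesurfer as fs

        ids = fs.read_label(path)
    else:
        ids = np.loadtxt(path, dtype=np.int64, ndmin=1)
    return FocusRegion(np.asarray(ids, dtype=np.int64), label=label)
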