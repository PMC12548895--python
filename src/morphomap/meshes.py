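"""Triangular surface meshes: extraction from masks, smoothing, rasterization,
geodesic neighbourhoods and propagation through motion fields.

The tissue is modelled as a surface ("Live-Shape"): a fixed triangulation
whose node positions evolve over time. Meshes store node positions in um
(world frame shared with the image masks via their voxel size).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage import measure

__all__ = [
    "SurfaceMesh",
    "LiveShapeSequence",
    "mask_to_mesh",
    "smooth_mesh",
    "mesh_to_mask",
    "mesh_to_shell_mask",
    "propagate_mesh",
    "face_areas",
    "face_centroids",
    "geodesic_neighbourhood",
    "load_mesh",
    "save_mesh",
]


@dataclass
class SurfaceMesh:
    """Triangle mesh with nodes in um world coordinates.

    ``provenance`` records how the mesh was produced (source mask, frame,
    smoothing settings, ...) and travels with derived meshes.
    """

    nodes: np.ndarray  # (n, 3) float, um
    faces: np.ndarray  # (m, 3) int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.nodes)
        ):
            raise ValueError("face indices out of range")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.nodes, faces=self.faces, process=False
        )

    def euler_characteristic(self) -> int:
        tm = self.to_trimesh()
        return int(tm.euler_number)

    def copy_with_nodes(self, nodes: np.ndarray) -> "SurfaceMesh":
        return SurfaceMesh(
            nodes=np.asarray(nodes, float),
            faces=self.faces.copy(),
            provenance=dict(self.provenance),
        )


@dataclass
class LiveShapeSequence:
    """One mesh topology with per-frame node positions.

    The triangulation is fixed over time (nodes are material points; no
    exchange of node identity), so any frame pair supports per-face
    deformation analysis.
    """

    topology: np.ndarray  # (m, 3) faces shared across time
    positions: np.ndarray  # (n_frames, n_nodes, 3) um
    anchor_frame: int
    out_of_domain: np.ndarray | None = None  # (n_frames, n_nodes) bool
    provenance: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    def mesh_at(self, frame: int) -> SurfaceMesh:
        return SurfaceMesh(
            nodes=self.positions[frame],
            faces=self.topology,
            provenance={**self.provenance, "frame": frame},
        )


def mask_to_mesh(mask, target_density: float | None = None) -> SurfaceMesh:
    """Extract a genus-0 surface mesh at the boundary of a binary mask.

    Marching cubes on the (hole-filled, padded) mask, keeping the largest
    connected surface component; coordinates are scaled to um by the
    mask's voxel size. ``target_density`` (faces per um^2) optionally
    triggers vertex-clustering decimation toward that density.

    Raises if the mask is empty, and reports component sizes if the
    foreground has several large connected components.
    """
    vox = np.asarray(mask.voxels, dtype=bool)
    if not vox.any():
        raise ValueError("mask_to_mesh: empty mask")
    voxel_size = np.asarray(getattr(mask, "voxel_size", (1.0, 1.0, 1.0)), float)

    labels, n_comp = ndimage.label(vox)
    if n_comp > 1:
        sizes = np.sort(np.bincount(labels.ravel())[1:])[::-1]
        if sizes.size > 1 and sizes[1] > 0.05 * sizes[0]:
            raise ValueError(
                "mask has multiple large foreground components; "
                f"sizes: {sizes.tolist()}"
            )
        keep = int(np.argmax(np.bincount(labels.ravel())[1:]) + 1)
        vox = labels == keep
    filled = ndimage.binary_fill_holes(vox)
    padded = np.pad(filled, 2)
    # mild smoothing of the indicator before contouring suppresses the
    # stair-casing bias of a raw binary surface (area/volume otherwise
    # run several percent high)
    smoothed = ndimage.gaussian_filter(padded.astype(float), 1.0)
    verts, faces, _, _ = measure.marching_cubes(
        smoothed, level=0.5, spacing=tuple(voxel_size)
    )
    verts = verts - 2 * voxel_size  # undo pad offset

    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    comps = tm.split(only_watertight=False)
    if len(comps) > 1:
        tm = max(comps, key=lambda c: len(c.faces))
    if tm.is_watertight and tm.volume < 0:
        tm.invert()  # outward-facing normals
    mesh = SurfaceMesh(
        nodes=np.asarray(tm.vertices),
        faces=np.asarray(tm.faces),
        provenance={
            "source": "mask_to_mesh",
            "frame": getattr(mask, "frame_index", None),
            "voxel_size": voxel_size.tolist(),
        },
    )
    if target_density is not None:
        current = mesh.n_faces / face_areas(mesh).sum()
        if current > target_density:
            # cluster pitch so that face density lands near the target
            pitch = 1.0 / np.sqrt(target_density)
            mesh = _cluster_decimate(mesh, pitch)
            mesh.provenance["decimated_to"] = target_density
    return mesh


def _cluster_decimate(mesh: SurfaceMesh, pitch: float) -> SurfaceMesh:
    """Vertex-clustering decimation: snap nodes to a grid of size ``pitch``,
    merge coincident nodes and drop collapsed faces."""
    keys = np.round(mesh.nodes / pitch).astype(np.int64)
    _, inverse, counts = np.unique(
        keys, axis=0, return_inverse=True, return_counts=True
    )
    # new node position = mean of its cluster
    new_nodes = np.zeros((counts.size, 3))
    np.add.at(new_nodes, inverse, mesh.nodes)
    new_nodes /= counts[:, None]
    new_faces = inverse[mesh.faces]
    ok = (
        (new_faces[:, 0] != new_faces[:, 1])
        & (new_faces[:, 1] != new_faces[:, 2])
        & (new_faces[:, 0] != new_faces[:, 2])
    )
    return SurfaceMesh(
        nodes=new_nodes,
        faces=new_faces[ok],
        provenance={**mesh.provenance, "decimation": "vertex-clustering"},
    )


def smooth_mesh(
    mesh: SurfaceMesh, alpha: float = 0.9, iterations: int = 5
) -> SurfaceMesh:
    """Laplacian smoothing: p <- (1-alpha) p + alpha * mean(neighbours).

    Defaults (0.9, 5 iterations) are the pipeline's standard surface
    clean-up after mask extraction. Topology is unchanged.
    """
    if alpha == 0 or iterations == 0:
        return mesh.copy_with_nodes(mesh.nodes.copy())
    n = mesh.n_nodes
    edges = np.vstack(
        [mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]
    )
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    adj = coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n)).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1
    pos = mesh.nodes.copy()
    for _ in range(iterations):
        mean_nb = adj @ pos / deg[:, None]
        pos = (1 - alpha) * pos + alpha * mean_nb
    out = mesh.copy_with_nodes(pos)
    out.provenance["smoothing"] = {"alpha": alpha, "iterations": iterations}
    return out


def _boundary_edge_count(tm: trimesh.Trimesh) -> int:
    edges = np.sort(tm.edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return int((counts == 1).sum())


def mesh_to_mask(mesh: SurfaceMesh, voxel_size):
    """Rasterize a closed mesh to a filled binary mask.

    The surface is voxelized at the given pitch and the interior filled.
    Open meshes are rejected with the boundary edge count (close holes
    first).
    """
    from .imaging import BinaryMask

    voxel_size = np.broadcast_to(np.asarray(voxel_size, float), (3,)).copy()
    tm = mesh.to_trimesh()
    if not tm.is_watertight:
        nb = _boundary_edge_count(tm)
        raise ValueError(
            f"mesh_to_mask requires a closed mesh ({nb} boundary edges found)"
        )
    pitch = float(voxel_size[0])
    if not np.allclose(voxel_size, pitch):
        raise ValueError("mesh_to_mask uses an isotropic voxel size")
    if tm.volume < 0:
        tm = tm.copy()
        tm.invert()
    # voxel centers at a half-pitch offset from the bounds, so that flat
    # axis-aligned surfaces never coincide with center planes; a center is
    # inside when the outward normal at the nearest surface sample points
    # away from it
    from scipy.spatial import cKDTree

    bounds = tm.bounds
    origin = bounds[0] - 1.5 * pitch
    shape = np.ceil((bounds[1] - origin) / pitch).astype(int) + 2
    idx = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    ).reshape(3, -1).T
    centers = idx * pitch + origin
    n_samp = max(5000, int(4 * tm.area / pitch**2))
    samples, fidx = trimesh.sample.sample_surface(tm, n_samp, seed=0)
    normals = np.asarray(tm.face_normals)[fidx]
    _, j = cKDTree(samples).query(centers, workers=-1)
    inside = np.einsum("ij,ij->i", centers - samples[j], normals[j]) < 0
    vox = inside.reshape(tuple(shape))
    return BinaryMask(
        voxels=vox,
        voxel_size=voxel_size,
        frame_index=mesh.provenance.get("frame"),
        origin=origin,
    )


def mesh_to_shell_mask(mesh: SurfaceMesh, voxel_size, origin=None, shape=None,
                       closing: int = 1):
    """Rasterize a surface (open or closed) to a one-voxel shell mask.

    This is the tissue-style mask used by the Atlas-projection pipeline:
    the surface itself is the foreground (thin tissue), no interior fill.
    ``origin``/``shape`` pin the voxel grid so several shapes can share
    one frame; ``closing`` applies a morphological closing to seal
    rasterization discontinuities.
    """
    from .imaging import BinaryMask

    voxel_size = np.broadcast_to(np.asarray(voxel_size, float), (3,)).copy()
    pitch = float(voxel_size[0])
    if origin is None:
        origin = mesh.nodes.min(axis=0) - 2 * pitch
    origin = np.asarray(origin, float)
    if shape is None:
        shape = np.ceil((mesh.nodes.max(axis=0) - origin) / pitch).astype(int) + 3
    shape = tuple(int(s) for s in shape)

    # sample each face densely enough to leave no holes at this pitch
    tm = mesh.to_trimesh()
    area = tm.area
    n_samples = max(2000, int(8 * area / pitch**2))
    pts, _ = trimesh.sample.sample_surface_even(tm, n_samples, seed=0)
    pts = np.vstack([pts, mesh.nodes])
    idx = np.round((pts - origin) / pitch).astype(int)
    ok = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
    vox = np.zeros(shape, dtype=bool)
    vox[tuple(idx[ok].T)] = True
    if closing > 0:
        vox = ndimage.binary_closing(vox, iterations=closing)
    return BinaryMask(
        voxels=vox, voxel_size=voxel_size,
        frame_index=mesh.provenance.get("frame"), origin=origin,
    )


def propagate_mesh(mesh: SurfaceMesh, tset) -> LiveShapeSequence:
    """Carry a mesh through a TransformSet: node positions at every frame.

    Node-wise :func:`morphomap.registration.propagate_points` from the
    anchor frame outward in both directions; the triangulation is fixed.
    """
    from .registration import propagate_points

    n_frames = tset.n_frames
    anchor = tset.anchor
    n = mesh.n_nodes
    positions = np.zeros((n_frames, n, 3))
    flags = np.zeros((n_frames, n), dtype=bool)
    positions[anchor] = mesh.nodes
    current = mesh.nodes
    for f in range(anchor + 1, n_frames):
        current, flag = propagate_points(current, tset, f - 1, f)
        positions[f] = current
        flags[f] = flags[f - 1] | flag
    current = mesh.nodes
    for f in range(anchor - 1, -1, -1):
        current, flag = propagate_points(current, tset, f + 1, f)
        positions[f] = current
        flags[f] = flags[f + 1] | flag
    return LiveShapeSequence(
        topology=mesh.faces.copy(),
        positions=positions,
        anchor_frame=anchor,
        out_of_domain=flags,
        provenance={**mesh.provenance, "propagated": True},
    )


def face_areas(mesh: SurfaceMesh) -> np.ndarray:
    """Per-face area in um^2 (half cross-product magnitude)."""
    v = mesh.nodes
    f = mesh.faces
    e1 = v[f[:, 1]] - v[f[:, 0]]
    e2 = v[f[:, 2]] - v[f[:, 0]]
    areas = 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)
    return areas


def face_centroids(mesh: SurfaceMesh) -> np.ndarray:
    return mesh.nodes[mesh.faces].mean(axis=1)


def _face_adjacency_graph(mesh: SurfaceMesh):
    tm = mesh.to_trimesh()
    adj = tm.face_adjacency  # (k, 2) pairs of adjacent faces
    cent = face_centroids(mesh)
    if len(adj) == 0:
        return coo_matrix((mesh.n_faces, mesh.n_faces)).tocsr()
    w = np.linalg.norm(cent[adj[:, 0]] - cent[adj[:, 1]], axis=1)
    i = np.concatenate([adj[:, 0], adj[:, 1]])
    j = np.concatenate([adj[:, 1], adj[:, 0]])
    return coo_matrix(
        (np.concatenate([w, w]), (i, j)), shape=(mesh.n_faces, mesh.n_faces)
    ).tocsr()


def geodesic_neighbourhood(
    mesh: SurfaceMesh, face: int, radius: float
) -> list[int]:
    """Faces within geodesic distance ``radius`` of ``face`` (seed included).

    Distance is the shortest path on the face-adjacency graph with edges
    weighted by centroid-to-centroid Euclidean distance.
    """
    if face < 0 or face >= mesh.n_faces:
        raise IndexError(f"face index {face} out of range")
    if radius <= 0:
        return [int(face)]
    graph = _graph_cache_get(mesh)
    dist = dijkstra(graph, indices=face, limit=radius)
    return np.flatnonzero(np.isfinite(dist)).astype(int).tolist()


# tiny memo so deformation-map smoothing does not rebuild the graph per face
_GRAPH_CACHE: dict[int, object] = {}


def _graph_cache_get(mesh: SurfaceMesh):
    key = id(mesh)
    if key not in _GRAPH_CACHE or _GRAPH_CACHE[key][0] is not mesh:
        if len(_GRAPH_CACHE) > 8:
            _GRAPH_CACHE.clear()
        _GRAPH_CACHE[key] = (mesh, _face_adjacency_graph(mesh))
    return _GRAPH_CACHE[key][1]


def save_mesh(mesh: SurfaceMesh, path, binary: bool = True) -> None:
    """Write PLY (binary little-endian by default, ASCII otherwise)."""
    tm = mesh.to_trimesh()
    encoding = "binary" if binary else "ascii"
    tm.export(str(path), encoding=encoding)


def load_mesh(path) -> SurfaceMesh:
    """Read a PLY/OFF mesh into a :class:`SurfaceMesh` (um units assumed)."""
    tm = trimesh.load_mesh(str(path), process=False)
    return SurfaceMesh(
        nodes=np.asarray(tm.vertices, float),
        faces=np.asarray(tm.faces, int),
        provenance={"source": str(path)},
    )
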