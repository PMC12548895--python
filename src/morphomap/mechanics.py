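"""Finite-deformation continuum mechanics on triangle meshes.

Tissue deformation between two states of a surface mesh (same topology,
corresponding faces) is described per triangle by the 2x2 deformation
gradient ``F`` mapping the rest edge frame onto the deformed edge frame.
From ``F`` we derive the local growth rate ``J = det(F)`` (area ratio:
J = 1 isochoric, J > 1 expansion, J < 1 compression), the Green-Lagrange
strain tensor ``eps = (F^T F - I) / 2``, and the anisotropy ratio
``theta = sigma_max / sigma_min`` of the principal stretches (singular
values of F), with the principal stretch direction lifted back to 3D.

All quantities are invariant to rigid motions of either mesh and to the
choice of in-plane basis; this is exercised by the property tests.

Note on conventions: the anisotropy ratio is computed from the principal
stretches of F, not from the eigenvalues of the strain tensor, which can
vanish or change sign under compression and would make a ratio ill-posed.
Uniform scaling yields theta = 1 under either reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .meshes import SurfaceMesh, face_areas, geodesic_neighbourhood

__all__ = [
    "TriangleFrame",
    "DeformationMap",
    "triangle_frame",
    "triangle_frames",
    "deformation_gradient",
    "growth_rate",
    "strain_tensor",
    "anisotropy",
    "deformation_map",
    "fit_deformation_axis",
]

#: faces with area below this (um^2) are flagged degenerate and excluded
DEGENERATE_AREA = 1e-9


@dataclass
class TriangleFrame:
    """Edge vectors of one triangle expressed in a local orthonormal basis.

    ``edge_matrix`` columns are the two edge vectors e1 = r2 - r1 and
    e2 = r3 - r1 in the 2D basis spanned by ``basis`` (two orthonormal
    3D vectors in the triangle plane); ``origin`` is the first vertex.
    """

    edge_matrix: np.ndarray  # (2, 2)
    basis: np.ndarray  # (2, 3) rows are in-plane unit vectors
    origin: np.ndarray  # (3,)
    degenerate: bool = False


def triangle_frame(vertices: np.ndarray) -> TriangleFrame:
    """Build the local 2D edge frame of a triangle.

    The basis comes from Gram-Schmidt on (e1, e2); the reconstruction
    ``basis.T @ edge_matrix`` reproduces the 3D edge vectors. Collinear
    vertices yield a frame flagged ``degenerate``.
    """
    v = np.asarray(vertices, dtype=float)
    if v.shape != (3, 3):
        raise ValueError("triangle_frame expects three 3D vertices")
    e1 = v[1] - v[0]
    e2 = v[2] - v[0]
    n1 = np.linalg.norm(e1)
    area2 = np.linalg.norm(np.cross(e1, e2))
    if n1 == 0 or area2 / 2.0 < DEGENERATE_AREA:
        return TriangleFrame(
            edge_matrix=np.zeros((2, 2)),
            basis=np.zeros((2, 3)),
            origin=v[0],
            degenerate=True,
        )
    b1 = e1 / n1
    e2_perp = e2 - (e2 @ b1) * b1
    b2 = e2_perp / np.linalg.norm(e2_perp)
    basis = np.vstack([b1, b2])
    edge_matrix = basis @ np.stack([e1, e2], axis=1)
    return TriangleFrame(edge_matrix=edge_matrix, basis=basis, origin=v[0])


def triangle_frames(mesh: SurfaceMesh) -> list[TriangleFrame]:
    """Per-face :func:`triangle_frame` for every face of ``mesh``."""
    return [triangle_frame(mesh.nodes[f]) for f in mesh.faces]


def deformation_gradient(rest: TriangleFrame, deformed: TriangleFrame) -> np.ndarray:
    """F = T R^-1, mapping rest edge coordinates onto deformed ones."""
    if rest.degenerate:
        raise ValueError("rest triangle frame is degenerate (singular R)")
    return deformed.edge_matrix @ np.linalg.inv(rest.edge_matrix)


def growth_rate(F: np.ndarray) -> float:
    """Growth rate J = det(F): deformed/rest area ratio of the element."""
    return float(np.linalg.det(F))


def strain_tensor(F: np.ndarray) -> np.ndarray:
    """Green-Lagrange strain eps = (F^T F - I) / 2 (symmetric 2x2)."""
    return 0.5 * (F.T @ F - np.eye(2))


def anisotropy(F: np.ndarray, frame: TriangleFrame) -> tuple[float, np.ndarray]:
    """Anisotropy ratio and principal stretch direction of one element.

    Returns ``(theta, direction)`` where theta = sigma_max / sigma_min >= 1
    is the ratio of the principal stretches (singular values of F) and
    ``direction`` is the major right-singular vector lifted to 3D through
    the rest basis, sign-normalized so its largest component is positive.
    A singular F yields theta = inf.
    """
    U, s, Vt = np.linalg.svd(F)
    if s[-1] <= 0:
        theta = np.inf
    else:
        theta = float(s[0] / s[-1])
    v2d = Vt[0]  # right-singular vector of sigma_max, in rest-plane coords
    direction = v2d @ frame.basis
    nrm = np.linalg.norm(direction)
    if nrm > 0:
        direction = direction / nrm
        i = int(np.argmax(np.abs(direction)))
        if direction[i] < 0:
            direction = -direction
    return theta, direction


@dataclass
class DeformationMap:
    """Per-face deformation quantities between two states of one mesh.

    Values are attached to the deformed-state mesh; ``valid`` marks faces
    that are non-degenerate in both states.
    """

    F: np.ndarray  # (n_faces, 2, 2)
    J: np.ndarray  # (n_faces,)
    theta_aniso: np.ndarray  # (n_faces,)
    principal_direction: np.ndarray  # (n_faces, 3)
    J_smooth: np.ndarray
    theta_smooth: np.ndarray
    attached_mesh: SurfaceMesh
    interval: tuple = (0, 1)
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "face": np.arange(len(self.J)),
                "J": self.J,
                "theta": self.theta_aniso,
                "dir_x": self.principal_direction[:, 0],
                "dir_y": self.principal_direction[:, 1],
                "dir_z": self.principal_direction[:, 2],
                "J_smooth": self.J_smooth,
                "theta_smooth": self.theta_smooth,
                "valid": self.valid,
            }
        )


def deformation_map(
    rest_mesh: SurfaceMesh,
    deformed_mesh: SurfaceMesh,
    smoothing_radius: float = 20.0,
    interval: tuple = (0, 1),
) -> DeformationMap:
    """Per-face deformation between two same-topology meshes.

    ``smoothing_radius`` (same units as node coordinates) controls the
    geodesic neighbourhood over which J and theta are averaged (unweighted
    mean); 0 disables smoothing. Degenerate faces are excluded from the
    smoothed fields and marked invalid, never silently filled.
    """
    if rest_mesh.faces.shape != deformed_mesh.faces.shape or not np.array_equal(
        rest_mesh.faces, deformed_mesh.faces
    ):
        raise ValueError("rest and deformed meshes must share topology")
    nf = len(rest_mesh.faces)
    F = np.zeros((nf, 2, 2))
    J = np.full(nf, np.nan)
    theta = np.full(nf, np.nan)
    pdir = np.zeros((nf, 3))
    valid = np.zeros(nf, dtype=bool)
    rest_frames = triangle_frames(rest_mesh)
    def_frames = triangle_frames(deformed_mesh)
    for i in range(nf):
        rf, df = rest_frames[i], def_frames[i]
        if rf.degenerate or df.degenerate:
            continue
        Fi = deformation_gradient(rf, df)
        F[i] = Fi
        J[i] = growth_rate(Fi)
        theta[i], pdir[i] = anisotropy(Fi, rf)
        valid[i] = np.isfinite(theta[i])

    J_smooth = J.copy()
    theta_smooth = theta.copy()
    if smoothing_radius > 0:
        for i in range(nf):
            if not valid[i]:
                continue
            nb = geodesic_neighbourhood(deformed_mesh, i, smoothing_radius)
            nb = [j for j in nb if valid[j]]
            J_smooth[i] = float(np.mean(J[nb]))
            theta_smooth[i] = float(np.mean(theta[nb]))

    return DeformationMap(
        F=F,
        J=J,
        theta_aniso=theta,
        principal_direction=pdir,
        J_smooth=J_smooth,
        theta_smooth=theta_smooth,
        attached_mesh=deformed_mesh,
        interval=interval,
        valid=valid,
    )


def principal_axis(points: np.ndarray) -> np.ndarray:
    """Unit first principal axis of a point set (undirected)."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points to fit an axis")
    centered = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] == 0:
        raise ValueError("degenerate point set: all points coincide")
    return vt[0]


def cosine_similarity_axes(axis_a: np.ndarray, axis_b: np.ndarray) -> float:
    """|cos| similarity between two undirected axes (1 parallel, 0 orthogonal)."""
    a = np.asarray(axis_a, float)
    b = np.asarray(axis_b, float)
    return float(abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b)))


def fit_deformation_axis(point_set_rest, tset, span):
    """Principal axis of a point set after propagation across ``span``.

    Propagates the rest points from frame ``span[0]`` to ``span[1]``
    through ``tset``, fits a principal line to the displaced set and
    returns ``(axis, propagated_points)``. Combine with
    :func:`cosine_similarity_axes` to compare against e.g. a cell
    division axis (axes are undirected, so similarity uses |dot|).
    """
    from .registration import propagate_points

    a, b = span
    moved, _ = propagate_points(np.asarray(point_set_rest, float), tset, a, b)
    return principal_axis(moved), moved
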