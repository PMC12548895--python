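"""Per-triangle finite-deformation quantities: F, J, strain, anisotropy."""

import numpy as np
import pytest

from conftest import rotation_matrix
from morphomap.mechanics import (
    anisotropy,
    cosine_similarity_axes,
    deformation_gradient,
    deformation_map,
    fit_deformation_axis,
    growth_rate,
    principal_axis,
    strain_tensor,
    triangle_frame,
)
from morphomap.meshes import face_areas
from morphomap.synthetic import SceneParams, SyntheticScene

TRI = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])


class TestTriangleFrame:
    def test_unit_right_triangle_gives_identity_edge_matrix(self):
        fr = triangle_frame(TRI)
        assert np.allclose(fr.edge_matrix, np.eye(2), atol=1e-12)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(3, 3))
        fr = triangle_frame(v)
        edges3d = np.stack([v[1] - v[0], v[2] - v[0]], axis=1)
        assert np.allclose(fr.basis.T @ fr.edge_matrix, edges3d, atol=1e-9)

    def test_rigid_rotation_preserves_singular_values(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(3, 3))
        R = rotation_matrix("x", 33) @ rotation_matrix("z", 71)
        s0 = np.linalg.svd(triangle_frame(v).edge_matrix, compute_uv=False)
        s1 = np.linalg.svd(triangle_frame(v @ R.T).edge_matrix,
                           compute_uv=False)
        assert np.allclose(s0, s1, atol=1e-9)

    def test_collinear_vertices_flagged_degenerate(self):
        fr = triangle_frame(np.array([[0.0, 0, 0], [1, 1, 1], [2, 2, 2]]))
        assert fr.degenerate


class TestDeformationGradient:
    def test_identity(self):
        fr = triangle_frame(TRI)
        assert np.allclose(deformation_gradient(fr, fr), np.eye(2))

    def test_uniform_double_scale(self):
        F = deformation_gradient(triangle_frame(TRI),
                                 triangle_frame(2 * TRI))
        assert np.allclose(F, 2 * np.eye(2), atol=1e-12)

    def test_defining_identity_F_R_equals_T(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a, b = rng.normal(size=(2, 3, 3))
            ra, rb = triangle_frame(a), triangle_frame(b)
            if ra.degenerate or rb.degenerate:
                continue
            F = deformation_gradient(ra, rb)
            assert np.allclose(F @ ra.edge_matrix, rb.edge_matrix, atol=1e-9)

    def test_degenerate_rest_raises(self):
        bad = triangle_frame(np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]]))
        with pytest.raises(ValueError):
            deformation_gradient(bad, triangle_frame(TRI))


class TestGrowthRateAndStrain:
    def test_in_plane_rotation_is_isochoric(self):
        R2 = rotation_matrix("z", 37)
        F = deformation_gradient(triangle_frame(TRI),
                                 triangle_frame(TRI @ R2.T))
        assert growth_rate(F) == pytest.approx(1.0, abs=1e-12)

    def test_double_scale_quadruples_area(self):
        assert growth_rate(2 * np.eye(2)) == pytest.approx(4.0)

    def test_compression(self):
        assert growth_rate(np.diag([0.5, 1.0])) == pytest.approx(0.5)

    def test_strain_identity_zero(self):
        assert np.allclose(strain_tensor(np.eye(2)), 0.0)

    def test_strain_diagonal_stretch(self):
        eps = strain_tensor(np.diag([2.0, 1.0]))
        assert np.allclose(eps, np.diag([1.5, 0.0]))

    def test_strain_symmetric(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            F = rng.normal(size=(2, 2))
            eps = strain_tensor(F)
            assert np.allclose(eps, eps.T, atol=1e-12)


class TestAnisotropy:
    def test_uniform_scaling_is_isotropic(self):
        fr = triangle_frame(TRI)
        for s in (0.3, 1.0, 1.7, 4.0):
            theta, _ = anisotropy(s * np.eye(2), fr)
            assert theta == pytest.approx(1.0, abs=1e-12)

    def test_pure_rotation_is_isotropic(self):
        fr = triangle_frame(TRI)
        c, s = np.cos(0.7), np.sin(0.7)
        theta, _ = anisotropy(np.array([[c, -s], [s, c]]), fr)
        assert theta == pytest.approx(1.0, abs=1e-12)

    def test_diagonal_stretch_ratio_and_direction(self):
        fr = triangle_frame(TRI)
        theta, direction = anisotropy(np.diag([2.0, 1.0]), fr)
        assert theta == pytest.approx(2.0)
        # stretch along the first in-plane basis vector (= x here)
        assert abs(direction @ np.array([1.0, 0, 0])) == pytest.approx(1.0)

    def test_singular_F_flagged_infinite(self):
        theta, _ = anisotropy(np.diag([1.0, 0.0]), triangle_frame(TRI))
        assert np.isinf(theta)


def _tube_mesh(t=0.3, nu=17, nv=13):
    scene = SyntheticScene(SceneParams(nu=nu, nv=nv), seed=0)
    return scene, scene.mesh_at(t)


class TestDeformationMap:
    def test_identity_deformation(self):
        _, mesh = _tube_mesh()
        dm = deformation_map(mesh, mesh, smoothing_radius=0.0)
        assert np.allclose(dm.J[dm.valid], 1.0, atol=1e-9)
        assert np.allclose(dm.theta_aniso[dm.valid], 1.0, atol=1e-9)

    def test_global_affine_matches_analytic_area_scale(self):
        _, mesh = _tube_mesh()
        A = np.diag([1.3, 1.3, 1.3])  # uniform: in-plane area scale 1.69
        deformed = mesh.copy_with_nodes(mesh.nodes @ A.T)
        dm = deformation_map(mesh, deformed, smoothing_radius=6.0)
        assert np.allclose(dm.J[dm.valid], 1.69, atol=1e-9)
        # a uniform field is untouched by smoothing
        assert np.allclose(dm.J_smooth[dm.valid], 1.69, atol=1e-9)

    def test_J_equals_face_area_ratio(self):
        scene, mesh = _tube_mesh()
        deformed = mesh.copy_with_nodes(scene.mesh_at(0.8).nodes)
        dm = deformation_map(mesh, deformed, smoothing_radius=0.0)
        ratio = face_areas(deformed) / face_areas(mesh)
        assert np.allclose(dm.J[dm.valid], ratio[dm.valid], atol=1e-9)

    def test_rigid_motion_invariance(self):
        scene, rest = _tube_mesh()
        deformed = rest.copy_with_nodes(
            SyntheticScene(SceneParams(nu=17, nv=13), seed=0)
            .mesh_at(0.9).nodes
        )
        dm0 = deformation_map(rest, deformed, smoothing_radius=0.0)
        R = rotation_matrix("y", 25) @ rotation_matrix("x", 63)
        t = np.array([5.0, -2.0, 11.0])
        dm1 = deformation_map(
            rest.copy_with_nodes(rest.nodes @ R.T + t),
            deformed.copy_with_nodes(deformed.nodes @ R.T + t),
            smoothing_radius=0.0,
        )
        assert np.allclose(dm0.J, dm1.J, atol=1e-9, equal_nan=True)
        assert np.allclose(dm0.theta_aniso, dm1.theta_aniso, atol=1e-9,
                           equal_nan=True)

    def test_composition_of_affines_multiplies_J(self):
        _, mesh = _tube_mesh()
        A = np.diag([1.2, 0.9, 1.1])
        B = np.diag([0.8, 1.4, 1.0]) @ rotation_matrix("z", 15)
        mA = mesh.copy_with_nodes(mesh.nodes @ A.T)
        mAB = mesh.copy_with_nodes(mA.nodes @ B.T)
        J_A = deformation_map(mesh, mA, 0.0).J
        J_B = deformation_map(mA, mAB, 0.0).J
        J_AB = deformation_map(mesh, mAB, 0.0).J
        ok = np.isfinite(J_AB)
        assert np.allclose(J_AB[ok], (J_A * J_B)[ok], atol=1e-9)

    def test_spike_smoothing_pulls_toward_neighbourhood_mean(self):
        _, mesh = _tube_mesh()
        deformed = mesh.copy_with_nodes(mesh.nodes.copy())
        # dilate one face's nodes slightly: local J spike
        f = mesh.faces[100]
        centroid = deformed.nodes[f].mean(0)
        deformed.nodes[f] = centroid + 1.5 * (deformed.nodes[f] - centroid)
        dm = deformation_map(mesh, deformed, smoothing_radius=10.0)
        assert dm.J[100] > 1.5
        assert dm.J_smooth[100] < dm.J[100]
        assert dm.J_smooth[100] > 0.99

    def test_refinement_halves_analytic_J_error(self):
        t0, t1 = 0.2, 0.7
        errs = []
        for nu, nv in ((13, 9), (25, 17)):
            scene = SyntheticScene(SceneParams(nu=nu, nv=nv), seed=0)
            rest, deformed = scene.mesh_at(t0), scene.mesh_at(t1)
            dm = deformation_map(rest, deformed, smoothing_radius=0.0)
            uv, faces = scene.grid_uv()
            cen = uv[faces].mean(axis=1)
            J_true = scene.analytic_J(cen[:, 0], cen[:, 1], t0, t1)
            errs.append(np.nanmean(np.abs(dm.J - J_true) / J_true))
        assert errs[1] < errs[0] / 2.0

    def test_topology_mismatch_raises(self):
        _, mesh = _tube_mesh()
        other = _tube_mesh(nu=15, nv=13)[1]
        with pytest.raises(ValueError):
            deformation_map(mesh, other)


class TestDeformationAxis:
    def test_axis_similarity_extremes(self):
        assert cosine_similarity_axes([1, 0, 0], [-1, 0, 0]) == 1.0
        assert cosine_similarity_axes([1, 0, 0], [0, 1, 0]) == 0.0

    def test_recovers_stretch_axis_from_flow(self):
        from conftest import linear_field
        from morphomap.registration import TransformSet

        shape = (40, 40, 40)
        # anisotropic stretch along x about the volume center
        A = np.diag([0.3, 0.0, 0.0])
        b = -np.asarray(A) @ np.full(3, 20.0)
        fld = linear_field(shape, A, b)
        tset = TransformSet(anchor=0, forward=[fld], backward=[],
                            n_frames=2, voxel_size=1.0)
        rng = np.random.default_rng(4)
        pts = rng.uniform(12, 28, size=(40, 3))
        axis, _ = fit_deformation_axis(pts, tset, (0, 1))
        # displacement field is x-aligned; the displaced cloud's principal
        # axis must align with x far better than an isotropic cloud would
        moved = pts + (pts @ A.T + b)
        true_axis = principal_axis(moved)
        assert cosine_similarity_axes(axis, true_axis) > 0.95

    def test_degenerate_point_set_raises(self):
        with pytest.raises(ValueError):
            principal_axis(np.zeros((5, 3)))
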