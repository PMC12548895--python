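"""Correspondence chains, cumulative deformation products, Dynamic Atlas
and zone-growth validation."""

import numpy as np
import pytest

from morphomap.fatemap import (
    HookPair,
    ZoneDefinition,
    build_chain,
    build_fate_map,
    compare_growth_profiles,
    cumulative_deformation,
    make_axial_zones,
    mean_stepwise_deformation,
    track_pseudo_cells,
    zone_growth_profiles,
)
from morphomap.mapping import SurfaceMap
from morphomap.mechanics import deformation_map
from morphomap.meshes import face_areas
from morphomap.pointset import CorrespondenceMap
from morphomap.synthetic import SceneParams, SyntheticScene


def as_smap(mesh, stage=""):
    """Wrap a mesh already in atlas space as a SurfaceMap."""
    n = mesh.n_faces
    return SurfaceMap(
        mesh=mesh,
        correspondence=CorrespondenceMap(pairs=np.arange(n),
                                         distances=np.zeros(n)),
        stage=stage,
    )


@pytest.fixture(scope="module")
def flow():
    """Analytic hooks: one scene sampled at 4 stages; hook SurfaceMaps are
    the exact atlas-space meshes (isolates chain logic from projection)."""
    scene = SyntheticScene(SceneParams(), seed=21)
    times = np.linspace(0, 1, 4)
    meshes = [scene.mesh_at(t) for t in times]
    # hooks at a different sampling density than the eye
    dense = SyntheticScene(SceneParams(nu=45, nv=33), seed=21)
    hook_meshes = [dense.mesh_at(t) for t in times]
    hooks = [
        HookPair(specimen_id=f"h{g}", transition=g,
                 smap_a=as_smap(hook_meshes[g]),
                 smap_b=as_smap(hook_meshes[g + 1]))
        for g in range(3)
    ]
    return scene, times, meshes, hooks


class TestBuildChain:
    def test_identity_motion_constant_positions(self, flow):
        scene, times, meshes, _ = flow
        eye = as_smap(meshes[0])
        static = [
            HookPair(specimen_id=f"s{g}", transition=g,
                     smap_a=as_smap(meshes[0]), smap_b=as_smap(meshes[0]))
            for g in range(3)
        ]
        chain = build_chain(eye, static, eye_stage=0)
        for g in range(4):
            assert np.allclose(chain.positions[g], eye.mesh.nodes,
                               atol=1e-9)

    def test_global_flow_chained_within_tolerance(self, flow):
        scene, times, meshes, hooks = flow
        eye = as_smap(meshes[0])
        chain = build_chain(eye, hooks, eye_stage=0)
        uv, _ = scene.grid_uv()
        for g in range(4):
            true = scene.surface(uv[:, 0], uv[:, 1], times[g])
            err = np.linalg.norm(chain.positions[g] - true, axis=1)
            assert np.median(err) < 2.0  # within 2 um (2 voxels)

    def test_uncovered_transition_truncates_with_report(self, flow):
        scene, times, meshes, hooks = flow
        eye = as_smap(meshes[0])
        chain = build_chain(eye, [hooks[0], hooks[2]], eye_stage=0)
        assert 2 not in chain.positions
        assert 3 not in chain.positions
        assert chain.truncated

    def test_invalid_mode_rejected(self, flow):
        _, _, meshes, hooks = flow
        with pytest.raises(ValueError):
            build_chain(as_smap(meshes[0]), hooks, mode="median")


class TestMeanStepwise:
    def _setup(self, flow, J_values):
        scene, times, meshes, _ = flow
        eye = as_smap(meshes[1])
        chain = build_chain(eye, [], eye_stage=1)
        chain.positions[1] = meshes[1].nodes
        return chain

    def test_single_embryo_mean_is_its_value(self, flow):
        scene, times, meshes, hooks = flow
        eye = as_smap(meshes[0])
        chain = build_chain(eye, hooks, eye_stage=0)
        dm = deformation_map(meshes[0], meshes[1], smoothing_radius=0.0)
        J, T, cnt = mean_stepwise_deformation(
            chain, 0, [(dm, as_smap(meshes[1]))], use_smoothed=False)
        # reference points = eye nodes; each samples its nearest face
        assert np.all(cnt == 1)
        assert np.isfinite(J).all()
        assert np.all(J > 0)

    def test_two_embryos_arithmetic_mean(self, flow):
        scene, times, meshes, hooks = flow
        eye = as_smap(meshes[0])
        chain = build_chain(eye, hooks, eye_stage=0)
        dm = deformation_map(meshes[0], meshes[1], smoothing_radius=0.0)
        dm_a = deformation_map(meshes[0], meshes[1], smoothing_radius=0.0)
        dm_a.J = np.full_like(dm.J, 1.1)
        dm_b = deformation_map(meshes[0], meshes[1], smoothing_radius=0.0)
        dm_b.J = np.full_like(dm.J, 1.3)
        J, _, cnt = mean_stepwise_deformation(
            chain, 0, [(dm_a, as_smap(meshes[1])),
                       (dm_b, as_smap(meshes[1]))], use_smoothed=False)
        assert np.allclose(J, 1.2)
        assert np.all(cnt == 2)

    def test_contributor_order_invariant(self, flow):
        scene, times, meshes, hooks = flow
        eye = as_smap(meshes[0])
        chain = build_chain(eye, hooks, eye_stage=0)
        dms = [deformation_map(meshes[0], meshes[1], smoothing_radius=0.0)
               for _ in range(3)]
        for k, d in enumerate(dms):
            d.J = d.J * (1 + 0.1 * k)
        pairs = [(d, as_smap(meshes[1])) for d in dms]
        J_fwd, _, _ = mean_stepwise_deformation(chain, 0, pairs,
                                                use_smoothed=False)
        J_rev, _, _ = mean_stepwise_deformation(chain, 0, pairs[::-1],
                                                use_smoothed=False)
        assert np.allclose(J_fwd, J_rev)


class TestCumulative:
    def _steps(self, values, n=50):
        return {
            g: (np.full(n, v), np.full(n, v), np.full(n, 1))
            for g, v in enumerate(values)
        }

    def test_identity_steps_give_one(self):
        cum = cumulative_deformation(self._steps([1.0, 1.0, 1.0]))
        assert np.allclose(cum.J_bar, 1.0)

    def test_two_step_product(self):
        cum = cumulative_deformation(self._steps([1.1, 1.2]))
        assert np.allclose(cum.J_bar, 1.32)

    def test_associative_over_interval_split(self):
        rng = np.random.default_rng(0)
        vals = {g: (rng.uniform(0.8, 1.3, 30), rng.uniform(1, 2, 30),
                    np.ones(30, int)) for g in range(5)}
        full = cumulative_deformation(vals, interval=(0, 4))
        left = cumulative_deformation(vals, interval=(0, 2))
        right = cumulative_deformation(vals, interval=(3, 4))
        assert np.allclose(full.J_bar, left.J_bar * right.J_bar, atol=1e-12)
        assert np.allclose(full.theta_bar, left.theta_bar * right.theta_bar,
                           atol=1e-12)

    def test_gap_in_coverage_rejected(self):
        steps = self._steps([1.1, 1.2, 1.3])
        del steps[1]
        with pytest.raises(ValueError, match="gap"):
            cumulative_deformation(steps, interval=(0, 2))

    def test_uncovered_point_excluded(self):
        steps = self._steps([1.1, 1.2])
        steps[1][0][7] = np.nan
        cum = cumulative_deformation(steps)
        assert not cum.covered[7]
        assert cum.covered.sum() == 49


class TestFateMap:
    def test_single_specimen_reproduces_own_motion(self, flow):
        scene, times, meshes, hooks = flow
        eye = as_smap(meshes[0])
        # path through ONE dense specimen's own motion
        fmap = build_fate_map(eye, meshes[0].faces, hooks, eye_stage=0)
        uv, _ = scene.grid_uv()
        for g in range(4):
            true = scene.surface(uv[:, 0], uv[:, 1], times[g])
            err = np.linalg.norm(fmap.positions[g] - true, axis=1)
            assert np.median(err) < 2.0

    def test_wrong_stage_hook_reported_as_discontinuity(self, flow):
        scene, times, meshes, hooks = flow
        eye = as_smap(meshes[0])
        bad = HookPair(specimen_id="bad", transition=1,
                       smap_a=as_smap(meshes[1]),
                       # wrong stage: jumps to a far translated copy
                       smap_b=as_smap(meshes[2].copy_with_nodes(
                           meshes[2].nodes + 300.0)))
        with pytest.raises(ValueError, match="discontinuity"):
            build_fate_map(eye, meshes[0].faces, [hooks[0], bad, hooks[2]],
                           eye_stage=0)

    def test_duplicate_transition_rejected(self, flow):
        _, _, meshes, hooks = flow
        with pytest.raises(ValueError, match="twice"):
            build_fate_map(as_smap(meshes[0]), meshes[0].faces,
                           [hooks[0], hooks[0]], eye_stage=0)


class TestTrackPseudoCells:
    @pytest.fixture
    def fmap(self, flow):
        scene, times, meshes, hooks = flow
        return build_fate_map(as_smap(meshes[0]), meshes[0].faces, hooks,
                              eye_stage=0)

    def test_same_stage_returns_snapped_positions(self, fmap):
        seeds = fmap.positions[0][:5] + 0.01
        traj, ids, rejected = track_pseudo_cells(fmap, seeds, 0, 0)
        assert traj.shape == (5, 1, 3)
        assert not rejected
        assert np.allclose(traj[:, 0], fmap.positions[0][ids], atol=1e-9)

    def test_stationary_atlas_constant_trajectories(self, flow):
        scene, times, meshes, _ = flow
        static_hooks = [
            HookPair(specimen_id=f"s{g}", transition=g,
                     smap_a=as_smap(meshes[0]), smap_b=as_smap(meshes[0]))
            for g in range(3)
        ]
        fmap = build_fate_map(as_smap(meshes[0]), meshes[0].faces,
                              static_hooks, eye_stage=0)
        traj, _, _ = track_pseudo_cells(fmap, fmap.positions[0][:8], 0, 3)
        assert np.allclose(traj - traj[:, :1], 0.0, atol=1e-9)

    def test_far_seed_rejected_with_distance(self, fmap):
        far = fmap.positions[0][:1] + 500.0
        traj, ids, rejected = track_pseudo_cells(fmap, far, 0, 3)
        assert len(traj) == 0
        assert rejected[0] > 400

    def test_backward_tracking(self, fmap):
        seeds = fmap.positions[3][:5]
        traj, ids, _ = track_pseudo_cells(fmap, seeds, 3, 0)
        assert traj.shape[1] == 4
        assert np.allclose(traj[:, 0], fmap.positions[3][ids], atol=1e-9)


class TestZoneGrowth:
    @pytest.fixture
    def shapes(self, flow):
        scene, times, meshes, _ = flow
        return {g: meshes[g] for g in range(4)}

    def test_static_shapes_flat_profiles(self, flow):
        scene, times, meshes, _ = flow
        shapes = {g: meshes[0] for g in range(4)}
        zones = make_axial_zones(meshes[0], 10)
        prof = zone_growth_profiles(shapes, zones)
        assert np.allclose(prof.raw, prof.raw[:, :1])
        assert np.allclose(prof.smoothed, prof.raw, atol=1e-6)

    def test_uniform_growth_geometric_profiles(self, flow):
        scene, times, meshes, _ = flow
        base = meshes[0]
        shapes = {g: base.copy_with_nodes(base.nodes * 1.1 ** (g / 2))
                  for g in range(4)}  # area ratio 1.1 per stage
        zones = make_axial_zones(base, 5)
        prof = zone_growth_profiles(shapes, zones)
        ratios = prof.raw[:, 1:] / prof.raw[:, :-1]
        assert np.allclose(ratios, 1.1, rtol=1e-6)

    def test_single_zone_is_total_area(self, shapes, flow):
        scene, times, meshes, _ = flow
        zones = ZoneDefinition(labels=np.zeros(meshes[0].n_faces, int))
        prof = zone_growth_profiles(shapes, zones)
        for g in range(4):
            assert prof.raw[0, g] == pytest.approx(
                face_areas(meshes[g]).sum())

    def test_zone_count_mismatch_rejected(self, shapes, flow):
        scene, times, meshes, _ = flow
        zones = ZoneDefinition(labels=np.zeros(10, int))
        with pytest.raises(ValueError):
            zone_growth_profiles(shapes, zones)


class TestCompareProfiles:
    def _profile(self, values):
        from morphomap.fatemap import GrowthProfile

        vals = np.asarray(values, float)
        return GrowthProfile(zones=list(range(len(vals))),
                             stages=[0, 1], raw=np.column_stack([vals, vals]),
                             smoothed=np.column_stack([vals, vals]))

    def test_identical_profiles_full_match(self):
        p = self._profile(np.arange(10.0))
        per_stage, overall = compare_growth_profiles(p, p)
        assert overall == 100.0

    def test_reversed_order_no_match(self):
        a = self._profile(np.arange(10.0))
        b = self._profile(np.arange(10.0)[::-1])
        _, overall = compare_growth_profiles(a, b, rank_tolerance=0)
        assert overall == 0.0

    def test_excluding_noisy_zone_improves_match(self):
        vals = np.arange(10.0)
        noisy = vals.copy()
        noisy[3] = 20.0  # one scrambled zone
        a = self._profile(vals)
        b = self._profile(noisy)
        _, with_noise = compare_growth_profiles(a, b, rank_tolerance=0)
        _, without = compare_growth_profiles(a, b, exclude=(3,),
                                             rank_tolerance=0)
        assert without >= with_noise
        assert without == 100.0

    def test_mismatched_zones_rejected(self):
        a = self._profile(np.arange(10.0))
        b = self._profile(np.arange(8.0))
        with pytest.raises(ValueError):
            compare_growth_profiles(a, b)
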