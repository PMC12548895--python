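"""Shared fixtures: synthetic scenes, estimated motion, and the cohort
integration harness. Heavy computations are session-scoped so the whole
suite pays for them once."""

from __future__ import annotations

import numpy as np
import pytest

from morphomap.imaging import preprocess
from morphomap.registration import (
    RegistrationParams,
    TransformField,
    TransformSet,
    register_sequence,
    _n_control,
)
from morphomap.synthetic import (
    SceneParams,
    SyntheticScene,
    make_cohort,
    make_synthetic_atlas,
    render_stack,
)

SEED = 1
#: synthetic cell diameter (um): 2 x SceneParams.cell_radius
CELL_DIAMETER = 6.0


def rotation_matrix(axis: str, degrees: float) -> np.ndarray:
    c, s = np.cos(np.radians(degrees)), np.sin(np.radians(degrees))
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], float)
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], float)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], float)


def constant_field(shape, displacement, spacing=4, direction=(0, 1),
                   voxel_size=1.0) -> TransformField:
    """FFD field with a spatially constant displacement (exact, by the
    partition of unity of the cubic B-spline basis)."""
    n_ctl = tuple(_n_control(s, spacing) for s in shape)
    control = np.zeros((3,) + n_ctl)
    for d in range(3):
        control[d] += displacement[d]
    return TransformField(control=control, spacing=spacing, domain=shape,
                          direction=direction, voxel_size=voxel_size)


def linear_field(shape, A, b, spacing=4, direction=(0, 1),
                 voxel_size=1.0) -> TransformField:
    """FFD field realizing the affine displacement u(x) = A x + b exactly
    (cubic B-splines reproduce linear functions)."""
    n_ctl = tuple(_n_control(s, spacing) for s in shape)
    grids = np.meshgrid(
        *[(np.arange(n) - 1.0) * spacing for n in n_ctl], indexing="ij"
    )
    pos = np.stack([g.ravel() for g in grids], axis=1)
    disp = pos @ np.asarray(A, float).T + np.asarray(b, float)
    control = disp.T.reshape((3,) + n_ctl)
    return TransformField(control=control, spacing=spacing, domain=shape,
                          direction=direction, voxel_size=voxel_size)


def constant_flow_tset(shape, n_frames, step, anchor=None, voxel_size=1.0
                       ) -> TransformSet:
    """TransformSet whose every step displaces points by ``step`` (um/frame
    toward later frames)."""
    step = np.asarray(step, float) / voxel_size
    anchor = n_frames // 2 if anchor is None else anchor
    fwd = [
        constant_field(shape, step, direction=(i, i + 1),
                       voxel_size=voxel_size)
        for i in range(anchor, n_frames - 1)
    ]
    bwd = [
        constant_field(shape, -step, direction=(i, i - 1),
                       voxel_size=voxel_size)
        for i in range(anchor, 0, -1)
    ]
    return TransformSet(anchor=anchor, forward=fwd, backward=bwd,
                        n_frames=n_frames, voxel_size=voxel_size)


@pytest.fixture(scope="session")
def scene():
    return SyntheticScene(SceneParams(), seed=SEED)


@pytest.fixture(scope="session")
def rendered(scene):
    """(preprocessed stack, tracks) of the default rendered scene."""
    stack, tracks = render_stack(scene)
    return preprocess(stack, sigma=0.5), tracks


@pytest.fixture(scope="session")
def registration_params():
    # lattice spacing = half the synthetic cell diameter, the same rule
    # the full-scale pipeline uses for cardiomyocytes
    return RegistrationParams(grid_spacing=CELL_DIAMETER / 2, levels=4,
                              max_iter=60)


@pytest.fixture(scope="session")
def estimated_tsets(rendered, registration_params):
    """Bidirectional and frame-0-anchored transform sets of the rendered
    scene (the expensive motion-estimation fixture)."""
    stack, _ = rendered
    bidi = register_sequence(stack, registration_params, bidirectional=True)
    uni = register_sequence(stack, registration_params, bidirectional=False)
    return bidi, uni


# ---------------------------------------------------------------------------
# cohort integration harness (staging -> mapping -> chain -> cumulative)


def run_integration(seed: int = SEED, n_stages: int = 8, n_specimens: int = 6):
    """Re-integrate a fragmented synthetic cohort and compare with the
    unfragmented flow. Returns a dict of intermediate and final results."""
    from morphomap.fatemap import (
        HookPair,
        build_chain,
        build_fate_map,
        cumulative_deformation,
        mean_stepwise_deformation,
        track_pseudo_cells,
    )
    from morphomap.mapping import project_to_atlas
    from morphomap.mechanics import deformation_map
    from morphomap.staging import (
        compute_features,
        fit_staging_model,
        stage_sequence,
    )

    atlas_shapes, calibration, stage_times = make_synthetic_atlas(
        n_stages=n_stages, seed=seed
    )
    cohort = make_cohort(n_specimens=n_specimens, seed=seed, render=False,
                         n_stages=n_stages)
    model = fit_staging_model(calibration)
    base_scene = SyntheticScene(SceneParams(), seed=seed)

    staged = {}
    for sp in cohort.specimens:
        hw = [compute_features(lm).h_over_w for lm in sp.landmarks]
        assign = stage_sequence(hw, model)
        staged[sp.specimen_id] = {
            g: assign.representative[label]
            for g, label in enumerate(cohort.stage_labels)
            if label in assign.representative
        }

    smaps = {}
    for sp in cohort.specimens:
        for g, f in staged[sp.specimen_id].items():
            smaps[(sp.specimen_id, g)] = project_to_atlas(
                sp.live_shape.mesh_at(f), atlas_shapes[g],
                specimen_id=sp.specimen_id, source_frame=f,
            )

    dmaps = {}
    for sp in cohort.specimens:
        fr = staged[sp.specimen_id]
        for g in sorted(fr):
            if g + 1 in fr:
                dm = deformation_map(
                    sp.live_shape.mesh_at(fr[g]),
                    sp.live_shape.mesh_at(fr[g + 1]),
                    smoothing_radius=4.0, interval=(g, g + 1),
                )
                dmaps[(sp.specimen_id, g)] = dm

    mid = n_stages // 2 - 1
    eye_key = next(k for k in sorted(smaps) if k[1] == mid)
    eye = smaps[eye_key]
    eye_sp = next(s for s in cohort.specimens
                  if s.specimen_id == eye_key[0])
    hooks = [
        HookPair(specimen_id=sid, transition=g, smap_a=smaps[(sid, g)],
                 smap_b=smaps[(sid, g + 1)])
        for (sid, g) in dmaps
    ]
    chain = build_chain(eye, hooks, mode="average", eye_stage=eye_key[1])

    step_means = {}
    for g in range(n_stages - 1):
        maps_g = [(dmaps[k], smaps[(k[0], g + 1)]) for k in dmaps
                  if k[1] == g]
        if maps_g and (g + 1) in chain.positions:
            step_means[g] = mean_stepwise_deformation(chain, g, maps_g)
    trans = sorted(step_means)
    cum = cumulative_deformation(step_means, interval=(trans[0], trans[-1]))

    uv = eye_sp.node_uv
    J_true = base_scene.analytic_J(
        uv[:, 0], uv[:, 1], stage_times[trans[0]], stage_times[trans[-1] + 1]
    )

    path_hooks = []
    for g in trans:
        cands = sorted((h for h in hooks if h.transition == g),
                       key=lambda h: -h.smap_a.mesh.n_nodes)
        path_hooks.append(cands[0])
    fmap = build_fate_map(eye, eye.mesh.faces, path_hooks,
                          eye_stage=eye_key[1])
    a, b = min(fmap.stages()), max(fmap.stages())
    rng = np.random.default_rng(seed + 100)
    sel = rng.choice(len(fmap.positions[a]), 200, replace=False)
    traj, ids, rejected = track_pseudo_cells(fmap, fmap.positions[a][sel],
                                             a, b)
    end_true = base_scene.surface(uv[ids][:, 0], uv[ids][:, 1],
                                  stage_times[b])
    endpoint_err = np.linalg.norm(traj[:, -1] - end_true, axis=1)

    return {
        "cohort": cohort,
        "atlas_shapes": atlas_shapes,
        "stage_times": stage_times,
        "staged": staged,
        "smaps": smaps,
        "chain": chain,
        "cumulative": cum,
        "J_true": J_true,
        "fate_map": fmap,
        "endpoint_err": endpoint_err,
        "base_scene": base_scene,
        "eye_specimen": eye_sp,
    }


@pytest.fixture(scope="session")
def integration():
    return run_integration()
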