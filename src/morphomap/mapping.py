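"""Spatial mapping of staged Live-Shapes into the Atlas geometry.

A staged Live-Shape frame is projected into its Atlas group in four
steps:

1. the Atlas shape is rigidly (similarity) aligned onto the live mesh by
   Student's-t mixture registration;
2. Atlas nodes with no live counterpart (regions missing from the
   acquisition, typically the tube ends) are removed, giving the
   "AtlasCut";
3. both shapes are rasterized to thin shell masks on a shared voxel grid
   and a non-rigid B-spline registration of the live mask onto the
   AtlasCut mask recovers the field that morphs the live nodes into
   Atlas space — the morphed mesh is the "SurfaceMap" (it keeps the
   live mesh's exact topology, standardizing the geometry while
   preserving the specimen's own dynamics);
4. each Atlas face is matched to its nearest SurfaceMap face centroid.

The mapping is validated quantitatively by transferring the live mesh's
per-face area pattern through the correspondence onto the Atlas and rank
-correlating transferred and original patterns (the anatomical layout of
large and small faces should survive the projection).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .meshes import (
    SurfaceMesh,
    face_areas,
    face_centroids,
    mesh_to_shell_mask,
)
from .pointset import (
    CorrespondenceMap,
    TMMParams,
    cut_unmatched,
    default_cut_threshold,
    face_to_face_match,
    tmm_register,
)
from .registration import RegistrationParams, register_pair

__all__ = [
    "AtlasShape",
    "SurfaceMap",
    "project_to_atlas",
    "validate_mapping_by_area",
]

VALID_STAGES = tuple(f"Gr{i}" for i in range(1, 11))


@dataclass
class AtlasShape:
    """One staged reference shape of the static Atlas (Gr1..Gr10)."""

    mesh: SurfaceMesh
    stage: str
    landmarks: object | None = None
    reference_parameter: float | None = None  # the Atlas's d1/d2 value

    def __post_init__(self):
        if self.stage not in VALID_STAGES:
            raise ValueError(f"invalid stage label {self.stage!r}")


@dataclass
class SurfaceMap:
    """A Live-Shape frame morphed into Atlas space.

    ``mesh`` has exactly the node/face structure of the source live
    frame; ``correspondence`` maps every Atlas face to its nearest
    SurfaceMap face. ``provenance`` records all four pipeline stages.
    """

    mesh: SurfaceMesh
    correspondence: CorrespondenceMap  # atlas face -> surfacemap face
    specimen_id: str = ""
    source_frame: int | None = None
    stage: str = ""
    provenance: dict = field(default_factory=dict)


def project_to_atlas(
    live: SurfaceMesh,
    atlas: AtlasShape,
    reg_params: RegistrationParams | None = None,
    tmm_params: TMMParams | None = None,
    cut_threshold: float | None = None,
    mask_voxel: float = 2.0,
    specimen_id: str = "",
    source_frame: int | None = None,
) -> SurfaceMap:
    """Project a staged live mesh into its Atlas group's geometry.

    ``mask_voxel`` (um) sets the rasterization pitch of the mask-based
    non-rigid step; ``cut_threshold`` defaults to 3x the live mesh's
    median node spacing. Any stage failure propagates with a stage tag.
    Returns the :class:`SurfaceMap`.
    """
    reg_params = reg_params or RegistrationParams(
        grid_spacing=4.0 * mask_voxel, levels=3, max_iter=60
    )
    tmm_params = tmm_params or TMMParams()
    prov = {"atlas_stage": atlas.stage, "mask_voxel": mask_voxel}

    # 1) rigid: atlas -> live
    try:
        rigid, atlas_aligned_nodes, rmse = tmm_register(
            atlas.mesh.nodes, live.nodes, tmm_params
        )
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"[rigid] {e}") from e
    atlas_aligned = atlas.mesh.copy_with_nodes(atlas_aligned_nodes)
    prov["rigid"] = {
        "scale": rigid.scale,
        "rotation_deg": rigid.rotation_angle_deg(),
        "rmse_um": rmse,
    }

    # 2) AtlasCut
    try:
        thr = cut_threshold or default_cut_threshold(live)
        atlas_cut, cut_record = cut_unmatched(atlas_aligned, live, thr)
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"[atlascut] {e}") from e
    prov["atlascut"] = {
        "threshold_um": float(thr),
        "removed_nodes": int(cut_record["removed_nodes"].size),
    }

    # 3) non-rigid: live mask -> AtlasCut mask; field sends live
    #    coordinates into Atlas space and is applied to the live nodes
    try:
        all_nodes = np.vstack([live.nodes, atlas_cut.nodes])
        origin = all_nodes.min(axis=0) - 4 * mask_voxel
        shape = (
            np.ceil((all_nodes.max(axis=0) - origin) / mask_voxel).astype(int)
            + 5
        )
        live_mask = mesh_to_shell_mask(
            live, mask_voxel, origin=origin, shape=shape
        )
        atlas_mask = mesh_to_shell_mask(
            atlas_cut, mask_voxel, origin=origin, shape=shape
        )
        from scipy import ndimage

        ref_img = ndimage.gaussian_filter(live_mask.voxels.astype(float), 1.0)
        mov_img = ndimage.gaussian_filter(atlas_mask.voxels.astype(float), 1.0)
        ref_img /= max(ref_img.max(), 1e-12)
        mov_img /= max(mov_img.max(), 1e-12)
        fld, energy = register_pair(
            ref_img, mov_img, reg_params, voxel_size=mask_voxel
        )
        live_vox = (live.nodes - origin) / mask_voxel
        morphed_vox, flags = fld.evaluate(live_vox)
        morphed_nodes = morphed_vox * mask_voxel + origin
        # the morph ran in the live pose frame (the atlas was rigidly
        # brought to the live mesh); undo the rigid alignment so the
        # SurfaceMap sits in the Atlas's own coordinate frame
        morphed_nodes = rigid.inverse().apply(morphed_nodes)
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"[morph] {e}") from e
    prov["morph"] = {
        "energy": float(energy),
        "out_of_domain_nodes": int(flags.sum()),
    }
    smap_mesh = live.copy_with_nodes(morphed_nodes)
    smap_mesh.provenance["surfacemap"] = True

    # 4) face-to-face: atlas faces -> morphed live faces
    try:
        corr = face_to_face_match(atlas.mesh, smap_mesh)
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"[match] {e}") from e
    prov["match"] = {
        "mean_distance_um": float(corr.distances.mean()),
        "atlas_faces": int(atlas.mesh.n_faces),
    }
    return SurfaceMap(
        mesh=smap_mesh,
        correspondence=corr,
        specimen_id=specimen_id,
        source_frame=source_frame,
        stage=atlas.stage,
        provenance=prov,
    )


def validate_mapping_by_area(
    live: SurfaceMesh, surface_map: SurfaceMap, atlas: AtlasShape
):
    """Transfer the live mesh's face-area pattern onto the Atlas and score it.

    Every Atlas face receives the area of the live face its SurfaceMap
    correspondent came from; the Spearman rank correlation between the
    transferred pattern and the SurfaceMap's own local areas at the
    matched faces measures how well the anatomical area layout survives
    the projection (1 = perfectly preserved, ~0 = scrambled).
    Returns ``(transferred_areas, rank_correlation)``.
    """
    corr = surface_map.correspondence
    if len(corr.pairs) == 0:
        raise ValueError("empty correspondence")
    live_areas = face_areas(live)
    transferred = live_areas[corr.pairs]
    # reference: the local area pattern actually sitting at each atlas
    # face's location in atlas space (geometric nearest morphed face),
    # independent of the correspondence being scored
    geometric = face_to_face_match(atlas.mesh, surface_map.mesh)
    reference_pattern = face_areas(surface_map.mesh)[geometric.pairs]
    rho, _ = stats.spearmanr(transferred, reference_pattern)
    return transferred, float(rho)
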