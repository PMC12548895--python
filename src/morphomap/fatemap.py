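"""Cross-stage integration: correspondence chains, cumulative deformation
and the in-silico fate map ("Dynamic Atlas").

No single acquisition covers the whole developmental window, so
anatomical correspondences are chained across stages: a reference point
cloud (the "eye-PC", one specimen's SurfaceMap) is carried through each
stage transition by a "hook" specimen whose own motion profile links its
SurfaceMaps at the two stages. Per reference point i, stepwise growth
and anisotropy are averaged over the embryos covering a transition, and
the cumulative deformation over an interval of groups is the product of
the step means:

    Jbar(i)    = prod_gr  mean_embryos J(i)_gr
    thetabar(i) = prod_gr  mean_embryos theta(i)_gr

Products are taken only over steps with coverage; points lacking a
contributor at any step are excluded rather than imputed. Carrying one
reference cloud through a single, most complete path of specimens yields
the Dynamic Atlas, which supports pseudo-cell tracking (fate mapping)
and region-level growth-profile validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .mapping import SurfaceMap
from .mechanics import DeformationMap
from .meshes import SurfaceMesh, face_areas, face_centroids

__all__ = [
    "HookPair",
    "CorrespondenceChain",
    "CumulativeDeformation",
    "DynamicAtlas",
    "ZoneDefinition",
    "GrowthProfile",
    "build_chain",
    "mean_stepwise_deformation",
    "cumulative_deformation",
    "build_fate_map",
    "track_pseudo_cells",
    "zone_growth_profiles",
    "compare_growth_profiles",
    "make_axial_zones",
]


@dataclass
class HookPair:
    """One specimen's SurfaceMaps at the two ends of a stage transition.

    Both maps share the specimen's live topology, so node k's motion
    between them is the specimen's own tissue motion expressed in Atlas
    space.
    """

    specimen_id: str
    transition: int  # stage index g, covering g -> g+1
    smap_a: SurfaceMap  # at stage g
    smap_b: SurfaceMap  # at stage g+1

    def __post_init__(self):
        if self.smap_a.mesh.n_nodes != self.smap_b.mesh.n_nodes:
            raise ValueError("hook SurfaceMaps must share topology")


@dataclass
class CorrespondenceChain:
    reference_ids: np.ndarray  # indices into the eye-PC nodes
    positions: dict  # stage index -> (n_ref, 3) um
    contributors: dict  # transition -> list of specimen ids
    eye_stage: int
    truncated: list = field(default_factory=list)  # uncovered transitions

    def stages(self) -> list:
        return sorted(self.positions)


def _carry(points: np.ndarray, hooks: list, forward: bool,
           refine: str = "none") -> np.ndarray:
    """Carry points across one transition via the hooks' own motion.

    Each point inherits the displacement of its nearest hook node
    (position + node displacement, not the raw node position, so the
    local offset between point and node is preserved and the hook's
    point density does not quantize the result). Averaged over hooks.

    ``refine="tmm"`` removes any residual rigid offset between the hook
    and the carried cloud (Student's-t alignment of the hook onto the
    points, applied to both of the hook's SurfaceMaps) before matching;
    the default assumes both already share the Atlas frame.
    """
    out = np.zeros_like(points)
    for hook in hooks:
        src = hook.smap_a.mesh.nodes if forward else hook.smap_b.mesh.nodes
        dst = hook.smap_b.mesh.nodes if forward else hook.smap_a.mesh.nodes
        if refine == "tmm":
            from .pointset import TMMParams, tmm_register

            trans, src, _ = tmm_register(src, points, TMMParams(seed=0))
            dst = trans.apply(dst)
        _, idx = cKDTree(src).query(points, workers=-1)
        out += points + (dst[idx] - src[idx])
    return out / len(hooks)


def build_chain(eye: SurfaceMap, hooks: list, mode: str = "average",
                eye_stage: int | None = None,
                refine: str = "none") -> CorrespondenceChain:
    """Carry the eye-PC across stages through hook specimens.

    ``hooks`` is a list of :class:`HookPair`; transitions are walked
    outward from ``eye_stage`` (default: the stage of ``eye``).
    ``mode="average"`` uses every available hook per transition,
    ``mode="single_path"`` exactly one (the fate-map mode). A transition
    with no hook truncates the chain on that side (recorded, not
    interpolated).
    """
    if mode not in ("average", "single_path"):
        raise ValueError("mode must be 'average' or 'single_path'")
    by_transition: dict = {}
    for h in hooks:
        by_transition.setdefault(h.transition, []).append(h)
    if eye_stage is None:
        eye_stage = min(by_transition) if by_transition else 0
    positions = {eye_stage: np.asarray(eye.mesh.nodes, float)}
    contributors = {}
    truncated = []

    g = eye_stage
    while (g in by_transition):
        hs = by_transition[g]
        hs = hs[:1] if mode == "single_path" else hs
        positions[g + 1] = _carry(positions[g], hs, forward=True,
                                  refine=refine)
        contributors[g] = [h.specimen_id for h in hs]
        g += 1
    if any(t >= g for t in by_transition):
        truncated.append(g)  # later transitions exist beyond this gap

    g = eye_stage - 1
    while (g in by_transition):
        hs = by_transition[g]
        hs = hs[:1] if mode == "single_path" else hs
        positions[g] = _carry(positions[g + 1], hs, forward=False,
                              refine=refine)
        contributors[g] = contributors.get(g, []) + [
            h.specimen_id for h in hs
        ]
        g -= 1
    if any(t <= g for t in by_transition):
        truncated.append(g)

    return CorrespondenceChain(
        reference_ids=np.arange(len(eye.mesh.nodes)),
        positions=positions,
        contributors=contributors,
        eye_stage=eye_stage,
        truncated=truncated,
    )


def mean_stepwise_deformation(chain: CorrespondenceChain, transition: int,
                              per_embryo_maps: list,
                              use_smoothed: bool = True,
                              mean: str = "arithmetic"):
    """Per-reference-point mean stepwise (J, theta) over embryos.

    ``per_embryo_maps`` is a list of ``(DeformationMap, SurfaceMap)``
    pairs for the transition: the deformation computed on the embryo's
    native Live-Shape between its two staged frames, and its SurfaceMap
    at the end stage (whose mesh shares the live topology and places the
    values in Atlas space). Each reference point samples the value of
    the nearest SurfaceMap face. Returns ``(J_mean, theta_mean, count)``
    arrays over reference points.
    """
    if transition + 1 not in chain.positions:
        raise KeyError(f"chain has no positions at stage {transition + 1}")
    pts = chain.positions[transition + 1]
    n = len(pts)
    acc_J = np.zeros((0, n))
    acc_T = np.zeros((0, n))
    for dmap, smap in per_embryo_maps:
        if not isinstance(dmap, DeformationMap):
            raise TypeError("expected (DeformationMap, SurfaceMap) pairs")
        if len(dmap.J) != smap.mesh.n_faces:
            raise ValueError("deformation map and SurfaceMap disagree on "
                             "face count")
        cents = face_centroids(smap.mesh)
        _, idx = cKDTree(cents).query(pts, workers=-1)
        J = dmap.J_smooth if use_smoothed else dmap.J
        T = dmap.theta_smooth if use_smoothed else dmap.theta_aniso
        acc_J = np.vstack([acc_J, J[idx]])
        acc_T = np.vstack([acc_T, T[idx]])
    if acc_J.shape[0] == 0:
        return np.full(n, np.nan), np.full(n, np.nan), np.zeros(n, int)
    count = np.isfinite(acc_J).sum(axis=0)
    with np.errstate(invalid="ignore"):
        if mean == "arithmetic":
            J_mean = np.nanmean(acc_J, axis=0)
            T_mean = np.nanmean(acc_T, axis=0)
        elif mean == "geometric":
            J_mean = np.exp(np.nanmean(np.log(acc_J), axis=0))
            T_mean = np.exp(np.nanmean(np.log(acc_T), axis=0))
        else:
            raise ValueError("mean must be 'arithmetic' or 'geometric'")
    J_mean[count == 0] = np.nan
    T_mean[count == 0] = np.nan
    return J_mean, T_mean, count


@dataclass
class CumulativeDeformation:
    J_bar: np.ndarray  # per reference point; nan where coverage broke
    theta_bar: np.ndarray
    interval: tuple  # (first transition, last transition) inclusive
    contributors_per_step: dict

    @property
    def covered(self) -> np.ndarray:
        return np.isfinite(self.J_bar)


def cumulative_deformation(step_means: dict,
                           interval: tuple | None = None
                           ) -> CumulativeDeformation:
    """Product of step means over a contiguous transition interval.

    ``step_means`` maps transition index -> (J_mean, theta_mean, count)
    as returned by :func:`mean_stepwise_deformation`. A point with no
    contributor at any step of the interval gets nan (excluded, never
    imputed). Products are associative over interval splits.
    """
    if not step_means:
        raise ValueError("no step means supplied")
    trans = sorted(step_means)
    if interval is None:
        interval = (trans[0], trans[-1])
    a, b = interval
    need = list(range(a, b + 1))
    for g in need:
        if g not in step_means:
            raise ValueError(f"gap in coverage at transition {g}")
    n = len(step_means[need[0]][0])
    J = np.ones(n)
    T = np.ones(n)
    contributors = {}
    for g in need:
        Jg, Tg, cnt = step_means[g]
        J = J * Jg
        T = T * Tg
        contributors[g] = cnt
    return CumulativeDeformation(
        J_bar=J, theta_bar=T, interval=(a, b),
        contributors_per_step=contributors,
    )


@dataclass
class DynamicAtlas:
    """The static Atlas endowed with concatenated live-derived motion.

    One reference point cloud (a reference mesh's nodes) with positions
    at every covered stage; ``reference_faces`` keeps the triangulation
    so per-stage meshes and zone areas can be evaluated.
    """

    positions: dict  # stage index -> (n, 3)
    reference_faces: np.ndarray
    path: list  # ordered specimen ids, one per transition
    stage_labels: dict = field(default_factory=dict)

    def stages(self) -> list:
        return sorted(self.positions)

    def mesh_at(self, stage: int) -> SurfaceMesh:
        return SurfaceMesh(
            nodes=self.positions[stage], faces=self.reference_faces,
            provenance={"dynamic_atlas_stage": stage},
        )


def build_fate_map(eye: SurfaceMap, reference_faces: np.ndarray,
                   path_hooks: list, eye_stage: int,
                   max_jump_factor: float = 5.0,
                   stage_labels: dict | None = None) -> DynamicAtlas:
    """Carry one reference cloud through a single specimen path.

    ``path_hooks`` holds exactly one :class:`HookPair` per covered
    transition. Trajectory continuity is enforced: if any point's
    stage-to-stage jump exceeds ``max_jump_factor`` times the median
    jump (plus the median node spacing as an absolute floor), the build
    fails naming the offending transition — the symptom of hooking a
    wrong-stage SurfaceMap into the path.
    """
    seen = {}
    for h in path_hooks:
        if h.transition in seen:
            raise ValueError(
                f"transition {h.transition} appears twice in the path"
            )
        seen[h.transition] = h
    chain = build_chain(eye, path_hooks, mode="single_path",
                        eye_stage=eye_stage)
    d, _ = cKDTree(eye.mesh.nodes).query(eye.mesh.nodes, k=2, workers=-1)
    spacing = float(np.median(d[:, 1]))
    stages = chain.stages()
    for s0, s1 in zip(stages[:-1], stages[1:]):
        jump = np.linalg.norm(chain.positions[s1] - chain.positions[s0],
                              axis=1)
        med = float(np.median(jump))
        limit = max_jump_factor * med + spacing
        if jump.max() > limit:
            raise ValueError(
                f"discontinuity at transition {s0}->{s1}: max jump "
                f"{jump.max():.2f} um exceeds {limit:.2f} um"
            )
        # a wrong-stage hook also shows as a globally outsized step
        # relative to the mesh's own node spacing
        if med > max_jump_factor * spacing:
            raise ValueError(
                f"discontinuity at transition {s0}->{s1}: median jump "
                f"{med:.2f} um is far beyond the node spacing "
                f"({spacing:.2f} um)"
            )
    return DynamicAtlas(
        positions=chain.positions,
        reference_faces=np.asarray(reference_faces, int),
        path=[seen[g].specimen_id for g in sorted(seen)],
        stage_labels=stage_labels or {},
    )


def track_pseudo_cells(atlas: DynamicAtlas, seeds: np.ndarray, a: int, b: int,
                       snap_radius: float | None = None):
    """Follow seed points through the Dynamic Atlas from stage a to b.

    Each seed snaps to its nearest reference point at stage ``a``
    (within ``snap_radius``, default the median inter-node spacing);
    its trajectory is that point's positions over the stages between
    ``a`` and ``b`` (either direction). Returns ``(trajectories,
    point_ids, rejected)`` where ``trajectories`` is (n_seeds, n_stages,
    3) and ``rejected`` maps seed index -> snap distance for seeds
    farther than the radius.
    """
    if a not in atlas.positions or b not in atlas.positions:
        raise KeyError("stage outside the Dynamic Atlas coverage")
    cloud = atlas.positions[a]
    tree = cKDTree(cloud)
    d_nn, _ = tree.query(cloud, k=2, workers=-1)
    if snap_radius is None:
        snap_radius = float(np.median(d_nn[:, 1]))
    seeds = np.atleast_2d(np.asarray(seeds, float))
    d, idx = tree.query(seeds, workers=-1)
    rejected = {int(i): float(d[i]) for i in np.flatnonzero(d > snap_radius)}
    keep = d <= snap_radius
    stages = [s for s in atlas.stages() if min(a, b) <= s <= max(a, b)]
    if b < a:
        stages = stages[::-1]
    traj = np.stack(
        [atlas.positions[s][idx[keep]] for s in stages], axis=1
    )
    return traj, idx[keep], rejected


@dataclass
class ZoneDefinition:
    """Partition of the reference faces into labelled zones."""

    labels: np.ndarray  # per face: zone label (int or str)

    def zone_ids(self):
        return sorted(set(self.labels.tolist()))


def make_axial_zones(mesh: SurfaceMesh, n_zones: int = 10) -> ZoneDefinition:
    """Default zoning: equal-count bins of face centroids along the
    mesh's first principal axis."""
    cents = face_centroids(mesh)
    c = cents - cents.mean(0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    proj = c @ vt[0]
    qs = np.quantile(proj, np.linspace(0, 1, n_zones + 1)[1:-1])
    labels = np.digitize(proj, qs)
    return ZoneDefinition(labels=labels)


@dataclass
class GrowthProfile:
    zones: list
    stages: list
    raw: np.ndarray  # (n_zones, n_stages) summed face area
    smoothed: np.ndarray  # degree-3 B-spline smoothed across stages


def _spline3_smooth(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares degree-3 B-spline across stages, evaluated at x."""
    from scipy.interpolate import LSQUnivariateSpline

    n = len(x)
    if n < 5:
        deg = min(3, n - 1)
        return np.polyval(np.polyfit(x, y, deg), x)
    n_knots = max(0, (n - 4) // 2)
    t = np.quantile(x, np.linspace(0, 1, n_knots + 2)[1:-1]) if n_knots \
        else []
    spl = LSQUnivariateSpline(x, y, t, k=3)
    return spl(x)


def zone_growth_profiles(shapes: dict, zones: ZoneDefinition) -> GrowthProfile:
    """Per-zone summed face area per stage, spline-smoothed across stages.

    ``shapes`` maps stage index -> SurfaceMesh on the reference topology.
    """
    stages = sorted(shapes)
    zone_ids = zones.zone_ids()
    nf = len(zones.labels)
    raw = np.zeros((len(zone_ids), len(stages)))
    for j, s in enumerate(stages):
        mesh = shapes[s]
        if mesh.n_faces != nf:
            raise ValueError(
                f"stage {s} mesh has {mesh.n_faces} faces, zones defined "
                f"on {nf}"
            )
        areas = face_areas(mesh)
        for i, z in enumerate(zone_ids):
            raw[i, j] = areas[zones.labels == z].sum()
    x = np.asarray(stages, float)
    smoothed = np.vstack([_spline3_smooth(x, row) for row in raw])
    return GrowthProfile(zones=zone_ids, stages=stages, raw=raw,
                         smoothed=smoothed)


def compare_growth_profiles(profile_a: GrowthProfile,
                            profile_b: GrowthProfile,
                            exclude=(), rank_tolerance: int = 1):
    """Sorted-rank agreement between two growth profiles.

    Per stage, zones are ranked by smoothed growth value in each
    profile; the per-stage agreement is the fraction of zones whose
    ranks agree within ``rank_tolerance``; the overall match is the mean
    across stages. ``exclude`` removes named zones (e.g. noisy border
    zones) before ranking. Returns ``(per_stage, overall)``.
    """
    if profile_a.zones != profile_b.zones or profile_a.stages != profile_b.stages:
        raise ValueError("profiles must share zones and stages")
    keep = [i for i, z in enumerate(profile_a.zones) if z not in set(exclude)]
    if not keep:
        raise ValueError("all zones excluded")
    A = profile_a.smoothed[keep]
    B = profile_b.smoothed[keep]
    per_stage = []
    for j in range(A.shape[1]):
        ra = np.argsort(np.argsort(A[:, j]))
        rb = np.argsort(np.argsort(B[:, j]))
        per_stage.append(float(np.mean(np.abs(ra - rb) <= rank_tolerance)))
    return np.asarray(per_stage) * 100.0, float(np.mean(per_stage) * 100.0)
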