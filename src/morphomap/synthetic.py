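"""Synthetic ground-truth scenes for end-to-end pipeline validation.

The generator emulates the data regime of fragmented live imaging of a
thin curved epithelium shaping into a tube: a parametric surface family
S(u, v, t) (a crescent-like open cylinder sheet that elongates, thickens
radially and closes circumferentially into a near-tube), imaged as a
membrane-intensity shell with bright blob "cells" advected by the flow,
plus Gaussian noise and exponential bleaching. Because every material
point is identified by its fixed (u, v) parameter, the flow map between
any two times, per-face area ratios (J) and principal stretch ratios
(theta) are available in closed form:

    S(u, v, t) = c + [ (u - 1/2) L(t),  r(u,t) sin a,  -r(u,t) cos a ]
    a = (v - 1/2) phi(t)
    L(t) = L0 (1 + eL t)                     axial elongation
    r(u, t) = r0 (1 + er t)(1 + b t sin(pi u))   radial growth + mid bulge
    phi(t) = phi0 + (phi1 - phi0) t          circumferential closing

S_u and S_v are orthogonal, so the principal stretches between t0 and t1
at (u, v) are exactly lam_u = |S_u|(t1)/|S_u|(t0) and
lam_v = (r phi)(t1)/(r phi)(t0), giving J = lam_u lam_v and
theta = max/min ratio.

Cohorts fragment the timeline into overlapping per-specimen windows with
random rigid poses, small shape perturbations and cut tube ends
(emulating the routinely missing inflow/outflow tracts), which is the
master fixture for the spatiotemporal integration strategy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .imaging import Hyperstack
from .meshes import LiveShapeSequence, SurfaceMesh
from .staging import LANDMARK_NAMES, LandmarkSet

__all__ = [
    "SceneParams",
    "SyntheticScene",
    "TrackSet",
    "make_scene",
    "render_stack",
    "make_synthetic_atlas",
    "make_cohort",
    "Specimen",
    "Cohort",
]

#: (u, v) surface anchors of the seven landmarks
LANDMARK_UV = {
    "pt1": (0.5, 0.0),
    "pt2": (0.5, 1.0),
    "pt3": (0.2, 0.5),
    "pt4": (0.8, 0.5),
    "pt5": (0.35, 0.0),
    "pt6": (0.35, 1.0),
    "pt7": (0.65, 0.5),
}


@dataclass
class SceneParams:
    # geometry (um)
    L0: float = 32.0
    elongation: float = 0.5  # eL: total fractional length growth
    r0: float = 10.0
    radial_growth: float = 0.2  # er
    bulge: float = 0.2  # b: mid-tube radial bulge amplitude
    taper: float = 0.15  # axial radius asymmetry (real tubes are asymmetric;
    # a perfectly fore-aft symmetric shape would leave rigid alignment free
    # to flip the correspondence end-for-end)
    bend: float = 8.0  # um mid-tube axis bend at t=1 (progressive looping;
    # without it the nearly closed late tube is nearly rotationally
    # symmetric and rigid alignment could twist the correspondence
    # azimuthally at no geometric cost)
    phi0: float = 1.1 * np.pi
    phi1: float = 1.85 * np.pi
    center: tuple = (32.0, 32.0, 32.0)
    # sampling
    n_frames: int = 8
    nu: int = 33  # axial mesh nodes
    nv: int = 25  # circumferential mesh nodes
    # cells / rendering
    n_cells: int = 80
    cell_radius: float = 3.0  # um; synthetic cell diameter = 6 um
    shell_sigma: float = 1.2  # um membrane shell half-thickness
    blob_sigma: float = 1.2  # um
    blob_amplitude: float = 1.0
    shell_amplitude: float = 0.6
    noise_sigma: float = 0.03
    bleach_rate: float = 0.02  # per frame
    volume_shape: tuple = (64, 64, 64)
    voxel_size: float = 1.0  # um, isotropic
    time_step: float = 15.0  # minutes between frames

    def validate(self) -> None:
        if self.phi1 >= 2 * np.pi:
            raise ValueError("phi1 >= 2*pi would self-intersect the seam")
        if self.r0 * (1 + min(0.0, self.radial_growth)) <= 0:
            raise ValueError("non-positive radius")
        if self.bulge < -1 or self.radial_growth < -1:
            raise ValueError("radius becomes negative over the timeline")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")


class SyntheticScene:
    """A deforming parametric surface with analytic flow and deformation."""

    def __init__(self, params: SceneParams, seed: int = 0):
        params.validate()
        self.params = params
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        p = params
        # cell anchors away from the very edges so blobs stay on-sheet
        self.cell_uv = np.column_stack(
            [rng.uniform(0.05, 0.95, p.n_cells),
             rng.uniform(0.05, 0.95, p.n_cells)]
        )
        self.cell_layer = np.array(
            ["Myo"] * p.n_cells, dtype=object
        )
        self.frame_times = np.linspace(0.0, 1.0, p.n_frames)

    # -- closed-form geometry ------------------------------------------------
    def _L(self, t):
        return self.params.L0 * (1.0 + self.params.elongation * t)

    def _r(self, u, t):
        p = self.params
        return p.r0 * (1.0 + p.radial_growth * t) \
            * (1.0 + p.bulge * t * np.sin(np.pi * u)) \
            * (1.0 + p.taper * (np.asarray(u) - 0.5))

    def _r_u(self, u, t):
        """Exact dr/du."""
        p = self.params
        u = np.asarray(u, float)
        base = p.r0 * (1.0 + p.radial_growth * t)
        bulge = 1.0 + p.bulge * t * np.sin(np.pi * u)
        taper = 1.0 + p.taper * (u - 0.5)
        d_bulge = p.bulge * t * np.pi * np.cos(np.pi * u)
        return base * (d_bulge * taper + bulge * p.taper)

    def _phi(self, t):
        p = self.params
        return p.phi0 + (p.phi1 - p.phi0) * t

    def surface(self, u, v, t) -> np.ndarray:
        """S(u, v, t) in um world coordinates; u, v broadcastable arrays."""
        p = self.params
        u, v = np.broadcast_arrays(np.asarray(u, float), np.asarray(v, float))
        a = (v - 0.5) * self._phi(t)
        r = self._r(u, t)
        pts = np.stack(
            [
                (u - 0.5) * self._L(t),
                r * np.sin(a),
                -r * np.cos(a) + p.bend * t * np.sin(np.pi * u),
            ],
            axis=-1,
        )
        return pts + np.asarray(p.center)

    def flow(self, uv: np.ndarray, t0: float, t1: float) -> np.ndarray:
        """phi_{t0->t1} applied to surface points given by their (u,v)."""
        return self.surface(uv[..., 0], uv[..., 1], t1)

    def _partials(self, u, v, t):
        """Exact tangents S_u, S_v of the surface at (u, v, t)."""
        p = self.params
        u, v = np.broadcast_arrays(np.asarray(u, float), np.asarray(v, float))
        a = (v - 0.5) * self._phi(t)
        r = self._r(u, t)
        r_u = self._r_u(u, t)
        S_u = np.stack(
            [
                np.broadcast_to(self._L(t), u.shape).copy(),
                r_u * np.sin(a),
                -r_u * np.cos(a)
                + p.bend * t * np.pi * np.cos(np.pi * u),
            ],
            axis=-1,
        )
        rphi = r * self._phi(t)
        S_v = np.stack(
            [np.zeros_like(u), rphi * np.cos(a), rphi * np.sin(a)], axis=-1
        )
        return S_u, S_v

    def _metric(self, u, v, t):
        """First fundamental form entries (E, F, G) at (u, v, t)."""
        S_u, S_v = self._partials(u, v, t)
        E = np.einsum("...i,...i->...", S_u, S_u)
        F = np.einsum("...i,...i->...", S_u, S_v)
        G = np.einsum("...i,...i->...", S_v, S_v)
        return E, F, G

    def stretches(self, u, v, t0: float, t1: float):
        """Exact principal stretches (lam_min, lam_max) between t0 and t1.

        Material points are identified by (u, v), so the surface map
        t0 -> t1 has metric-tensor pullback C = G0^-1 G1; the principal
        stretches are the square roots of its eigenvalues.
        """
        E0, F0, G0 = self._metric(u, v, t0)
        E1, F1, G1 = self._metric(u, v, t1)
        det0 = E0 * G0 - F0**2
        # C = inv([[E0,F0],[F0,G0]]) @ [[E1,F1],[F1,G1]]
        c11 = (G0 * E1 - F0 * F1) / det0
        c12 = (G0 * F1 - F0 * G1) / det0
        c21 = (-F0 * E1 + E0 * F1) / det0
        c22 = (-F0 * F1 + E0 * G1) / det0
        tr = c11 + c22
        det = c11 * c22 - c12 * c21
        disc = np.sqrt(np.maximum(tr**2 / 4.0 - det, 0.0))
        lam_hi = np.sqrt(tr / 2.0 + disc)
        lam_lo = np.sqrt(np.maximum(tr / 2.0 - disc, 1e-300))
        return lam_lo, lam_hi

    def analytic_J(self, u, v, t0, t1):
        lam_u, lam_v = self.stretches(u, v, t0, t1)
        return lam_u * lam_v

    def analytic_theta(self, u, v, t0, t1):
        lam_u, lam_v = self.stretches(u, v, t0, t1)
        return np.maximum(lam_u, lam_v) / np.minimum(lam_u, lam_v)

    # -- meshes --------------------------------------------------------------
    def grid_uv(self, u_range=(0.0, 1.0), nu=None, nv=None):
        p = self.params
        nu = nu or p.nu
        nv = nv or p.nv
        uu = np.linspace(u_range[0], u_range[1], nu)
        vv = np.linspace(0.0, 1.0, nv)
        U, V = np.meshgrid(uu, vv, indexing="ij")
        uv = np.column_stack([U.ravel(), V.ravel()])
        faces = []
        for i in range(nu - 1):
            for j in range(nv - 1):
                a = i * nv + j
                b = a + 1
                c = a + nv
                d = c + 1
                faces.append((a, c, b))
                faces.append((b, c, d))
        return uv, np.asarray(faces, int)

    def mesh_at(self, t: float, u_range=(0.0, 1.0), pose=None) -> SurfaceMesh:
        uv, faces = self.grid_uv(u_range)
        nodes = self.surface(uv[:, 0], uv[:, 1], t)
        if pose is not None:
            nodes = pose.apply(nodes)
        mesh = SurfaceMesh(nodes=nodes, faces=faces,
                           provenance={"synthetic_t": float(t)})
        mesh.provenance["uv"] = uv
        return mesh

    def live_shape(self, times=None, u_range=(0.0, 1.0), pose=None):
        """Ground-truth LiveShapeSequence sampled at ``times``.

        Returns ``(sequence, node_uv)``; the anchor is the midpoint frame.
        """
        times = self.frame_times if times is None else np.asarray(times, float)
        uv, faces = self.grid_uv(u_range)
        positions = np.stack(
            [self.surface(uv[:, 0], uv[:, 1], t) for t in times]
        )
        if pose is not None:
            positions = np.stack([pose.apply(p) for p in positions])
        seq = LiveShapeSequence(
            topology=faces, positions=positions,
            anchor_frame=len(times) // 2,
            provenance={"synthetic": True, "times": times.tolist()},
        )
        return seq, uv

    def face_deformation_tables(self, times=None, u_range=(0.0, 1.0)):
        """Analytic per-face (J, theta) for every ordered frame pair."""
        times = self.frame_times if times is None else np.asarray(times, float)
        uv, faces = self.grid_uv(u_range)
        cen = uv[faces].mean(axis=1)
        tables = {}
        for i in range(len(times)):
            for j in range(len(times)):
                if i == j:
                    continue
                tables[(i, j)] = (
                    self.analytic_J(cen[:, 0], cen[:, 1], times[i], times[j]),
                    self.analytic_theta(cen[:, 0], cen[:, 1], times[i],
                                        times[j]),
                )
        return tables

    # -- cells ---------------------------------------------------------------
    def tracks(self, times=None, mixing_step: float = 0.0,
               pose=None, u_range=(0.0, 1.0)) -> "TrackSet":
        """Ground-truth cell trajectories.

        ``mixing_step`` > 0 superimposes random tangential walks in (u,v)
        on the coherent flow (the cell-mixing negative control under
        which Lagrangian propagation must break down).
        """
        times = self.frame_times if times is None else np.asarray(times, float)
        rng = np.random.default_rng(self.seed + 1)
        inside = (
            (self.cell_uv[:, 0] >= u_range[0])
            & (self.cell_uv[:, 0] <= u_range[1])
        )
        uv0 = self.cell_uv[inside]
        n = len(uv0)
        pos = np.zeros((len(times), n, 3))
        uv = uv0.copy()
        for k, t in enumerate(times):
            if mixing_step > 0 and k > 0:
                uv = uv + rng.normal(0.0, mixing_step, uv.shape)
                uv[:, 0] = np.clip(uv[:, 0], u_range[0], u_range[1])
                uv[:, 1] = np.clip(uv[:, 1], 0.0, 1.0)
            pts = self.surface(uv[:, 0], uv[:, 1], t)
            pos[k] = pose.apply(pts) if pose is not None else pts
        return TrackSet(
            positions=pos,
            layer=self.cell_layer[inside].copy(),
            dividing=np.zeros(n, dtype=bool),
            times=times.copy(),
        )

    def landmarks_at(self, t: float, pose=None) -> LandmarkSet:
        pts = {}
        for name in LANDMARK_NAMES:
            u, v = LANDMARK_UV[name]
            p = self.surface(u, v, t)
            pts[name] = pose.apply(p[None])[0] if pose is not None else p
        return LandmarkSet(points=pts)


@dataclass
class TrackSet:
    """Ground-truth cell tracks: (n_frames, n_cells, 3) um positions."""

    positions: np.ndarray
    layer: np.ndarray  # per cell: Myo / Spl / Endo style label
    dividing: np.ndarray  # per cell bool; metrics exclude dividing cells
    times: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.positions.shape[1]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]


def make_scene(params: SceneParams | None = None, seed: int = 0):
    """Scene + ground-truth Live-Shape + analytic deformation tables.

    Same seed gives bit-identical outputs.
    """
    params = params or SceneParams()
    scene = SyntheticScene(params, seed=seed)
    seq, uv = scene.live_shape()
    tables = scene.face_deformation_tables()
    return scene, seq, tables


def render_stack(scene: SyntheticScene, mixing_step: float = 0.0,
                 times=None, pose=None, u_range=(0.0, 1.0)):
    """Render the scene into a Hyperstack and matching TrackSet.

    Membrane shell intensity exp(-d^2 / 2 sigma_shell^2) from the
    distance d to the surface, Gaussian blobs at cell anchors, additive
    Gaussian noise, exponential bleaching exp(-rate * frame). The stack
    is raw (not normalized); preprocessing rescales per frame. ``times``,
    ``pose`` and ``u_range`` render a specimen-style acquisition (its own
    window, rigid orientation and cut tube ends).
    """
    p = scene.params
    times = scene.frame_times if times is None else np.asarray(times, float)
    shape = tuple(int(s) for s in p.volume_shape)
    extent = np.asarray(shape) * p.voxel_size
    # surface must fit at the extreme frames
    uu9 = np.linspace(u_range[0], u_range[1], 9)[:, None]
    vv9 = np.linspace(0, 1, 9)[None, :]
    for t_probe in (times[0], times[-1]):
        probe = scene.surface(uu9, vv9, t_probe).reshape(-1, 3)
        if pose is not None:
            probe = pose.apply(probe)
        if probe.min() < 0 or (probe.max(0) > extent).any():
            raise ValueError("volume too small to contain the surface")
    rng = np.random.default_rng(scene.seed + 2)
    tracks = scene.tracks(times=times, mixing_step=mixing_step, pose=pose,
                          u_range=u_range)

    grids = np.meshgrid(
        *[(np.arange(s) + 0.0) * p.voxel_size for s in shape], indexing="ij"
    )
    vox_pts = np.stack([g.ravel() for g in grids], axis=1)
    data = np.zeros(shape + (len(times),), dtype=float)

    # dense surface sampling for the distance-to-surface shell
    du = max(int(np.ceil(p.L0 * 2)), 96)
    dv = max(int(np.ceil(p.r0 * 2 * np.pi)), 96)
    uu = np.linspace(u_range[0], u_range[1], du)
    vv = np.linspace(0, 1, dv)
    U, V = np.meshgrid(uu, vv, indexing="ij")

    cutoff = 4.0 * p.shell_sigma
    for k, t in enumerate(times):
        samples = scene.surface(U, V, t).reshape(-1, 3)
        if pose is not None:
            samples = pose.apply(samples)
        tree = cKDTree(samples)
        d, _ = tree.query(vox_pts, distance_upper_bound=cutoff, workers=-1)
        frame = np.zeros(len(vox_pts))
        hit = np.isfinite(d)
        frame[hit] = p.shell_amplitude * np.exp(
            -(d[hit] ** 2) / (2 * p.shell_sigma**2)
        )
        frame = frame.reshape(shape)
        for c in range(tracks.n_cells):
            frame = _add_blob(frame, tracks.positions[k, c], p.blob_sigma,
                              p.blob_amplitude, p.voxel_size)
        frame *= np.exp(-p.bleach_rate * k)
        frame += rng.normal(0.0, p.noise_sigma, shape)
        data[..., k] = frame

    stack = Hyperstack(
        intensity=data, voxel_size=(p.voxel_size,) * 3,
        time_step=p.time_step,
        meta={"synthetic": True, "seed": scene.seed,
              "mixing_step": mixing_step},
    )
    return stack, tracks


def _add_blob(frame, center_um, sigma, amplitude, voxel_size):
    c = np.asarray(center_um) / voxel_size
    s = sigma / voxel_size
    lo = np.maximum(np.floor(c - 4 * s).astype(int), 0)
    hi = np.minimum(np.ceil(c + 4 * s).astype(int) + 1,
                    np.asarray(frame.shape))
    if (lo >= hi).any():
        return frame
    gx = [np.arange(lo[d], hi[d]) - c[d] for d in range(3)]
    blob = amplitude * np.exp(
        -(gx[0][:, None, None] ** 2 + gx[1][None, :, None] ** 2
          + gx[2][None, None, :] ** 2) / (2 * s**2)
    )
    frame[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += blob
    return frame


# ---------------------------------------------------------------------------
# Atlas and cohort


def make_synthetic_atlas(n_stages: int = 8, seed: int = 0,
                         params: SceneParams | None = None,
                         calibration_n: int = 6,
                         calibration_sigma: float | None = None):
    """Staged reference shapes along the canonical flow.

    Returns a list of :class:`morphomap.mapping.AtlasShape` labelled
    Gr2..Gr(n_stages+1), plus a calibration table (group -> h/w samples
    drawn around each stage's true value) and the stage pseudo-times.
    The per-group calibration sd defaults to 1/5 of the smallest gap
    between adjacent group means, mimicking a cleanly separable staging
    parameter; h/w is strictly monotone across stages by construction.
    """
    from .mapping import AtlasShape
    from .staging import compute_features

    if n_stages < 2:
        raise ValueError("n_stages must be >= 2")
    params = params or SceneParams()
    scene = SyntheticScene(params, seed=seed)
    stage_times = np.linspace(0.0, 1.0, n_stages)
    rng = np.random.default_rng(seed + 3)

    shapes = []
    hw = []
    for g, t in enumerate(stage_times):
        mesh = scene.mesh_at(t)
        lms = scene.landmarks_at(t)
        feats = compute_features(lms)
        hw.append(feats.h_over_w)
        shapes.append(
            AtlasShape(
                mesh=mesh, stage=f"Gr{g + 2}", landmarks=lms,
                reference_parameter=0.5 + 1.5 * t,
            )
        )
    hw = np.asarray(hw)
    if calibration_sigma is None:
        calibration_sigma = float(np.min(np.diff(hw)) / 5.0)
    calibration = {
        s.stage: rng.normal(hw[g], calibration_sigma, calibration_n).tolist()
        for g, s in enumerate(shapes)
    }
    return shapes, calibration, stage_times


@dataclass
class Specimen:
    """One synthetic acquisition: a contiguous stage window of the flow,
    under its own rigid pose, shape jitter and cap cut."""

    specimen_id: str
    scene: SyntheticScene
    window: tuple  # (first stage index, last stage index), inclusive
    frame_times: np.ndarray
    true_stages: list  # per frame: Atlas group label
    live_shape: LiveShapeSequence
    node_uv: np.ndarray
    tracks: TrackSet
    landmarks: list  # per frame LandmarkSet (posed)
    pose: object  # SimilarityTransform
    u_range: tuple
    hyperstack: Hyperstack | None = None


@dataclass
class Cohort:
    specimens: list
    stage_times: np.ndarray
    stage_labels: list
    base_params: SceneParams
    seed: int

    def covering(self, transition: int) -> list:
        """Specimens whose window covers stage transition g -> g+1."""
        return [
            sp for sp in self.specimens
            if sp.window[0] <= transition and sp.window[1] >= transition + 1
        ]


def _random_pose(rng, center):
    """Uniform random rotation about ``center`` plus a small translation."""
    from .pointset import SimilarityTransform

    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 2] *= -1
    c = np.asarray(center, float)
    t = rng.uniform(-3.0, 3.0, 3)
    return SimilarityTransform(rotation=Q, translation=c - Q @ c + t,
                               scale=1.0)


def make_cohort(n_specimens: int = 6, window_policy: str = "overlap",
                cap_cut_fraction: float = 0.15, seed: int = 0,
                n_stages: int = 8, params: SceneParams | None = None,
                render: bool = True) -> Cohort:
    """A fragmented multi-specimen cohort sharing one global flow.

    Each specimen gets a contiguous window of 2-3 stage transitions
    (one frame per stage time), a random rigid pose, a small per-specimen
    perturbation of the shape parameters, and both tube-end caps removed
    per ``cap_cut_fraction``. Window starts are staggered with one-stage
    overlaps so that every transition is covered by at least one
    specimen; a policy that leaves a gap raises.
    """
    base = params or SceneParams()
    rng = np.random.default_rng(seed)
    stage_times = np.linspace(0.0, 1.0, n_stages)
    stage_labels = [f"Gr{g + 2}" for g in range(n_stages)]
    n_trans = n_stages - 1

    if n_specimens == 1:
        # single acquisition covering the whole timeline
        windows = [(0, n_trans)]
    else:
        windows = _staggered_windows(rng, n_trans, n_specimens, window_policy)
    covered = set()
    for a, b in windows:
        covered.update(range(a, b))
    if covered != set(range(n_trans)):
        missing = sorted(set(range(n_trans)) - covered)
        raise ValueError(
            f"sampled windows leave stage transitions {missing} uncovered; "
            "increase n_specimens"
        )
    return _build_specimens(base, rng, windows, stage_times, stage_labels,
                            cap_cut_fraction, seed, render)


def _staggered_windows(rng, n_trans, n_specimens, window_policy):
    overlap = window_policy == "overlap"
    step = 2 if overlap else 3  # net timeline advance of a later w=3 window
    windows = []
    start = 0
    while start < n_trans:
        if len(windows) == n_specimens:
            raise ValueError(
                "n_specimens too small to cover all stage transitions"
            )
        specs_left = n_specimens - len(windows) - 1
        w = int(rng.integers(2, 4))  # 2-3 transitions
        # force the long window when the remaining specimen budget
        # could not otherwise reach the end of the timeline
        if (n_trans - start) - w > step * specs_left:
            w = 3
            if (n_trans - start) - w > step * specs_left:
                raise ValueError(
                    "n_specimens too small to cover all stage transitions"
                )
        end = min(start + w, n_trans)
        windows.append((start, end))
        start = end - 1 if (overlap and end < n_trans) else end
    while len(windows) < n_specimens:
        w = int(rng.integers(2, 4))
        s0 = int(rng.integers(0, max(1, n_trans - w + 1)))
        windows.append((s0, min(s0 + w, n_trans)))
    return windows


def _build_specimens(base, rng, windows, stage_times, stage_labels,
                     cap_cut_fraction, seed, render):
    specimens = []
    for i, (a, b) in enumerate(windows):
        jitter = 1.0 + rng.uniform(-0.05, 0.05, 2)
        p_i = replace(
            base,
            radial_growth=base.radial_growth * jitter[0],
            bulge=base.bulge * jitter[1],
            # roomier volume so any rigid pose keeps the shell inside
            volume_shape=(72, 72, 72),
            center=(36.0, 36.0, 36.0),
        )
        scene = SyntheticScene(p_i, seed=seed + 10 + i)
        pose = _random_pose(rng, p_i.center)
        u_range = (cap_cut_fraction, 1.0 - cap_cut_fraction)
        times = stage_times[a:b + 1]
        seq, uv = scene.live_shape(times=times, u_range=u_range, pose=pose)
        tracks = scene.tracks(times=times, pose=pose, u_range=u_range)
        lms = [scene.landmarks_at(t, pose=pose) for t in times]
        hs = None
        if render:
            hs, _ = render_stack(scene, times=times, pose=pose,
                                 u_range=u_range)
        specimens.append(
            Specimen(
                specimen_id=f"s{i:02d}",
                scene=scene,
                window=(a, b),
                frame_times=times,
                true_stages=[stage_labels[g] for g in range(a, b + 1)],
                live_shape=seq,
                node_uv=uv,
                tracks=tracks,
                landmarks=lms,
                pose=pose,
                u_range=u_range,
                hyperstack=hs,
            )
        )
    return Cohort(
        specimens=specimens, stage_times=stage_times,
        stage_labels=stage_labels, base_params=base, seed=seed,
    )
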