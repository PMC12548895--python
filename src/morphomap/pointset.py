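"""Rigid/similarity point-cloud and mesh alignment.

The workhorse is an EM fit of a Student's-t mixture (TMM): mixture
components sit at a subsample of the source cloud (half the source nodes
by default), the similarity transform (rotation, translation, isotropic
scale) is re-estimated each M-step by weighted Procrustes, and the heavy
t tails (3 degrees of freedom by default) down-weight unmatched points,
which makes the alignment robust to the missing regions typical of live
acquisitions (cut inflow/outflow tracts). ICP and Gaussian-mixture CPD
are provided as baselines.

Clouds are centered on the origin internally before EM; all methods are
seeded by a PCA axis alignment so large rotations (tens of degrees) stay
inside the capture range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .meshes import SurfaceMesh, face_centroids

__all__ = [
    "SimilarityTransform",
    "TMMParams",
    "CorrespondenceMap",
    "tmm_register",
    "icp_register",
    "cpd_register",
    "cut_unmatched",
    "default_cut_threshold",
    "face_to_face_match",
]


@dataclass
class SimilarityTransform:
    rotation: np.ndarray  # (3,3), det +1
    translation: np.ndarray  # (3,)
    scale: float = 1.0

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float)
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3),
                           atol=1e-6):
            raise ValueError("rotation must be orthonormal")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * (np.asarray(points, float) @ self.rotation.T) \
            + self.translation

    def compose_with(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """self after other: x -> self(other(x))."""
        return SimilarityTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.scale * (other.translation @ self.rotation.T)
            + self.translation,
            scale=self.scale * other.scale,
        )

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3), scale=1.0)

    def inverse(self) -> "SimilarityTransform":
        Rinv = self.rotation.T
        return SimilarityTransform(
            rotation=Rinv,
            translation=-(Rinv @ self.translation) / self.scale,
            scale=1.0 / self.scale,
        )

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class TMMParams:
    n_components: int | None = None  # default: ceil(n_source / 2)
    max_iter: int = 150
    dof: float = 3.0  # low dof = heavy tails = strong outlier robustness
    tol: float = 1e-6  # relative log-likelihood change
    seed: int = 0

    def __post_init__(self):
        if self.n_components is not None and self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.dof <= 0:
            raise ValueError("dof must be > 0")


def _weighted_umeyama(X: np.ndarray, Y: np.ndarray, w: np.ndarray,
                      with_scale: bool = True) -> SimilarityTransform:
    """Similarity transform minimizing sum_i w_i |Y_i - (sR X_i + t)|^2."""
    w = np.asarray(w, float)
    W = w.sum()
    mx = (w[:, None] * X).sum(0) / W
    my = (w[:, None] * Y).sum(0) / W
    Xc = X - mx
    Yc = Y - my
    S = (w[:, None] * Yc).T @ Xc / W
    U, D, Vt = np.linalg.svd(S)
    d = np.sign(np.linalg.det(U @ Vt))
    E = np.diag([1.0, 1.0, d])
    R = U @ E @ Vt
    if with_scale:
        var_x = (w * (Xc**2).sum(1)).sum() / W
        s = float(np.trace(np.diag(D) @ E) / var_x) if var_x > 0 else 1.0
        s = float(np.clip(s, 0.05, 20.0))  # keep degenerate fits bounded
    else:
        s = 1.0
    t = my - s * (R @ mx)
    return SimilarityTransform(rotation=R, translation=t, scale=s)


def _check_cloud(p: np.ndarray, name: str, min_n: int = 4) -> np.ndarray:
    p = np.asarray(p, float)
    if p.ndim != 2 or p.shape[1] != 3:
        raise ValueError(f"{name} must be (n, 3)")
    if len(p) < min_n:
        raise ValueError(f"{name} needs at least {min_n} points")
    c = p - p.mean(0)
    s = np.linalg.svd(c, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError(f"{name} is degenerate (collinear points)")
    return p


def _pca_axes(p: np.ndarray) -> np.ndarray:
    c = p - p.mean(0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    U = vt.T
    if np.linalg.det(U) < 0:
        U[:, 2] *= -1
    return U


def _init_candidates(src: np.ndarray, tgt: np.ndarray):
    """Identity plus proper PCA axis alignments (clouds centered).

    Besides the four det+1 sign flips, the target axis frame is also
    tried with its 2nd/3rd axes swapped: elongated shapes often have
    near-degenerate minor axes, and partial overlap (cut regions) can
    swap their order between the two clouds.
    """
    from itertools import permutations

    Us, Ut = _pca_axes(src), _pca_axes(tgt)
    rms_s = np.sqrt((src**2).sum(1).mean())
    rms_t = np.sqrt((tgt**2).sum(1).mean())
    s0 = rms_t / rms_s if rms_s > 0 else 1.0
    cands = [SimilarityTransform.identity()]
    for perm in permutations(range(3)):
        Up = Ut[:, list(perm)]
        for flips in ([1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1],
                      [-1, -1, -1], [-1, 1, 1], [1, -1, 1], [1, 1, -1]):
            U = Up * np.asarray(flips)
            if np.linalg.det(U) < 0:
                continue
            R = U @ Us.T
            cands.append(
                SimilarityTransform(rotation=R, translation=np.zeros(3),
                                    scale=s0)
            )
    return cands


def _mutual_nn_rmse(src: np.ndarray, tgt: np.ndarray) -> float:
    """RMSE over mutual nearest-neighbour pairs (ignores deliberately
    missing regions on either side)."""
    ts = cKDTree(src)
    tt = cKDTree(tgt)
    d_st, j_st = tt.query(src, workers=-1)
    _, j_ts = ts.query(tgt, workers=-1)
    mutual = j_ts[j_st] == np.arange(len(src))
    if not mutual.any():
        return float(np.sqrt((d_st**2).mean()))
    return float(np.sqrt((d_st[mutual] ** 2).mean()))


def _mixture_em(src, tgt, params: TMMParams, student_t: bool,
                outlier_w: float = 0.0):
    """Shared EM loop for the TMM (student_t=True) and CPD variants.

    Mixture centers are a subsample of the (centered) source; the
    similarity transform is solved by weighted Procrustes each M-step.
    Returns the transform between the *centered* clouds.
    """
    rng = np.random.default_rng(params.seed)
    K = params.n_components or int(np.ceil(len(src) / 2))
    K = min(K, len(src))
    idx = rng.choice(len(src), size=K, replace=False) if K < len(src) \
        else np.arange(len(src))
    X = src[idx]
    Y = tgt
    nu = params.dof

    # phase 1: short EM runs on subsampled clouds from every proper PCA
    # axis alignment (25 candidates) sort out the symmetry basin; phase 2
    # refines the best two on the full clouds, ranked by log-likelihood
    warm = min(25, params.max_iter)
    Xw = X[rng.choice(len(X), min(len(X), 150), replace=False)]
    Yw = Y[rng.choice(len(Y), min(len(Y), 250), replace=False)]
    scored = []
    for T in _init_candidates(src, tgt):
        trans, ll = _em_run(Xw, Yw, T, warm, params, student_t, outlier_w, nu)
        scored.append((ll, trans))
    scored.sort(key=lambda x: -x[0])
    finals = []
    for _, T in scored[:2]:
        trans, ll = _em_run(X, Y, T, params.max_iter, params, student_t,
                            outlier_w, nu)
        finals.append((ll, trans))
    finals.sort(key=lambda x: -x[0])
    return finals[0][1]


def _em_run(X, Y, T, max_iter, params, student_t, outlier_w, nu):
    """One EM run from init ``T``; returns (transform, log-likelihood)."""
    K = len(X)
    sigma2 = cdist(Y, T.apply(X), "sqeuclidean").mean() / 3.0
    trans = T
    ll_prev = -np.inf
    for _ in range(max_iter):
        Xt = trans.apply(X)
        d2 = cdist(Y, Xt, "sqeuclidean")  # (J, K)
        if student_t:
            log_k = -1.5 * np.log(sigma2) \
                - 0.5 * (nu + 3.0) * np.log1p(d2 / (nu * sigma2))
        else:
            log_k = -1.5 * np.log(sigma2) - 0.5 * d2 / sigma2
        m = log_k.max(axis=1, keepdims=True)
        p = np.exp(log_k - m)
        denom = p.sum(axis=1, keepdims=True)
        if outlier_w > 0:
            # uniform outlier component, CPD style
            vol = np.prod(Y.max(0) - Y.min(0)) + 1e-12
            c_out = outlier_w / (1 - outlier_w) * K / vol \
                * (2 * np.pi * sigma2) ** 1.5
            denom = denom + c_out * np.exp(-m)
        r = p / denom
        ll = float(np.sum(np.log(denom.ravel()) + m.ravel()))
        if student_t:
            u = (nu + 3.0) / (nu + d2 / sigma2)
            wgt = r * u
        else:
            wgt = r
        Wk = wgt.sum(axis=0)  # (K,)
        keep = Wk > 1e-12
        if keep.sum() < 4:
            break
        Yhat = (wgt.T @ Y)[keep] / Wk[keep, None]
        trans = _weighted_umeyama(X[keep], Yhat, Wk[keep])
        d2_new = cdist(Y, trans.apply(X), "sqeuclidean")
        sigma2 = max(float((wgt * d2_new).sum() / (3.0 * r.sum())), 1e-12)
        if abs(ll - ll_prev) < params.tol * (abs(ll_prev) + 1e-12):
            ll_prev = ll
            break
        ll_prev = ll
    return trans, ll_prev


def _register(source, target, params: TMMParams, student_t: bool,
              outlier_w: float = 0.0):
    src = _check_cloud(source, "source")
    tgt = _check_cloud(target, "target")
    mu_s = src.mean(0)
    mu_t = tgt.mean(0)
    # center and bring to unit rms (one shared factor, so the recovered
    # scale is unchanged): EM densities and the outlier level are then
    # data-scale independent
    f = np.sqrt(((tgt - mu_t) ** 2).sum(1).mean())
    f = f if f > 0 else 1.0
    trans_c = _mixture_em((src - mu_s) / f, (tgt - mu_t) / f, params,
                          student_t, outlier_w)
    # lift the normalized-cloud transform back to world coordinates
    R, s = trans_c.rotation, trans_c.scale
    t = f * trans_c.translation + mu_t - s * (R @ mu_s)
    trans = SimilarityTransform(rotation=R, translation=t, scale=s)
    aligned = trans.apply(src)
    rmse = _mutual_nn_rmse(aligned, tgt)
    return trans, aligned, rmse


def tmm_register(source, target, params: TMMParams | None = None):
    """Student's-t mixture similarity registration of ``source`` onto
    ``target``. Returns ``(transform, aligned_source, rmse)`` with RMSE
    over mutual nearest-neighbour pairs."""
    return _register(source, target, params or TMMParams(), student_t=True)


def cpd_register(source, target, params: TMMParams | None = None):
    """Gaussian-mixture (coherent point drift style) similarity
    registration; same contract as :func:`tmm_register`."""
    return _register(source, target, params or TMMParams(), student_t=False,
                     outlier_w=0.1)


def icp_register(source, target, max_iter: int = 50):
    """Iterative closest point with a similarity Procrustes update.

    Nearest-neighbour correspondences and a closed-form similarity fit,
    iterated to convergence; the mean NN distance is monotone
    non-increasing. Large initial rotations can trap ICP in a local
    minimum -- the returned RMSE flags such failures.
    """
    src = _check_cloud(source, "source")
    tgt = _check_cloud(target, "target")
    tree = cKDTree(tgt)
    src_tree = cKDTree(src)
    trans = SimilarityTransform.identity()
    best = (np.inf, trans)
    stall = 0
    for _ in range(max_iter):
        moved = trans.apply(src)
        d, j = tree.query(moved, workers=-1)
        # mutual nearest neighbours give an (almost) unbiased pairing;
        # one-sided NN correspondences stall ICP short of the optimum
        moved_tree = cKDTree(moved)
        _, j_back = moved_tree.query(tgt, workers=-1)
        mutual = j_back[j] == np.arange(len(src))
        if mutual.sum() < 10:
            mutual = np.ones(len(src), bool)
        obj = float((d[mutual] ** 2).mean())
        # the objective can bump transiently when the mutual set changes;
        # stop only after a run of iterations without real progress
        if obj < best[0] * (1 - 1e-9):
            best = (obj, trans)
            stall = 0
        else:
            stall += 1
            if stall >= 8:
                break
        trans = _weighted_umeyama(src[mutual], tgt[j[mutual]],
                                  np.ones(int(mutual.sum())))
    trans = best[1]
    aligned = trans.apply(src)
    return trans, aligned, _mutual_nn_rmse(aligned, tgt)


def default_cut_threshold(live_mesh: SurfaceMesh) -> float:
    """3x the median nearest-neighbour spacing of the live mesh nodes."""
    tree = cKDTree(live_mesh.nodes)
    d, _ = tree.query(live_mesh.nodes, k=2, workers=-1)
    return 3.0 * float(np.median(d[:, 1]))


def cut_unmatched(atlas_mesh: SurfaceMesh, live_mesh: SurfaceMesh,
                  threshold: float):
    """Remove Atlas nodes with no live-mesh counterpart ("AtlasCut").

    After rigid alignment, Atlas nodes farther than ``threshold`` (um)
    from every live node are removed with their incident faces. Returns
    ``(cut_mesh, record)`` where ``record`` maps the cut mesh back to the
    original (kept node indices, removed node indices, face mask).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    tree = cKDTree(live_mesh.nodes)
    d, _ = tree.query(atlas_mesh.nodes, workers=-1)
    keep = d <= threshold
    kept_idx = np.flatnonzero(keep)
    removed_idx = np.flatnonzero(~keep)
    remap = -np.ones(atlas_mesh.n_nodes, dtype=int)
    remap[kept_idx] = np.arange(kept_idx.size)
    face_ok = keep[atlas_mesh.faces].all(axis=1)
    new_faces = remap[atlas_mesh.faces[face_ok]]
    cut = SurfaceMesh(
        nodes=atlas_mesh.nodes[kept_idx],
        faces=new_faces,
        provenance={**atlas_mesh.provenance, "atlascut": True,
                    "cut_threshold": float(threshold)},
    )
    record = {
        "kept_nodes": kept_idx,
        "removed_nodes": removed_idx,
        "face_mask": face_ok,
        "threshold": float(threshold),
    }
    return cut, record


@dataclass
class CorrespondenceMap:
    """source face/node index -> target index, with pair distances (um).

    Every source index appears exactly once; many-to-one is allowed.
    """

    pairs: np.ndarray  # (n_source,) target indices
    distances: np.ndarray  # (n_source,) um

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "source_face": np.arange(len(self.pairs)),
                "target_face": self.pairs,
                "distance_um": self.distances,
            }
        )


def face_to_face_match(source_mesh: SurfaceMesh,
                       target_mesh: SurfaceMesh) -> CorrespondenceMap:
    """Match each source face to the nearest target face centroid (k=1)."""
    if source_mesh.n_faces == 0 or target_mesh.n_faces == 0:
        raise ValueError("face_to_face_match: empty mesh")
    cs = face_centroids(source_mesh)
    ct = face_centroids(target_mesh)
    tree = cKDTree(ct)
    d, j = tree.query(cs, workers=-1)
    return CorrespondenceMap(pairs=j.astype(int), distances=d)
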