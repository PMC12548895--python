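"""Morphometric staging of live sequences against a reference Atlas.

Each frame of a Live-Shape sequence is assigned to one of the Atlas
groups (Gr1..Gr10; Gr2..Gr9 by default for deformation work) from a
single morphometric feature, the landmark-distance ratio h/w, modelled
per group as a normal distribution: the staging system is a Gaussian
mixture over groups with equal priors, and a frame's posterior over
groups is the responsibility vector at its h/w value.

Landmarks pt1..pt7 are placed on the surface mesh (manually in the
original protocol, three replicates reduced by coordinatewise median);
only the anchor frame needs annotation, as landmark positions at every
other frame follow from the motion profile (point propagation).

Features: w = |pt1-pt2|, h = |pt3-pt4|, s = |pt5-pt6| (see note below),
theta_lm = angle at pt7 subtended by pt5 and pt6. Staging uses h/w only.

Note: the feature s is reported as the pt5-pt6 distance by convention;
outputs label it ``s (pt5-pt6, convention)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "LandmarkSet",
    "FeatureVector",
    "StagingModel",
    "StageAssignment",
    "median_landmarks",
    "axis_point",
    "compute_features",
    "propagate_landmarks",
    "feature_reference_correlation",
    "check_normality",
    "fit_staging_model",
    "stage_sequence",
]

LANDMARK_NAMES = ("pt1", "pt2", "pt3", "pt4", "pt5", "pt6", "pt7")
DEFAULT_GROUPS = tuple(f"Gr{i}" for i in range(2, 10))


@dataclass
class LandmarkSet:
    """The seven myocardial landmarks, as 3D um positions."""

    points: dict  # name -> (3,) array
    replicate_count: int = 1

    def __post_init__(self):
        if set(self.points) != set(LANDMARK_NAMES):
            raise ValueError(f"expected exactly landmarks {LANDMARK_NAMES}")
        self.points = {k: np.asarray(v, float) for k, v in self.points.items()}
        if np.allclose(self.points["pt1"], self.points["pt2"]):
            raise ValueError("pt1 and pt2 coincide")
        if np.allclose(self.points["pt3"], self.points["pt4"]):
            raise ValueError("pt3 and pt4 coincide")
        p5, p6, p7 = (self.points[k] for k in ("pt5", "pt6", "pt7"))
        cr = np.cross(p6 - p5, p7 - p5)
        if np.linalg.norm(cr) < 1e-12:
            raise ValueError("pt5, pt6, pt7 are collinear")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def as_array(self) -> np.ndarray:
        return np.stack([self.points[k] for k in LANDMARK_NAMES])


@dataclass
class FeatureVector:
    w: float
    h: float
    s: float
    theta_lm: float  # degrees
    h_over_w: float
    h_over_s: float
    s_label: str = "s (pt5-pt6, convention)"


@dataclass
class StagingModel:
    """Per-group normal model of h/w with equal priors."""

    groups: tuple
    means: np.ndarray
    sds: np.ndarray
    priors: np.ndarray
    boundary_threshold: float = 0.75

    def __post_init__(self):
        self.means = np.asarray(self.means, float)
        self.sds = np.asarray(self.sds, float)
        self.priors = np.asarray(self.priors, float)
        if np.any(self.sds <= 0):
            raise ValueError("group sd must be > 0")
        if abs(self.priors.sum() - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")

    def posterior(self, value: float) -> np.ndarray:
        if not np.isfinite(value):
            return np.full(len(self.groups), np.nan)
        logp = stats.norm.logpdf(value, self.means, self.sds) + np.log(self.priors)
        logp -= logp.max()
        p = np.exp(logp)
        return p / p.sum()

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "groups": list(self.groups),
                    "means": self.means.tolist(),
                    "sds": self.sds.tolist(),
                    "priors": self.priors.tolist(),
                    "boundary_threshold": self.boundary_threshold,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "StagingModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            groups=tuple(d["groups"]), means=d["means"], sds=d["sds"],
            priors=d["priors"],
            boundary_threshold=d.get("boundary_threshold", 0.75),
        )


@dataclass
class StageAssignment:
    labels: list  # per frame: group label or "unassigned"
    posteriors: np.ndarray  # (n_frames, n_groups)
    representative: dict  # group label -> frame index
    groups: tuple = DEFAULT_GROUPS


def median_landmarks(replicates: list) -> LandmarkSet:
    """Coordinatewise median across replicate landmark placements."""
    if len(replicates) == 0:
        raise ValueError("need at least one replicate")
    pts = {}
    for name in LANDMARK_NAMES:
        arr = np.stack([r[name] for r in replicates])
        pts[name] = np.median(arr, axis=0)
    return LandmarkSet(points=pts, replicate_count=len(replicates))


def axis_point(mesh, orientation_hint=None) -> np.ndarray:
    """pt7: where the longitudinal symmetry axis exits the mesh surface.

    The axis is the first principal component of the mesh nodes, weighted
    by one-third of each node's incident face area (faces are unevenly
    sized, especially in small anatomical regions, and unweighted PCA
    would tip the axis). ``orientation_hint`` (a rough direction) selects
    which of the two exits; without it, an ambiguous axis (two leading
    eigenvalues within 1%) is an error.
    """
    from .meshes import face_areas

    areas = face_areas(mesh)
    w = np.zeros(mesh.n_nodes)
    np.add.at(w, mesh.faces.ravel(), np.repeat(areas / 3.0, 3))
    mu = np.average(mesh.nodes, axis=0, weights=w)
    centered = mesh.nodes - mu
    cov = (centered * w[:, None]).T @ centered / w.sum()
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] > 0 and (evals[0] - evals[1]) / evals[0] < 0.01:
        if orientation_hint is None:
            raise ValueError(
                "principal axis ambiguous (two leading eigenvalues within "
                "1%); provide an orientation_hint"
            )
    axis = evecs[:, 0]
    if orientation_hint is not None:
        hint = np.asarray(orientation_hint, float)
        if axis @ hint < 0:
            axis = -axis
    # farthest node along the oriented axis = where the axis exits
    proj = centered @ axis
    return mesh.nodes[int(np.argmax(proj))]


def compute_features(landmarks: LandmarkSet) -> FeatureVector:
    """Distances w, h, s, landmark angle theta_lm and the staging ratios."""
    p = landmarks.points
    w = float(np.linalg.norm(p["pt1"] - p["pt2"]))
    h = float(np.linalg.norm(p["pt3"] - p["pt4"]))
    s = float(np.linalg.norm(p["pt5"] - p["pt6"]))
    if min(w, h, s) <= 0:
        raise ValueError("coincident landmark pair")
    a = p["pt5"] - p["pt7"]
    b = p["pt6"] - p["pt7"]
    cosang = np.clip(
        a @ b / (np.linalg.norm(a) * np.linalg.norm(b)), -1.0, 1.0
    )
    theta = float(np.degrees(np.arccos(cosang)))
    return FeatureVector(
        w=w, h=h, s=s, theta_lm=theta, h_over_w=h / w, h_over_s=h / s
    )


def propagate_landmarks(landmarks: LandmarkSet, tset) -> list:
    """Landmark sets at every frame via the continuous motion profile.

    The anchor-frame landmarks are carried through the TransformSet with
    point propagation, so per-frame features need no re-annotation.
    """
    from .registration import propagate_points

    names = LANDMARK_NAMES
    anchor_pts = np.stack([landmarks[k] for k in names])
    out: list = [None] * tset.n_frames
    out[tset.anchor] = landmarks
    cur = anchor_pts
    for f in range(tset.anchor + 1, tset.n_frames):
        cur, _ = propagate_points(cur, tset, f - 1, f)
        out[f] = LandmarkSet(
            points=dict(zip(names, cur)),
            replicate_count=landmarks.replicate_count,
        )
    cur = anchor_pts
    for f in range(tset.anchor - 1, -1, -1):
        cur, _ = propagate_points(cur, tset, f + 1, f)
        out[f] = LandmarkSet(
            points=dict(zip(names, cur)),
            replicate_count=landmarks.replicate_count,
        )
    return out


def feature_reference_correlation(feature_values, reference_values):
    """OLS fit of the Atlas reference parameter on a candidate feature.

    Returns ``(r_squared, p_value, slope)`` of the simple regression;
    used to select which morphometric feature stands in for the Atlas's
    d1/d2 staging parameter.
    """
    x = np.asarray(feature_values, float)
    y = np.asarray(reference_values, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("feature has zero variance")
    res = stats.linregress(x, y)
    return float(res.rvalue**2), float(res.pvalue), float(res.slope)


def check_normality(values_per_group: dict) -> dict:
    """Shapiro-Wilk normality check per group (3 <= n <= 50).

    Groups with fewer than 3 samples are skipped with a warning entry.
    Model fitting proceeds regardless of the outcome; results are for the
    record.
    """
    out = {}
    for group, vals in values_per_group.items():
        vals = np.asarray(vals, float)
        if len(vals) < 3:
            out[group] = {"skipped": True, "n": int(len(vals))}
            continue
        w, p = stats.shapiro(vals)
        out[group] = {"W": float(w), "p": float(p), "n": int(len(vals))}
    return out


def fit_staging_model(calibration: dict, sd_floor: float = 1e-6,
                      boundary_threshold: float = 0.75) -> StagingModel:
    """Fit per-group normals to calibration h/w values.

    ``calibration`` maps group label -> iterable of h/w values (n >= 2
    each; at least two groups). Priors are equal; groups are ordered by
    mean. A zero sample sd is floored at ``sd_floor`` with a warning.
    """
    import warnings

    if len(calibration) < 2:
        raise ValueError("need at least two groups to calibrate staging")
    if len(set(calibration)) != len(calibration):
        raise ValueError("overlapping group labels")
    groups, means, sds = [], [], []
    for g, vals in calibration.items():
        vals = np.asarray(list(vals), float)
        if len(vals) < 2:
            raise ValueError(f"group {g} needs n >= 2 calibration values")
        mu = float(vals.mean())
        sd = float(vals.std(ddof=1))
        if sd <= 0:
            warnings.warn(f"group {g} has zero variance; sd floored",
                          stacklevel=2)
            sd = sd_floor
        groups.append(g)
        means.append(mu)
        sds.append(sd)
    order = np.argsort(means)
    groups = tuple(np.asarray(groups, object)[order])
    means = np.asarray(means)[order]
    sds = np.asarray(sds)[order]
    priors = np.full(len(groups), 1.0 / len(groups))
    return StagingModel(
        groups=groups, means=means, sds=sds, priors=priors,
        boundary_threshold=boundary_threshold,
    )


def stage_sequence(features, model: StagingModel) -> StageAssignment:
    """Assign each frame's h/w value to an Atlas group.

    Label = argmax posterior. The maximal leading and trailing runs of
    frames sharing the first (resp. last) assigned group are the
    uncertain boundary of the acquisition window; frames there keep
    their label only with posterior > ``model.boundary_threshold``
    (default 0.75), else they are "unassigned". Non-finite features are
    unassigned. Per group, the representative frame is the one with the
    highest posterior (ties toward the earlier frame).
    """
    feats = np.asarray(features, float)
    n = len(feats)
    post = np.stack([model.posterior(v) for v in feats])
    labels = []
    argmax = np.full(n, -1)
    for i in range(n):
        if not np.isfinite(feats[i]):
            labels.append("unassigned")
            continue
        k = int(np.argmax(post[i]))
        argmax[i] = k
        labels.append(model.groups[k])

    finite = np.flatnonzero(argmax >= 0)
    if finite.size:
        first_k = argmax[finite[0]]
        lead = []
        for i in finite:
            if argmax[i] == first_k:
                lead.append(i)
            else:
                break
        last_k = argmax[finite[-1]]
        trail = []
        for i in finite[::-1]:
            if argmax[i] == last_k:
                trail.append(i)
            else:
                break
        for i in set(lead) | set(trail):
            if post[i, argmax[i]] <= model.boundary_threshold:
                labels[i] = "unassigned"

    representative = {}
    for k, g in enumerate(model.groups):
        best, best_p = None, -1.0
        for i in range(n):
            if labels[i] == g and post[i, k] > best_p:
                best, best_p = i, post[i, k]
        if best is not None:
            representative[g] = best
    return StageAssignment(
        labels=labels, posteriors=post, representative=representative,
        groups=model.groups,
    )
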