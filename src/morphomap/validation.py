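"""Validation metrics for the motion estimation, on ground-truth tracks.

The estimated motion is judged Lagrangianly: ground-truth cell positions
are propagated through the estimated transformation fields and compared
with where the cells actually went. Stepwise error propagates one frame
at a time from fresh ground truth; accumulated error chains the
propagation over the whole span from the anchor frame, so it exposes
drift. The misregistration rate counts point-frames whose error exceeds
an average cell diameter (20 um in the original tissue; the synthetic
scenes use their own cell diameter). Dividing cells are excluded from
all error sets (their tracks jump at mitosis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .registration import RegistrationParams, TransformSet, propagate_points

__all__ = [
    "ErrorReport",
    "stepwise_error",
    "accumulated_error",
    "misregistration_rate",
    "resolution_sweep",
    "mixing_control",
    "error_slope",
]


@dataclass
class ErrorReport:
    """Per-cell, per-frame Euclidean propagation errors (um).

    ``errors[f, c]`` is nan where cell c has no value at frame f.
    ``normalized`` divides each error by the cell's ground-truth
    displacement over the same span (nan where that displacement is 0).
    """

    errors: np.ndarray  # (n_frames, n_cells) um
    normalized: np.ndarray
    times: np.ndarray  # minutes, relative to the report's reference frame
    kind: str = "stepwise"
    meta: dict = field(default_factory=dict)

    def frame_summary(self):
        import pandas as pd

        with np.errstate(invalid="ignore"):
            return pd.DataFrame(
                {
                    "time_min": self.times,
                    "mean": np.nanmean(self.errors, axis=1),
                    "median": np.nanmedian(self.errors, axis=1),
                    "sd": np.nanstd(self.errors, axis=1),
                }
            )

    def overall_mean(self) -> float:
        return float(np.nanmean(self.errors))


def _usable_cells(tracks) -> np.ndarray:
    return ~np.asarray(tracks.dividing, bool)


def stepwise_error(tracks, tset: TransformSet) -> ErrorReport:
    """One-step propagation error at every frame pair.

    Each ground-truth position is pushed one step through the pairwise
    field for that step (in the field's own direction relative to the
    anchor) and compared with the next ground-truth position. Dividing
    cells are skipped; the skipped count is recorded in ``meta``.
    """
    keep = _usable_cells(tracks)
    n_frames = tracks.n_frames
    if n_frames != tset.n_frames:
        raise ValueError("tracks and transform set disagree on frame count")
    errors = np.full((n_frames, tracks.n_cells), np.nan)
    normalized = np.full_like(errors, np.nan)
    pos = tracks.positions
    for i in range(n_frames - 1):
        if i >= tset.anchor:
            src, dst, f = i, i + 1, i
        else:
            # backward-side fields run i+1 -> i
            src, dst, f = i + 1, i, i + 1
        moved, _ = propagate_points(pos[src][keep], tset, src, dst)
        err = np.linalg.norm(moved - pos[dst][keep], axis=1)
        disp = np.linalg.norm(pos[dst][keep] - pos[src][keep], axis=1)
        errors[f, keep] = err
        with np.errstate(divide="ignore", invalid="ignore"):
            normalized[f, keep] = np.where(disp > 0, err / disp, np.nan)
    dt = float(np.mean(np.diff(tracks.times))) if n_frames > 1 else 1.0
    return ErrorReport(
        errors=errors, normalized=normalized,
        times=(np.arange(n_frames) - tset.anchor) * dt,
        kind="stepwise",
        meta={"excluded_dividing": int((~keep).sum())},
    )


def accumulated_error(tracks, tset: TransformSet,
                      from_frame: int | None = None) -> ErrorReport:
    """Error of sequential propagation over the full span.

    Initial positions at ``from_frame`` (default: the anchor) are
    propagated frame by frame outward; each propagated position feeds
    the next step, so per-step errors accumulate. The error at the
    start frame is 0 by construction.
    """
    keep = _usable_cells(tracks)
    anchor = tset.anchor if from_frame is None else from_frame
    n_frames = tracks.n_frames
    errors = np.full((n_frames, tracks.n_cells), np.nan)
    normalized = np.full_like(errors, np.nan)
    pos = tracks.positions
    errors[anchor, keep] = 0.0
    for direction in (+1, -1):
        cur = pos[anchor][keep]
        f = anchor
        while 0 <= f + direction < n_frames:
            nxt = f + direction
            try:
                cur, _ = propagate_points(cur, tset, f, nxt)
            except ValueError:
                break  # no fields on this side (unidirectional set)
            err = np.linalg.norm(cur - pos[nxt][keep], axis=1)
            disp = np.linalg.norm(pos[nxt][keep] - pos[anchor][keep], axis=1)
            errors[nxt, keep] = err
            with np.errstate(divide="ignore", invalid="ignore"):
                normalized[nxt, keep] = np.where(disp > 0, err / disp, np.nan)
            f = nxt
    dt = float(np.mean(np.diff(tracks.times))) if n_frames > 1 else 1.0
    return ErrorReport(
        errors=errors, normalized=normalized,
        times=(np.arange(n_frames) - anchor) * dt,
        kind="accumulated",
        meta={"from_frame": anchor,
              "excluded_dividing": int((~keep).sum())},
    )


def misregistration_rate(report: ErrorReport, diameter: float = 20.0) -> float:
    """Fraction of point-frames with error above one cell diameter."""
    vals = report.errors[np.isfinite(report.errors)]
    if vals.size == 0:
        raise ValueError("empty error report")
    return float(np.mean(vals > diameter))


def error_slope(report: ErrorReport, bin_minutes: float = 20.0) -> float:
    """OLS slope (um per bin step) of the median error vs binned |time|.

    Frames are binned at ``bin_minutes``; the fit runs on per-bin
    medians, mirroring how error-growth rates are compared between
    tissue regimes.
    """
    with np.errstate(invalid="ignore"):
        med = np.nanmedian(report.errors, axis=1)
    t = np.abs(report.times)
    ok = np.isfinite(med)
    t, med = t[ok], med[ok]
    if len(t) < 3:
        raise ValueError("span too short for a slope fit (<3 frames)")
    bins = np.round(t / bin_minutes).astype(int)
    xs, ys = [], []
    for b in np.unique(bins):
        xs.append(b)
        ys.append(np.median(med[bins == b]))
    if len(xs) < 2:
        xs, ys = t, med
    coeffs = np.polyfit(np.asarray(xs, float), np.asarray(ys, float), 1)
    return float(coeffs[0])


def resolution_sweep(stack, tracks, fractions=(0.10, 0.15, 0.20, 0.25),
                     params: RegistrationParams | None = None):
    """Registration accuracy vs downscale level.

    For each fraction the stack is downscaled (cubic), registered with
    the matching lattice spacing, and the stepwise error of the tracks
    evaluated. Wall time is logged for information only and never
    asserted. Returns a DataFrame with one row per fraction.
    """
    import time

    import pandas as pd

    from .registration import downscale_for_registration, register_sequence

    rows = []
    for frac in fractions:
        small, grid_vox = downscale_for_registration(stack, frac)
        p = params or RegistrationParams()
        p = RegistrationParams(
            grid_spacing=grid_vox * float(small.voxel_size[0]),
            lambda_reg=p.lambda_reg, tol=p.tol, max_iter=p.max_iter,
            levels=p.levels,
        )
        t0 = time.perf_counter()
        tset = register_sequence(small, p, bidirectional=True)
        wall = time.perf_counter() - t0
        rep = stepwise_error(tracks, tset)
        rows.append(
            {
                "fraction": frac,
                "grid_voxels": grid_vox,
                "voxel_um": float(small.voxel_size[0]),
                "mean_stepwise_um": rep.overall_mean(),
                "median_stepwise_um": float(np.nanmedian(rep.errors)),
                "wall_seconds": wall,
            }
        )
    return pd.DataFrame(rows)


def mixing_control(coherent_tracks, mixing_tracks, tset_c: TransformSet,
                   tset_m: TransformSet, bin_minutes: float = 20.0):
    """Error-growth comparison: coherent tissue vs mixing tissue.

    Fits the slope of median accumulated error vs time for each regime
    and returns ``(slope_mixing, slope_coherent, ratio)``. Lagrangian
    propagation assumes tissue-like spatiotemporal continuity; on a
    mixing tissue the accumulated error must grow much faster, which is
    the method's documented domain limit.
    """
    if coherent_tracks.n_frames < 4 or mixing_tracks.n_frames < 4:
        raise ValueError("span too short (<3 intervals)")
    rep_c = accumulated_error(coherent_tracks, tset_c)
    rep_m = accumulated_error(mixing_tracks, tset_m)
    m_c = error_slope(rep_c, bin_minutes)
    m_m = error_slope(rep_m, bin_minutes)
    ratio = m_m / m_c if m_c != 0 else np.inf
    return m_m, m_c, float(ratio)
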