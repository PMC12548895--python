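"""Reading, writing and preprocessing of 3D+t hyperstacks and binary masks.

Canonical conventions used throughout the package:

* axis order ``(x, y, z, t)`` (a channel axis, when present, comes last:
  ``(x, y, z, t, c)``);
* 0-based voxel indices; world coordinates in um via ``voxel_size``;
* intensities of preprocessed frames rescaled to [0, 1] per frame.

The helpers :meth:`Hyperstack.voxel_to_world` / ``world_to_voxel`` are the
single authority for the voxel <-> um conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import nibabel as nib
import tifffile
from scipy import ndimage
from skimage.registration import phase_cross_correlation

__all__ = [
    "Hyperstack",
    "BinaryMask",
    "load_hyperstack",
    "save_hyperstack",
    "merge_channels",
    "resample_isotropic",
    "preprocess",
    "correct_drift",
    "fill_holes",
    "load_mask",
    "save_mask",
]

MERGE_MODES = ("sum-clip", "max")


@dataclass
class Hyperstack:
    """3D+t intensity volume with voxel/time metadata.

    ``intensity`` is indexed ``(x, y, z, t)`` for single-channel data and
    ``(x, y, z, t, c)`` with 2 channels before merging.
    """

    intensity: np.ndarray
    voxel_size: np.ndarray  # um per voxel along x, y, z
    time_step: float = 1.0  # minutes between frames
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity)
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, float), (3,)
        ).copy()
        if self.intensity.ndim not in (4, 5):
            raise ValueError("intensity must be 4D (x,y,z,t) or 5D (x,y,z,t,c)")

    @property
    def n_channels(self) -> int:
        return 1 if self.intensity.ndim == 4 else self.intensity.shape[4]

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[3]

    @property
    def shape3(self) -> tuple:
        return self.intensity.shape[:3]

    @property
    def isotropic(self) -> bool:
        return bool(np.ptp(self.voxel_size) < 1e-9)

    def frame(self, t: int) -> np.ndarray:
        if self.intensity.ndim != 4:
            raise ValueError("merge channels before frame access")
        return self.intensity[..., t]

    def voxel_to_world(self, idx) -> np.ndarray:
        return np.asarray(idx, float) * self.voxel_size

    def world_to_voxel(self, pos) -> np.ndarray:
        return np.asarray(pos, float) / self.voxel_size


@dataclass
class BinaryMask:
    """Binary tissue segmentation of one frame, in the hyperstack voxel grid.

    ``origin`` is the um world position of voxel (0,0,0); masks produced
    from a hyperstack have origin 0.
    """

    voxels: np.ndarray
    voxel_size: np.ndarray
    frame_index: int | None = None
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels).astype(bool)
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, float), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, float)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be a 3D boolean grid")


# ---------------------------------------------------------------------------
# I/O

def load_hyperstack(path, axis_order: str = "xyzt",
                    voxel_size=(1.0, 1.0, 1.0), time_step: float = 1.0
                    ) -> Hyperstack:
    """Load a multi-page TIFF as a Hyperstack.

    ``axis_order`` declares the on-disk axis layout using the letters
    x, y, z, t, c (e.g. ImageJ hyperstacks are commonly ``tzcyx`` or
    ``tzyx``); the data is transposed to the canonical (x, y, z, t[, c])
    order. A time axis is required.
    """
    arr = tifffile.imread(str(path))
    axis_order = axis_order.lower()
    if "t" not in axis_order:
        raise ValueError("time axis required: declare 't' in axis_order")
    if arr.ndim != len(axis_order):
        raise ValueError(
            f"axis-order/shape mismatch: data is {arr.ndim}D "
            f"but axis_order {axis_order!r} declares {len(axis_order)} axes"
        )
    want = "xyzt" if "c" not in axis_order else "xyztc"
    perm = [axis_order.index(a) for a in want]
    arr = np.transpose(arr, perm)
    return Hyperstack(
        intensity=arr, voxel_size=voxel_size, time_step=time_step,
        meta={"path": str(path), "axis_order": axis_order},
    )


def save_hyperstack(stack: Hyperstack, path) -> None:
    """Write as multi-page TIFF in ``tzyx`` (ImageJ-friendly) page order."""
    arr = stack.intensity
    if arr.ndim == 5:
        arr = np.transpose(arr, (3, 2, 4, 1, 0))  # t z c y x
    else:
        arr = np.transpose(arr, (3, 2, 1, 0))  # t z y x
    tifffile.imwrite(str(path), np.ascontiguousarray(arr))


def load_mask(path) -> BinaryMask:
    """Read a NIfTI mask; voxel size from the affine diagonal."""
    img = nib.load(str(path))
    vox = np.asarray(img.dataobj) > 0
    aff = img.affine
    voxel_size = np.abs(np.diag(aff)[:3])
    origin = aff[:3, 3]
    return BinaryMask(voxels=vox, voxel_size=voxel_size, origin=origin)


def save_mask(mask: BinaryMask, path) -> None:
    aff = np.diag(list(mask.voxel_size) + [1.0])
    aff[:3, 3] = mask.origin
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), aff)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Preprocessing

def merge_channels(stack: Hyperstack, mode: str = "sum-clip") -> Hyperstack:
    """Combine a 2-channel stack into one channel, rescaled to [0, 1].

    ``sum-clip`` adds the channels and clips at the joint maximum;
    ``max`` takes the voxelwise maximum. Either way the output range is
    rescaled to [0, 1] per frame.
    """
    if stack.n_channels < 2:
        raise ValueError("merge_channels requires a 2-channel stack")
    if mode not in MERGE_MODES:
        raise ValueError(
            f"unknown merge mode {mode!r}; supported: {', '.join(MERGE_MODES)}"
        )
    data = stack.intensity.astype(float)
    if mode == "sum-clip":
        merged = np.clip(data.sum(axis=4), 0, None)
    else:
        merged = data.max(axis=4)
    merged = _rescale_frames(merged)
    return Hyperstack(
        intensity=merged, voxel_size=stack.voxel_size,
        time_step=stack.time_step, meta={**stack.meta, "merged": mode},
    )


def _rescale_frames(data: np.ndarray) -> np.ndarray:
    """Per-frame min-max rescale to [0,1]; constant frames map to zeros."""
    out = np.empty_like(data, dtype=float)
    for t in range(data.shape[3]):
        frame = data[..., t]
        lo, hi = frame.min(), frame.max()
        out[..., t] = 0.0 if hi == lo else (frame - lo) / (hi - lo)
    return out


def resample_isotropic(stack: Hyperstack) -> Hyperstack:
    """Nearest-neighbour resampling of the z axis to the in-plane voxel size.

    Anisotropic voxels [a, a, b] (b >= a) become [a, a, a]; the z extent
    grows by b/a. Nearest-neighbour keeps the original intensity value
    set (no interpolated values are introduced). In-plane anisotropy is
    not supported.
    """
    a_x, a_y, b = stack.voxel_size
    if abs(a_x - a_y) > 1e-9:
        raise ValueError("in-plane anisotropy (x != y) unsupported")
    if stack.isotropic:
        return stack
    if b < a_x:
        raise ValueError("z voxel size smaller than in-plane size unsupported")
    nz = stack.intensity.shape[2]
    new_nz = int(round(nz * b / a_x))
    # nearest-neighbour index lookup along z
    src = np.clip(
        np.round((np.arange(new_nz) + 0.5) * nz / new_nz - 0.5).astype(int),
        0, nz - 1,
    )
    data = stack.intensity[:, :, src, ...]
    return Hyperstack(
        intensity=data, voxel_size=(a_x, a_x, a_x),
        time_step=stack.time_step, meta={**stack.meta, "resampled": True},
    )


def preprocess(stack: Hyperstack, sigma: float = 0.5, crop=None,
               rotate90_y: bool = False) -> Hyperstack:
    """Standard frame preparation before motion estimation.

    Optional crop (pairs of (lo, hi) voxel bounds per axis), 3D Gaussian
    smoothing with ``sigma`` voxels (0.5 by default; 0 disables), and a
    per-frame intensity rescale to [0, 1] which also mitigates
    photobleaching. ``rotate90_y`` records a 90-degree rotation about the
    y axis in the metadata after applying it.
    """
    if not stack.isotropic:
        raise ValueError("preprocess expects an isotropic stack")
    data = stack.intensity.astype(float)
    if crop is not None:
        (x0, x1), (y0, y1), (z0, z1) = crop
        shape = data.shape
        if not (0 <= x0 < x1 <= shape[0] and 0 <= y0 < y1 <= shape[1]
                and 0 <= z0 < z1 <= shape[2]):
            raise ValueError("crop box outside volume")
        data = data[x0:x1, y0:y1, z0:z1, ...]
    if sigma > 0:
        out = np.empty_like(data)
        for t in range(data.shape[3]):
            out[..., t] = ndimage.gaussian_filter(data[..., t], sigma=sigma)
        data = out
    if rotate90_y:
        data = np.rot90(data, k=1, axes=(0, 2))
    data = _rescale_frames(data)
    meta = {**stack.meta, "sigma": sigma, "rotated90_y": rotate90_y}
    return Hyperstack(
        intensity=data, voxel_size=stack.voxel_size,
        time_step=stack.time_step, meta=meta,
    )


def correct_drift(stack: Hyperstack):
    """Remove rigid stage drift by translational phase correlation.

    Each frame is aligned to the previous corrected frame; returns the
    corrected stack and the per-frame cumulative shift table (voxels).
    """
    if stack.n_frames < 2:
        raise ValueError("drift correction needs at least 2 frames")
    data = stack.intensity.astype(float)
    out = data.copy()
    shifts = np.zeros((stack.n_frames, 3))
    for t in range(1, stack.n_frames):
        # incremental shift between raw consecutive frames (no resampled
        # borders in the correlation), accumulated into the applied shift
        inc, _, _ = phase_cross_correlation(
            data[..., t - 1], data[..., t], upsample_factor=10
        )
        shifts[t] = shifts[t - 1] + inc
        out[..., t] = ndimage.shift(data[..., t], shifts[t], order=1,
                                    mode="constant")
    return (
        Hyperstack(
            intensity=out, voxel_size=stack.voxel_size,
            time_step=stack.time_step,
            meta={**stack.meta, "drift_corrected": True},
        ),
        shifts,
    )


def fill_holes(mask: BinaryMask, max_gap: int = 1) -> BinaryMask:
    """Close enclosed background cavities up to ``max_gap`` voxels.

    Morphological closing with a (2*max_gap+1) box seals gaps of up to
    ``max_gap`` voxels, then fully enclosed cavities are filled. The
    foreground count never decreases; the operation is idempotent.
    """
    vox = mask.voxels
    if max_gap > 0:
        structure = np.ones((2 * max_gap + 1,) * 3, dtype=bool)
        closed = ndimage.binary_closing(vox, structure=structure)
        vox = vox | closed
    vox = ndimage.binary_fill_holes(vox)
    return BinaryMask(
        voxels=vox, voxel_size=mask.voxel_size,
        frame_index=mask.frame_index, origin=mask.origin,
    )
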