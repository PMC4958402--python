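"""3D ultrasound volume reconstruction from tracked 2D frames.

Pixel-nearest-neighbour (forward) reconstruction with mean compounding:
each in-sector pixel of each frame is mapped into CT coordinates through
the navigation chain CT_T_R . R_T_B . B_T_US and binned into its
containing voxel; a voxel's value is the mean of all contributions it
received.  Voxels that receive no pixel are NaN and are excluded from all
downstream statistics and segmentation.  An optional hole-filling pass
replaces empty voxels having at least 9 filled 26-neighbours with the mean
of those neighbours.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .image import ImageVolume, USFrame
from .transforms import RigidTransform, compose

__all__ = ["EmptyReconstructionError", "fill_holes", "reconstruct"]


class EmptyReconstructionError(ValueError):
    """No frames, or no pixel fell inside the reconstruction grid."""


def reconstruct(
    frames: list[USFrame],
    reg: RigidTransform,
    calib: RigidTransform,
    spacing: float = 0.5,
    grid_bounds: tuple[np.ndarray, np.ndarray] | None = None,
    hole_fill: bool = False,
    margin: float = 1.0,
    return_counts: bool = False,
) -> ImageVolume:
    """Reconstruct a volume in the CT frame from tracked US frames.

    Parameters
    ----------
    frames
        Tracked frames; each must carry a pose R_T_B.
    reg, calib
        Image-to-patient registration CT_T_R and probe calibration B_T_US.
    spacing
        Isotropic voxel size in mm (default 0.5).
    grid_bounds
        Optional (lo, hi) world bounds of the grid; by default the tight
        bounding box of all inserted pixels plus ``margin``.
    hole_fill
        Run the 26-neighbour hole-filling pass.
    return_counts
        Also return the per-voxel contribution counts (before hole
        filling), for conservation checks.
    """
    if not frames:
        raise EmptyReconstructionError("no frames to reconstruct")
    all_pts = []
    all_vals = []
    for frame in frames:
        if frame.pose is None:
            raise ValueError("frame without a pose cannot be reconstructed")
        chain = compose(compose(reg, frame.pose), calib)
        pts_us, vals = frame.us_points()
        all_pts.append(pts_us @ chain.rotation.T + chain.translation)
        all_vals.append(vals)
    pts = np.vstack(all_pts)
    vals = np.concatenate(all_vals).astype(np.float64)

    if grid_bounds is None:
        lo = pts.min(axis=0) - margin
        hi = pts.max(axis=0) + margin
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in grid_bounds)
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    origin = lo

    idx = np.round((pts - origin) / spacing).astype(int)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    if not np.any(inside):
        raise EmptyReconstructionError("all pixels fall outside the grid")
    idx = idx[inside]
    vals = vals[inside]

    flat = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), tuple(shape))
    sums = np.zeros(int(np.prod(shape)))
    counts = np.zeros(int(np.prod(shape)), dtype=np.int64)
    np.add.at(sums, flat, vals)
    np.add.at(counts, flat, 1)

    out = np.full(int(np.prod(shape)), np.nan)
    filled = counts > 0
    out[filled] = sums[filled] / counts[filled]
    vol = ImageVolume(
        out.reshape(tuple(shape)).astype(np.float32),
        np.full(3, float(spacing)),
        origin,
        frame=reg.frame_to or "CT",
    )
    if hole_fill:
        vol = fill_holes(vol)
    if return_counts:
        return vol, counts.reshape(tuple(shape))
    return vol


def fill_holes(vol: ImageVolume, min_neighbors: int = 9) -> ImageVolume:
    """Fill empty (NaN) voxels that have >= ``min_neighbors`` filled
    26-neighbours with the mean of those neighbours (single pass)."""
    v = np.asarray(vol.voxels, dtype=np.float64)
    filled = np.isfinite(v)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    neighbor_count = ndimage.convolve(
        filled.astype(np.float64), kernel, mode="constant", cval=0.0
    )
    neighbor_sum = ndimage.convolve(
        np.where(filled, v, 0.0), kernel, mode="constant", cval=0.0
    )
    fillable = (~filled) & (neighbor_count >= min_neighbors)
    out = v.copy()
    out[fillable] = neighbor_sum[fillable] / neighbor_count[fillable]
    return ImageVolume(out.astype(np.float32), vol.spacing, vol.origin, frame=vol.frame)
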