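"""Closed-form point-based rigid registration.

Solves the orthogonal Procrustes problem constrained to proper rotations:
given index-matched source and destination point sets, find the rigid
transform T minimizing sum_i ||T . src_i - dst_i||^2.  The solver is the
SVD of the centred cross-covariance with a sign correction on the smallest
singular vector (the Arun/Umeyama family, without scale): both spaces are
metric millimetres, so only rotation and translation are estimated.

The same solver serves two roles in the pipeline: image-to-patient fiducial
registration (producing CT_T_R) and the final solve of the ultrasound probe
calibration (producing B_T_US).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transforms import Point3, RigidTransform, apply

__all__ = [
    "DegenerateConfigurationError",
    "RegistrationResult",
    "register_image_to_patient",
    "rigid_register",
    "target_registration_error",
]


class DegenerateConfigurationError(ValueError):
    """Too few points or a collinear configuration: rotation unrecoverable."""


def _as_array(points, name: str) -> np.ndarray:
    if len(points) and isinstance(points[0], Point3):
        arr = np.array([p.xyz for p in points], dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"{name} must be an (N, 3) point set, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite coordinates")
    return arr


@dataclass(frozen=True)
class RegistrationResult:
    """A fitted rigid transform with its residual diagnostics.

    ``fre_rms`` is the root-mean-square fiducial registration error, i.e.
    the RMS of ``per_point_residuals`` (per-point distances ||T.src - dst||
    in mm after the fit).  ``condition_number`` is the ratio of largest to
    smallest singular value of the centred source set; near-planar
    configurations (e.g. the in-plane calibration points) make one
    rotational degree of freedom weakly determined, which this flags.
    """

    transform: RigidTransform
    fre_rms: float
    per_point_residuals: np.ndarray
    condition_number: float

    @property
    def n_points(self) -> int:
        return len(self.per_point_residuals)


def rigid_register(
    source,
    destination,
    frame_from: str | None = None,
    frame_to: str | None = None,
) -> RegistrationResult:
    """Least-squares rigid transform mapping ``source`` onto ``destination``.

    Parameters
    ----------
    source, destination
        Index-matched point sets (lists of :class:`Point3` or (N, 3)
        arrays), N >= 3, source not all collinear.

    Returns
    -------
    RegistrationResult
        Proper-rotation rigid fit with per-point residuals and FRE.

    Raises
    ------
    DegenerateConfigurationError
        Fewer than 3 points, length mismatch, or (near-)collinear source.
    """
    src = _as_array(source, "source")
    dst = _as_array(destination, "destination")
    if src.shape != dst.shape:
        raise DegenerateConfigurationError(
            f"point sets differ in length: {src.shape[0]} vs {dst.shape[0]}"
        )
    n = src.shape[0]
    if n < 3:
        raise DegenerateConfigurationError(f"need >= 3 correspondences, got {n}")

    src_c = src - src.mean(axis=0)
    dst_c = dst - dst.mean(axis=0)

    sv_src = np.linalg.svd(src_c, compute_uv=False)
    # collinear: second singular value vanishes relative to the first
    if sv_src[1] <= 1e-9 * max(sv_src[0], 1.0):
        raise DegenerateConfigurationError(
            "source points are collinear; rotation about the line is undetermined"
        )
    condition_number = sv_src[0] / sv_src[2] if sv_src[2] > 0 else np.inf

    h = src_c.T @ dst_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    # sign correction on the smallest singular vector keeps det(R) = +1
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = dst.mean(axis=0) - rot @ src.mean(axis=0)
    transform = RigidTransform.from_rotation_translation(
        rot, t, frame_from=frame_from, frame_to=frame_to
    )

    residuals = np.linalg.norm(apply(transform, src) - dst, axis=1)
    fre_rms = float(np.sqrt(np.mean(residuals**2)))
    return RegistrationResult(transform, fre_rms, residuals, float(condition_number))


def register_image_to_patient(ct_fiducials, tracked_fiducials) -> RegistrationResult:
    """Fiducial-based image-to-patient registration CT_T_R.

    ``ct_fiducials`` are the fiducial positions pinpointed in the CT volume;
    ``tracked_fiducials`` the same fiducials localized with the tracked
    pointer, expressed relative to the phantom reference sensor.  The fit
    maps reference-sensor coordinates into CT coordinates, so the tracked
    set is the source and the CT set the destination.  Correspondence is by
    index; no automatic matching is attempted.
    """
    return rigid_register(
        tracked_fiducials, ct_fiducials, frame_from="R_phantom", frame_to="CT"
    )


def target_registration_error(
    result: RegistrationResult, probe_points_src, probe_points_dst
) -> np.ndarray:
    """Per-point error ||T.src - dst|| (mm) at points not used in the fit."""
    src = _as_array(probe_points_src, "probe_points_src")
    dst = _as_array(probe_points_dst, "probe_points_dst")
    if src.shape != dst.shape:
        raise ValueError(
            f"probe point sets differ in length: {src.shape[0]} vs {dst.shape[0]}"
        )
    return np.linalg.norm(apply(result.transform, src) - dst, axis=1)
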