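"""Ultrasound probe calibration from robot-swept sphere recordings.

The probe calibration B_T_US is the fixed rigid transform from the 2D US
image plane to the EM sensor mounted on the probe.  It is estimated by
imaging a small plastic sphere (diameter 11.5 mm) of known position p_R
relative to a reference sensor on a calibration arm.  The sphere is swept
slowly (1 mm/s) through the image plane, forward and back, at nine
positions spread over the plane — 18 recordings in all.  For each
recording:

1. every frame's sphere cross-section is localized with an edge-detection +
   least-squares circle fit (:func:`fit_circle`);
2. the plane-crossing frame is the one with the largest fitted radius — the
   chord radius r(d) = sqrt(R^2 - d^2) of a sphere cut |d| mm off-centre
   peaks exactly when the centre lies in the plane
   (:func:`find_crossing_frame`);
3. the sphere centre is expressed in the probe-sensor frame as
   p_B = (R_T_B)^-1 . p_R using the tracked pose of that frame
   (:func:`target_in_probe_frame`).

The 18 correspondences {p_US = (x, y, 0)} <-> {p_B} are then solved
closed-form with the same SVD registration used for image-to-patient
registration (:func:`solve_calibration`).  Because all source points lie in
the z = 0 plane, rotation about the plane normal is the best-conditioned
DOF and the fit's condition number is reported so degenerate protocols are
visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .image import SectorGeometry, USFrame
from .registration import RegistrationResult, rigid_register
from .transforms import Point3, RigidTransform, apply, invert

__all__ = [
    "CalibrationRecording",
    "CalibrationResult",
    "ImplausibleFitWarning",
    "SphereNotVisibleError",
    "SphereObservation",
    "SweepMissedPlaneError",
    "calibrate",
    "find_crossing_frame",
    "fit_circle",
    "solve_calibration",
    "target_in_probe_frame",
]


def _lsq_circle(points: np.ndarray) -> tuple[float, float, float]:
    """Algebraic least-squares circle (Kasa fit) through (N, 2) points.

    Linear in the parameters, exact for noise-free circles, and unbiased
    for full symmetric rims; adequate here because rim pixels densely
    cover an annulus of known, small thickness.
    """
    x, y = points[:, 0], points[:, 1]
    a = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    (cx, cy, c), *_ = np.linalg.lstsq(a, b, rcond=None)
    radius = float(np.sqrt(c + cx**2 + cy**2))
    return float(cx), float(cy), radius


class SphereNotVisibleError(ValueError):
    """No edge points above threshold: the sphere is not in this frame."""


class SweepMissedPlaneError(ValueError):
    """No frame of the recording shows the sphere: the sweep missed the plane."""


class ImplausibleFitWarning(UserWarning):
    """Fitted circle radius deviates > 50% from the nominal sphere radius."""


@dataclass
class CalibrationRecording:
    """One sweep of the sphere through the US plane (frames + poses).

    18 recordings make up the default protocol: position_index 1..9, each
    swept forward and reverse.
    """

    frames: list[USFrame]
    sweep_id: int
    direction: str  # "forward" | "reverse"
    position_index: int
    true_crossing_time: float | None = None  # simulator ground truth, if known

    def __post_init__(self) -> None:
        if len(self.frames) < 3:
            raise ValueError(f"recording needs >= 3 frames, got {len(self.frames)}")
        ts = np.array([f.timestamp for f in self.frames])
        if not np.all(np.diff(ts) > 0):
            raise ValueError("frame timestamps must be strictly increasing")
        if any(f.pose is None for f in self.frames):
            raise ValueError("every frame must carry a synchronized pose")
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"direction must be forward|reverse: {self.direction}")


@dataclass
class SphereObservation:
    """The localized sphere at its plane crossing, in both US and B frames."""

    crossing_frame_index: int
    center_us: Point3  # (x, y, 0) in the US image plane, mm
    fitted_radius: float
    p_b: Point3 | None = None  # sphere centre in the probe-sensor frame
    radius_error: float | None = None  # |fitted - nominal|, quality metric


@dataclass
class CalibrationResult:
    """The solved probe calibration B_T_US with its fit diagnostics."""

    b_t_us: RigidTransform
    residual_rms: float
    n_points: int
    condition_number: float
    per_point_residuals: np.ndarray = field(default_factory=lambda: np.empty(0))


def fit_circle(
    image: np.ndarray,
    geometry: SectorGeometry,
    nominal_radius: float,
    edge_threshold_frac: float = 0.8,
    min_edge_points: int = 8,
) -> tuple[np.ndarray, float]:
    """Least-squares circle through the bright sphere rim of one frame.

    Edge pixels are those within the sector mask whose intensity exceeds
    ``edge_threshold_frac`` of the frame peak (a high percentile, robust to
    noise outliers); the default 0.8 sits between the mid-gray sphere
    interior and the bright rim so only rim pixels are fitted.  Their
    physical in-plane coordinates are fitted with an algebraic
    least-squares circle.  Mirrors the manual procedure of adjusting a
    virtual circle of the sphere's diameter until it matches the imaged
    rim, but automated for reproducibility.

    Returns
    -------
    (center, radius)
        Circle centre (x, y) in mm in the US plane, and radius in mm.

    Raises
    ------
    SphereNotVisibleError
        If fewer than ``min_edge_points`` edge pixels are found.

    Warns
    -----
    ImplausibleFitWarning
        If the fitted radius deviates more than 50% from ``nominal_radius``.
    """
    img = np.asarray(image, dtype=float)
    mask = geometry.sector_mask()
    in_sector = img[mask]
    if in_sector.size == 0:
        raise SphereNotVisibleError("empty sector")
    # a sphere-free frame is near-uniform background: no bright rim contrast
    median = np.median(in_sector)
    peak = np.percentile(in_sector, 99.5)
    if peak - median < 0.2 * max(peak, 1e-12):
        raise SphereNotVisibleError("frame is blank inside the sector (no contrast)")
    edges = mask & (img >= edge_threshold_frac * peak)
    n_edge = int(edges.sum())
    if n_edge < min_edge_points:
        raise SphereNotVisibleError(
            f"only {n_edge} edge pixels above threshold (need {min_edge_points})"
        )
    x, y = geometry.pixel_coordinates()
    data = np.column_stack([x[edges], y[edges]])
    cx, cy, radius = _lsq_circle(data)
    if nominal_radius > 0 and abs(radius - nominal_radius) > 0.5 * nominal_radius:
        warnings.warn(
            f"fitted radius {radius:.2f} mm deviates > 50% from nominal "
            f"{nominal_radius:.2f} mm",
            ImplausibleFitWarning,
            stacklevel=2,
        )
    return np.array([cx, cy]), float(radius)


def find_crossing_frame(
    rec: CalibrationRecording,
    nominal_radius: float,
    p_r: Point3 | None = None,
) -> SphereObservation:
    """Locate the frame in which the sphere centre crosses the image plane.

    The in-plane cross-section radius of a sphere of radius R whose centre
    is |d| mm off-plane is sqrt(R^2 - d^2), maximal at d = 0; the crossing
    frame is therefore the frame with the largest fitted radius.  On a
    plateau of (numerically) equal maxima the middle frame is taken.  If
    ``p_r`` (sphere centre relative to the calibration-arm reference) is
    given, the observation also carries p_B via that frame's tracked pose.
    """
    radii = np.full(len(rec.frames), -np.inf)
    centers = np.zeros((len(rec.frames), 2))
    with warnings.catch_warnings():
        # small chords near sweep entry/exit are expected, not implausible
        warnings.simplefilter("ignore", ImplausibleFitWarning)
        for i, frame in enumerate(rec.frames):
            try:
                centers[i], radii[i] = fit_circle(
                    frame.image, frame.geometry, nominal_radius
                )
            except SphereNotVisibleError:
                continue
    if not np.any(np.isfinite(radii)):
        raise SweepMissedPlaneError(
            f"sweep {rec.sweep_id}: sphere never visible; the sweep missed the plane"
        )
    r_max = radii.max()
    plateau = np.flatnonzero(radii >= r_max - 1e-9)
    idx = int(plateau[(len(plateau) - 1) // 2])
    center_us = Point3(np.array([centers[idx, 0], centers[idx, 1], 0.0]), frame="US")
    p_b = None
    if p_r is not None:
        p_b = target_in_probe_frame(rec.frames[idx].pose, p_r)
    return SphereObservation(
        crossing_frame_index=idx,
        center_us=center_us,
        fitted_radius=float(r_max),
        p_b=p_b,
        radius_error=abs(float(r_max) - nominal_radius),
    )


def target_in_probe_frame(pose: RigidTransform, p_r: Point3) -> Point3:
    """Sphere centre in the probe-sensor frame: p_B = (R_T_B)^-1 . p_R."""
    return apply(invert(pose), p_r)


def solve_calibration(observations: list[SphereObservation]) -> CalibrationResult:
    """Closed-form solve of B_T_US from plane-crossing observations.

    Source points are the in-plane sphere centres embedded as (x, y, 0);
    destination points are the corresponding p_B.  The rigid least-squares
    fit minimizes the total squared distance between the two 18-point sets.
    """
    if any(o.p_b is None for o in observations):
        raise ValueError("all observations must carry p_B (pass p_r when localizing)")
    src = [o.center_us for o in observations]
    dst = [o.p_b for o in observations]
    result: RegistrationResult = rigid_register(src, dst, frame_from="US", frame_to="B")
    return CalibrationResult(
        b_t_us=result.transform,
        residual_rms=result.fre_rms,
        n_points=result.n_points,
        condition_number=result.condition_number,
        per_point_residuals=result.per_point_residuals,
    )


def calibrate(
    recordings,
    p_r: Point3,
    sphere_diameter: float = 11.5,
) -> tuple[CalibrationResult, list[SphereObservation]]:
    """Full calibration: localize every recording's crossing, then solve.

    ``recordings`` may be any iterable of :class:`CalibrationRecording` —
    a lazy generator keeps only one sweep's frames in memory at a time.
    """
    nominal_radius = sphere_diameter / 2.0
    observations = [
        find_crossing_frame(rec, nominal_radius, p_r=p_r) for rec in recordings
    ]
    return solve_calibration(observations), observations
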