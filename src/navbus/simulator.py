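"""Deterministic simulator of the gelatin airway phantom and its acquisitions.

This module stands in for all hardware: it generates the phantom scene (a
Y-shaped trachea/main-bronchi centerline, 11 silicone-tumour-like targets
named after IASLC mediastinal stations, 10 registration fiducials on the
container), a synthetic CT volume, 40 Hz electromagnetic tracking streams
with the tracker's stated 0.48 mm accuracy, convex-sector B-mode frames,
complete navigated-EBUS acquisition sessions, and the 18-sweep sphere
protocol used for probe calibration.

Everything is a pure function of (configuration, seed).  The world frame is
the CT frame of the noise-free phantom; all ground-truth transforms are
generated from it and retained alongside the data so that the pipeline
under test can be scored against them, while the pipeline itself only sees
the simulated measurements.

US frames are geometric tissue-class renderings, not physical speckle
simulations: target boundaries are bright rings, interiors mid-gray,
gelatin dark.  The pipeline only needs localizable boundaries; acoustic
realism is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .image import ImageVolume, SectorGeometry, USFrame
from .transforms import Point3, RigidTransform, identity, invert

__all__ = [
    "CT_INTENSITY",
    "US_INTENSITY",
    "EbusAcquisition",
    "EbusSession",
    "NoiseModel",
    "Phantom",
    "SyncError",
    "Target",
    "TrackingStream",
    "build_phantom",
    "default_calibration_truth",
    "default_sphere_offset",
    "iter_calibration_sweeps",
    "render_ct",
    "render_sector_frame",
    "render_us_frame",
    "simulate_calibration_session",
    "simulate_ebus_session",
    "simulate_tracking",
]

#: CT tissue-class intensities: Hounsfield-like contrast so threshold
#: segmentation behaves like it does on real data; values are conventions.
CT_INTENSITY = {"background": 50.0, "lumen": -1000.0, "target": 300.0, "fiducial": 1000.0}

#: B-mode rendering intensities (8-bit-like scale).
US_INTENSITY = {"outside": 0.0, "background": 30.0, "interior": 150.0, "ring": 255.0}

_RING_HALF_MM = 0.4  # half-thickness of the rendered boundary ring
_TRACKING_RATE_HZ = 40.0  # tracker sampling frequency
_FIDUCIAL_RADIUS_MM = 1.5

#: station labels of the 11 phantom targets
STATION_LABELS = (
    "2R1", "2R2", "2L1", "2L2", "4R1", "4R2", "4L1", "4L2", "7", "10L", "11R",
)


# --------------------------------------------------------------------------
# noise
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise configuration, fully determined by ``seed``.

    ``tracking_sigma`` is the per-axis positional noise; its default
    0.48/sqrt(3) mm makes the 3D positional RMS equal the tracker's stated
    0.48 mm accuracy.  ``rotation_sigma_deg`` (default 0.1 deg, an assumed
    value) perturbs orientations via small random rotation vectors.
    ``pixel_noise`` is additive Gaussian image noise as a fraction of the
    rendering peak.
    """

    tracking_sigma: float = 0.48 / np.sqrt(3.0)
    rotation_sigma_deg: float = 0.1
    pixel_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.tracking_sigma, self.rotation_sigma_deg, self.pixel_noise) < 0:
            raise ValueError("noise sigmas must be non-negative")

    @classmethod
    def zero(cls, seed: int = 0) -> "NoiseModel":
        return cls(tracking_sigma=0.0, rotation_sigma_deg=0.0, pixel_noise=0.0, seed=seed)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def perturb_pose(self, pose: RigidTransform, rng: np.random.Generator) -> RigidTransform:
        """Perturb a pose by the positional and rotational noise model."""
        if self.tracking_sigma == 0.0 and self.rotation_sigma_deg == 0.0:
            return pose
        t = pose.translation + rng.normal(0.0, self.tracking_sigma, size=3)
        r = pose.rotation
        if self.rotation_sigma_deg > 0.0:
            rotvec = rng.normal(0.0, np.deg2rad(self.rotation_sigma_deg), size=3)
            r = _rotvec_matrix(rotvec) @ r
        return RigidTransform.from_rotation_translation(
            r, t, frame_from=pose.frame_from, frame_to=pose.frame_to
        )


def _rotvec_matrix(rotvec: np.ndarray) -> np.ndarray:
    """Rotation matrix of a rotation vector (Rodrigues)."""
    angle = float(np.linalg.norm(rotvec))
    if angle < 1e-15:
        return np.eye(3)
    k = rotvec / angle
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * kx + (1 - np.cos(angle)) * kx @ kx


# --------------------------------------------------------------------------
# phantom
# --------------------------------------------------------------------------
@dataclass
class Target:
    """One silicone-tumour-like target: an axis-aligned ellipsoid (mm)."""

    label: str
    center: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.radii = np.asarray(self.radii, dtype=float).reshape(3)
        if np.any(self.radii <= 0):
            raise ValueError(f"target {self.label}: radii must be positive")


@dataclass
class Phantom:
    """Ground-truth phantom scene in world (= noise-free CT) coordinates."""

    centerline: np.ndarray  # (N, 3) polyline vertices, mm
    centerline_radii: np.ndarray  # (N-1,) lumen tube radius per segment, mm
    targets: list[Target]
    fiducials: np.ndarray  # (10, 3) on the container surface
    reference_pose: RigidTransform  # world_T_Rphantom (= ground-truth CT_T_R)
    container_bounds: tuple[np.ndarray, np.ndarray]

    def centerline_samples(self, step: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """Densely sampled centerline points and unit tangents."""
        pts, tans = [], []
        for a, b in zip(self.centerline[:-1], self.centerline[1:]):
            seg = b - a
            length = np.linalg.norm(seg)
            n = max(int(np.ceil(length / step)), 1)
            ts = np.linspace(0.0, 1.0, n, endpoint=False)
            pts.append(a + ts[:, None] * seg)
            tans.append(np.tile(seg / length, (n, 1)))
        pts.append(self.centerline[-1:])
        tans.append(tans[-1][-1:])
        return np.vstack(pts), np.vstack(tans)

    def nearest_centerline_point(self, point: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest densely-sampled centerline point and its unit tangent."""
        pts, tans = self.centerline_samples(step=0.5)
        d = np.linalg.norm(pts - np.asarray(point, dtype=float), axis=1)
        i = int(np.argmin(d))
        return pts[i], tans[i]

    def distance_to_centerline(self, point: np.ndarray) -> float:
        return float(
            np.linalg.norm(self.nearest_centerline_point(point)[0] - point)
        )


def _default_centerline() -> tuple[np.ndarray, np.ndarray]:
    # trachea descending, bifurcating into right (-x) and left (+x) bronchi
    trachea = np.array([[0.0, 0.0, 115.0], [0.0, 0.0, 55.0]])
    right = np.array([[-35.0, -5.0, 25.0]])
    left = np.array([[30.0, -5.0, 30.0]])
    # polyline: top -> carina -> right tip, then carina -> left tip is a
    # second branch; represent as one vertex list with per-segment radii via
    # explicit segment list
    vertices = np.vstack([trachea, right, trachea[1:], left])
    radii = np.array([6.0, 4.5, 0.0, 4.5])  # zero-radius joins carry no lumen
    return vertices, radii


_DEFAULT_TARGETS = [
    ("2R1", (-14.0, 6.0, 95.0), (5.0, 5.0, 5.0)),
    ("2R2", (-15.0, -8.0, 85.0), (5.0, 6.0, 5.0)),
    ("2L1", (14.0, 6.0, 95.0), (5.0, 5.0, 6.0)),
    ("2L2", (15.0, -8.0, 85.0), (6.0, 5.0, 5.0)),
    ("4R1", (-15.0, 5.0, 68.0), (5.0, 5.0, 5.0)),
    ("4R2", (-16.0, -7.0, 62.0), (5.0, 5.0, 6.0)),
    ("4L1", (14.0, 5.0, 68.0), (6.0, 5.0, 5.0)),
    ("4L2", (15.0, -7.0, 62.0), (5.0, 6.0, 5.0)),
    ("7", (0.0, -10.0, 45.0), (7.0, 6.0, 6.0)),
    ("10L", (28.0, 8.0, 38.0), (6.0, 5.0, 5.0)),
    ("11R", (-28.0, 8.0, 30.0), (5.0, 5.0, 5.0)),
]

_DEFAULT_FIDUCIALS = np.array(
    [
        [-55.0, -35.0, 10.0],
        [55.0, -35.0, 15.0],
        [-55.0, 35.0, 20.0],
        [55.0, 35.0, 25.0],
        [-55.0, 0.0, 60.0],
        [55.0, 0.0, 70.0],
        [0.0, -35.0, 100.0],
        [0.0, 35.0, 105.0],
        [-30.0, -35.0, 55.0],
        [30.0, 35.0, 40.0],
    ]
)

_DEFAULT_BOUNDS = (np.array([-55.0, -35.0, 0.0]), np.array([55.0, 35.0, 120.0]))


def _default_reference_pose() -> RigidTransform:
    axis = np.array([0.2, 0.3, 0.9])
    rot = _rotvec_matrix(axis / np.linalg.norm(axis) * np.deg2rad(25.0))
    return RigidTransform.from_rotation_translation(
        rot, (12.0, -8.0, 40.0), frame_from="R_phantom", frame_to="CT"
    )


def build_phantom(config: dict | None = None) -> Phantom:
    """Construct the phantom scene (defaults emulate the physical phantom).

    ``config`` keys (all optional): ``targets`` (list of {label, center,
    radii}), ``fiducials`` ((N, 3)), ``container_bounds``, ``jitter_mm``
    and ``seed`` (Gaussian jitter of the default target centres — a seeded
    layout variant), ``reference_pose`` (4x4 matrix).

    The default layout has the 11 station-labelled targets, 10 non-coplanar
    fiducials on the container and a Y-shaped airway centerline; invariants
    (targets inside the container, within 25 mm of the centerline and not
    intersecting the lumen) are validated and violations rejected.
    """
    config = dict(config or {})
    vertices, seg_radii = _default_centerline()

    target_spec = config.get("targets")
    if target_spec is None:
        target_spec = [
            {"label": lab, "center": c, "radii": r} for lab, c, r in _DEFAULT_TARGETS
        ]
        if config.get("jitter_mm"):
            rng = np.random.default_rng(config.get("seed", 0))
            for t in target_spec:
                t["center"] = np.asarray(t["center"]) + rng.normal(
                    0.0, float(config["jitter_mm"]), size=3
                )
    targets = [Target(t["label"], t["center"], t["radii"]) for t in target_spec]

    fiducials = np.asarray(config.get("fiducials", _DEFAULT_FIDUCIALS), dtype=float)
    fiducials = fiducials.reshape(-1, 3)
    # 0 fiducials is allowed (rendering-only phantoms); registration needs >= 3
    if fiducials.shape[0] in (1, 2):
        raise ValueError("need at least 3 fiducials for registration (or none)")

    bounds = config.get("container_bounds", _DEFAULT_BOUNDS)
    lo, hi = (np.asarray(b, dtype=float) for b in bounds)

    if "reference_pose" in config:
        ref = RigidTransform(
            np.asarray(config["reference_pose"], dtype=float),
            frame_from="R_phantom",
            frame_to="CT",
        )
    else:
        ref = _default_reference_pose()

    phantom = Phantom(vertices, seg_radii, targets, fiducials, ref, (lo, hi))

    # invariants
    for t in targets:
        if np.any(t.center < lo) or np.any(t.center > hi):
            raise ValueError(f"target {t.label} center {t.center} outside container")
        d = phantom.distance_to_centerline(t.center)
        if d > 25.0:
            raise ValueError(
                f"target {t.label} is {d:.1f} mm from the centerline (> 25 mm, "
                "not reachable by US)"
            )
    labels = [t.label for t in targets]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate target labels")
    if fiducials.shape[0] >= 4:
        centered = fiducials - fiducials.mean(axis=0)
        if np.linalg.svd(centered, compute_uv=False)[2] < 1e-9:
            raise ValueError("fiducials are coplanar; registration is ill-conditioned")
    return phantom


# --------------------------------------------------------------------------
# CT rendering
# --------------------------------------------------------------------------
def _axis_grids(origin, spacing, shape):
    return [origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)]


def _subbox(axes, lo, hi):
    """Index slices of the voxel grid covering world box [lo, hi]."""
    slices = []
    for a in range(3):
        i0 = int(np.searchsorted(axes[a], lo[a], side="left"))
        i1 = int(np.searchsorted(axes[a], hi[a], side="right"))
        slices.append(slice(max(i0 - 1, 0), min(i1 + 1, len(axes[a]))))
    return tuple(slices)


def render_ct(
    phantom: Phantom,
    spacing=(0.5, 0.5, 0.3),
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    margin: float = 5.0,
    max_voxels: int = 400_000_000,
) -> ImageVolume:
    """Voxelize the phantom into a synthetic CT volume.

    Gelatin background 50, airway lumen -1000, targets 300, fiducial
    markers 1000 (Hounsfield-like contrast); a voxel belongs to a target
    iff its centre lies inside the ellipsoid.  Default spacing is
    (0.5, 0.5, 0.3) mm — the 0.3 mm slice thickness of the phantom CT.
    Optional additive Gaussian noise (sigma in intensity units).
    """
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    lo, hi = phantom.container_bounds
    origin = lo - margin
    shape = np.ceil((hi - lo + 2 * margin) / spacing).astype(int) + 1
    if int(np.prod(shape)) > max_voxels:
        raise ValueError(
            f"volume of {np.prod(shape):.2e} voxels exceeds cap {max_voxels:.0e}; "
            "use coarser spacing"
        )
    vol = np.full(tuple(shape), CT_INTENSITY["background"], dtype=np.float32)
    axes = _axis_grids(origin, spacing, shape)

    # airway lumen: tube around each centerline segment
    for (a, b), radius in zip(
        zip(phantom.centerline[:-1], phantom.centerline[1:]), phantom.centerline_radii
    ):
        if radius <= 0:
            continue
        box_lo = np.minimum(a, b) - radius - 1.0
        box_hi = np.maximum(a, b) + radius + 1.0
        sl = _subbox(axes, box_lo, box_hi)
        xs, ys, zs = (axes[i][sl[i]] for i in range(3))
        px = xs[:, None, None]
        py = ys[None, :, None]
        pz = zs[None, None, :]
        d = b - a
        len2 = float(d @ d)
        t = ((px - a[0]) * d[0] + (py - a[1]) * d[1] + (pz - a[2]) * d[2]) / len2
        t = np.clip(t, 0.0, 1.0)
        dist2 = (
            (px - (a[0] + t * d[0])) ** 2
            + (py - (a[1] + t * d[1])) ** 2
            + (pz - (a[2] + t * d[2])) ** 2
        )
        vol[sl][dist2 <= radius**2] = CT_INTENSITY["lumen"]

    # targets: ellipsoid interiors
    for target in phantom.targets:
        sl = _subbox(axes, target.center - target.radii, target.center + target.radii)
        xs, ys, zs = (axes[i][sl[i]] for i in range(3))
        rho2 = (
            ((xs[:, None, None] - target.center[0]) / target.radii[0]) ** 2
            + ((ys[None, :, None] - target.center[1]) / target.radii[1]) ** 2
            + ((zs[None, None, :] - target.center[2]) / target.radii[2]) ** 2
        )
        vol[sl][rho2 <= 1.0] = CT_INTENSITY["target"]

    # fiducial markers: small bright spheres
    r_fid = _FIDUCIAL_RADIUS_MM
    for f in phantom.fiducials:
        sl = _subbox(axes, f - r_fid, f + r_fid)
        xs, ys, zs = (axes[i][sl[i]] for i in range(3))
        dist2 = (
            (xs[:, None, None] - f[0]) ** 2
            + (ys[None, :, None] - f[1]) ** 2
            + (zs[None, None, :] - f[2]) ** 2
        )
        vol[sl][dist2 <= r_fid**2] = CT_INTENSITY["fiducial"]

    if noise_sigma > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        vol = vol + rng.normal(0.0, noise_sigma, size=vol.shape).astype(np.float32)

    return ImageVolume(vol, spacing, origin, frame="CT")


# --------------------------------------------------------------------------
# tracking
# --------------------------------------------------------------------------
class SyncError(ValueError):
    """No tracking sample close enough in time to a requested timestamp."""


@dataclass
class TrackingStream:
    """Time-stamped rigid poses sampled at the tracker rate."""

    timestamps: np.ndarray
    poses: list[RigidTransform]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.timestamps) != len(self.poses):
            raise ValueError("timestamps and poses differ in length")
        if len(self.timestamps) == 0:
            raise ValueError("empty tracking stream")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.poses)

    def pose_at(self, t: float, tol: float = 1.0 / (2 * _TRACKING_RATE_HZ)) -> RigidTransform:
        """Nearest-timestamp pose; gaps beyond ``tol`` seconds are an error."""
        i = int(np.argmin(np.abs(self.timestamps - t)))
        if abs(self.timestamps[i] - t) > tol + 1e-12:
            raise SyncError(
                f"no tracking sample within {tol * 1e3:.1f} ms of t = {t:.4f} s"
            )
        return self.poses[i]


def simulate_tracking(
    path,
    t_span: tuple[float, float],
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
    rate: float = _TRACKING_RATE_HZ,
) -> TrackingStream:
    """Sample a continuous pose path at the tracker frequency (40 Hz).

    ``path`` is a callable t -> RigidTransform.  Samples cover the
    half-open interval [t0, t1) — one second of tracking yields exactly 40
    samples.  Each sample is perturbed by the noise model; with zero
    sigmas the path is returned exactly.
    """
    t0, t1 = t_span
    if t1 < t0:
        raise ValueError("empty time span")
    n = max(1, int(round((t1 - t0) * rate)))
    times = t0 + np.arange(n) / rate
    noise = noise or NoiseModel.zero()
    rng = rng if rng is not None else noise.rng()
    poses = [noise.perturb_pose(path(t), rng) for t in times]
    return TrackingStream(times, poses)


# --------------------------------------------------------------------------
# US frame rendering
# --------------------------------------------------------------------------
def render_sector_frame(
    world_t_us: RigidTransform,
    geometry: SectorGeometry,
    ellipsoids: list[tuple[np.ndarray, np.ndarray]],
    pixel_noise: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one convex-sector frame of a scene of world-frame ellipsoids.

    Pixels inside the sector see the tissue class at their world position
    (boundary ring bright, interior mid-gray, background dark); pixels
    outside the sector are zero.  Only pixels inside each ellipsoid's
    bounding window are classified — everything else is provably
    background.
    """
    mask = geometry.sector_mask()
    img = np.where(mask, US_INTENSITY["background"], US_INTENSITY["outside"]).astype(
        np.float32
    )
    us_t_world = invert(world_t_us)
    ny, nx = geometry.image_shape
    for center, radii in ellipsoids:
        center = np.asarray(center, dtype=float)
        radii = np.asarray(radii, dtype=float)
        c_us = us_t_world.rotation @ center + us_t_world.translation
        r_ext = float(radii.max()) + _RING_HALF_MM
        if abs(c_us[2]) > r_ext:
            continue  # ellipsoid does not intersect the image plane
        row0, col0 = geometry.pixel_index(c_us[0] - r_ext, c_us[1] - r_ext)
        row1, col1 = geometry.pixel_index(c_us[0] + r_ext, c_us[1] + r_ext)
        i0, i1 = max(int(np.floor(row0)), 0), min(int(np.ceil(row1)) + 1, ny)
        j0, j1 = max(int(np.floor(col0)), 0), min(int(np.ceil(col1)) + 1, nx)
        if i0 >= i1 or j0 >= j1:
            continue
        x, y = geometry.pixel_coordinates()
        xs = x[i0:i1, j0:j1]
        ys = y[i0:i1, j0:j1]
        pts_us = np.stack([xs, ys, np.zeros_like(xs)], axis=-1)
        pts_world = pts_us @ world_t_us.rotation.T + world_t_us.translation
        rho = np.sqrt((((pts_world - center) / radii) ** 2).sum(axis=-1))
        sub = img[i0:i1, j0:j1]
        submask = mask[i0:i1, j0:j1]
        interior = submask & (rho < 1.0)
        ring = submask & (np.abs(rho - 1.0) * radii.min() <= _RING_HALF_MM)
        sub[interior] = US_INTENSITY["interior"]
        sub[ring] = US_INTENSITY["ring"]
    if pixel_noise > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        img = img + rng.normal(
            0.0, pixel_noise * US_INTENSITY["ring"], size=img.shape
        ).astype(np.float32)
        np.maximum(img, 0.0, out=img)
    return img


def render_us_frame(
    probe_pose_world: RigidTransform,
    calib_truth: RigidTransform,
    geometry: SectorGeometry,
    phantom: Phantom,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
    timestamp: float = 0.0,
    tracked_pose: RigidTransform | None = None,
) -> USFrame:
    """Render the B-mode frame seen from a world-frame probe pose.

    ``probe_pose_world`` is world_T_B (the true pose used for rendering);
    ``calib_truth`` the ground-truth B_T_US.  ``tracked_pose`` (the noisy
    R_T_B handed to the pipeline) is attached to the frame if given.
    """
    world_t_us = RigidTransform(
        probe_pose_world.matrix @ calib_truth.matrix
    )
    ellipsoids = [(t.center, t.radii) for t in phantom.targets]
    pixel_noise = noise.pixel_noise if noise is not None else 0.0
    img = render_sector_frame(world_t_us, geometry, ellipsoids, pixel_noise, rng)
    return USFrame(img, geometry, timestamp=timestamp, pose=tracked_pose)


# --------------------------------------------------------------------------
# EBUS acquisition sessions
# --------------------------------------------------------------------------
@dataclass
class EbusAcquisition:
    """One US sweep of one target: frames, tracking and ground truth."""

    acquisition_id: str
    target_label: str
    repetition: int
    frames: list[USFrame]
    tracking: TrackingStream
    true_target_center: np.ndarray


@dataclass
class EbusSession:
    """A complete simulated navigated-EBUS experiment."""

    phantom: Phantom
    geometry: SectorGeometry
    acquisitions: list[EbusAcquisition]
    ground_truth: dict


def simulate_ebus_session(
    phantom: Phantom,
    calib_truth: RigidTransform,
    visit_order: list[str] | None = None,
    repetitions: int = 3,
    noise: NoiseModel | None = None,
    geometry: SectorGeometry | None = None,
    sweep_speed: float = 5.0,
    frame_rate: float = 10.0,
    sweep_margin: float = 4.0,
) -> EbusSession:
    """Simulate the accuracy experiment: visit every target, three times.

    For each visit the probe is placed at the centerline point nearest the
    target, the image plane oriented to contain the target centre, and the
    probe swept through the target along the plane normal (elevation) so
    the frame stack covers the whole target.  Frames are rendered from the
    true pose; the attached pose is the nearest 40 Hz tracking sample with
    the noise model applied.  Targets farther from the centerline than the
    imaging depth are flagged and skipped with a warning.
    """
    noise = noise or NoiseModel.zero()
    geometry = geometry or SectorGeometry()
    if visit_order is None:
        visit_order = list(STATION_LABELS)
    rng = noise.rng()
    targets = {t.label: t for t in phantom.targets}
    ref_inv = invert(phantom.reference_pose)  # Rphantom_T_world
    acquisitions = []
    for rep in range(1, repetitions + 1):
        for label in visit_order:
            if label not in targets:
                warnings.warn(f"visit order names unknown target {label!r}; skipped")
                continue
            target = targets[label]
            p0, tangent = phantom.nearest_centerline_point(target.center)
            e = target.center - p0
            depth = float(np.linalg.norm(e))
            if depth > geometry.r_max - target.radii.max():
                warnings.warn(
                    f"target {label} at {depth:.1f} mm exceeds imaging depth; skipped"
                )
                continue
            e_hat = e / depth
            n = tangent - (tangent @ e_hat) * e_hat
            if np.linalg.norm(n) < 1e-6:  # tangent parallel to view direction
                n = np.cross(e_hat, [1.0, 0.0, 0.0])
                if np.linalg.norm(n) < 1e-6:
                    n = np.cross(e_hat, [0.0, 1.0, 0.0])
            n = n / np.linalg.norm(n)
            x_lat = np.cross(e_hat, n)
            rot = np.column_stack([x_lat, e_hat, n])
            half = float(target.radii.max()) + sweep_margin
            duration = 2 * half / sweep_speed

            def world_t_b(t, rot=rot, p0=p0, n=n, half=half):
                offset = -half + sweep_speed * t
                world_t_us = RigidTransform.from_rotation_translation(
                    rot, p0 + offset * n
                )
                return RigidTransform(world_t_us.matrix @ invert(calib_truth).matrix)

            def r_t_b(t):
                m = ref_inv.matrix @ world_t_b(t).matrix
                return RigidTransform(m, frame_from="B", frame_to="R_phantom")

            tracking = simulate_tracking(r_t_b, (0.0, duration), noise, rng)
            n_frames = max(1, int(round(duration * frame_rate)))
            frames = []
            for k in range(n_frames):
                t = k / frame_rate
                frames.append(
                    render_us_frame(
                        world_t_b(t),
                        calib_truth,
                        geometry,
                        phantom,
                        noise,
                        rng,
                        timestamp=t,
                        tracked_pose=tracking.pose_at(t),
                    )
                )
            acquisitions.append(
                EbusAcquisition(
                    acquisition_id=f"{label}_r{rep}",
                    target_label=label,
                    repetition=rep,
                    frames=frames,
                    tracking=tracking,
                    true_target_center=target.center.copy(),
                )
            )
    ground_truth = {
        "calib": calib_truth,
        "reg": phantom.reference_pose,
        "target_centers": {t.label: t.center.copy() for t in phantom.targets},
    }
    return EbusSession(phantom, geometry, acquisitions, ground_truth)


# --------------------------------------------------------------------------
# calibration sessions
# --------------------------------------------------------------------------
def default_calibration_truth(seed: int = 7) -> RigidTransform:
    """A repeatable non-trivial ground-truth probe calibration B_T_US."""
    rng = np.random.default_rng(seed)
    rotvec = rng.normal(0.0, 0.3, size=3)
    t = rng.uniform(-15.0, 15.0, size=3)
    return RigidTransform.from_rotation_translation(
        _rotvec_matrix(rotvec), t, frame_from="US", frame_to="B"
    )


def default_sphere_offset() -> Point3:
    """Default sphere-centre position relative to the calibration-arm
    reference sensor (measured once before the sweeps in a real session)."""
    return Point3((4.0, -3.0, 12.0), frame="R_arm")


def iter_calibration_sweeps(
    calib_truth: RigidTransform,
    geometry: SectorGeometry | None = None,
    noise: NoiseModel | None = None,
    n_positions: int = 9,
    sphere_diameter: float = 11.5,
    speed: float = 1.0,
    sweep_halfspan: float = 8.0,
    p_r: Point3 | None = None,
    frame_rate: float = _TRACKING_RATE_HZ,
):
    """Lazily generate the sphere-sweep recordings of the calibration
    protocol, one at a time.

    Identical draws and outputs to :func:`simulate_calibration_session`,
    but each recording can be localized and discarded before the next is
    rendered — the full protocol at 40 Hz holds gigabytes of frames if
    materialized at once.
    """
    from .calibration import CalibrationRecording  # local import avoids cycle

    geometry = geometry or SectorGeometry()
    noise = noise or NoiseModel.zero()
    radius = sphere_diameter / 2.0
    side = int(round(np.sqrt(n_positions)))
    if side * side != n_positions:
        raise ValueError("n_positions must be a perfect square (grid layout)")
    depth_lo = geometry.r_min + radius + 2.0
    depth_hi = geometry.r_max - radius - 2.0
    if depth_hi <= depth_lo:
        raise ValueError(
            f"sector depth range {geometry.depth_range} too small for "
            f"{n_positions} positions with a {sphere_diameter} mm sphere"
        )
    depths = np.linspace(depth_lo, depth_hi, side)
    angles = np.linspace(-0.6, 0.6, side) * geometry.half_angle_rad
    positions = [
        np.array([d * np.sin(a), d * np.cos(a), 0.0]) for d in depths for a in angles
    ]

    if p_r is None:
        p_r = default_sphere_offset()
    arm_rot = _rotvec_matrix(np.array([1.0, 1.0, 0.0]) / np.sqrt(2) * np.deg2rad(15.0))

    world_t_b = identity()  # probe held fixed; world = probe-sensor frame
    world_t_us = RigidTransform(world_t_b.matrix @ calib_truth.matrix)
    normal_w = world_t_us.rotation[:, 2]
    rng = noise.rng()
    duration = 2 * sweep_halfspan / speed
    n_frames = max(1, int(round(duration * frame_rate)))

    sweep_id = 0
    for pos_idx, u in enumerate(positions, start=1):
        q = world_t_us.rotation @ u + world_t_us.translation  # crossing point, world
        for direction in ("forward", "reverse"):
            sweep_id += 1

            def sphere_center(t):
                s = -sweep_halfspan + speed * t
                if direction == "reverse":
                    s = -s
                return q + s * normal_w

            def world_t_arm(t):
                c = sphere_center(t)
                return RigidTransform.from_rotation_translation(
                    arm_rot, c - arm_rot @ p_r.xyz
                )

            def r_t_b(t):
                m = invert(world_t_arm(t)).matrix @ world_t_b.matrix
                return RigidTransform(m, frame_from="B", frame_to="R_arm")

            tracking = simulate_tracking(r_t_b, (0.0, duration), noise, rng)
            frames = []
            for k in range(n_frames):
                t = k / frame_rate
                img = render_sector_frame(
                    world_t_us,
                    geometry,
                    [(sphere_center(t), np.full(3, radius))],
                    noise.pixel_noise,
                    rng,
                )
                frames.append(
                    USFrame(img, geometry, timestamp=t, pose=tracking.pose_at(t))
                )
            yield CalibrationRecording(
                frames=frames,
                sweep_id=sweep_id,
                direction=direction,
                position_index=pos_idx,
                true_crossing_time=sweep_halfspan / speed,
            )


def simulate_calibration_session(
    calib_truth: RigidTransform,
    geometry: SectorGeometry | None = None,
    noise: NoiseModel | None = None,
    n_positions: int = 9,
    sphere_diameter: float = 11.5,
    speed: float = 1.0,
    sweep_halfspan: float = 8.0,
    p_r: Point3 | None = None,
    frame_rate: float = _TRACKING_RATE_HZ,
):
    """Simulate the 18-sweep sphere calibration protocol.

    Nine crossing positions are spread evenly over the image plane (a 3x3
    grid in angle x depth); at each, the 11.5 mm sphere is moved at 1 mm/s
    along the plane normal through the plane and back, with frames and
    tracking at 40 Hz.  Returns ``(recordings, p_r, ground_truth)`` where
    ground truth holds the true calibration and the crossing points.  For
    long sweeps prefer :func:`iter_calibration_sweeps`, which generates
    recordings lazily instead of materializing them all.
    """
    if p_r is None:
        p_r = default_sphere_offset()
    recordings = list(
        iter_calibration_sweeps(
            calib_truth,
            geometry=geometry,
            noise=noise,
            n_positions=n_positions,
            sphere_diameter=sphere_diameter,
            speed=speed,
            sweep_halfspan=sweep_halfspan,
            p_r=p_r,
            frame_rate=frame_rate,
        )
    )
    ground_truth = {"calib": calib_truth, "p_r": p_r}
    return recordings, p_r, ground_truth
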