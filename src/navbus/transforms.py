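"""Rigid-body transform algebra and the US-to-CT navigation chain.

Every quantity in the system is expressed in one of four coordinate frames:

``US``
    the 2D ultrasound image plane, embedded in 3D with the out-of-plane
    coordinate fixed at zero (millimetres),
``B``
    the electromagnetic position sensor mounted on the bronchoscope tip,
``R``
    a reference sensor (``R_phantom`` on the phantom container during the
    experiment, ``R_arm`` on the calibration arm during probe calibration),
``CT``
    the preoperative CT image volume.

A point in the US image is mapped into CT coordinates by the chain

    p_CT = CT_T_R . R_T_B(t) . B_T_US . p_US

where ``CT_T_R`` is the image-to-patient registration, ``R_T_B(t)`` the
tracked bronchoscope pose at time ``t`` and ``B_T_US`` the probe
calibration.  All transforms are proper rigid (rotation + translation) 4x4
homogeneous matrices in millimetres; frame tags are carried and checked so
that a chain assembled in the wrong order fails loudly instead of silently
producing garbage coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass


import numpy as np

__all__ = [
    "FrameMismatchError",
    "InvalidTransformError",
    "Point3",
    "RigidTransform",
    "apply",
    "compose",
    "identity",
    "invert",
    "nearest_rotation",
    "random_rigid_transform",
    "us_point_to_ct",
]

#: rotations with ||R^T R - I|| below this are accepted as-is
_ORTHO_OK = 1e-9
#: rotations up to this defect are re-orthonormalized (tracker-log rounding)
_ORTHO_REPAIR = 1e-6


class InvalidTransformError(ValueError):
    """Matrix is not a proper rigid-body transform (within repair tolerance)."""


class FrameMismatchError(ValueError):
    """Coordinate-frame tags do not chain (e.g. applying B_T_US to a CT point)."""


def nearest_rotation(m: np.ndarray) -> np.ndarray:
    """Project a 3x3 matrix onto the nearest proper rotation (Frobenius norm).

    Uses the SVD polar projection ``U diag(1, 1, det(UV^T)) V^T``.
    """
    u, _, vt = np.linalg.svd(np.asarray(m, dtype=float))
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


@dataclass(frozen=True)
class Point3:
    """A 3D point in millimetres tagged with its coordinate frame."""

    xyz: np.ndarray
    frame: str | None = None

    def __post_init__(self) -> None:
        xyz = np.asarray(self.xyz, dtype=float).reshape(3)
        if not np.all(np.isfinite(xyz)):
            raise ValueError(f"non-finite point coordinates: {xyz}")
        object.__setattr__(self, "xyz", xyz)

    @property
    def homogeneous(self) -> np.ndarray:
        return np.append(self.xyz, 1.0)

    def __iter__(self):
        return iter(self.xyz)


@dataclass(frozen=True)
class RigidTransform:
    """A 4x4 homogeneous proper rigid-body transform (mm).

    ``frame_from``/``frame_to`` tag the source and destination frames; a
    ``None`` tag opts out of frame checking.  Rotations whose orthonormality
    defect lies between 1e-9 and 1e-6 (rounding noise in real tracker logs)
    are silently projected onto the nearest rotation; anything worse raises
    :class:`InvalidTransformError`.
    """

    matrix: np.ndarray
    frame_from: str | None = None
    frame_to: str | None = None

    def __post_init__(self) -> None:
        m = np.array(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise InvalidTransformError(f"expected 4x4 matrix, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise InvalidTransformError("matrix contains non-finite entries")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-12):
            raise InvalidTransformError(f"bottom row must be [0 0 0 1], got {m[3]}")
        m[3] = [0.0, 0.0, 0.0, 1.0]
        r = m[:3, :3]
        defect = np.linalg.norm(r.T @ r - np.eye(3))
        if defect > _ORTHO_REPAIR:
            raise InvalidTransformError(
                f"rotation block orthonormality defect {defect:.3e} exceeds "
                f"repair tolerance {_ORTHO_REPAIR:.0e}"
            )
        if defect > _ORTHO_OK:
            r = nearest_rotation(r)
            m[:3, :3] = r
        if np.linalg.det(r) < 0:
            raise InvalidTransformError("rotation block is a reflection (det < 0)")
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    # -- accessors ---------------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        """3x3 rotation block."""
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        """3-vector translation (mm)."""
        return self.matrix[:3, 3]

    @classmethod
    def from_rotation_translation(
        cls,
        rotation: np.ndarray,
        translation: np.ndarray,
        frame_from: str | None = None,
        frame_to: str | None = None,
    ) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = rotation
        m[:3, 3] = np.asarray(translation, dtype=float).reshape(3)
        return cls(m, frame_from=frame_from, frame_to=frame_to)

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "frame_from": self.frame_from,
                "frame_to": self.frame_to,
                "matrix": self.matrix.tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        obj = json.loads(text)
        return cls(
            np.asarray(obj["matrix"], dtype=float),
            frame_from=obj.get("frame_from"),
            frame_to=obj.get("frame_to"),
        )

    # -- algebra (methods mirror the module-level functions) ---------------
    def compose(self, other: "RigidTransform") -> "RigidTransform":
        return compose(self, other)

    def invert(self) -> "RigidTransform":
        return invert(self)

    def apply(self, p: Point3 | np.ndarray) -> Point3 | np.ndarray:
        return apply(self, p)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return compose(self, other)


def identity(frame: str | None = None) -> RigidTransform:
    """The identity transform (optionally tagged frame -> frame)."""
    return RigidTransform(np.eye(4), frame_from=frame, frame_to=frame)


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """``a . b``: apply ``b`` first, then ``a`` (matrix product ``a @ b``).

    Frame tags must chain: ``b.frame_to == a.frame_from`` (when both set).
    """
    if (
        a.frame_from is not None
        and b.frame_to is not None
        and a.frame_from != b.frame_to
    ):
        raise FrameMismatchError(
            f"cannot compose {a.frame_from}<-? after ?<-{b.frame_to}: "
            f"inner frames differ ({a.frame_from!r} != {b.frame_to!r})"
        )
    return RigidTransform(
        a.matrix @ b.matrix, frame_from=b.frame_from, frame_to=a.frame_to
    )


def invert(t: RigidTransform) -> RigidTransform:
    """Closed-form rigid inverse: rotation R^T, translation -R^T t."""
    r = t.rotation.T
    return RigidTransform.from_rotation_translation(
        r, -r @ t.translation, frame_from=t.frame_to, frame_to=t.frame_from
    )


def apply(t: RigidTransform, p: Point3 | np.ndarray) -> Point3 | np.ndarray:
    """Map a point (or an (N, 3) array of points) through ``t``.

    A :class:`Point3` whose frame tag conflicts with ``t.frame_from`` is
    rejected; the result carries ``t.frame_to``.  Raw arrays skip frame
    checking.
    """
    if isinstance(p, Point3):
        if (
            p.frame is not None
            and t.frame_from is not None
            and p.frame != t.frame_from
        ):
            raise FrameMismatchError(
                f"point is in frame {p.frame!r} but transform maps from "
                f"{t.frame_from!r}"
            )
        return Point3(t.rotation @ p.xyz + t.translation, frame=t.frame_to)
    arr = np.asarray(p, dtype=float)
    return arr @ t.rotation.T + t.translation


def us_point_to_ct(
    reg: RigidTransform,
    track: RigidTransform,
    calib: RigidTransform,
    p_us: Point3,
) -> Point3:
    """Navigation chain: p_CT = CT_T_R . R_T_B . B_T_US . p_US.

    ``reg`` is the image-to-patient registration CT_T_R, ``track`` the
    bronchoscope pose R_T_B at the frame's acquisition time, ``calib`` the
    probe calibration B_T_US.  Implemented as compose-then-apply so it is
    bitwise identical to assembling the chain once and reusing it.
    """
    return apply(compose(compose(reg, track), calib), p_us)


def random_rigid_transform(
    rng: np.random.Generator,
    translation_scale: float = 100.0,
    frame_from: str | None = None,
    frame_to: str | None = None,
) -> RigidTransform:
    """A uniformly random rotation with a uniform translation in a cube.

    Utility for seeded tests and simulator ground truth; rotation is drawn
    via QR decomposition of a Gaussian matrix (Haar measure up to sign fix).
    """
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, [0, 1]] = q[:, [1, 0]]
    t = rng.uniform(-translation_scale, translation_scale, size=3)
    return RigidTransform.from_rotation_translation(
        q, t, frame_from=frame_from, frame_to=frame_to
    )
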