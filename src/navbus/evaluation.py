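"""System accuracy evaluation: US-vs-CT target deviations and aggregation.

For every acquired US volume, the deviation between the reconstructed
target and its CT segmentation is measured by a translation-only shift
correction (sign convention US - CT, so that CT centre + deviation = US
centre); the per-acquisition Euclidean error is the L2 norm of that
deviation.  Measurements are aggregated into a per-target / footer table
(one row per target with per-axis min-max ranges, footer rows n, Mean, SD,
Maximum) mirroring how phantom navigation accuracy is conventionally
reported.

The shift correction is automated: the primary method is the centroid
difference between the segmented US target and the CT target; an optional
refinement minimizes the mean squared nearest-surface distance over a pure
translation, started from the centroid solution.  Rotation is never
estimated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.spatial import cKDTree

from .image import ImageVolume
from .reconstruction import EmptyReconstructionError, reconstruct
from .simulator import EbusSession
from .segmentation import SegmentedTarget, threshold_segment

from .transforms import RigidTransform

__all__ = [
    "AccuracySummary",
    "ShiftCorrectionError",
    "TargetMeasurement",
    "euclidean_error",
    "run_accuracy_experiment",
    "shift_correct",
    "summarize",
]

logger = logging.getLogger(__name__)

#: default threshold for segmenting rendered targets in reconstructed US
#: volumes: between the dark gelatin background (30) and target interior (150)
US_SEGMENT_THRESHOLD = 90.0


class ShiftCorrectionError(ValueError):
    """The US target could not be segmented (too few filled voxels)."""


@dataclass(frozen=True)
class TargetMeasurement:
    """One acquisition's US-vs-CT deviation vector and Euclidean error."""

    target_label: str
    acquisition_id: str
    deviation: np.ndarray  # (3,) mm, US - CT
    error: float  # mm, = ||deviation||
    method: str = "centroid"

    def __post_init__(self) -> None:
        dev = np.asarray(self.deviation, dtype=float).reshape(3)
        object.__setattr__(self, "deviation", dev)
        object.__setattr__(self, "error", float(np.linalg.norm(dev)))


def euclidean_error(deviation) -> float:
    """L2 norm of a deviation vector (mm)."""
    dev = np.asarray(deviation, dtype=float).reshape(3)
    if not np.all(np.isfinite(dev)):
        raise ValueError(f"non-finite deviation {dev}")
    return float(np.linalg.norm(dev))


def shift_correct(
    us_vol: ImageVolume,
    ct_target: SegmentedTarget,
    threshold: float = US_SEGMENT_THRESHOLD,
    min_voxels: int = 27,
    refine: bool = False,
) -> tuple[np.ndarray, str]:
    """Translation-only alignment of the reconstructed US target onto CT.

    Segments the US volume at ``threshold``, takes the component nearest
    the CT target centroid, and returns ``(deviation, method)`` with
    deviation = US centroid - CT centroid.  With ``refine=True`` the
    deviation is polished by minimizing the mean squared distance from the
    shifted CT surface to the nearest US surface voxel (Powell, started at
    the centroid solution).  Rotation is never estimated.

    Raises
    ------
    ShiftCorrectionError
        If no component of at least ``min_voxels`` voxels is found.
    """
    components = threshold_segment(us_vol, threshold, min_voxels=min_voxels)
    if not components:
        raise ShiftCorrectionError(
            f"no US component above {threshold} with >= {min_voxels} voxels"
        )
    ct_centroid = np.asarray(ct_target.centroid, dtype=float)
    us_target = min(
        components, key=lambda c: np.linalg.norm(c.centroid - ct_centroid)
    )
    deviation = us_target.centroid - ct_centroid
    method = "centroid"
    if refine:
        us_surface = us_target.surface_world
        ct_surface = ct_target.surface_world
        tree = cKDTree(us_surface)

        def cost(shift):
            d, _ = tree.query(ct_surface + shift)
            return float(np.mean(d**2))

        res = optimize.minimize(cost, deviation, method="Powell", options={"xtol": 1e-4})
        deviation = np.asarray(res.x, dtype=float)
        method = "surface"
    return deviation, method


@dataclass
class AccuracySummary:
    """Aggregate accuracy statistics in the per-target table layout.

    ``per_target`` maps station label -> dict with ``n`` and per-axis and
    error (min, max) ranges.  Axis means/SDs use the sample SD (n-1); SD is
    ``None`` for a single measurement.
    """

    n: int
    mean: np.ndarray  # (3,) per-axis mean deviation, mm
    sd: np.ndarray | None  # (3,) per-axis sample SD, mm (None when n = 1)
    mean_error: float
    sd_error: float | None
    max_error: float
    per_target: dict[str, dict]

    def to_dataframe(self) -> pd.DataFrame:
        """Table with one row per target (ranges) and n/Mean/SD/Maximum footer."""
        rows = []

        def fmt_range(lo, hi):
            return f"{lo:.1f} to {hi:.1f}"

        for label, stats in self.per_target.items():
            rows.append(
                {
                    "target": label,
                    "n": stats["n"],
                    "X": fmt_range(*stats["x"]),
                    "Y": fmt_range(*stats["y"]),
                    "Z": fmt_range(*stats["z"]),
                    "Error": fmt_range(*stats["error"]),
                }
            )
        rows.append({"target": "n", "n": self.n, "X": "", "Y": "", "Z": "", "Error": ""})
        rows.append(
            {
                "target": "Mean",
                "n": "",
                "X": f"{self.mean[0]:.1f}",
                "Y": f"{self.mean[1]:.1f}",
                "Z": f"{self.mean[2]:.1f}",
                "Error": f"{self.mean_error:.1f}",
            }
        )
        if self.sd is not None:
            rows.append(
                {
                    "target": "SD",
                    "n": "",
                    "X": f"{self.sd[0]:.1f}",
                    "Y": f"{self.sd[1]:.1f}",
                    "Z": f"{self.sd[2]:.1f}",
                    "Error": f"{self.sd_error:.1f}",
                }
            )
        rows.append(
            {
                "target": "Maximum",
                "n": "",
                "X": "",
                "Y": "",
                "Z": "",
                "Error": f"{self.max_error:.1f}",
            }
        )
        return pd.DataFrame(rows)


def summarize(measurements: list[TargetMeasurement]) -> AccuracySummary:
    """Aggregate per-acquisition measurements into the accuracy table."""
    if not measurements:
        raise ValueError("no measurements to summarize")
    dev = np.array([m.deviation for m in measurements])
    err = np.array([m.error for m in measurements])
    n = len(measurements)
    sd = dev.std(axis=0, ddof=1) if n > 1 else None
    sd_error = float(err.std(ddof=1)) if n > 1 else None
    per_target: dict[str, dict] = {}
    for m in measurements:
        per_target.setdefault(m.target_label, []).append(m)
    table = {}
    for label, ms in per_target.items():
        d = np.array([m.deviation for m in ms])
        e = np.array([m.error for m in ms])
        table[label] = {
            "n": len(ms),
            "x": (float(d[:, 0].min()), float(d[:, 0].max())),
            "y": (float(d[:, 1].min()), float(d[:, 1].max())),
            "z": (float(d[:, 2].min()), float(d[:, 2].max())),
            "error": (float(e.min()), float(e.max())),
        }
    return AccuracySummary(
        n=n,
        mean=dev.mean(axis=0),
        sd=sd,
        mean_error=float(err.mean()),
        sd_error=sd_error,
        max_error=float(err.max()),
        per_target=table,
    )


@dataclass
class ExperimentRecord:
    """Per-acquisition intermediates retained for replay/inspection."""

    acquisition_id: str
    target_label: str
    us_volume: ImageVolume | None
    measurement: TargetMeasurement | None
    flag: str | None = None


def run_accuracy_experiment(
    session: EbusSession,
    reg: RigidTransform,
    calib: RigidTransform,
    ct_targets: dict[str, SegmentedTarget],
    spacing: float = 0.5,
    threshold: float = US_SEGMENT_THRESHOLD,
    refine: bool = False,
    keep_volumes: bool = False,
) -> tuple[AccuracySummary, list[TargetMeasurement], list[ExperimentRecord]]:
    """Full accuracy pipeline over every acquisition of a session.

    For each acquisition: reconstruct the US volume with the *estimated*
    registration and calibration, segment it, shift-correct against the CT
    target of the visited station, and record the deviation and error.
    Invalid acquisitions (unsegmentable US target) are flagged and
    excluded; the experiment fails only if no acquisition is valid.
    """
    measurements: list[TargetMeasurement] = []
    records: list[ExperimentRecord] = []
    for acq in session.acquisitions:
        ct_target = ct_targets.get(acq.target_label)
        if ct_target is None:
            records.append(
                ExperimentRecord(acq.acquisition_id, acq.target_label, None, None,
                                 flag="no CT target for station"))
            logger.warning("%s: no CT target for station; skipped", acq.acquisition_id)
            continue
        try:
            us_vol = reconstruct(acq.frames, reg, calib, spacing=spacing)
            deviation, method = shift_correct(
                us_vol, ct_target, threshold=threshold, refine=refine
            )
        except (EmptyReconstructionError, ShiftCorrectionError) as exc:
            records.append(
                ExperimentRecord(acq.acquisition_id, acq.target_label, None, None,
                                 flag=str(exc)))
            logger.warning("%s: %s; excluded", acq.acquisition_id, exc)
            continue
        m = TargetMeasurement(
            target_label=acq.target_label,
            acquisition_id=acq.acquisition_id,
            deviation=deviation,
            error=float(np.linalg.norm(deviation)),
            method=method,
        )
        measurements.append(m)
        records.append(
            ExperimentRecord(
                acq.acquisition_id,
                acq.target_label,
                us_vol if keep_volumes else None,
                m,
            )
        )
    if not measurements:
        raise RuntimeError("no valid acquisition in the whole session")
    return summarize(measurements), measurements, records


def measurements_to_dataframe(measurements: list[TargetMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [m.target_label for m in measurements],
            "acquisition": [m.acquisition_id for m in measurements],
            "dx": [m.deviation[0] for m in measurements],
            "dy": [m.deviation[1] for m in measurements],
            "dz": [m.deviation[2] for m in measurements],
            "error": [m.error for m in measurements],
            "method": [m.method for m in measurements],
        }
    )
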