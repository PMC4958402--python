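"""Threshold segmentation of target models in CT and reconstructed US
volumes, and centroid-based cross-modality target matching."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["MatchResult", "SegmentedTarget", "match_targets", "threshold_segment"]

_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SegmentedTarget:
    """One 26-connected component above threshold.

    ``centroid`` is the unweighted mean of the component's voxel-centre
    world coordinates (mm) — the reproducible surrogate for manually
    pinpointed target centres.  ``surface_indices`` are the component's
    boundary voxels (those with at least one non-component 6-neighbour).
    """

    label: str | None
    voxel_indices: np.ndarray  # (N, 3) integer indices
    centroid: np.ndarray  # (3,) world mm
    surface_indices: np.ndarray
    surface_world: np.ndarray  # (M, 3) world mm of the boundary voxels
    n_voxels: int


def threshold_segment(
    vol,
    threshold: float,
    min_voxels: int = 27,
    upper: float | None = None,
) -> list[SegmentedTarget]:
    """Segment connected bright components of a volume.

    The binary mask is ``voxels > threshold`` (and ``< upper`` when an
    upper bound is given, which excludes e.g. metal fiducial markers when
    segmenting soft-tissue targets); NaN (empty) voxels are excluded.
    Components are 26-connected; components smaller than ``min_voxels``
    are discarded as noise specks.  An empty result is a valid outcome,
    not an error.
    """
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    v = np.asarray(vol.voxels, dtype=float)
    mask = np.isfinite(v) & (v > threshold)
    if upper is not None:
        mask &= v < upper
    labels, n = ndimage.label(mask, structure=_STRUCTURE_26)
    targets: list[SegmentedTarget] = []
    if n == 0:
        return targets
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    for comp in range(1, n + 1):
        if sizes[comp - 1] < min_voxels:
            continue
        comp_mask = labels == comp
        idx = np.argwhere(comp_mask)
        centroid = vol.world_coordinates(idx).mean(axis=0)
        interior = ndimage.binary_erosion(comp_mask)
        surface = np.argwhere(comp_mask & ~interior)
        targets.append(
            SegmentedTarget(
                label=None,
                voxel_indices=idx,
                centroid=centroid,
                surface_indices=surface,
                surface_world=vol.world_coordinates(surface),
                n_voxels=int(sizes[comp - 1]),
            )
        )
    targets.sort(key=lambda t: -t.n_voxels)
    return targets


@dataclass
class MatchResult:
    """Mutual-nearest-centroid assignment between two target lists."""

    pairs: list[tuple[int, int]]  # (segmented index, reference index)
    unmatched_segmented: list[int] = field(default_factory=list)
    unmatched_reference: list[int] = field(default_factory=list)
    ambiguous: list[int] = field(default_factory=list)  # segmented indices


def _centroid_of(obj) -> np.ndarray:
    if hasattr(obj, "centroid"):
        return np.asarray(obj.centroid, dtype=float)
    if hasattr(obj, "center"):
        return np.asarray(obj.center, dtype=float)
    return np.asarray(obj, dtype=float)


def match_targets(segmented: list, reference: list, ambiguity_mm: float = 1.0) -> MatchResult:
    """Assign segmented components to reference targets by mutual nearest
    centroids.

    ``reference`` entries may be :class:`SegmentedTarget`, phantom targets,
    or raw centroids.  Pairs are mutual nearest neighbours; everything else
    is reported unmatched.  A segmented component whose two nearest
    references are within ``ambiguity_mm`` of each other is flagged
    ambiguous (but still assigned).
    """
    if not segmented or not reference:
        return MatchResult(
            pairs=[],
            unmatched_segmented=list(range(len(segmented))),
            unmatched_reference=list(range(len(reference))),
        )
    seg_c = np.array([_centroid_of(s) for s in segmented])
    ref_c = np.array([_centroid_of(r) for r in reference])
    d = np.linalg.norm(seg_c[:, None, :] - ref_c[None, :, :], axis=2)
    nearest_ref = d.argmin(axis=1)
    nearest_seg = d.argmin(axis=0)
    pairs, ambiguous = [], []
    matched_s, matched_r = set(), set()
    for i, j in enumerate(nearest_ref):
        if nearest_seg[j] == i:
            pairs.append((i, int(j)))
            matched_s.add(i)
            matched_r.add(int(j))
            if d.shape[1] > 1:
                two = np.sort(d[i])[:2]
                if two[1] - two[0] < ambiguity_mm:
                    ambiguous.append(i)
    return MatchResult(
        pairs=pairs,
        unmatched_segmented=[i for i in range(len(segmented)) if i not in matched_s],
        unmatched_reference=[j for j in range(len(reference)) if j not in matched_r],
        ambiguous=ambiguous,
    )
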