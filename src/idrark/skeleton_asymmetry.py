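"""Symmetric deep-WM skeleton and the voxel-wise asymmetry index.

The skeleton represents deep white-matter tract cores: the cohort-mean FA
volume is thresholded (default 0.2, excluding partial-volume superficial
WM), thinned to a medial surface, and symmetrized by intersection with its
own mirror image about the midsagittal plane.  Each skeleton voxel on the
right hemisphere is paired with its mirror voxel on the left, and per pair
the asymmetry index

    AI = (right - left) / (right + left)

is computed for a projected metric, yielding one value per pair — a
half-brain map.  AI is dimensionless, sign-coded (positive = larger on the
right), bounded in (-1, 1) for positive inputs, and invariant under a
common rescaling of both hemispheres.

Thinning here is a distance-transform ridge: a supra-threshold voxel
belongs to the skeleton when its distance to the thresholded boundary is a
local maximum along at least one grid axis and at least 2 voxels deep.
This keeps the medial sheet of the thresholded WM, the same object the
TBSS skeletonization targets, without that tool's projection search; on
real data a precomputed skeleton mask may be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi

from .cohort_io import (
    MIRROR_AXIS,
    AnalysisConfig,
    CohortValidationError,
    LobeAtlas,
    ParametricMapSet,
)

__all__ = [
    "SymmetricSkeleton",
    "AsymmetryMap",
    "build_symmetric_skeleton",
    "project_to_skeleton",
    "asymmetry_index",
]


class SkeletonError(RuntimeError):
    pass


@dataclass
class SymmetricSkeleton:
    """Mirror-symmetric skeleton with enumerated left-right voxel pairs.

    ``pairs_right``/``pairs_left`` are (n_pairs, 3) voxel-index arrays in
    lexicographic order of the right-hemisphere member; ``lobe_of_pair``
    gives each pair's lobe name (identical for both members because the
    atlas is symmetric).
    """

    skeleton_mask: np.ndarray
    pairs_right: np.ndarray
    pairs_left: np.ndarray
    lobe_of_pair: np.ndarray  # array of str

    @property
    def n_pairs(self) -> int:
        return len(self.pairs_right)

    def hemisphere_coords(self, hemisphere: str) -> np.ndarray:
        if hemisphere == "right":
            return self.pairs_right
        if hemisphere == "left":
            return self.pairs_left
        raise KeyError(hemisphere)


@dataclass
class AsymmetryMap:
    """Per-pair AI values for one subject and metric."""

    metric: str
    subject_id: str
    ai: np.ndarray


def _mirror(volume: np.ndarray) -> np.ndarray:
    return np.flip(volume, axis=MIRROR_AXIS)


def _medial_ridge(supra: np.ndarray, min_depth: float = 2.0) -> np.ndarray:
    dt = ndi.distance_transform_edt(supra)
    ridge = np.zeros_like(supra)
    for ax in range(3):
        ridge |= (dt >= np.roll(dt, 1, ax)) & (dt >= np.roll(dt, -1, ax))
    return ridge & supra & (dt >= min_depth)


def _assign_lobes(
    coords: np.ndarray, atlas: LobeAtlas
) -> np.ndarray:
    """Lobe name per coordinate; unlabelled voxels take the nearest label."""
    labels = atlas.labels
    vals = labels[tuple(coords.T)]
    if (vals == 0).any():
        # nearest nonzero label via EDT feature transform
        _, nearest = ndi.distance_transform_edt(labels == 0, return_indices=True)
        filled = labels[tuple(nearest)]
        vals = np.where(vals == 0, filled[tuple(coords.T)], vals)
    return np.array([atlas.legend[int(v)][0] for v in vals])


def build_symmetric_skeleton(
    cohort_fa_maps: Sequence[np.ndarray],
    brain_mask: np.ndarray,
    atlas: LobeAtlas,
    cfg: AnalysisConfig,
    skeleton_mask: Optional[np.ndarray] = None,
) -> SymmetricSkeleton:
    """Build the paired deep-WM skeleton from cohort FA maps.

    When ``skeleton_mask`` is given (e.g. a TBSS skeleton computed
    externally) it replaces the internal thinning; it is still symmetrized
    and thresholded on the cohort-mean FA before pairing.
    """
    if len(cohort_fa_maps) < 2:
        raise CohortValidationError("need at least two FA maps for a mean skeleton")
    n = brain_mask.shape[MIRROR_AXIS]
    if n % 2 != 0:
        raise CohortValidationError(
            "left-right extent must be even to place the midsagittal plane"
        )
    mean_fa = np.mean(np.stack(cohort_fa_maps), axis=0)
    supra = (mean_fa >= cfg.fa_skeleton_threshold) & brain_mask.astype(bool)
    if skeleton_mask is None:
        skel = _medial_ridge(supra)
    else:
        skel = skeleton_mask.astype(bool) & supra
    skel = skel & _mirror(skel)
    if not skel.any():
        raise SkeletonError(
            "symmetrized skeleton is empty; lower fa_skeleton_threshold or "
            "supply a skeleton mask"
        )

    half = n // 2
    right = np.zeros_like(skel)
    sl = [slice(None)] * 3
    sl[MIRROR_AXIS] = slice(half, None)
    right[tuple(sl)] = skel[tuple(sl)]
    pairs_right = np.argwhere(right)  # argwhere is lexicographic already
    pairs_left = pairs_right.copy()
    pairs_left[:, MIRROR_AXIS] = n - 1 - pairs_right[:, MIRROR_AXIS]
    lobes = _assign_lobes(pairs_right, atlas)
    return SymmetricSkeleton(
        skeleton_mask=skel,
        pairs_right=pairs_right,
        pairs_left=pairs_left,
        lobe_of_pair=lobes,
    )


def project_to_skeleton(
    map_set: ParametricMapSet, skeleton: SymmetricSkeleton, metric: str
) -> Tuple[np.ndarray, np.ndarray]:
    """Sample a subject's metric at each pair's right and left voxel."""
    vol = map_set.metric(metric)
    if vol.shape != skeleton.skeleton_mask.shape:
        raise CohortValidationError(
            f"subject {map_set.subject_id}: map grid differs from skeleton grid"
        )
    right = vol[tuple(skeleton.pairs_right.T)]
    left = vol[tuple(skeleton.pairs_left.T)]
    for side, vals, coords in (
        ("right", right, skeleton.pairs_right),
        ("left", left, skeleton.pairs_left),
    ):
        bad = ~np.isfinite(vals)
        if bad.any():
            ijk = coords[np.argmax(bad)]
            raise CohortValidationError(
                f"subject {map_set.subject_id}: non-finite {metric.upper()} at "
                f"{side} skeleton voxel {tuple(int(x) for x in ijk)}"
            )
    return right, left


def asymmetry_index(
    right_values: np.ndarray, left_values: np.ndarray
) -> np.ndarray:
    """AI = (right - left) / (right + left), elementwise.

    A zero denominator indicates a masking defect (physical maps are
    positive on white matter) and aborts rather than emitting 0.
    """
    right_values = np.asarray(right_values, dtype=float)
    left_values = np.asarray(left_values, dtype=float)
    denom = right_values + left_values
    if np.any(denom == 0):
        bad = int(np.argmax(denom == 0))
        raise ZeroDivisionError(
            f"degenerate pair {bad}: right + left == 0 on the skeleton"
        )
    return (right_values - left_values) / denom


def asymmetry_maps(
    subjects: Sequence[ParametricMapSet],
    skeleton: SymmetricSkeleton,
    metric: str,
) -> List[AsymmetryMap]:
    """AI maps for a list of subjects (convenience for cohort-level use)."""
    out = []
    for s in subjects:
        r, l = project_to_skeleton(s, skeleton, metric)
        out.append(AsymmetryMap(metric=metric, subject_id=s.subject_id,
                                ai=asymmetry_index(r, l)))
    return out
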