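"""Voxel-wise epileptogenic-zone candidates: the iDrArK overlap map.

A candidate voxel must show the full lesion signature simultaneously:
significantly increased MD, decreased FA and decreased MK, each from a
one-tailed patient-vs-controls t-map thresholded at an uncorrected p
(default 0.001) within the analysis brain mask.  The three binary maps are
intersected, connected components below the minimum cluster size are
removed, and — when the lobar asymmetry step produced a significant result
— the map is restricted to the detected lobe (with the size filter
re-applied, since splitting clusters at the lobe boundary can leave
sub-threshold remnants).

The same machinery with one or two masks produces the single-metric and
pairwise-overlap comparison maps (MD, FA, MK, MD_MK, MD_FA, FA_MK).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi

from .cohort_io import (
    AnalysisConfig,
    CohortValidationError,
    LobeAtlas,
    ParametricMapSet,
)
from .lobar_detection import LobarResult
from .voxel_inference import (
    GLMDesign,
    connectivity_structure,
    parametric_t_threshold,
)

__all__ = [
    "IDrArKMap",
    "binarize_direction_maps",
    "intersect_and_filter",
    "restrict_to_lobe",
]

#: one-tailed direction of the pathological change per metric
METRIC_TAILS = {"md": "greater", "fa": "less", "mk": "less"}


@dataclass
class Cluster:
    cluster_id: int
    coords: np.ndarray  # (n, 3) voxel indices

    @property
    def size(self) -> int:
        return len(self.coords)


@dataclass
class IDrArKMap:
    """Binary overlap volume with its surviving clusters."""

    subject_id: str
    overlap_mask: np.ndarray
    clusters: List[Cluster]
    source_masks: Dict[str, np.ndarray] = field(default_factory=dict)
    restricted_to: Optional[Tuple[str, str]] = None

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def binarize_direction_maps(
    patient: ParametricMapSet,
    controls: Sequence[ParametricMapSet],
    brain_mask: np.ndarray,
    cfg: AnalysisConfig,
    metrics: Sequence[str] = ("md", "fa", "mk"),
) -> Dict[str, np.ndarray]:
    """Direction-specific significant masks per metric (3-D boolean).

    MD uses the "greater" tail, FA and MK the "less" tail, each a
    parametric one-tailed t-map thresholded at ``cfg.voxelwise_p``
    (uncorrected) with sex and age as covariates.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    coords = np.argwhere(mask)
    subjects = list(controls) + [patient]
    group = np.array([0.0] * len(controls) + [1.0])
    sex = np.array([1.0 if s.sex == "M" else 0.0 for s in subjects])
    age = np.array([s.age for s in subjects])
    out: Dict[str, np.ndarray] = {}
    for metric in metrics:
        metric = metric.lower()
        Y = np.stack([s.metric(metric)[mask] for s in subjects])
        design = GLMDesign(
            response=Y,
            group_indicator=group,
            sex=sex,
            age=age,
            tail=METRIC_TAILS[metric],
        )
        res = parametric_t_threshold(design, cfg.voxelwise_p)
        vol = np.zeros(mask.shape, dtype=bool)
        vol[tuple(coords.T)] = res.sig_mask
        out[metric] = vol
    return out


def _label_clusters(
    mask: np.ndarray, cfg: AnalysisConfig
) -> Tuple[np.ndarray, List[Cluster]]:
    labels, n = ndi.label(
        mask, structure=connectivity_structure(cfg.cluster_connectivity)
    )
    clusters: List[Cluster] = []
    kept = np.zeros_like(mask)
    next_id = 1
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab)
        if len(coords) >= cfg.min_cluster_voxels:
            clusters.append(Cluster(cluster_id=next_id, coords=coords))
            kept[tuple(coords.T)] = True
            next_id += 1
    return kept, clusters


def intersect_and_filter(
    masks: Dict[str, np.ndarray],
    cfg: AnalysisConfig,
    subject_id: str = "",
) -> IDrArKMap:
    """Voxelwise AND of the given masks, then the minimum-size filter.

    With the three canonical masks this is the iDrArK map; with subsets it
    yields the single-metric / pairwise comparison maps.
    """
    if not masks:
        raise CohortValidationError("no masks to intersect")
    shapes = {m.shape for m in masks.values()}
    if len(shapes) != 1:
        raise CohortValidationError("masks are not on one grid")
    overlap = np.ones(shapes.pop(), dtype=bool)
    for m in masks.values():
        overlap &= np.asarray(m, dtype=bool)
    kept, clusters = _label_clusters(overlap, cfg)
    return IDrArKMap(
        subject_id=subject_id,
        overlap_mask=kept,
        clusters=clusters,
        source_masks={k: np.asarray(v, dtype=bool) for k, v in masks.items()},
    )


def restrict_to_lobe(
    ez_map: IDrArKMap,
    lobar: LobarResult,
    atlas: LobeAtlas,
    cfg: AnalysisConfig,
) -> IDrArKMap:
    """Mask the map to the lobe selected by the asymmetry step.

    Subjects without a significant lobar result keep the whole-brain map
    unchanged.  After masking, clusters are relabelled and the size filter
    re-applied; restriction is idempotent and never adds voxels.
    """
    if not lobar.significant or lobar.selected is None:
        return ez_map
    lobe_name, hemisphere = lobar.selected
    region = atlas.region_mask(lobe_name, hemisphere)
    if region.shape != ez_map.overlap_mask.shape:
        raise CohortValidationError("atlas grid differs from map grid")
    kept, clusters = _label_clusters(ez_map.overlap_mask & region, cfg)
    return replace(
        ez_map,
        overlap_mask=kept,
        clusters=clusters,
        restricted_to=(lobe_name, hemisphere),
    )
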