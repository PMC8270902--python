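"""Lobar asymmetry index (LAI): lobe-level detection of the impaired lobe.

Significant AI pairs from the skeleton permutation test are attributed to a
hemisphere by the direction of the effect and the physiology of each
metric: pathology raises MD and lowers FA/MK, and AI is (right - left) /
(right + left), so an increased-MD asymmetry points at the right
hemisphere while an increased-FA/MK asymmetry points at the left (and vice
versa).  Within each (lobe, hemisphere), significant skeleton voxels are
cluster-filtered (components under ``min_cluster_voxels`` discarded) and

    LAI = surviving significant voxels / skeleton voxels in the lobe.

The (lobe, hemisphere) with the highest LAI is the detected impaired lobe;
a subject with no surviving voxels has no significant lobar detection.
Cohort-level accuracy is the fraction of subjects with any significant
detection whose detected lobe matches the truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi

from .cohort_io import AnalysisConfig, CohortValidationError, LobeAtlas
from .skeleton_asymmetry import SymmetricSkeleton
from .voxel_inference import connectivity_structure

__all__ = [
    "LobarResult",
    "LobarEvaluation",
    "attribute_hemisphere",
    "lobar_asymmetry_index",
    "evaluate_lobar_cohort",
]

LobeHemi = Tuple[str, str]


def attribute_hemisphere(metric: str, tail: str) -> str:
    """Impaired hemisphere implied by a one-tailed AI effect for a metric."""
    metric = metric.lower()
    if metric not in ("md", "fa", "mk"):
        raise KeyError(f"unknown metric {metric!r}")
    if tail not in ("greater", "less"):
        raise KeyError(f"unknown tail {tail!r}")
    if metric == "md":
        return "right" if tail == "greater" else "left"
    return "left" if tail == "greater" else "right"


@dataclass
class LobarResult:
    """Per-(lobe, hemisphere) LAI table and the selected lobe for one
    subject/metric."""

    metric: str
    subject_id: str
    lai_table: Dict[LobeHemi, float]
    n_vx_lobe: Dict[LobeHemi, int]
    n_sig_lobe: Dict[LobeHemi, int]
    selected: Optional[LobeHemi]
    significant: bool


@dataclass
class LobarEvaluation:
    """Cohort-level lobar detection accuracy = SLD / ALD."""

    metric: str
    sld: int
    ald: int

    @property
    def accuracy(self) -> Optional[float]:
        return self.sld / self.ald if self.ald else None


def _surviving_count(
    coords: np.ndarray, shape: Tuple[int, ...], cfg: AnalysisConfig
) -> int:
    """Count voxels in connected components of size >= min_cluster_voxels."""
    if len(coords) == 0:
        return 0
    vol = np.zeros(shape, dtype=bool)
    vol[tuple(coords.T)] = True
    labels, n = ndi.label(vol, structure=connectivity_structure(cfg.cluster_connectivity))
    if n == 0:
        return 0
    sizes = np.bincount(labels.ravel())[1:]
    return int(sizes[sizes >= cfg.min_cluster_voxels].sum())


def lobar_asymmetry_index(
    sig_masks: Mapping[str, np.ndarray],
    skeleton: SymmetricSkeleton,
    atlas: LobeAtlas,
    cfg: AnalysisConfig,
    metric: str,
    subject_id: str = "",
) -> LobarResult:
    """Aggregate per-tail significant pairs into the LAI table.

    ``sig_masks`` maps tail name ("greater"/"less") to a boolean vector over
    skeleton pairs (FWE-corrected significance of the AI contrast in that
    direction).  Each tail contributes to the hemisphere it implicates;
    cluster filtering runs per (lobe, hemisphere, tail) on the skeleton
    voxels of that hemisphere.
    """
    shape = skeleton.skeleton_mask.shape
    lobe_names = sorted({name for name, _ in atlas.lobe_hemis()})
    n_vx: Dict[LobeHemi, int] = {}
    for name in lobe_names:
        in_lobe = skeleton.lobe_of_pair == name
        n_vx[(name, "left")] = int(in_lobe.sum())
        n_vx[(name, "right")] = int(in_lobe.sum())
    n_sig: Dict[LobeHemi, int] = {k: 0 for k in n_vx}

    for tail, sig in sig_masks.items():
        sig = np.asarray(sig, dtype=bool)
        if sig.shape != (skeleton.n_pairs,):
            raise CohortValidationError(
                "significance mask length differs from skeleton pair count"
            )
        hemisphere = attribute_hemisphere(metric, tail)
        coords_all = skeleton.hemisphere_coords(hemisphere)
        for name in lobe_names:
            pick = sig & (skeleton.lobe_of_pair == name)
            n_sig[(name, hemisphere)] += _surviving_count(
                coords_all[pick], shape, cfg
            )

    lai = {
        key: (n_sig[key] / n_vx[key] if n_vx[key] else 0.0) for key in n_vx
    }
    significant = any(v > 0 for v in n_sig.values())
    selected: Optional[LobeHemi] = None
    if significant:
        # argmax on LAI; ties broken by higher surviving count, then name
        best = max(lai.values())
        candidates = [k for k, v in lai.items() if v == best]
        candidates.sort(key=lambda k: (-n_sig[k], k))
        selected = candidates[0]
    return LobarResult(
        metric=metric,
        subject_id=subject_id,
        lai_table=lai,
        n_vx_lobe=n_vx,
        n_sig_lobe=n_sig,
        selected=selected,
        significant=significant,
    )


def evaluate_lobar_cohort(
    results: List[LobarResult], truth: Mapping[str, LobeHemi]
) -> LobarEvaluation:
    """SLD/ALD accuracy of lobar detection against per-subject truth."""
    sld = 0
    ald = 0
    metric = results[0].metric if results else ""
    for r in results:
        if not r.significant:
            continue
        ald += 1
        if r.subject_id not in truth:
            raise CohortValidationError(
                f"no ground-truth lobe for significant subject {r.subject_id!r}"
            )
        if r.selected == tuple(truth[r.subject_id]):
            sld += 1
    return LobarEvaluation(metric=metric, sld=sld, ald=ald)
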