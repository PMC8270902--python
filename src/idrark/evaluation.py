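"""Scoring detections against surgical resection zones.

The resection zone (RZ) is dilated by a world-space Euclidean ball
(default 10 mm) into the extended resection zone (eRZ), absorbing the
brain shift that follows resective surgery.  Per subject and method,

    PPV = clusters within the eRZ / all clusters,

where a cluster counts as "within" when the majority (> 50%) of its voxels
lie inside the eRZ.  Subjects are classified SD (successful detection,
PPV >= 0.5), UD (unsuccessful, PPV < 0.5) or NS (no significant clusters);
cohort summaries are

    accuracy       = SD / (SD + UD)
    detection rate = (SD + UD) / (SD + UD + NS).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .cohort_io import CohortValidationError
from .ez_detection import IDrArKMap

__all__ = [
    "DetectionResult",
    "CohortEvaluation",
    "extend_resection_zone",
    "positive_predictive_value",
    "evaluate_cohort",
    "two_step_utility",
    "percent",
]


def percent(x: Optional[float], decimals: int = 1) -> Optional[float]:
    """Ratio -> percentage rounded to the reporting precision."""
    if x is None:
        return None
    return float(np.round(100.0 * x, decimals))


@dataclass
class DetectionResult:
    """Per-subject cluster-level PPV and SD/UD/NS class for one method."""

    subject_id: str
    method: str
    nc: int
    nc_erz: int
    restricted: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.nc_erz <= self.nc:
            raise CohortValidationError("nc_erz must lie in [0, nc]")

    @property
    def ppv(self) -> Optional[float]:
        return self.nc_erz / self.nc if self.nc else None

    def status(self, success_threshold: float = 0.5) -> str:
        if self.nc == 0:
            return "NS"
        return "SD" if self.ppv >= success_threshold else "UD"


@dataclass
class CohortEvaluation:
    """SD/UD/NS counts with the derived accuracy and detection rate."""

    method: str
    sd: int
    ud: int
    ns: int

    @property
    def accuracy(self) -> Optional[float]:
        return self.sd / (self.sd + self.ud) if (self.sd + self.ud) else None

    @property
    def detection_rate(self) -> float:
        total = self.sd + self.ud + self.ns
        return (self.sd + self.ud) / total if total else 0.0

    def as_row(self) -> dict:
        return {
            "method": self.method,
            "SD": self.sd,
            "UD": self.ud,
            "NS": self.ns,
            "accuracy_pct": percent(self.accuracy),
            "detection_rate_pct": percent(self.detection_rate),
        }


def extend_resection_zone(
    rz: np.ndarray, voxel_mm: Sequence[float], dilation_mm: float
) -> np.ndarray:
    """Dilate the RZ by a Euclidean ball of ``dilation_mm`` in world units.

    Anisotropic voxels are handled through the per-axis sampling of the
    distance transform; dilation_mm = 0 returns the RZ itself.
    """
    rz = np.asarray(rz, dtype=bool)
    if not rz.any():
        raise CohortValidationError("resection zone is empty")
    if dilation_mm < 0:
        raise CohortValidationError("dilation_mm must be >= 0")
    if dilation_mm == 0:
        return rz.copy()
    dist = ndi.distance_transform_edt(~rz, sampling=tuple(voxel_mm))
    return dist <= dilation_mm


def positive_predictive_value(
    ez_map: IDrArKMap,
    erz: np.ndarray,
    method: str = "iDrArK",
) -> DetectionResult:
    """Count clusters whose majority of voxels lies inside the eRZ."""
    erz = np.asarray(erz, dtype=bool)
    if erz.shape != ez_map.overlap_mask.shape:
        raise CohortValidationError("eRZ grid differs from map grid")
    nc_erz = 0
    for cluster in ez_map.clusters:
        inside = erz[tuple(cluster.coords.T)].sum()
        if inside > 0.5 * cluster.size:
            nc_erz += 1
    return DetectionResult(
        subject_id=ez_map.subject_id,
        method=method,
        nc=ez_map.n_clusters,
        nc_erz=nc_erz,
        restricted=ez_map.restricted_to is not None,
    )


def evaluate_cohort(
    results: Iterable[DetectionResult], success_threshold: float = 0.5
) -> CohortEvaluation:
    """Aggregate per-subject classifications into cohort counts."""
    results = list(results)
    method = results[0].method if results else ""
    counts = {"SD": 0, "UD": 0, "NS": 0}
    for r in results:
        counts[r.status(success_threshold)] += 1
    return CohortEvaluation(
        method=method, sd=counts["SD"], ud=counts["UD"], ns=counts["NS"]
    )


def two_step_utility(
    results_unrestricted: Sequence[DetectionResult],
    results_restricted: Sequence[DetectionResult],
    subgroup: Sequence[str],
    success_threshold: float = 0.5,
) -> pd.DataFrame:
    """Accuracy/DR of the one-step vs two-step approach on the subgroup of
    subjects with a significant lobar result."""
    rows = []
    for name, results in (
        ("one_step", results_unrestricted),
        ("two_step", results_restricted),
    ):
        by_id = {r.subject_id: r for r in results}
        missing = [sid for sid in subgroup if sid not in by_id]
        if missing:
            raise CohortValidationError(
                f"{name}: missing results for subgroup subjects {missing}"
            )
        ev = evaluate_cohort(
            [by_id[sid] for sid in subgroup], success_threshold
        )
        row = ev.as_row()
        row["method"] = name
        rows.append(row)
    return pd.DataFrame(rows)
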