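"""End-to-end orchestration of the two-step detection.

Per patient: (1) build the symmetric skeleton from the patient-plus-controls
FA maps, test the AI maps of one metric in both directions with the
permutation-FWE procedure, and aggregate into the lobar asymmetry index;
(2) build the iDrArK overlap map (and optionally the single-metric and
pairwise comparison maps) from uncorrected one-tailed t-maps, restricted to
the detected lobe when step 1 was significant; (3) score each map against
the dilated resection zone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohort_io import AnalysisConfig, Cohort, CohortValidationError
from .ez_detection import (
    IDrArKMap,
    binarize_direction_maps,
    intersect_and_filter,
    restrict_to_lobe,
)
from .evaluation import (
    CohortEvaluation,
    DetectionResult,
    evaluate_cohort,
    extend_resection_zone,
    positive_predictive_value,
)
from .lobar_detection import LobarResult, lobar_asymmetry_index
from .skeleton_asymmetry import (
    SymmetricSkeleton,
    asymmetry_index,
    build_symmetric_skeleton,
    project_to_skeleton,
)
from .voxel_inference import GLMDesign, permutation_fwe

__all__ = [
    "METHOD_METRICS",
    "analyze_lobar",
    "analyze_ez",
    "run_patient",
    "run_cohort",
]

#: evaluated map families: metric subsets fed to the overlap constructor
METHOD_METRICS: Dict[str, Tuple[str, ...]] = {
    "FA": ("fa",),
    "MD": ("md",),
    "MK": ("mk",),
    "MD_MK": ("md", "mk"),
    "MD_FA": ("md", "fa"),
    "FA_MK": ("fa", "mk"),
    "iDrArK": ("md", "fa", "mk"),
}


def _covariates(subjects) -> Tuple[np.ndarray, np.ndarray]:
    sex = np.array([1.0 if s.sex == "M" else 0.0 for s in subjects])
    age = np.array([s.age for s in subjects])
    return sex, age


def analyze_lobar(
    cohort: Cohort,
    patient_id: str,
    cfg: AnalysisConfig,
    metric: str = "mk",
    skeleton: Optional[SymmetricSkeleton] = None,
) -> Tuple[LobarResult, SymmetricSkeleton]:
    """Step 1 for one patient: skeleton AI permutation test + LAI."""
    patient = cohort.patient(patient_id)
    subjects = cohort.controls + [patient]
    if skeleton is None:
        skeleton = build_symmetric_skeleton(
            [s.fa for s in subjects], cohort.brain_mask, cohort.lobe_atlas, cfg
        )
    ai_rows = []
    for s in subjects:
        r, l = project_to_skeleton(s, skeleton, metric)
        ai_rows.append(asymmetry_index(r, l))
    Y = np.stack(ai_rows)
    group = np.array([0.0] * len(cohort.controls) + [1.0])
    sex, age = _covariates(subjects)
    sig_masks = {}
    for tail in ("greater", "less"):
        design = GLMDesign(
            response=Y, group_indicator=group, sex=sex, age=age, tail=tail
        )
        res = permutation_fwe(
            design,
            positions=skeleton.pairs_right,
            shape=skeleton.skeleton_mask.shape,
            cfg=cfg,
        )
        sig_masks[tail] = res.sig_mask
    lobar = lobar_asymmetry_index(
        sig_masks, skeleton, cohort.lobe_atlas, cfg, metric=metric,
        subject_id=patient_id,
    )
    return lobar, skeleton


def analyze_ez(
    cohort: Cohort,
    patient_id: str,
    cfg: AnalysisConfig,
    lobar: Optional[LobarResult] = None,
    methods: Sequence[str] = ("iDrArK",),
) -> Dict[str, IDrArKMap]:
    """Step 2 for one patient: overlap maps for the requested methods,
    lobe-restricted when a significant lobar result is supplied."""
    patient = cohort.patient(patient_id)
    needed = sorted({m for name in methods for m in METHOD_METRICS[name]})
    masks = binarize_direction_maps(
        patient, cohort.controls, cohort.brain_mask, cfg, metrics=needed
    )
    out: Dict[str, IDrArKMap] = {}
    for name in methods:
        sub = {m: masks[m] for m in METHOD_METRICS[name]}
        ez = intersect_and_filter(sub, cfg, subject_id=patient_id)
        if lobar is not None:
            ez = restrict_to_lobe(ez, lobar, cohort.lobe_atlas, cfg)
        out[name] = ez
    return out


@dataclass
class PatientOutcome:
    """Everything the pipeline derives for one patient."""

    subject_id: str
    lobar: Optional[LobarResult]
    ez_maps: Dict[str, IDrArKMap]
    detections: Dict[str, DetectionResult]


def run_patient(
    cohort: Cohort,
    patient_id: str,
    cfg: AnalysisConfig,
    lai_metric: str = "mk",
    methods: Sequence[str] = tuple(METHOD_METRICS),
    restrict: bool = True,
    skeleton: Optional[SymmetricSkeleton] = None,
) -> PatientOutcome:
    lobar: Optional[LobarResult] = None
    if restrict:
        lobar, _ = analyze_lobar(
            cohort, patient_id, cfg, metric=lai_metric, skeleton=skeleton
        )
    ez_maps = analyze_ez(cohort, patient_id, cfg, lobar=lobar, methods=methods)
    detections: Dict[str, DetectionResult] = {}
    rz = cohort.resection_zones.get(patient_id)
    if rz is not None:
        erz = extend_resection_zone(rz, cohort.voxel_mm, cfg.erz_dilation_mm)
        for name, ez in ez_maps.items():
            detections[name] = positive_predictive_value(ez, erz, method=name)
    return PatientOutcome(
        subject_id=patient_id, lobar=lobar, ez_maps=ez_maps,
        detections=detections,
    )


def run_cohort(
    cohort: Cohort,
    cfg: AnalysisConfig,
    lai_metric: str = "mk",
    methods: Sequence[str] = tuple(METHOD_METRICS),
    restrict: bool = True,
) -> Tuple[pd.DataFrame, List[PatientOutcome]]:
    """Run every patient and build the method-by-method summary table."""
    missing = [
        p.subject_id
        for p in cohort.patients
        if p.subject_id not in cohort.resection_zones
    ]
    if missing:
        raise CohortValidationError(
            f"evaluation requires resection zones; missing for {missing}"
        )
    outcomes = [
        run_patient(cohort, p.subject_id, cfg, lai_metric, methods, restrict)
        for p in cohort.patients
    ]
    rows = []
    for name in methods:
        ev: CohortEvaluation = evaluate_cohort(
            [o.detections[name] for o in outcomes],
            cfg.ppv_success_threshold,
        )
        rows.append(ev.as_row())
    return pd.DataFrame(rows), outcomes
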