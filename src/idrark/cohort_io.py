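"""Cohort data model and NIfTI / manifest I/O.

A cohort is described by a CSV manifest (one row per subject, columns
``subject_id, group, sex, age, md_file, fa_file, mk_file`` and optionally
``rz_file`` for patients with a known resection zone) plus three shared
volumes that live next to it: ``brain_mask.nii.gz``, ``lobe_atlas.nii.gz``
and a ``lobe_legend.csv`` mapping atlas labels to (lobe, hemisphere).

All volumes must be co-registered on a single grid; a grid mismatch is an
error, never a silent resample, because the left-right voxel pairing of the
asymmetry analysis depends on exact voxel correspondence.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ParametricMapSet",
    "LobeAtlas",
    "Cohort",
    "AnalysisConfig",
    "CohortValidationError",
    "read_volume",
    "write_map",
    "read_cohort",
    "write_cohort",
]

METRICS = ("md", "fa", "mk")

#: axis across which left/right hemispheres mirror (voxel index i -> nx-1-i).
#: The half with the larger index along this axis is "right".
MIRROR_AXIS = 0


class CohortValidationError(ValueError):
    """A cohort, map set or atlas violates a structural invariant."""


def _affines_match(a: np.ndarray, b: np.ndarray, tol: float = 1e-4) -> bool:
    return a.shape == b.shape and np.allclose(a, b, atol=tol)


@dataclass
class ParametricMapSet:
    """One subject's co-registered MD/FA/MK volumes plus demographics.

    MD is in um^2/ms, FA dimensionless in [0, 1], MK dimensionless >= 0.
    """

    subject_id: str
    group: str  # "patient" | "control"
    sex: str  # "M" | "F"
    age: float
    md: np.ndarray
    fa: np.ndarray
    mk: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise CohortValidationError(
                f"subject {self.subject_id}: unknown group {self.group!r}"
            )
        if self.sex not in ("M", "F"):
            raise CohortValidationError(
                f"subject {self.subject_id}: unknown sex {self.sex!r}"
            )
        if not self.age > 0:
            raise CohortValidationError(
                f"subject {self.subject_id}: age must be positive"
            )
        if not (self.md.shape == self.fa.shape == self.mk.shape):
            raise CohortValidationError(
                f"subject {self.subject_id}: MD/FA/MK shapes differ"
            )

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.md.shape

    @property
    def voxel_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def metric(self, name: str) -> np.ndarray:
        name = name.lower()
        if name not in METRICS:
            raise KeyError(f"unknown metric {name!r}")
        return getattr(self, name)

    def validate_ranges(self, brain_mask: np.ndarray) -> None:
        """Check physical value ranges inside the brain mask."""
        m = brain_mask.astype(bool)
        fa = self.fa[m]
        if fa.size and (fa.min() < -1e-6 or fa.max() > 1 + 1e-6):
            raise CohortValidationError(
                f"subject {self.subject_id}: FA outside [0, 1] inside mask"
            )
        for name in ("md", "mk"):
            v = getattr(self, name)[m]
            if v.size and v.min() < -1e-6:
                raise CohortValidationError(
                    f"subject {self.subject_id}: negative {name.upper()} inside mask"
                )


@dataclass
class LobeAtlas:
    """Integer-labelled lobe parcellation, mirror-symmetric across the
    midsagittal plane.

    ``legend`` maps each nonzero label to ``(lobe_name, hemisphere)`` with
    hemisphere in {"left", "right"}.  The midsagittal plane sits between the
    two central slices along :data:`MIRROR_AXIS`, i.e. at voxel index
    ``(n - 1) / 2``.
    """

    labels: np.ndarray
    legend: Dict[int, Tuple[str, str]]

    def __post_init__(self) -> None:
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.legend)
        if missing:
            raise CohortValidationError(
                f"atlas labels without legend entry: {sorted(missing)}"
            )
        for lab, (_, hemi) in self.legend.items():
            if hemi not in ("left", "right"):
                raise CohortValidationError(
                    f"atlas label {lab}: bad hemisphere {hemi!r}"
                )

    @property
    def midsagittal_plane(self) -> float:
        return (self.labels.shape[MIRROR_AXIS] - 1) / 2.0

    def mirror_index(self, idx: Tuple[int, int, int]) -> Tuple[int, int, int]:
        out = list(idx)
        out[MIRROR_AXIS] = self.labels.shape[MIRROR_AXIS] - 1 - idx[MIRROR_AXIS]
        return tuple(out)

    def region_mask(self, lobe_name: str, hemisphere: str) -> np.ndarray:
        """Binary mask of one (lobe, hemisphere) region."""
        labs = [
            lab
            for lab, (name, hemi) in self.legend.items()
            if name == lobe_name and hemi == hemisphere
        ]
        if not labs:
            raise KeyError(f"no atlas label for ({lobe_name}, {hemisphere})")
        return np.isin(self.labels, labs)

    def lobe_hemis(self) -> List[Tuple[str, str]]:
        return sorted(set(self.legend.values()))

    def check_symmetry(self) -> None:
        """Verify the mirror invariant: a voxel's mirror carries the same
        lobe name on the opposite hemisphere."""
        mirrored = np.flip(self.labels, axis=MIRROR_AXIS)
        pair_of: Dict[int, int] = {0: 0}
        for lab, (name, hemi) in self.legend.items():
            opp = "left" if hemi == "right" else "right"
            partner = [
                l2 for l2, v in self.legend.items() if v == (name, opp)
            ]
            if len(partner) != 1:
                raise CohortValidationError(
                    f"atlas label {lab} ({name}, {hemi}) has no unique mirror label"
                )
            pair_of[lab] = partner[0]
        lut = np.zeros(max(pair_of) + 1, dtype=self.labels.dtype)
        for lab, partner in pair_of.items():
            lut[lab] = partner
        if not np.array_equal(lut[mirrored], self.labels):
            raise CohortValidationError("lobe atlas is not left-right symmetric")


@dataclass
class Cohort:
    """A control group plus patients on one shared grid."""

    controls: List[ParametricMapSet]
    patients: List[ParametricMapSet]
    brain_mask: np.ndarray
    lobe_atlas: LobeAtlas
    affine: np.ndarray
    resection_zones: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        subjects = self.controls + self.patients
        if not subjects:
            raise CohortValidationError("cohort has no subjects")
        shape = self.brain_mask.shape
        for s in subjects:
            if s.shape != shape:
                raise CohortValidationError(
                    f"subject {s.subject_id}: grid shape {s.shape} != cohort {shape}"
                )
            if not _affines_match(s.affine, self.affine):
                raise CohortValidationError(
                    f"subject {s.subject_id}: affine differs from cohort affine"
                )
        if self.lobe_atlas.labels.shape != shape:
            raise CohortValidationError("lobe atlas grid differs from cohort grid")
        patient_ids = {p.subject_id for p in self.patients}
        for pid, rz in self.resection_zones.items():
            if pid not in patient_ids:
                raise CohortValidationError(
                    f"resection zone for unknown patient {pid!r}"
                )
            if rz.shape != shape:
                raise CohortValidationError(
                    f"resection zone for {pid}: grid mismatch"
                )
        for s in subjects:
            s.validate_ranges(self.brain_mask)

    @property
    def voxel_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def patient(self, subject_id: str) -> ParametricMapSet:
        for p in self.patients:
            if p.subject_id == subject_id:
                return p
        raise KeyError(f"no patient {subject_id!r} in cohort")


@dataclass
class AnalysisConfig:
    """All tunable constants of the detection protocol.

    Defaults reproduce the published protocol: deep-WM skeleton from mean FA
    thresholded at 0.2; skeleton inference with permutation FWE at alpha
    0.05; whole-volume maps thresholded at one-tailed p < 0.001 uncorrected;
    clusters under 20 voxels discarded; resection zones dilated by 10 mm;
    a detection counts as successful when at least half of its clusters fall
    inside the extended resection zone.
    """

    fa_skeleton_threshold: float = 0.2
    voxelwise_p: float = 0.001
    fwe_alpha: float = 0.05
    min_cluster_voxels: int = 20
    erz_dilation_mm: float = 10.0
    ppv_success_threshold: float = 0.5
    n_permutations: Optional[int] = None  # None -> exhaustive label reassignment
    tfce_E: float = 0.5
    tfce_H: float = 2.0
    tfce_dh: Optional[float] = None  # None -> max(stat)/100 per map
    cluster_connectivity: int = 26
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fa_skeleton_threshold",
            "voxelwise_p",
            "fwe_alpha",
            "min_cluster_voxels",
        ):
            if not getattr(self, name) > 0:
                raise CohortValidationError(f"config: {name} must be positive")
        if self.erz_dilation_mm < 0:
            raise CohortValidationError("config: erz_dilation_mm must be >= 0")
        if not 0 < self.ppv_success_threshold <= 1:
            raise CohortValidationError(
                "config: ppv_success_threshold must lie in (0, 1]"
            )
        if self.cluster_connectivity not in (6, 18, 26):
            raise CohortValidationError(
                "config: cluster_connectivity must be 6, 18 or 26"
            )

    @classmethod
    def from_file(cls, path: str) -> "AnalysisConfig":
        """Load from YAML (or JSON, which YAML subsumes); unknown keys error."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise CohortValidationError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# NIfTI and manifest I/O


def read_volume(path: str) -> Tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (data, affine)."""
    img = nib.load(path)
    return np.asarray(img.get_fdata()), np.asarray(img.affine)


def write_map(volume: np.ndarray, affine: np.ndarray, path: str) -> None:
    """Write a volume as NIfTI-1; round-trips bit-stable for the dtype used.

    Boolean/integer masks are stored as uint8, everything else as float32.
    """
    directory = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(directory):
        raise IOError(f"output directory does not exist: {directory}")
    if volume.dtype == bool or np.issubdtype(volume.dtype, np.integer):
        data = volume.astype(np.uint8 if volume.max(initial=0) < 256 else np.int32)
    else:
        data = volume.astype(np.float32)
    nib.save(nib.Nifti1Image(data, np.asarray(affine, dtype=float)), path)


def _read_subject_volume(
    row: pd.Series, metric: str, volumes_dir: str
) -> Tuple[np.ndarray, np.ndarray]:
    fname = row[f"{metric}_file"]
    path = os.path.join(volumes_dir, fname)
    if not os.path.exists(path):
        raise IOError(
            f"subject {row['subject_id']}: missing {metric} volume {path!r}"
        )
    return read_volume(path)


def read_legend(path: str) -> Dict[int, Tuple[str, str]]:
    df = pd.read_csv(path)
    return {
        int(r.label): (str(r.lobe_name), str(r.hemisphere))
        for r in df.itertuples()
    }


def write_cohort(cohort: Cohort, out_dir: str) -> str:
    """Write a cohort as NIfTI volumes + manifest CSV; returns the manifest
    path.  The layout is the one :func:`read_cohort` expects."""
    os.makedirs(out_dir, exist_ok=True)
    aff = cohort.affine
    write_map(cohort.brain_mask, aff, os.path.join(out_dir, "brain_mask.nii.gz"))
    write_map(
        cohort.lobe_atlas.labels, aff, os.path.join(out_dir, "lobe_atlas.nii.gz")
    )
    pd.DataFrame(
        [
            {"label": lab, "lobe_name": name, "hemisphere": hemi}
            for lab, (name, hemi) in sorted(cohort.lobe_atlas.legend.items())
        ]
    ).to_csv(os.path.join(out_dir, "lobe_legend.csv"), index=False)
    rows = []
    for s in cohort.controls + cohort.patients:
        row = {
            "subject_id": s.subject_id,
            "group": s.group,
            "sex": s.sex,
            "age": s.age,
        }
        for metric in METRICS:
            fname = f"{s.subject_id}_{metric}.nii.gz"
            write_map(s.metric(metric), aff, os.path.join(out_dir, fname))
            row[f"{metric}_file"] = fname
        rz = cohort.resection_zones.get(s.subject_id)
        if rz is not None:
            fname = f"{s.subject_id}_rz.nii.gz"
            write_map(rz, aff, os.path.join(out_dir, fname))
            row["rz_file"] = fname
        rows.append(row)
    manifest_path = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return manifest_path


def read_cohort(manifest_path: str, volumes_dir: Optional[str] = None) -> Cohort:
    """Load a full cohort from a manifest CSV.

    Relative volume paths resolve against ``volumes_dir`` (default: the
    manifest's directory).  Shared volumes ``brain_mask.nii.gz``,
    ``lobe_atlas.nii.gz`` and ``lobe_legend.csv`` are read from the same
    directory.
    """
    if volumes_dir is None:
        volumes_dir = os.path.dirname(os.path.abspath(manifest_path))
    manifest = pd.read_csv(manifest_path, dtype={"subject_id": str})
    required = {"subject_id", "group", "sex", "age"} | {
        f"{m}_file" for m in METRICS
    }
    missing_cols = required - set(manifest.columns)
    if missing_cols:
        raise CohortValidationError(
            f"manifest missing columns: {sorted(missing_cols)}"
        )

    mask_path = os.path.join(volumes_dir, "brain_mask.nii.gz")
    atlas_path = os.path.join(volumes_dir, "lobe_atlas.nii.gz")
    legend_path = os.path.join(volumes_dir, "lobe_legend.csv")
    for p in (mask_path, atlas_path, legend_path):
        if not os.path.exists(p):
            raise IOError(f"missing shared cohort file {p!r}")
    brain_mask, affine = read_volume(mask_path)
    brain_mask = brain_mask > 0.5
    atlas_data, atlas_aff = read_volume(atlas_path)
    if not _affines_match(affine, atlas_aff):
        raise CohortValidationError("lobe atlas affine differs from brain mask")
    atlas = LobeAtlas(np.rint(atlas_data).astype(int), read_legend(legend_path))

    controls: List[ParametricMapSet] = []
    patients: List[ParametricMapSet] = []
    resection_zones: Dict[str, np.ndarray] = {}
    for _, row in manifest.iterrows():
        vols = {}
        for metric in METRICS:
            data, aff = _read_subject_volume(row, metric, volumes_dir)
            if not _affines_match(aff, affine):
                raise CohortValidationError(
                    f"subject {row['subject_id']}: {metric} affine differs "
                    "from cohort affine (no silent resampling)"
                )
            vols[metric] = data
        subject = ParametricMapSet(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            sex=str(row["sex"]),
            age=float(row["age"]),
            md=vols["md"],
            fa=vols["fa"],
            mk=vols["mk"],
            affine=affine,
        )
        (patients if subject.group == "patient" else controls).append(subject)
        rz_file = row.get("rz_file")
        if isinstance(rz_file, str) and rz_file:
            rz_path = os.path.join(volumes_dir, rz_file)
            if not os.path.exists(rz_path):
                raise IOError(
                    f"subject {subject.subject_id}: missing resection zone "
                    f"{rz_path!r}"
                )
            rz, rz_aff = read_volume(rz_path)
            if not _affines_match(rz_aff, affine):
                raise CohortValidationError(
                    f"subject {subject.subject_id}: resection zone affine mismatch"
                )
            resection_zones[subject.subject_id] = rz > 0.5

    return Cohort(
        controls=controls,
        patients=patients,
        brain_mask=brain_mask,
        lobe_atlas=atlas,
        affine=affine,
        resection_zones=resection_zones,
    )
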