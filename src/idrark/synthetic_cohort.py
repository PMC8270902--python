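"""Synthetic diffusion-map cohorts with planted pathology.

The generator emulates the statistical structure the detection pipeline
assumes: smooth, approximately left-right symmetric MD/FA/MK fields with
inter-subject variability for controls, and patients carrying (a) a focal
lesion with increased MD, reduced FA and reduced MK — the tissue signature
of an epileptogenic lesion — and optionally (b) a widespread mean-kurtosis
reduction across the deep white matter of one lobe, the large-scale change
the lobar asymmetry step is designed to pick up.

Default field values are conventional for healthy adult white matter:
MD ~ 0.8 um^2/ms, FA ~ 0.45 in deep WM tapering below 0.2 toward the
cortical border, MK ~ 1.0.  The phantom grid is 2 mm isotropic so that the
10 mm resection-zone dilation corresponds to a 5-voxel ball.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi

from .cohort_io import (
    MIRROR_AXIS,
    Cohort,
    CohortValidationError,
    LobeAtlas,
    ParametricMapSet,
)

__all__ = [
    "LesionSpec",
    "PhantomAnatomy",
    "make_phantom_anatomy",
    "simulate_control",
    "simulate_patient",
    "simulate_cohort",
]

# healthy-tissue reference values
MD_WM = 0.8  # um^2/ms
FA_DEEP_WM = 0.45
MK_WM = 1.0
#: coefficient of variation of the smooth subject-specific field
SUBJECT_CV = 0.03
#: relative sd of unsmoothed voxel noise
VOXEL_NOISE = 0.01
#: Gaussian sigma (voxels) of the subject-specific smooth field; stands in
#: for the smoothness real maps acquire during preprocessing
SMOOTH_SIGMA = 2.0

LOBE_NAMES = (
    "frontal",
    "parietal",
    "temporal",
    "occipital",
    "insular",
    "limbic",
)


@dataclass
class LesionSpec:
    """A focal lesion: a tapered ball with the epileptogenic DWI signature
    (MD up, FA down, MK down), plus an optional lobe-wide deep-WM MK drop.

    ``lobar_mk_decrease`` is ``(lobe_name, hemisphere, fraction)``.
    """

    center: Tuple[int, int, int]
    radius_mm: float
    delta_md: float = 0.2
    delta_fa: float = 0.2
    delta_mk: float = 0.2
    lobar_mk_decrease: Optional[Tuple[str, str, float]] = None

    def __post_init__(self) -> None:
        if not self.radius_mm > 0:
            raise CohortValidationError("lesion radius must be positive")
        for name in ("delta_md", "delta_fa", "delta_mk"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise CohortValidationError(f"lesion {name} must lie in [0, 1)")
        if self.lobar_mk_decrease is not None:
            frac = self.lobar_mk_decrease[2]
            if not 0 < frac < 1:
                raise CohortValidationError(
                    "lobar MK decrease fraction must lie in (0, 1)"
                )


@dataclass
class PhantomAnatomy:
    """Shared anatomy of a synthetic cohort: mask, atlas, WM, grid."""

    brain_mask: np.ndarray
    lobe_atlas: LobeAtlas
    wm_mask: np.ndarray
    affine: np.ndarray
    voxel_mm: float


def _ellipsoid_mask(shape: Tuple[int, int, int]) -> np.ndarray:
    idx = np.indices(shape).astype(float)
    center = [(n - 1) / 2.0 for n in shape]
    semi = [0.45 * n for n in shape]
    r2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return r2 <= 1.0


def make_phantom_anatomy(
    shape: Tuple[int, int, int] = (40, 48, 40),
    voxel_mm: float = 2.0,
    n_lobes_per_hemisphere: int = 4,
    rng_seed: int = 0,
) -> PhantomAnatomy:
    """Build an ellipsoidal brain with a mirror-symmetric lobe atlas.

    The left-right extent must be even so the midsagittal mirror plane
    falls between the two central slices.  Lobes are contiguous
    anterior-posterior slabs within each hemisphere, labelled
    ``1..n`` (right) and ``n+1..2n`` (left).
    """
    if shape[MIRROR_AXIS] % 2 != 0:
        raise CohortValidationError(
            "left-right extent must be even for a midsagittal mirror plane"
        )
    if not 1 <= n_lobes_per_hemisphere <= len(LOBE_NAMES):
        raise CohortValidationError(
            f"n_lobes_per_hemisphere must be in 1..{len(LOBE_NAMES)}"
        )
    brain_mask = _ellipsoid_mask(shape)
    wm_mask = ndi.binary_erosion(brain_mask, iterations=3)

    # anterior-posterior slabs of equal occupied extent per hemisphere
    labels = np.zeros(shape, dtype=int)
    occupied = np.where(brain_mask.any(axis=(0, 2)))[0]
    bounds = np.linspace(
        occupied[0], occupied[-1] + 1, n_lobes_per_hemisphere + 1
    ).astype(int)
    half = shape[MIRROR_AXIS] // 2
    right = np.indices(shape)[MIRROR_AXIS] >= half
    for lobe_idx in range(n_lobes_per_hemisphere):
        slab = np.zeros(shape, dtype=bool)
        slab[:, bounds[lobe_idx] : bounds[lobe_idx + 1], :] = True
        slab &= brain_mask
        labels[slab & right] = lobe_idx + 1
        labels[slab & ~right] = n_lobes_per_hemisphere + lobe_idx + 1
    legend: Dict[int, Tuple[str, str]] = {}
    for lobe_idx in range(n_lobes_per_hemisphere):
        name = LOBE_NAMES[lobe_idx]
        legend[lobe_idx + 1] = (name, "right")
        legend[n_lobes_per_hemisphere + lobe_idx + 1] = (name, "left")
    atlas = LobeAtlas(labels, legend)
    atlas.check_symmetry()

    affine = np.diag([voxel_mm] * 3 + [1.0])
    affine[:3, 3] = -np.array([(n - 1) / 2.0 for n in shape]) * voxel_mm
    return PhantomAnatomy(brain_mask, atlas, wm_mask, affine, voxel_mm)


def _mean_fields(anatomy: PhantomAnatomy) -> Dict[str, np.ndarray]:
    """Noise-free symmetric mean MD/FA/MK fields."""
    d = ndi.distance_transform_edt(anatomy.brain_mask)
    fa = FA_DEEP_WM * np.minimum(d / 4.0, 1.0)
    md = np.where(anatomy.brain_mask, MD_WM, 0.0)
    mk = np.where(anatomy.brain_mask, MK_WM, 0.0)
    return {"md": md, "fa": fa, "mk": mk}


def _smooth_field(rng: np.random.Generator, shape, mask) -> np.ndarray:
    """Unit-sd smooth random field inside the mask."""
    f = ndi.gaussian_filter(rng.standard_normal(shape), SMOOTH_SIGMA)
    sd = f[mask].std()
    return f / sd if sd > 0 else f


def _draw_maps(
    anatomy: PhantomAnatomy, rng: np.random.Generator
) -> Dict[str, np.ndarray]:
    means = _mean_fields(anatomy)
    mask = anatomy.brain_mask
    out = {}
    for name, mean in means.items():
        smooth = _smooth_field(rng, mean.shape, mask)
        noise = rng.standard_normal(mean.shape)
        vol = mean * (1.0 + SUBJECT_CV * smooth + VOXEL_NOISE * noise)
        vol = np.where(mask, vol, 0.0)
        if name == "fa":
            vol = np.clip(vol, 0.0, 1.0)
        else:
            vol = np.maximum(vol, 0.0)
        out[name] = vol
    return out


def _demographics(rng: np.random.Generator) -> Tuple[str, float]:
    sex = "M" if rng.random() < 0.5 else "F"
    age = float(np.round(rng.uniform(20, 45), 1))
    return sex, age


def simulate_control(
    anatomy: PhantomAnatomy, rng_seed: int, subject_id: str = "control"
) -> ParametricMapSet:
    """Draw one healthy subject; expectation over seeds is symmetric."""
    rng = np.random.default_rng(rng_seed)
    sex, age = _demographics(rng)
    maps = _draw_maps(anatomy, rng)
    return ParametricMapSet(
        subject_id=subject_id,
        group="control",
        sex=sex,
        age=age,
        md=maps["md"],
        fa=maps["fa"],
        mk=maps["mk"],
        affine=anatomy.affine,
    )


def lesion_ball(
    anatomy: PhantomAnatomy, center: Tuple[int, int, int], radius_mm: float
) -> np.ndarray:
    """Voxels within ``radius_mm`` (world units) of the lesion center."""
    idx = np.indices(anatomy.brain_mask.shape).astype(float)
    r2 = sum(
        ((idx[a] - center[a]) * anatomy.voxel_mm) ** 2 for a in range(3)
    )
    return r2 <= radius_mm**2


def simulate_patient(
    anatomy: PhantomAnatomy,
    lesion: LesionSpec,
    rng_seed: int,
    subject_id: str = "patient",
) -> Tuple[ParametricMapSet, np.ndarray]:
    """Draw a patient: a control draw with the lesion signature applied.

    With all deltas zero the maps equal the control draw for the same seed.
    Returns (maps, resection_zone); the resection zone is the lesion ball.
    """
    rng = np.random.default_rng(rng_seed)
    sex, age = _demographics(rng)
    maps = _draw_maps(anatomy, rng)

    if not anatomy.brain_mask[tuple(lesion.center)]:
        raise CohortValidationError("lesion center lies outside the brain mask")
    ball = lesion_ball(anatomy, lesion.center, lesion.radius_mm)

    # full effect over the lesion core, partial-volume ramp on the outer
    # quarter of the radius, 0 outside the ball
    idx = np.indices(anatomy.brain_mask.shape).astype(float)
    dist_mm = np.sqrt(
        sum(((idx[a] - lesion.center[a]) * anatomy.voxel_mm) ** 2 for a in range(3))
    )
    taper = np.clip((1.0 - dist_mm / lesion.radius_mm) / 0.25, 0.0, 1.0)
    maps["md"] = maps["md"] * (1.0 + lesion.delta_md * taper)
    maps["fa"] = maps["fa"] * (1.0 - lesion.delta_fa * taper)
    maps["mk"] = maps["mk"] * (1.0 - lesion.delta_mk * taper)

    if lesion.lobar_mk_decrease is not None:
        lobe_name, hemisphere, frac = lesion.lobar_mk_decrease
        region = anatomy.lobe_atlas.region_mask(lobe_name, hemisphere)
        deep = region & anatomy.wm_mask
        maps["mk"] = np.where(deep, maps["mk"] * (1.0 - frac), maps["mk"])

    patient = ParametricMapSet(
        subject_id=subject_id,
        group="patient",
        sex=sex,
        age=age,
        md=maps["md"],
        fa=np.clip(maps["fa"], 0.0, 1.0),
        mk=maps["mk"],
        affine=anatomy.affine,
    )
    return patient, ball & anatomy.brain_mask


def simulate_cohort(
    anatomy: PhantomAnatomy,
    n_controls: int,
    lesions: Dict[str, LesionSpec],
    rng_seed: int,
) -> Cohort:
    """Simulate ``n_controls`` controls plus one patient per lesion spec.

    All per-subject randomness derives from independent child seeds of
    ``rng_seed``, so results do not depend on generation order.
    """
    root = np.random.SeedSequence(rng_seed)
    seeds = root.generate_state(n_controls + len(lesions)) % (2**31)
    controls = [
        simulate_control(anatomy, int(seeds[i]), subject_id=f"ctrl{i:03d}")
        for i in range(n_controls)
    ]
    patients = []
    resection_zones = {}
    for offset, (pid, lesion) in enumerate(sorted(lesions.items())):
        pat, rz = simulate_patient(
            anatomy, lesion, int(seeds[n_controls + offset]), subject_id=pid
        )
        patients.append(pat)
        resection_zones[pid] = rz
    return Cohort(
        controls=controls,
        patients=patients,
        brain_mask=anatomy.brain_mask,
        lobe_atlas=anatomy.lobe_atlas,
        affine=anatomy.affine,
        resection_zones=resection_zones,
    )
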