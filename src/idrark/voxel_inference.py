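"""Single-patient versus control-group inference.

Two regimes are used by the pipeline:

* skeleton AI maps — one-tailed two-sample t (one patient vs controls, sex
  and age as nuisance covariates) assessed nonparametrically: the test
  statistic is enhanced with threshold-free cluster enhancement (TFCE) and
  compared against the permutation distribution of its maximum, giving
  family-wise-error-corrected p-values;
* whole-volume parametric maps — the same GLM t statistic thresholded at
  an uncorrected one-tailed parametric p (default 0.001).

With a single patient the only exchangeable permutation scheme is to move
the "patient" label across subjects; the group column of the design is
relabelled while data and nuisance covariates stay attached to their
subjects, so every null statistic is the covariate-adjusted deviation of
one subject.  The permutation p-value uses the +1 correction, so the
smallest attainable p with N subjects is 1/N.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from scipy import stats

from .cohort_io import AnalysisConfig, CohortValidationError

__all__ = [
    "GLMDesign",
    "StatResult",
    "fit_glm_t",
    "tfce",
    "permutation_fwe",
    "parametric_t_threshold",
    "connectivity_structure",
]


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3-D structuring element for 6/18/26-neighbourhoods."""
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise CohortValidationError("connectivity must be 6, 18 or 26")
    return ndi.generate_binary_structure(3, order[connectivity])


@dataclass
class GLMDesign:
    """One patient against controls, with optional sex/age nuisances.

    ``response`` is (n_subjects, n_voxels); ``group_indicator`` carries a
    single 1 for the patient.  ``tail`` selects the alternative for the
    group coefficient: "greater" (patient above controls) or "less".
    """

    response: np.ndarray
    group_indicator: np.ndarray
    sex: Optional[np.ndarray] = None  # coded 0/1
    age: Optional[np.ndarray] = None  # years; mean-centered internally
    tail: str = "greater"

    def __post_init__(self) -> None:
        self.response = np.atleast_2d(np.asarray(self.response, dtype=float))
        self.group_indicator = np.asarray(self.group_indicator, dtype=float)
        if self.group_indicator.sum() != 1:
            raise CohortValidationError(
                "exactly one subject must carry the patient label"
            )
        if self.tail not in ("greater", "less"):
            raise CohortValidationError("tail must be 'greater' or 'less'")
        if self.response.shape[0] != self.group_indicator.size:
            raise CohortValidationError("response rows != number of subjects")

    @property
    def n_subjects(self) -> int:
        return self.response.shape[0]

    def design_matrix(self) -> np.ndarray:
        n = self.n_subjects
        cols = [np.ones(n), self.group_indicator]
        if self.sex is not None:
            cols.append(np.asarray(self.sex, dtype=float))
        if self.age is not None:
            age = np.asarray(self.age, dtype=float)
            cols.append(age - age.mean())
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise CohortValidationError("rank-deficient design matrix")
        return X


def _t_from_X(X: np.ndarray, Y: np.ndarray, coef: int = 1) -> Tuple[np.ndarray, int]:
    """Vectorized OLS t statistic for one coefficient across all voxels."""
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise CohortValidationError(f"non-positive residual df ({df})")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[coef, coef], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[coef] / se, 0.0)
    return t, df


def fit_glm_t(design: GLMDesign) -> Tuple[np.ndarray, int]:
    """Per-voxel group-coefficient t and its residual df.

    Equivalent, without covariates, to the unequal-n two-sample t with
    n1 = 1 (the single-case-versus-controls statistic).
    """
    return _t_from_X(design.design_matrix(), design.response)


def tfce(
    stat_map: np.ndarray,
    E: float = 0.5,
    H: float = 2.0,
    dh: Optional[float] = None,
    connectivity: int = 26,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a nonnegative 3-D map.

    TFCE(v) = sum over thresholds h (step dh) of extent(v, h)^E * h^H * dh,
    where extent(v, h) is the size of the connected supra-threshold
    component containing v.  Negative input values are clamped to zero;
    ``dh`` defaults to max(stat)/100.
    """
    if dh is not None and not dh > 0:
        raise CohortValidationError("tfce dh must be positive")
    stat = np.maximum(np.asarray(stat_map, dtype=float), 0.0)
    out = np.zeros_like(stat)
    m = float(stat.max())
    if m <= 0:
        return out
    if dh is None:
        dh = m / 100.0
    structure = connectivity_structure(connectivity)
    h = dh
    while h <= m + 1e-12:
        supra = stat >= h
        labels, n = ndi.label(supra, structure=structure)
        if n == 0:
            break
        sizes = np.bincount(labels.ravel())
        out[supra] += sizes[labels[supra]] ** E * h**H * dh
        h += dh
    return out


def _tfce_max_and_map(
    t: np.ndarray,
    positions: np.ndarray,
    shape: Tuple[int, int, int],
    cfg: AnalysisConfig,
    dh: Optional[float],
) -> Tuple[np.ndarray, float]:
    vol = np.zeros(shape)
    vol[tuple(positions.T)] = np.maximum(t, 0.0)
    enh = tfce(
        vol, E=cfg.tfce_E, H=cfg.tfce_H, dh=dh,
        connectivity=cfg.cluster_connectivity,
    )
    vals = enh[tuple(positions.T)]
    return vals, float(vals.max(initial=0.0))


@dataclass
class StatResult:
    """Voxel/pair-wise statistics with the applied significance rule."""

    t_map: np.ndarray
    p_map: np.ndarray
    sig_mask: np.ndarray
    alpha: float
    method: str  # "permutation_tfce_fwe" | "parametric_uncorrected"
    tail: str
    df: int


def permutation_fwe(
    design: GLMDesign,
    positions: np.ndarray,
    shape: Tuple[int, int, int],
    cfg: AnalysisConfig,
    n_permutations: Optional[int] = None,
) -> StatResult:
    """Permutation max-TFCE FWE-corrected test of the patient-vs-controls
    contrast.

    ``positions`` (n_values, 3) places each response column in the volume
    ``shape`` so that TFCE sees the true spatial adjacency (for skeleton AI
    maps: the right-hemisphere pair coordinates).

    The null reassigns the patient label to each other subject in turn
    (direct relabeling: the group column of the design moves while data
    and covariates stay attached to their subjects), capping permutations
    at n_subjects - 1; corrected
    p(v) = (1 + #{perm max >= observed(v)}) / (1 + n_perm).
    """
    n = design.n_subjects
    cap = n - 1
    if n_permutations is None:
        n_permutations = cfg.n_permutations if cfg.n_permutations else cap
    if not 1 <= n_permutations <= cap:
        raise CohortValidationError(
            f"n_permutations must be in 1..{cap} (distinct reassignments of "
            f"the patient label among {n} subjects)"
        )

    X = design.design_matrix()
    Y = design.response
    t_obs, df = _t_from_X(X, Y)
    signed = t_obs if design.tail == "greater" else -t_obs
    dh = cfg.tfce_dh
    obs_map, _ = _tfce_max_and_map(signed, positions, shape, cfg, dh)

    patient_row = int(np.argmax(design.group_indicator))
    others = [i for i in range(n) if i != patient_row]
    if n_permutations < cap:
        rng = np.random.default_rng(cfg.rng_seed)
        others = list(rng.choice(others, size=n_permutations, replace=False))
    max_null = np.empty(len(others))
    for k, j in enumerate(others):
        Xj = X.copy()
        Xj[:, 1] = 0.0
        Xj[j, 1] = 1.0  # subject j takes the patient label
        t_perm, _ = _t_from_X(Xj, Y)
        signed_perm = t_perm if design.tail == "greater" else -t_perm
        _, max_null[k] = _tfce_max_and_map(signed_perm, positions, shape, cfg, dh)

    n_perm = len(others)
    exceed = (max_null[None, :] >= obs_map[:, None]).sum(axis=1)
    p = (1.0 + exceed) / (1.0 + n_perm)
    return StatResult(
        t_map=t_obs,
        p_map=p,
        sig_mask=p < cfg.fwe_alpha,
        alpha=cfg.fwe_alpha,
        method="permutation_tfce_fwe",
        tail=design.tail,
        df=df,
    )


def parametric_t_threshold(design: GLMDesign, p_threshold: float) -> StatResult:
    """One-tailed parametric Student-t thresholding, uncorrected."""
    t, df = fit_glm_t(design)
    if design.tail == "greater":
        p = stats.t.sf(t, df)
    else:
        p = stats.t.cdf(t, df)
    return StatResult(
        t_map=t,
        p_map=p,
        sig_mask=p < p_threshold,
        alpha=p_threshold,
        method="parametric_uncorrected",
        tail=design.tail,
        df=df,
    )
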