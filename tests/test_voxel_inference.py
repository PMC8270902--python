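"""GLM t-maps, TFCE and permutation-FWE inference."""

import numpy as np
import pytest
from scipy import stats

from idrark import (
    AnalysisConfig,
    CohortValidationError,
    GLMDesign,
    fit_glm_t,
    parametric_t_threshold,
    permutation_fwe,
    tfce,
)


def crawford_howell_t(patient, controls):
    """Closed-form unequal-n two-sample t with n1 = 1 (oracle)."""
    controls = np.asarray(controls, dtype=float)
    n = len(controls)
    return (patient - controls.mean()) / (
        controls.std(ddof=1) * np.sqrt(1 + 1 / n)
    )


class TestGLM:
    def test_patient_at_control_mean_gives_zero_t(self):
        controls = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.append(controls, controls.mean())[:, None]
        design = GLMDesign(y, np.array([0, 0, 0, 0, 0, 1.0]))
        t, df = fit_glm_t(design)
        assert t[0] == pytest.approx(0.0)
        assert df == 4

    def test_matches_closed_form_single_case_t(self):
        controls = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.append(controls, 10.0)[:, None]
        design = GLMDesign(y, np.array([0, 0, 0, 0, 0, 1.0]))
        t, df = fit_glm_t(design)
        assert t[0] == pytest.approx(crawford_howell_t(10.0, controls))
        assert df == len(controls) - 1

    def test_matches_closed_form_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = rng.integers(5, 40)
            controls = rng.normal(size=n)
            patient = rng.normal(scale=3.0)
            y = np.append(controls, patient)[:, None]
            design = GLMDesign(y, np.append(np.zeros(n), 1.0))
            t, _ = fit_glm_t(design)
            assert t[0] == pytest.approx(
                crawford_howell_t(patient, controls), rel=1e-10
            )

    def test_location_invariance(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(12, 7))
        g = np.zeros(12)
        g[3] = 1.0
        t1, _ = fit_glm_t(GLMDesign(y, g))
        t2, _ = fit_glm_t(GLMDesign(y + 42.0, g))
        assert np.allclose(t1, t2)

    def test_covariates_consume_degrees_of_freedom(self):
        rng = np.random.default_rng(2)
        n = 15
        y = rng.normal(size=(n, 3))
        g = np.zeros(n)
        g[0] = 1.0
        sex = (np.arange(n) % 2).astype(float)
        age = rng.uniform(20, 40, n)
        _, df = fit_glm_t(GLMDesign(y, g, sex=sex, age=age))
        assert df == n - 4

    def test_multiple_patients_rejected(self):
        with pytest.raises(CohortValidationError, match="exactly one"):
            GLMDesign(np.zeros((4, 2)), np.array([1, 1, 0, 0.0]))

    def test_rank_deficient_design_rejected(self):
        n = 8
        g = np.zeros(n)
        g[0] = 1.0
        with pytest.raises(CohortValidationError, match="rank"):
            GLMDesign(
                np.zeros((n, 1)), g, sex=np.ones(n), age=np.full(n, 30.0)
            ).design_matrix()


class TestTFCE:
    def test_constant_blob_matches_closed_form(self):
        """For a constant map of height h0 over one connected component of
        n voxels, the threshold integral is n^E * h0^(H+1) / (H+1)."""
        E, H = 0.5, 2.0
        vol = np.zeros((12, 12, 12))
        vol[3:9, 3:9, 3:9] = 0.8
        n = 6**3
        expected = n**E * 0.8 ** (H + 1) / (H + 1)
        for dh, tol in [(0.8 / 100, 0.02), (0.8 / 200, 0.01)]:
            enh = tfce(vol, E=E, H=H, dh=dh)
            got = enh[5, 5, 5]
            assert got == pytest.approx(expected, rel=tol)

    def test_riemann_error_shrinks_linearly_with_dh(self):
        vol = np.zeros((10, 10, 10))
        vol[2:8, 2:8, 2:8] = 1.0
        n, E, H = 6**3, 0.5, 2.0
        exact = n**E * 1.0 / (H + 1)
        err = []
        for dh in (0.04, 0.02, 0.01):
            err.append(abs(tfce(vol, dh=dh)[4, 4, 4] - exact))
        assert err[1] < err[0] and err[2] < err[1]
        # first-order bound: error <= dh * n^E * max(h)^H
        for dh, e in zip((0.04, 0.02, 0.01), err):
            assert e <= dh * n**E * 1.0 + 1e-9

    def test_zero_map_stays_zero_and_negatives_clamped(self):
        assert tfce(np.zeros((5, 5, 5))).sum() == 0.0
        assert tfce(np.full((5, 5, 5), -3.0)).sum() == 0.0

    def test_pointwise_monotone_in_input(self):
        rng = np.random.default_rng(3)
        a = rng.random((8, 8, 8))
        b = a + rng.random((8, 8, 8))
        dh = b.max() / 100
        assert np.all(tfce(b, dh=dh) >= tfce(a, dh=dh) - 1e-12)

    def test_nonpositive_dh_rejected(self):
        with pytest.raises(CohortValidationError, match="dh"):
            tfce(np.ones((4, 4, 4)), dh=0.0)


def _null_design(n_controls, n_vox, rng, tail="greater"):
    y = rng.normal(size=(n_controls + 1, n_vox))
    g = np.zeros(n_controls + 1)
    g[-1] = 1.0
    return GLMDesign(y, g, tail=tail)


class TestPermutationFWE:
    def test_minimum_attainable_p_is_one_over_n_subjects(self):
        rng = np.random.default_rng(4)
        n_controls, n_vox = 9, 8
        design = _null_design(n_controls, n_vox, rng)
        positions = np.column_stack(
            [np.arange(n_vox), np.zeros(n_vox, int), np.zeros(n_vox, int)]
        )
        cfg = AnalysisConfig(rng_seed=0)
        res = permutation_fwe(design, positions, (n_vox, 1, 1), cfg)
        assert res.p_map.min() >= 1 / (n_controls + 1)
        assert np.all(res.p_map <= 1.0)

    def test_permutation_count_above_cap_errors(self):
        rng = np.random.default_rng(5)
        design = _null_design(6, 4, rng)
        positions = np.column_stack(
            [np.arange(4), np.zeros(4, int), np.zeros(4, int)]
        )
        cfg = AnalysisConfig()
        with pytest.raises(CohortValidationError, match="reassignments"):
            permutation_fwe(design, positions, (4, 1, 1), cfg,
                            n_permutations=99)

    def test_planted_strong_effect_detected(self, small_anatomy):
        """Power check: a strong one-sided shift at a block of voxels must
        reach FWE significance under exhaustive reassignment."""
        rng = np.random.default_rng(6)
        n_controls, n_vox = 25, 60
        design = _null_design(n_controls, n_vox, rng)
        design.response[-1, 10:30] += 8.0  # patient carries the effect
        positions = np.column_stack(
            [np.arange(n_vox), np.zeros(n_vox, int), np.zeros(n_vox, int)]
        )
        cfg = AnalysisConfig(rng_seed=0)
        res = permutation_fwe(design, positions, (n_vox, 1, 1), cfg)
        assert res.sig_mask[10:30].all()
        assert not res.sig_mask[:10].any() and not res.sig_mask[30:].any()


class TestParametricThreshold:
    def test_zero_t_gives_half_p_not_significant(self):
        controls = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.append(controls, controls.mean())[:, None]
        design = GLMDesign(y, np.append(np.zeros(5), 1.0))
        res = parametric_t_threshold(design, 0.001)
        assert res.p_map[0] == pytest.approx(0.5)
        assert not res.sig_mask[0]

    def test_boundary_quantile_excluded_by_strict_inequality(self):
        """A t exactly at the 0.999 Student quantile has one-tailed
        p = 0.001 and is excluded by p < 0.001 (oracle: quantile lookup)."""
        rng = np.random.default_rng(7)
        n = 30
        controls = rng.normal(size=n)
        y = np.append(controls, 0.0)[:, None]
        g = np.append(np.zeros(n), 1.0)
        design = GLMDesign(y, g)
        t, df = fit_glm_t(design)
        t_crit = stats.t.ppf(0.999, df)
        # rescale the patient value so the t statistic lands on t_crit
        mu, sd = controls.mean(), controls.std(ddof=1)
        patient = mu + t_crit * sd * np.sqrt(1 + 1 / n)
        design = GLMDesign(np.append(controls, patient)[:, None], g)
        res = parametric_t_threshold(design, 0.001)
        assert res.p_map[0] == pytest.approx(0.001, rel=1e-9)
        # strict inequality is the rule (boundary excluded up to float
        # round-trip of the quantile)
        assert res.sig_mask[0] == (res.p_map[0] < 0.001)
        # a t just below the quantile has p > 0.001 and is excluded
        design = GLMDesign(
            np.append(controls, patient - 0.01 * sd)[:, None], g
        )
        res = parametric_t_threshold(design, 0.001)
        assert res.p_map[0] > 0.001 and not res.sig_mask[0]

    def test_tail_flip_mirrors_significance(self):
        rng = np.random.default_rng(8)
        n = 20
        y = rng.normal(size=(n + 1, 10))
        y[-1, :5] += 5.0
        y[-1, 5:] -= 5.0
        g = np.append(np.zeros(n), 1.0)
        up = parametric_t_threshold(GLMDesign(y, g, tail="greater"), 0.01)
        dn = parametric_t_threshold(GLMDesign(y, g, tail="less"), 0.01)
        assert up.sig_mask[:5].all() and not up.sig_mask[5:].any()
        assert dn.sig_mask[5:].all() and not dn.sig_mask[:5].any()
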