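"""iDrArK overlap construction, cluster filtering and lobe restriction."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from idrark import (
    AnalysisConfig,
    LesionSpec,
    LobarResult,
    binarize_direction_maps,
    intersect_and_filter,
    restrict_to_lobe,
    simulate_cohort,
)


def _cfg(**kw):
    return AnalysisConfig(**kw)


def _lobar(selected, significant):
    return LobarResult(
        metric="mk", subject_id="p", lai_table={}, n_vx_lobe={},
        n_sig_lobe={}, selected=selected, significant=significant,
    )


class TestBinarize:
    def test_patient_equal_to_control_field_gives_empty_masks(
        self, small_anatomy
    ):
        cohort = simulate_cohort(
            small_anatomy, 12,
            {"p": LesionSpec(center=(14, 16, 10), radius_mm=6.0,
                             delta_md=0, delta_fa=0, delta_mk=0)},
            rng_seed=3,
        )
        masks = binarize_direction_maps(
            cohort.patients[0], cohort.controls, cohort.brain_mask, _cfg()
        )
        # p < 0.001 in a null patient: a handful of voxels at most
        n_mask = cohort.brain_mask.sum()
        for m in masks.values():
            assert m.sum() < 0.01 * n_mask

    def test_strong_lesion_covered_by_all_three_masks(self, small_cohort):
        cohort = small_cohort
        masks = binarize_direction_maps(
            cohort.patients[0], cohort.controls, cohort.brain_mask, _cfg()
        )
        core = tuple((14, 16, 10))
        for m in masks.values():
            assert m[core]

    def test_md_only_lesion_leaves_fa_mk_masks_empty_at_core(
        self, small_anatomy
    ):
        cohort = simulate_cohort(
            small_anatomy, 12,
            {"p": LesionSpec(center=(14, 16, 10), radius_mm=6.0,
                             delta_md=0.3, delta_fa=0.0, delta_mk=0.0)},
            rng_seed=4,
        )
        masks = binarize_direction_maps(
            cohort.patients[0], cohort.controls, cohort.brain_mask, _cfg()
        )
        ball = ndi.binary_dilation(
            cohort.resection_zones["p"], iterations=1
        )
        assert masks["md"][ball].sum() > 0
        assert masks["fa"][ball].sum() == 0
        assert masks["mk"][ball].sum() == 0


class TestIntersectAndFilter:
    def _block_mask(self, shape, n_voxels):
        m = np.zeros(shape, dtype=bool)
        # one connected block of exactly n_voxels (fill a 5x5 column)
        count = 0
        for i in range(shape[0]):
            for j in range(5):
                for k in range(5):
                    if count < n_voxels:
                        m[i, j, k] = True
                        count += 1
        return m

    def test_empty_member_absorbs_intersection(self):
        shape = (10, 10, 10)
        a = np.ones(shape, dtype=bool)
        b = np.ones(shape, dtype=bool)
        c = np.zeros(shape, dtype=bool)
        out = intersect_and_filter({"md": a, "fa": b, "mk": c}, _cfg())
        assert out.overlap_mask.sum() == 0 and out.n_clusters == 0

    @pytest.mark.parametrize("n,kept", [(19, 0), (20, 1), (21, 1)])
    def test_minimum_cluster_size_boundary(self, n, kept):
        shape = (10, 10, 10)
        m = self._block_mask(shape, n)
        out = intersect_and_filter({"md": m}, _cfg())
        assert out.n_clusters == kept
        assert out.overlap_mask.sum() == (n if kept else 0)

    def test_overlap_is_subset_of_every_source(self):
        rng = np.random.default_rng(5)
        shape = (12, 12, 12)
        masks = {
            m: ndi.binary_dilation(rng.random(shape) < 0.15, iterations=2)
            for m in ("md", "fa", "mk")
        }
        out = intersect_and_filter(masks, _cfg(min_cluster_voxels=1))
        for m in masks.values():
            assert not (out.overlap_mask & ~m).any()
        for c in out.clusters:
            assert c.size >= 1

    def test_grid_mismatch_rejected(self):
        with pytest.raises(Exception, match="grid"):
            intersect_and_filter(
                {"md": np.ones((5, 5, 5), bool), "fa": np.ones((6, 6, 6), bool)},
                _cfg(),
            )


class TestRestriction:
    def _map_in_two_lobes(self, anatomy, cfg):
        """Overlap with one cluster inside (frontal,right) and one inside
        (parietal,left)."""
        atlas = anatomy.lobe_atlas
        m = np.zeros(anatomy.brain_mask.shape, dtype=bool)
        for lobe, hemi in [("frontal", "right"), ("parietal", "left")]:
            region = atlas.region_mask(lobe, hemi) & anatomy.wm_mask
            coords = np.argwhere(region)
            seed = tuple(coords[len(coords) // 2])
            blob = np.zeros_like(m)
            blob[seed] = True
            blob = ndi.binary_dilation(blob, iterations=3) & region
            m |= blob
        return intersect_and_filter({"md": m}, cfg, subject_id="p")

    def test_no_significant_lobar_result_is_identity(self, small_anatomy):
        cfg = _cfg(min_cluster_voxels=5)
        ez = self._map_in_two_lobes(small_anatomy, cfg)
        out = restrict_to_lobe(ez, _lobar(None, False),
                               small_anatomy.lobe_atlas, cfg)
        assert out is ez

    def test_restriction_keeps_only_selected_lobe(self, small_anatomy):
        cfg = _cfg(min_cluster_voxels=5)
        ez = self._map_in_two_lobes(small_anatomy, cfg)
        assert ez.n_clusters == 2
        out = restrict_to_lobe(
            ez, _lobar(("frontal", "right"), True),
            small_anatomy.lobe_atlas, cfg,
        )
        assert out.n_clusters == 1
        region = small_anatomy.lobe_atlas.region_mask("frontal", "right")
        assert not (out.overlap_mask & ~region).any()
        # never adds voxels
        assert not (out.overlap_mask & ~ez.overlap_mask).any()

    def test_restriction_noop_when_all_clusters_inside(self, small_anatomy):
        cfg = _cfg(min_cluster_voxels=5)
        ez = self._map_in_two_lobes(small_anatomy, cfg)
        out = restrict_to_lobe(
            ez, _lobar(("frontal", "right"), True),
            small_anatomy.lobe_atlas, cfg,
        )
        again = restrict_to_lobe(
            out, _lobar(("frontal", "right"), True),
            small_anatomy.lobe_atlas, cfg,
        )
        assert again.n_clusters == out.n_clusters
        assert np.array_equal(again.overlap_mask, out.overlap_mask)

    def test_boundary_remnant_removed_by_refiltering(self, small_anatomy):
        """A cluster straddling the lobe boundary whose inside part falls
        below the size filter disappears (oracle: brute-force relabel of
        the masked volume)."""
        atlas = small_anatomy.lobe_atlas
        cfg = _cfg(min_cluster_voxels=20)
        region = atlas.region_mask("frontal", "right")
        # build a 30-voxel cluster with only 12 voxels inside the region
        boundary = np.argwhere(region)
        j_edge = boundary[:, 1].max()  # lobes are y-slabs
        m = np.zeros(region.shape, dtype=bool)
        i0, _, k0 = boundary[boundary[:, 1] == j_edge][0]
        count_in = 0
        for dj in range(-1, 4):
            for di in range(3):
                for dk in range(2):
                    vx = (i0 + di, j_edge + dj, k0 + dk)
                    m[vx] = True
        assert m.sum() == 30
        inside = (m & region).sum()
        assert 0 < inside < 20
        ez = intersect_and_filter({"md": m}, cfg)
        assert ez.n_clusters == 1
        out = restrict_to_lobe(ez, _lobar(("frontal", "right"), True),
                               atlas, cfg)
        # oracle: relabel the masked volume directly
        lab, n = ndi.label(m & region, ndi.generate_binary_structure(3, 3))
        sizes = np.bincount(lab.ravel())[1:]
        assert (sizes >= 20).sum() == 0
        assert out.n_clusters == 0 and out.overlap_mask.sum() == 0
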