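"""Threshold selection, vessel extraction, volumetry, large-vessel QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lsavol.errors import DegenerateInputError, SeedError, SelectionError
from lsavol.image_io import RegionLabelMask, ScalarVolume
from lsavol.segment import (
    extract_vessels,
    flag_large_vessels,
    quantify_region_volumes,
    select_threshold,
    vascular_volume_mm3,
)
from lsavol.synth import Segment, render_angiogram


class TestSelectThreshold:
    def test_bimodal_selects_in_gap(self, bimodal_enhanced, whole_grid_roi):
        vol, truth = bimodal_enhanced()
        roi = whole_grid_roi(vol.shape)
        sel = select_threshold(vol, roi)
        assert 0.2 < sel.selected_threshold < 0.8
        # brute-force audit: every threshold in the gap yields the same mask
        gap_mask = vol.data >= sel.selected_threshold
        for t in np.linspace(0.25, 0.75, 11):
            np.testing.assert_array_equal(vol.data >= t, gap_mask)
        np.testing.assert_array_equal(gap_mask, truth)

    def test_gap_selection_across_seeds(self, bimodal_enhanced, whole_grid_roi):
        for seed in range(8):
            vol, _ = bimodal_enhanced(seed=seed, vessel_frac=0.015 + 0.003 * seed)
            sel = select_threshold(vol, whole_grid_roi(vol.shape))
            assert 0.2 < sel.selected_threshold < 0.8

    def test_unreachable_delta_raises(self, bimodal_enhanced, whole_grid_roi):
        vol, _ = bimodal_enhanced()
        with pytest.raises(SelectionError):
            select_threshold(vol, whole_grid_roi(vol.shape), delta_star=100.0)

    def test_volume_curve_non_increasing_in_threshold(self, bimodal_enhanced, whole_grid_roi):
        vol, _ = bimodal_enhanced()
        sel = select_threshold(vol, whole_grid_roi(vol.shape))
        # candidates descend, so counts grow along the walk
        assert np.all(np.diff(sel.volume_curve) >= 0)
        assert np.all(sel.ratio_change_curve >= 0)

    def test_affine_intensity_rescale_invariance(self, bimodal_enhanced, whole_grid_roi):
        vol, _ = bimodal_enhanced()
        roi = whole_grid_roi(vol.shape)
        a = select_threshold(vol, roi)
        b = select_threshold(vol.with_data(3.5 * vol.data + 11.0), roi)
        assert a.selected_step_index == b.selected_step_index
        assert b.selected_threshold == pytest.approx(
            3.5 * a.selected_threshold + 11.0, rel=1e-9
        )

    def test_constant_roi_rejected(self, whole_grid_roi):
        vol = ScalarVolume(np.full((16, 16, 16), 2.0), spacing=(1, 1, 1))
        with pytest.raises(DegenerateInputError):
            select_threshold(vol, whole_grid_roi(vol.shape, spacing=(1, 1, 1)))

    @given(step=st.floats(0.1, 5.0), seed=st.integers(0, 100))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_selected_threshold_is_a_candidate(self, step, seed):
        rng = np.random.default_rng(seed)
        data = rng.uniform(size=(12, 12, 12))
        data[:3] += 5.0  # ensure a dense low mode and sparse high mode
        vol = ScalarVolume(data, spacing=(1, 1, 1))
        roi = RegionLabelMask(np.ones(vol.shape, dtype=np.int16), {"r": 1}, spacing=(1, 1, 1))
        try:
            sel = select_threshold(vol, roi, step_percentile=step)
        except SelectionError:
            return
        assert np.isclose(sel.candidate_thresholds, sel.selected_threshold).any()


class TestExtractVessels:
    def test_no_seed_bimodal_matches_truth(self, bimodal_enhanced, whole_grid_roi):
        vol, truth = bimodal_enhanced()
        roi = whole_grid_roi(vol.shape)
        sel = select_threshold(vol, roi)
        mask = extract_vessels(vol, sel, roi)
        inter = (mask & truth).sum()
        dice = 2 * inter / (mask.sum() + truth.sum())
        assert dice >= 0.9

    def test_seed_removes_isolated_specks(self, bimodal_enhanced, whole_grid_roi):
        vol, truth = bimodal_enhanced()
        data = vol.data.copy()
        specks = [(2, 2, 2), (2, 28, 3), (28, 2, 28), (29, 29, 2), (3, 15, 28)]
        for s in specks:
            data[s] = 0.95
        vol2 = vol.with_data(data)
        roi = whole_grid_roi(vol.shape)
        sel = select_threshold(vol2, roi)
        seed = tuple(np.argwhere(truth)[0])
        mask = extract_vessels(vol2, sel, roi, seed=seed)
        # oracle: scipy connected components say the specks are isolated
        from scipy import ndimage

        labels, _ = ndimage.label(vol2.data >= sel.selected_threshold, structure=np.ones((3, 3, 3)))
        assert all(labels[s] != labels[seed] for s in specks)
        assert not any(mask[s] for s in specks)
        np.testing.assert_array_equal(mask, truth)

    def test_threshold_above_max_gives_empty_mask(self, bimodal_enhanced, whole_grid_roi):
        vol, _ = bimodal_enhanced()
        roi = whole_grid_roi(vol.shape)
        sel = select_threshold(vol, roi)
        object.__setattr__(sel, "selected_threshold", vol.data.max() + 1.0)
        object.__setattr__(sel, "candidate_thresholds",
                           np.array([vol.data.max() + 1.0]))
        assert not extract_vessels(vol, sel, roi).any()

    def test_subthreshold_seed_snaps_with_warning(self, bimodal_enhanced, whole_grid_roi):
        vol, truth = bimodal_enhanced()
        roi = whole_grid_roi(vol.shape)
        sel = select_threshold(vol, roi)
        inside = np.argwhere(truth)[0]
        outside = tuple(np.clip(inside - 2, 0, None))  # just off the blob
        assert not truth[outside]
        with pytest.warns(UserWarning, match="below threshold"):
            mask = extract_vessels(vol, sel, roi, seed=outside)
        assert mask.sum() == truth.sum()

    def test_far_seed_raises(self, bimodal_enhanced, whole_grid_roi):
        vol, truth = bimodal_enhanced()
        roi = whole_grid_roi(vol.shape)
        sel = select_threshold(vol, roi)
        with pytest.warns(UserWarning):
            with pytest.raises(SeedError):
                extract_vessels(vol, sel, roi, seed=(0, 0, 0))


class TestQuantify:
    def test_volume_rule_matches_printed_study_arithmetic(self):
        # 998.01 voxels at 0.23 x 0.23 x 0.36 mm resolution -> 19.01 mm^3
        vol = vascular_volume_mm3(998.01, (0.23, 0.23, 0.36))
        assert round(vol, 2) == 19.01

    def test_unit_spacing_count(self, whole_grid_roi):
        shape = (16, 16, 16)
        mask = np.zeros(shape, dtype=bool)
        mask.ravel()[:1000] = True
        roi = whole_grid_roi(shape, spacing=(1.0, 1.0, 1.0))
        rep = quantify_region_volumes(mask, roi, (1.0, 1.0, 1.0))
        assert rep.total_volume_mm3 == 1000.0

    def test_empty_mask_flags_fractions_undefined(self, whole_grid_roi):
        shape = (12, 12, 12)
        roi = whole_grid_roi(shape, spacing=(0.4, 0.4, 0.4))
        rep = quantify_region_volumes(np.zeros(shape, dtype=bool), roi, (0.4, 0.4, 0.4))
        assert rep.total_volume_mm3 == 0.0
        assert not rep.fractions_defined
        assert rep.per_region["roi"]["fraction_of_total_vessel"] is None

    def test_per_region_additivity_and_fractions(self):
        shape = (20, 20, 20)
        labels = np.zeros(shape, dtype=np.int16)
        labels[:10] = 1
        labels[10:] = 2
        roi = RegionLabelMask(labels, {"a": 1, "b": 2}, spacing=(0.5, 0.5, 0.5))
        rng = np.random.default_rng(0)
        mask = rng.uniform(size=shape) < 0.1
        rep = quantify_region_volumes(mask, roi, (0.5, 0.5, 0.5))
        counts = [rep.per_region[n]["voxels"] for n in ("a", "b")]
        assert sum(counts) == rep.total_voxel_count
        fr = [rep.per_region[n]["fraction_of_total_vessel"] for n in ("a", "b")]
        assert sum(fr) == pytest.approx(1.0)
        for n in ("a", "b"):
            row = rep.per_region[n]
            assert row["volume_mm3"] == row["voxels"] * 0.125


class TestLargeVesselQC:
    def _tube_mask(self, shape, spacing, radius_mm):
        seg = Segment(
            0,
            None,
            np.array([[2.0, shape[1] * spacing[1] / 2, shape[2] * spacing[2] / 2],
                      [shape[0] * spacing[0] - 2.0, shape[1] * spacing[1] / 2,
                       shape[2] * spacing[2] / 2]]),
            radius_mm,
            0,
        )
        _, truth = render_angiogram([seg], shape, spacing)
        return truth.vessel_mask

    def test_small_tubes_pass(self):
        spacing = (0.4, 0.4, 0.4)
        mask = self._tube_mask((48, 48, 48), spacing, radius_mm=0.8)  # d = 4 vox
        qc = flag_large_vessels(mask, spacing, d_max=5)
        assert qc.passed

    def test_oversized_tube_flagged(self):
        spacing = (0.4, 0.4, 0.4)
        mask = self._tube_mask((48, 48, 48), spacing, radius_mm=2.4)  # d = 12 vox
        qc = flag_large_vessels(mask, spacing, d_max=5)
        assert not qc.passed
        assert len(qc.flagged_components) == 1
        # oracle: distance transform of the truth mask
        from scipy import ndimage

        edt = ndimage.distance_transform_edt(mask, sampling=spacing)
        assert qc.flagged_components[0]["max_inscribed_radius_mm"] == pytest.approx(
            edt.max()
        )

    def test_empty_mask_passes(self):
        qc = flag_large_vessels(np.zeros((8, 8, 8), dtype=bool), (1, 1, 1))
        assert qc.passed and qc.flagged_components == []
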