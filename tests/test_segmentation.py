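"""Outlier threshold, T1 false-positive filter, and pipeline behavior."""

import numpy as np
import pytest
from dataclasses import replace

from mmseg.core import BinaryMask, connected_components
from mmseg.phantom import (
    PhantomSpec,
    confounder_blob,
    generate_phantom_pair,
    _default_organs,
)
from mmseg.registration import AtlasBundle
from mmseg.search_region import RegionSelectionParams, combine_region
from mmseg.segmentation import (
    T1FilterParams,
    ThresholdParams,
    compute_iqr_threshold,
    psoas_reference_mean,
    run_pipeline,
    t1_component_filter,
    threshold_segment,
)
from mmseg.validation import match_lesions

from .conftest import make_image, make_mask


def quartile_oracle(values):
    """Independent sort-based quartiles with linear interpolation."""
    x = np.sort(np.asarray(values, dtype=float))
    out = []
    for q in (0.25, 0.75):
        pos = (len(x) - 1) * q
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        out.append(x[lo] + (pos - lo) * (x[hi] - x[lo]))
    return out


class TestIqrThreshold:
    def test_worked_example(self):
        # {1,2,3,4,100}: Q1=2, Q3=4 -> 4 + 4*2 = 12
        assert compute_iqr_threshold([1, 2, 3, 4, 100], ThresholdParams(k=4)) == 12.0

    def test_constant_input_warns_and_degenerates(self):
        with pytest.warns(UserWarning, match="interquartile"):
            thr = compute_iqr_threshold([7.0] * 10, ThresholdParams(k=3))
        assert thr == 7.0

    def test_matches_sort_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        k = 4.0
        for _ in range(1000):
            x = rng.normal(size=rng.integers(4, 50))
            q1, q3 = quartile_oracle(x)
            assert compute_iqr_threshold(x, ThresholdParams(k=k)) == pytest.approx(
                q3 + k * (q3 - q1), rel=1e-12
            )

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            compute_iqr_threshold([1.0, 2.0, 3.0])

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            ThresholdParams(k=0.0)


class TestThresholdSegment:
    def _region_image(self, blob_value=400.0, seed=0):
        rng = np.random.default_rng(seed)
        data = rng.normal(100.0, 5.0, (20, 20, 20))
        region = np.ones_like(data, dtype=bool)
        data[3:7, 3:7, 3:5] = blob_value  # 50-ish voxel blob... exactly 4*4*2=32
        return make_image(data), make_mask(region)

    def test_single_bright_blob_recovered_exactly(self):
        dwi, region = self._region_image()
        comps = threshold_segment(dwi, region, ThresholdParams(k=4))
        assert comps.n_components == 1
        assert comps.components[0].voxel_count == 32

    def test_zero_components_for_huge_k(self):
        dwi, region = self._region_image()
        comps = threshold_segment(dwi, region, ThresholdParams(k=1e9))
        assert comps.n_components == 0

    def test_candidate_set_antitone_in_k(self):
        dwi, region = self._region_image()
        prev = None
        for k in (2.5, 4.0, 7.5):
            comps = threshold_segment(dwi, region, ThresholdParams(k=k))
            cur = comps.labels > 0
            if prev is not None:
                assert np.all(cur <= prev)
            prev = cur

    def test_segmented_voxels_inside_region(self):
        dwi, _ = self._region_image()
        region_data = np.zeros(dwi.shape, dtype=bool)
        region_data[2:10, 2:10, 2:10] = True
        comps = threshold_segment(dwi, make_mask(region_data), ThresholdParams(k=2.5))
        assert np.all((comps.labels > 0) <= region_data)

    def test_empty_region_rejected(self):
        dwi, _ = self._region_image()
        with pytest.raises(ValueError, match="empty"):
            threshold_segment(dwi, make_mask(np.zeros(dwi.shape)))

    def test_constant_region_warns_and_returns_nothing(self):
        dwi = make_image(np.full((8, 8, 8), 42.0))
        region = make_mask(np.ones((8, 8, 8)))
        with pytest.warns(UserWarning, match="IQR"):
            comps = threshold_segment(dwi, region)
        assert comps.n_components == 0


class TestPsoasReference:
    def test_constant_mask_mean(self):
        t1 = make_image(np.full((5, 5, 5), 200.0))
        mask = make_mask(np.ones((5, 5, 5)))
        assert psoas_reference_mean(t1, mask) == 200.0

    def test_arithmetic_mean(self):
        data = np.zeros((3, 1, 1))
        data[:, 0, 0] = [100.0, 200.0, 300.0]
        t1 = make_image(data)
        mask = make_mask(np.ones((3, 1, 1)))
        assert psoas_reference_mean(t1, mask) == 200.0

    def test_sampling_bound_on_noisy_region(self):
        rng = np.random.default_rng(4)
        n = 4000
        data = rng.normal(150.0, 10.0, (20, 20, 10))
        t1 = make_image(data)
        mask = make_mask(np.ones_like(data))
        assert psoas_reference_mean(t1, mask) == pytest.approx(
            150.0, abs=3 * 10 / np.sqrt(n)
        )

    def test_empty_mask_rejected(self):
        t1 = make_image(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError, match="empty"):
            psoas_reference_mean(t1, make_mask(np.zeros((3, 3, 3))))


class TestT1ComponentFilter:
    def _components(self):
        data = np.zeros((10, 4, 4), dtype=bool)
        data[0:2, 0:2, 0:2] = True  # component 1: 8 voxels
        data[5:7, 0:2, 0:2] = True  # component 2: 8 voxels
        return connected_components(make_mask(data))

    def test_hypointense_component_kept(self):
        comps = self._components()
        t1 = make_image(np.full(comps.shape, 50.0))
        out = t1_component_filter(comps, t1, psoas_mean=150.0)
        assert out.n_components == 2

    def test_fraction_at_cutoff_removed(self):
        # 10-voxel component, 9 above the psoas mean, cutoff 0.9 -> removed
        data = np.zeros((10, 1, 1), dtype=bool)
        data[:, 0, 0] = True
        comps = connected_components(make_mask(data), connectivity=6)
        t1_data = np.full((10, 1, 1), 300.0)
        t1_data[0, 0, 0] = 100.0  # 9/10 above
        out = t1_component_filter(comps, make_image(t1_data), 150.0, T1FilterParams(0.90))
        assert out.n_components == 0

    def test_fraction_below_cutoff_kept(self):
        data = np.zeros((10, 1, 1), dtype=bool)
        data[:, 0, 0] = True
        comps = connected_components(make_mask(data), connectivity=6)
        t1_data = np.full((10, 1, 1), 300.0)
        t1_data[0:2, 0, 0] = 100.0  # 8/10 above < 0.9
        out = t1_component_filter(comps, make_image(t1_data), 150.0, T1FilterParams(0.90))
        assert out.n_components == 1

    def test_survivors_keep_voxel_membership_and_relabel(self):
        comps = self._components()
        t1 = make_image(np.where(comps.labels == 1, 500.0, 50.0))
        out = t1_component_filter(comps, t1, psoas_mean=150.0)
        assert out.n_components == 1
        assert out.components[0].id == 1
        np.testing.assert_array_equal(out.labels > 0, comps.labels == 2)

    def test_surviving_set_antitone_in_strictness(self):
        rng = np.random.default_rng(6)
        comps = self._components()
        t1 = make_image(rng.uniform(0, 400, comps.shape))
        prev = None
        # lower cutoff = stricter filter; survivors grow with cutoff
        for cutoff in (0.2, 0.5, 0.8, 1.0):
            out = t1_component_filter(comps, t1, 150.0, T1FilterParams(cutoff))
            ids = {c.voxel_count for c in out.components}
            cur = out.n_components
            if prev is not None:
                assert cur >= prev
            prev = cur

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            T1FilterParams(0.0)


class TestSearchRegionAlgebra:
    def test_region_subset_of_dilated_skeleton_disjoint_from_organs(self):
        rng = np.random.default_rng(1)
        skel = make_mask(rng.random((16, 16, 16)) > 0.9, spacing=(2.0, 2.0, 2.0))
        organs = make_mask(rng.random((16, 16, 16)) > 0.9, spacing=(2.0, 2.0, 2.0))
        params = RegionSelectionParams(4.0, 6.0)
        region = combine_region(skel, organs, params)
        from mmseg.core import dilate_mask

        assert np.all(region.data <= dilate_mask(skel, 6.0).data)
        assert not (region.data & dilate_mask(organs, 4.0).data).any()

    def test_monotone_in_dilation_radii(self):
        rng = np.random.default_rng(2)
        skel = make_mask(rng.random((14, 14, 14)) > 0.92, spacing=(2.0, 2.0, 2.0))
        organs = make_mask(rng.random((14, 14, 14)) > 0.95, spacing=(2.0, 2.0, 2.0))
        base = combine_region(skel, organs, RegionSelectionParams(4.0, 6.0))
        more_organ = combine_region(skel, organs, RegionSelectionParams(8.0, 6.0))
        more_skel = combine_region(skel, organs, RegionSelectionParams(4.0, 10.0))
        assert np.all(more_organ.data <= base.data)
        assert np.all(base.data <= more_skel.data)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            RegionSelectionParams(-1.0, 6.0)


@pytest.fixture(scope="module")
def pipeline_setup():
    """Atlas identical in geometry to the patient population, plus one patient
    carrying three lesions and one T1-bright confounder in the band."""
    spec = PhantomSpec(
        shape=(48, 36, 80), spacing=(3.0, 3.0, 3.0), n_lesions=3, seed=31
    )
    spec = replace(
        spec, organ_blobs=tuple(_default_organs(spec)) + (confounder_blob(spec),)
    )
    atlas_ph = generate_phantom_pair(
        replace(spec, n_lesions=0, noise_sigma=0.0, organ_blobs=None)
    )
    atlas = AtlasBundle(
        template=atlas_ph.clean["dwi_high"],
        organ_mask=atlas_ph.truth["organ_mask"],
        skeleton_mask=atlas_ph.truth["skeleton_mask"],
    )
    patient = generate_phantom_pair(spec)
    return atlas, patient


class TestPipeline:
    def test_detects_planted_lesions_and_removes_confounder(
        self, pipeline_setup, desk_cfg
    ):
        atlas, patient = pipeline_setup
        res = run_pipeline(
            patient.dwi_high,
            patient.dwi_b0,
            patient.t1,
            atlas,
            patient.truth["psoas_mask"],
            reg_cfg=desk_cfg,
        )
        gt = connected_components(patient.truth["lesion_mask"])
        m = match_lesions(res.components, gt)
        assert m.sensitivity == 1.0
        assert m.ppv == 1.0
        assert res.provenance["n_candidate_components"] == 4  # 3 lesions + mimic

    def test_dwi_only_mode_keeps_confounder(self, pipeline_setup, desk_cfg):
        atlas, patient = pipeline_setup
        res = run_pipeline(
            patient.dwi_high,
            patient.dwi_b0,
            None,
            atlas,
            None,
            reg_cfg=desk_cfg,
            use_t1_filter=False,
        )
        gt = connected_components(patient.truth["lesion_mask"])
        m = match_lesions(res.components, gt)
        assert m.sensitivity == 1.0
        assert m.ppv < 1.0  # the T1-bright mimic survives without the filter

    def test_all_lesion_voxels_inside_search_region(self, pipeline_setup, desk_cfg):
        atlas, patient = pipeline_setup
        res = run_pipeline(
            patient.dwi_high,
            patient.dwi_b0,
            patient.t1,
            atlas,
            patient.truth["psoas_mask"],
            reg_cfg=desk_cfg,
        )
        assert np.all((res.components.labels > 0) <= res.region.data)

    def test_provenance_records_parameters(self, pipeline_setup, desk_cfg):
        atlas, patient = pipeline_setup
        res = run_pipeline(
            patient.dwi_high,
            patient.dwi_b0,
            patient.t1,
            atlas,
            patient.truth["psoas_mask"],
            threshold_params=ThresholdParams(k=5.0),
            reg_cfg=desk_cfg,
        )
        prov = res.provenance
        assert prov["k"] == 5.0
        assert prov["threshold"] == pytest.approx(
            prov["q3"] + 5.0 * (prov["q3"] - prov["q1"])
        )
        assert prov["wall_time_s"] > 0

    def test_t1_filter_requires_psoas(self, pipeline_setup, desk_cfg):
        atlas, patient = pipeline_setup
        with pytest.raises(ValueError, match="psoas"):
            run_pipeline(
                patient.dwi_high, patient.dwi_b0, patient.t1, atlas, None, reg_cfg=desk_cfg
            )
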