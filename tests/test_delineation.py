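"""Threshold delineation and lesion metrics (SUVmax/SUVmean, MTV, TLG)."""

from datetime import datetime

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from petquant import (PhantomSpec, SegmentationMask, SubjectInfo, VolumetricImage,
                      compute_lesion_metrics, compute_mtv, generate_nema_phantom,
                      segment_fixed_threshold)
from petquant.errors import InvalidArgumentError, SegmentationError

T0 = datetime(2021, 1, 1, 9, 0)
FULL = (slice(None), slice(None), slice(None))


def _subject(**kw):
    defaults = dict(sex="male", body_weight_kg=70.0, height_cm=175.0,
                    injected_activity_MBq=350.0, injection_time=T0, scan_time=T0)
    defaults.update(kw)
    return SubjectInfo(**defaults)


def test_cross_pattern_at_half_max(toy_cross_image):
    mask = segment_fixed_threshold(toy_cross_image, FULL, 50.0)
    assert mask.n_voxels == 7
    assert mask.mask[3, 3, 3]


def test_threshold_excludes_disconnected_supra_threshold_voxels(toy_cross_image):
    # add a bright but disconnected voxel: it must not join the VOI
    toy_cross_image.data[0, 0, 0] = 9.0
    mask = segment_fixed_threshold(toy_cross_image, FULL, 50.0)
    assert not mask.mask[0, 0, 0]
    assert mask.n_voxels == 7


def test_binary_sphere_recovered_at_any_threshold():
    spec = PhantomSpec(sphere_diameters_mm=(22.0,), sphere_centers_mm=((40.0, 40.0, 40.0),),
                       background_concentration=0.0, sphere_concentration=10000.0,
                       psf_fwhm_mm=0.0, noise_sd_fraction=0.0,
                       grid_shape=(41, 41, 41), seed=0)
    image, truth = generate_nema_phantom(spec)
    for th in (1, 40, 75, 99):
        mask = segment_fixed_threshold(image, FULL, th)
        assert np.array_equal(mask.mask, truth[0].mask)


def test_mask_size_non_increasing_in_threshold(clean_phantom):
    spec, image, _ = clean_phantom
    region = spec.search_region(2)
    sizes = [segment_fixed_threshold(image, region, th).n_voxels
             for th in range(5, 100, 5)]
    assert all(a >= b for a, b in zip(sizes, sizes[1:]))


def test_max_tie_broken_by_lowest_linear_index():
    data = np.zeros((3, 3, 3))
    data[0, 0, 1] = 5.0
    data[2, 2, 2] = 5.0
    img = VolumetricImage(data, (1.0, 1.0, 1.0))
    mask = segment_fixed_threshold(img, FULL, 99.0)
    assert mask.mask[0, 0, 1] and not mask.mask[2, 2, 2]


@pytest.mark.parametrize("th", [0.5, 100.0, -3.0])
def test_out_of_range_threshold_rejected(toy_cross_image, th):
    with pytest.raises(SegmentationError):
        segment_fixed_threshold(toy_cross_image, FULL, th)


def test_empty_and_allzero_regions_rejected(toy_cross_image):
    with pytest.raises(SegmentationError):
        segment_fixed_threshold(toy_cross_image, np.zeros((7, 7, 7), bool), 50.0)
    zeros = VolumetricImage(np.zeros((4, 4, 4)), (1.0, 1.0, 1.0))
    with pytest.raises(SegmentationError):
        segment_fixed_threshold(zeros, FULL, 50.0)


def test_mtv_arithmetic():
    mask = SegmentationMask(np.ones((10, 10, 10), bool), voxel_volume_cm3=0.008)
    assert compute_mtv(mask) == pytest.approx(8.0)
    empty = SegmentationMask(np.zeros((4, 4, 4), bool), voxel_volume_cm3=0.008)
    assert compute_mtv(empty) == 0.0


def test_mtv_of_fine_voxelized_sphere_matches_analytic():
    spec = PhantomSpec(sphere_diameters_mm=(37.0,), sphere_centers_mm=((25.0, 25.0, 25.0),),
                       psf_fwhm_mm=0.0, noise_sd_fraction=0.0,
                       voxel_spacing_mm=(1.0, 1.0, 1.0), grid_shape=(51, 51, 51), seed=0)
    _, truth = generate_nema_phantom(spec)
    assert compute_mtv(truth[0]) == pytest.approx(26.522, rel=0.02)


def test_mtv_additive_over_disjoint_parts(clean_phantom):
    spec, image, truth = clean_phantom
    m = truth[4].mask
    z = np.nonzero(m)[0].mean()
    lower, upper = m.copy(), m.copy()
    lower[int(z):] = False
    upper[: int(z)] = False
    vv = truth[4].voxel_volume_cm3
    assert (compute_mtv(SegmentationMask(lower, vv))
            + compute_mtv(SegmentationMask(upper, vv))) == pytest.approx(compute_mtv(truth[4]))


def test_toy_lesion_metrics_hand_computed(toy_cross_image):
    """Mask {10, 6×6} kBq/mL, A=350 MBq, BW=70 kg, 2 mm voxels:
    SUVmean(BW) = (46/7)*70/350 = 1.3143, MTV = 7*0.008 = 0.056 cm³,
    TLG(BW) = 0.0736."""
    img = VolumetricImage(toy_cross_image.data * 1000.0, toy_cross_image.spacing_mm)  # Bq/mL
    mask = segment_fixed_threshold(img, FULL, 50.0)
    metrics = compute_lesion_metrics(img, mask, _subject())
    assert metrics.suv_mean.suv_bw == pytest.approx(1.3143, abs=5e-4)
    assert metrics.suv_max.suv_bw == pytest.approx(2.0)
    assert metrics.mtv_cm3 == pytest.approx(0.056)
    assert metrics.tlg_bw == pytest.approx(0.0736, abs=5e-4)


def test_constant_mask_makes_max_equal_mean():
    img = VolumetricImage(np.full((5, 5, 5), 4000.0), (2.0, 2.0, 2.0))
    mask = SegmentationMask(np.ones((5, 5, 5), bool), img.voxel_volume_cm3)
    m = compute_lesion_metrics(img, mask, _subject())
    assert m.suv_max.suv_bw == m.suv_mean.suv_bw
    assert m.suv_max.raw_bq_per_ml == m.suv_mean.raw_bq_per_ml
    assert m.suv_max.suv_lbm == m.suv_mean.suv_lbm


def test_tlg_is_bitexact_product(small_cohort):
    from petquant import calibrate_thresholds, quantify_cohort, DEFAULT_VARIANTS, PhantomSpec

    table = calibrate_thresholds(PhantomSpec(noise_sd_fraction=0.0, seed=11),
                                 small_cohort.variants)
    for metrics in quantify_cohort(small_cohort, table).values():
        for m in metrics:
            assert m.tlg_bw == m.suv_mean.suv_bw * m.mtv_cm3
            assert m.tlg_raw == m.suv_mean.raw_bq_per_ml * m.mtv_cm3
            if m.suv_mean.suv_lbm is not None:
                assert m.tlg_lbm == m.suv_mean.suv_lbm * m.mtv_cm3
            assert m.suv_max.suv_bw >= m.suv_mean.suv_bw


def test_unit_system_consistency(toy_cross_image):
    """SUVmean(BW)/SUVmean(LBM) = LBM/BW: both rescale the same mean."""
    img = VolumetricImage(toy_cross_image.data * 1000.0, toy_cross_image.spacing_mm)
    mask = segment_fixed_threshold(img, FULL, 50.0)
    subject = _subject()
    m = compute_lesion_metrics(img, mask, subject)
    ratio = m.suv_mean.suv_bw / m.suv_mean.suv_lbm
    assert ratio == pytest.approx(
        subject.body_weight_kg / subject.lean_body_mass_kg, rel=1e-12)


def test_lbm_omitted_for_variant_without_lbm(toy_cross_image):
    from petquant import VariantConvention

    img = VolumetricImage(toy_cross_image.data * 1000.0, toy_cross_image.spacing_mm)
    mask = segment_fixed_threshold(img, FULL, 50.0)
    no_lbm = VariantConvention("X", supports_lbm=False)
    m = compute_lesion_metrics(img, mask, _subject(), no_lbm)
    assert m.suv_mean.suv_lbm is None and m.tlg_lbm is None


def test_empty_mask_rejected(toy_cross_image):
    empty = SegmentationMask(np.zeros((7, 7, 7), bool), 0.008)
    with pytest.raises(InvalidArgumentError):
        compute_lesion_metrics(toy_cross_image, empty, _subject())


@given(th1=st.integers(1, 99), th2=st.integers(1, 99))
def test_threshold_monotonicity_property(toy_cross_image, th1, th2):
    if th1 > th2:
        th1, th2 = th2, th1
    m1 = segment_fixed_threshold(toy_cross_image, FULL, th1)
    m2 = segment_fixed_threshold(toy_cross_image, FULL, th2)
    assert compute_mtv(m1) >= compute_mtv(m2)
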