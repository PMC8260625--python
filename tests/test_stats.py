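"""Agreement statistics: Pearson bands, Shapiro–Wilk, paired tests, report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from petquant import (build_comparison_report, classify_correlation, paired_compare,
                      pearson_r, shapiro_wilk, summarize)
from petquant.errors import DegenerateTestError, InvalidArgumentError
from petquant.stats import metrics_to_frame

# Independent oracle: R's shapiro.test on the same frozen seeded sample
# (standard-normal draws, default_rng(42), n=30) gives W=0.965142, p=0.416055.
R_ORACLE_W, R_ORACLE_P = 0.965142, 0.416055


def test_pearson_perfect_linear():
    assert pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
    assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)


def test_pearson_matches_covariance_formula():
    rng = np.random.default_rng(1)
    x, y = rng.normal(size=10), rng.normal(size=10)
    direct = np.sum((x - x.mean()) * (y - y.mean())) / (
        np.sqrt(np.sum((x - x.mean()) ** 2)) * np.sqrt(np.sum((y - y.mean()) ** 2)))
    assert pearson_r(x, y) == pytest.approx(direct, abs=1e-12)


def test_pearson_error_paths():
    with pytest.raises(InvalidArgumentError):
        pearson_r([1, 2], [1, 2])
    with pytest.raises(InvalidArgumentError):
        pearson_r([1, 2, 3], [1, 2])
    with pytest.raises(DegenerateTestError):
        pearson_r([1, 1, 1], [1, 2, 3])


@given(a=st.floats(0.1, 5), b=st.floats(-10, 10))
def test_pearson_affine_invariance_and_symmetry(a, b):
    rng = np.random.default_rng(3)
    x, y = rng.normal(size=12), rng.normal(size=12)
    r = pearson_r(x, y)
    assert pearson_r(a * x + b, y) == pytest.approx(r, abs=1e-9)
    assert pearson_r(y, x) == pytest.approx(r, abs=1e-12)


@pytest.mark.parametrize("r, band", [
    (0.9863, "very strong"), (0.75, "very strong"), (0.7, "very strong"),
    (0.69, "strong"), (0.5, "strong"),
    (0.4841, "moderate"), (0.3, "moderate"),
    (0.25, "low"), (0.0, "low"), (-0.9, "very strong"),
])
def test_correlation_bands(r, band):
    assert classify_correlation(r) == band


def test_correlation_band_rejects_out_of_range():
    with pytest.raises(InvalidArgumentError):
        classify_correlation(1.2)


@given(r1=st.floats(0, 1), r2=st.floats(0, 1))
def test_correlation_band_is_monotone_step(r1, r2):
    order = ["low", "moderate", "strong", "very strong"]
    if r1 > r2:
        r1, r2 = r2, r1
    assert order.index(classify_correlation(r1)) <= order.index(classify_correlation(r2))


def test_shapiro_matches_independent_r_oracle():
    x = np.round(np.random.default_rng(42).standard_normal(30), 6)
    w, p = shapiro_wilk(x)
    assert w == pytest.approx(R_ORACLE_W, abs=5e-4)
    assert p == pytest.approx(R_ORACLE_P, abs=5e-4)


def test_shapiro_null_calibration():
    """Normal samples should rarely be rejected (p > 0.05 in >= 95/100 runs)."""
    ok = sum(shapiro_wilk(np.random.default_rng(s).standard_normal(1000))[1] > 0.05
             for s in range(100))
    assert ok >= 95


def test_shapiro_detects_lognormal_at_cohort_size():
    x = np.exp(np.random.default_rng(7).standard_normal(98))
    assert shapiro_wilk(x)[1] < 0.05


def test_shapiro_input_validation():
    with pytest.raises(InvalidArgumentError):
        shapiro_wilk([1.0, 2.0])
    with pytest.raises(InvalidArgumentError):
        shapiro_wilk(np.ones(10))


def test_paired_compare_identical_vectors_degenerate():
    with pytest.raises(DegenerateTestError):
        paired_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


def test_paired_compare_strong_shift_detected():
    rng = np.random.default_rng(10)
    a = rng.normal(size=98)
    b = a + 2.0 + rng.normal(scale=0.5, size=98)  # 2 SD shift
    test, p = paired_compare(b, a)
    assert p < 0.005


def test_paired_compare_uses_wilcoxon_for_skewed_differences():
    rng = np.random.default_rng(2)
    a = np.exp(rng.standard_normal(98) * 1.5)
    b = a * np.exp(rng.standard_normal(98) * 0.5)
    test, _ = paired_compare(a, b)
    assert test == "wilcoxon signed-rank"


def test_paired_compare_type_one_error_calibrated():
    """Null rejection rate at alpha=0.05 within binomial 99% bounds, 200 runs."""
    from scipy.stats import binom

    n_rep, alpha = 200, 0.05
    rejections = 0
    for s in range(n_rep):
        rng = np.random.default_rng(1000 + s)
        a, b = rng.normal(size=(2, 98))
        rejections += paired_compare(a, b)[1] < alpha
    lo = binom.ppf(0.005, n_rep, alpha)
    hi = binom.ppf(0.995, n_rep, alpha)
    assert lo <= rejections <= hi


def test_summarize():
    assert summarize([1.0, 2.0, 3.0]) == (2.0, 1.0)
    assert summarize([5.0, 5.0, 5.0])[1] == 0.0
    rng = np.random.default_rng(4)
    x = rng.normal(size=50)
    mean, sd = summarize(x)
    assert mean == pytest.approx(x.sum() / 50, abs=1e-12)
    assert sd == pytest.approx(np.sqrt(np.sum((x - mean) ** 2) / 49), abs=1e-12)
    with pytest.raises(InvalidArgumentError):
        summarize([1.0])
    pop_sd = summarize(x, population_sd=True)[1]
    assert pop_sd < sd


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def _metrics_frames(small_cohort):
    from petquant import PhantomSpec, calibrate_thresholds, quantify_cohort

    table = calibrate_thresholds(PhantomSpec(noise_sd_fraction=0.0, seed=11),
                                 small_cohort.variants)
    return quantify_cohort(small_cohort, table)


def test_identical_variants_report_all_unity(small_cohort):
    metrics = _metrics_frames(small_cohort)["B"]
    report = build_comparison_report({"one": metrics, "two": list(metrics)})
    assert np.allclose(report.correlations["r"], 1.0)
    assert (report.correlations["band"] == "very strong").all()
    assert not report.difference_tests["significant"].any()


def test_report_skips_lbm_cells_for_non_lbm_variant(small_cohort):
    metrics = _metrics_frames(small_cohort)
    report = build_comparison_report(metrics)
    lbm_pairs = report.correlations.query("parameter.str.endswith('_lbm')")["pair"]
    assert not lbm_pairs.str.contains("A").any()  # variant A has no LBM
    assert set(report.summaries.query("parameter == 'suv_max_lbm'")["variant"]) == {"B", "C"}


def test_report_permutation_equivariance(small_cohort):
    metrics = _metrics_frames(small_cohort)
    perm = np.random.default_rng(0).permutation(len(small_cohort.records))
    frames = {k: metrics_to_frame(v) for k, v in metrics.items()}
    shuffled = {k: f.iloc[perm].reset_index(drop=True) for k, f in frames.items()}
    r1 = build_comparison_report(frames)
    r2 = build_comparison_report(shuffled)
    pd.testing.assert_frame_equal(r1.correlations, r2.correlations)
    pd.testing.assert_frame_equal(r1.summaries, r2.summaries)


def test_report_rejects_mismatched_cohorts(small_cohort):
    metrics = _metrics_frames(small_cohort)
    with pytest.raises(InvalidArgumentError):
        build_comparison_report({"a": metrics["B"], "b": metrics["C"][:-1]})
    with pytest.raises(InvalidArgumentError):
        build_comparison_report({"a": metrics["B"]})


def test_holm_adjustment_never_decreases_p(small_cohort):
    metrics = _metrics_frames(small_cohort)
    raw = build_comparison_report(metrics, holm=False)
    adj = build_comparison_report(metrics, holm=True)
    merged = raw.difference_tests.merge(adj.difference_tests,
                                        on=["parameter", "pair"], suffixes=("_raw", "_holm"))
    merged = merged.dropna(subset=["p_value_raw"])  # degenerate pairs stay NaN
    assert (merged["p_value_holm"] >= merged["p_value_raw"] - 1e-15).all()
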