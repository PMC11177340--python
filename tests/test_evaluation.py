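"""Dosimetric metric contracts: DVH order statistics, gamma vs brute force,
overlap/surface metrics, and plan criteria."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from dosecast.evaluation import (
    DVHCurve,
    GammaParams,
    check_plan_criteria,
    dose_at_volume,
    dose_max,
    dvh,
    gamma_index,
    isodose_overlap,
    low_dose_voxel_counts,
    masked_errors,
    volume_at_dose,
)

RNG = np.random.default_rng(17)


# independent gamma oracle + smooth field generator shared with acceptance
from gamma_oracle_util import bruteforce_pass_rate, smooth_pair as smooth_dose_pair


# -- masked errors ---------------------------------------------------------

def test_masked_errors_identity_offset_and_mask_independence():
    truth = RNG.random((4, 8, 8)) * 45
    body = np.zeros((4, 8, 8), bool)
    body[:, 2:6, 2:6] = True
    assert masked_errors(truth, truth, body) == (0.0, 0.0, 0.0)

    mae, mse, rmse = masked_errors(truth + 1.0, truth, body)
    np.testing.assert_allclose([mae, mse, rmse], [1.0, 1.0, 1.0])

    corrupted = truth.copy()
    corrupted[~body] += RNG.random((~body).sum()) * 1000
    np.testing.assert_allclose(masked_errors(corrupted, truth, body),
                               masked_errors(truth, truth, body))
    with pytest.raises(ValueError, match="empty"):
        masked_errors(truth, truth, np.zeros_like(body))


# -- DVH -------------------------------------------------------------------

def test_dvh_uniform_structure_step_curve():
    dose = np.full((3, 4, 4), 45.0)
    mask = np.ones_like(dose, bool)
    curve = dvh(dose, mask, bin_width_Gy=1.0)
    assert curve.cum_volume_pct[0] == 100.0
    np.testing.assert_array_equal(curve.cum_volume_pct[curve.dose_bins_Gy <= 45.0], 100.0)
    np.testing.assert_array_equal(curve.cum_volume_pct[curve.dose_bins_Gy > 45.0], 0.0)


def test_dvh_matches_exhaustive_counting_and_monotone():
    dose = RNG.random((10,)) * 50
    mask = np.ones(10, bool)
    curve = dvh(dose, mask, bin_width_Gy=0.5)
    for b, pct in zip(curve.dose_bins_Gy, curve.cum_volume_pct):
        count = sum(1 for d in dose if d >= b)  # brute-force count
        assert pct == count / 10 * 100.0
    assert np.all(np.diff(curve.cum_volume_pct) <= 0)


def test_dq_order_statistic_convention():
    dose = np.arange(1.0, 101.0)
    mask = np.ones(100, bool)
    assert dose_at_volume(dose, mask, 95.0) == 5.0
    assert dose_at_volume(dose, mask, 0.0) == 100.0
    assert dose_at_volume(dose, mask, 100.0) == 1.0
    uniform = np.full(64, 45.0)
    assert dose_at_volume(uniform, np.ones(64, bool), 95.0) == 45.0
    assert volume_at_dose(uniform, np.ones(64, bool), 30.0) == 100.0


def test_dq_vd_consistency_property():
    dose = RNG.random(100) * 60
    mask = np.ones(100, bool)
    for q in (2, 50, 95, 98):
        dq = dose_at_volume(dose, mask, q)
        assert volume_at_dose(dose, mask, dq) >= q
    # Vd non-increasing in d
    vds = [volume_at_dose(dose, mask, d) for d in np.linspace(0, 60, 13)]
    assert all(a >= b for a, b in zip(vds, vds[1:]))


# -- gamma -----------------------------------------------------------------

def test_gamma_identity_passes_everywhere():
    pred, truth = smooth_dose_pair(np.random.default_rng(0))
    gmap, rate = gamma_index(truth, truth, GammaParams(), spacing_mm=(2.5, 2.5))
    assert rate == 100.0
    evaluated = ~np.isnan(gmap)
    np.testing.assert_allclose(gmap[evaluated], 0.0, atol=1e-12)
    # low-dose region is excluded from evaluation
    assert np.isnan(gmap[truth < 0.1 * truth.max()]).all()


def test_gamma_uniform_scaling_within_global_tolerance():
    _, truth = smooth_dose_pair(np.random.default_rng(1))
    _, rate = gamma_index(1.03 * truth, truth, GammaParams(), spacing_mm=(2.5, 2.5))
    assert rate == 100.0


@pytest.mark.parametrize("seed", [2, 3, 4, 5])
def test_gamma_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    pred, truth = smooth_dose_pair(rng, perturb=0.04)
    params = GammaParams()
    _, rate = gamma_index(pred, truth, params, spacing_mm=(2.5, 2.5))
    oracle = bruteforce_pass_rate(pred, truth, params, (2.5, 2.5))
    assert abs(rate - oracle) <= 0.5


def test_gamma_pass_rate_monotone_in_tolerances():
    pred, truth = smooth_dose_pair(np.random.default_rng(6), perturb=0.06)
    rates = {}
    for tol, dta in [(3.0, 2.0), (5.0, 2.0), (3.0, 3.0), (5.0, 3.0)]:
        _, rates[(tol, dta)] = gamma_index(
            pred, truth, GammaParams(dose_tolerance_pct=tol, dta_mm=dta),
            spacing_mm=(2.5, 2.5))
    assert rates[(5.0, 2.0)] >= rates[(3.0, 2.0)]
    assert rates[(3.0, 3.0)] >= rates[(3.0, 2.0)]
    assert rates[(5.0, 3.0)] >= max(rates[(5.0, 2.0)], rates[(3.0, 3.0)])


def test_gamma_respects_body_mask_and_3d_input():
    pred, truth = smooth_dose_pair(np.random.default_rng(7))
    body = np.zeros_like(truth, bool)
    body[4:20, 4:20] = True
    gmap, _ = gamma_index(pred, truth, GammaParams(), body_mask=body,
                          spacing_mm=(2.5, 2.5))
    assert np.isnan(gmap[~body]).all()

    vol_t = np.stack([truth] * 3)
    _, rate3d = gamma_index(vol_t, vol_t, GammaParams(), spacing_mm=(5.0, 2.5, 2.5))
    assert rate3d == 100.0


# -- isodose overlap -------------------------------------------------------

def test_isodose_identity_and_disjoint():
    dose = RNG.random((3, 8, 8)) * 30
    report = isodose_overlap(dose, dose, 10.0, spacing_mm=(5, 2.5, 2.5))
    assert report.dsc == 1.0 and report.jaccard == 1.0
    assert report.hausdorff_mm == 0.0 and report.hd95_mm == 0.0

    a = np.zeros((1, 6, 6))
    b = np.zeros((1, 6, 6))
    a[0, :2, :2] = 20.0
    b[0, 4:, 4:] = 20.0
    report = isodose_overlap(b, a, 10.0, spacing_mm=(5, 1, 1))
    assert report.dsc == 0.0


def test_isodose_half_overlap_squares():
    truth = np.zeros((1, 8, 8))
    pred = np.zeros((1, 8, 8))
    truth[0, 2:6, 0:4] = 10.0   # 4x4 square
    pred[0, 2:6, 2:6] = 10.0    # shifted by 2: overlap is 4x2
    report = isodose_overlap(pred, truth, 4.0, spacing_mm=(5, 1, 1))
    np.testing.assert_allclose(report.dsc, 2 * 8 / (16 + 16))
    np.testing.assert_allclose(report.jaccard, 8 / 24)


def test_jaccard_dsc_identity_and_hd95_bound():
    for seed in range(5):
        rng = np.random.default_rng(seed)
        pred = gaussian_filter(rng.random((4, 12, 12)), 1.5) * 30
        truth = gaussian_filter(rng.random((4, 12, 12)), 1.5) * 30
        r = isodose_overlap(pred, truth, 12.0, spacing_mm=(5, 2.5, 2.5))
        if np.isnan(r.dsc):
            continue
        np.testing.assert_allclose(r.jaccard, r.dsc / (2 - r.dsc), atol=1e-12)
        if not r.undefined_distances:
            assert r.hd95_mm <= r.hausdorff_mm


def test_isodose_empty_side_flagged():
    dose = np.zeros((1, 4, 4))
    hot = np.full((1, 4, 4), 20.0)
    report = isodose_overlap(dose, hot, 10.0, spacing_mm=(5, 1, 1))
    assert report.undefined_distances
    assert np.isnan(report.hausdorff_mm)


# -- plan criteria ---------------------------------------------------------

def test_plan_criteria_uniform_prescription_passes_coverage():
    dose = np.full((2, 6, 6), 45.0)
    ptv = np.zeros_like(dose, bool)
    ptv[:, 2:4, 2:4] = True
    table = check_plan_criteria(dose, {"PTV": ptv})
    d95 = table[(table.structure == "PTV") & (table.metric == "D95")].iloc[0]
    assert d95.passed and d95.value == 45.0
    # missing OARs are reported but not evaluable
    assert not table[table.structure == "bladder"].evaluable.any()


def test_plan_criteria_zero_dose():
    dose = np.zeros((2, 6, 6))
    masks = {name: np.zeros_like(dose, bool) for name in
             ("PTV", "bladder", "rectum", "femoral_head_left",
              "femoral_head_right", "spinal_cord")}
    for m in masks.values():
        m[:, 1:3, 1:3] = True
    table = check_plan_criteria(dose, masks)
    ptv_rows = table[table.structure == "PTV"]
    assert not ptv_rows[ptv_rows.metric == "D95"].iloc[0].passed
    oar_rows = table[table.structure != "PTV"]
    assert oar_rows.passed.all()


def test_plan_criteria_bladder_boundary_case():
    dose = np.zeros((1, 2, 4))
    bladder = np.ones_like(dose, bool)
    dose[0, 0, :] = 35.0     # half the structure at 35 Gy -> V30 = 50%
    table = check_plan_criteria(dose, {"bladder": bladder})
    v30 = table[(table.structure == "bladder") & (table.metric == "V30")].iloc[0]
    assert v30.value == 50.0 and not v30.passed   # strict "< 50%"


# -- low-dose bands --------------------------------------------------------

def test_low_dose_band_counts():
    body = np.ones((2, 4, 4), bool)
    uniform = np.full((2, 4, 4), 5.0)
    counts = low_dose_voxel_counts(uniform, body_mask=body)
    assert counts[(4.0, 10.0)] == body.sum()
    assert counts[(10.0, 15.0)] == 0 and counts[(15.0, 20.0)] == 0

    dose = RNG.random((4, 6, 6)) * 30
    counts = low_dose_voxel_counts(dose, body_mask=np.ones((4, 6, 6), bool))
    total_in_range = ((dose >= 4.0) & (dose < 20.0)).sum()
    assert sum(counts.values()) == total_in_range
    # naive loop oracle
    for (lo, hi), n in counts.items():
        assert n == sum(1 for v in dose.ravel() if lo <= v < hi)
    with pytest.raises(ValueError, match="non-overlapping"):
        low_dose_voxel_counts(dose, bands=[(4.0, 12.0), (10.0, 15.0)])


def test_dvh_curve_interpolated_readout():
    curve = DVHCurve(np.array([0.0, 10.0, 20.0]), np.array([100.0, 50.0, 0.0]))
    np.testing.assert_allclose(curve.dose_at_volume(50.0), 10.0)


def test_dose_max():
    dose = RNG.random((3, 3)) * 10
    assert dose_max(dose, np.ones((3, 3), bool)) == dose.max()
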