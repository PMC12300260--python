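"""IVIVE scaling: intrinsic clearances, well-stirred liver, fm decomposition."""

import numpy as np
import pytest

import sultpbpk as sp
from sultpbpk.ivive import ClearanceModel, hepatic_clearance
from sultpbpk.physiology import SystemParameters


@pytest.fixture(scope="module")
def uncalibrated(apap_profile, physiology):
    return ClearanceModel(apap_profile, physiology, calibrate=False)


def _sys(q=90.0, fu=0.82, bp=1.0):
    return SystemParameters(
        age=20.0, body_weight=70.0, liver_weight=1587.0, hepatic_blood_flow=q,
        mppgl=39.0, cppgl=90.0, gfr_fraction=1.0, fu_plasma=fu, blood_plasma_ratio=bp,
    )


def test_adult_sult1a1_per_mg_clint_matches_vmax_over_km(uncalibrated, physiology, apap_profile):
    sys20 = physiology.system_parameters(20.0)
    scale = sys20.cppgl * sys20.liver_weight * apap_profile.active_hepatic_scalar * 60e-6
    per_mg = uncalibrated.pathway_clint("SULT1A1", 20.0, 0.0) / scale
    assert per_mg == pytest.approx(1549.0 / 2400.0, rel=1e-9)


def test_clint_vanishes_at_saturating_concentration(uncalibrated):
    low = uncalibrated.total_clint(20.0, 0.0)
    high = uncalibrated.total_clint(20.0, 1e7)
    assert high < 1e-3 * low


def test_clint_monotone_decreasing_in_concentration(uncalibrated):
    concs = np.logspace(-2, 3, 30)
    clints = [uncalibrated.total_clint(20.0, c) for c in concs]
    assert np.all(np.diff(clints) < 0)


def test_clint_linear_in_ontogeny_multiplier(uncalibrated):
    base = uncalibrated.total_clint(0.5, 0.0, multipliers={"SULT1A1": 1.0})
    doubled = uncalibrated.total_clint(0.5, 0.0, multipliers={"SULT1A1": 2.0})
    single = uncalibrated._clint_map(0.5, 0.0)["SULT1A1"]
    assert doubled - base == pytest.approx(single, rel=1e-9)


def test_well_stirred_limits_and_midpoint():
    sys = _sys()
    assert hepatic_clearance(0.0, sys) == 0.0
    assert hepatic_clearance(1e12, sys) == pytest.approx(sys.hepatic_blood_flow, rel=1e-6)
    # fu_B * CLint = Q  ->  CLh = Q/2
    clint_mid = sys.hepatic_blood_flow / (sys.fu_plasma / sys.blood_plasma_ratio)
    assert hepatic_clearance(clint_mid, sys) == pytest.approx(sys.hepatic_blood_flow / 2)


def test_well_stirred_increasing_concave_below_flow():
    sys = _sys()
    clints = np.linspace(0, 500, 200)
    clh = np.array([hepatic_clearance(c, sys) for c in clints])
    assert np.all(np.diff(clh) > 0)
    assert np.all(np.diff(clh, 2) < 1e-9)
    assert np.all(clh < sys.hepatic_blood_flow)


def test_uncalibrated_adult_clearance_within_ivive_sanity_band(uncalibrated, apap_profile):
    cl = uncalibrated.systemic_clearance(20.0)
    assert 0.5 * apap_profile.cl_iv_reference <= cl <= 2.0 * apap_profile.cl_iv_reference


def test_calibrated_adult_clearance_matches_reference(clearance_model, apap_profile):
    assert clearance_model.systemic_clearance(20.0) == pytest.approx(
        apap_profile.cl_iv_reference, rel=1e-9
    )
    assert 0.3 < clearance_model.calibration < 3.0


@pytest.mark.parametrize("age", [7 / 365.25, 0.5, 2.0, 7.0, 20.0])
def test_fm_sums_to_one(clearance_model, age):
    breakdown = clearance_model.fm_breakdown(age)
    assert sum(breakdown.fm.values()) == pytest.approx(1.0, abs=1e-9)
    assert all(f >= 0 for f in breakdown.fm.values())
    assert breakdown.clh < clearance_model.physiology.system_parameters(age).hepatic_blood_flow


def test_fm_invariant_to_uniform_vmax_rescaling(apap_profile, physiology):
    base = ClearanceModel(apap_profile, physiology, calibrate=False)
    scaled_profile = apap_profile
    for pathway, kin in apap_profile.kinetics.items():
        scaled_profile = scaled_profile.with_kinetics(pathway, vmax=kin.vmax * 3.0)
    # renal share changes with total CLh, so compare hepatic shares of CLint
    scaled = ClearanceModel(scaled_profile, physiology, calibrate=False)
    b0, b1 = base.fm_breakdown(1.0), scaled.fm_breakdown(1.0)
    shares0 = {p: v / b0.total_clint for p, v in b0.clint.items()}
    shares1 = {p: v / b1.total_clint for p, v in b1.clint.items()}
    for pathway in shares0:
        assert shares1[pathway] == pytest.approx(shares0[pathway], rel=1e-9)


def test_developmental_shift_sulfation_to_glucuronidation(clearance_model):
    neonate = clearance_model.fm_breakdown(7 / 365.25).fm_by_category()
    child = clearance_model.fm_breakdown(7.0).fm_by_category()
    assert neonate["SULT"] > child["SULT"]
    assert neonate["UGT"] < child["UGT"]
    assert child["UGT"] > child["SULT"]  # glucuronidation dominant by childhood


def test_saturation_shifts_fm_toward_high_km_pathways(clearance_model):
    linear = clearance_model.fm_breakdown(20.0)
    saturated = clearance_model.fm_breakdown(20.0, conc=20.0)
    # CYP3A4 (Km 130 uM) saturates first; its share must fall
    assert saturated.fm["CYP3A4"] < linear.fm["CYP3A4"]


def test_fm_report_layout(clearance_model):
    report = clearance_model.fm_report([0.02, 1.0, 7.0, 25.0])
    assert set(report.columns) == {"age_group", "age_years", "pathway", "fm"}
    sums = report.groupby("age_years")["fm"].sum()
    assert np.allclose(sums.to_numpy(), 1.0)
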