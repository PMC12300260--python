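"""PBPK simulation engine: analytic oracles, conservation, populations."""

import numpy as np
import pytest

from sultpbpk.engine import DoseRegimen, adult_regimen, pediatric_regimen
from sultpbpk.nca import nca
from sultpbpk.synthetic import VirtualSubject


@pytest.fixture(scope="module")
def adult_subject():
    return VirtualSubject("adult-ref", 20.0, 70.0)


def test_regimen_validation():
    with pytest.raises(ValueError):
        DoseRegimen(5.0, 3.0, 2.0, 1, 24.0)       # infusion longer than interval
    with pytest.raises(ValueError):
        DoseRegimen(5.0, 0.25, 4.0, 12, 24.0)     # horizon too short
    with pytest.raises(KeyError):
        pediatric_regimen("child", "weird")


def test_zero_dose_gives_zero_profile(pbpk_model, adult_subject):
    prof = pbpk_model.simulate_subject(adult_subject, adult_regimen(0.0))
    assert np.all(prof.conc == 0.0)


def test_forced_linear_matches_one_compartment_closed_form(pbpk_model, adult_subject):
    """During a constant-rate infusion the linear one-compartment solution is
    C(t) = R0/CL * (1 - exp(-k t)); afterwards it decays mono-exponentially."""
    regimen = adult_regimen(5.0)
    prof = pbpk_model.simulate_subject(adult_subject, regimen, force_linear=True)
    cl, v = prof.clearance_linear, prof.volume
    k = cl / v
    r0 = regimen.infusion_rate(adult_subject.body_weight)
    t = prof.time
    t_inf = regimen.infusion_duration
    expected = np.where(
        t <= t_inf,
        r0 / cl * (1 - np.exp(-k * t)),
        r0 / cl * (1 - np.exp(-k * t_inf)) * np.exp(-k * (t - t_inf)),
    )
    mask = expected > 1e-3 * expected.max()
    rel_err = np.abs(prof.conc[mask] - expected[mask]) / expected[mask]
    assert rel_err.max() < 0.005


def test_mass_balance_within_tenth_of_percent(pbpk_model, adult_subject):
    prof = pbpk_model.simulate_subject(adult_subject, adult_regimen(20.0))
    assert prof.mass_balance_error() < 1e-3
    assert prof.dose_total == pytest.approx(20.0 * 70.0, rel=1e-12)


def test_linear_auc_equals_dose_over_clearance(pbpk_model, adult_subject):
    regimen = adult_regimen(5.0, horizon_h=48.0)
    prof = pbpk_model.simulate_subject(adult_subject, regimen, force_linear=True)
    summ = nca(prof)
    expected = prof.dose_total / prof.clearance_linear
    assert summ.auc_0_inf == pytest.approx(expected, rel=0.01)


def test_linear_dose_proportionality_and_saturation_excess(pbpk_model, adult_subject):
    lin5 = pbpk_model.simulate_subject(adult_subject, adult_regimen(5.0, horizon_h=48.0), force_linear=True)
    lin20 = pbpk_model.simulate_subject(adult_subject, adult_regimen(20.0, horizon_h=48.0), force_linear=True)
    assert nca(lin20).auc_0_inf == pytest.approx(4 * nca(lin5).auc_0_inf, rel=0.01)
    # with Michaelis-Menten kinetics the high dose carries a saturation excess
    mm5 = pbpk_model.simulate_subject(adult_subject, adult_regimen(5.0, horizon_h=48.0))
    mm20 = pbpk_model.simulate_subject(adult_subject, adult_regimen(20.0, horizon_h=48.0))
    assert nca(mm20).auc_0_inf >= 4 * nca(mm5).auc_0_inf


def test_steady_state_interval_auc_matches_single_dose_superposition(pbpk_model, adult_subject):
    """In the linear regime AUC over the final interval at steady state equals
    the single-dose AUC(0-inf)."""
    multi = DoseRegimen(5.0, 0.5, 6.0, 8, 48.0)
    prof_ss = pbpk_model.simulate_subject(adult_subject, multi, force_linear=True)
    auc_tau = nca(prof_ss, tau=6.0).auc_0_tau
    single = DoseRegimen(5.0, 0.5, 48.0, 1, 48.0)
    prof_sd = pbpk_model.simulate_subject(adult_subject, single, force_linear=True)
    assert auc_tau == pytest.approx(nca(prof_sd).auc_0_inf, rel=0.01)


def test_profile_grid_density_and_monotonicity(pbpk_model, adult_subject):
    regimen = pediatric_regimen("child", "table")
    child = VirtualSubject("child-ref", 7.0, 23.0)
    prof = pbpk_model.simulate_subject(child, regimen)
    assert np.all(np.diff(prof.time) > 0)
    assert np.all(prof.conc >= 0)
    # at least 20 points per dosing interval
    for start in regimen.dose_times:
        n_pts = np.sum((prof.time >= start) & (prof.time < start + regimen.interval))
        assert n_pts >= 20


def test_population_seed_determinism(pbpk_model):
    reg = pediatric_regimen("neonate", "table")
    a = pbpk_model.simulate_population("neonate", reg, 2, trials=3, seed=9)
    b = pbpk_model.simulate_population("neonate", reg, 2, trials=3, seed=9)
    assert np.array_equal(a.conc_matrix, b.conc_matrix)
    c = pbpk_model.simulate_population("neonate", reg, 2, trials=3, seed=10)
    assert not np.array_equal(a.conc_matrix, c.conc_matrix)


def test_percentile_envelope_brackets_mean(pbpk_model):
    reg = pediatric_regimen("infant", "table")
    pop = pbpk_model.simulate_population("infant", reg, 6, trials=3, seed=4)
    assert np.all(pop.p05 <= pop.mean + 1e-12)
    assert np.all(pop.mean <= pop.p95 + 1e-12)
    assert pop.n_subjects == 18


def test_no_variability_collapses_percentile_band(pbpk_model):
    # adult physiology is age-invariant, so zero enzyme/Vss CV collapses the
    # band (up to the asymptotic tails of the maturation profiles, <1e-5)
    pop = pbpk_model.simulate_population(
        "adult", adult_regimen(5.0), 5, trials=2, seed=0, enzyme_cv=0.0, vss_cv=0.0
    )
    scale = pop.mean.max()
    assert np.allclose(pop.p05, pop.mean, atol=1e-4 * scale)
    assert np.allclose(pop.p95, pop.mean, atol=1e-4 * scale)


def test_representative_exposure_ordering_neonate_infant_child(pbpk_model):
    """Weight-normalised clearance immaturity makes neonatal interval exposure
    the highest under the same mg/kg dosing."""
    aucs = {}
    for group in ("neonate", "infant", "child"):
        reg = pediatric_regimen(group, "table")
        subj = pbpk_model.representative_subject(group)
        prof = pbpk_model.simulate_subject(subj, reg)
        aucs[group] = nca(prof, tau=reg.interval).auc_0_tau
    assert aucs["neonate"] > aucs["infant"] > aucs["child"]
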