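"""Ontogeny models and the regression/selection engine."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sultpbpk.ontogeny import (
    AbundanceRecord,
    ConstantOntogeny,
    OntogenyFit,
    OntogenyPiecewise3,
    OntogenyRegression,
    builtin_ontogeny_library,
    evaluate_abundance,
    fit_ontogeny,
    relative_activity,
    select_best,
)
from sultpbpk.synthetic import AbundanceSimSpec, simulate_abundance_dataset


@pytest.mark.parametrize(
    "enzyme, age, expected",
    [
        ("SULT1A1", 0.0, 107.8),          # birth intercept
        ("SULT1A1", 20.0, 445.2),         # adult plateau
        ("SULT1A3", 20.0, 97.2),
        ("SULT1A3", 2.0, 60.0),           # evaluated by segment 2 at its anchor
        ("SULT2A1", 1.0, 1680.5),         # 705.3 + 975.2*1.0
        ("SULT2A1", 20.0, 1095.0),
        ("SULT1B1", 20.0, 115.0),
        ("SULT1E1", 0.0, 1.0),
    ],
)
def test_builtin_segment_values(ontogeny_library, enzyme, age, expected):
    assert evaluate_abundance(ontogeny_library[enzyme], age) == pytest.approx(expected, rel=1e-12)


def test_sult1a3_near_continuity_at_first_breakpoint(ontogeny_library):
    # segment-1 limit at age 2 is 117.3 - 28.7*2 = 59.9, next segment starts at 60.0
    model = ontogeny_library["SULT1A3"]
    assert model.abundance(2.0 - 1e-9) == pytest.approx(59.9, abs=1e-5)
    assert model.abundance(2.0) == pytest.approx(60.0)


def test_constant_beyond_second_breakpoint(ontogeny_library):
    for enzyme in ("SULT1A1", "SULT1A3", "SULT2A1", "SULT1B1"):
        model = ontogeny_library[enzyme]
        ages = np.linspace(model.breakpoint2 + 1e-9, 100.0, 50)
        assert np.all(model.abundance(ages) == model.plateau)


def test_builtin_abundance_nonnegative_on_age_grid(ontogeny_library):
    ages = np.linspace(0.0, 100.0, 2001)
    for model in ontogeny_library.values():
        assert np.all(model.abundance(ages) >= 0.0)


def test_negative_age_is_domain_error(ontogeny_library):
    with pytest.raises(ValueError):
        ontogeny_library["SULT1A1"].abundance(-0.1)


@pytest.mark.parametrize(
    "enzyme, age, expected",
    [
        ("SULT1A1", 0.0, 107.8 / 445.2),   # ~24% of adult at birth
        ("SULT1A3", 0.0, 117.3 / 97.2),
        ("SULT1E1", 5.0, 1.0),
    ],
)
def test_relative_activity_values(ontogeny_library, enzyme, age, expected):
    assert relative_activity(ontogeny_library[enzyme], age) == pytest.approx(expected, rel=1e-12)


@given(age=st.floats(0.0, 100.0, allow_nan=False))
def test_relative_activity_is_one_at_reference(age):
    model = builtin_ontogeny_library()["SULT1A1"]
    assert relative_activity(model, age, reference_age=age) == pytest.approx(1.0)


@given(
    c1=st.floats(10.0, 500.0),
    s1=st.floats(-100.0, 100.0),
    bp1=st.floats(0.5, 5.0),
    a2=st.floats(10.0, 2000.0),
    s2=st.floats(-50.0, 50.0),
    width=st.floats(1.0, 20.0),
    age=st.floats(0.0, 60.0),
)
def test_piecewise_evaluation_matches_phase_formula(c1, s1, bp1, a2, s2, width, age):
    bp2 = bp1 + width
    plateau = a2 + s2 * (bp2 - bp1)
    if plateau <= 0:
        return
    model = OntogenyPiecewise3(c1, s1, bp1, a2, s2, bp2, plateau)
    if age < bp1:
        expected = c1 + s1 * age
    elif age <= bp2:
        expected = a2 + s2 * (age - bp1)
    else:
        expected = plateau
    assert model.abundance(age) == pytest.approx(expected, rel=1e-12, abs=1e-12)


def test_invalid_piecewise_parameters_rejected():
    with pytest.raises(ValueError):
        OntogenyPiecewise3(1, 1, 5.0, 1, 1, 2.0, 10.0)   # breakpoints out of order
    with pytest.raises(ValueError):
        OntogenyPiecewise3(1, 1, 1.0, 1, 1, 2.0, -1.0)   # non-positive plateau


def test_abundance_record_invariants():
    with pytest.raises(ValueError):
        AbundanceRecord("SULT1A1", -1.0, 100.0)
    with pytest.raises(ValueError):
        AbundanceRecord("SULT1A1", 1.0, 0.0)


# ---------------------------------------------------------------------------
# regression engine
# ---------------------------------------------------------------------------


def test_noise_free_recovery_within_one_percent(ontogeny_library):
    truth = ontogeny_library["SULT1A1"]
    records = simulate_abundance_dataset(
        AbundanceSimSpec("SULT1A1", truth, n_subjects=120, noise_cv=0.0, seed=3)
    )
    fit = fit_ontogeny(records, "piecewise3")
    true_vec = np.array([107.8, 88.6, 1.83, 370.1, 6.99, 12.6])
    assert np.max(np.abs(fit.params - true_vec) / np.abs(true_vec)) < 0.01
    assert fit.r2 == pytest.approx(1.0, abs=1e-9)
    model = fit.as_model()
    assert model.plateau == pytest.approx(445.2, rel=0.01)


def test_single_age_design_is_unidentifiable():
    records = [AbundanceRecord("SULT1A1", 1.0, 100.0 + i) for i in range(20)]
    with pytest.raises(ValueError):
        fit_ontogeny(records, "piecewise3")


def test_too_few_records_rejected():
    records = [AbundanceRecord("SULT1A1", float(i), 100.0) for i in range(4)]
    with pytest.raises(ValueError):
        fit_ontogeny(records, "piecewise3")


def test_select_best_tie_breaks_on_fewer_parameters():
    small = OntogenyFit("exponential", np.zeros(3), 1.0, 100.0, 0.5, 50)
    big = OntogenyFit("piecewise3", np.zeros(6), 1.0, 100.0, 0.5, 50)
    assert select_best([big, small]).form == "exponential"
    assert select_best([small]).form == "exponential"
    with pytest.raises(ValueError):
        select_best([])


def test_aic_selection_invariant_to_unit_rescaling(ontogeny_library):
    truth = ontogeny_library["SULT1A1"]
    records = simulate_abundance_dataset(
        AbundanceSimSpec("SULT1A1", truth, n_subjects=150, noise_cv=0.25, seed=1)
    )
    frame_fits = OntogenyRegression(records).fit_all()
    base_best = select_best(frame_fits).form
    for scale in (0.01, 1000.0):
        scaled = [
            AbundanceRecord(r.enzyme, r.age, r.abundance * scale) for r in records
        ]
        fits = OntogenyRegression(scaled).fit_all()
        assert select_best(fits).form == base_best
        # AIC shifts by the same additive constant n*ln(scale^2) for every form
        shifts = [f.aic - g.aic for f, g in zip(fits, frame_fits)]
        expected = len(records) * np.log(scale**2)
        assert np.allclose(shifts, expected, atol=0.5)


def test_nonconvergent_smooth_fit_is_flagged_not_raised():
    # two distinct ages cannot pin down a 3-parameter exponential
    records = [
        AbundanceRecord("SULT1A1", age, ab)
        for age, ab in [(0.0, 1.0), (0.0, 2.0), (1.0, 1.5), (1.0, 2.5), (0.5, 2.0)]
    ]
    fit = fit_ontogeny(records, "exponential")
    assert isinstance(fit, OntogenyFit)  # degenerate designs may still converge,
    assert np.isfinite(fit.rss)          # but must never raise


def test_constant_ontogeny_relative_activity():
    c = ConstantOntogeny(5.0)
    assert c.abundance(50.0) == 5.0
    assert c.relative_activity(0.0) == 1.0
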