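"""Dose-response inference: scoring, probit fits, ratios, pooled GLM."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from symbiofit import presets
from symbiofit.bioassay import (
    fit_dose_response,
    lc50_regression_with_slope_test,
    pooled_bioassay_glm,
    resistance_ratio,
    score_mortality,
)
from symbiofit.exceptions import ConvergenceError, ValidationError
from symbiofit.synthetic_data import BioassayDesign, gen_bioassay


# -- mortality scoring -------------------------------------------------------


@pytest.mark.parametrize(
    "alive, mass, expected",
    [
        (True, 4.9, "dead"),   # growth-arrested survivor below 5 mg
        (True, 5.0, "alive"),  # the 5 mg cut is strict: exactly 5 mg lives
        (True, 120.0, "alive"),
        (False, 50.0, "dead"),
        (False, None, "dead"),
    ],
)
def test_mortality_scoring_five_mg_rule(alive, mass, expected):
    assert score_mortality(alive, mass) == expected


def test_mortality_scoring_rejects_negative_mass():
    with pytest.raises(ValidationError):
        score_mortality(True, -1.0)


# -- dose-response fitting ---------------------------------------------------


def _arm_table(doses, n, dead):
    return pd.DataFrame({"strain": "S", "hadv2": "negative", "dose_ug_ml": doses, "n_tested": n, "n_dead": dead})


def test_symmetric_design_puts_lc50_at_middle_dose():
    """Mortalities 10/50/90% at doses 0.1/1/10 pin the LC50 at 1.0."""
    tab = _arm_table([0.1, 1.0, 10.0], [10, 10, 10], [1, 5, 9])
    fit = fit_dose_response(tab, link="probit")
    assert fit.converged
    assert fit.lc50 == pytest.approx(1.0, rel=1e-6)


def test_lc50_identity_holds_to_machine_precision(bioassay_table):
    fit = fit_dose_response(bioassay_table)
    assert fit.log10_lc50 == pytest.approx(-fit.intercept / fit.slope, abs=1e-14)
    assert fit.ci95_lc50[0] < fit.lc50 < fit.ci95_lc50[1]
    assert fit.heterogeneity_factor >= 1.0


def test_recovered_lc50_within_its_own_interval(basic_bioassay_design, bioassay_table):
    fit = fit_dose_response(bioassay_table)
    lo, hi = np.log10(fit.ci95_lc50[0]), np.log10(fit.ci95_lc50[1])
    assert lo <= basic_bioassay_design.true_log10_lc50 <= hi


def test_irls_matches_direct_likelihood_grid(bioassay_table):
    """The IRLS optimum beats every point of a fine likelihood grid."""
    from scipy.special import ndtr, xlogy

    fit = fit_dose_response(bioassay_table)
    d = bioassay_table
    logd = np.log10(d["dose_ug_ml"].to_numpy())
    y, n = d["n_dead"].to_numpy(float), d["n_tested"].to_numpy(float)

    def loglik(a, b):
        mu = np.clip(ndtr(a + b * logd), 1e-12, 1 - 1e-12)
        return np.sum(xlogy(y, mu) + xlogy(n - y, 1 - mu))

    best_grid = max(
        loglik(a, b)
        for a in np.linspace(fit.intercept - 0.5, fit.intercept + 0.5, 41)
        for b in np.linspace(fit.slope - 0.5, fit.slope + 0.5, 41)
    )
    assert loglik(fit.intercept, fit.slope) >= best_grid - 1e-6


def test_dose_doubling_shifts_lc50_by_log2(bioassay_table):
    fit0 = fit_dose_response(bioassay_table)
    doubled = bioassay_table.assign(dose_ug_ml=bioassay_table["dose_ug_ml"] * 2)
    fit2 = fit_dose_response(doubled)
    assert fit2.log10_lc50 - fit0.log10_lc50 == pytest.approx(np.log10(2), abs=1e-8)
    assert fit2.slope == pytest.approx(fit0.slope, abs=1e-8)


def test_probit_and_logit_lc50s_agree_near_the_median(bioassay_table):
    p = fit_dose_response(bioassay_table, link="probit")
    l = fit_dose_response(bioassay_table, link="logit")
    assert abs(np.log10(p.lc50 / l.lc50)) < np.log10(1.10)


def test_abbott_correction_recenters_control_mortality():
    """With 20% background mortality, correction pulls the LC50 back up."""
    design = BioassayDesign(
        "LF", "negative", 0.0, 2.0,
        tuple(10.0**x for x in np.linspace(-1.25, 1.25, 6)),
        n_per_dose=5000, control_mortality=0.2,
    )
    tab = gen_bioassay(design, seed=77)
    raw = fit_dose_response(tab, control_correction=False)
    adj = fit_dose_response(tab, control_correction=True)
    assert adj.log10_lc50 > raw.log10_lc50
    assert abs(adj.log10_lc50 - 0.0) < abs(raw.log10_lc50 - 0.0)


@pytest.mark.parametrize(
    "doses, dead, match",
    [
        ([1.0, 2.0], [1, 5], "3 positive-dose"),
        ([1.0, 1.0, 1.0], [1, 3, 5], "identical"),
        ([0.1, 1.0, 10.0], [0, 0, 0], "all-alive"),
    ],
)
def test_unfittable_designs_are_rejected(doses, dead, match):
    tab = _arm_table(doses, [10] * len(doses), dead)
    with pytest.raises(ValidationError, match=match):
        fit_dose_response(tab)


# -- ratios ------------------------------------------------------------------


def _fixed_fit(log10_lc50, se=0.05):
    tab = _arm_table(
        [10**(log10_lc50 - 1), 10**log10_lc50, 10**(log10_lc50 + 1)],
        [100, 100, 100],
        [16, 50, 84],
    )
    return fit_dose_response(tab)


def test_resistance_ratio_arithmetic():
    """LC50s of 96 and 0.4 give the 240-fold resistance ratio."""
    hi = _fixed_fit(np.log10(96.0))
    lo = _fixed_fit(np.log10(0.4))
    est = resistance_ratio(hi, lo)
    assert est.ratio == pytest.approx(240.0, rel=1e-6)
    assert est.ci95[0] < 240.0 < est.ci95[1]


def test_resistance_ratio_identity_and_reciprocity(bioassay_table):
    fit = fit_dose_response(bioassay_table)
    same = resistance_ratio(fit, fit)
    assert same.ratio == pytest.approx(1.0)
    assert same.ci95[0] < 1.0 < same.ci95[1]
    other = _fixed_fit(0.5)
    ab = resistance_ratio(fit, other)
    ba = resistance_ratio(other, fit)
    assert ab.ratio * ba.ratio == pytest.approx(1.0, rel=1e-12)


def test_tolerance_ratio_recovers_generated_uplift():
    """Infected/uninfected arms generated at ratio 1.5 recover it in CI."""
    neg, pos = presets.bioassay_arm_designs("LF")  # tolerance ratio 1.5
    fneg = fit_dose_response(gen_bioassay(neg, seed=101))
    fpos = fit_dose_response(gen_bioassay(pos, seed=202))
    est = resistance_ratio(fpos, fneg)
    assert est.ci95[0] < 1.5 < est.ci95[1]


def test_ratio_requires_converged_fits(bioassay_table):
    fit = fit_dose_response(bioassay_table)
    bad = fit_dose_response(bioassay_table)
    bad.converged = False
    with pytest.raises(ConvergenceError):
        resistance_ratio(fit, bad)


# -- pooled GLM --------------------------------------------------------------


def _two_strain_table(seed=1, uplift=1.0):
    frames = []
    for i, (strain, lc) in enumerate([("LF", 0.0), ("LF60", 1.2)]):
        for j, status in enumerate(["negative", "positive"]):
            shift = np.log10(uplift) if status == "positive" else 0.0
            d = BioassayDesign(
                strain, status, lc + shift, 2.0,
                tuple(10.0**x for x in np.linspace(lc - 1.2, lc + 1.2, 6)),
                n_per_dose=72,
            )
            frames.append(gen_bioassay(d, seed + 10 * i + j))
    return pd.concat(frames, ignore_index=True)


def test_pooled_glm_matches_statsmodels_sequential_deviances():
    """Term chi-squares equal an independent GLM's deviance drops."""
    tab = _two_strain_table(seed=5)
    table = pooled_bioassay_glm(tab)

    logd = np.log10(tab["dose_ug_ml"].to_numpy())
    strain = pd.get_dummies(tab["strain"], drop_first=True).to_numpy(float)
    hadv2 = (tab["hadv2"] == "positive").to_numpy(float)[:, None]
    resp = np.column_stack([tab["n_dead"], tab["n_tested"] - tab["n_dead"]])
    ones = np.ones((len(tab), 1))
    designs = [
        ones,
        np.hstack([ones, strain]),
        np.hstack([ones, strain, logd[:, None]]),
        np.hstack([ones, strain, logd[:, None], strain * logd[:, None]]),
        np.hstack([ones, strain, logd[:, None], strain * logd[:, None], hadv2]),
    ]
    devs = [
        sm.GLM(resp, X, family=sm.families.Binomial()).fit().deviance for X in designs
    ]
    expected = [devs[i] - devs[i + 1] for i in range(4)]
    got = [row["chi2"] for row in table.terms]
    assert np.allclose(got, expected, atol=1e-6)
    assert table.residual_deviance == pytest.approx(devs[-1], abs=1e-6)


def test_pooled_glm_deviance_drops_are_nonnegative():
    table = pooled_bioassay_glm(_two_strain_table(seed=9))
    assert all(row["chi2"] >= 0 for row in table.terms)


def test_infection_coefficient_sign_tracks_higher_lc50():
    """Arms generated with higher infected LC50 show lower infected mortality."""
    tab = _two_strain_table(seed=3, uplift=1.8)
    table = pooled_bioassay_glm(tab)
    coef, _ = table.coef["hadv2"]
    assert coef < 0


def test_pooled_glm_rejects_single_strain():
    tab = _two_strain_table(seed=1)
    with pytest.raises(ValidationError, match="2 strains"):
        pooled_bioassay_glm(tab[tab["strain"] == "LF"])


# -- LC50 regression with slope test ----------------------------------------


def test_exact_line_fixture_recovers_its_coefficients():
    """Noiseless points on y = 1.2794x + 2.8726 give that slope and r2 = 1."""
    x = np.array([0.4, 2.0, 24.0, 48.0, 96.0])
    y = 1.2794 * x + 2.8726
    res = lc50_regression_with_slope_test(np.column_stack([x, y]))
    assert res.slope == pytest.approx(1.2794, abs=1e-10)
    assert res.intercept == pytest.approx(2.8726, abs=1e-8)
    assert res.r2 == pytest.approx(1.0, abs=1e-10)
    assert res.t_vs_1 > 0  # slope exceeds one


def test_identity_line_gives_zero_slope_test():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    res = lc50_regression_with_slope_test(np.column_stack([x, x]))
    assert res.slope == pytest.approx(1.0)
    assert res.t_vs_1 == pytest.approx(0.0, abs=1e-8)


def test_slope_test_matches_normal_equation_arithmetic():
    """Hand-picked points cross-checked against closed-form OLS formulas."""
    pts = np.array([[1.0, 2.1], [2.0, 3.9], [3.0, 6.2], [4.0, 7.8]])
    res = lc50_regression_with_slope_test(pts)
    x, y = pts[:, 0], pts[:, 1]
    sxx = np.sum((x - x.mean()) ** 2)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    resid = y - (y.mean() + slope * (x - x.mean()))
    se = np.sqrt(resid @ resid / 2 / sxx)
    assert res.slope == pytest.approx(slope, abs=1e-12)
    assert res.se_slope == pytest.approx(se, abs=1e-12)
    assert res.t_vs_1 == pytest.approx((slope - 1) / se, abs=1e-10)
    assert res.df == 2


def test_slope_test_needs_three_points():
    with pytest.raises(ValidationError):
        lc50_regression_with_slope_test([(1.0, 1.0), (2.0, 2.0)])


# -- properties --------------------------------------------------------------


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_fitted_lc50_identity_is_exact_for_any_seed(seed):
    """10^(-intercept/slope) equals the fitted LC50 on arbitrary seeded data."""
    design = BioassayDesign(
        "LF", "negative", 0.2, 2.5,
        tuple(10.0**x for x in np.linspace(-1.0, 1.4, 6)), n_per_dose=72,
    )
    tab = gen_bioassay(design, seed=seed)
    try:
        fit = fit_dose_response(tab)
    except ValidationError:
        return  # an all-dead/all-alive draw is legitimately unfittable
    if fit.converged:
        assert fit.lc50 == pytest.approx(10.0 ** (-fit.intercept / fit.slope), rel=1e-12)
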