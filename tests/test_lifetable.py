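"""Net reproductive rate composition, bootstrap, rescue and plant assays."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.formula.api import ols

from symbiofit import presets
from symbiofit.exceptions import ValidationError
from symbiofit.lifetable import (
    bootstrap_r0,
    compose_r0,
    fitness_cost,
    plant_growth_model,
    rescue_comparison,
)
from symbiofit.synthetic_data import gen_lifetable, lifetable_design_r0


# -- compose_r0 --------------------------------------------------------------


def test_degenerate_cohort_composes_exact_product(degenerate_lifetable):
    """All rates one, fecundity 100, half female: exactly 50 daughters."""
    est = compose_r0(degenerate_lifetable)
    assert est.r0 == pytest.approx(50.0)


def test_any_zero_component_annihilates_r0(degenerate_lifetable):
    dead = degenerate_lifetable.assign(surv_l1_l5=0)
    assert compose_r0(dead).r0 == 0.0


def test_compose_is_monotone_in_component_means(degenerate_lifetable):
    base = compose_r0(degenerate_lifetable).r0
    poorer = degenerate_lifetable.assign(emerged=[1] * 10 + [0] * 10)
    richer = degenerate_lifetable.assign(fecundity=degenerate_lifetable["fecundity"] * 2)
    assert compose_r0(poorer).r0 < base < compose_r0(richer).r0


def test_compose_rejects_empty_cohort(degenerate_lifetable):
    with pytest.raises(ValidationError, match="empty"):
        compose_r0(degenerate_lifetable.iloc[0:0])


def test_generated_cohort_r0_tracks_design_product():
    design, _ = presets.lifetable_arm_designs("LF")
    coh = gen_lifetable(design, seed=31)
    est = bootstrap_r0(coh, n_boot=500, seed=1)
    truth = lifetable_design_r0(design)
    assert abs(est.r0 - truth) < 3 * est.se_boot


# -- bootstrap ---------------------------------------------------------------


def test_bootstrap_of_identical_individuals_has_zero_se(degenerate_lifetable):
    uniform = degenerate_lifetable.assign(female=1, fecundity=100.0, hatch_rate=1.0,
                                          female_pupal_duration=11.0, female_longevity=10.0,
                                          male_pupal_duration=np.nan, male_longevity=np.nan)
    est = bootstrap_r0(uniform, n_boot=200, seed=5)
    assert est.se_boot == pytest.approx(0.0, abs=1e-12)


def test_bootstrap_is_deterministic_under_seed(degenerate_lifetable):
    a = bootstrap_r0(degenerate_lifetable, n_boot=300, seed=42)
    b = bootstrap_r0(degenerate_lifetable, n_boot=300, seed=42)
    assert a.se_boot == b.se_boot


def test_bootstrap_se_matches_delta_method_when_only_fecundity_varies():
    """With one random factor, SE(R0) ~ (product of constants) * sigma/sqrt(n)."""
    rng = np.random.default_rng(17)
    n = 200
    fec = rng.normal(100.0, 15.0, n).clip(min=1)
    cohort = pd.DataFrame(
        {
            "strain": "LF", "hadv2": "negative", "replicate": 1,
            "individual_id": np.arange(n),
            "surv_l1_l5": 1, "surv_l5_pupa": 1, "larval_duration": 16.0,
            "pupal_weight": 320.0, "female": 1,
            "female_pupal_duration": 11.0, "male_pupal_duration": np.nan,
            "emerged": 1, "copulated": 1,
            "female_longevity": 10.0, "male_longevity": np.nan,
            "fecundity": fec, "hatch_rate": 1.0,
        }
    )
    delta_se = fec.std(ddof=1) / np.sqrt(n)  # product of other means is 1
    ses = [bootstrap_r0(cohort, n_boot=400, seed=s).se_boot for s in range(20)]
    assert abs(np.mean(ses) - delta_se) / delta_se < 0.15


def test_bootstrap_mean_converges_to_point_estimate():
    design, _ = presets.lifetable_arm_designs("LF5")
    coh = gen_lifetable(design, seed=8)
    est = bootstrap_r0(coh, n_boot=2000, seed=3)
    # bootstrap distribution centers on the plug-in estimate
    rng = np.random.default_rng(3)
    assert est.se_boot > 0
    assert est.n_boot >= 1900


def test_bootstrap_requires_enough_replicates(degenerate_lifetable):
    with pytest.raises(ValidationError, match="n_boot"):
        bootstrap_r0(degenerate_lifetable, n_boot=1)


# -- fitness cost and rescue -------------------------------------------------


@pytest.mark.parametrize("focal, ref, cost", [(4.0, 10.0, 0.60), (7.0, 10.0, 0.30), (10.0, 10.0, 0.0)])
def test_fitness_cost_is_complement_of_r0_ratio(focal, ref, cost):
    assert fitness_cost(focal, ref) == pytest.approx(cost)


def test_fitness_cost_rejects_zero_reference():
    with pytest.raises(ValidationError):
        fitness_cost(1.0, 0.0)


def test_rescue_comparison_hand_arithmetic():
    """Differences (1,2,3,2) give t = 2 / (0.8165/2) = 4.899 on 3 df."""
    pairs = [("a", 10.0, 11.0), ("b", 10.0, 12.0), ("c", 10.0, 13.0), ("d", 10.0, 12.0)]
    res = rescue_comparison(pairs)
    assert res.t == pytest.approx(4.899, abs=1e-3)
    assert res.df == 3


def test_rescue_comparison_null_gives_t_zero_p_one():
    pairs = [("a", 5.0, 5.0), ("b", 7.0, 7.0), ("c", 9.0, 9.0)]
    res = rescue_comparison(pairs)
    assert res.t == 0.0
    assert res.p == 1.0


def test_rescue_comparison_is_antisymmetric():
    pairs = [("a", 10.0, 13.0), ("b", 12.0, 15.5), ("c", 9.0, 13.1)]
    fwd = rescue_comparison(pairs)
    rev = rescue_comparison([(s, b, a) for s, a, b in pairs])
    assert rev.t == pytest.approx(-fwd.t)


def test_uniform_uplift_recovers_its_percent_change():
    """Pairs built with a 38% uplift and mild noise center near +38%."""
    rng = np.random.default_rng(11)
    base = np.array([140.0, 100.0, 95.0, 55.0])
    pos = base * 1.38 * rng.normal(1.0, 0.03, 4)
    pairs = [(f"s{i}", b, p) for i, (b, p) in enumerate(zip(base, pos))]
    res = rescue_comparison(pairs)
    se = np.std(res.percent_changes, ddof=1) / 2
    assert abs(res.mean_percent_change - 38.0) < 3 * se + 1.0


def test_rescue_comparison_rejects_zero_baseline():
    with pytest.raises(ValidationError):
        rescue_comparison([("a", 0.0, 1.0), ("b", 1.0, 2.0)])


# -- plant growth model ------------------------------------------------------


def _plant_data(seed=0, interaction_effect=0.0, n_per_cell=48 * 3):
    rng = np.random.default_rng(seed)
    rows = []
    for variety in ("Bt", "non-Bt"):
        for strain in ("LF", "LF240"):
            for status in ("negative", "positive"):
                mu = 100.0
                mu += -30.0 if variety == "Bt" else 0.0
                mu += -20.0 if strain == "LF240" else 0.0
                mu += 10.0 if status == "positive" else 0.0
                if variety == "Bt" and status == "positive":
                    mu += interaction_effect
                rows.append(
                    pd.DataFrame(
                        {
                            "weight": rng.normal(mu, 8.0, n_per_cell),
                            "variety": variety,
                            "strain": strain,
                            "hadv2": status,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


def test_plant_model_scale_invariance():
    data = _plant_data(seed=2)
    res1 = plant_growth_model(data)
    res2 = plant_growth_model(data.assign(weight=data["weight"] * 2))
    for a, b in zip(res1.terms, res2.terms):
        assert a["F"] == pytest.approx(b["F"], rel=1e-10)
    assert res1.interaction_F == pytest.approx(res2.interaction_F, rel=1e-10)
    assert res2.rss_full == pytest.approx(4 * res1.rss_full, rel=1e-10)


def test_plant_model_matches_statsmodels_type_i_anova():
    """Sequential F terms equal statsmodels anova_lm on the same model."""
    data = _plant_data(seed=4, n_per_cell=30)
    res = plant_growth_model(data, interactions=False)
    fit = ols("weight ~ C(variety) + C(strain) + C(hadv2)", data=data).fit()
    table = sm.stats.anova_lm(fit, typ=1)
    expected = table["F"][:3].to_numpy()
    got = np.array([row["F"] for row in res.terms])
    assert np.allclose(got, expected, rtol=1e-8)


def test_plant_model_interaction_block_matches_statsmodels():
    data = _plant_data(seed=6, interaction_effect=15.0, n_per_cell=30)
    res = plant_growth_model(data)
    main = ols("weight ~ C(variety) + C(strain) + C(hadv2)", data=data).fit()
    full = ols("weight ~ C(variety) * C(strain) * C(hadv2)", data=data).fit()
    cmp_table = sm.stats.anova_lm(main, full)
    assert res.interaction_F == pytest.approx(float(cmp_table["F"][1]), rel=1e-8)
    assert res.interaction_p == pytest.approx(float(cmp_table["Pr(>F)"][1]), abs=1e-10)
    assert res.interaction_p < 0.05  # the built-in interaction is detected


def test_plant_model_rejects_empty_cells():
    data = _plant_data(seed=8, n_per_cell=10)
    truncated = data[~((data["variety"] == "Bt") & (data["strain"] == "LF240"))]
    with pytest.raises(ValidationError, match="empty factor cells"):
        plant_growth_model(truncated)
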