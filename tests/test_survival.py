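"""Logistic candidate sets, AICc arithmetic, model averaging, and effect
sign recovery on simulated release cohorts."""

import math

import numpy as np
import pandas as pd
import pytest

from genmon.survival import (
    COVARIATES,
    ModelFit,
    aicc_rank_and_average,
    akaike_weights,
    build_candidate_sets,
    fit_logistic,
    model_table,
    predicted_survival_curve,
)
from genmon.synthetic import simulate_survival_dataset


def _null_data(n_success, n_total):
    return pd.DataFrame(
        {
            "detected": [1] * n_success + [0] * (n_total - n_success),
            "release_day": 0.0,
            "release_weight": 0.0,
            "sex": "M",
            "HL": 0.0,
            "CB": 0.0,
            "year": 2014,
        }
    )


def test_null_model_intercept_is_logit_of_pooled_rate():
    """25 detections among 125 releases: the null MLE intercept equals
    log(25/100) = -1.3863."""
    fit = fit_logistic(_null_data(25, 125), ())
    assert fit.params["intercept"] == pytest.approx(
        math.log(25 / 100), abs=1e-6
    )
    assert fit.k == 1 and fit.n == 125


def test_zero_effect_covariate_estimates_near_zero():
    rng = np.random.default_rng(5)
    n = 4000
    df = pd.DataFrame(
        {
            "detected": rng.integers(0, 2, n),
            "release_day": rng.normal(size=n),
            "release_weight": rng.normal(size=n),
            "sex": np.where(rng.integers(0, 2, n) == 1, "F", "M"),
            "HL": rng.random(n),
            "CB": rng.random(n) * 100,
            "year": 2014,
        }
    )
    fit = fit_logistic(df, ("release_day",))
    assert abs(fit.params["release_day"]) < 3 * fit.bse["release_day"]


def test_simulated_effect_recovered_within_three_se():
    data = simulate_survival_dataset(
        n=1000, beta={"release_day": 0.01, "release_weight": 0.0,
                      "sex": 0.0, "HL": 0.0, "CB": 0.0},
        seed=3,
    )
    fit = fit_logistic(data, ("release_day",))
    assert abs(fit.params["release_day"] - 0.01) < 3 * fit.bse["release_day"]


def test_candidate_sets_structure():
    adults = build_candidate_sets("adult")
    assert len(adults) == 32
    assert () in adults  # null model present
    assert len(set(adults)) == 32  # no duplicates
    juv = build_candidate_sets("juvenile")
    assert len(juv) == 32
    assert all(t[0] == "year" for t in juv)
    pens = build_candidate_sets("release_pen")
    assert len(pens) == 32 and all("year" not in t for t in pens)
    with pytest.raises(ValueError):
        build_candidate_sets("nope")


def test_aicc_formula_and_aic_limit():
    fit = ModelFit(
        terms=("x",), params=pd.Series({"intercept": 0.0, "x": 1.0}),
        bse=pd.Series({"intercept": 0.1, "x": 0.1}),
        loglik=-100.0, k=2, n=50,
    )
    expected = 200 + 4 + 2 * 2 * 3 / (50 - 3)
    assert fit.aicc == pytest.approx(expected, abs=1e-12)
    big = ModelFit(fit.terms, fit.params, fit.bse, -100.0, 2, 10**6)
    assert abs(big.aicc - big.aic) < 1e-3
    tiny = ModelFit(fit.terms, fit.params, fit.bse, -1.0, 5, 6)
    assert math.isinf(tiny.aicc)


def test_akaike_weights_hand_computed():
    """Three fabricated fits: weights equal the exp(-delta/2) table."""
    aiccs = [100.0, 102.0, 106.0]
    w = akaike_weights(aiccs)
    raw = np.array([1.0, math.exp(-1.0), math.exp(-3.0)])
    np.testing.assert_allclose(w, raw / raw.sum(), atol=1e-12)
    assert w.sum() == pytest.approx(1.0)
    # equal AICc -> equal split
    np.testing.assert_allclose(akaike_weights([5.0, 5.0]), [0.5, 0.5])


def _fabricated_fit(terms, ll, params):
    names = ["intercept"] + list(params)
    vals = [0.0] + [params[t] for t in params]
    return ModelFit(
        terms=tuple(terms),
        params=pd.Series(vals, index=names),
        bse=pd.Series([0.5] * len(names), index=names),
        loglik=ll, k=len(names), n=200,
    )


def test_single_model_average_is_identity():
    fit = _fabricated_fit(("x",), -80.0, {"x": 1.5})
    res = aicc_rank_and_average([fit])
    assert res.table.loc["x", "estimate"] == pytest.approx(1.5)
    assert res.weights.iloc[0] == pytest.approx(1.0)


def test_natural_averaging_renormalizes_within_subset():
    """A parameter present in a strict subset of models is averaged with
    that subset's weights renormalized (hand-checked)."""
    f1 = _fabricated_fit(("x",), -100.0, {"x": 1.0})
    f2 = _fabricated_fit(("x", "z"), -100.0, {"x": 2.0, "z": 0.3})
    f3 = _fabricated_fit((), -100.0, {})
    res = aicc_rank_and_average([f1, f2, f3])
    w = akaike_weights([f1.aicc, f2.aicc, f3.aicc])
    expect_x = (w[0] * 1.0 + w[1] * 2.0) / (w[0] + w[1])
    assert res.table.loc["x", "estimate"] == pytest.approx(expect_x)
    assert res.table.loc["x", "n_models"] == 2
    assert res.table.loc["z", "n_models"] == 1
    # weights over the whole candidate set still sum to 1
    assert res.weights.sum() == pytest.approx(1.0)
    # CI ordering invariant
    assert (res.table["ci95_low"] <= res.table["estimate"]).all()
    assert (res.table["estimate"] <= res.table["ci95_high"]).all()
    # 85% bands nest inside 95% bands
    assert (res.table["ci85_low"] >= res.table["ci95_low"]).all()


def test_unconditional_se_folds_in_model_spread():
    f1 = _fabricated_fit(("x",), -100.0, {"x": 0.0})
    f2 = _fabricated_fit(("x", "z"), -100.0, {"x": 4.0, "z": 0.0})
    res = aicc_rank_and_average([f1, f2])
    assert res.table.loc["x", "unconditional_se"] > 0.5


def test_full_candidate_run_weights_sum_to_one():
    data = simulate_survival_dataset(n=400, seed=11)
    from genmon.survival import fit_candidates

    fits = fit_candidates(data, "adult")
    assert len(fits) == 32
    tab = model_table(fits)
    assert tab["weight"].sum() == pytest.approx(1.0, abs=1e-9)
    res = aicc_rank_and_average(fits)
    assert res.weights.sum() == pytest.approx(1.0, abs=1e-9)


def test_year_always_in_juvenile_models():
    years = (2012, 2013, 2014, 2015, 2016)
    data = simulate_survival_dataset(
        n=600, seed=13,
        year_effects={2012: 1.0, 2013: 0.3, 2014: 0.0, 2015: -1.5, 2016: -0.3},
    )
    fit = fit_logistic(data, ("year",))
    # reference year 2014 absorbed into the intercept
    assert "year_2014" not in fit.params.index
    assert {"year_2012", "year_2013", "year_2015", "year_2016"} <= set(
        fit.params.index
    )


def test_sign_recovery_on_study_scale_cohorts():
    """Simulations at the released-juvenile cohort size (n=1354) with the
    monitoring study's qualitative effects (later release day and higher
    weight help, homozygosity hurts) recover all three signs in >= 95% of
    200 replicates."""
    ok = 0
    n_rep = 200
    for rep in range(n_rep):
        data = simulate_survival_dataset(n=1354, seed=40_000 + rep)
        fit = fit_logistic(
            data, ("release_day", "release_weight", "HL")
        )
        signs = (
            fit.params["release_day"] > 0
            and fit.params["release_weight"] > 0
            and fit.params["HL"] < 0
        )
        ok += bool(signs)
    assert ok / n_rep >= 0.95


def test_predicted_curve_flat_for_null_and_monotone_in_day():
    data = simulate_survival_dataset(n=800, seed=21)
    null = fit_logistic(data, ())
    grid = pd.DataFrame({"release_day": np.linspace(120, 270, 5)})
    p_null = predicted_survival_curve(null, grid, data)
    rate = data["detected"].mean()
    np.testing.assert_allclose(p_null, rate, atol=1e-9)
    day_fit = fit_logistic(data, ("release_day",))
    if day_fit.params["release_day"] > 0:
        p = predicted_survival_curve(day_fit, grid, data)
        assert np.all(np.diff(p) > 0)
    # linear predictor exactly zero -> probability one half
    zero = ModelFit(
        terms=(), params=pd.Series({"intercept": 0.0}),
        bse=pd.Series({"intercept": 1.0}), loglik=0.0, k=1, n=10,
    )
    p_half = predicted_survival_curve(
        zero, pd.DataFrame({"release_day": [150.0]}), data
    )
    assert p_half[0] == pytest.approx(0.5)
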