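"""Logistic IRLS, DiD effect estimation, diagnostics, screening, imputation
and bootstrap prevalence intervals.

The saturated time-by-country model has closed-form coefficients (empirical
log odds and odds-ratio contrasts of the 2x2x2 counts); that oracle and an
independent statsmodels GLM fit cross-check the IRLS implementation.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import logit

from duicdid import (ModelSpec, bootstrap_prevalence, build_design,
                     did_effect, fit_logistic_irls, gvif, impute_subgroup,
                     nagelkerke_r2, screen_covariates)
from duicdid.did import DID_TERM
from duicdid.errors import AliasingError, SeparationError

from conftest import did_frame_from_counts, saturated_oracle

cell_counts = st.tuples(
    *[st.tuples(st.integers(1, 400), st.integers(1, 400)) for _ in range(4)])


def test_intercept_only_fit_recovers_logit_of_mean():
    y = np.array([1.0] * 30 + [0.0] * 70)
    X = pd.DataFrame({"Intercept": np.ones(100)})
    fit = fit_logistic_irls(X, y)
    assert fit.params["Intercept"] == pytest.approx(float(logit(0.3)),
                                                    abs=1e-10)


@given(cell_counts)
def test_saturated_fit_matches_count_oracle(cells):
    successes = [s for s, _ in cells]
    ns = [s + f for s, f in cells]
    df, w = did_frame_from_counts(successes, ns)
    res = did_effect(df, ModelSpec("y", weighted=True), weights=w)
    oracle = saturated_oracle(successes, ns)
    for name in ("Intercept", "time[t1]", "country[intervention]", DID_TERM):
        assert res.fit.params[name] == pytest.approx(oracle[name], abs=1e-8)
    assert res.fit.bse[DID_TERM] == pytest.approx(oracle["se_interaction"],
                                                  abs=1e-8)


def test_half_weight_duplication_leaves_coefficients_unchanged():
    df, w = did_frame_from_counts([20, 35, 10, 12], [100, 120, 60, 70])
    res1 = did_effect(df, ModelSpec("y", weighted=True), weights=w)
    df2 = pd.concat([df, df], ignore_index=True)
    w2 = np.concatenate([w, w]) / 2.0
    res2 = did_effect(df2, ModelSpec("y", weighted=True), weights=w2)
    pd.testing.assert_series_equal(res1.fit.params, res2.fit.params,
                                   atol=1e-10)


def test_irls_matches_statsmodels_glm_with_covariates(clean_samples):
    sm = pytest.importorskip("statsmodels.api")
    clean = clean_samples[0]
    spec = ModelSpec("cannabis_12m", covariates=("gender", "age_group"))
    X, y, terms = build_design(clean, spec)
    fit = fit_logistic_irls(X, y, terms=terms)
    ref = sm.GLM(y, X.to_numpy(dtype=float),
                 family=sm.families.Binomial()).fit()
    assert np.allclose(fit.params.to_numpy(), ref.params, atol=1e-8)
    assert np.allclose(fit.bse.to_numpy(), ref.bse, atol=1e-6)
    assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)


def test_reconstructed_user_sample_interaction_or():
    # counts reconstructed from prevalences 28.5/26.8/12.8/16.3 percent at
    # arm sizes 393/589/86/92; ratio-of-odds-ratios oracle ~= 0.692
    df, w = did_frame_from_counts([112, 158, 11, 15], [393, 589, 86, 92])
    res = did_effect(df, ModelSpec("y", weighted=True), weights=w)
    oracle = ((158 / 431) / (112 / 281)) / ((15 / 77) / (11 / 75))
    assert res.odds_ratio == pytest.approx(oracle, abs=1e-8)
    assert res.odds_ratio == pytest.approx(0.692, abs=5e-4)


def test_population_prevalence_interaction_or_near_printed_value():
    # weighted cell prevalences 12.1/14.4/9.4/9.6 percent imply an
    # interaction OR of ~1.19, consistent with the published 1.18 (0.95-1.48)
    ns = np.array([6670, 9692, 2132, 2102])
    prev = np.array([0.121, 0.144, 0.094, 0.096])
    successes = np.round(ns * prev).astype(int)
    df, w = did_frame_from_counts(successes, ns)
    res = did_effect(df, ModelSpec("y", weighted=True), weights=w)
    assert res.odds_ratio == pytest.approx(1.19, abs=0.02)
    assert res.ci_low < 1.18 < res.ci_high


def test_equal_trends_interaction_ci_covers_one():
    # both countries share identical trends: the DiD null case
    df, w = did_frame_from_counts([120, 180, 60, 90], [1000, 1500, 500, 750])
    res = did_effect(df, ModelSpec("y", weighted=True), weights=w)
    assert res.ci_low < 1.0 < res.ci_high
    assert res.odds_ratio == pytest.approx(1.0, abs=1e-8)


def test_separation_raises():
    df = pd.DataFrame({
        "country": ["intervention"] * 10 + ["control"] * 10,
        "wave": ["t0", "t1"] * 10,
        "y": [1.0] * 10 + [0.0] * 10,
    })
    with pytest.raises(SeparationError):
        did_effect(df, ModelSpec("y"))


def test_aliased_design_names_columns():
    df, w = did_frame_from_counts([20, 35, 10, 12], [100, 120, 60, 70])
    X, y, terms = build_design(df, ModelSpec("y"))
    X["copy_of_time"] = X["time[t1]"]
    with pytest.raises(AliasingError, match="copy_of_time|time"):
        fit_logistic_irls(X, y, weights=w)


class TestNagelkerke:
    def test_null_model_scores_zero(self):
        y = np.array([1.0] * 40 + [0.0] * 60)
        X = pd.DataFrame({"Intercept": np.ones(100)})
        fit = fit_logistic_irls(X, y)
        assert nagelkerke_r2(fit) == pytest.approx(0.0, abs=1e-12)

    def test_formula_oracle(self):
        df, w = did_frame_from_counts([30, 80, 10, 12], [100, 120, 60, 70])
        res = did_effect(df, ModelSpec("y", weighted=True), weights=w)
        fit = res.fit
        n = fit.n
        cs = 1 - np.exp(2 / n * (fit.null_loglik - fit.loglik))
        expected = cs / (1 - np.exp(2 / n * fit.null_loglik))
        assert res.nagelkerke == pytest.approx(expected, abs=1e-10)

    def test_near_perfect_predictor_approaches_one(self):
        # 200 per group, exactly 2 misclassified each way: the MLE is
        # finite and the predictor is almost perfectly informative
        x = np.repeat([0.0, 1.0], 200)
        y = x.copy()
        y[:2] = 1.0
        y[-2:] = 0.0
        X = pd.DataFrame({"Intercept": 1.0, "x": x})
        fit = fit_logistic_irls(X, y)
        assert fit.converged
        assert nagelkerke_r2(fit) > 0.9


class TestGVIF:
    def test_orthogonal_predictors_give_unit_gvif(self):
        # balanced 2x2 factorial: the two dummies are uncorrelated
        df = pd.DataFrame({
            "country": ["intervention", "intervention", "control",
                        "control"] * 50,
            "wave": ["t0", "t1", "t0", "t1"] * 50,
        })
        rng = np.random.default_rng(0)
        df["y"] = rng.integers(0, 2, len(df)).astype(float)
        X, y, terms = build_design(df, ModelSpec("y", interaction=False))
        fit = fit_logistic_irls(X, y, terms=terms)
        tab = gvif(fit)
        assert np.allclose(tab["gvif"], 1.0, atol=1e-10)

    def test_two_correlated_predictors_closed_form(self):
        rng = np.random.default_rng(4)
        n = 2000
        x1 = rng.normal(size=n)
        x2 = 0.6 * x1 + 0.8 * rng.normal(size=n)
        y = (rng.random(n) < 0.3).astype(float)
        X = pd.DataFrame({"Intercept": 1.0, "x1": x1, "x2": x2})
        fit = fit_logistic_irls(X, y, terms={"x1": ["x1"], "x2": ["x2"]})
        r = np.corrcoef(x1, x2)[0, 1]
        tab = gvif(fit)
        assert tab.loc["x1", "gvif"] == pytest.approx(1 / (1 - r ** 2),
                                                      rel=1e-10)

    def test_interaction_term_gvif_exceeds_one(self, clean_samples):
        clean = clean_samples[0]
        res = did_effect(clean, ModelSpec("cannabis_12m"))
        assert res.gvif_table.loc["time:country", "gvif"] > 1.0


class TestScreening:
    def test_outcome_as_its_own_covariate_is_selected(self, clean_samples):
        clean = clean_samples[0].copy()
        clean["self"] = clean["cannabis_12m"].map({True: "yes", False: "no"})
        selected, report = screen_covariates(clean, "cannabis_12m", ["self"])
        assert selected == ["self"]
        assert report.loc[0, "p_value"] < 1e-10

    def test_empty_candidate_list(self, clean_samples):
        selected, report = screen_covariates(clean_samples[0],
                                             "cannabis_12m", [])
        assert selected == [] and report.empty

    def test_single_level_covariate_skipped_with_warning(self, clean_samples):
        clean = clean_samples[0].copy()
        clean["const"] = "same"
        with pytest.warns(UserWarning, match="single level"):
            selected, report = screen_covariates(clean, "cannabis_12m",
                                                 ["const"])
        assert selected == []
        assert not report.loc[0, "selected"]

    def test_independent_covariate_rarely_selected(self):
        rng = np.random.default_rng(12)
        kept = 0
        for _ in range(60):
            df = pd.DataFrame({
                "wave": "t0",
                "y": (rng.random(2000) < 0.12).astype(float),
                "noise": rng.choice(["a", "b", "c"], 2000),
            })
            sel, _ = screen_covariates(df, "y", ["noise"])
            kept += bool(sel)
        assert kept / 60 <= 0.10 + 3 * np.sqrt(0.1 * 0.9 / 60)


class TestImputation:
    @pytest.fixture
    def t0_subgroup(self, clean_samples):
        clean = clean_samples[0]
        sub = clean[(clean["wave"] == "t0")
                    & (clean["cannabis_freq"] == "less_than_monthly")]
        assert sub["duic_12m"].isna().all()
        return clean

    def test_rate_zero_imputes_all_false(self, t0_subgroup):
        out = impute_subgroup(t0_subgroup, 0.0)
        mask = ((out["wave"] == "t0")
                & (out["cannabis_freq"] == "less_than_monthly"))
        assert (out.loc[mask, "duic_12m"] == 0.0).all()

    def test_deterministic_largest_remainder(self, t0_subgroup):
        small = pd.concat(
            [t0_subgroup[(t0_subgroup["wave"] == "t0")
                         & (t0_subgroup["cannabis_freq"]
                            == "less_than_monthly")].head(10)],
            ignore_index=True)
        out = impute_subgroup(small, 0.25, mode="deterministic")
        assert out["duic_12m"].sum() in (2.0, 3.0)

    def test_stochastic_mode_reproducible(self, t0_subgroup):
        a = impute_subgroup(t0_subgroup, 0.3, mode="stochastic", seed=5)
        b = impute_subgroup(t0_subgroup, 0.3, mode="stochastic", seed=5)
        assert (a["duic_12m"].fillna(-1) == b["duic_12m"].fillna(-1)).all()
        assert a.attrs["imputation_mode"] == "stochastic"

    def test_empty_subgroup_warns(self, clean_samples):
        t1_only = clean_samples[0].query("wave == 't1'")
        with pytest.warns(UserWarning, match="empty"):
            impute_subgroup(t1_only, 0.3)


class TestBootstrapPrevalence:
    def test_all_zero_outcome_gives_degenerate_ci(self, small_table):
        df = small_table.head(200).copy()
        df["zero"] = 0.0
        out = bootstrap_prevalence(df, "zero", B=100, seed=1)
        assert (out["ci_low"] == 0.0).all() and (out["ci_high"] == 0.0).all()

    def test_same_seed_identical_ci(self, clean_samples):
        clean = clean_samples[0]
        a = bootstrap_prevalence(clean, "cannabis_12m", B=200, seed=9)
        b = bootstrap_prevalence(clean, "cannabis_12m", B=200, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_point_estimate_is_weighted_mean(self, clean_samples):
        clean = clean_samples[0]
        rng = np.random.default_rng(0)
        w = rng.uniform(0.5, 2.0, len(clean))
        out = bootstrap_prevalence(clean, "cannabis_12m", weights=w, B=50,
                                   seed=2)
        for _, row in out.iterrows():
            grp = clean[(clean["country"] == row["country"])
                        & (clean["wave"] == row["wave"])]
            ww = w[grp.index.to_numpy()]
            expect = (ww * grp["cannabis_12m"]).sum() / ww.sum()
            assert row["prevalence"] == pytest.approx(expect, abs=1e-12)
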