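"""Discrete-time hazard model: oracles, identities and decision rules."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit

from trainsurv import (
    CohortSpec,
    FitError,
    RankDeficiencyError,
    baseline_hazards,
    build_person_period,
    effect_estimates,
    fit,
    generate_cohort,
    interaction_decision,
    interaction_rule,
    lr_test,
    published_cohort_scenario,
    pattern_curve,
    pseudo_r2,
    recode_reference,
    risk_table,
    select_entry_cohort,
)


def build_pp(n=3000, seed=1, **replace_kw):
    cfg = published_cohort_scenario(n_trainees=n, seed=seed)
    if replace_kw:
        cfg = cfg.replace(**replace_kw)
    records = generate_cohort(cfg)
    spec = CohortSpec()
    cohort = select_entry_cohort(records, spec, validate=False)
    return build_person_period(records, cohort, spec)


@pytest.fixture(scope="module")
def pp():
    return build_pp()


@pytest.fixture(scope="module")
def toy_pp():
    """Twelve hand-written person-period rows over three periods."""
    rows = [
        ("p1", 1, 0, "female"), ("p1", 2, 0, "female"), ("p1", 3, 1, "female"),
        ("p2", 1, 0, "female"), ("p2", 2, 1, "female"),
        ("p3", 1, 0, "male"), ("p3", 2, 0, "male"), ("p3", 3, 0, "male"),
        ("p4", 1, 0, "male"), ("p4", 2, 0, "male"), ("p4", 3, 1, "male"),
        ("p5", 1, 1, "male"),
    ]
    df = pd.DataFrame(rows, columns=["person_id", "time", "event", "gender"])
    df["entry_year"] = 2012
    return df


class TestFitOracle:
    def test_intercepts_only_hazards_equal_empirical_event_proportions(self, pp):
        result = fit(pp)
        curve = baseline_hazards(result)
        rt = risk_table(pp)
        empirical = (rt["events"] / rt["n_at_risk"]).to_numpy()
        assert np.max(np.abs(curve.hazards - empirical)) < 1e-8

    def test_agrees_with_statsmodels_glm(self, pp):
        result = fit(pp, covariates=["gender", "pmq_region"])
        X = np.column_stack(
            [
                *[(pp["time"] == t).to_numpy(float) for t in range(1, 6)],
                (pp["gender"] == "female").to_numpy(float),
                (pp["pmq_region"] == "non-UK").to_numpy(float),
            ]
        )
        glm = sm.GLM(pp["event"].to_numpy(float), X, family=sm.families.Binomial()).fit()
        ours = result.coef().to_numpy()
        assert np.allclose(ours, glm.params, atol=1e-6)
        assert np.allclose(result.se().to_numpy(), glm.bse, atol=1e-6)
        assert np.isclose(result.minus2LL, -2 * glm.llf, atol=1e-6)

    def test_parameter_recovery_within_three_standard_errors(self):
        pp20 = build_pp(n=20000, seed=3)
        cfg = published_cohort_scenario()
        covs = [s.name for s in cfg.covariate_specs]
        result = fit(pp20, covariates=covs)
        se = result.se()
        for s in cfg.covariate_specs:
            b = result.covariate_coefficients[s.name]
            assert abs(b - s.effect) < 3 * se[s.name], s.name

    def test_complete_case_drop_is_counted(self, pp):
        result = fit(pp, covariates=["gender", "pmq_region", "disability"])
        assert result.n_dropped_rows > 0
        assert result.n_persons < pp["person_id"].nunique()
        assert result.n_dropped_persons == pp["person_id"].nunique() - result.n_persons

    def test_likelihood_only_improves_with_covariates(self, pp):
        result = fit(pp, covariates=["gender"])
        assert result.minus2LL <= result.null_minus2LL
        assert result.converged

    def test_constant_covariate_raises_named_rank_error(self, toy_pp):
        df = toy_pp.assign(gender="female")
        with pytest.raises(RankDeficiencyError, match="gender"):
            fit(df, covariates=["gender"], max_time=3)

    def test_duplicated_covariate_detected_not_silently_fitted(self, pp):
        df = pp.assign(ethnicity=np.where(pp["gender"] == "female", "BME", "White"))
        with pytest.raises(RankDeficiencyError):
            fit(df, covariates=["gender", "ethnicity"])

    def test_global_intercept_refused(self, pp):
        with pytest.raises(FitError, match="intercept"):
            fit(pp, global_intercept=True)

    def test_all_event_or_no_event_rejected(self, toy_pp):
        with pytest.raises(FitError, match="event"):
            fit(toy_pp.assign(event=0), max_time=3)


class TestCurves:
    def test_zero_coefficient_means_half_hazard(self):
        from trainsurv.model import survival_from_hazards
        assert expit(0.0) == 0.5
        np.testing.assert_allclose(
            survival_from_hazards([0.2, 0.1, 0.571, 0.1, 0.1])[-1],
            0.8 * 0.9 * 0.429 * 0.9 * 0.9,
            rtol=1e-12,
        )

    def test_positive_coefficient_means_hazard_above_half(self, pp):
        result = fit(pp)
        curve = baseline_hazards(result)
        for b, h in zip(result.time_coefficients, curve.hazards):
            assert (b > 0) == (h > 0.5)

    def test_survival_is_product_of_one_minus_hazard(self, pp):
        result = fit(pp, covariates=["gender"])
        c = pattern_curve(result, {"gender": "female"})
        np.testing.assert_allclose(
            c.survival, np.cumprod(1 - c.hazards), rtol=0, atol=1e-12
        )
        assert (np.diff(c.survival) <= 0).all()

    def test_reference_pattern_reproduces_baseline(self, pp):
        result = fit(pp, covariates=["gender", "pmq_region"])
        ref = pattern_curve(result, {"gender": "male", "pmq_region": "UK"})
        base = baseline_hazards(result)
        np.testing.assert_allclose(ref.hazards, base.hazards, atol=1e-12)

    def test_disadvantaged_pattern_has_uniformly_higher_hazard(self, pp):
        result = fit(pp, covariates=["gender", "pmq_region"])
        base = baseline_hazards(result)
        worse = pattern_curve(result, {"gender": "female", "pmq_region": "non-UK"})
        assert (worse.hazards > base.hazards).all()

    def test_pattern_curves_never_cross(self, pp):
        result = fit(pp, covariates=["gender", "pmq_region"])
        men = pattern_curve(result, {"gender": "male", "pmq_region": "UK"})
        women = pattern_curve(result, {"gender": "female", "pmq_region": "UK"})
        diff = men.survival - women.survival
        assert (diff > 0).all() or (diff < 0).all()

    def test_unknown_pattern_covariate_rejected(self, pp):
        result = fit(pp, covariates=["gender"])
        with pytest.raises(FitError, match="unknown"):
            pattern_curve(result, {"gender": "female", "age": 1})

    def test_proportionality_by_construction(self, pp):
        # the fitted per-period OR for a covariate is one number, independent
        # of t: the hazard-odds ratio between two patterns differing in one
        # covariate is exactly exp(beta) at every period
        result = fit(pp, covariates=["gender"])
        f = pattern_curve(result, {"gender": "female"})
        m = pattern_curve(result, {"gender": "male"})
        odds = (f.hazards / (1 - f.hazards)) / (m.hazards / (1 - m.hazards))
        np.testing.assert_allclose(
            odds, np.exp(result.covariate_coefficients["gender"]), rtol=1e-10
        )


class TestEffects:
    def test_wald_ci_is_log_symmetric_and_contains_or(self, pp):
        result = fit(pp, covariates=["gender", "pmq_region"])
        for e in effect_estimates(result):
            assert e.ci_low <= e.odds_ratio <= e.ci_high
            assert np.isclose(e.ci_high / e.odds_ratio, e.odds_ratio / e.ci_low, rtol=1e-9)

    def test_recoding_reference_gives_reciprocal_or(self, pp):
        result = fit(pp, covariates=["gender"])
        flipped_pp = pp.assign(
            gender=pp["gender"].map({"female": "male", "male": "female"})
        )
        flipped = fit(flipped_pp, covariates=["gender"])
        e = effect_estimates(result)[0]
        ef = effect_estimates(flipped)[0]
        assert np.isclose(ef.odds_ratio, 1 / e.odds_ratio, rtol=1e-6)
        r = recode_reference(e)
        assert np.isclose(r.odds_ratio, 1 / e.odds_ratio, rtol=1e-12)
        assert np.isclose(r.ci_low, 1 / e.ci_high, rtol=1e-12)
        assert r.p_value == e.p_value


class TestLikelihoodMachinery:
    def test_lr_test_identical_models_gives_zero(self, pp):
        a = fit(pp, covariates=["gender"])
        chi2, df, p = lr_test(a, a)
        assert chi2 == 0 and df == 0 and p == 1.0

    def test_lr_test_nonnested_rejected(self, pp):
        a = fit(pp, covariates=["gender"])
        b = fit(pp, covariates=["pmq_region"])
        with pytest.raises(FitError, match="nested"):
            lr_test(a, b)

    def test_lr_chi2_nonnegative_and_df_counts_terms(self, pp):
        full = fit(pp, covariates=["gender", "pmq_region"])
        reduced = fit(pp, covariates=["gender"])
        chi2, df, p = lr_test(full, reduced)
        assert chi2 >= 0 and df == 1 and 0 <= p <= 1

    def test_pseudo_r2_zero_without_covariates(self, pp):
        result = fit(pp)
        cs, nk = pseudo_r2(result)
        assert cs == 0.0 and nk == 0.0

    def test_nagelkerke_at_least_cox_snell(self, pp):
        result = fit(pp, covariates=["gender", "pmq_region"])
        cs, nk = pseudo_r2(result)
        assert 0 < cs <= nk < 1

    def test_pseudo_r2_matches_brute_force_likelihood_on_toy_table(self, toy_pp):
        result = fit(toy_pp, covariates=["gender"], max_time=3)

        def neg_ll(beta, X, y):
            mu = expit(X @ beta)
            return -np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu))

        X_full = np.column_stack(
            [
                *[(toy_pp["time"] == t).to_numpy(float) for t in (1, 2, 3)],
                (toy_pp["gender"] == "female").to_numpy(float),
            ]
        )
        y = toy_pp["event"].to_numpy(float)
        full = minimize(neg_ll, np.zeros(4), args=(X_full, y), method="BFGS")
        null = minimize(neg_ll, np.zeros(3), args=(X_full[:, :3], y), method="BFGS")
        n = len(toy_pp)
        cs_expected = 1 - np.exp(-(2 * null.fun - 2 * full.fun) / n)
        nk_expected = cs_expected / (1 - np.exp(-2 * null.fun / n))
        cs, nk = pseudo_r2(result)
        assert np.isclose(cs, cs_expected, atol=1e-6)
        assert np.isclose(nk, nk_expected, atol=1e-6)
        assert np.isclose(result.minus2LL, 2 * full.fun, atol=1e-8)


class TestInteractionRule:
    def test_no_improvement_and_nonsignificant_excluded(self):
        assert interaction_rule(p_value=0.850, delta_minus2LL=0.0) is False

    def test_threshold_is_inclusive(self):
        assert interaction_rule(p_value=0.850, delta_minus2LL=4.0) is True
        assert interaction_rule(p_value=0.850, delta_minus2LL=3.999) is False

    def test_significance_alone_suffices(self):
        assert interaction_rule(p_value=0.01, delta_minus2LL=0.0) is True

    def test_decision_from_fits_excludes_null_interaction(self, pp):
        without = fit(pp, covariates=["gender", "pmq_region"])
        with_int = fit(
            pp,
            covariates=["gender", "pmq_region"],
            interactions=[("gender", "pmq_region")],
        )
        decision = interaction_decision(with_int, without)
        # generator has no gender x pmq interaction: should usually exclude
        assert decision.delta_minus2LL >= 0
        assert "Wald p" in decision.rationale

    def test_strong_simulated_interaction_included(self):
        # simulate person-periods directly with a true gender x PMQ
        # interaction of log-odds 1.0 on the non-progression hazard
        rng = np.random.default_rng(99)
        n = 20000
        female = rng.random(n) < 0.5
        non_uk = rng.random(n) < 0.5
        haz = expit(-1.5 + 0.2 * female + 0.3 * non_uk + 1.0 * (female & non_uk))
        u = rng.random((n, 5))
        failed = u < haz[:, None]
        t_event = np.where(failed.any(1), failed.argmax(1) + 1, 6)
        n_rows = np.minimum(t_event, 5)
        pidx = np.repeat(np.arange(n), n_rows)
        t = np.concatenate([np.arange(1, k + 1) for k in n_rows])
        pp = pd.DataFrame(
            {
                "person_id": pidx.astype(str),
                "time": t,
                "event": (t == t_event[pidx]).astype(int),
                "gender": np.where(female[pidx], "female", "male"),
                "pmq_region": np.where(non_uk[pidx], "non-UK", "UK"),
            }
        )
        pp["entry_year"] = 2012
        without = fit(pp, covariates=["gender", "pmq_region"])
        with_int = fit(
            pp,
            covariates=["gender", "pmq_region"],
            interactions=[("gender", "pmq_region")],
        )
        decision = interaction_decision(with_int, without)
        assert decision.include
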