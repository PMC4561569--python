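"""GLMM machinery: standardization, Laplace ML fits (nesting to plain
GLMs, parameter recovery), AICc, candidate-set enumeration and model
averaging against hand-computed oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from floaterqg.glmm import (
    FitResult,
    ModelSpec,
    aicc,
    average_fits,
    ars_candidate_terms,
    behaviour_candidate_terms,
    build_candidate_set,
    design_matrix,
    fit_glmm,
    model_average,
    standardize,
)
from floaterqg.simulate import (
    SimulationConfig,
    behaviour_recovery_config,
    simulate_dataset,
)


@pytest.fixture(scope="module")
def recovery_table():
    _, df = simulate_dataset(behaviour_recovery_config(3))
    out, scaling = standardize(df)
    return out, scaling


class TestStandardize:
    def test_symmetric_triple_maps_to_unit_steps(self):
        df = pd.DataFrame({"age": [1, 2, 3], "status": ["floater"] * 3,
                           "male_id": list("abc"), "year": [1, 1, 1]})
        out, _ = standardize(df, predictors=("age",))
        assert np.allclose(out["age_s"], [-1.0, 0.0, 1.0])

    def test_idempotent_on_standardized_column(self, rng):
        x = rng.normal(3, 2, 100)
        df = pd.DataFrame({"age": x})
        once, _ = standardize(df, predictors=("age",))
        twice, _ = standardize(pd.DataFrame({"age": once["age_s"]}), predictors=("age",))
        assert np.abs(twice["age_s"].to_numpy() - once["age_s"].to_numpy()).max() < 1e-12

    def test_posthoc_mean_zero_variance_one(self, rng):
        df = pd.DataFrame({"age": rng.integers(1, 9, 200).astype(float),
                           "f": rng.random(200), "tarsus": rng.normal(20, 1, 200)})
        out, _ = standardize(df)
        for col in ("age_s", "age2_s", "f_s", "tarsus_s"):
            assert abs(out[col].mean()) < 1e-10
            assert abs(out[col].var(ddof=1) - 1.0) < 1e-10

    def test_constant_predictor_error_names_column(self):
        df = pd.DataFrame({"age": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError, match="age"):
            standardize(df, predictors=("age",))

    def test_scaling_metadata_reproduces_linear_predictor(self, recovery_table):
        """Back-transforming standardized coefficients onto the raw scale
        reproduces the fitted linear predictor exactly."""
        df, scaling = recovery_table
        spec = ModelSpec("status", ("age", "age2"))
        fr = fit_glmm(spec, df, forced_varcomps={"year": 0.0, "individual": 0.0})
        X, names = design_matrix(spec, df)
        eta_std = X @ np.array([fr.beta[n] for n in names])
        m1, s1 = scaling["age"]
        m2, s2 = scaling["age2"]
        age = df["age"].to_numpy(dtype=float)
        z = (age - m1) / s1
        eta_raw = fr.beta["intercept"] + fr.beta["age"] * z + fr.beta["age2"] * (z**2 - m2) / s2
        assert np.abs(eta_std - eta_raw).max() < 1e-6


class TestAicc:
    def test_formula_arithmetic(self):
        assert aicc(-100.0, 3, 100) == pytest.approx(206.25)

    def test_large_n_limit_is_aic(self):
        assert aicc(-100.0, 3, 10**9) == pytest.approx(206.0, abs=1e-6)

    def test_delta_invariant_to_loglik_translation(self):
        lls = [-100.0, -102.5, -98.0]
        ks = [3, 4, 5]
        a0 = [aicc(ll, k, 200) for ll, k in zip(lls, ks)]
        a1 = [aicc(ll + 7.3, k, 200) for ll, k in zip(lls, ks)]
        assert np.allclose(np.diff(a0), np.diff(a1))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)


class TestFitGlmm:
    def test_zero_variance_binomial_equals_plain_glm(self, recovery_table):
        import statsmodels.api as sm

        df, _ = recovery_table
        spec = ModelSpec("status", ("age", "age2", "f", "tarsus"))
        fr = fit_glmm(spec, df, forced_varcomps={"year": 0.0, "individual": 0.0})
        X, _ = design_matrix(spec, df)
        y = (df["status"] == "territorial").astype(float)
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.abs(np.array(list(fr.beta.values())) - glm.params).max() < 1e-6
        assert fr.loglik == pytest.approx(glm.llf, abs=1e-6)

    def test_zero_variance_poisson_equals_plain_glm(self, recovery_table):
        import statsmodels.api as sm

        df, _ = recovery_table
        spec = ModelSpec("ars", ("behaviour", "age", "age2"), family="poisson")
        fr = fit_glmm(spec, df, forced_varcomps={"year": 0.0, "individual": 0.0})
        X, _ = design_matrix(spec, df)
        glm = sm.GLM(df["ars"], X, family=sm.families.Poisson()).fit()
        assert np.abs(np.array(list(fr.beta.values())) - glm.params).max() < 1e-6
        assert fr.loglik == pytest.approx(glm.llf, abs=1e-6)

    def test_mixed_fit_dominates_glm_and_counts_parameters(self, recovery_table):
        df, _ = recovery_table
        spec = ModelSpec("status", ("age", "age2"))
        glm = fit_glmm(spec, df, forced_varcomps={"year": 0.0, "individual": 0.0})
        mix = fit_glmm(spec, df)
        assert mix.loglik >= glm.loglik - 1e-6
        assert mix.k == glm.k + 2  # two free variance parameters
        assert mix.aicc >= -2 * mix.loglik + 2 * mix.k  # AICc >= AIC

    def test_nested_model_never_has_higher_loglik(self, recovery_table):
        df, _ = recovery_table
        small = fit_glmm(ModelSpec("status", ("age", "age2")), df)
        big = fit_glmm(ModelSpec("status", ("age", "age2", "tarsus")), df)
        assert big.loglik >= small.loglik - 1e-4

    def test_poisson_behaviour_effect_recovered_across_seeds(self):
        """True territorial log-advantage 1.15 recovered within +-2 SE in
        >= 90% of seeds at the default study scale (~800 records)."""
        spec = ModelSpec("ars", ("behaviour", "age", "age2"), family="poisson")
        hits = 0
        n_seeds = 25
        for seed in range(1, n_seeds + 1):
            _, df = simulate_dataset(SimulationConfig(rng_seed=seed))
            tab, _ = standardize(df)
            fr = fit_glmm(spec, tab)
            hits += abs(fr.beta["behaviour"] - 1.15) <= 2 * fr.se["behaviour"]
        assert hits >= math.ceil(0.9 * n_seeds) - 1

    def test_binomial_age_curve_recovered_across_seeds(self):
        """True standardized age effects (2.3, -2.2) recovered within
        +-2 SE, with correct signs, in >= 90% of seeds at n ~ 360."""
        spec = ModelSpec("status", ("age", "age2", "f", "tarsus"))
        hits = 0
        n_seeds = 25
        for seed in range(1, n_seeds + 1):
            _, df = simulate_dataset(behaviour_recovery_config(seed))
            tab, _ = standardize(df)
            fr = fit_glmm(spec, tab)
            ok = (
                fr.beta["age"] > 0
                and fr.beta["age2"] < 0
                and abs(fr.beta["age"] - 2.3) <= 2 * fr.se["age"]
                and abs(fr.beta["age2"] + 2.2) <= 2 * fr.se["age2"]
            )
            hits += ok
        assert hits >= math.ceil(0.9 * n_seeds) - 1


class TestCandidateSet:
    def test_two_mains_give_powerset_of_four(self):
        specs = build_candidate_set("status", ("f", "tarsus"))
        assert len(specs) == 4

    def test_marginality_for_interactions_and_quadratics(self):
        specs = build_candidate_set("status", ("age", "age2", "f"),
                                    (("age2", "f"),))
        for s in specs:
            if ("age2", "f") in s.interactions:
                assert {"age2", "f"} <= set(s.terms)
            if "age2" in s.terms:
                assert "age" in s.terms
        with pytest.raises(ValueError):
            ModelSpec("status", ("age2",))
        with pytest.raises(ValueError):
            ModelSpec("status", ("age",), (("age", "f"),))

    def test_behaviour_set_matches_exhaustive_enumeration(self):
        terms, inters = behaviour_candidate_terms()
        specs = build_candidate_set("status", terms, inters)
        # independent brute-force enumeration over term/interaction masks
        count = 0
        for mains in itertools.chain.from_iterable(
            itertools.combinations(terms, r) for r in range(len(terms) + 1)
        ):
            if "age2" in mains and "age" not in mains:
                continue
            legal = [ix for ix in inters if set(ix) <= set(mains)]
            count += 2 ** len(legal)
        assert len(specs) == count == 23
        assert len({s.label for s in specs}) == len(specs)

    def test_ars_set_includes_behaviour_interactions(self):
        terms, inters = ars_candidate_terms()
        specs = build_candidate_set("ars", terms, inters, family="poisson")
        assert any(("behaviour", "age") in s.interactions for s in specs)


def _toy_fit(label_terms, loglik, k, n=200, beta=None, se=None):
    spec = ModelSpec("status", tuple(label_terms))
    names = ("intercept",) + spec.all_terms()
    beta = beta or {t: 1.0 for t in names}
    se = se or {t: 0.5 for t in names}
    return FitResult(spec=spec, beta=beta, se=se, varcomps={}, loglik=loglik,
                     k=k, n=n, aicc=aicc(loglik, k, n), converged=True,
                     grad_norm=0.0)


class TestModelAveraging:
    def test_single_model_in_set_is_returned_unchanged(self):
        f1 = _toy_fit(("age",), -100.0, 3, beta={"intercept": 0.2, "age": 1.4},
                      se={"intercept": 0.1, "age": 0.3})
        f2 = _toy_fit((), -110.0, 2, beta={"intercept": 0.4}, se={"intercept": 0.1})
        avg = average_fits([f1, f2])
        assert len(avg.confidence_set) == 1
        assert avg.averaged_beta["age"] == 1.4
        assert avg.relative_importance["age"] == 1.0

    def test_equal_aicc_gives_half_half_weights(self):
        f1 = _toy_fit(("age",), -100.0, 3)
        f2 = _toy_fit(("f",), -100.0, 3)
        avg = average_fits([f1, f2])
        assert np.allclose(list(avg.weights.values()), [0.5, 0.5])

    def test_three_model_hand_computed_average(self):
        """Conditional averaging against a spreadsheet-style hand calculation."""
        n = 200
        f1 = _toy_fit(("age",), -100.0, 3, beta={"intercept": 0.0, "age": 2.0},
                      se={"intercept": 0.1, "age": 0.4})
        f2 = _toy_fit(("age", "f"), -99.6, 4,
                      beta={"intercept": 0.0, "age": 1.6, "f": -0.5},
                      se={"intercept": 0.1, "age": 0.5, "f": 0.2})
        f3 = _toy_fit(("f",), -104.0, 3, beta={"intercept": 0.0, "f": -0.9},
                      se={"intercept": 0.1, "f": 0.3})  # outside delta < 2
        a = [aicc(-100.0, 3, n), aicc(-99.6, 4, n), aicc(-104.0, 3, n)]
        d = np.array(a) - min(a)
        assert d[2] >= 2.0  # hand-check: third model excluded
        w = np.exp(-0.5 * d[:2]); w /= w.sum()
        avg = average_fits([f1, f2, f3])
        assert avg.averaged_beta["age"] == pytest.approx(w[0] * 2.0 + w[1] * 1.6)
        assert avg.averaged_beta["f"] == pytest.approx(-0.5)  # only model 2 has f
        assert avg.relative_importance["f"] == pytest.approx(w[1])
        assert avg.relative_importance["age"] == pytest.approx(1.0)
        # weighted unconditional SE for age, Burnham-Anderson style
        b_bar = w[0] * 2.0 + w[1] * 1.6
        se_u = w[0] * math.sqrt(0.4**2 + (2.0 - b_bar) ** 2) + w[1] * math.sqrt(
            0.5**2 + (1.6 - b_bar) ** 2
        )
        assert avg.ci_high["age"] - avg.averaged_beta["age"] == pytest.approx(
            1.959963984540054 * se_u
        )

    def test_weights_sum_to_one_and_order_invariance(self):
        fits = [_toy_fit(("age",), -100.0, 3), _toy_fit(("f",), -100.4, 3),
                _toy_fit(("tarsus",), -100.9, 3)]
        avg = average_fits(fits)
        assert sum(avg.weights.values()) == pytest.approx(1.0)
        rev = average_fits(fits[::-1])
        for t in avg.averaged_beta:
            assert rev.averaged_beta[t] == pytest.approx(avg.averaged_beta[t], abs=1e-12)
            assert rev.relative_importance[t] == pytest.approx(
                avg.relative_importance[t], abs=1e-12
            )

    def test_full_averaging_shrinks_toward_zero(self):
        f1 = _toy_fit(("age",), -100.0, 3, beta={"intercept": 0.0, "age": 2.0},
                      se={"intercept": 0.1, "age": 0.4})
        f2 = _toy_fit((), -100.9, 2, beta={"intercept": 0.0}, se={"intercept": 0.1})
        cond = average_fits([f1, f2], method="conditional")
        full = average_fits([f1, f2], method="full")
        assert len(cond.confidence_set) == 2
        w_age = cond.weights[f1.spec.label]
        assert cond.averaged_beta["age"] == pytest.approx(2.0)  # only f1 has age
        assert full.averaged_beta["age"] == pytest.approx(w_age * 2.0)

    def test_empty_candidate_set_rejected(self):
        with pytest.raises(ValueError):
            average_fits([])

    def test_end_to_end_averaging_on_complete_cases(self, default_dataset):
        """Rows lacking f are dropped before every fit so AICc is comparable;
        the averaged table mirrors the published layout."""
        _, df = default_dataset
        specs = build_candidate_set("status", ("age", "age2", "f"))
        avg = model_average(specs, df)
        n_complete = df.dropna(subset=["f"]).shape[0]
        assert all(f.n == n_complete for f in avg.confidence_set)
        assert {"model", "k", "AICc", "delta_AICc", "weight"} <= set(avg.table.columns)
        assert avg.table["delta_AICc"].iloc[0] == 0.0
        assert sum(avg.weights.values()) == pytest.approx(1.0)
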