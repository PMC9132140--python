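import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from intelligrowth import (
    LengthImputer,
    LengthWeightModel,
    LengthWeights,
    SimulationConfig,
    composite_for_cohort,
    fit_imputation_models,
    fit_length_probability,
    impute_profile,
    length_weights,
    multiword_composite,
    simulate_cohort,
)

from conftest import MULTIWORD_COLS


def chain_cohort(n=120, rho=0.9, seed=0, noise=0.0):
    """Cohort with the planted logit-scale relation
    logit(score_L) = rho * logit(score_{L-1}); optionally noiseless."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(-1.0, 2.0, n)
    df = pd.DataFrame({
        "child_id": np.arange(n),
        "age_months": rng.integers(30, 120, n),
        "longest_length": 7,
    })
    eta = base.copy()
    df["score_len1"] = expit(eta)
    for L in range(2, 8):
        eta = rho * eta + noise * rng.normal(size=n)
        df[f"score_len{L}"] = expit(eta)
    return df


class TestImputer:
    def test_noiseless_chain_matches_closed_form(self):
        """With a deterministic logit-linear relation planted, the carried-
        forward imputation chain reproduces the closed-form extension."""
        train = chain_cohort(n=150, seed=1)
        imputer = fit_imputation_models(train)
        target = chain_cohort(n=40, seed=2)
        truncated = target.copy()
        truncated["longest_length"] = 5
        truncated[["score_len6", "score_len7"]] = np.nan
        filled = imputer.transform(truncated)
        np.testing.assert_allclose(filled["score_len6"], target["score_len6"], atol=1e-6)
        np.testing.assert_allclose(filled["score_len7"], target["score_len7"], atol=1e-6)

    def test_carried_forward_prediction_order(self):
        """Length 6 is predicted from observed 1-5 plus the ceiling; length 7
        then uses the freshly imputed length-6 value as a predictor."""
        train = chain_cohort(n=150, seed=1)
        imputer = fit_imputation_models(train)
        profile = chain_cohort(n=1, seed=5).iloc[0].copy()
        profile["longest_length"] = 5
        profile[["score_len6", "score_len7"]] = np.nan
        filled = impute_profile(profile, imputer)
        m6, m7 = imputer.models_[6], imputer.models_[7]
        x6 = np.r_[1.0, [logit(profile[f"score_len{l}"]) for l in range(1, 6)], 5.0]
        pred6 = expit(x6 @ m6["coef"])
        assert filled["score_len6"] == pytest.approx(pred6, abs=1e-12)
        x7 = np.r_[1.0, [logit(profile[f"score_len{l}"]) for l in range(1, 6)], logit(pred6), 5.0]
        assert filled["score_len7"] == pytest.approx(expit(x7 @ m7["coef"]), abs=1e-12)

    def test_idempotent_and_observed_untouched(self):
        cohort = chain_cohort(n=60, seed=3, noise=0.1)
        imputer = fit_imputation_models(cohort)
        once = imputer.transform(cohort)
        pd.testing.assert_frame_equal(once, cohort)  # complete profile: no-op
        partial = cohort.copy()
        partial.loc[:9, "longest_length"] = 4
        partial.loc[:9, ["score_len5", "score_len6", "score_len7"]] = np.nan
        filled = imputer.transform(partial)
        again = imputer.transform(filled)
        pd.testing.assert_frame_equal(filled, again)
        observed_cols = ["score_len1", "score_len2", "score_len3", "score_len4"]
        pd.testing.assert_frame_equal(filled[observed_cols], cohort[observed_cols])

    def test_insufficient_training_data_flags_model_unavailable(self):
        cohort = chain_cohort(n=30, seed=4, noise=0.05)
        cohort.loc[cohort.index[:25], "longest_length"] = 6
        cohort.loc[cohort.index[:25], "score_len7"] = np.nan
        with pytest.warns(UserWarning, match="length-7"):
            imputer = fit_imputation_models(cohort)
        assert imputer.models_[7] is None
        with pytest.raises(RuntimeError, match="length 7"):
            imputer.transform(cohort)

    def test_out_of_sample_beats_mean_predictor(self):
        """Cross-validated RMSE of the length-6 model is below the marginal
        SD of length-6 scores on the default synthetic cohort."""
        cohort = simulate_cohort(SimulationConfig(n_children=538, seed=9))
        obs6 = cohort[cohort["score_len6"].notna()]
        half = len(obs6) // 2
        train, test = obs6.iloc[:half], obs6.iloc[half:]
        imputer = fit_imputation_models(train)
        holdout = test.copy()
        holdout["score_len6"] = np.nan
        holdout["score_len7"] = np.nan
        pred = imputer.transform(holdout)["score_len6"]
        rmse = np.sqrt(np.mean((pred - test["score_len6"]) ** 2))
        assert rmse < test["score_len6"].std(ddof=1)


class TestLengthProbability:
    def test_all_reach_seven_gives_probability_near_one(self):
        rng = np.random.default_rng(0)
        ages = rng.integers(30, 120, 200)
        model = LengthWeightModel().fit(ages, np.full(200, 7))
        probs = model.predict_proba([35.0, 70.0, 110.0])
        assert (probs.to_numpy() > 0.99).all()

    def test_recovers_configured_ceiling(self, default_cohort):
        children, _ = default_cohort
        model = fit_length_probability(children)
        assert model.predict_proba([30.0])[7].iloc[0] < 0.1
        assert model.predict_proba([100.0])[7].iloc[0] > 0.9

    @pytest.mark.parametrize("method", ["logistic", "empirical", "ordinal"])
    def test_nesting_after_isotonization(self, default_cohort, method):
        children, _ = default_cohort
        model = LengthWeightModel(method=method).fit(
            children["age_months"].to_numpy(float), children["longest_length"].to_numpy(int))
        P = model.predict_proba(np.arange(30.0, 120.0)).to_numpy()
        assert (np.diff(P, axis=1) <= 1e-12).all()

    def test_too_few_distinct_ages_rejected(self):
        with pytest.raises(ValueError, match="distinct ages"):
            LengthWeightModel().fit([40.0, 40.0, 40.0], [3, 4, 5])


class TestWeights:
    def test_weights_sum_to_one(self, default_cohort):
        children, _ = default_cohort
        model = fit_length_probability(children)
        for age in (30.0, 47.0, 60.0, 119.0):
            w = length_weights(age, model)
            assert sum(w.weights.values()) == pytest.approx(1.0, abs=1e-12)

    def test_equal_weights_when_all_lengths_certain(self):
        model = LengthWeightModel().fit(
            np.linspace(30, 119, 100), np.full(100, 7))
        w = length_weights(60.0, model)
        for L in range(2, 8):
            assert w.weights[L] == pytest.approx(1.0 / 6.0, abs=1e-3)

    def test_long_utterances_downweighted_at_youngest_age(self, default_cohort):
        children, _ = default_cohort
        w = length_weights(30.0, fit_length_probability(children))
        assert w.weights[6] + w.weights[7] < 0.05

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            LengthWeights(age_months=40.0, weights={L: 0.5 for L in range(2, 8)})


class TestComposite:
    def make_weights(self, values):
        return LengthWeights(age_months=60.0, weights=dict(zip(range(2, 8), values)))

    def make_profile(self, scores):
        return pd.Series({"score_len1": 0.5, **{f"score_len{L}": s for L, s in zip(range(2, 8), scores)}})

    def test_equal_weights_constant_scores(self):
        w = self.make_weights([1 / 6] * 6)
        assert multiword_composite(self.make_profile([0.6] * 6), w) == pytest.approx(0.6)

    def test_one_hot_weight(self):
        w = self.make_weights([0, 0, 1.0, 0, 0, 0])
        assert multiword_composite(self.make_profile([0.5, 0.6, 0.72, 0.8, 0.9, 1.0]), w) == pytest.approx(0.72)

    def test_direct_arithmetic(self):
        w = self.make_weights([0.3, 0.3, 0.2, 0.1, 0.05, 0.05])
        prof = self.make_profile([0.5, 0.6, 0.7, 0.8, 0.9, 1.0])
        assert multiword_composite(prof, w) == pytest.approx(0.645)

    def test_incomplete_profile_rejected(self):
        prof = self.make_profile([0.5, 0.6, np.nan, 0.8, 0.9, 1.0])
        with pytest.raises(ValueError, match="complete"):
            multiword_composite(prof, self.make_weights([1 / 6] * 6))

    def test_monotone_in_each_length(self):
        w = self.make_weights([0.3, 0.3, 0.2, 0.1, 0.05, 0.05])
        base = [0.5, 0.6, 0.7, 0.8, 0.9, 0.95]
        c0 = multiword_composite(self.make_profile(base), w)
        for j in range(6):
            bumped = list(base)
            bumped[j] += 0.04
            assert multiword_composite(self.make_profile(bumped), w) >= c0

    def test_no_ceiling_composite_identical_with_or_without_imputation(self, noceiling_cohort):
        model = fit_length_probability(noceiling_cohort)
        direct = composite_for_cohort(noceiling_cohort, model)
        imputed = fit_imputation_models(noceiling_cohort).transform(noceiling_cohort)
        via_imputation = composite_for_cohort(imputed, model)
        np.testing.assert_allclose(direct.to_numpy(), via_imputation.to_numpy())
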