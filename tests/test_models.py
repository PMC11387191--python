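import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from rtquant.design import ModelSpec, Term, factorial_term, main_term
from rtquant.features import features_table
from rtquant.models import (
    ReadthroughModel,
    added_position_scan,
    coefficient_stats,
    cross_validate,
    explainable_variance,
    multistop_correlation,
    pooled_r2,
)
from rtquant.simulate import simulate_library

SMALL_SPEC = ModelSpec(
    "drug_f4", (main_term("stop_type"), main_term("down_1"))
)


def small_features(n, seed=0):
    contexts = simulate_library(n, seed=seed)
    return features_table(contexts, include_controls=False)


class TestFit:
    def test_constant_response_gives_null_coefficients(self):
        feats = small_features(600)
        rtp = np.full(len(feats), 50.0)
        res = ReadthroughModel(rtp, feats, spec=SMALL_SPEC).fit()
        assert res.params["Intercept"] == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(res.params.drop("Intercept"), 0.0, atol=1e-8)

    def test_needs_more_rows_than_columns(self):
        feats = small_features(100)
        with pytest.raises(ValueError, match="exceed"):
            ReadthroughModel(
                np.full(100, 10.0), feats, spec=ModelSpec.drug_f4()
            ).fit()

    def test_training_r2_is_one_on_exact_data(self, truth_5000):
        feats, rtp, _ = truth_5000
        res = ReadthroughModel(rtp, feats).fit()
        assert res.rsquared == pytest.approx(1.0, abs=1e-6)

    def test_summary_mentions_terms_and_fit(self, truth_5000):
        feats, rtp, _ = truth_5000
        res = ReadthroughModel(
            rtp.head(1000), feats.head(1000), spec=SMALL_SPEC,
            condition="drugA",
        ).fit()
        text = res.summary()
        assert "drugA" in text and "stop_type" in text
        assert "training r2" in text


class TestPredict:
    def test_reference_row_is_intercept_only(self):
        feats = small_features(600)
        rtp = 100.0 * expit(
            -2.0 + 0.8 * (feats["down_1"] == "C").to_numpy()
        )
        res = ReadthroughModel(rtp, feats, spec=SMALL_SPEC).fit()
        ref = pd.DataFrame({"stop_type": ["UAA"], "down_1": ["A"]})
        expected = 100.0 * expit(res.params["Intercept"])
        assert res.predict(ref)[0] == pytest.approx(expected)

    def test_matches_dot_product_oracle(self, truth_5000):
        feats, rtp, _ = truth_5000
        res = ReadthroughModel(
            rtp.head(1500), feats.head(1500), spec=SMALL_SPEC
        ).fit()
        X = res.builder.transform(feats.iloc[2000:2100], allow_unseen=True)
        oracle = 100.0 * expit(X.to_numpy() @ res.params.to_numpy())
        assert np.allclose(res.predict(feats.iloc[2000:2100]), oracle)

    def test_monotone_in_single_indicator(self):
        feats = small_features(600)
        rtp = 100.0 * expit(
            -2.0 + 0.8 * (feats["down_1"] == "C").to_numpy()
        )
        res = ReadthroughModel(rtp, feats, spec=SMALL_SPEC).fit()
        lo = pd.DataFrame({"stop_type": ["UAA"], "down_1": ["A"]})
        hi = pd.DataFrame({"stop_type": ["UAA"], "down_1": ["C"]})
        assert res.predict(hi)[0] > res.predict(lo)[0]


class TestCrossValidation:
    def test_deterministic_given_seed(self):
        feats = small_features(500, seed=3)
        rng = np.random.default_rng(0)
        rtp = 100.0 * expit(rng.normal(-3, 0.5, len(feats)))
        model = ReadthroughModel(rtp, feats, spec=SMALL_SPEC)
        cv1 = cross_validate(model, seed=7)
        cv2 = cross_validate(model, seed=7)
        assert cv1.pooled_r2 == cv2.pooled_r2
        assert all(
            np.array_equal(a, b) for a, b in zip(cv1.folds, cv2.folds)
        )

    def test_default_ten_percent_folds_are_disjoint(self):
        feats = small_features(500, seed=3)
        model = ReadthroughModel(
            np.linspace(1, 60, len(feats)), feats, spec=SMALL_SPEC
        )
        cv = cross_validate(model, seed=7)
        all_idx = np.concatenate(cv.folds)
        assert len(all_idx) == len(set(all_idx))
        assert all(len(f) == 50 for f in cv.folds)

    def test_exact_response_recovers_r2_one(self, truth_5000):
        feats, rtp, _ = truth_5000
        model = ReadthroughModel(
            rtp.head(1200), feats.head(1200), spec=SMALL_SPEC
        )
        # response regenerated exactly from the small spec itself
        res = model.fit()
        exact = res.predict(feats.head(1200))
        cv = cross_validate(
            ReadthroughModel(exact, feats.head(1200), spec=SMALL_SPEC),
            seed=1,
        )
        assert cv.pooled_r2 >= 0.99

    def test_permuted_labels_have_no_signal(self, truth_5000):
        feats, rtp, _ = truth_5000
        rng = np.random.default_rng(13)
        shuffled = pd.Series(
            rng.permutation(rtp.to_numpy()), index=rtp.index
        )
        cv = cross_validate(
            ReadthroughModel(shuffled, feats), seed=13
        )
        assert cv.pooled_r2 <= 0.02


class TestNestedModels:
    def test_training_r2_non_decreasing_with_down_positions(self, truth_5000):
        feats, rtp, _ = truth_5000
        feats, rtp = feats.head(1500), rtp.head(1500)
        r2 = [
            ReadthroughModel(rtp, feats, spec=ModelSpec.drug_f5(k))
            .fit()
            .rsquared
            for k in (3, 4, 5)
        ]
        assert r2[0] <= r2[1] + 1e-9 <= r2[2] + 2e-9


class TestPanDrugEquivalence:
    def test_pan_model_matches_per_drug_fits(self):
        base = ModelSpec.simplified_no_stopdown()
        pan_terms = list(base.terms) + [main_term("drug")]
        pan_terms += [
            t.crossed_with("drug", f"drug_x_{t.name}") for t in base.terms
        ]
        pan_spec = ModelSpec("pan_f6", tuple(pan_terms))
        rng = np.random.default_rng(5)
        frames = []
        per_drug_pred = {}
        for i, drug in enumerate(("dapA", "driB")):
            feats = small_features(2000, seed=10 + i)
            feats = feats.set_index(
                pd.Index([f"{drug}_{v}" for v in feats.index])
            )
            rtp = 100.0 * expit(
                rng.normal(-3 - 0.3 * i, 0.4, len(feats))
                + 0.7 * (feats["down_1"] == "C").to_numpy()
            )
            res = ReadthroughModel(rtp, feats, spec=base).fit()
            per_drug_pred[drug] = res.predict(feats)
            feats = feats.assign(drug=drug)
            frames.append(feats.assign(rtp=rtp))
        stacked = pd.concat(frames)
        pan = ReadthroughModel.from_dataframe(stacked, spec=pan_spec).fit()
        for drug in per_drug_pred:
            sub = stacked[stacked["drug"] == drug]
            np.testing.assert_allclose(
                pan.predict(sub),
                per_drug_pred[drug],
                atol=0.05,
            )


class TestAblation:
    def test_sole_informative_term_drop_is_one(self):
        feats = small_features(800, seed=2)
        rtp = 100.0 * expit(
            -3.0 + 1.2 * (feats["stop_type"] == "UGA").to_numpy()
        )
        spec = ModelSpec(
            "drug_f4",
            (main_term("stop_type"), factorial_term("up_1", ("up_1",))),
        )
        model = ReadthroughModel(rtp, feats, spec=spec)
        from rtquant.models import ablation

        drops = ablation(model, seed=4)
        assert drops.loc["stop_type", "normalized_drop"] == pytest.approx(
            1.0, abs=0.05
        )
        assert abs(drops.loc["up_1", "normalized_drop"]) < 0.02

    def test_invariant_to_row_order(self):
        feats = small_features(500, seed=6)
        rtp = pd.Series(
            100.0
            * expit(-3.0 + 0.9 * (feats["down_1"] == "C").to_numpy()),
            index=feats.index,
        )
        spec = ModelSpec(
            "drug_f4", (main_term("stop_type"), main_term("down_1"))
        )
        from rtquant.models import ablation

        drops = ablation(ReadthroughModel(rtp, feats, spec=spec), seed=9)
        perm = np.random.default_rng(0).permutation(len(feats))
        shuffled = feats.iloc[perm]
        drops_shuffled = ablation(
            ReadthroughModel(rtp.iloc[perm], shuffled, spec=spec), seed=9
        )
        pd.testing.assert_frame_equal(drops, drops_shuffled)


class TestAddedPositionScan:
    def test_only_informative_position_is_significant(self):
        feats = small_features(1500, seed=8)
        rtp = 100.0 * expit(
            -3.0 + 1.5 * (feats["down_1"] == "C").to_numpy()
        )
        scan = added_position_scan(rtp, feats, n_rounds=20, seed=5)
        assert scan.loc[1, "p_adj"] < 0.01
        assert (scan.loc[2:, "p_adj"] > 0.05).all()
        assert scan.loc[1, "delta_mean_r2"] > 0.5

    def test_identical_models_reported_non_significant(self):
        from rtquant.models import _paired_onesided_t

        r2 = np.array([0.5, 0.6, 0.7, 0.8])
        tstat, pval = _paired_onesided_t(r2, r2.copy())
        assert (tstat, pval) == (0.0, 1.0)

    def test_constant_response_has_no_valid_folds(self):
        feats = small_features(300, seed=9)
        with pytest.raises(ValueError, match="skipped"):
            added_position_scan(
                np.full(len(feats), 25.0), feats, positions=(1,),
                n_rounds=5, seed=2,
            )


class TestCoefficientStats:
    def test_all_zero_folds_not_significant(self):
        coefs = pd.DataFrame(np.zeros((5, 2)), columns=["a", "b"])
        stats_table = coefficient_stats(coefs)
        assert (stats_table["p"] == 1.0).all()
        assert stats_table["degenerate"].all()

    def test_constant_nonzero_folds_flagged_degenerate(self):
        coefs = pd.DataFrame({"a": [1.0] * 5, "b": [0.0, 1, -1, 0.5, -0.5]})
        stats_table = coefficient_stats(coefs)
        assert stats_table.loc["a", "degenerate"]
        assert stats_table.loc["a", "sd"] == 0.0
        assert stats_table.loc["a", "p"] == np.finfo(float).tiny

    def test_bh_adjustment_matches_stepup_oracle(self, rng):
        coefs = pd.DataFrame(
            rng.normal(0, 1, size=(6, 8)),
            columns=[f"c{i}" for i in range(8)],
        )
        table = coefficient_stats(coefs)
        p = table["p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        stepup = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            running = min(running, p[order[rank]] * m / (rank + 1))
            stepup[order[rank]] = running
        np.testing.assert_allclose(table["p_adj"].to_numpy(), stepup)

    def test_requires_three_folds(self):
        with pytest.raises(ValueError):
            coefficient_stats(pd.DataFrame({"a": [1.0, 2.0]}))


class TestExplainableVariance:
    def test_identical_replicates_ceiling_one(self):
        rep = pd.Series(np.linspace(0, 10, 200))
        max_r2, fraction = explainable_variance(rep, rep, model_r2=0.8)
        assert max_r2 == pytest.approx(1.0)
        assert fraction == pytest.approx(0.8)

    def test_model_at_ceiling_explains_everything(self, rng):
        signal = rng.uniform(0, 10, 500)
        rep1 = pd.Series(signal + rng.normal(0, 1, 500))
        rep2 = pd.Series(signal + rng.normal(0, 1, 500))
        max_r2, _ = explainable_variance(rep1, rep2, model_r2=0.0)
        _, fraction = explainable_variance(rep1, rep2, model_r2=max_r2)
        assert fraction == pytest.approx(1.0)

    def test_replicate_correlation_matches_reliability_form(self, rng):
        n = 20_000
        signal = rng.uniform(0, 10, n)
        sigma = 1.5
        rep1 = pd.Series(signal + rng.normal(0, sigma, n))
        rep2 = pd.Series(signal + rng.normal(0, sigma, n))
        max_r2, _ = explainable_variance(rep1, rep2, model_r2=0.5)
        reliability = signal.var() / (signal.var() + sigma**2)
        assert np.sqrt(max_r2) == pytest.approx(reliability, abs=0.03)


class TestMultistop:
    def _table(self, a, b):
        n = len(a)
        return pd.DataFrame(
            {
                "position": list(range(n)) * 2,
                "stop_type": ["UAA"] * n + ["UGA"] * n,
                "rtp": np.concatenate([a, b]),
            }
        )

    def test_identical_vectors(self):
        a = np.linspace(1, 5, 30)
        result = multistop_correlation(self._table(a, a))
        assert result.loc[0, "pearson_r"] == pytest.approx(1.0)
        assert result.loc[0, "median_ratio"] == pytest.approx(1.0)

    def test_doubled_vector(self):
        a = np.linspace(1, 5, 30)
        result = multistop_correlation(self._table(2 * a, a))
        assert result.loc[0, "pearson_r"] == pytest.approx(1.0)
        assert result.loc[0, "median_ratio"] == pytest.approx(2.0)

    def test_independent_vectors_near_zero(self, rng):
        a = rng.uniform(0, 5, 200)
        b = rng.uniform(0, 5, 200)
        result = multistop_correlation(self._table(a, b))
        assert abs(result.loc[0, "pearson_r"]) < 0.2

    def test_small_pairs_omitted(self):
        a = np.array([1.0, 2.0])
        result = multistop_correlation(self._table(a, a))
        assert result.empty


def test_pooled_r2_degenerate_inputs():
    assert pooled_r2([1, 1, 1], [1, 2, 3]) == 0.0
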