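"""Training machinery: folds, oversampling, the network, CV strategies."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from ckdfair import (
    FittedModel,
    GeneratorConfig,
    MlpConfig,
    generate_cohort,
    make_cv_folds,
    oversample_duplicate,
    predict_risk,
    run_biomarker_variant,
    run_strategy,
    train_mlp,
)
from ckdfair.fairness_eval import auc


class TestMakeCvFolds:
    def test_partition_and_determinism(self, small_cohort):
        folds = make_cv_folds(small_cohort, k=5, seed=42)
        assert len(folds) == len(small_cohort)
        assert set(np.unique(folds)) == set(range(5))
        assert np.array_equal(folds, make_cv_folds(small_cohort, k=5, seed=42))
        assert not np.array_equal(folds, make_cv_folds(small_cohort, k=5, seed=43))

    def test_race_composition_comparable_across_folds(self, small_cohort):
        folds = make_cv_folds(small_cohort, k=5, seed=42)
        black = small_cohort["race"].to_numpy() == "Black"
        for f in range(5):
            n_black = int(black[folds == f].sum())
            expected = black.sum() / 5
            assert abs(n_black - expected) <= 1

    def test_outcome_stratified(self, small_cohort):
        folds = make_cv_folds(small_cohort, k=5, seed=0)
        y = small_cohort["progression"].to_numpy()
        rates = [y[folds == f].mean() for f in range(5)]
        assert max(rates) - min(rates) < 0.03

    def test_small_stratum_raises(self):
        cohort = pd.DataFrame({
            "race": ["Black"] * 3 + ["White"] * 50,
            "progression": [1, 1, 1] + [0, 1] * 25,
        })
        with pytest.raises(ValueError, match="stratum"):
            make_cv_folds(cohort, k=5, seed=0)


class TestOversampleDuplicate:
    def test_counts_with_factor_two(self):
        idx = np.arange(100)
        labels = np.array([1] * 10 + [0] * 90)
        out = oversample_duplicate(idx, labels, 2)
        assert len(out) == 110
        counts = pd.Series(out).value_counts()
        assert (counts[idx[:10]] == 2).all()
        assert (counts[idx[10:]] == 1).all()

    def test_factor_one_is_identity(self):
        idx = np.array([5, 7, 9])
        assert np.array_equal(
            oversample_duplicate(idx, np.array([1, 0, 0]), 1), idx
        )

    def test_expanded_prevalence(self):
        idx = np.arange(100)
        labels = np.array([1] * 10 + [0] * 90)
        out = oversample_duplicate(idx, labels, 2)
        prevalence = labels[out].mean()
        assert prevalence == pytest.approx(20 / 110)  # 2p/(1+p) with p=0.1

    def test_no_minority_raises(self):
        with pytest.raises(ValueError, match="minority"):
            oversample_duplicate(np.arange(4), np.zeros(4, dtype=int), 2)


def _toy_problem(n=200, seed=0, separable=True):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 4))
    if separable:
        y = (X[:, 0] + X[:, 1] > 0).astype(float)
    else:
        y = rng.integers(0, 2, n).astype(float)
    return X, y


class TestTrainMlp:
    def test_same_seed_identical_weights_and_predictions(self):
        X, y = _toy_problem()
        cfg = dataclasses.replace(MlpConfig(), max_epochs=15,
                                  early_stopping_patience=5)
        m1 = train_mlp(X, y, cfg, seed=3)
        m2 = train_mlp(X, y, cfg, seed=3)
        for (w1, b1), (w2, b2) in zip(m1.weights, m2.weights):
            assert np.array_equal(w1, w2) and np.array_equal(b1, b2)
        assert np.array_equal(predict_risk(m1, X), predict_risk(m2, X))

    def test_separable_problem_learned(self):
        X, y = _toy_problem(n=200, separable=True)
        cfg = dataclasses.replace(
            MlpConfig(), class_weight=1.0, oversample_factor=1, max_epochs=80,
            early_stopping_patience=20,
        )
        model = train_mlp(X, y, cfg, seed=1)
        acc = ((predict_risk(model, X) >= 0.5) == y).mean()
        assert acc >= 0.97

    def test_single_class_raises(self):
        X, _ = _toy_problem()
        with pytest.raises(ValueError, match="single class"):
            train_mlp(X, np.ones(len(X)), MlpConfig(), seed=0)

    def test_missing_features_raise(self):
        X, y = _toy_problem()
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            train_mlp(X, y, MlpConfig(), seed=0)

    def test_class_weight_raises_mean_prediction(self):
        # With the positive class up-weighted and no prior correction, the
        # model predicts systematically higher risk than the unweighted fit.
        X, y = _toy_problem(n=400, seed=5, separable=True)
        base = dataclasses.replace(
            MlpConfig(), oversample_factor=1, prior_correction=False,
            max_epochs=25, early_stopping_patience=8,
        )
        weighted = train_mlp(X, y, dataclasses.replace(base, class_weight=3.0), seed=2)
        unweighted = train_mlp(X, y, dataclasses.replace(base, class_weight=1.0), seed=2)
        assert predict_risk(weighted, X).mean() > predict_risk(unweighted, X).mean()


class TestPredictRisk:
    def test_zero_weights_give_half(self):
        model = FittedModel(
            weights=[(np.zeros((3, 2)), np.zeros(2)), (np.zeros((2, 1)), np.zeros(1))],
            feature_names=["a", "b", "c"],
            prior_correction=False,
        )
        assert np.allclose(predict_risk(model, np.ones((5, 3))), 0.5)

    def test_batch_invariance(self):
        X, y = _toy_problem(n=120)
        cfg = dataclasses.replace(MlpConfig(), max_epochs=10,
                                  early_stopping_patience=3)
        model = train_mlp(X, y, cfg, seed=0)
        batch = predict_risk(model, X)
        rowwise = np.concatenate([predict_risk(model, X[i:i + 1]) for i in range(len(X))])
        # BLAS may reorder sums across batch shapes; agreement is to float
        # round-off, not bitwise
        assert np.allclose(batch, rowwise, rtol=0, atol=1e-10)

    def test_duplicated_rows_get_identical_outputs(self):
        X, y = _toy_problem(n=60)
        cfg = dataclasses.replace(MlpConfig(), max_epochs=10,
                                  early_stopping_patience=3)
        model = train_mlp(X, y, cfg, seed=0)
        doubled = np.vstack([X[:1], X[:1]])
        p = predict_risk(model, doubled)
        assert p[0] == p[1]

    def test_serialization_round_trip(self):
        X, y = _toy_problem(n=100)
        cfg = dataclasses.replace(MlpConfig(), max_epochs=10,
                                  early_stopping_patience=3)
        model = train_mlp(X, y, cfg, seed=0)
        clone = FittedModel.from_json(model.to_json())
        assert np.allclose(predict_risk(model, X), predict_risk(clone, X),
                           atol=1e-12)

    def test_schema_mismatch_raises(self):
        X, y = _toy_problem(n=60)
        cfg = dataclasses.replace(MlpConfig(), max_epochs=5,
                                  early_stopping_patience=2)
        model = train_mlp(pd.DataFrame(X, columns=list("abcd")), y, cfg, seed=0)
        with pytest.raises(ValueError, match="schema"):
            predict_risk(model, pd.DataFrame(X, columns=list("abce")))


class TestRunStrategy:
    def test_every_patient_predicted_once(self, small_cohort, fast_mlp_config):
        preds = run_strategy(small_cohort, "pooled", fast_mlp_config)
        assert len(preds) == len(small_cohort)
        assert not preds["id"].duplicated().any()
        assert preds["risk"].between(0, 1).all()

    def test_null_signal_gives_chance_auc(self, small_cohort, fast_mlp_config):
        shuffled = small_cohort.copy()
        rng = np.random.default_rng(0)
        shuffled["progression"] = rng.permutation(
            shuffled["progression"].to_numpy()
        )
        preds = run_strategy(shuffled, "pooled", fast_mlp_config)
        assert abs(auc(preds["risk"], preds["outcome"]) - 0.5) < 0.05

    def test_out_of_fold_purity_under_test_row_mutation(
        self, small_cohort, fast_mlp_config
    ):
        # Corrupting the lab values of some fold-0 test rows must not change
        # predictions for the *other* fold-0 rows: the fold-0 model and its
        # preprocessor never see any fold-0 row.
        folds = make_cv_folds(small_cohort, k=5, seed=fast_mlp_config.seed)
        fold0_ids = small_cohort.loc[folds == 0, "id"].to_numpy()
        mutated = small_cohort.copy()
        victim = fold0_ids[:10]
        keep = fold0_ids[10:]
        mutated.loc[mutated["id"].isin(victim), "sbp"] = 240.0
        p1 = run_strategy(small_cohort, "pooled", fast_mlp_config)
        p2 = run_strategy(mutated, "pooled", fast_mlp_config)
        a = p1[p1["id"].isin(keep)].set_index("id")["risk"]
        b = p2[p2["id"].isin(keep)].set_index("id")["risk"]
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_modular_scores_each_patient_with_own_race_model(
        self, small_cohort, fast_mlp_config
    ):
        preds = run_strategy(small_cohort, "modular", fast_mlp_config)
        assert len(preds) == len(small_cohort)
        assert set(preds["race"]) == {"Black", "White"}

    def test_modular_equals_pooled_under_homogeneity(self):
        # When both races share one generating process, per-group AUCs of the
        # two strategies agree within sampling error.
        base = GeneratorConfig()
        shared_coefs = base.outcome_coefficients["White"]
        shared_means = base.covariate_means["White"]
        shared_sds = base.covariate_sds["White"]
        shared_prev = base.comorbidity_prevalences["White"]
        config = dataclasses.replace(
            base,
            n_total=1500,
            biomarker_subset_size=0,
            outcome_coefficients={"Black": shared_coefs, "White": shared_coefs},
            covariate_means={"Black": shared_means, "White": shared_means},
            covariate_sds={"Black": shared_sds, "White": shared_sds},
            comorbidity_prevalences={"Black": shared_prev, "White": shared_prev},
            target_event_rates={"Black": 0.24, "White": 0.24},
            seed=9,
        )
        cohort = generate_cohort(config)
        cfg = dataclasses.replace(MlpConfig(), max_epochs=40,
                                  early_stopping_patience=8)
        pooled = run_strategy(cohort, "pooled", cfg)
        modular = run_strategy(cohort, "modular", cfg)
        # at this scale the per-race models see few training rows, so allow a
        # wider finite-sample margin; the tighter check runs at larger n in
        # the acceptance suite
        for race in ("Black", "White"):
            ap = auc(*pooled.loc[pooled["race"] == race, ["risk", "outcome"]].T.to_numpy())
            am = auc(*modular.loc[modular["race"] == race, ["risk", "outcome"]].T.to_numpy())
            assert abs(ap - am) < 0.08

    def test_unknown_strategy_raises(self, small_cohort, fast_mlp_config):
        with pytest.raises(ValueError, match="strategy"):
            run_strategy(small_cohort, "hybrid", fast_mlp_config)


class TestBiomarkerVariant:
    def test_rows_without_biomarkers_rejected(self, small_cohort, fast_mlp_config):
        with pytest.raises(ValueError, match="never"):
            run_biomarker_variant(small_cohort, "pooled", fast_mlp_config)

    def test_runs_on_measured_subset(self, small_cohort, fast_mlp_config):
        sub = small_cohort[small_cohort["tnfr1"].notna()].reset_index(drop=True)
        preds = run_biomarker_variant(sub, "pooled", fast_mlp_config, k=3)
        assert len(preds) == len(sub)
        assert (preds["variant"] == "biomarker").all()
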