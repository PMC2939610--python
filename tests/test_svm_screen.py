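"""Randomized-negative SVM screen: sampling, CV metrics, ensemble votes."""

import numpy as np
import pandas as pd
import pytest

from multiscreen.structure_features import FEATURE_NAMES
from multiscreen.svm_screen import (
    ClassifierPerformance,
    TrainingSet,
    cross_validate,
    ensemble_predict,
    evaluate_feature_sets,
    sample_training_set,
)
from multiscreen.synthetic_fixtures import simulate_protein_features


def pools(n_pos, n_neg, separation, seed=0, n_test_pos=0, n_test_neg=0, signal_dims=None):
    feats, meta = simulate_protein_features(
        n_pos, n_neg, n_test_pos=n_test_pos, n_test_neg=n_test_neg,
        separation=separation, seed=seed, signal_dims=signal_dims,
    )
    by_role = {role: feats.loc[meta.index[meta["role"] == role]] for role in meta["role"].unique()}
    return by_role


class TestPerformanceMetrics:
    def test_worked_confusion_counts(self):
        p = ClassifierPerformance(tp=8, fn=2, tn=7, fp=3)
        assert p.qp == pytest.approx(0.8)
        assert p.qn == pytest.approx(0.7)
        assert p.qa == pytest.approx(0.75)

    def test_qa_is_weighted_mix_of_qp_qn(self):
        p = ClassifierPerformance(tp=13, fn=4, tn=21, fp=9)
        total = p.tp + p.fn + p.tn + p.fp
        assert p.qa == pytest.approx(
            (p.qp * (p.tp + p.fn) + p.qn * (p.tn + p.fp)) / total
        )

    def test_undefined_ratio_is_missing(self):
        assert ClassifierPerformance(tp=0, fn=0, tn=5, fp=1).qp is None


class TestSampleTrainingSet:
    def test_size_contract_and_disjointness(self):
        p = pools(5, 100, separation=1.0)
        tset = sample_training_set(p["train_pos"], p["train_neg"], seed=1)
        assert len(tset.positives) == len(tset.negatives) == 5
        assert not set(tset.positives.index) & set(tset.negatives.index)

    def test_same_seed_reproduces_draw(self):
        p = pools(5, 100, separation=1.0)
        a = sample_training_set(p["train_pos"], p["train_neg"], seed=9)
        b = sample_training_set(p["train_pos"], p["train_neg"], seed=9)
        assert list(a.negatives.index) == list(b.negatives.index)

    def test_pool_too_small_is_error(self):
        p = pools(5, 100, separation=1.0)
        with pytest.raises(ValueError):
            sample_training_set(p["train_neg"], p["train_pos"], seed=0)

    def test_uniform_negative_usage_over_many_draws(self):
        p = pools(5, 1000, separation=0.0, seed=3)
        counts = pd.Series(0, index=p["train_neg"].index)
        for i in range(1000):
            tset = sample_training_set(p["train_pos"], p["train_neg"], seed=i)
            counts[tset.negatives.index] += 1
        freq = counts / 1000
        # total draws are fixed, so the mean is exactly |pos|/|pool|
        assert freq.mean() == pytest.approx(0.005)
        se = np.sqrt(0.005 * 0.995 / 1000)
        assert (np.abs(freq - 0.005) <= 6 * se).all()

    def test_unbalanced_training_set_rejected(self):
        p = pools(5, 100, separation=1.0)
        with pytest.raises(ValueError):
            TrainingSet(positives=p["train_pos"], negatives=p["train_neg"], seed=0)


class TestCrossValidate:
    def test_separable_classes_near_perfect(self):
        p = pools(50, 50, separation=10.0, seed=1)
        tset = TrainingSet(p["train_pos"], p["train_neg"], seed=1)
        perf = cross_validate(tset, n_folds=5, seed=1)
        assert perf.qa >= 0.98

    def test_one_class_folds_raise_after_reshuffle(self):
        # one sample per class, two folds: every training split is single-class
        X = pd.DataFrame(np.zeros((1, 3)))
        tset = TrainingSet(
            positives=X.set_axis(["p1"]), negatives=X.set_axis(["n1"]), seed=0
        )
        with pytest.raises(ValueError):
            cross_validate(tset, n_folds=2)

    def test_fold_count_validated(self):
        p = pools(5, 5, separation=1.0)
        with pytest.raises(ValueError):
            cross_validate(TrainingSet(p["train_pos"], p["train_neg"], seed=0), n_folds=1)


class TestEvaluateFeatureSets:
    def test_single_randomization_degenerate_summary(self):
        p = pools(20, 60, separation=5.0, seed=2)
        out = evaluate_feature_sets(
            p["train_pos"], p["train_neg"], n_randomizations=1, n_folds=4, seed=2
        )
        assert (out["qa_min"] == out["qa_max"]).all()
        assert (out["qa_sd"] == 0.0).all()

    def test_signal_in_composition_favors_full_features(self):
        # signal lives in dims 1-20, so the 8-dim secondary subset is noise
        p = pools(30, 90, separation=5.0, seed=4, signal_dims=list(range(1, 21)))
        out = evaluate_feature_sets(
            p["train_pos"], p["train_neg"], n_randomizations=8, n_folds=5, seed=4
        ).set_index("feature_set")
        assert out.loc["full_28dim", "qa_mean"] > out.loc["secondary_8dim", "qa_mean"]


class TestEnsemblePredict:
    def test_planted_test_genes_recovered(self):
        p = pools(25, 100, separation=8.0, seed=5, n_test_pos=10, n_test_neg=10)
        ens = ensemble_predict(
            p["train_pos"], p["train_neg"],
            pd.concat([p["test_pos"], p["test_neg"]]),
            n_randomizations=30, seed=5, record_sets=True,
        )
        pos_votes = ens.vote_fraction[p["test_pos"].index]
        neg_votes = ens.vote_fraction[p["test_neg"].index]
        assert (pos_votes > 0.9).all() and (neg_votes < 0.1).all()
        assert set(p["test_pos"].index) <= ens.candidates
        assert not set(p["test_neg"].index) & ens.candidates
        for s in ens.prediction_sets:
            assert ens.candidates <= s
        assert ens.mean_margin[p["test_pos"].index].mean() > 0

    def test_keep_fraction_relaxation_is_monotone(self):
        p = pools(15, 60, separation=2.0, seed=6, n_test_pos=15, n_test_neg=15)
        test = pd.concat([p["test_pos"], p["test_neg"]])
        strict = ensemble_predict(p["train_pos"], p["train_neg"], test,
                                  n_randomizations=20, keep_fraction=1.0, seed=6)
        relaxed = ensemble_predict(p["train_pos"], p["train_neg"], test,
                                   n_randomizations=20, keep_fraction=0.9, seed=6)
        assert strict.candidates <= relaxed.candidates

    def test_more_randomizations_never_grow_intersection(self):
        p = pools(15, 60, separation=2.0, seed=8, n_test_pos=20, n_test_neg=0)
        test = p["test_pos"]
        sizes = []
        for n in (5, 20, 60):
            ens = ensemble_predict(p["train_pos"], p["train_neg"], test,
                                   n_randomizations=n, seed=8)
            sizes.append(ens.candidates)
        assert sizes[2] <= sizes[1] <= sizes[0]

    def test_bit_reproducible_under_fixed_seed(self):
        p = pools(10, 40, separation=3.0, seed=9, n_test_pos=5, n_test_neg=5)
        test = pd.concat([p["test_pos"], p["test_neg"]])
        a = ensemble_predict(p["train_pos"], p["train_neg"], test, n_randomizations=10, seed=9)
        b = ensemble_predict(p["train_pos"], p["train_neg"], test, n_randomizations=10, seed=9)
        assert a.candidates == b.candidates
        assert (a.vote_fraction == b.vote_fraction).all()
        assert (a.mean_margin == b.mean_margin).all()

    def test_test_set_must_be_disjoint(self):
        p = pools(10, 40, separation=3.0, seed=9)
        with pytest.raises(ValueError):
            ensemble_predict(p["train_pos"], p["train_neg"], p["train_pos"].iloc[:2])

    def test_empty_test_set(self):
        p = pools(10, 40, separation=3.0, seed=9)
        empty = pd.DataFrame(columns=FEATURE_NAMES)
        ens = ensemble_predict(p["train_pos"], p["train_neg"], empty, n_randomizations=3)
        assert ens.candidates == set() and len(ens.vote_fraction) == 0
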