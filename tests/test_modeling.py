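"""Threshold-optimized RF training, metrics, ensembling, applicability domain."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from dictox.features import FeatureMatrix
from dictox.modeling import (
    _oversample,
    ad_report,
    cv_train,
    ensemble_predict,
    evaluate,
    predict_unlabeled,
    rescale_score,
    youden_threshold,
)


def exhaustive_youden(scores, labels):
    """Oracle: scan every distinct score as a cut, largest cut wins ties.

    J is compared as the exact fraction (TP·n_neg − FP·n_pos)/(n_pos·n_neg)
    so ties are genuine ties rather than float artifacts."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    best = (-(n_pos * n_neg + 1), -np.inf)
    for cut in np.unique(scores):
        pred = scores >= cut
        j = int((pred & (y == 1)).sum()) * n_neg - int((pred & (y == 0)).sum()) * n_pos
        best = max(best, (j, cut))
    return best[1]


class TestYoudenThreshold:
    def test_perfectly_separated(self):
        t = youden_threshold([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert t == 0.8

    def test_overlapping_scores_hand_case(self):
        scores = [0.9, 0.6, 0.4, 0.5, 0.3, 0.1]
        labels = [1, 1, 1, 0, 0, 0]
        assert youden_threshold(scores, labels) == 0.6
        assert youden_threshold(scores, labels) == exhaustive_youden(scores, labels)

    def test_constant_scores_degenerate(self):
        assert youden_threshold([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_matches_oracle_on_random_fixtures(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 51))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.choice(np.round(rng.random(12), 2), size=n)
            assert youden_threshold(scores, labels) == exhaustive_youden(
                scores, labels
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_threshold([0.1, 0.9], [1, 1])


class TestEvaluate:
    def test_perfect_predictions(self):
        rep = evaluate([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], threshold=0.5)
        for metric in ("balanced_accuracy", "sensitivity", "specificity",
                       "f1", "mcc", "auc_roc", "auc_pr"):
            assert getattr(rep, metric) == pytest.approx(1.0)

    def test_uninformative_baseline_is_prevalence(self):
        # constant scores: AUCPR = prevalence, AUC-ROC = 0.5
        y = [1] * 65 + [0] * 25
        rep = evaluate([0.5] * 90, y, threshold=0.5)
        assert rep.auc_pr == pytest.approx(65 / 90)
        assert rep.auc_roc == pytest.approx(0.5)
        assert rep.prevalence == pytest.approx(65 / 90)

    def test_all_positive_at_zero_threshold(self):
        rep = evaluate([0.3, 0.6, 0.2, 0.9], [1, 0, 0, 1], threshold=0.0)
        assert rep.sensitivity == 1.0
        assert rep.specificity == 0.0
        assert rep.balanced_accuracy == 0.5

    def test_single_class_gives_na_auc(self):
        rep = evaluate([0.2, 0.9], [1, 1], threshold=0.5)
        assert math.isnan(rep.auc_roc) and math.isnan(rep.auc_pr)
        assert rep.sensitivity == 0.5


class TestOversample:
    def test_balances_classes_without_touching_majority(self, rng):
        X = np.arange(30).reshape(-1, 1)
        y = np.array([1] * 20 + [0] * 10)
        Xo, yo = _oversample(X, y, rng)
        assert (yo == 1).sum() == (yo == 0).sum() == 20
        # majority rows appear exactly once
        assert sorted(Xo[yo == 1, 0]) == list(range(20))


def _separable_fixture(n=160, seed=0):
    rng = np.random.default_rng(seed)
    keys = [f"c{i}" for i in range(n)]
    y = rng.integers(0, 2, size=n)
    X = rng.integers(0, 2, size=(n, 32)).astype(float)
    X[:, 0] = y  # label is feature 0
    fm = FeatureMatrix(
        "structure",
        pd.DataFrame(X, index=keys, columns=[f"bit_{i}" for i in range(32)]),
    )
    labels = pd.DataFrame({"key": keys, "label": y})
    return fm, labels


class TestCvTrain:
    def test_separable_features_give_high_oof_auc(self):
        fm, labels = _separable_fixture()
        model = cv_train(fm, labels, seed=0, n_candidates=4)
        auc = roc_auc_score(model.oof_labels, model.oof_scores)
        assert auc > 0.95
        assert 0.0 < model.threshold < 1.0

    def test_deterministic_given_seed(self):
        fm, labels = _separable_fixture(n=80)
        a = cv_train(fm, labels, seed=3, n_candidates=3)
        b = cv_train(fm, labels, seed=3, n_candidates=3)
        assert a.hyperparameters == b.hyperparameters
        assert a.threshold == b.threshold
        assert np.array_equal(a.oof_scores, b.oof_scores)

    def test_permuted_labels_stay_near_chance(self):
        fm, labels = _separable_fixture(n=120, seed=1)
        rng = np.random.default_rng(9)
        aucs = []
        for s in range(3):
            shuffled = labels.copy()
            shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
            m = cv_train(fm, shuffled, seed=s, n_candidates=2)
            aucs.append(roc_auc_score(m.oof_labels, m.oof_scores))
        assert 0.3 < float(np.mean(aucs)) < 0.7

    def test_single_class_rejected(self):
        fm, labels = _separable_fixture(n=40)
        labels["label"] = 1
        with pytest.raises(ValueError):
            cv_train(fm, labels, seed=0)


class TestRescaleAndEnsemble:
    def test_threshold_maps_to_half(self):
        for t in (0.2, 0.5, 0.66):
            assert rescale_score(t, t) == pytest.approx(0.5)
        assert rescale_score(0.0, 0.4) == 0.0
        assert rescale_score(1.0, 0.4) == 1.0

    def test_hand_computed_two_model_vote(self):
        # (t=0.4, p=0.8) -> 0.5 + 0.5*0.4/0.6 = 0.8333; (t=0.6, p=0.3) -> 0.25
        s1 = rescale_score(0.8, 0.4)
        s2 = rescale_score(0.3, 0.6)
        assert s1 == pytest.approx(0.83333, abs=1e-4)
        assert s2 == pytest.approx(0.25)
        assert (s1 + s2) / 2 == pytest.approx(0.54167, abs=1e-4)
        assert (s1 + s2) / 2 >= 0.5  # -> predicted toxic

    def test_single_model_ensemble_reproduces_model(self):
        fm, labels = _separable_fixture(n=80, seed=2)
        model = cv_train(fm, labels, seed=0, n_candidates=3)
        keys = fm.keys[:20]
        ens = ensemble_predict([model], {"structure": fm}, keys)
        direct = (
            model.predict_scores(fm, keys).to_numpy() >= model.threshold
        ).astype(int)
        assert np.array_equal(ens["label"].to_numpy(), direct)

    def test_k_copies_reproduce_single_model(self):
        fm, labels = _separable_fixture(n=80, seed=2)
        model = cv_train(fm, labels, seed=0, n_candidates=3)
        keys = fm.keys[:15]
        one = ensemble_predict([model], {"structure": fm}, keys)
        three = ensemble_predict([model] * 3, {"structure": fm}, keys)
        assert np.allclose(one["score"], three["score"])

    def test_missing_space_named(self):
        fm, labels = _separable_fixture(n=80)
        model = cv_train(fm, labels, seed=0, n_candidates=2)
        with pytest.raises(ValueError, match="structure"):
            ensemble_predict([model], {}, fm.keys[:5])


class TestApplicabilityDomain:
    def test_identical_compound_lands_in_top_bin(self):
        fm, labels = _separable_fixture(n=60, seed=4)
        model = cv_train(fm, labels, seed=0, n_candidates=2)
        test_key = model.training_keys[0]
        rep = ad_report([test_key], model, fm, labels)
        assert rep.per_bin[(0.8, 1.0)]["n"] == 1
        assert sum(v["n"] for v in rep.per_bin.values()) == 1

    def test_bin_metrics_match_direct_recomputation(self):
        fm, labels = _separable_fixture(n=100, seed=5)
        train = labels.iloc[:80]
        test = labels.iloc[80:]
        train_fm = FeatureMatrix("structure", fm.data.iloc[:80])
        model = cv_train(train_fm, train, seed=0, n_candidates=2)
        rep = ad_report(list(test["key"]), model, fm, labels)
        assert sum(v["n"] for v in rep.per_bin.values()) == len(test)
        # recompute: every test compound's nearest same-label neighbor
        from dictox.features import tanimoto

        lab = labels.set_index("key")
        for (lo, hi), entry in rep.per_bin.items():
            n_direct = 0
            for k in test["key"]:
                fp = fm.data.loc[k].to_numpy(dtype=bool)
                same = [
                    t for t in model.training_keys
                    if lab.loc[t, "label"] == lab.loc[k, "label"]
                ]
                sim = max(
                    tanimoto(fp, fm.data.loc[t].to_numpy(dtype=bool))
                    for t in same
                )
                if lo <= sim < hi or (hi == 1.0 and sim == 1.0):
                    n_direct += 1
            assert entry["n"] == n_direct


class TestPredictUnlabeled:
    def test_empty_input_and_score_bounds(self):
        fm, labels = _separable_fixture(n=60, seed=6)
        model = cv_train(fm, labels, seed=0, n_candidates=2)
        empty = predict_unlabeled(
            model, FeatureMatrix("structure", fm.data.iloc[0:0])
        )
        assert len(empty) == 0
        out = predict_unlabeled(model, fm)
        assert ((out["score"] >= 0) & (out["score"] <= 1)).all()
        assert set(out["label"]) <= {0, 1}
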