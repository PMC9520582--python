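"""Unit tests for metrics, upsampling and the profile classifier."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import average_precision_score

from audioprofiles.classify import (EvaluationReport, ProfileClassifier,
                                    StrategyConfig, compute_metric,
                                    evaluate_test, split_train_test, train,
                                    tune_and_select, upsample_gaussian)


def _blobs(n_per=40, k=3, d=5, sep=6.0, seed=0):
    """Well-separated Gaussian classes as a (DataFrame, labels) pair."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(k):
        mu = np.zeros(d)
        mu[c % d] = sep * c
        X.append(rng.normal(mu, 1.0, size=(n_per, d)))
        y.append(np.full(n_per, c + 1))
    X = pd.DataFrame(np.vstack(X), columns=[f"f{j}" for j in range(d)])
    return X, np.concatenate(y)


# ---------------------------------------------------------------------------
# metrics


def test_kappa_on_a_hand_worked_confusion_table():
    # TP=2, FN=1, FP=1, TN=2 -> p_o = 2/3, p_e = 1/2, kappa = 1/3
    y_true = [1, 1, 1, 0, 0, 0]
    y_pred = [1, 1, 0, 1, 0, 0]
    res = compute_metric(y_true, y_pred, metric="kappa")
    assert res.p_o == pytest.approx(2 / 3)
    assert res.p_e == pytest.approx(0.5)
    assert res.score == pytest.approx(1 / 3)


def test_kappa_is_one_for_perfect_and_near_zero_for_random_predictions():
    y = np.array([1, 2, 3, 1, 2, 3])
    assert compute_metric(y, y, metric="kappa").score == pytest.approx(1.0)
    rng = np.random.default_rng(123)
    y_true = rng.integers(0, 3, size=10000)
    y_pred = rng.integers(0, 3, size=10000)
    assert abs(compute_metric(y_true, y_pred, metric="kappa").score) < 0.05


def test_kappa_never_exceeds_raw_accuracy():
    rng = np.random.default_rng(9)
    for _ in range(20):
        y_true = rng.integers(0, 4, size=200)
        y_pred = rng.integers(0, 4, size=200)
        res = compute_metric(y_true, y_pred, metric="kappa")
        assert res.score <= res.p_o + 1e-12


def test_balanced_accuracy_hand_value():
    # class 1: sens 2/3, spec 1; class 0: sens 1, spec 2/3
    y_true = [1, 1, 1, 0, 0, 0]
    y_pred = [1, 1, 0, 0, 0, 0]
    res = compute_metric(y_true, y_pred, metric="balanced_accuracy")
    assert res.per_class[1] == pytest.approx((2 / 3 + 1) / 2)
    assert res.per_class[0] == pytest.approx((1 + 2 / 3) / 2)
    assert res.score == pytest.approx(5 / 6)


def test_macro_f1_is_invariant_to_consistent_relabeling():
    rng = np.random.default_rng(4)
    y_true = rng.integers(0, 3, size=150)
    y_pred = rng.integers(0, 3, size=150)
    a = compute_metric(y_true, y_pred, metric="f1").score
    relabel = np.array([7, 5, 9])
    b = compute_metric(relabel[y_true], relabel[y_pred], metric="f1").score
    assert a == pytest.approx(b)


def test_f1_excludes_never_predicted_classes():
    y_true = [0, 0, 1, 1, 2, 2]
    y_pred = [0, 0, 1, 1, 0, 1]  # class 2 never predicted
    res = compute_metric(y_true, y_pred, metric="f1")
    assert 2 in res.excluded
    assert set(res.per_class) == {0, 1}


def test_auprc_matches_sklearn_per_class():
    rng = np.random.default_rng(8)
    y_true = rng.integers(0, 3, size=120)
    scores = rng.random((120, 3))
    res = compute_metric(y_true, metric="auprc", scores=scores,
                         classes=np.array([0, 1, 2]))
    for c in (0, 1, 2):
        expect = average_precision_score((y_true == c).astype(int), scores[:, c])
        assert res.per_class[c] == pytest.approx(expect)
    assert res.score == pytest.approx(np.mean(list(res.per_class.values())))
    with pytest.raises(ValueError):
        compute_metric(y_true, metric="auprc")


# ---------------------------------------------------------------------------
# data handling


def test_split_is_stratified_disjoint_and_warns_on_singletons():
    X, y = _blobs(n_per=40, k=3)
    X_tr, X_te, y_tr, y_te = split_train_test(X, y, train_frac=0.75, seed=3)
    assert set(X_tr.index).isdisjoint(X_te.index)
    assert len(X_tr) + len(X_te) == len(X)
    for c in (1, 2, 3):
        assert np.sum(y_tr == c) == 30 and np.sum(y_te == c) == 10

    y_single = y.copy()
    y_single[0] = 99  # singleton profile
    with pytest.warns(UserWarning, match="single"):
        X_tr, X_te, y_tr, y_te = split_train_test(X, y_single, seed=3)
    assert 99 in y_tr and 99 not in y_te


def test_upsampling_pads_minorities_and_keeps_originals():
    X, y = _blobs(n_per=10, k=2)
    X2 = pd.concat([X, X.iloc[:5]], ignore_index=True)
    y2 = np.concatenate([y, np.full(5, 3)])
    Xu, yu = upsample_gaussian(X2, y2, seed=0)
    _, counts = np.unique(yu, return_counts=True)
    assert (counts == 10).all()
    # original rows come first, unchanged
    pd.testing.assert_frame_equal(Xu.iloc[: len(X2)], X2)
    assert np.array_equal(yu[: len(y2)], y2)


def test_upsampling_respects_ordinal_coding():
    rng = np.random.default_rng(2)
    X = pd.DataFrame({
        "f0": rng.normal(size=30),
        "bisgaard_index": np.clip(np.round(rng.normal(5, 2, 30)), 0, 18),
    })
    y = np.array([1] * 25 + [2] * 5)
    Xu, yu = upsample_gaussian(X, y, seed=1)
    new = Xu["bisgaard_index"].iloc[30:]
    assert (new == np.round(new)).all()
    assert new.between(0, 18).all()


# ---------------------------------------------------------------------------
# the classifier


def test_learner_counts_match_the_strategy():
    cfg = StrategyConfig()
    for k in (2, 3, 5):
        assert StrategyConfig(strategy="multiclass").n_learners(k) == 1
        assert StrategyConfig(strategy="OVA").n_learners(k) == k
        assert StrategyConfig(strategy="OVO").n_learners(k) == k * (k - 1) // 2
        assert cfg.n_learners(k) == k + k * (k - 1) // 2

    X, y = _blobs(n_per=15, k=3)
    for strategy in ("multiclass", "OVA", "OVO", "OVAOVO"):
        clf = ProfileClassifier(strategy=strategy, n_trees=10, mtry_grid=(2,),
                                random_state=0).fit(X, y)
        assert len(clf.learners_) == StrategyConfig(strategy=strategy).n_learners(3)


def test_strategy_config_validation():
    with pytest.raises(ValueError):
        StrategyConfig(strategy="bagging")
    with pytest.raises(ValueError):
        StrategyConfig(cv="bootstrap")
    with pytest.raises(ValueError):
        StrategyConfig(metric="accuracy")
    with pytest.raises(ValueError):
        StrategyConfig(n_trees=0)


def test_separable_classes_are_recovered_by_every_strategy():
    X, y = _blobs(n_per=25, k=3, sep=8.0, seed=5)
    X_tr, X_te, y_tr, y_te = split_train_test(X, y, seed=0)
    for strategy in ("multiclass", "OVA", "OVO", "OVAOVO"):
        clf = ProfileClassifier(strategy=strategy, n_trees=30, mtry_grid=(2,),
                                random_state=0).fit(X_tr, y_tr)
        assert np.mean(clf.predict(X_te) == y_te) >= 0.95


def test_ovaovo_agrees_with_ova_when_at_most_one_learner_claims():
    X, y = _blobs(n_per=25, k=3, sep=8.0, seed=6)
    combo = ProfileClassifier(strategy="OVAOVO", n_trees=30, mtry_grid=(2,),
                              random_state=1).fit(X, y)
    pred, shares, _ = combo.predict_with_uncertainty(X)
    at_most_one = (shares > combo.positive_threshold).sum(axis=1) <= 1
    # where no OVO arbitration is needed, the decision is the pure OVA rule
    ova_rule = combo.classes_[np.argmax(shares, axis=1)]
    assert np.array_equal(pred[at_most_one], ova_rule[at_most_one])


def test_predict_with_uncertainty_returns_consistent_shapes():
    X, y = _blobs(n_per=15, k=3, seed=7)
    clf = train("OVO", X, y, StrategyConfig(strategy="OVO", n_trees=10,
                                            mtry_grid=(2,), seed=0))
    pred, scores, share = clf.predict_with_uncertainty(X.iloc[:8])
    assert pred.shape == (8,) and share.shape == (8,)
    assert scores.shape == (8, 3)
    assert np.all((share >= 0) & (share <= 1))
    with pytest.raises(ValueError, match="missing"):
        clf.predict(X.iloc[:2].mask([[True] * 5, [False] * 5]))


def test_fit_is_deterministic_for_a_fixed_seed():
    X, y = _blobs(n_per=15, k=3, seed=8)
    a = ProfileClassifier(n_trees=15, mtry_grid=(2, 3), cv="repcv", cv_folds=3,
                          cv_repeats=1, random_state=4).fit(X, y)
    b = ProfileClassifier(n_trees=15, mtry_grid=(2, 3), cv="repcv", cv_folds=3,
                          cv_repeats=1, random_state=4).fit(X, y)
    assert a.chosen_mtry_ == b.chosen_mtry_
    assert np.array_equal(a.predict(X), b.predict(X))


def test_single_profile_is_rejected():
    X, _ = _blobs(n_per=10, k=1)
    with pytest.raises(ValueError, match="2 profiles"):
        ProfileClassifier(n_trees=5).fit(X, np.ones(10))


# ---------------------------------------------------------------------------
# evaluation and strategy selection


def test_evaluation_excludes_small_training_profiles_from_the_means():
    X, y = _blobs(n_per=30, k=2, sep=8.0, seed=9)
    # append a tiny third profile (5 training members < 10)
    rng = np.random.default_rng(10)
    X_small = pd.DataFrame(rng.normal(20.0, 1.0, size=(8, 5)), columns=X.columns)
    X_all = pd.concat([X, X_small], ignore_index=True)
    y_all = np.concatenate([y, np.full(8, 3)])
    X_tr, X_te, y_tr, y_te = split_train_test(X_all, y_all, seed=0)
    clf = ProfileClassifier(strategy="OVA", n_trees=20, mtry_grid=(2,),
                            random_state=0).fit(X_tr, y_tr)
    report = evaluate_test(clf, X_te, y_te, min_profile_size=10)
    assert isinstance(report, EvaluationReport)
    assert 3 in report.excluded
    flagged = report.per_profile.set_index("profile")
    assert flagged.loc[3, "flag"] == "small profile"
    incl = flagged[flagged["included"]]
    assert report.mean_precision == pytest.approx(incl["precision"].mean())
    assert report.mean_sensitivity == pytest.approx(incl["sensitivity"].mean())
    assert report.mean_precision >= 0.9
    d = report.to_dict()
    assert set(d) == {"per_profile", "mean_precision", "mean_sensitivity", "excluded"}
    with pytest.raises(ValueError):
        evaluate_test(clf, X_te.iloc[:0], y_te[:0])


def test_tune_and_select_is_deterministic_and_prefers_parsimony_on_ties():
    X, y = _blobs(n_per=20, k=3, sep=8.0, seed=11)
    configs = [
        StrategyConfig(strategy="multiclass", n_trees=15, mtry_grid=(2,), seed=0),
        StrategyConfig(strategy="OVA", n_trees=15, mtry_grid=(2,), seed=0),
    ]
    best_a, table_a = tune_and_select(X, y, configs, min_profile_size=10,
                                      selection_folds=3, seed=2)
    best_b, table_b = tune_and_select(X, y, configs, min_profile_size=10,
                                      selection_folds=3, seed=2)
    assert best_a is best_b or best_a == best_b
    pd.testing.assert_frame_equal(table_a, table_b)
    assert set(table_a["config"]) == {0, 1}
    # perfectly separable: both reach F1 = 1 and the tie goes to fewer learners
    if table_a["mean_f1"].nunique() == 1:
        assert best_a.strategy == "multiclass"
    with pytest.raises(ValueError):
        tune_and_select(X, y, [], seed=0)
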