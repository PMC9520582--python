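"""Unit tests for chained-equations imputation with predictive mean matching."""

import numpy as np
import pandas as pd
import pytest

from audioprofiles.impute import CompletedSet, ImputationConfig, mice_impute


def _correlated_data(n=400, d=6, rho=0.8, seed=42):
    rng = np.random.default_rng(seed)
    cov = rho + (1 - rho) * np.eye(d)
    X = rng.multivariate_normal(np.zeros(d), cov, size=n) * 1.5 + 2.0
    return X


def _masked(X, rate=0.1, seed=7):
    rng = np.random.default_rng(seed)
    Xm = X.copy()
    Xm[rng.random(X.shape) < rate] = np.nan
    return Xm


def test_observed_cells_identical_across_all_completions():
    X = _correlated_data()
    Xm = _masked(X)
    comp = mice_impute(Xm, ImputationConfig(m=4, n_chain_iterations=5, seed=0))
    obs = ~np.isnan(Xm)
    for ds in comp.datasets:
        assert np.array_equal(ds.to_numpy()[obs], Xm[obs])
        assert not np.isnan(ds.to_numpy()).any()


def test_pmm_values_come_from_the_observed_support():
    X = _correlated_data()
    Xm = _masked(X)
    comp = mice_impute(Xm, ImputationConfig(m=2, n_chain_iterations=5, seed=1))
    miss = np.isnan(Xm)
    for ds in comp.datasets:
        arr = ds.to_numpy()
        for j in range(X.shape[1]):
            support = set(np.round(Xm[~miss[:, j], j], 12))
            imputed = np.round(arr[miss[:, j], j], 12)
            assert set(imputed) <= support


def test_imputation_error_is_below_marginal_spread():
    # with strongly correlated features the conditional draws beat the
    # marginal SD as a predictor of the held-out truth
    X = _correlated_data()
    Xm = _masked(X)
    comp = mice_impute(Xm, ImputationConfig(m=5, n_chain_iterations=8, seed=2))
    miss = np.isnan(Xm)
    for j in range(X.shape[1]):
        truth = X[miss[:, j], j]
        preds = np.mean([d.to_numpy()[miss[:, j], j] for d in comp.datasets], axis=0)
        rmse = np.sqrt(np.mean((preds - truth) ** 2))
        assert rmse < np.std(X[~miss[:, j], j])


def test_same_seed_is_bitwise_reproducible_and_chains_differ():
    Xm = _masked(_correlated_data())
    a = mice_impute(Xm, ImputationConfig(m=3, n_chain_iterations=4, seed=5))
    b = mice_impute(Xm, ImputationConfig(m=3, n_chain_iterations=4, seed=5))
    for da, db in zip(a.datasets, b.datasets):
        pd.testing.assert_frame_equal(da, db)
    arrs = [d.to_numpy() for d in a.datasets]
    assert not np.array_equal(arrs[0], arrs[1])  # chains are distinct draws


def test_fully_missing_feature_is_reported_by_name():
    Xm = pd.DataFrame(_masked(_correlated_data(n=50)),
                      columns=[f"f{j}" for j in range(6)])
    Xm["f3"] = np.nan
    with pytest.raises(ValueError, match="f3"):
        mice_impute(Xm, ImputationConfig(m=1, seed=0))


def test_complete_matrix_passes_through():
    X = _correlated_data(n=50)
    comp = mice_impute(X, ImputationConfig(m=2, seed=0))
    assert comp.m == 2
    for ds in comp.datasets:
        assert np.array_equal(ds.to_numpy(), X)


def test_ordinal_hook_rounds_and_clips():
    rng = np.random.default_rng(3)
    base = rng.normal(10, 3, size=(300, 3))
    frame = pd.DataFrame(base, columns=["a", "b", "score"])
    frame["score"] = np.clip(np.round(frame["score"]), 0, 18)
    masked = frame.copy()
    masked.iloc[rng.choice(300, 30, replace=False), 2] = np.nan
    comp = mice_impute(masked, ImputationConfig(
        m=2, n_chain_iterations=4, seed=0, ordinal_ranges={"score": (0, 18)}
    ))
    miss = masked["score"].isna()
    for ds in comp.datasets:
        v = ds.loc[miss, "score"]
        assert (v == np.round(v)).all()
        assert v.between(0, 18).all()


def test_passive_columns_satisfy_their_identity_in_every_completion():
    rng = np.random.default_rng(11)
    a = rng.normal(size=500)
    b = rng.normal(size=500)
    c = rng.normal(size=500)
    frame = pd.DataFrame({"a": a, "b": b, "c": c, "diff": a - b})
    masked = frame.copy()
    for col in ("a", "b", "c"):
        masked.loc[rng.choice(500, 25, replace=False), col] = np.nan
    # a derived column is missing whenever one of its parents is
    masked.loc[masked["a"].isna() | masked["b"].isna(), "diff"] = np.nan
    comp = mice_impute(masked, ImputationConfig(
        m=3, n_chain_iterations=4, seed=0,
        passive={"diff": ({"a": 1.0, "b": -1.0}, 0.0)},
    ))
    obs = ~masked.isna()
    for ds in comp.datasets:
        assert np.allclose(ds["diff"], ds["a"] - ds["b"], atol=1e-10)
        for col in frame.columns:  # observed cells still untouched
            assert np.array_equal(ds.loc[obs[col], col], masked.loc[obs[col], col])
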