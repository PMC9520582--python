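"""Unit tests for the constrained Gaussian-mixture engine."""

import numpy as np
import pytest

from audioprofiles import (ConstrainedGaussianMixture, cov_param_count, e_step,
                           fit_em, fit_grid, m_step, n_free_params)
from audioprofiles.mixture import ALL_MODELS, FitFailure

from helpers import expected_complete_loglik, gaussian_mle_loglik


EXPECTED_COV_PARAMS = {
    # (model, k, d) -> count
    ("EII", 3, 5): 1,
    ("VII", 3, 5): 3,
    ("EEI", 3, 5): 5,
    ("VEI", 3, 5): 3 + 4,
    ("EVI", 3, 5): 1 + 3 * 4,
    ("VVI", 3, 5): 15,
    ("EEE", 3, 5): 15,
    ("VVV", 3, 5): 45,
}


def test_covariance_parameter_counts():
    for (model, k, d), expected in EXPECTED_COV_PARAMS.items():
        assert cov_param_count(model, k, d) == expected
    assert n_free_params("VEI", 3, 5) == (3 - 1) + 3 * 5 + 7
    with pytest.raises(ValueError):
        cov_param_count("XYZ", 2, 2)


def _two_blob_data(rng, n=150, d=3):
    return np.vstack([
        rng.normal(0.0, 1.0, size=(n // 2, d)),
        rng.normal(4.0, 1.3, size=(n - n // 2, d)),
    ])


@pytest.mark.parametrize("model", ALL_MODELS)
def test_em_increases_loglik_every_iteration(model, rng):
    X = _two_blob_data(rng)
    resp = rng.random((len(X), 2))
    resp /= resp.sum(axis=1, keepdims=True)
    prev = -np.inf
    for _ in range(25):
        params = m_step(X, resp, model)
        resp, loglik = e_step(X, params)
        assert loglik >= prev - 1e-8
        prev = loglik


@pytest.mark.parametrize("model", ALL_MODELS)
def test_single_component_matches_gaussian_mle(model, rng):
    X = rng.normal(size=(200, 3)) * np.array([1.0, 2.0, 0.5]) + 1.0
    fit = fit_em(X, 1, model, seed=0, n_init=1, variance_floor=1e-12)
    assert fit.loglik == pytest.approx(gaussian_mle_loglik(X, model), abs=1e-8)


def test_bic_formula(vei_sample):
    fit = fit_em(vei_sample.X, 3, "VEI", seed=0, n_init=1)
    n = len(vei_sample.X)
    assert fit.bic == pytest.approx(
        2.0 * fit.loglik - fit.n_params * np.log(n), abs=1e-9
    )
    assert fit.n_params == n_free_params("VEI", 3, 4)


def test_fit_is_invariant_to_row_order(vei_sample):
    X = vei_sample.X
    perm = np.random.default_rng(3).permutation(len(X))
    a = fit_em(X, 3, "VEI", seed=0, n_init=1)
    b = fit_em(X[perm], 3, "VEI", seed=0, n_init=1)
    assert a.loglik == pytest.approx(b.loglik, abs=1e-6)


def test_responsibilities_are_posterior_probabilities(vei_sample):
    fit = fit_em(vei_sample.X, 3, "VEI", seed=0, n_init=1)
    assert np.allclose(fit.responsibilities.sum(axis=1), 1.0)
    assert fit.responsibilities.min() >= 0.0


def test_estimator_interface(vei_sample):
    est = ConstrainedGaussianMixture(
        n_components=3, covariance_type="VEI", n_init=1, random_state=0
    ).fit(vei_sample.X)
    assert est.weights_.shape == (3,)
    assert est.means_.shape == (3, 4)
    assert np.isfinite(est.bic_)
    labels = est.predict(vei_sample.X)
    proba = est.predict_proba(vei_sample.X)
    assert np.array_equal(labels, np.argmax(proba, axis=1))
    # score_samples is the log of the mixture density
    dens = est.score_samples(vei_sample.X[:10])
    assert dens.shape == (10,)
    # fitted shapes have unit determinant where the family constrains them
    assert np.allclose(np.prod(est.shapes_, axis=1), 1.0)


def test_vei_shape_is_shared_and_unit_determinant(vei_sample):
    fit = fit_em(vei_sample.X, 3, "VEI", seed=0, n_init=1)
    shapes = fit.params.shapes
    assert np.allclose(shapes, shapes[0])
    assert np.prod(shapes[0]) == pytest.approx(1.0, abs=1e-10)
    # composition: sigma2 = lambda_g * A
    assert np.allclose(
        fit.params.sigma2, fit.params.volumes[:, None] * shapes, atol=1e-12
    )


def test_full_families_fail_on_collinear_data(rng):
    base = rng.normal(size=(120, 3))
    X = np.column_stack([base, base[:, 0] - base[:, 1]])  # exact identity
    for model in ("EEE", "VVV"):
        fit = fit_em(X, 2, model, seed=0, n_init=1)
        assert not fit.converged
        assert "singular" in (fit.failure_reason or "")
    # diagonal families remain well defined on the same matrix
    fit = fit_em(X, 2, "VVI", seed=0, n_init=1)
    assert np.isfinite(fit.loglik)


def test_grid_prefers_generating_structure(vei_sample):
    grid = fit_grid(vei_sample.X, k_range=range(2, 5), models=list(ALL_MODELS),
                    seed=0, n_init=1)
    best = grid.best
    assert best.k == 3
    assert best.model in ("EEI", "VEI", "EVI", "VVI", "EII", "VII")
    assert len(grid.table) == 3 * len(ALL_MODELS)


def test_component_collapse_is_reported():
    X = np.random.default_rng(0).normal(size=(30, 2))
    fit = fit_em(X, 25, "VVV", seed=0, n_init=1)
    assert not fit.converged
    assert fit.failure_reason


def test_mstep_q_not_below_random_parameters(rng):
    X = _two_blob_data(rng, n=80, d=2)
    resp = rng.random((len(X), 2))
    resp /= resp.sum(axis=1, keepdims=True)
    for model in ALL_MODELS:
        params = m_step(X, resp, model)
        q_opt = expected_complete_loglik(X, resp, params)
        jittered = m_step(X, resp, model)
        jittered.means = jittered.means + rng.normal(0, 0.2, jittered.means.shape)
        assert q_opt >= expected_complete_loglik(X, resp, jittered)
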