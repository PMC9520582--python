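"""Shared test oracles: numerical M-step maximization, brute-force label
matching, and closed-form Gaussian log-likelihoods."""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize

from audioprofiles.mixture import (ALL_MODELS, MixtureParams, _log_densities,
                                   m_step)


def expected_complete_loglik(X: np.ndarray, resp: np.ndarray,
                             params: MixtureParams) -> float:
    """Q(theta) = sum_ig r_ig [log w_g + log N(x_i | mu_g, Sigma_g)]."""
    log_dens = _log_densities(np.asarray(X, float), params)
    return float(np.sum(resp * (np.log(params.weights) + log_dens)))


def _params_from_vector(model: str, theta: np.ndarray, k: int, d: int,
                        weights: np.ndarray) -> MixtureParams:
    """Unpack a free-parameter vector into MixtureParams for one family.

    Log-parameterizations keep variances positive; shapes use d-1 free logs
    with the last fixed so the shape determinant is 1.
    """
    pos = 0

    def take(m):
        nonlocal pos
        out = theta[pos:pos + m]
        pos += m
        return out

    means = take(k * d).reshape(k, d)

    def shape_from_logs(logs):  # d-1 free entries, det(A)=1
        full = np.append(logs, -np.sum(logs))
        return np.exp(full)

    if model == "EII":
        lam = np.exp(take(1)[0])
        sigma2 = np.full((k, d), lam)
    elif model == "VII":
        lam = np.exp(take(k))
        sigma2 = np.repeat(lam[:, None], d, axis=1)
    elif model == "EEI":
        diag = np.exp(take(d))
        sigma2 = np.repeat(diag[None], k, axis=0)
    elif model == "VEI":
        lam = np.exp(take(k))
        A = shape_from_logs(take(d - 1))
        sigma2 = lam[:, None] * A[None, :]
    elif model == "EVI":
        lam = np.exp(take(1)[0])
        A = np.stack([shape_from_logs(take(d - 1)) for _ in range(k)])
        sigma2 = lam * A
    elif model == "VVI":
        sigma2 = np.exp(take(k * d)).reshape(k, d)
    elif model in ("EEE", "VVV"):
        n_chol = d * (d + 1) // 2
        n_mats = 1 if model == "EEE" else k
        covs = []
        tril = np.tril_indices(d)
        for _ in range(n_mats):
            L = np.zeros((d, d))
            L[tril] = take(n_chol)
            L[np.diag_indices(d)] = np.exp(np.diag(L))  # positive diagonal
            covs.append(L @ L.T)
        cov = np.repeat(covs[0][None], k, axis=0) if model == "EEE" else np.stack(covs)
        return MixtureParams(model=model, weights=weights, means=means,
                             cov_full=cov)
    else:
        raise ValueError(model)
    return MixtureParams(model=model, weights=weights, means=means,
                         sigma2=sigma2)


def _n_free(model: str, k: int, d: int) -> int:
    base = k * d
    return base + {
        "EII": 1, "VII": k, "EEI": d, "VEI": k + d - 1,
        "EVI": 1 + k * (d - 1), "VVI": k * d,
        "EEE": d * (d + 1) // 2, "VVV": k * d * (d + 1) // 2,
    }[model]


def numeric_mstep_best_q(X: np.ndarray, resp: np.ndarray, model: str,
                         n_restarts: int = 4, seed: int = 0) -> float:
    """Best expected-complete-data log-likelihood found by direct numerical
    maximization over the family's free parameters (weights analytic)."""
    X = np.asarray(X, float)
    n, d = X.shape
    k = resp.shape[1]
    weights = resp.sum(axis=0) / n

    def neg_q(theta):
        try:
            p = _params_from_vector(model, theta, k, d, weights)
            return -expected_complete_loglik(X, resp, p)
        except (np.linalg.LinAlgError, FloatingPointError):
            return 1e12

    rng = np.random.default_rng(seed)
    starts = [np.concatenate([
        (resp.T @ X / resp.sum(axis=0)[:, None]).ravel(),
        np.zeros(_n_free(model, k, d) - k * d),
    ])]
    for _ in range(n_restarts):
        starts.append(starts[0] + rng.normal(0, 0.3, size=len(starts[0])))
    best = np.inf
    for s in starts:
        res = minimize(neg_q, s, method="Nelder-Mead",
                       options={"maxiter": 40000, "xatol": 1e-10,
                                "fatol": 1e-12})
        res = minimize(neg_q, res.x, method="Powell",
                       options={"maxiter": 40000, "xtol": 1e-12,
                                "ftol": 1e-14})
        best = min(best, res.fun)
    return -best


def closed_form_q(X: np.ndarray, resp: np.ndarray, model: str) -> float:
    """Q value achieved by the package's closed-form/alternating M step."""
    params = m_step(np.asarray(X, float), resp, model, variance_floor=1e-12)
    return expected_complete_loglik(X, resp, params)


def brute_force_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Maximal label-matched agreement over all permutations (k <= ~7)."""
    k = int(max(a.max(), b.max())) + 1
    table = np.zeros((k, k))
    np.add.at(table, (a, b), 1.0)
    best = 0.0
    for perm in itertools.permutations(range(k)):
        best = max(best, sum(table[i, perm[i]] for i in range(k)))
    return best / len(a)


def gaussian_mle_loglik(X: np.ndarray, model: str) -> float:
    """Closed-form maximized log-likelihood of a single Gaussian under each
    family's k=1 covariance constraint."""
    X = np.asarray(X, float)
    n, d = X.shape
    S = np.cov(X, rowvar=False, bias=True)
    var = np.var(X, axis=0)
    c = -0.5 * n * d * np.log(2 * np.pi)
    if model in ("EII", "VII"):
        s2 = float(var.mean())
        return c - 0.5 * n * (d * np.log(s2) + d)
    if model in ("EEI", "VEI", "EVI", "VVI"):
        return c - 0.5 * n * (np.sum(np.log(var)) + d)
    # EEE / VVV: full covariance MLE
    sign, logdet = np.linalg.slogdet(S)
    return c - 0.5 * n * (logdet + d)
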