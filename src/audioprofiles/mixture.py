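"""Finite Gaussian mixtures with constrained covariance parameterizations.

The covariance of cluster ``g`` is decomposed as ``Sigma_g = lambda_g * A_g``
where ``lambda_g`` is a scalar volume and ``A_g`` a shape matrix with
``det(A_g) = 1``.  Eight families are supported, following the established
model-based-clustering nomenclature (E = equal across clusters, V = variable;
the three letters code volume, shape and orientation):

========  ==========================================  cov-parameter count
EII       spherical, equal volume                      1
VII       spherical, variable volume                   k
EEI       diagonal, equal volume and shape             d
VEI       diagonal, variable volume, equal shape       k + (d - 1)
EVI       diagonal, equal volume, variable shape       1 + k (d - 1)
VVI       diagonal, fully free                         k d
EEE       one full covariance shared by all clusters   d (d + 1) / 2
VVV       full covariance per cluster                  k d (d + 1) / 2
========  ==========================================  ====================

Model selection uses ``BIC = 2 loglik - n_params ln(n)``, maximized.

The public surface is the scikit-learn style estimator
:class:`ConstrainedGaussianMixture` plus thin functional wrappers
(:func:`e_step`, :func:`m_step`, :func:`fit_em`, :func:`fit_grid`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import kmeans_plusplus

from ._seeds import derive_seed

DIAGONAL_MODELS = ("EII", "VII", "EEI", "VEI", "EVI", "VVI")
FULL_MODELS = ("EEE", "VVV")
ALL_MODELS = DIAGONAL_MODELS + FULL_MODELS

_LOG2PI = np.log(2.0 * np.pi)


class FitFailure(RuntimeError):
    """A fit became degenerate (component collapse or singular covariance)."""


def cov_param_count(model: str, k: int, d: int) -> int:
    """Number of free covariance parameters for a family at given (k, d)."""
    if model == "EII":
        return 1
    if model == "VII":
        return k
    if model == "EEI":
        return d
    if model == "VEI":
        return k + (d - 1)
    if model == "EVI":
        return 1 + k * (d - 1)
    if model == "VVI":
        return k * d
    if model == "EEE":
        return d * (d + 1) // 2
    if model == "VVV":
        return k * d * (d + 1) // 2
    raise ValueError(f"unknown covariance model {model!r}")


def n_free_params(model: str, k: int, d: int) -> int:
    """Total parameter count: mixing weights + means + covariance terms."""
    return (k - 1) + k * d + cov_param_count(model, k, d)


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class MixtureParams:
    """Parameters of one constrained Gaussian mixture.

    ``sigma2`` holds the composed per-cluster diagonal variances (k, d) for
    diagonal families; ``cov_full`` the full matrices (k, d, d) otherwise.
    ``volumes`` and ``shapes`` store the lambda/A factorization where the
    family constrains it.
    """

    model: str
    weights: np.ndarray          # (k,)
    means: np.ndarray            # (k, d)
    sigma2: np.ndarray | None = None      # (k, d) diagonal families
    cov_full: np.ndarray | None = None    # (k, d, d) EEE/VVV
    volumes: np.ndarray | None = None     # scalar-per-cluster lambda_g, shape (k,)
    shapes: np.ndarray | None = None      # (k, d) diagonal of A_g (det 1)

    @property
    def k(self) -> int:
        return self.means.shape[0]

    @property
    def d(self) -> int:
        return self.means.shape[1]

    def covariances(self) -> np.ndarray:
        """Per-cluster covariance matrices, shape (k, d, d)."""
        if self.cov_full is not None:
            return self.cov_full
        return np.stack([np.diag(s) for s in self.sigma2])


@dataclass
class MixtureFit:
    """One fitted mixture: parameters, fit diagnostics and scores."""

    k: int
    model: str
    params: MixtureParams | None
    loglik: float
    n_params: int
    bic: float
    converged: bool
    responsibilities: np.ndarray | None
    n_iter: int = 0
    seed: int | None = None
    failure_reason: str | None = None

    @property
    def labels(self) -> np.ndarray:
        return np.argmax(self.responsibilities, axis=1)

    def to_dict(self) -> dict:
        """JSON-serializable record of the fit (documented schema)."""
        p = self.params
        return {
            "model": self.model,
            "k": self.k,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "bic": self.bic,
            "converged": self.converged,
            "seed": self.seed,
            "weights": None if p is None else p.weights.tolist(),
            "means": None if p is None else p.means.tolist(),
            "volumes": None if p is None or p.volumes is None else p.volumes.tolist(),
            "shapes": None if p is None or p.shapes is None else p.shapes.tolist(),
            "covariances": None if p is None else p.covariances().tolist(),
            "failure_reason": self.failure_reason,
        }


# ---------------------------------------------------------------------------
# E step


def _log_gauss_diag(X: np.ndarray, means: np.ndarray, sigma2: np.ndarray) -> np.ndarray:
    """Log density of each row under each diagonal Gaussian. Returns (n, k)."""
    # (n, k): sum_j [(x_ij - mu_gj)^2 / s2_gj]
    prec = 1.0 / sigma2                                    # (k, d)
    log_det = np.sum(np.log(sigma2), axis=1)               # (k,)
    quad = (
        (X**2) @ prec.T
        - 2.0 * X @ (means * prec).T
        + np.sum(means**2 * prec, axis=1)
    )
    d = X.shape[1]
    return -0.5 * (d * _LOG2PI + log_det + quad)


def _log_gauss_full(
    X: np.ndarray, means: np.ndarray, covs: np.ndarray, shared: bool = False
) -> np.ndarray:
    d = X.shape[1]
    if shared:
        # one Cholesky whitening applied to data and means at once
        try:
            L = np.linalg.cholesky(covs[0])
        except np.linalg.LinAlgError as exc:
            raise FitFailure("singular shared covariance") from exc
        Y = solve_triangular(L, X.T, lower=True, check_finite=False).T
        M = solve_triangular(L, means.T, lower=True, check_finite=False).T
        log_det = 2.0 * np.sum(np.log(np.diag(L)))
        quad = (
            np.sum(Y**2, axis=1)[:, None]
            - 2.0 * Y @ M.T
            + np.sum(M**2, axis=1)
        )
        return -0.5 * (d * _LOG2PI + log_det + quad)
    out = np.empty((X.shape[0], means.shape[0]))
    for g in range(means.shape[0]):
        try:
            L = np.linalg.cholesky(covs[g])
        except np.linalg.LinAlgError as exc:
            raise FitFailure(f"singular covariance in component {g}") from exc
        diff = X - means[g]
        z = solve_triangular(L, diff.T, lower=True, check_finite=False)
        log_det = 2.0 * np.sum(np.log(np.diag(L)))
        out[:, g] = -0.5 * (d * _LOG2PI + log_det + np.sum(z**2, axis=0))
    return out


def _log_densities(X: np.ndarray, params: MixtureParams) -> np.ndarray:
    if params.cov_full is not None:
        return _log_gauss_full(
            X, params.means, params.cov_full, shared=(params.model == "EEE")
        )
    return _log_gauss_diag(X, params.means, params.sigma2)


def e_step(X: np.ndarray, params: MixtureParams) -> tuple[np.ndarray, float]:
    """Posterior responsibilities and total log-likelihood (log-sum-exp)."""
    X = np.asarray(X, dtype=float)
    log_dens = _log_densities(X, params)
    weighted = log_dens + np.log(params.weights)
    # inline log-sum-exp (hot path)
    m = weighted.max(axis=1)
    shifted = np.exp(weighted - m[:, None])
    total = shifted.sum(axis=1)
    norm = m + np.log(total)
    if not np.all(np.isfinite(norm)):
        raise FitFailure("non-finite mixture density")
    resp = shifted / total[:, None]
    return resp, float(norm.sum())


# ---------------------------------------------------------------------------
# M step

_COLLAPSE_FRAC = 1e-10
_SHAPE_TOL = 1e-8
_SHAPE_MAX_ITER = 200
# relative eigenvalue threshold below which a full covariance is treated as
# singular (numerical rank detection at sqrt machine precision)
_SINGULAR_RCOND = 1e-8


def _normalize_shape(diag: np.ndarray) -> tuple[float, np.ndarray]:
    """Factor a positive diagonal into (scale, unit-determinant shape)."""
    log_vol = np.mean(np.log(diag))
    lam = float(np.exp(log_vol))
    return lam, diag / lam


def m_step(
    X: np.ndarray,
    resp: np.ndarray,
    model: str,
    variance_floor: float = 1e-4,
) -> MixtureParams:
    """Constrained maximization of the expected complete-data log-likelihood.

    Closed form for every family except VEI, whose (lambda_g, A) pair is
    obtained by alternating updates to relative tolerance 1e-8.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    k = resp.shape[1]
    nk = resp.sum(axis=0)
    if np.any(nk < _COLLAPSE_FRAC * n):
        raise FitFailure("component collapse (empty cluster)")
    weights = nk / n
    means = (resp.T @ X) / nk[:, None]

    if model in FULL_MODELS:
        W = np.empty((k, d, d))
        for g in range(k):
            diff = X - means[g]
            W[g] = (resp[:, g][:, None] * diff).T @ diff
        if model == "EEE":
            sigma = W.sum(axis=0) / n
            cov = np.repeat(sigma[None], k, axis=0)
        else:  # VVV
            cov = W / nk[:, None, None]
        # A full covariance whose smallest eigenvalue is numerically zero
        # relative to the largest means the data are (locally) collinear.
        # Flooring it would inflate the likelihood along the degenerate
        # direction and invalidate BIC comparison, so the fit fails instead
        # (matching the reference model-based-clustering behaviour).
        n_check = 1 if model == "EEE" else k
        for g in range(n_check):
            eig = np.linalg.eigvalsh(cov[g])
            if eig[0] <= _SINGULAR_RCOND * eig[-1]:
                raise FitFailure(
                    f"numerically singular covariance in component {g}"
                )
        idx = np.arange(d)
        cov[:, idx, idx] = np.maximum(cov[:, idx, idx], variance_floor)
        return MixtureParams(model=model, weights=weights, means=means, cov_full=cov)

    # diagonal scatter, per cluster: W_g[j] = sum_i r_ig (x_ij - mu_gj)^2
    Wd = resp.T @ (X**2) - nk[:, None] * means**2
    Wd = np.maximum(Wd, 0.0)

    volumes = shapes = None
    if model == "EII":
        lam = float(Wd.sum() / (n * d))
        lam = max(lam, variance_floor)
        volumes = np.full(k, lam)
        shapes = np.ones((k, d))
        sigma2 = np.full((k, d), lam)
    elif model == "VII":
        lam = np.maximum(Wd.sum(axis=1) / (nk * d), variance_floor)
        volumes = lam
        shapes = np.ones((k, d))
        sigma2 = np.repeat(lam[:, None], d, axis=1)
    elif model == "EEI":
        diag = np.maximum(Wd.sum(axis=0) / n, variance_floor)
        lam, A = _normalize_shape(diag)
        volumes = np.full(k, lam)
        shapes = np.repeat(A[None], k, axis=0)
        sigma2 = np.repeat(diag[None], k, axis=0)
    elif model == "VVI":
        sigma2 = np.maximum(Wd / nk[:, None], variance_floor)
        volumes = np.exp(np.mean(np.log(sigma2), axis=1))
        shapes = sigma2 / volumes[:, None]
    elif model == "EVI":
        # A_g = diag(W_g)/|diag(W_g)|^{1/d};  lambda = sum_g |diag(W_g)|^{1/d} / n
        Wd_f = np.maximum(Wd, variance_floor * nk[:, None])
        dets_root = np.exp(np.mean(np.log(Wd_f), axis=1))   # |W_g|^{1/d}
        A = Wd_f / dets_root[:, None]
        lam = max(float(dets_root.sum() / n), variance_floor)
        volumes = np.full(k, lam)
        shapes = A
        sigma2 = np.maximum(lam * A, variance_floor)
    elif model == "VEI":
        # alternate: lambda_g = tr(W_g A^-1) / (nk_g d);  A ∝ diag(sum_g W_g/lambda_g)
        A = np.ones(d)
        lam = np.maximum(Wd.sum(axis=1) / (nk * d), variance_floor)
        for _ in range(_SHAPE_MAX_ITER):
            lam_old, A_old = lam.copy(), A.copy()
            B = (Wd / lam[:, None]).sum(axis=0)
            B = np.maximum(B, variance_floor)
            A = B / np.exp(np.mean(np.log(B)))
            lam = np.maximum((Wd / A[None, :]).sum(axis=1) / (nk * d), variance_floor)
            if (
                np.max(np.abs(lam - lam_old) / np.maximum(lam_old, 1e-300)) < _SHAPE_TOL
                and np.max(np.abs(A - A_old) / np.maximum(A_old, 1e-300)) < _SHAPE_TOL
            ):
                break
        volumes = lam
        shapes = np.repeat(A[None], k, axis=0)
        sigma2 = np.maximum(lam[:, None] * A[None, :], variance_floor)
    else:
        raise ValueError(f"unknown covariance model {model!r}")

    return MixtureParams(
        model=model, weights=weights, means=means,
        sigma2=sigma2, volumes=volumes, shapes=shapes,
    )


# ---------------------------------------------------------------------------
# EM driver


def _init_responsibilities(X: np.ndarray, k: int, seed: int) -> np.ndarray:
    """k-means++-style hard partition as one-hot responsibilities.

    Rows are visited in a canonical (lexicographic) order before seeding so
    that the chosen partition depends on the data content only, making the
    fitted log-likelihood invariant to row shuffles for a fixed seed.
    """
    order = np.lexsort(X.T[::-1])
    centers, _ = kmeans_plusplus(X[order], n_clusters=k, random_state=seed)
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    hard = np.argmin(d2, axis=1)
    resp = np.zeros((X.shape[0], k))
    resp[np.arange(X.shape[0]), hard] = 1.0
    # every center is near at least its own seed point, but guard regardless
    for g in range(k):
        if resp[:, g].sum() == 0:
            resp[np.argmin(d2[:, g])] = 0.0
            resp[np.argmin(d2[:, g]), g] = 1.0
    return resp


def _run_em(
    X: np.ndarray,
    k: int,
    model: str,
    seed: int,
    max_iter: int,
    tol: float,
    variance_floor: float,
    trace: list | None = None,
) -> tuple[MixtureParams, np.ndarray, float, int]:
    resp = _init_responsibilities(X, k, seed)
    params = m_step(X, resp, model, variance_floor)
    loglik = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        resp, new_loglik = e_step(X, params)
        if trace is not None:
            trace.append(new_loglik)
        if np.isfinite(loglik) and abs(new_loglik - loglik) <= tol * abs(loglik):
            loglik = new_loglik
            break
        loglik = new_loglik
        params = m_step(X, resp, model, variance_floor)
    return params, resp, loglik, n_iter


class ConstrainedGaussianMixture(ClusterMixin, BaseEstimator):
    """EM estimator for Gaussian mixtures with a constrained covariance family.

    Parameters
    ----------
    n_components : int
        Number of mixture components (clusters) ``k``.
    covariance_type : str
        One of ``EII, VII, EEI, VEI, EVI, VVI, EEE, VVV``.
    n_init : int
        Number of k-means++-seeded restarts; the run with the highest
        log-likelihood is kept.
    max_iter, tol : EM stopping rule (relative log-likelihood change).
    variance_floor : float
        Lower bound applied to every covariance diagonal (default 1e-4,
        i.e. an SD of 1% of the min–max range), guarding against singular
        components and point-mass spikes on integer-coded features.
    random_state : int
        Seed for the initialization streams.

    Attributes (after ``fit``)
    --------------------------
    weights_, means_, covariances_, volumes_, shapes_ : parameters
    loglik_, n_params_, bic_ : fit scores, ``bic_ = 2 loglik - p ln n``
    responsibilities_, labels_, converged_, n_iter_, failure_reason_
    """

    def __init__(
        self,
        n_components: int = 2,
        covariance_type: str = "VEI",
        n_init: int = 3,
        max_iter: int = 500,
        tol: float = 1e-6,
        variance_floor: float = 1e-4,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.covariance_type = covariance_type
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.variance_floor = variance_floor
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, d = X.shape
        k = int(self.n_components)
        if k < 1 or n <= k:
            raise ValueError(f"need n > k >= 1, got n={n}, k={k}")
        if self.covariance_type not in ALL_MODELS:
            raise ValueError(f"unknown covariance model {self.covariance_type!r}")

        best = None
        reasons = []
        for i in range(int(self.n_init)):
            seed = derive_seed(int(self.random_state or 0), i)
            try:
                params, resp, loglik, n_iter = _run_em(
                    X, k, self.covariance_type, seed,
                    int(self.max_iter), float(self.tol), float(self.variance_floor),
                )
            except (FitFailure, np.linalg.LinAlgError) as exc:
                reasons.append(str(exc))
                continue
            if best is None or loglik > best[2]:
                best = (params, resp, loglik, n_iter)

        self.n_params_ = n_free_params(self.covariance_type, k, d)
        if best is None:
            self.converged_ = False
            self.failure_reason_ = "; ".join(reasons) or "no successful initialization"
            self.loglik_ = -np.inf
            self.bic_ = -np.inf
            self.responsibilities_ = None
            self.labels_ = None
            return self

        params, resp, loglik, n_iter = best
        self.weights_ = params.weights
        self.means_ = params.means
        self.volumes_ = params.volumes
        self.shapes_ = params.shapes
        self.covariances_ = params.covariances()
        self._params = params
        self.loglik_ = loglik
        self.bic_ = 2.0 * loglik - self.n_params_ * np.log(n)
        self.responsibilities_ = resp
        self.labels_ = np.argmax(resp, axis=1)
        self.n_iter_ = n_iter
        self.converged_ = n_iter < int(self.max_iter)
        self.failure_reason_ = None
        return self

    def predict_proba(self, X):
        resp, _ = e_step(np.asarray(X, dtype=float), self._params)
        return resp

    def predict(self, X):
        return np.argmax(self.predict_proba(X), axis=1)

    def score_samples(self, X):
        X = np.asarray(X, dtype=float)
        w = _log_densities(X, self._params) + np.log(self._params.weights)
        m = w.max(axis=1)
        return m + np.log(np.exp(w - m[:, None]).sum(axis=1))

    def score(self, X, y=None):
        return float(np.sum(self.score_samples(X)))

    def to_fit(self) -> MixtureFit:
        """Snapshot as a :class:`MixtureFit` record."""
        return MixtureFit(
            k=int(self.n_components),
            model=self.covariance_type,
            params=getattr(self, "_params", None),
            loglik=self.loglik_,
            n_params=self.n_params_,
            bic=self.bic_,
            converged=self.converged_,
            responsibilities=self.responsibilities_,
            n_iter=getattr(self, "n_iter_", 0),
            seed=self.random_state,
            failure_reason=self.failure_reason_,
        )


def fit_em(
    X,
    k: int,
    model: str,
    seed: int = 0,
    n_init: int = 3,
    max_iter: int = 500,
    tol: float = 1e-6,
    variance_floor: float = 1e-4,
) -> MixtureFit:
    """Fit one (k, family) mixture; best of ``n_init`` seeded restarts."""
    est = ConstrainedGaussianMixture(
        n_components=k, covariance_type=model, n_init=n_init,
        max_iter=max_iter, tol=tol, variance_floor=variance_floor,
        random_state=seed,
    ).fit(X)
    return est.to_fit()


@dataclass
class FitGridResult:
    """Every (k, model) fit of a BIC model search, plus the best entry."""

    table: pd.DataFrame
    fits: dict = field(repr=False, default_factory=dict)

    @property
    def best(self) -> MixtureFit:
        ok = self.table[self.table["converged"]]
        if ok.empty:
            raise FitFailure("no converged fit in the grid")
        row = ok.loc[ok["bic"].idxmax()]
        return self.fits[(int(row["k"]), row["model"])]


def fit_grid(
    X,
    k_range: Iterable[int] = range(2, 31),
    models: Sequence[str] = ALL_MODELS,
    seed: int = 0,
    n_init: int = 3,
    max_iter: int = 500,
    tol: float = 1e-6,
    keep_responsibilities: bool = True,
) -> FitGridResult:
    """Fit every (k, family) pair and score by BIC.

    Failed fits are recorded with their reason and excluded from best-entry
    selection. Raises :class:`FitFailure` if nothing converges.
    """
    X = np.asarray(X, dtype=float)
    k_range = list(k_range)
    if max(k_range) >= X.shape[0]:
        raise ValueError("max(k_range) must be < n")
    rows = []
    fits: dict = {}
    for k in k_range:
        for model in models:
            fit = fit_em(X, k, model, seed=derive_seed(seed, k, models.index(model)),
                         n_init=n_init, max_iter=max_iter, tol=tol)
            if not keep_responsibilities and fit.converged:
                fit.responsibilities = None
            fits[(k, model)] = fit
            rows.append({
                "k": k, "model": model, "bic": fit.bic, "loglik": fit.loglik,
                "n_params": fit.n_params, "converged": fit.converged,
                "failure_reason": fit.failure_reason,
            })
    table = pd.DataFrame(rows)
    result = FitGridResult(table=table, fits=fits)
    result.best  # raises if zero converged fits
    return result
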