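"""Multiple imputation by chained equations (MICE) with predictive mean matching.

Each of the ``m`` chains starts from random draws out of the observed
marginals and then cycles through the features, regressing each feature's
observed values on all others and filling its missing cells by predictive
mean matching (PMM): the imputed value is the observed value of one of the
``donors`` rows whose regression prediction is nearest. PMM keeps every
imputation inside the observed support, so ordinal codes stay valid without
extra treatment; an explicit rounding/clipping hook is applied when ordinal
ranges are supplied (relevant if the matrix is in original units).

Observed cells are never altered and are identical across the m completed
datasets; a fixed seed reproduces the result bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import rng_from


@dataclass
class ImputationConfig:
    """Chained-equations settings: ``m`` completed datasets, chain length,
    PMM donor count and the master seed for the per-chain streams."""

    m: int = 20
    n_chain_iterations: int = 10
    donors: int = 5
    seed: int = 0
    ordinal_ranges: dict | None = None
    #: passive (derived) columns: {target: (coeffs {column: weight}, intercept)}.
    #: Targets are deterministic affine functions of other columns; their
    #: missing cells are recomputed from the current completed values instead
    #: of being regression-imputed, so definitional identities (for example
    #: an air-bone gap being the difference of two pure-tone averages) hold
    #: in every completed dataset. Observed cells are still never altered.
    passive: dict | None = None

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.donors < 1:
            raise ValueError("donors must be >= 1")
        if self.n_chain_iterations < 1:
            raise ValueError("n_chain_iterations must be >= 1")


@dataclass
class CompletedSet:
    """The ``m`` completed matrices plus the mask of cells that were imputed."""

    datasets: list[pd.DataFrame]
    imputed_mask: pd.DataFrame = field(repr=False, default=None)

    @property
    def m(self) -> int:
        return len(self.datasets)

    def matrices(self) -> list[np.ndarray]:
        return [d.to_numpy(dtype=float) for d in self.datasets]


def _regress_predict(
    X: np.ndarray, j: int, obs: np.ndarray, predictors: np.ndarray
) -> np.ndarray:
    """OLS of column j on the predictor columns (with intercept); predictions
    for every row."""
    others = predictors[predictors != j]
    design = np.column_stack([np.ones(X.shape[0]), X[:, others]])
    coef, *_ = np.linalg.lstsq(design[obs], X[obs, j], rcond=None)
    return design @ coef


def _pmm_draw(
    pred_obs: np.ndarray,
    y_obs: np.ndarray,
    pred_mis: np.ndarray,
    donors: int,
    rng: np.random.Generator,
) -> np.ndarray:
    k = min(donors, len(y_obs))
    dist = np.abs(pred_mis[:, None] - pred_obs[None, :])
    nearest = np.argpartition(dist, k - 1, axis=1)[:, :k]
    pick = rng.integers(0, k, size=len(pred_mis))
    return y_obs[nearest[np.arange(len(pred_mis)), pick]]


def mice_impute(matrix, config: ImputationConfig | None = None) -> CompletedSet:
    """Produce ``config.m`` completed datasets from a matrix with missing cells.

    ``matrix`` may be a DataFrame, ndarray or a ``ScaledFeatureMatrix``.
    Raises ``ValueError`` naming any feature that is entirely missing, and
    when the observed support is too thin to regress on (no fully observed
    feature and some feature with fewer than 10 observed values).
    """
    config = config or ImputationConfig()
    if hasattr(matrix, "values") and hasattr(matrix, "bounds"):  # ScaledFeatureMatrix
        matrix = matrix.values
    frame = pd.DataFrame(matrix)
    X0 = frame.to_numpy(dtype=float)
    n, d = X0.shape
    miss = np.isnan(X0)

    fully_missing = miss.all(axis=0)
    if fully_missing.any():
        names = [str(frame.columns[j]) for j in np.flatnonzero(fully_missing)]
        raise ValueError(f"feature(s) entirely missing: {', '.join(names)}")
    obs_counts = (~miss).sum(axis=0)
    if not ((obs_counts == n).any() or (obs_counts >= 10).all()):
        raise ValueError(
            "need at least one fully observed feature or >= 10 observed values per feature"
        )

    imputed_mask = pd.DataFrame(miss, index=frame.index, columns=frame.columns)
    if not miss.any():
        return CompletedSet(
            datasets=[frame.copy() for _ in range(config.m)], imputed_mask=imputed_mask
        )

    ordinal_cols = {}
    if config.ordinal_ranges:
        for name, (lo, hi) in config.ordinal_ranges.items():
            if name in frame.columns:
                ordinal_cols[frame.columns.get_loc(name)] = (lo, hi)

    # passive (derived) columns: resolved to indices, recomputed not regressed
    passive_cols: dict[int, tuple[dict[int, float], float]] = {}
    if config.passive:
        for target, (coeffs, intercept) in config.passive.items():
            t = frame.columns.get_loc(target) if target in frame.columns else int(target)
            passive_cols[t] = (
                {
                    (frame.columns.get_loc(c) if c in frame.columns else int(c)): w
                    for c, w in coeffs.items()
                },
                float(intercept),
            )

    def apply_passive(X: np.ndarray) -> None:
        for t, (coeffs, intercept) in passive_cols.items():
            rows = miss[:, t]
            if rows.any():
                val = np.full(rows.sum(), intercept)
                for c, w in coeffs.items():
                    val += w * X[rows, c]
                X[rows, t] = val

    predictors = np.array(
        [j for j in range(d) if j not in passive_cols], dtype=int
    )
    cols_with_missing = np.flatnonzero(miss.any(axis=0))
    active_cols = [j for j in cols_with_missing if j not in passive_cols]
    datasets = []
    for c in range(config.m):
        rng = rng_from(config.seed, 10, c)
        X = X0.copy()
        for j in active_cols:  # initialize from observed marginals
            pool = X0[~miss[:, j], j]
            X[miss[:, j], j] = rng.choice(pool, size=miss[:, j].sum(), replace=True)
        apply_passive(X)
        for _ in range(config.n_chain_iterations):
            for j in active_cols:
                obs = ~miss[:, j]
                pred = _regress_predict(X, j, obs, predictors)
                X[miss[:, j], j] = _pmm_draw(
                    pred[obs], X0[obs, j], pred[miss[:, j]], config.donors, rng
                )
                if j in ordinal_cols:
                    lo, hi = ordinal_cols[j]
                    X[miss[:, j], j] = np.clip(np.round(X[miss[:, j], j]), lo, hi)
            apply_passive(X)
        datasets.append(pd.DataFrame(X, index=frame.index, columns=frame.columns))
    return CompletedSet(datasets=datasets, imputed_mask=imputed_mask)
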