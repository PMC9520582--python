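"""Robust selection of the mixture structure (k, covariance family).

The cohort is subsampled B times (without replacement, 95% of rows by
default — subsampling rather than resampling, so duplicates cannot pose as
mini-clusters). Each subsample is multiply imputed into m completed
datasets; a full BIC grid over (k, family) is fitted to each; the m best
entries are reduced to one candidate per subsample by majority vote, and
the final structure is the majority over the B candidates. Ties break
toward smaller k, then fewer covariance parameters.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._seeds import derive_seed, rng_from
from .impute import ImputationConfig, mice_impute
from .mixture import ALL_MODELS, FitFailure, cov_param_count, fit_grid


@dataclass
class SelectionConfig:
    """Subsampling/imputation/grid settings for robust structure selection.

    Study-scale defaults are B=1000 subsamples at 95% with m=20 imputations
    over k=2..30 and all 8 families; ``desk_scale()`` gives a preset sized
    for interactive use and testing.
    """

    B: int = 1000
    subsample_frac: float = 0.95
    m: int = 20
    k_range: Sequence[int] = tuple(range(2, 31))
    models: Sequence[str] = ALL_MODELS
    seed: int = 0
    n_init: int = 3
    imputation_iterations: int = 10
    #: passive-imputation spec forwarded to the imputation engine, so that
    #: definitional identities among derived features hold in every
    #: completed dataset (see ``features.identity_constraints``)
    passive: dict | None = None

    def __post_init__(self):
        if not (0.0 < self.subsample_frac <= 1.0):
            raise ValueError("subsample_frac must lie in (0, 1]")
        if self.B < 1 or self.m < 1:
            raise ValueError("B and m must be >= 1")

    @classmethod
    def desk_scale(cls, seed: int = 0, **overrides) -> "SelectionConfig":
        """Small preset (B=30, m=3, k=2..10, single EM start) for desk runs."""
        defaults = dict(
            B=30, m=3, k_range=tuple(range(2, 11)), seed=seed, n_init=1,
            imputation_iterations=5,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class ModelChoice:
    """Final (k, family) choice with per-subsample candidates and tallies."""

    k: int
    model: str
    candidates: list[tuple[int, str]] = field(default_factory=list)
    candidate_tally: Counter = field(default_factory=Counter)
    n_failed_subsamples: int = 0

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "model": self.model,
            "candidates": [list(c) for c in self.candidates],
            "candidate_tally": {f"{k}:{m}": c for (k, m), c in self.candidate_tally.items()},
            "n_failed_subsamples": self.n_failed_subsamples,
        }


def majority_vote(items: Sequence[tuple[int, str]], d: int | None = None) -> tuple[int, str]:
    """Modal (k, family); ties break by smaller k, then fewer covariance
    parameters (parsimony). ``d`` is the feature dimension used in the
    parameter-count tie-break (defaults to 20)."""
    if not items:
        raise ValueError("majority_vote of an empty list")
    d = 20 if d is None else d
    tally = Counter(tuple(it) for it in items)
    return min(
        tally,
        key=lambda km: (-tally[km], km[0], cov_param_count(km[1], km[0], d)),
    )


def run_robust_selection(matrix, config: SelectionConfig) -> ModelChoice:
    """Two-level majority vote over subsampled, imputed BIC grid searches.

    ``matrix`` is an n x d feature matrix (DataFrame or ndarray) that may
    contain missing cells. With B=1 and m=1 and no missing data the
    procedure reduces exactly to a single grid search's best entry.
    """
    frame = pd.DataFrame(matrix)
    n, d = frame.shape
    n_sub = int(np.floor(config.subsample_frac * n))
    if n_sub <= max(config.k_range):
        raise ValueError("subsample size must exceed max(k_range)")

    candidates: list[tuple[int, str]] = []
    n_failed = 0
    for b in range(config.B):
        rng = rng_from(config.seed, 100, b)
        rows = rng.choice(n, size=n_sub, replace=False)
        sub = frame.iloc[rows]
        completed = mice_impute(
            sub,
            ImputationConfig(
                m=config.m,
                n_chain_iterations=config.imputation_iterations,
                seed=derive_seed(config.seed, 101, b),
                passive=config.passive,
            ),
        )
        per_dataset: list[tuple[int, str]] = []
        for j, ds in enumerate(completed.datasets):
            try:
                grid = fit_grid(
                    ds.to_numpy(dtype=float),
                    k_range=config.k_range,
                    models=list(config.models),
                    seed=derive_seed(config.seed, 102, b, j),
                    n_init=config.n_init,
                    keep_responsibilities=False,
                )
            except FitFailure:
                continue
            best = grid.best
            per_dataset.append((best.k, best.model))
        if not per_dataset:
            n_failed += 1
            continue
        candidates.append(majority_vote(per_dataset, d=d))

    if not candidates:
        raise FitFailure("every subsample failed during robust selection")
    k, model = majority_vote(candidates, d=d)
    return ModelChoice(
        k=k,
        model=model,
        candidates=candidates,
        candidate_tally=Counter(candidates),
        n_failed_subsamples=n_failed,
    )
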