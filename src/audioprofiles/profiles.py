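"""Consensus auditory-profile generation from multiply-imputed clusterings.

The selected mixture structure is fitted to each of the m completed datasets
of the full cohort, giving m candidate clustering solutions. Pairwise
solution overlap is the fraction of patients allocated identically after the
best one-to-one label matching (Hungarian assignment on the co-assignment
contingency table). The consensus solution is the candidate with the highest
mean overlap against the others — the one least driven by imputed values.

Profiles are then renumbered 1..k by ascending median speech-in-noise SRT
(GOESA), so higher numbers mean stronger impairment, and summarized by
per-feature descriptive ranges in original units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from ._seeds import derive_seed
from .mixture import MixtureFit, fit_em


@dataclass
class ClusteringSolution:
    """Hard assignments + posterior responsibilities of one mixture fit."""

    assignments: np.ndarray            # (n,) labels in 0..k-1
    responsibilities: np.ndarray       # (n, k)
    fit: MixtureFit | None = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return len(self.assignments)

    @property
    def k(self) -> int:
        return self.responsibilities.shape[1]

    @classmethod
    def from_fit(cls, fit: MixtureFit) -> "ClusteringSolution":
        return cls(
            assignments=np.argmax(fit.responsibilities, axis=1),
            responsibilities=fit.responsibilities,
            fit=fit,
        )


def solution_similarity(a: ClusteringSolution, b: ClusteringSolution) -> float:
    """Matched-agreement overlap between two solutions, in [0, 1].

    Builds the k x k contingency table of co-assignments and maximizes the
    total agreement over one-to-one label matchings (Hungarian assignment);
    the similarity is the matched agreement count divided by n. Components
    that collapsed (empty clusters) simply contribute empty rows/columns.
    """
    if a.n != b.n:
        raise ValueError("solutions must cover the same patients")
    k = max(a.k, b.k)
    table = np.zeros((k, k))
    np.add.at(table, (a.assignments, b.assignments), 1.0)
    rows, cols = linear_sum_assignment(-table)
    return float(table[rows, cols].sum() / a.n)


def select_consensus(
    solutions: list[ClusteringSolution],
) -> tuple[int, np.ndarray]:
    """Index of the solution with the highest mean overlap with the others.

    Returns ``(index, mean_similarities)``. Ties go to the lowest index.
    A single solution is returned trivially with mean similarity 1.0 (by
    convention, since there is nothing to compare against).
    """
    if not solutions:
        raise ValueError("no solutions to select from")
    if len(solutions) == 1:
        return 0, np.array([1.0])
    m = len(solutions)
    sims = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            sims[i, j] = sims[j, i] = solution_similarity(solutions[i], solutions[j])
    means = sims.sum(axis=1) / (m - 1)
    return int(np.argmax(means)), means


@dataclass
class ProfileSet:
    """Consensus profiles renumbered by ascending median GOESA SRT.

    ``assignments`` holds per-patient profile numbers 1..k; ``sizes`` the
    per-profile patient counts; ``summaries`` a per-profile, per-feature
    table of median, IQR bounds, min and max in original units.
    """

    assignments: np.ndarray
    sizes: dict[int, int]
    summaries: pd.DataFrame
    consensus_index: int = 0
    mean_similarity: float = float("nan")
    max_similarity: float = float("nan")
    similarity_means: np.ndarray | None = None

    @property
    def k(self) -> int:
        return len(self.sizes)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "consensus_index": self.consensus_index,
            "mean_similarity": self.mean_similarity,
            "max_similarity": self.max_similarity,
            "sizes": {int(p): int(s) for p, s in self.sizes.items()},
            "assignments": self.assignments.tolist(),
            "summaries": self.summaries.reset_index().to_dict(orient="records"),
        }


def summarize_profiles(
    consensus: ClusteringSolution,
    features: pd.DataFrame,
    srt_column: str = "goesa_srt",
) -> ProfileSet:
    """Renumber clusters by ascending median SRT and summarize each profile.

    ``features`` must be in original units and aligned row-wise with the
    consensus assignments. Equal median SRTs are broken by descending
    profile size; empty clusters keep a number, size 0 and no summaries.
    """
    labels = consensus.assignments
    k = consensus.k
    n = len(labels)
    if len(features) != n:
        raise ValueError("features and assignments must align")

    med_srt = np.full(k, np.inf)
    counts = np.zeros(k, dtype=int)
    for g in range(k):
        in_g = labels == g
        counts[g] = in_g.sum()
        if counts[g]:
            med_srt[g] = np.nanmedian(features[srt_column].to_numpy(dtype=float)[in_g])
    order = sorted(range(k), key=lambda g: (med_srt[g], -counts[g]))
    renumber = {g: i + 1 for i, g in enumerate(order)}
    new_labels = np.array([renumber[g] for g in labels])

    rows = []
    feat_cols = [c for c in features.columns if c != "true_label"]
    for g in order:
        p = renumber[g]
        sub = features.loc[labels == g, feat_cols]
        for c in feat_cols:
            v = sub[c].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            if len(v) == 0:
                continue
            rows.append({
                "profile": p, "feature": c,
                "median": float(np.median(v)),
                "q1": float(np.percentile(v, 25)),
                "q3": float(np.percentile(v, 75)),
                "min": float(np.min(v)), "max": float(np.max(v)),
                "n": int(len(v)),
            })
    summaries = pd.DataFrame(rows)
    sizes = {renumber[g]: int(counts[g]) for g in range(k)}
    return ProfileSet(assignments=new_labels, sizes=dict(sorted(sizes.items())),
                      summaries=summaries)


def generate_profiles(
    matrix,
    k: int,
    model: str,
    features: pd.DataFrame,
    m: int = 20,
    seed: int = 0,
    n_init: int = 3,
    imputation_iterations: int = 10,
    passive: dict | None = None,
) -> ProfileSet:
    """Full profile-generation stage on the original (unsubsampled) cohort.

    Imputes ``m`` completed datasets from the scaled matrix, fits the
    selected (k, family) mixture to each, selects the consensus solution by
    maximal mean overlap, and emits profiles summarized on ``features``
    (original units).
    """
    from .impute import ImputationConfig, mice_impute  # local to avoid cycle

    completed = mice_impute(
        matrix,
        ImputationConfig(m=m, n_chain_iterations=imputation_iterations,
                         seed=derive_seed(seed, 200), passive=passive),
    )
    solutions = []
    # the same EM initialization stream is used for every completed dataset,
    # so differences between the m solutions reflect imputation variability
    # rather than initialization variability
    for ds in completed.datasets:
        fit = fit_em(ds.to_numpy(dtype=float), k, model,
                     seed=derive_seed(seed, 201), n_init=n_init)
        solutions.append(ClusteringSolution.from_fit(fit))
    idx, means = select_consensus(solutions)
    profile_set = summarize_profiles(solutions[idx], features)
    profile_set.consensus_index = idx
    profile_set.mean_similarity = float(np.mean(means)) if len(means) > 1 else 1.0
    profile_set.max_similarity = float(means[idx])
    profile_set.similarity_means = means
    return profile_set
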