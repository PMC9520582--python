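"""Random-forest classification of patients into auditory profiles.

Profiles learned on the full 20-feature battery are predicted from a reduced
12-feature set (ACALOS, GOESA, air-conduction audiogram summaries, age) so
new patients can be stratified after a short clinical test session.

Four strategies are compared: a plain multiclass forest and three
binarizations — one-vs-all (OVA, k forests with cost-sensitive class
weights), one-vs-one (OVO, k(k-1)/2 pairwise forests with voting) and their
combination OVAOVO (OVA first; if several OVA learners claim the patient,
an OVO vote among the claimants decides). Class imbalance is addressed by
upsampling every profile to the size of the largest one, adding zero-mean
Gaussian noise (1 within-profile SD per feature) to the duplicated rows.
The forests' ``mtry`` (max_features) is tuned by cross-validation against a
configurable metric: Cohen's kappa, balanced accuracy, macro F1 or macro
area under the precision-recall curve.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, confusion_matrix
from sklearn.model_selection import LeaveOneOut, StratifiedKFold, train_test_split

from ._seeds import derive_seed, rng_from
from .features import ORDINAL_RANGES

STRATEGIES = ("multiclass", "OVA", "OVO", "OVAOVO")
METRICS = ("kappa", "balanced_accuracy", "f1", "auprc")
CV_SCHEMES = ("loocv", "repcv")


# ---------------------------------------------------------------------------
# metrics


@dataclass
class MetricResult:
    """One evaluation-metric value with its per-class breakdown.

    For kappa the observed (``p_o``) and chance (``p_e``) agreement are
    reported; classes for which a component of the metric is undefined
    (e.g. never predicted) are listed in ``excluded`` and left out of the
    macro average.
    """

    metric: str
    score: float
    p_o: float | None = None
    p_e: float | None = None
    per_class: dict = field(default_factory=dict)
    excluded: list = field(default_factory=list)


def _binary_rates(y_true, y_pred, cls):
    t = np.asarray(y_true) == cls
    p = np.asarray(y_pred) == cls
    tp = np.sum(t & p)
    fn = np.sum(t & ~p)
    fp = np.sum(~t & p)
    tn = np.sum(~t & ~p)
    return tp, fn, fp, tn


def compute_metric(y_true, y_pred=None, metric: str = "kappa", scores=None,
                   classes=None) -> MetricResult:
    """Evaluate predictions (or score rankings, for AUPRC) against truth.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the marginal products;
    balanced accuracy = mean over classes of (sensitivity + specificity)/2;
    F1 = macro-averaged 2PR/(P+R); AUPRC = macro-averaged step-wise area
    under the one-vs-rest precision-recall curve (requires ``scores`` as an
    (n, k) column-per-class matrix).
    """
    y_true = np.asarray(y_true)
    if classes is None:
        pool = y_true if y_pred is None else np.concatenate([y_true, np.asarray(y_pred)])
        classes = np.unique(pool)

    if metric == "auprc":
        if scores is None:
            raise ValueError("AUPRC needs per-class scores")
        scores = np.asarray(scores, dtype=float)
        per, excluded = {}, []
        for j, c in enumerate(classes):
            pos = (y_true == c).astype(int)
            if pos.sum() == 0:
                excluded.append(c)
                continue
            per[c] = float(average_precision_score(pos, scores[:, j]))
        return MetricResult(metric="auprc", score=float(np.mean(list(per.values()))),
                            per_class=per, excluded=excluded)

    y_pred = np.asarray(y_pred)
    n = len(y_true)
    if metric == "kappa":
        cm = confusion_matrix(y_true, y_pred, labels=classes)
        p_o = np.trace(cm) / n
        p_e = float(np.sum(cm.sum(axis=0) * cm.sum(axis=1)) / n**2)
        score = 1.0 if p_e >= 1.0 else (p_o - p_e) / (1.0 - p_e)
        return MetricResult(metric="kappa", score=float(score), p_o=float(p_o), p_e=p_e)

    per, excluded = {}, []
    for c in classes:
        tp, fn, fp, tn = _binary_rates(y_true, y_pred, c)
        if metric == "balanced_accuracy":
            if tp + fn == 0 or fp + tn == 0:
                excluded.append(c)
                continue
            sens = tp / (tp + fn)
            spec = tn / (tn + fp)
            per[c] = (sens + spec) / 2.0
        elif metric == "f1":
            if tp + fn == 0 or tp + fp == 0:
                excluded.append(c)  # no truth or no predictions of this class
                continue
            prec = tp / (tp + fp)
            rec = tp / (tp + fn)
            per[c] = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
        else:
            raise ValueError(f"unknown metric {metric!r}")
    score = float(np.mean(list(per.values()))) if per else float("nan")
    return MetricResult(metric=metric, score=score, per_class=per, excluded=excluded)


# ---------------------------------------------------------------------------
# data handling


def split_train_test(X: pd.DataFrame, y, train_frac: float = 0.75, seed: int = 0):
    """Stratified train/test split; profile singletons all go to train.

    Returns ``(X_train, X_test, y_train, y_test)``; the two index sets are
    disjoint and their union is the input.
    """
    if len(X) == 0:
        raise ValueError("empty input")
    y = np.asarray(y)
    counts = pd.Series(y).value_counts()
    singleton_classes = set(counts.index[counts < 2])
    if singleton_classes:
        warnings.warn(
            f"profiles with a single member kept entirely in train: {sorted(singleton_classes)}",
            stacklevel=2,
        )
    movable = ~pd.Series(y).isin(singleton_classes).to_numpy()
    Xm, ym = X.iloc[movable], y[movable]
    X_tr, X_te, y_tr, y_te = train_test_split(
        Xm, ym, train_size=train_frac, stratify=ym, random_state=derive_seed(seed, 0)
    )
    if singleton_classes:
        X_tr = pd.concat([X_tr, X.iloc[~movable]])
        y_tr = np.concatenate([y_tr, y[~movable]])
    return X_tr, X_te, y_tr, y_te


def upsample_gaussian(
    X: pd.DataFrame,
    y,
    target: int | None = None,
    noise_scale: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Pad minority classes to ``target`` (default: largest class size).

    Padded rows are drawn uniformly with replacement from the class and
    perturbed with zero-mean Gaussian noise of SD ``noise_scale`` times the
    within-class per-feature SD (global per-feature SD where the class SD is
    zero or the class has one member). Ordinal features are rounded and
    clipped to their coded range; original rows are returned unchanged.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    target = int(counts.max()) if target is None else int(target)
    rng = rng_from(seed, 4)
    global_sd = X.std(axis=0, ddof=0).to_numpy(dtype=float)

    parts_X, parts_y = [X], [y]
    for c, cnt in zip(classes, counts):
        deficit = target - cnt
        if deficit <= 0:
            continue
        sub = X[y == c]
        sd = sub.std(axis=0, ddof=0).to_numpy(dtype=float) if cnt > 1 else np.zeros(len(global_sd))
        sd = np.where(sd > 0, sd, global_sd)
        picks = rng.integers(0, cnt, size=deficit)
        new = sub.iloc[picks].to_numpy(dtype=float)
        new = new + rng.normal(0.0, 1.0, size=new.shape) * (noise_scale * sd)
        new = pd.DataFrame(new, columns=X.columns)
        for col, (lo, hi) in ORDINAL_RANGES.items():
            if col in new.columns:
                new[col] = np.clip(np.round(new[col]), lo, hi)
        parts_X.append(new)
        parts_y.append(np.full(deficit, c, dtype=y.dtype))
    return pd.concat(parts_X, ignore_index=True), np.concatenate(parts_y)


# ---------------------------------------------------------------------------
# strategy configuration


@dataclass
class StrategyConfig:
    """One candidate classifier configuration (strategy x CV x metric)."""

    strategy: str = "OVAOVO"
    cv: str = "repcv"
    metric: str = "kappa"
    n_trees: int = 500
    mtry_grid: Sequence[int] = (2, 3, 4, 6)
    cv_folds: int = 10
    cv_repeats: int = 10
    noise_scale: float = 1.0
    upsample: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.cv not in CV_SCHEMES:
            raise ValueError(f"cv must be one of {CV_SCHEMES}")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    def n_learners(self, k: int) -> int:
        if self.strategy == "multiclass":
            return 1
        if self.strategy == "OVA":
            return k
        if self.strategy == "OVO":
            return k * (k - 1) // 2
        return k + k * (k - 1) // 2


# ---------------------------------------------------------------------------
# the estimator


class ProfileClassifier(ClassifierMixin, BaseEstimator):
    """Binarized random-forest classifier for auditory profiles.

    Scikit-learn style: ``fit(X, y)`` then ``predict`` /
    ``predict_with_uncertainty``. See the module docstring for the
    strategy semantics. ``positive_threshold`` is the OVA vote share above
    which a learner claims the patient (0.5).
    """

    def __init__(
        self,
        strategy: str = "OVAOVO",
        n_trees: int = 500,
        mtry_grid: Sequence[int] = (2, 3, 4, 6),
        cv: str = "repcv",
        cv_folds: int = 10,
        cv_repeats: int = 10,
        metric: str = "kappa",
        upsample: bool = True,
        noise_scale: float = 1.0,
        positive_threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.strategy = strategy
        self.n_trees = n_trees
        self.mtry_grid = mtry_grid
        self.cv = cv
        self.cv_folds = cv_folds
        self.cv_repeats = cv_repeats
        self.metric = metric
        self.upsample = upsample
        self.noise_scale = noise_scale
        self.positive_threshold = positive_threshold
        self.random_state = random_state

    # -- tuning -----------------------------------------------------------

    def _cv_repeats_iter(self, y_task: np.ndarray):
        """Yield one list of (train, test) index pairs per CV repeat.

        LOOCV is a single partition; repeated K-fold yields one partition
        per repeat so the tuning metric can be computed on pooled
        out-of-fold predictions within each repeat and averaged across
        repeats (per-fold averaging would leave kappa undefined for
        single-sample folds).
        """
        if self.cv == "loocv":
            yield list(LeaveOneOut().split(np.zeros(len(y_task)), y_task))
            return
        _, counts = np.unique(y_task, return_counts=True)
        folds = int(min(self.cv_folds, counts.min()))
        folds = max(folds, 2)
        for r in range(int(self.cv_repeats)):
            skf = StratifiedKFold(
                n_splits=folds, shuffle=True,
                random_state=derive_seed(int(self.random_state), 5, r),
            )
            yield list(skf.split(np.zeros(len(y_task)), y_task))

    def _forest(self, mtry: int, weighted: bool, seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=int(self.n_trees),
            max_features=int(mtry),
            class_weight="balanced" if weighted else None,
            random_state=seed,
            n_jobs=1,
        )

    def _score_partition(self, forest, X, y, pairs) -> float:
        preds = np.empty_like(np.asarray(y))
        scores = np.zeros((len(y), len(np.unique(y))))
        classes = np.unique(y)
        for tr, te in pairs:
            f = forest.fit(X[tr], y[tr])
            preds[te] = f.predict(X[te])
            if self.metric == "auprc":
                proba = f.predict_proba(X[te])
                for j, c in enumerate(f.classes_):
                    scores[np.ix_(te, np.flatnonzero(classes == c))] = proba[:, [j]]
        res = compute_metric(y, preds, metric=self.metric,
                             scores=scores if self.metric == "auprc" else None,
                             classes=classes)
        return res.score

    def _tune_mtry(self, X: np.ndarray, y: np.ndarray, weighted: bool, seed: int) -> int:
        grid = [m for m in self.mtry_grid if m <= X.shape[1]] or [X.shape[1]]
        if len(grid) == 1:
            return grid[0]
        best_mtry, best_score = grid[0], -np.inf
        for mtry in grid:
            repeat_scores = [
                self._score_partition(self._forest(mtry, weighted, seed), X, y, pairs)
                for pairs in self._cv_repeats_iter(y)
            ]
            score = float(np.nanmean(repeat_scores))
            if score > best_score:
                best_mtry, best_score = mtry, score
        return best_mtry

    # -- fitting ----------------------------------------------------------

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 profiles to train")
        self.feature_names_in_ = np.asarray(X.columns)
        self.train_class_counts_ = dict(zip(*np.unique(y, return_counts=True)))

        if self.upsample:
            X_fit, y_fit = upsample_gaussian(
                X, y, noise_scale=self.noise_scale,
                seed=derive_seed(int(self.random_state), 6),
            )
        else:
            X_fit, y_fit = X.reset_index(drop=True), y

        Xa = X_fit.to_numpy(dtype=float)
        self.learners_: dict = {}
        self.chosen_mtry_: dict = {}

        def train_task(key, mask, task_y, weighted):
            seed = derive_seed(int(self.random_state), 7, len(self.learners_))
            mtry = self._tune_mtry(Xa[mask], task_y, weighted, seed)
            forest = self._forest(mtry, weighted, seed).fit(Xa[mask], task_y)
            self.learners_[key] = forest
            self.chosen_mtry_[key] = mtry

        if self.strategy in ("multiclass",):
            train_task("multiclass", np.ones(len(y_fit), bool), y_fit, False)
        if self.strategy in ("OVA", "OVAOVO"):
            for c in self.classes_:
                task_y = np.where(y_fit == c, 1, 0)
                train_task(("ova", c), np.ones(len(y_fit), bool), task_y, True)
        if self.strategy in ("OVO", "OVAOVO"):
            for a, b in itertools.combinations(self.classes_, 2):
                mask = (y_fit == a) | (y_fit == b)
                train_task(("ovo", a, b), mask, y_fit[mask], False)
        return self

    # -- prediction -------------------------------------------------------

    def _check_X(self, X) -> np.ndarray:
        X = pd.DataFrame(X)[list(self.feature_names_in_)].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValueError(
                "missing feature values: impute or measure before classification"
            )
        return X

    def _ova_shares(self, X: np.ndarray) -> np.ndarray:
        """(n, k) positive vote shares of the k OVA forests."""
        out = np.zeros((X.shape[0], len(self.classes_)))
        for j, c in enumerate(self.classes_):
            f = self.learners_[("ova", c)]
            proba = f.predict_proba(X)
            pos = np.flatnonzero(f.classes_ == 1)
            out[:, j] = proba[:, pos[0]] if len(pos) else 0.0
        return out

    def _ovo_votes(self, X: np.ndarray, candidates=None) -> np.ndarray:
        """(n, k) pairwise-vote counts, optionally restricted per row to a
        candidate subset (non-candidates get -inf)."""
        k = len(self.classes_)
        votes = np.zeros((X.shape[0], k))
        idx = {c: j for j, c in enumerate(self.classes_)}
        for a, b in itertools.combinations(self.classes_, 2):
            pred = self.learners_[("ovo", a, b)].predict(X)
            votes[pred == a, idx[a]] += 1
            votes[pred == b, idx[b]] += 1
        if candidates is not None:
            masked = np.full_like(votes, -np.inf)
            for i, cand in enumerate(candidates):
                cols = [idx[c] for c in cand]
                masked[i, cols] = votes[i, cols]
            votes = masked
        return votes

    def predict_with_uncertainty(self, X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Predicted profile, per-class score matrix and winning vote share.

        The score matrix is the strategy's native score: class vote shares
        (multiclass), OVA positive shares, or normalized OVO votes.
        """
        Xa = self._check_X(X)
        n = Xa.shape[0]
        k = len(self.classes_)

        if self.strategy == "multiclass":
            proba = self.learners_["multiclass"].predict_proba(Xa)
            # align learner classes to self.classes_
            scores = np.zeros((n, k))
            for j, c in enumerate(self.learners_["multiclass"].classes_):
                scores[:, np.flatnonzero(self.classes_ == c)[0]] = proba[:, j]
            winner = np.argmax(scores, axis=1)
            return self.classes_[winner], scores, scores[np.arange(n), winner]

        if self.strategy == "OVO":
            votes = self._ovo_votes(Xa)
            shares = votes / (k - 1)
            winner = np.argmax(votes, axis=1)
            return self.classes_[winner], shares, shares[np.arange(n), winner]

        shares = self._ova_shares(Xa)
        positive = shares > self.positive_threshold
        winner = np.argmax(shares, axis=1)  # fallback: no (or one) positive
        n_pos = positive.sum(axis=1)
        single = n_pos == 1
        winner[single] = np.argmax(positive[single], axis=1)

        multi = np.flatnonzero(n_pos > 1)
        if len(multi):
            if self.strategy == "OVA":
                masked = np.where(positive[multi], shares[multi], -np.inf)
                winner[multi] = np.argmax(masked, axis=1)
            else:  # OVAOVO: OVO vote restricted to the positive candidates
                cand = [self.classes_[positive[i]] for i in multi]
                votes = self._ovo_votes(Xa[multi], candidates=cand)
                top = votes == votes.max(axis=1, keepdims=True)
                ties = top.sum(axis=1) > 1
                w = np.argmax(votes, axis=1)
                if ties.any():  # tie after OVO -> max OVA share among tied
                    for row in np.flatnonzero(ties):
                        cols = np.flatnonzero(top[row])
                        w[row] = cols[np.argmax(shares[multi[row], cols])]
                winner[multi] = w
        return self.classes_[winner], shares, shares[np.arange(n), winner]

    def predict(self, X):
        return self.predict_with_uncertainty(X)[0]

    def predict_scores(self, X) -> np.ndarray:
        return self.predict_with_uncertainty(X)[1]


def train(strategy: str, X: pd.DataFrame, y, config: StrategyConfig) -> ProfileClassifier:
    """Fit a :class:`ProfileClassifier` from a :class:`StrategyConfig`."""
    return ProfileClassifier(
        strategy=strategy,
        n_trees=config.n_trees,
        mtry_grid=tuple(config.mtry_grid),
        cv=config.cv,
        cv_folds=config.cv_folds,
        cv_repeats=config.cv_repeats,
        metric=config.metric,
        upsample=config.upsample,
        noise_scale=config.noise_scale,
        random_state=config.seed,
    ).fit(X, y)


# ---------------------------------------------------------------------------
# selection and evaluation


@dataclass
class EvaluationReport:
    """Held-out per-profile precision and sensitivity, with macro means over
    the profiles large enough to score reliably."""

    per_profile: pd.DataFrame
    mean_precision: float
    mean_sensitivity: float
    excluded: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_profile": self.per_profile.to_dict(orient="records"),
            "mean_precision": self.mean_precision,
            "mean_sensitivity": self.mean_sensitivity,
            "excluded": [str(e) for e in self.excluded],
        }


def evaluate_test(
    classifier: ProfileClassifier,
    X_test: pd.DataFrame,
    y_test,
    min_profile_size: int = 10,
) -> EvaluationReport:
    """Per-profile precision/sensitivity on held-out data.

    Profiles whose *training* membership is below ``min_profile_size`` are
    excluded from the macro means (mirroring the exclusion of unreliably
    small profiles), as are never-predicted profiles (undefined precision,
    flagged).
    """
    if len(X_test) == 0:
        raise ValueError("empty test set")
    y_test = np.asarray(y_test)
    y_pred = classifier.predict(X_test)
    rows, excluded = [], []
    prec_incl, sens_incl = [], []
    train_counts = getattr(classifier, "train_class_counts_", {})
    for c in classifier.classes_:
        tp, fn, fp, tn = _binary_rates(y_test, y_pred, c)
        prec = np.nan if tp + fp == 0 else tp / (tp + fp)
        sens = np.nan if tp + fn == 0 else tp / (tp + fn)
        small = train_counts.get(c, 0) < min_profile_size
        included = not small and np.isfinite(prec) and np.isfinite(sens)
        rows.append({
            "profile": c, "precision": prec, "sensitivity": sens,
            "n_test": int(tp + fn), "n_train": int(train_counts.get(c, 0)),
            "included": included,
            "flag": ("small profile" if small else
                     "never predicted" if not np.isfinite(prec) else ""),
        })
        if included:
            prec_incl.append(prec)
            sens_incl.append(sens)
        else:
            excluded.append(c)
    return EvaluationReport(
        per_profile=pd.DataFrame(rows),
        mean_precision=float(np.mean(prec_incl)) if prec_incl else float("nan"),
        mean_sensitivity=float(np.mean(sens_incl)) if sens_incl else float("nan"),
        excluded=excluded,
    )


def tune_and_select(
    X: pd.DataFrame,
    y,
    configs: Sequence[StrategyConfig],
    min_profile_size: int = 10,
    selection_folds: int = 5,
    seed: int = 0,
) -> tuple[StrategyConfig, pd.DataFrame]:
    """Pick the configuration with the highest out-of-fold mean F1.

    Each config is trained in a stratified K-fold over the training data;
    per-profile F1 is computed on the pooled out-of-fold predictions and
    averaged over profiles with at least ``min_profile_size`` training
    members (smaller ones are listed as excluded). Ties break toward fewer
    base learners, then lower config index.
    """
    if not configs:
        raise ValueError("no configurations to select from")
    y = np.asarray(y)
    X = pd.DataFrame(X).reset_index(drop=True)
    counts = pd.Series(y).value_counts()
    included_profiles = [c for c in counts.index if counts[c] >= min_profile_size]
    excluded_profiles = [c for c in counts.index if counts[c] < min_profile_size]
    k = len(counts)

    folds = max(2, min(selection_folds, int(counts.min())))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=derive_seed(seed, 8))

    rows = []
    for idx, cfg in enumerate(configs):
        oof = np.empty(len(y), dtype=object)
        failed = False
        for tr, te in skf.split(X, y):
            try:
                clf = train(cfg.strategy, X.iloc[tr], y[tr], cfg)
            except ValueError:
                failed = True
                break
            oof[te] = clf.predict(X.iloc[te])
        if failed:
            rows.append({"config": idx, "strategy": cfg.strategy, "cv": cfg.cv,
                         "metric": cfg.metric, "mean_f1": np.nan,
                         "n_learners": cfg.n_learners(k), "failed": True})
            continue
        f1s = []
        for c in included_profiles:
            res = compute_metric(y == c, oof == c, metric="f1")
            f1s.append(res.per_class.get(True, 0.0))
        rows.append({"config": idx, "strategy": cfg.strategy, "cv": cfg.cv,
                     "metric": cfg.metric, "mean_f1": float(np.mean(f1s)),
                     "n_learners": cfg.n_learners(k), "failed": False})
    table = pd.DataFrame(rows)
    table["excluded_profiles"] = [list(excluded_profiles)] * len(table)
    ok = table[~table["failed"] & table["mean_f1"].notna()]
    if ok.empty:
        raise ValueError("every configuration failed")
    best_row = ok.sort_values(
        ["mean_f1", "n_learners", "config"], ascending=[False, True, True]
    ).iloc[0]
    return configs[int(best_row["config"])], table
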