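"""End-to-end orchestration: raw cohort -> profiles -> classifier -> report.

Stages are pure file interfaces — every artifact is a delimited text table or
JSON document under the output directory, and a manifest records the
configuration, seeds and a content hash per artifact so a rerun with the same
seed and input is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._seeds import derive_seed
from .classify import (StrategyConfig, evaluate_test, split_train_test, train,
                       tune_and_select)
from .features import (CLASSIFICATION_FEATURES, derive_features,
                       encode_and_scale, identity_constraints)
from .profiles import generate_profiles
from .selection import SelectionConfig, run_robust_selection
from .synthetic import CohortSpec, generate_cohort, read_cohort, write_cohort

log = logging.getLogger("audioprofiles")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; a single master seed fans out into
    named per-stage streams."""

    out_dir: str
    input_path: str | None = None
    cohort: CohortSpec | None = None
    seed: int = 0
    desk_scale: bool = True
    selection: SelectionConfig | None = None
    profile_m: int = 20
    #: EM restarts for the profile-generation fits. Decoupled from the
    #: selection grid's n_init: only m fits run here, so extra restarts are
    #: cheap, and consistent basins across the m completed datasets are what
    #: makes the consensus-overlap comparison meaningful.
    profile_n_init: int = 10
    min_profile_size: int = 10
    train_frac: float = 0.75
    strategies: list[StrategyConfig] = field(default_factory=list)

    def __post_init__(self):
        if self.input_path is None and self.cohort is None:
            raise ValueError("either input_path or a cohort spec is required")
        if self.selection is None:
            self.selection = (
                SelectionConfig.desk_scale(seed=derive_seed(self.seed, 300))
                if self.desk_scale
                else SelectionConfig(seed=derive_seed(self.seed, 300))
            )
        if self.desk_scale and self.profile_m == 20:
            self.profile_m = 5
        if not self.strategies:
            base = dict(cv="repcv", metric="kappa", seed=derive_seed(self.seed, 301))
            if self.desk_scale:
                base.update(n_trees=100, cv_folds=3, cv_repeats=1, mtry_grid=(3,))
            self.strategies = [
                StrategyConfig(strategy=s, **base)
                for s in ("multiclass", "OVAOVO")
            ]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError("pipeline config must be a mapping")
        if "cohort" in raw and raw["cohort"] is not None:
            raw["cohort"] = CohortSpec(**raw["cohort"])
        if "selection" in raw and raw["selection"] is not None:
            sel = dict(raw["selection"])
            if "k_range" in sel:
                sel["k_range"] = tuple(sel["k_range"])
            raw["selection"] = SelectionConfig(**sel)
        if "strategies" in raw and raw["strategies"]:
            raw["strategies"] = [StrategyConfig(**s) for s in raw["strategies"]]
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the artifact manifest (also written to
    ``manifest.json``). Raises a structured error naming the failing stage."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "artifacts": {}}
    t_all = time.time()

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"][name] = {"started": time.time() - t_all}
        return time.time()

    def finish(name, t0):
        manifest["stages"][name]["seconds"] = round(time.time() - t0, 3)

    def emit(name, path: Path):
        manifest["artifacts"][name] = {
            "path": str(path.relative_to(out)), "sha256": _sha256(path)
        }

    try:
        t0 = stage("cohort")
        if config.input_path is not None:
            if not Path(config.input_path).exists():
                raise FileNotFoundError(f"input table not found: {config.input_path}")
            cohort = read_cohort(config.input_path)
        else:
            cohort = generate_cohort(config.cohort)
        cohort_path = out / "cohort.csv"
        write_cohort(cohort, cohort_path)
        emit("cohort", cohort_path)
        finish("cohort", t0)

        t0 = stage("features")
        feats = derive_features(cohort)
        feats.to_csv(out / "features.csv", index=False)
        emit("features", out / "features.csv")
        scaled, scaler = encode_and_scale(feats)
        scaled.values.to_csv(out / "features_scaled.csv", index=False)
        emit("features_scaled", out / "features_scaled.csv")
        (out / "scaling_bounds.json").write_text(
            json.dumps(scaler.bounds_frame().to_dict(), indent=2)
        )
        emit("scaling_bounds", out / "scaling_bounds.json")
        finish("features", t0)

        t0 = stage("robust_selection")
        config.selection.passive = identity_constraints(scaler)
        choice = run_robust_selection(scaled.values, config.selection)
        (out / "model_choice.json").write_text(json.dumps(choice.to_dict(), indent=2))
        emit("model_choice", out / "model_choice.json")
        finish("robust_selection", t0)

        t0 = stage("profile_generation")
        profile_set = generate_profiles(
            scaled.values, choice.k, choice.model, feats,
            m=config.profile_m, seed=derive_seed(config.seed, 302),
            n_init=config.profile_n_init,
            imputation_iterations=config.selection.imputation_iterations,
            passive=identity_constraints(scaler),
        )
        (out / "profiles.json").write_text(json.dumps(profile_set.to_dict(), indent=2))
        emit("profiles", out / "profiles.json")
        assign = pd.DataFrame({
            "id": cohort["id"] if "id" in cohort else np.arange(len(cohort)),
            "profile": profile_set.assignments,
        })
        assign.to_csv(out / "assignments.csv", index=False)
        emit("assignments", out / "assignments.csv")
        finish("profile_generation", t0)

        t0 = stage("classification")
        # complete classification features: fill the few missing cells from
        # the consensus completed dataset, mapped back to original units
        from .impute import ImputationConfig, mice_impute

        completed = mice_impute(
            scaled.values,
            ImputationConfig(m=1, seed=derive_seed(config.seed, 303),
                             passive=identity_constraints(scaler)),
        ).datasets[0]
        clf_feats = scaler.inverse_transform(completed)[list(CLASSIFICATION_FEATURES)]
        y = profile_set.assignments
        X_tr, X_te, y_tr, y_te = split_train_test(
            clf_feats, y, train_frac=config.train_frac,
            seed=derive_seed(config.seed, 304),
        )
        best_cfg, table = tune_and_select(
            X_tr, y_tr, config.strategies,
            min_profile_size=config.min_profile_size,
            selection_folds=3 if config.desk_scale else 5,
            seed=derive_seed(config.seed, 305),
        )
        table.to_csv(out / "strategy_selection.csv", index=False)
        emit("strategy_selection", out / "strategy_selection.csv")
        clf = train(best_cfg.strategy, X_tr, y_tr, best_cfg)
        report = evaluate_test(clf, X_te, y_te, min_profile_size=config.min_profile_size)
        (out / "evaluation.json").write_text(json.dumps(report.to_dict(), indent=2))
        emit("evaluation", out / "evaluation.json")
        finish("classification", t0)
    except Exception as exc:
        failed = list(manifest["stages"])[-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline stage '{failed}' failed: {exc}") from exc

    manifest["selected_model"] = {"k": choice.k, "model": choice.model}
    manifest["consensus"] = {
        "mean_similarity": profile_set.mean_similarity,
        "max_similarity": profile_set.max_similarity,
    }
    manifest["best_strategy"] = {
        "strategy": best_cfg.strategy, "cv": best_cfg.cv, "metric": best_cfg.metric,
    }
    manifest["test_performance"] = {
        "mean_precision": report.mean_precision,
        "mean_sensitivity": report.mean_sensitivity,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def verify_manifest(out_dir) -> bool:
    """Re-hash every artifact listed in the manifest; True if all match."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    return all(
        _sha256(out / art["path"]) == art["sha256"]
        for art in manifest["artifacts"].values()
    )
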