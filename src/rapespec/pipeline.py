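"""End-to-end orchestration: simulate → label → select → train → evaluate.

A single :class:`RunConfig` (serializable to YAML/JSON) drives the whole run;
one master seed is fanned out to named per-stage sub-seeds so adding a stage
never perturbs earlier stages' randomness. All artifacts are plain text
(CSV/JSON) with fixed column order and 6-significant-digit floats, so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import yaml

from . import evaluation as ev
from . import models as mdl
from .features import assemble_pool, fused_features
from .indices import compute_index_matrix
from .labeling import RGBThresholds, label_samples
from .synthetic import GeneratorConfig, config_from_dict, generate_samples, write_samples

_STAGES = ("simulate", "label", "select", "train", "evaluate")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage '{stage}': {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    thresholds: RGBThresholds = field(default_factory=RGBThresholds)
    index_reps: int = 10
    trilateral_reps: int = 100
    trilateral_subset: int = 150
    lasso_cv_folds: int = 10
    models: tuple[str, ...] = ("plsr", "logit", "rf", "svc")
    M_grid: tuple[int, ...] = tuple(range(150, 241, 10))
    eval_reps: int = 10
    master_seed: int = 0
    out_dir: str = "rapespec_run"

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence(self.master_seed, spawn_key=(_STAGES.index(stage),))
        return int(ss.generate_state(1, dtype=np.uint32)[0] % 2**31)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"]["wavelength_grid"] = [float(w) for w in self.generator.wavelength_grid]
        d["models"] = list(self.models)
        d["M_grid"] = list(self.M_grid)
        d["thresholds"] = {k: list(v) for k, v in d["thresholds"].items()}
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "generator" in data:
            data["generator"] = config_from_dict(data["generator"])
        if "thresholds" in data:
            data["thresholds"] = RGBThresholds(**{k: tuple(v) for k, v in data["thresholds"].items()})
        if "models" in data:
            data["models"] = tuple(data["models"])
        if "M_grid" in data:
            data["M_grid"] = tuple(int(m) for m in data["M_grid"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_all(config: RunConfig) -> Path:
    """Execute every stage, writing artifacts and a manifest to the output dir.

    On failure the manifest records the failed stage before the error is
    re-raised as :class:`PipelineError`.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stage_seeds": {s: config.stage_seed(s) for s in _STAGES},
        "version": _pkg_version("rapespec"),
        "stages_completed": [],
        "failed_stage": None,
    }

    def _save_manifest() -> None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    stage = "simulate"
    try:
        gen = dataclasses.replace(config.generator, seed=config.stage_seed("simulate"))
        samples = generate_samples(gen)
        write_samples(samples, out / "samples.csv")
        manifest["stages_completed"].append(stage)

        stage = "label"
        labeled, counts = label_samples(samples, config.thresholds)
        write_samples(labeled, out / "labeled.csv")
        manifest["label_counts"] = counts
        manifest["stages_completed"].append(stage)

        stage = "select"
        selection = ev.select_features(
            labeled, index_reps=config.index_reps,
            trilateral_reps=config.trilateral_reps,
            trilateral_subset=min(config.trilateral_subset, labeled.n),
            lasso=any(k in ("rf", "svc") for k in config.models),
            cv_folds=config.lasso_cv_folds, seed=config.stage_seed("select"))
        (out / "selected_features.json").write_text(json.dumps({
            "index_specs": [dataclasses.asdict(s) for s in selection.index_specs],
            "top3_trilateral": list(selection.top3_trilateral),
            "lasso_selected": list(selection.lasso_selected),
            "lasso_lambda": selection.lasso_lambda,
        }, indent=2))
        manifest["stages_completed"].append(stage)

        stage = "train"
        models_dir = out / "models"
        models_dir.mkdir(exist_ok=True)
        _train_final_models(labeled, selection, config, models_dir)
        manifest["stages_completed"].append(stage)

        stage = "evaluate"
        plan = ev.SplitPlan(config.M_grid, config.eval_reps, config.stage_seed("evaluate"))
        report = ev.run_experiment(labeled, list(config.models), plan, selection,
                                   thresholds=config.thresholds)
        report.to_csv(out / "report.csv", index=False, float_format="%.6g")
        manifest["stages_completed"].append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _save_manifest()
        raise PipelineError(stage, exc) from exc
    _save_manifest()
    return out


def _train_final_models(labeled, selection, config: RunConfig, models_dir: Path) -> None:
    """Fit each configured model once on the full labeled lot and persist it."""
    import joblib

    tri = None
    for kind in config.models:
        if kind == "plsr":
            for channel in ("R", "G", "B"):
                x = fused_features(labeled, channel, selection.index_specs,
                                   selection.top3_trilateral)
                model = mdl.fit_plsr(x, labeled.channel(channel), target_names=[channel])
                model.to_json(models_dir / f"plsr_{channel}.json")
        elif kind == "logit":
            specs = [s for s in selection.index_specs if s.channel == "R"]
            model = mdl.fit_logit(compute_index_matrix(labeled, specs), labeled.label)
            model.to_json(models_dir / "logit.json")
        elif kind in ("rf", "svc"):
            cols = list(selection.lasso_selected)
            if not cols:
                raise ValueError("rf/svc require a non-empty lasso-selected feature set")
            pool = assemble_pool(labeled, selection.index_specs)
            fit = mdl.fit_rf if kind == "rf" else mdl.fit_svc
            model = fit(pool[cols], labeled.label, seed=config.stage_seed("train"))
            joblib.dump(model.estimator, models_dir / f"{kind}.joblib")
            (models_dir / f"{kind}.json").write_text(json.dumps({
                "kind": kind, "feature_names": model.feature_names,
                "standardization": {"mean": model.mean.tolist(), "sd": model.sd.tolist()},
                "estimator_file": f"{kind}.joblib",
            }, indent=2))
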