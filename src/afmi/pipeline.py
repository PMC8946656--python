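"""End-to-end experiment orchestration.

Stages: simulate -> preprocess -> signatures -> classify / map / stats.
A single global seed is fanned out to per-stage child seeds by a fixed
hash derivation so partial reruns reproduce exactly.  Every artifact path
is recorded in the run manifest; the summary JSON excludes timestamps so
identical config + seed produces identical summaries.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from . import boundary as boundary_mod
from . import channel_stats as stats_mod
from .classify import cross_validate
from .phantom import PhantomSpec, generate_cohort
from .preprocess import PreprocessConfig, preprocess_stack
from .signatures import (
    cohort_relative_signatures,
    extract_signatures,
    rss_matrix,
    signature_matrix,
    training_rows,
)

__all__ = [
    "STAGES",
    "RunConfig",
    "RunConfigError",
    "PipelineStageError",
    "stage_seed",
    "run_experiment",
    "load_run_config",
]

STAGES = ("simulate", "preprocess", "signatures", "classify", "map", "stats")
_DEPENDENCIES = {
    "preprocess": ("simulate",),
    "signatures": ("preprocess",),
    "classify": ("signatures",),
    "map": ("signatures",),
    "stats": ("signatures",),
}


class RunConfigError(ValueError):
    """Invalid run configuration."""


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


@dataclass
class RunConfig:
    stages: tuple[str, ...]
    seed: int = 0
    output_dir: Path = Path("afmi_run")
    simulate: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    signatures: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)
    map: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise RunConfigError(f"unknown stages {sorted(unknown)}")
        requested = set(self.stages)
        for stage in self.stages:
            missing = set(_DEPENDENCIES.get(stage, ())) - requested
            if missing:
                raise RunConfigError(
                    f"stage {stage!r} requires {sorted(missing)} in the stage list"
                )

    def config_hash(self) -> str:
        payload = {
            "stages": list(self.stages),
            "seed": self.seed,
            "simulate": self.simulate,
            "preprocess": self.preprocess,
            "signatures": self.signatures,
            "classify": self.classify,
            "map": self.map,
            "stats": self.stats,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_run_config(path: str | Path) -> RunConfig:
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "stages" not in raw:
        raise RunConfigError("run config must be a mapping with a 'stages' list")
    return RunConfig(
        stages=tuple(raw["stages"]),
        seed=int(raw.get("seed", 0)),
        output_dir=Path(raw.get("output_dir", "afmi_run")),
        simulate=raw.get("simulate", {}) or {},
        preprocess=raw.get("preprocess", {}) or {},
        signatures=raw.get("signatures", {}) or {},
        classify=raw.get("classify", {}) or {},
        map=raw.get("map", {}) or {},
        stats=raw.get("stats", {}) or {},
    )


def _run_stage(stage: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - reported with stage name
        raise PipelineStageError(stage, exc) from exc


def run_experiment(cfg: RunConfig) -> dict[str, Any]:
    """Execute the configured stages and return the run manifest."""
    out_dir = cfg.output_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": list(cfg.stages),
        "artifacts": {},
        "started_at": time.time(),
    }
    summary: dict[str, Any] = {"config_hash": cfg.config_hash(), "seed": cfg.seed}

    cohort = None
    if "simulate" in cfg.stages:
        sim_kwargs = dict(cfg.simulate)
        sim_kwargs.setdefault("seed", stage_seed(cfg.seed, "simulate"))
        if "image_shape" in sim_kwargs:
            sim_kwargs["image_shape"] = tuple(sim_kwargs["image_shape"])
        spec = _run_stage("simulate", PhantomSpec, **sim_kwargs)
        cohort = _run_stage("simulate", generate_cohort, spec)
        summary["simulate"] = {
            "n_patients": spec.n_patients,
            "image_shape": list(spec.image_shape),
            "n_channels": spec.n_channels,
        }

    if "preprocess" in cfg.stages:
        pre_cfg = PreprocessConfig(**cfg.preprocess)
        processed = []
        for stack in cohort:
            corrected, report = _run_stage("preprocess", preprocess_stack, stack, pre_cfg)
            processed.append(corrected)
        cohort = processed
        summary["preprocess"] = {"n_stacks": len(cohort)}

    sig_df = None
    refs = None
    if "signatures" in cfg.stages:
        sector_px = int(cfg.signatures.get("sector_px", 16))
        min_normal = int(cfg.signatures.get("min_normal", 10))
        frames = [
            _run_stage("signatures", extract_signatures, st, sector_px)
            for st in cohort
        ]
        all_df = pd.concat(frames, ignore_index=True)
        refs, sig_df, excluded = _run_stage(
            "signatures", cohort_relative_signatures, all_df, min_normal
        )
        sig_path = out_dir / "signatures.csv"
        sig_df.to_csv(sig_path, index=False, float_format="%.10g")
        refs_path = out_dir / "normal_references.json"
        refs_path.write_text(
            json.dumps({p: r.to_dict() for p, r in refs.items()}, indent=1)
        )
        manifest["artifacts"]["signatures"] = str(sig_path)
        manifest["artifacts"]["normal_references"] = str(refs_path)
        summary["signatures"] = {
            "n_sectors": int(len(sig_df)),
            "n_patients": len(refs),
            "excluded_patients": excluded,
        }

    if "classify" in cfg.stages:
        task = cfg.classify.get("task", "ptg-vs-ossn")
        framework = cfg.classify.get("framework", "fused")
        cv_mode = cfg.classify.get("cv", "kfold")
        k = int(cfg.classify.get("k", 10))
        pca_k = int(cfg.classify.get("pca_k", 5))
        purity = float(cfg.classify.get("purity_threshold", 0.8))
        task_classes = {
            "ptg-vs-ossn": ("PTG", "OSSN"),
            "ossn-vs-normal": ("normal", "OSSN"),
            "ptg-vs-normal": ("normal", "PTG"),
            "three-way": ("normal", "PTG", "OSSN"),
        }[task]
        rows = training_rows(sig_df, classes=task_classes, purity_threshold=purity)
        X = rss_matrix(rows) if framework == "fused" else signature_matrix(rows)
        report = _run_stage(
            "classify",
            cross_validate,
            X,
            rows["label"].to_numpy(),
            rows["patient_id"].to_numpy(),
            mode=cv_mode,
            k=k,
            framework=framework,
            pca_k=pca_k,
            seed=stage_seed(cfg.seed, "classify"),
        )
        eval_path = out_dir / f"eval_{task}_{framework}_{cv_mode}.json"
        eval_path.write_text(json.dumps(report.to_dict(), indent=1))
        manifest["artifacts"]["classify"] = str(eval_path)
        summary["classify"] = {
            "task": task,
            "framework": framework,
            "cv": cv_mode,
            "auc": report.auc,
            "accuracy_mean": report.accuracy_mean,
            "accuracy_sd": report.accuracy_sd,
            "sensitivity_mean": report.sensitivity_mean,
            "specificity_mean": report.specificity_mean,
            "pooled_accuracy": report.pooled_accuracy,
        }

    if "map" in cfg.stages:
        patient_idx = int(cfg.map.get("patient_index", 0))
        stack = cohort[patient_idx]
        psig = sig_df[sig_df["patient_id"] == stack.patient_id]
        ann = boundary_mod.select_annotations(
            psig,
            frac=float(cfg.map.get("train_frac", 0.3)),
            min_per_class=int(cfg.map.get("min_per_class", 20)),
            seed=stage_seed(cfg.seed, "map"),
        )
        bmap = _run_stage(
            "map",
            boundary_mod.detect_boundaries,
            stack,
            ann,
            sig_df=psig,
            min_per_class=int(cfg.map.get("min_per_class", 20)),
            pca_k=int(cfg.map.get("pca_k", 5)),
            base_channel=int(cfg.map.get("base_channel", 10)),
        )
        if cfg.map.get("smooth", False):
            bmap = boundary_mod.smooth_map(bmap)
        grid_path = out_dir / f"boundary_grid_{stack.patient_id}.csv"
        pd.DataFrame(bmap.grid).to_csv(grid_path, index=False, header=False)
        manifest["artifacts"]["boundary_grid"] = str(grid_path)
        overlay_path = out_dir / f"boundary_overlay_{stack.patient_id}.png"
        try:
            import imageio.v3 as iio

            iio.imwrite(overlay_path, bmap.overlay_rgb)
            manifest["artifacts"]["boundary_overlay"] = str(overlay_path)
        except Exception:
            pass
        summary["map"] = {
            "patient_id": stack.patient_id,
            "agreement": bmap.agreement,
        }

    if "stats" in cfg.stages:
        channels = cfg.stats.get("channels", [3, 12, 30, 52])
        mode = cfg.stats.get("mode", "sectors")
        table = _run_stage(
            "stats", stats_mod.compare_channels, sig_df, channels, mode=mode
        )
        stats_path = out_dir / "channel_comparisons.csv"
        table.to_csv(stats_path, index=False, float_format="%.10g")
        manifest["artifacts"]["channel_comparisons"] = str(stats_path)
        summary["stats"] = {
            "channels": list(channels),
            "significant": int((table["p"] < 0.05).sum()),
            "comparisons": int(len(table)),
        }

    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
    manifest["artifacts"]["summary"] = str(summary_path)
    manifest["finished_at"] = time.time()
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return manifest
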