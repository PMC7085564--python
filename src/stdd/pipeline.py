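"""End-to-end orchestration: simulate -> extract -> block1 -> block2 -> report.

A :class:`PipelineConfig` gathers every tunable constant of the method
(window geometry, EMA look-back, sleep rule, social weight, forest size,
simulation conditions) in one serialisable object, so a run is fully
described by a config file plus a seed.  ``run_pipeline`` executes the
stages in order, logs record counts per stage, writes all report artifacts
and a run manifest, and is bit-identical across reruns with the same
config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from . import block1, block2, sensing_io, synthetic_data
from .features import EmaLinkConfig, WindowingConfig, extract_features
from .synthetic_data import StudyConfig

logger = logging.getLogger("stdd.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    windowing: WindowingConfig = field(default_factory=WindowingConfig)
    ema_link: EmaLinkConfig = field(default_factory=EmaLinkConfig)
    sleep: block1.SleepConfig = field(default_factory=block1.SleepConfig)
    social: block1.SocialConfig = field(default_factory=block1.SocialConfig)
    group_model: block2.GroupModelConfig = field(
        default_factory=block2.GroupModelConfig)
    sim: StudyConfig = field(default_factory=StudyConfig)
    seed: int = 42
    algo: str = "rf"

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self, seed=seed,
            group_model=dataclasses.replace(self.group_model, seed=seed))


class ConfigError(ValueError):
    """Invalid configuration; ``errors`` lists field-path messages."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


# ---------------------------------------------------------------------------
# Config (de)serialisation

def config_to_dict(cfg: PipelineConfig) -> dict[str, Any]:
    d = dataclasses.asdict(cfg)
    d["sim"]["start_date"] = cfg.sim.start_date.isoformat()
    d["schema_version"] = 1
    return d


def config_from_dict(data: Mapping[str, Any]) -> PipelineConfig:
    errors: list[str] = []
    data = dict(data)
    data.pop("schema_version", None)

    def build(cls, key: str):
        sub = dict(data.get(key) or {})
        if key == "sim" and "start_date" in sub and isinstance(
                sub["start_date"], str):
            sub["start_date"] = Date.fromisoformat(sub["start_date"])
        if key == "sim":
            if "compliance" in sub and sub["compliance"] is not None:
                sub["compliance"] = {int(k): float(v)
                                     for k, v in sub["compliance"].items()}
            if "n_per_group" in sub and sub["n_per_group"] is not None:
                sub["n_per_group"] = {str(k): int(v)
                                      for k, v in sub["n_per_group"].items()}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(sub) - known
        for u in sorted(unknown):
            errors.append(f"{key}.{u}: unknown field")
            sub.pop(u)
        try:
            return cls(**sub)
        except (TypeError, ValueError):
            # attribute the failure to individual fields where possible
            blamed = False
            for name, value in sorted(sub.items()):
                try:
                    cls(**{name: value})
                except (TypeError, ValueError) as exc:
                    errors.append(f"{key}.{name}: {exc}")
                    blamed = True
            if not blamed:
                try:
                    cls(**sub)
                except (TypeError, ValueError) as exc:
                    errors.append(f"{key}: {exc}")
            return cls()

    kwargs = {
        "windowing": build(WindowingConfig, "windowing"),
        "ema_link": build(EmaLinkConfig, "ema_link"),
        "sleep": build(block1.SleepConfig, "sleep"),
        "social": build(block1.SocialConfig, "social"),
        "group_model": build(block2.GroupModelConfig, "group_model"),
        "sim": build(StudyConfig, "sim"),
    }
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "algo" in data:
        if data["algo"] not in ("rf", "svm"):
            errors.append(f"algo: must be 'rf' or 'svm', got {data['algo']!r}")
        else:
            kwargs["algo"] = data["algo"]
    if errors:
        raise ConfigError(errors)
    return PipelineConfig(**kwargs)


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML config file; raises :class:`ConfigError`."""
    path = Path(path)
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError([f"unparseable YAML: {exc}"]) from exc
    return config_from_dict(data)


def save_config(cfg: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)
    return path


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(config_to_dict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Pipeline stages

def _stage(out_dir: Path, name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                (out_dir / "FAILED").write_text(f"stage: {name}\n{exc}\n")
                logger.error("stage %s: FAILED (%s)", name, exc)
                raise PipelineError(name, exc) from exc
            logger.info("stage %s: done", name)
            return False
    return _Ctx()


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 dataset_dir: str | Path | None = None) -> dict[str, Path]:
    """Execute the full analysis; returns the artifact paths.

    If ``dataset_dir`` is None a synthetic study is generated under
    ``out_dir/dataset`` from ``config.sim`` and ``config.seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    artifacts: dict[str, Path] = {}

    with _stage(out, "simulate"):
        if dataset_dir is None:
            dataset_dir = synthetic_data.simulate_study(
                seed=config.seed, out_dir=out / "dataset", config=config.sim)
        dataset_dir = Path(dataset_dir)
        participants = sensing_io.list_participants(dataset_dir)
        if not participants:
            raise FileNotFoundError(f"no participants under {dataset_dir}")
        logger.info("dataset %s: %d participants", dataset_dir,
                    len(participants))
    artifacts["dataset"] = dataset_dir

    features_by_pid: dict[str, pd.DataFrame] = {}
    level_frames: list[pd.DataFrame] = []
    manifests: dict[str, sensing_io.ParticipantManifest] = {}
    ema_logs: dict[str, pd.DataFrame] = {}
    timezones: dict[str, str] = {}

    with _stage(out, "extract+block1"):
        for pid in participants:
            ds = sensing_io.load_participant(dataset_dir, pid)
            manifests[pid] = ds.manifest
            ema_logs[pid] = ds.ema
            timezones[pid] = ds.timezone
            feats = extract_features(ds, config.windowing, config.ema_link)
            features_by_pid[pid] = feats
            levels = block1.compute_level_vectors(
                ds, feats, config.windowing, config.ema_link, config.sleep,
                config.social, algo=config.algo, seed=config.seed)
            if len(levels):
                level_frames.append(levels)
            logger.info("%s: %d labeled windows, %d level vectors",
                        pid, len(feats), len(levels))
        levels_df = pd.concat(level_frames, ignore_index=True)
        levels_path = out / "levels.csv"
        levels_df.to_csv(levels_path, index=False)
    artifacts["levels"] = levels_path

    with _stage(out, "block1-metrics"):
        table4, table4_detail = block1.evaluate_personal_models(
            features_by_pid, algo=config.algo, seed=config.seed)
        table4.to_csv(out / "table4.csv", index=False)
        table4_detail.to_csv(out / "table4_detail.csv", index=False)
    artifacts["table4"] = out / "table4.csv"

    with _stage(out, "block2"):
        groups = {pid: block2.assign_group(m) for pid, m in manifests.items()}
        X, y, n_dropped = block2.build_group_dataset(levels_df, groups)
        report = block2.evaluate_group_classifier(X, y, config.group_model)
        report.to_frame().to_csv(out / "table5.csv", index=False)
        imp = block2.feature_importance(samples=(X.to_numpy(), y))
        imp.rename_axis("feature").reset_index().to_csv(
            out / "importance.csv", index=False)
        block2.response_rates(ema_logs, timezones).to_csv(
            out / "table3.csv", index=False)
        agreement = block2.evaluate_agreement(levels_df)
        pd.DataFrame([{"cluster": k, "pearson_r": v}
                      for k, v in agreement.items()]).to_csv(
            out / "agreement.csv", index=False)
        logger.info("block2: %d samples (%d dropped), accuracy %.2f%%",
                    len(X), n_dropped, report.accuracy)
    artifacts.update(table5=out / "table5.csv",
                     importance=out / "importance.csv",
                     table3=out / "table3.csv",
                     agreement=out / "agreement.csv")

    with _stage(out, "manifest"):
        run_manifest = {
            "config_hash": config_hash(config),
            "seed": config.seed,
            "stdd_version": __version__,
            "python": platform.python_version(),
            "n_participants": len(participants),
            "n_level_vectors": int(len(levels_df)),
            "n_group_samples": int(len(X)),
            "n_dropped_periods": n_dropped,
            "overall_accuracy_pct": round(report.accuracy, 2),
        }
        (out / "run_manifest.json").write_text(
            json.dumps(run_manifest, indent=2, sort_keys=True) + "\n")
    artifacts["run_manifest"] = out / "run_manifest.json"
    return artifacts
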