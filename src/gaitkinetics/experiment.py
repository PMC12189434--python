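"""Experiment configuration and the end-to-end study driver.

Reproduces the study design at configurable scale: sample a population,
simulate ``trials_per_subject`` gait cycles per subject, preprocess into
stance samples, hold out whole subjects as the test set, train the model
bank and evaluate it.  Stages are content-addressed by a hash of the
part of the configuration they depend on, so re-running with an
unchanged configuration reuses cached artifacts and a changed
configuration invalidates downstream stages only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .evaluation import EvaluationReport, evaluate_bank, render_tables
from .models import (CnnSpec, MlpSpec, TrainConfig, TrainedEstimator,
                     load_estimator, train_model_bank)
from .preprocessing import (COMPONENTS, GaitDataset, build_samples_from_trial,
                            split_by_subject)
from .synthetic import GeneratorConfig, sample_population, simulate_trial

__all__ = [
    "PopulationConfig", "PreprocessingConfig", "SplitConfig", "TrainingConfig",
    "ExperimentConfig", "ConfigError", "run_experiment", "derive_seed",
]

logger = logging.getLogger("gaitkinetics")


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass(frozen=True)
class PopulationConfig:
    n_male: int = 62
    n_female: int = 84
    trials_per_subject: int = 10


@dataclass(frozen=True)
class PreprocessingConfig:
    threshold_n: float = 20.0
    right_stance_policy: str = "first"

    def __post_init__(self) -> None:
        if self.right_stance_policy not in ("first", "second", "both"):
            raise ConfigError(
                f"right_stance_policy must be first/second/both, "
                f"got {self.right_stance_policy!r}")


@dataclass(frozen=True)
class SplitConfig:
    n_test_male: int = 5
    n_test_female: int = 5


@dataclass(frozen=True)
class TrainingConfig:
    architectures: tuple[str, ...] = ("mlp", "cnn")
    components: tuple[str, ...] = COMPONENTS
    sides: tuple[str, ...] = ("right", "left")
    batch_size: int = 128
    epochs: int = 1000
    cnn_epochs: int | None = None          # defaults to ``epochs``
    mlp_learning_rate: float = 0.01
    cnn_learning_rate: float = 1e-4
    side_px: int = 227

    def __post_init__(self) -> None:
        for arch in self.architectures:
            if arch not in ("mlp", "cnn"):
                raise ConfigError(f"unknown architecture {arch!r}")
        for comp in self.components:
            if comp not in COMPONENTS:
                raise ConfigError(f"unknown component {comp!r}")
        for side in self.sides:
            if side not in ("right", "left"):
                raise ConfigError(f"unknown side {side!r}")


@dataclass(frozen=True)
class ExperimentConfig:
    """Complete description of one experiment; all stage seeds derive from
    ``master_seed``."""

    master_seed: int = 0
    population: PopulationConfig = field(default_factory=PopulationConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        sections = {
            "population": PopulationConfig,
            "generator": GeneratorConfig,
            "preprocessing": PreprocessingConfig,
            "split": SplitConfig,
            "training": TrainingConfig,
        }
        kwargs: dict = {}
        if "master_seed" in d:
            kwargs["master_seed"] = int(d.pop("master_seed"))
        for name, klass in sections.items():
            sub = d.pop(name, {})
            if not isinstance(sub, dict):
                raise ConfigError(f"section [{name}] must be a table")
            known = {f.name for f in dataclasses.fields(klass)}
            unknown = set(sub) - known
            if unknown:
                raise ConfigError(
                    f"unknown key(s) in [{name}]: {', '.join(sorted(unknown))}")
            coerced = {}
            for f in dataclasses.fields(klass):
                if f.name not in sub:
                    continue
                v = sub[f.name]
                coerced[f.name] = tuple(v) if isinstance(v, list) else v
            try:
                kwargs[name] = klass(**coerced)
            except ConfigError:
                raise
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid [{name}] section: {exc}") from exc
        if d:
            raise ConfigError(f"unknown top-level key(s): {', '.join(sorted(d))}")
        return cls(**kwargs)

    @classmethod
    def from_toml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def to_toml(self, path: str | Path) -> Path:
        path = Path(path)
        lines = [f"master_seed = {self.master_seed}", ""]
        for name in ("population", "generator", "preprocessing", "split", "training"):
            section = getattr(self, name)
            lines.append(f"[{name}]")
            for f in dataclasses.fields(section):
                v = getattr(section, f.name)
                if v is None:      # TOML has no null; omit and keep the default
                    continue
                lines.append(f"{f.name} = {_toml_value(v)}")
            lines.append("")
        path.write_text("\n".join(lines))
        return path


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (tuple, list)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    if v is None:
        return '"none"'
    if isinstance(v, float):
        return repr(v)
    return str(v)


def derive_seed(master_seed: int, label: str) -> int:
    """A deterministic sub-seed (< 2^31) for one named randomness source."""
    digest = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % 2**31


def _stage_hash(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class _Stage:
    """Content-addressed stage bookkeeping inside the output directory."""

    def __init__(self, out_dir: Path, name: str, payload: dict) -> None:
        self.state_path = out_dir / f".stage_{name}.json"
        self.name = name
        self.hash = _stage_hash(payload)

    def is_current(self, artifacts: list[Path]) -> bool:
        if not self.state_path.exists():
            return False
        state = json.loads(self.state_path.read_text())
        return state.get("hash") == self.hash and all(p.exists() for p in artifacts)

    def mark(self) -> None:
        self.state_path.write_text(json.dumps({"hash": self.hash, "time": time.time()}))


def _log_stage(name: str, t0: float, seed: int | None, n_in: int, n_out: int) -> None:
    logger.info("stage=%s wall_s=%.2f seed=%s n_in=%d n_out=%d",
                name, time.time() - t0, seed, n_in, n_out)


def _specs_for(training: TrainingConfig) -> list[MlpSpec | CnnSpec]:
    specs: list[MlpSpec | CnnSpec] = []
    for arch in training.architectures:
        if arch == "mlp":
            specs.append(MlpSpec(learning_rate=training.mlp_learning_rate))
        else:
            specs.append(CnnSpec(side_px=training.side_px,
                                 learning_rate=training.cnn_learning_rate))
    return specs


def build_dataset(config: ExperimentConfig) -> GaitDataset:
    """Simulate the population, preprocess every trial, apply the split."""
    t0 = time.time()
    pop_seed = derive_seed(config.master_seed, "population")
    subjects = sample_population(config.population.n_male,
                                 config.population.n_female, seed=pop_seed)
    samples = []
    for subject in subjects:
        for j in range(config.population.trials_per_subject):
            trial = simulate_trial(subject, trial_seed=j, config=config.generator)
            samples.extend(build_samples_from_trial(
                trial, threshold_n=config.preprocessing.threshold_n))
    dataset = GaitDataset(samples=samples)
    _log_stage("simulate+preprocess", t0, pop_seed, len(subjects), len(samples))

    t0 = time.time()
    split_seed = derive_seed(config.master_seed, "split")
    dataset = split_by_subject(dataset, config.split.n_test_male,
                               config.split.n_test_female, seed=split_seed)
    n_test = sum(1 for v in dataset.split.values() if v == "test")
    _log_stage("split", t0, split_seed, len(subjects), n_test)
    return dataset


def run_experiment(config: ExperimentConfig, out_dir: str | Path
                   ) -> tuple[GaitDataset, dict, EvaluationReport]:
    """Run simulate -> preprocess -> split -> train -> evaluate, cached.

    Returns the dataset, the estimator bank and the evaluation report;
    artifacts (dataset archive, model bank, report CSVs, rendered tables)
    are written under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_toml(out_dir / "config.toml")
    cfg_d = config.to_dict()

    # ---- dataset stage ----------------------------------------------------
    data_payload = {k: cfg_d[k] for k in
                    ("master_seed", "population", "generator", "preprocessing", "split")}
    stage = _Stage(out_dir, "dataset", data_payload)
    data_path = out_dir / "dataset.npz"
    if stage.is_current([data_path]):
        logger.info("stage=dataset cached hash=%s", stage.hash)
        dataset = GaitDataset.load(data_path)
    else:
        dataset = build_dataset(config)
        dataset.save(data_path)
        stage.mark()

    # ---- training stage ---------------------------------------------------
    train_payload = dict(data_payload, training=cfg_d["training"])
    stage = _Stage(out_dir, "train", train_payload)
    bank_dir = out_dir / "bank"
    manifest = bank_dir / "manifest.csv"
    tcfg = TrainConfig(batch_size=config.training.batch_size,
                       epochs=config.training.epochs,
                       seed=derive_seed(config.master_seed, "train"))
    specs = _specs_for(config.training)
    if stage.is_current([manifest]):
        logger.info("stage=train cached hash=%s", stage.hash)
        bank = {}
        for spec in specs:
            for comp in config.training.components:
                for side in config.training.sides:
                    key = (spec.name, comp, side)
                    bank[key] = load_estimator(bank_dir / "_".join(key))
    else:
        t0 = time.time()
        bank = {}
        for spec in specs:
            arch_cfg = tcfg if not (spec.name == "cnn" and config.training.cnn_epochs) \
                else dataclasses.replace(tcfg, epochs=config.training.cnn_epochs)
            bank.update(train_model_bank(
                dataset, [spec], arch_cfg,
                components=config.training.components,
                sides=config.training.sides, out_dir=bank_dir))
        _log_stage("train", t0, tcfg.seed, len(dataset.train_samples()), len(bank))
        stage.mark()

    # ---- evaluation stage -------------------------------------------------
    stage = _Stage(out_dir, "evaluate", cfg_d)
    t0 = time.time()
    report = evaluate_bank(bank, dataset,
                           right_stance_policy=config.preprocessing.right_stance_policy)
    report_dir = out_dir / "report"
    report.to_csv(report_dir)
    (report_dir / "tables.txt").write_text(render_tables(report))
    stage.mark()
    _log_stage("evaluate", t0, None,
               len(report.per_sample), len(report.aggregates))
    return dataset, bank, report
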