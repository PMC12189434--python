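"""The two stance-curve regressors and their training drivers.

One model is trained per (architecture, component, side) triple:

* **MLP** — 6300 inputs (flattened 3 x 21 x 100 tensor), three hidden
  layers of 100 ReLU units, 100 sigmoid outputs, RMSE loss, SGD.
* **CNN** — AlexNet topology (5 convolutional + 3 fully connected
  layers) over the RGB trajectory image, 100 sigmoid outputs, MSE loss,
  Adam.  The canonical input is 227 x 227; a quarter-width variant is
  generated for smaller image sizes so that scaled-down studies keep the
  same 5-conv/3-fc topology.

Targets are scaled into [0.05, 0.95] during training and mapped back to
physical units (BW or mm) at prediction time.  MLP inputs are
standardized per feature with train-partition statistics stored on the
estimator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import nn
from .encoding import (TargetScaler, compute_channel_ranges, encode_image,
                       fit_target_scaler, flatten_for_mlp)
from .preprocessing import COMPONENTS, GaitDataset, StanceSample

__all__ = [
    "MlpSpec", "CnnSpec", "TrainConfig", "TrainedEstimator",
    "train", "predict", "train_model_bank",
    "save_estimator", "load_estimator",
]

SIDES = ("right", "left")


@dataclass(frozen=True)
class MlpSpec:
    """Multilayer-perceptron architecture and optimizer settings."""

    input_size: int = 6300
    hidden: tuple[int, ...] = (100, 100, 100)
    output_size: int = 100
    learning_rate: float = 0.01
    name: str = "mlp"


@dataclass(frozen=True)
class CnnSpec:
    """AlexNet-family architecture: 5 conv layers then 3 fully connected."""

    side_px: int = 227
    output_size: int = 100
    learning_rate: float = 1e-4
    name: str = "cnn"

    def layer_plan(self) -> dict:
        """Conv/pool/fc layout for the configured image size."""
        if self.side_px >= 128:
            return {
                "conv": [  # (c_out, kernel, stride, pad)
                    (96, 11, 4, 0), (256, 5, 1, 2),
                    (384, 3, 1, 1), (384, 3, 1, 1), (256, 3, 1, 1)],
                "pool_after": {0, 1, 4},
                "fc": (4096, 4096),
            }
        # quarter-width profile for scaled-down studies
        return {
            "conv": [
                (24, 7, 2, 0), (64, 5, 1, 2),
                (96, 3, 1, 1), (96, 3, 1, 1), (64, 3, 1, 1)],
            "pool_after": {0, 1, 4},
            "fc": (1024, 1024),
        }


@dataclass(frozen=True)
class TrainConfig:
    """Mini-batch training settings (batch 128, 1000 epochs by default)."""

    batch_size: int = 128
    epochs: int = 1000
    seed: int = 0
    shuffle: bool = True
    validation_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in [0, 1)")


@dataclass
class TrainedEstimator:
    """A fitted network for one (architecture, component, side) triple."""

    arch: str
    component: str
    side: str
    network: nn.Network
    target_scaler: TargetScaler
    spec: MlpSpec | CnnSpec
    config: TrainConfig
    loss_history: list[float] = field(default_factory=list)
    input_mean: np.ndarray | None = None       # MLP feature standardization
    input_std: np.ndarray | None = None
    channel_ranges: list[tuple[float, float]] | None = None   # CNN only

    @property
    def final_loss(self) -> float:
        return self.loss_history[-1] if self.loss_history else float("nan")


def build_mlp(spec: MlpSpec, rng: np.random.Generator) -> nn.Network:
    layers: list[nn.Layer] = []
    n_in = spec.input_size
    for width in spec.hidden:
        layers += [nn.Dense(n_in, width, rng), nn.ReLU()]
        n_in = width
    layers += [nn.Dense(n_in, spec.output_size, rng), nn.Sigmoid()]
    return nn.Network(layers)


def build_cnn(spec: CnnSpec, rng: np.random.Generator,
              dtype=np.float32) -> nn.Network:
    """CNN weights default to float32: convolution dominates the compute
    and single precision is ample for Adam training."""
    plan = spec.layer_plan()
    layers: list[nn.Layer] = []
    c_in, h = 3, spec.side_px
    for i, (c_out, k, s, p) in enumerate(plan["conv"]):
        conv = nn.Conv2D(c_in, c_out, k, rng, stride=s, pad=p, dtype=dtype)
        layers.append(conv)
        layers.append(nn.ReLU())
        h, _ = conv.out_size(h, h)
        if i in plan["pool_after"]:
            pool = nn.MaxPool2D(3, 2)
            if h >= 3:
                layers.append(pool)
                h, _ = pool.out_size(h, h)
        c_in = c_out
        if h < 1:
            raise ValueError(f"image side {spec.side_px} too small for the CNN plan")
    layers.append(nn.Flatten())
    n_in = c_in * h * h
    for width in plan["fc"][:2]:
        layers += [nn.Dense(n_in, width, rng, dtype=dtype), nn.ReLU()]
        n_in = width
    layers += [nn.Dense(n_in, spec.output_size, rng, dtype=dtype), nn.Sigmoid()]
    return nn.Network(layers)


def _encode_inputs(samples: Sequence[StanceSample], estimator: TrainedEstimator) -> np.ndarray:
    if estimator.arch == "mlp":
        x = np.stack([flatten_for_mlp(s) for s in samples])
        return (x - estimator.input_mean) / estimator.input_std
    imgs = np.stack([encode_image(s, estimator.channel_ranges,
                                  side_px=estimator.spec.side_px) for s in samples])
    return (imgs.transpose(0, 3, 1, 2).astype(np.float32) / np.float32(255.0))


def train(spec: MlpSpec | CnnSpec, dataset: GaitDataset, component: str,
          side: str, config: TrainConfig) -> TrainedEstimator:
    """Train one estimator on the dataset's train partition.

    Target scalers, input statistics and CNN channel ranges are fitted on
    the training partition only.  Deterministic given ``config.seed``.
    """
    if component not in COMPONENTS:
        raise ValueError(f"unknown component {component!r}")
    if side not in SIDES:
        raise ValueError(f"unknown side {side!r}")
    samples = dataset.train_samples(side=side)
    if not samples:
        raise ValueError(f"no training samples for side {side!r}")

    scaler = fit_target_scaler([s.targets[component] for s in samples], component)
    y = scaler.transform(np.stack([s.targets[component] for s in samples]))

    init_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 11)))
    shuffle_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 13)))

    if isinstance(spec, MlpSpec):
        raw = np.stack([flatten_for_mlp(s) for s in samples])
        mean = raw.mean(axis=0)
        std = raw.std(axis=0)
        std[std < 1e-8] = 1.0
        x = (raw - mean) / std
        network = build_mlp(spec, init_rng)
        est = TrainedEstimator(arch=spec.name, component=component, side=side,
                               network=network, target_scaler=scaler, spec=spec,
                               config=config, input_mean=mean, input_std=std)
        loss, opt = nn.RMSELoss(), nn.SGD(spec.learning_rate)
    else:
        ranges = compute_channel_ranges(samples)
        network = build_cnn(spec, init_rng)
        est = TrainedEstimator(arch=spec.name, component=component, side=side,
                               network=network, target_scaler=scaler, spec=spec,
                               config=config, channel_ranges=ranges)
        x = _encode_inputs(samples, est)
        y = y.astype(np.float32)
        loss, opt = nn.MSELoss(), nn.Adam(spec.learning_rate)

    est.loss_history = network.fit(x, y, loss, opt, epochs=config.epochs,
                                   batch_size=config.batch_size, rng=shuffle_rng,
                                   shuffle=config.shuffle)
    return est


def predict(estimator: TrainedEstimator, samples: Sequence[StanceSample]) -> np.ndarray:
    """Predict length-100 curves in physical units (BW or mm) for samples.

    All samples must match the estimator's side.
    """
    for s in samples:
        if s.side != estimator.side:
            raise ValueError(
                f"sample side {s.side!r} does not match estimator side {estimator.side!r}")
    if not samples:
        return np.zeros((0, estimator.spec.output_size))
    x = _encode_inputs(samples, estimator)
    scaled = estimator.network.predict(x)
    return estimator.target_scaler.inverse(scaled)


def train_model_bank(dataset: GaitDataset,
                     architectures: Sequence[MlpSpec | CnnSpec],
                     config: TrainConfig,
                     components: Sequence[str] = COMPONENTS,
                     sides: Sequence[str] = SIDES,
                     out_dir: str | Path | None = None,
                     ) -> dict[tuple[str, str, str], TrainedEstimator]:
    """Train one estimator per (architecture, component, side) triple.

    With both architectures, all five components and both sides this is
    the full 20-model bank.  Failures are re-raised with the offending
    triple named.  If ``out_dir`` is given, each estimator and a
    ``manifest.csv`` are written there.
    """
    bank: dict[tuple[str, str, str], TrainedEstimator] = {}
    rows = []
    for spec in architectures:
        for comp in components:
            for side in sides:
                try:
                    est = train(spec, dataset, comp, side, config)
                except Exception as exc:
                    raise RuntimeError(
                        f"training failed for ({spec.name}, {comp}, {side}): {exc}") from exc
                bank[(spec.name, comp, side)] = est
                rows.append({"arch": spec.name, "component": comp, "side": side,
                             "final_loss": est.final_loss, "seed": config.seed})
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for key, est in bank.items():
            save_estimator(est, out_dir / "_".join(key))
        pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    return bank


# ---------------------------------------------------------------------------
# persistence: one weights archive + one JSON sidecar per estimator

def save_estimator(est: TrainedEstimator, stem: str | Path) -> tuple[Path, Path]:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    wpath = stem.with_suffix(".npz")
    np.savez_compressed(wpath, **{f"w{i}": w for i, w in enumerate(est.network.get_weights())})
    meta = {
        "arch": est.arch, "component": est.component, "side": est.side,
        "spec": est.spec.__dict__ | {"kind": type(est.spec).__name__},
        "config": est.config.__dict__,
        "target_scaler": est.target_scaler.to_dict(),
        "loss_history": est.loss_history,
        "channel_ranges": est.channel_ranges,
        "input_mean": None if est.input_mean is None else est.input_mean.tolist(),
        "input_std": None if est.input_std is None else est.input_std.tolist(),
    }
    jpath = stem.with_suffix(".json")
    jpath.write_text(json.dumps(meta))
    return wpath, jpath


def load_estimator(stem: str | Path) -> TrainedEstimator:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    spec_d = dict(meta["spec"])
    kind = spec_d.pop("kind")
    if kind == "MlpSpec":
        spec_d["hidden"] = tuple(spec_d["hidden"])
        spec: MlpSpec | CnnSpec = MlpSpec(**spec_d)
    else:
        spec = CnnSpec(**spec_d)
    config = TrainConfig(**meta["config"])
    rng = np.random.default_rng(0)     # weights overwritten below
    network = build_mlp(spec, rng) if kind == "MlpSpec" else build_cnn(spec, rng)
    arch = np.load(stem.with_suffix(".npz"))
    network.set_weights([arch[f"w{i}"] for i in range(len(arch.files))])
    est = TrainedEstimator(
        arch=meta["arch"], component=meta["component"], side=meta["side"],
        network=network, target_scaler=TargetScaler.from_dict(meta["target_scaler"]),
        spec=spec, config=config, loss_history=list(meta["loss_history"]),
        channel_ranges=None if meta["channel_ranges"] is None else
        [tuple(r) for r in meta["channel_ranges"]],
        input_mean=None if meta["input_mean"] is None else np.asarray(meta["input_mean"]),
        input_std=None if meta["input_std"] is None else np.asarray(meta["input_std"]),
    )
    return est
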