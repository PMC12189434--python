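"""Model/Results front end for the GRF + COP estimation study.

:class:`GaitKineticsModel` wraps a :class:`~gaitkinetics.preprocessing.GaitDataset`
together with the architectures, components and sides to fit;
:meth:`GaitKineticsModel.fit` trains the estimator bank and returns a
:class:`GaitKineticsResults` carrying the trained estimators, the held-out
evaluation report and a text ``summary()``.

Typical use::

    cfg = ExperimentConfig(master_seed=1, ...)
    dataset = build_dataset(cfg)
    model = GaitKineticsModel(dataset, architectures=("mlp",),
                              components=("GRFz",), epochs=200)
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .evaluation import EvaluationReport, evaluate_bank, plot_mean_curves, render_tables
from .models import (CnnSpec, MlpSpec, TrainConfig, TrainedEstimator,
                     train_model_bank)
from .preprocessing import COMPONENTS, GaitDataset

__all__ = ["GaitKineticsModel", "GaitKineticsResults"]


class GaitKineticsModel:
    """Stance-curve regression study on a gait dataset.

    Parameters
    ----------
    dataset
        Preprocessed samples with a subject-wise train/test split.
    architectures
        Architecture names ("mlp", "cnn") or explicit spec objects.
    components, sides
        Which target curves and stance sides to fit (defaults: all five
        components, both sides).
    epochs, batch_size, seed
        Training settings shared by all estimators.
    side_px
        CNN image size (227 canonical; smaller for scaled-down studies).
    """

    def __init__(self, dataset: GaitDataset,
                 architectures: Sequence[str | MlpSpec | CnnSpec] = ("mlp", "cnn"),
                 components: Sequence[str] = COMPONENTS,
                 sides: Sequence[str] = ("right", "left"),
                 epochs: int = 1000, batch_size: int = 128, seed: int = 0,
                 side_px: int = 227, mlp_learning_rate: float = 0.01,
                 cnn_learning_rate: float = 1e-4,
                 right_stance_policy: str = "first") -> None:
        self.dataset = dataset
        self.specs: list[MlpSpec | CnnSpec] = []
        for arch in architectures:
            if isinstance(arch, (MlpSpec, CnnSpec)):
                self.specs.append(arch)
            elif arch == "mlp":
                self.specs.append(MlpSpec(learning_rate=mlp_learning_rate))
            elif arch == "cnn":
                self.specs.append(CnnSpec(side_px=side_px,
                                          learning_rate=cnn_learning_rate))
            else:
                raise ValueError(f"unknown architecture {arch!r}")
        self.components = tuple(components)
        self.sides = tuple(sides)
        self.config = TrainConfig(batch_size=batch_size, epochs=epochs, seed=seed)
        self.right_stance_policy = right_stance_policy

    def fit(self, out_dir: str | Path | None = None) -> "GaitKineticsResults":
        """Train the estimator bank and evaluate it on the test partition."""
        bank = train_model_bank(self.dataset, self.specs, self.config,
                                components=self.components, sides=self.sides,
                                out_dir=out_dir)
        report = evaluate_bank(bank, self.dataset,
                               right_stance_policy=self.right_stance_policy)
        return GaitKineticsResults(model=self, bank=bank, report=report)


@dataclass
class GaitKineticsResults:
    """Trained estimators plus their held-out evaluation."""

    model: GaitKineticsModel
    bank: Mapping[tuple[str, str, str], TrainedEstimator]
    report: EvaluationReport

    @property
    def aggregates(self) -> pd.DataFrame:
        """Mean +- SD of r and rRMSE per (component, side, architecture)."""
        return self.report.aggregates

    def summary(self) -> str:
        n_test = (self.report.per_sample.groupby("arch")["sample_id"].count()
                  if not self.report.per_sample.empty else None)
        head = ["Gait kinetics estimation results",
                f"estimators: {len(self.bank)}  "
                f"(architectures={sorted({k[0] for k in self.bank})}, "
                f"components={sorted({k[1] for k in self.bank})}, "
                f"sides={sorted({k[2] for k in self.bank})})", ""]
        return "\n".join(head) + render_tables(self.report)

    def plot_mean_curves(self, component: str, side: str, ax=None):
        samples = self.model.dataset.test_samples(
            side=side, right_stance_policy=self.model.right_stance_policy)
        return plot_mean_curves(self.bank, samples, component, side, ax=ax)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        self.report.to_csv(directory)
        (directory / "tables.txt").write_text(self.summary())
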