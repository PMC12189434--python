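"""Curve-level evaluation: rRMSE, Pearson r, paired t-tests and reports.

The accuracy of an estimated stance curve u1 against its measured
counterpart u2 is summarized by

* ``rRMSE = 100 * RMSE / (0.5 * (range(u1) + range(u2)))`` (percent), and
* the product-moment correlation r over the 100 normalized time frames.

Per-sample metrics are aggregated as mean +- SD (sample SD, n-1) per
(component, side, architecture), and the two architectures are compared
with paired-samples t-tests at alpha = 0.05.  No multiple-testing
correction is applied across the comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import TrainedEstimator, predict
from .preprocessing import GaitDataset, StanceSample

__all__ = [
    "ZeroRangeError", "ConstantCurveError", "DegenerateTestError",
    "rrmse", "pearson_r", "paired_ttest",
    "EvaluationReport", "evaluate_bank", "render_tables", "plot_mean_curves",
]


class ZeroRangeError(ValueError):
    """Both curves are constant: the rRMSE denominator is zero."""


class ConstantCurveError(ValueError):
    """A constant curve has no defined correlation."""


class DegenerateTestError(ValueError):
    """Paired differences have zero variance: the t statistic is undefined."""


def _check_pair(estimated: np.ndarray, true: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    e = np.asarray(estimated, dtype=float).ravel()
    t = np.asarray(true, dtype=float).ravel()
    if e.shape != t.shape:
        raise ValueError(f"curve length mismatch: {e.size} vs {t.size}")
    if e.size < 2:
        raise ValueError("curves must have at least 2 points")
    return e, t


def rrmse(estimated: np.ndarray, true: np.ndarray) -> float:
    """Relative RMSE in percent: RMSE over the mean of the two ranges."""
    e, t = _check_pair(estimated, true)
    denom = 0.5 * ((e.max() - e.min()) + (t.max() - t.min()))
    if denom == 0.0:
        raise ZeroRangeError("both curves are constant; rRMSE undefined")
    rmse = float(np.sqrt(np.mean((e - t) ** 2)))
    return 100.0 * rmse / denom


def pearson_r(estimated: np.ndarray, true: np.ndarray) -> float:
    """Product-moment correlation of the two curves over their frames."""
    e, t = _check_pair(estimated, true)
    de = e - e.mean()
    dt = t - t.mean()
    se = np.sqrt(np.sum(de ** 2))
    st = np.sqrt(np.sum(dt ** 2))
    if se == 0.0 or st == 0.0:
        raise ConstantCurveError("correlation undefined for a constant curve")
    return float(np.sum(de * dt) / (se * st))


def paired_ttest(metric_a: Sequence[float], metric_b: Sequence[float]
                 ) -> tuple[float, float, int]:
    """Two-sided paired-samples t-test; returns (t, p, df).

    ``t = mean(d) / (sd(d)/sqrt(n))`` with ``d = a - b``, ``df = n - 1``.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = a - b
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise DegenerateTestError("zero variance of paired differences")
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, p, df


@dataclass
class EvaluationReport:
    """Per-sample metrics, mean +- SD aggregates and model comparisons."""

    per_sample: pd.DataFrame    # sample_id, component, side, arch, r, rrmse
    aggregates: pd.DataFrame    # component, side, arch, r_mean, r_sd, rrmse_mean, rrmse_sd, n
    comparisons: pd.DataFrame   # component, side, metric, t_value, p_value, df

    def to_csv(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, frame in (("report", self.per_sample),
                            ("aggregates", self.aggregates),
                            ("comparisons", self.comparisons)):
            path = directory / f"{name}.csv"
            frame.to_csv(path, index=False, float_format="%.6f")
            paths[name] = path
        return paths


def evaluate_bank(bank: Mapping[tuple[str, str, str], TrainedEstimator],
                  test_samples: Sequence[StanceSample] | GaitDataset,
                  right_stance_policy: str = "first") -> EvaluationReport:
    """Score every estimator in the bank on the test samples.

    ``test_samples`` may be a dataset (its test partition is used) or an
    explicit sample list.  Comparisons between architectures are paired by
    sample identity and computed wherever both architectures cover a
    (component, side).
    """
    if isinstance(test_samples, GaitDataset):
        samples = {side: test_samples.test_samples(side=side,
                                                   right_stance_policy=right_stance_policy)
                   for side in ("right", "left")}
    else:
        samples = {"right": [s for s in test_samples if s.side == "right"],
                   "left": [s for s in test_samples if s.side == "left"]}

    triples = sorted(bank.keys())
    rows = []
    for arch, comp, side in triples:
        est = bank[(arch, comp, side)]
        side_samples = samples[side]
        if not side_samples:
            continue
        preds = predict(est, side_samples)
        for s, pred in zip(side_samples, preds):
            rows.append({
                "sample_id": f"{s.trial_id}_s{s.stance_index}",
                "subject_id": s.subject_id, "component": comp, "side": side,
                "arch": arch,
                "r": pearson_r(pred, s.targets[comp]),
                "rrmse": rrmse(pred, s.targets[comp]),
            })
    per_sample = pd.DataFrame(rows)

    if per_sample.empty:
        empty_agg = pd.DataFrame(columns=["component", "side", "arch", "r_mean",
                                          "r_sd", "rrmse_mean", "rrmse_sd", "n"])
        empty_cmp = pd.DataFrame(columns=["component", "side", "metric",
                                          "t_value", "p_value", "df"])
        return EvaluationReport(per_sample, empty_agg, empty_cmp)

    agg = (per_sample.groupby(["component", "side", "arch"], as_index=False)
           .agg(r_mean=("r", "mean"), r_sd=("r", lambda v: v.std(ddof=1)),
                rrmse_mean=("rrmse", "mean"),
                rrmse_sd=("rrmse", lambda v: v.std(ddof=1)),
                n=("r", "size")))

    cmp_rows = []
    archs = sorted(per_sample["arch"].unique())
    if len(archs) == 2:
        a0, a1 = archs
        for (comp, side), grp in per_sample.groupby(["component", "side"]):
            pa = grp[grp["arch"] == a0].set_index("sample_id")
            pb = grp[grp["arch"] == a1].set_index("sample_id")
            common = pa.index.intersection(pb.index)
            if len(common) < 2:
                continue
            for metric in ("r", "rrmse"):
                try:
                    t, p, df = paired_ttest(pa.loc[common, metric].to_numpy(),
                                            pb.loc[common, metric].to_numpy())
                except DegenerateTestError:
                    t, p, df = np.nan, np.nan, len(common) - 1
                cmp_rows.append({"component": comp, "side": side, "metric": metric,
                                 "t_value": t, "p_value": p, "df": df})
    comparisons = pd.DataFrame(cmp_rows, columns=["component", "side", "metric",
                                                  "t_value", "p_value", "df"])
    return EvaluationReport(per_sample, agg, comparisons)


_COMP_ORDER = ("GRFx", "GRFy", "GRFz", "COPx", "COPy")


def render_tables(report: EvaluationReport) -> str:
    """Render the r and rRMSE summary tables as text.

    One row per (side, component); cells are mean +- SD per architecture;
    an asterisk flags comparisons with p strictly below 0.05.
    """
    if report.aggregates.empty:
        return ("Correlation coefficient (r)\n(no data)\n\n"
                "rRMSE (%)\n(no data)\n")
    archs = sorted(report.aggregates["arch"].unique())
    cmp_idx = {}
    for _, row in report.comparisons.iterrows():
        cmp_idx[(row["component"], row["side"], row["metric"])] = (
            row["t_value"], row["p_value"])

    def one_table(metric: str, title: str) -> str:
        mean_col, sd_col = f"{metric}_mean", f"{metric}_sd"
        header = ["Side", "Component"] + archs + ["t", "p"]
        lines = [title, "  ".join(f"{h:>12}" for h in header)]
        for side in ("right", "left"):
            for comp in _COMP_ORDER:
                sel = report.aggregates[(report.aggregates["side"] == side)
                                        & (report.aggregates["component"] == comp)]
                if sel.empty:
                    continue
                cells = [f"{side:>12}", f"{comp:>12}"]
                for arch in archs:
                    row = sel[sel["arch"] == arch]
                    if row.empty:
                        cells.append(f"{'-':>12}")
                    else:
                        cells.append(f"{row[mean_col].iloc[0]:.3f} ± "
                                     f"{row[sd_col].iloc[0]:.3f}".rjust(12))
                t_p = cmp_idx.get((comp, side, metric))
                if t_p is None or not np.isfinite(t_p[1]):
                    cells += [f"{'-':>12}", f"{'-':>12}"]
                else:
                    flag = "*" if t_p[1] < 0.05 else ""
                    cells.append(f"{t_p[0]:.3f}".rjust(12))
                    cells.append(f"{t_p[1]:.3f}{flag}".rjust(12))
                lines.append("  ".join(cells))
        return "\n".join(lines)

    footer = ("* p < 0.05 (paired-samples t-test, two-sided); "
              "no multiple-testing correction applied.")
    return (one_table("r", "Correlation coefficient (r)") + "\n\n"
            + one_table("rrmse", "rRMSE (%)") + "\n\n" + footer + "\n")


def plot_mean_curves(bank: Mapping[tuple[str, str, str], TrainedEstimator],
                     test_samples: Sequence[StanceSample], component: str,
                     side: str, ax=None):
    """Convenience overlay of mean true vs mean predicted curve."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    side_samples = [s for s in test_samples if s.side == side]
    truth = np.stack([s.targets[component] for s in side_samples]).mean(axis=0)
    pct = np.linspace(0, 100, truth.size)
    ax.plot(pct, truth, "-", label="true (mean)")
    for (arch, comp, sd), est in sorted(bank.items()):
        if comp != component or sd != side:
            continue
        pred = predict(est, side_samples).mean(axis=0)
        ax.plot(pct, pred, "--", label=f"{arch} (mean)")
    ax.set_xlabel("stance phase (%)")
    unit = "BW" if component.startswith("GRF") else "mm"
    ax.set_ylabel(f"{component} [{unit}]")
    ax.legend()
    return ax
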