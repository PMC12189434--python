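"""Metrics, paired tests, report aggregation and table rendering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gaitkinetics import evaluation
from gaitkinetics.evaluation import (ConstantCurveError, DegenerateTestError,
                                     EvaluationReport, ZeroRangeError,
                                     evaluate_bank, paired_ttest, pearson_r,
                                     render_tables, rrmse)


def rrmse_oracle(e, t):
    """Brute-force rRMSE: explicit loops, no shared code with the package."""
    T = len(e)
    sq = sum((e[i] - t[i]) ** 2 for i in range(T))
    rmse = (sq / T) ** 0.5
    denom = ((max(e) - min(e)) + (max(t) - min(t))) / 2.0
    return 100.0 * rmse / denom


def pearson_oracle(e, t):
    T = len(e)
    me = sum(e) / T
    mt = sum(t) / T
    cov = sum((e[i] - me) * (t[i] - mt) for i in range(T))
    ve = sum((x - me) ** 2 for x in e)
    vt = sum((x - mt) ** 2 for x in t)
    return cov / (ve ** 0.5 * vt ** 0.5)


class TestRrmse:
    def test_identity_is_zero(self):
        y = np.random.default_rng(0).normal(size=100)
        assert rrmse(y, y) == 0.0

    def test_hand_computed_offset_example(self):
        true = np.arange(10, dtype=float)
        est = true + 2.0
        # RMSE = 2, both ranges 9 -> 100 * 2 / 9
        assert rrmse(est, true) == pytest.approx(22.222, abs=1e-3)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        e, t = rng.normal(size=100), rng.normal(size=100)
        base = rrmse(e, t)
        for c in (0.5, 3.0, 1e4):
            assert rrmse(c * e, c * t) == pytest.approx(base, rel=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000),
           st.floats(min_value=-100, max_value=100))
    def test_translation_invariance(self, seed, shift):
        rng = np.random.default_rng(seed)
        e, t = rng.normal(size=50), rng.normal(size=50)
        assert rrmse(e + shift, t + shift) == pytest.approx(rrmse(e, t), rel=1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            e = rng.normal(size=100)
            t = rng.normal(size=100)
            assert rrmse(e, t) == pytest.approx(rrmse_oracle(list(e), list(t)),
                                                abs=1e-10)

    def test_zero_range_error(self):
        with pytest.raises(ZeroRangeError):
            rrmse(np.full(10, 2.0), np.full(10, 3.0))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            rrmse(np.zeros(10), np.zeros(11))


class TestPearsonR:
    def test_positive_affine_gives_one(self):
        t = np.random.default_rng(2).normal(size=100)
        assert pearson_r(2.0 * t + 3.0, t) == pytest.approx(1.0, abs=1e-12)

    def test_negation_gives_minus_one(self):
        t = np.random.default_rng(3).normal(size=100)
        assert pearson_r(-t, t) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            e = rng.normal(size=100)
            t = rng.normal(size=100)
            assert pearson_r(e, t) == pytest.approx(pearson_oracle(list(e), list(t)),
                                                    abs=1e-12)

    def test_matches_numpy_corrcoef(self):
        rng = np.random.default_rng(5)
        e, t = rng.normal(size=100), rng.normal(size=100)
        assert pearson_r(e, t) == pytest.approx(np.corrcoef(e, t)[0, 1], abs=1e-12)

    def test_constant_curve_error(self):
        with pytest.raises(ConstantCurveError):
            pearson_r(np.full(10, 1.0), np.arange(10, dtype=float))


class TestPairedTtest:
    def test_closed_form_hand_example(self):
        b = np.zeros(4)
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, p, df = paired_ttest(a, b)
        # d = (1,2,3,4): mean 2.5, sd 1.2910 -> t = 2.5 / (1.2910/2)
        assert t == pytest.approx(3.873, abs=1e-3)
        assert df == 3

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a = rng.normal(size=30)
            b = rng.normal(size=30)
            t, p, df = paired_ttest(a, b)
            ref = stats.ttest_rel(a, b)
            assert t == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)
            assert df == 29

    def test_antisymmetry(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=20), rng.normal(size=20)
        t1, p1, _ = paired_ttest(a, b)
        t2, p2, _ = paired_ttest(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_identical_inputs_degenerate(self):
        a = np.arange(5, dtype=float)
        with pytest.raises(DegenerateTestError):
            paired_ttest(a, a.copy())

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0], [2.0])


class _OracleEstimator:
    """Stand-in estimator whose predictions are the true target curves."""

    def __init__(self, arch, component, side):
        self.arch, self.component, self.side = arch, component, side


class TestEvaluateBank:
    @pytest.fixture()
    def oracle_bank(self, monkeypatch):
        def perfect_predict(est, samples):
            return np.stack([s.targets[est.component] for s in samples])
        monkeypatch.setattr(evaluation, "predict", perfect_predict)
        return {(a, c, s): _OracleEstimator(a, c, s)
                for a in ("mlp", "cnn") for c in ("GRFz", "COPy")
                for s in ("right", "left")}

    def test_perfect_oracle_scores(self, oracle_bank, tiny_dataset):
        report = evaluate_bank(oracle_bank, tiny_dataset)
        assert np.allclose(report.per_sample["r"], 1.0)
        assert np.allclose(report.per_sample["rrmse"], 0.0)

    def test_row_counts_per_triple(self, oracle_bank, tiny_dataset):
        report = evaluate_bank(oracle_bank, tiny_dataset)
        counts = report.per_sample.groupby(["arch", "component", "side"]).size()
        n_right = len(tiny_dataset.test_samples(side="right"))
        n_left = len(tiny_dataset.test_samples(side="left"))
        for (arch, comp, side), n in counts.items():
            assert n == (n_right if side == "right" else n_left)

    def test_aggregates_match_recomputation(self, oracle_bank, tiny_dataset, monkeypatch):
        def noisy_predict(est, samples):
            rng = np.random.default_rng(abs(hash((est.arch, est.component, est.side))) % 2**31)
            return np.stack([s.targets[est.component] + rng.normal(0, 0.05, 100)
                             for s in samples])
        monkeypatch.setattr(evaluation, "predict", noisy_predict)
        report = evaluate_bank(oracle_bank, tiny_dataset)
        for _, row in report.aggregates.iterrows():
            grp = report.per_sample[
                (report.per_sample["component"] == row["component"])
                & (report.per_sample["side"] == row["side"])
                & (report.per_sample["arch"] == row["arch"])]
            assert row["r_mean"] == pytest.approx(grp["r"].mean(), abs=1e-12)
            assert row["r_sd"] == pytest.approx(grp["r"].std(ddof=1), abs=1e-12)
            assert row["rrmse_mean"] == pytest.approx(grp["rrmse"].mean(), abs=1e-12)
        assert not report.comparisons.empty

    def test_csv_round_trip(self, oracle_bank, tiny_dataset, tmp_path):
        report = evaluate_bank(oracle_bank, tiny_dataset)
        paths = report.to_csv(tmp_path)
        assert set(paths) == {"report", "aggregates", "comparisons"}
        assert (tmp_path / "aggregates.csv").exists()


def _toy_report(p_value):
    agg = pd.DataFrame([
        {"component": c, "side": s, "arch": a, "r_mean": 0.95, "r_sd": 0.01,
         "rrmse_mean": 7.0, "rrmse_sd": 1.0, "n": 10}
        for c in ("GRFx", "GRFy", "GRFz", "COPx", "COPy")
        for s in ("right", "left") for a in ("mlp", "cnn")])
    cmp_ = pd.DataFrame([
        {"component": c, "side": s, "metric": m, "t_value": 2.0,
         "p_value": p_value, "df": 9}
        for c in ("GRFx", "GRFy", "GRFz", "COPx", "COPy")
        for s in ("right", "left") for m in ("r", "rrmse")])
    return EvaluationReport(pd.DataFrame({"x": [1]}), agg, cmp_)


class TestRenderTables:
    def test_full_report_has_ten_rows_per_table(self):
        text = render_tables(_toy_report(0.01))
        lines = [l for l in text.splitlines() if l.strip().startswith(("right", "left"))]
        assert len(lines) == 20          # 2 tables x (2 sides x 5 components)

    def test_empty_report(self):
        empty = EvaluationReport(pd.DataFrame(), pd.DataFrame(), pd.DataFrame())
        assert "(no data)" in render_tables(empty)

    def test_significance_flag_strict_inequality(self):
        assert "*" not in render_tables(_toy_report(0.05)).replace(
            "* p < 0.05", "")          # footer aside, no flags at p = 0.05
        flagged = render_tables(_toy_report(0.049))
        assert "0.049*" in flagged
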