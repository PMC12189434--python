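"""Event detection, segmentation, spline normalization and splitting."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitkinetics.preprocessing import (COMPONENTS, GaitDataset, NoContactError,
                                        SegmentationError, build_sample,
                                        build_samples_from_trial,
                                        detect_stance_events, segment_cycle,
                                        split_by_subject, time_normalize)
from gaitkinetics.synthetic import ForcePlateRecord, sample_population, simulate_trial
from conftest import NOISE_FREE


def natural_spline_oracle(y: np.ndarray, x_out: np.ndarray) -> np.ndarray:
    """Textbook natural cubic spline via direct tridiagonal solve.

    Solves for the interior second derivatives M_i of the spline on the
    uniform grid x_i = i/(n-1) with M_0 = M_{n-1} = 0, then evaluates the
    piecewise cubic.  Independent of scipy's implementation.
    """
    n = y.size
    x = np.linspace(0.0, 1.0, n)
    h = x[1] - x[0]
    # tridiagonal system: h/6 M_{i-1} + 2h/3 M_i + h/6 M_{i+1} = d_i
    m = n - 2
    A = np.zeros((m, m))
    rhs = np.zeros(m)
    for i in range(m):
        A[i, i] = 2.0 * h / 3.0
        if i > 0:
            A[i, i - 1] = h / 6.0
        if i < m - 1:
            A[i, i + 1] = h / 6.0
        rhs[i] = (y[i + 2] - y[i + 1]) / h - (y[i + 1] - y[i]) / h
    M = np.zeros(n)
    M[1:-1] = np.linalg.solve(A, rhs)
    out = np.empty_like(x_out)
    for j, xo in enumerate(x_out):
        i = min(int(np.floor(xo / h)), n - 2)
        a, b = x[i], x[i + 1]
        t1, t2 = xo - a, b - xo
        out[j] = (M[i] * t2**3 + M[i + 1] * t1**3) / (6 * h) \
            + (y[i] / h - M[i] * h / 6) * t2 + (y[i + 1] / h - M[i + 1] * h / 6) * t1
    return out


class TestDetectStanceEvents:
    def test_matches_generator_truth_within_10ms(self, quiet_trial):
        for plate, (_, hs, to) in zip(quiet_trial.plates, quiet_trial.true_events):
            hs_d, to_d = detect_stance_events(plate)
            assert abs(hs_d - hs) < 0.010
            assert abs(to_d - to) < 0.010

    def test_robust_to_default_noise(self, noisy_trial):
        for plate, (_, hs, to) in zip(noisy_trial.plates, noisy_trial.true_events):
            hs_d, to_d = detect_stance_events(plate)
            assert abs(hs_d - hs) < 0.010
            assert abs(to_d - to) < 0.010

    def test_all_zero_record_raises(self):
        plate = ForcePlateRecord(plate_id=1, side="right",
                                 grf=np.zeros((500, 3)), cop=np.full((500, 2), np.nan),
                                 rate_hz=1000.0)
        with pytest.raises(NoContactError):
            detect_stance_events(plate)

    def test_threshold_above_peak_raises(self, quiet_trial):
        plate = quiet_trial.plates[0]
        with pytest.raises(NoContactError):
            detect_stance_events(plate, threshold_n=plate.grf[:, 2].max() + 1.0)

    def test_short_blips_ignored(self):
        fz = np.zeros(2000)
        fz[100:130] = 500.0            # 30 ms blip: below the 100 ms debounce
        fz[500:1200] = 600.0
        plate = ForcePlateRecord(plate_id=1, side="right",
                                 grf=np.stack([np.zeros(2000)] * 2 + [fz], axis=1),
                                 cop=np.full((2000, 2), np.nan), rate_hz=1000.0)
        hs, to = detect_stance_events(plate)
        assert hs == pytest.approx(0.5, abs=2e-3)
        assert to == pytest.approx(1.199, abs=2e-3)


class TestSegmentCycle:
    def test_three_segments_right_left_right(self, quiet_trial):
        segments = segment_cycle(quiet_trial)
        assert len(segments) == 3
        assert [s.side for s in segments] == ["right", "left", "right"]
        assert [s.stance_index for s in segments] == [1, 2, 3]

    def test_segment_frames_lie_in_stance(self, quiet_trial):
        for seg in segment_cycle(quiet_trial):
            assert seg.kin_times_s[0] >= seg.heel_strike_s
            assert seg.kin_times_s[-1] <= seg.toe_off_s
            assert seg.kin_times_s.size >= 4
            assert seg.kinetic_times_s.size > seg.kin_times_s.size

    def test_out_of_order_events_rejected(self, quiet_trial):
        (s1, h1, t1), (s2, h2, t2), (s3, h3, t3) = quiet_trial.true_events
        with pytest.raises(SegmentationError):
            segment_cycle(quiet_trial, events=[(s2, h2, t2), (s1, h1, t1), (s3, h3, t3)])

    def test_missing_stance_named(self, quiet_trial):
        silent = ForcePlateRecord(plate_id=2, side="left",
                                  grf=np.zeros_like(quiet_trial.plates[1].grf),
                                  cop=np.full_like(quiet_trial.plates[1].cop, np.nan),
                                  rate_hz=1000.0)
        broken = dataclasses.replace(quiet_trial,
                                     plates=[quiet_trial.plates[0], silent,
                                             quiet_trial.plates[2]])
        with pytest.raises(SegmentationError, match="plate 2"):
            segment_cycle(broken)


class TestTimeNormalize:
    def test_identity_on_matching_grid(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=100)
        np.testing.assert_allclose(time_normalize(y, 100), y, atol=1e-12)

    def test_reproduces_cubic_polynomials(self):
        x = np.linspace(0.0, 1.0, 37)
        y = 2.0 - x + 3.0 * x**2 - 0.5 * x**3
        out = time_normalize(y, 100)
        ref = np.linspace(0.0, 1.0, 100)
        expected = 2.0 - ref + 3.0 * ref**2 - 0.5 * ref**3
        np.testing.assert_allclose(out, expected, rtol=1e-9, atol=1e-12)

    def test_matches_tridiagonal_oracle(self):
        rng = np.random.default_rng(3)
        for n in (7, 23, 64, 311):
            y = rng.normal(size=n)
            x_out = np.linspace(0.0, 1.0, 100)
            np.testing.assert_allclose(time_normalize(y, 100, bc_type="natural"),
                                       natural_spline_oracle(y, x_out), atol=1e-8)

    def test_endpoints_preserved(self):
        y = np.random.default_rng(5).normal(size=17)
        out = time_normalize(y, 100)
        assert out[0] == y[0]
        assert out[-1] == y[-1]

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            time_normalize(np.array([1.0, 2.0, 3.0]), 100)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=4, max_value=60))
    def test_idempotent_on_own_output(self, n):
        y = np.random.default_rng(n).normal(size=n)
        once = time_normalize(y, 100)
        np.testing.assert_allclose(time_normalize(once, 100), once, atol=1e-12)

    def test_multidimensional_along_axis0(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(50, 4))
        out = time_normalize(y, 100)
        assert out.shape == (100, 4)
        np.testing.assert_allclose(out[:, 2], time_normalize(y[:, 2], 100), atol=1e-12)


class TestBuildSample:
    def test_shapes_and_components(self, quiet_trial):
        samples = build_samples_from_trial(quiet_trial)
        assert len(samples) == 3
        for s in samples:
            assert s.kin.shape == (3, 21, 100)
            assert set(s.targets) == set(COMPONENTS)

    def test_vertical_grf_peak_in_bw_units(self, quiet_trial):
        for s in build_samples_from_trial(quiet_trial):
            assert 1.0 <= s.targets["GRFz"].max() <= 1.3
            assert np.all(s.targets["GRFz"] >= -0.05)

    def test_cop_heel_referenced_near_zero_at_heel_strike(self, quiet_trial, subject):
        for s in build_samples_from_trial(quiet_trial):
            # COP starts just anterior of the heel marker (~5% foot length)
            assert abs(s.targets["COPy"][0]) < 0.1 * subject.foot_length * 1000
            assert s.targets["COPy"][-1] > 0.7 * subject.foot_length * 1000

    def test_pelvis_referenced_kinematics(self, quiet_trial):
        s = build_samples_from_trial(quiet_trial)[0]
        pelvis0 = s.kin[:, 2, 0]              # pelvis is marker index 2
        np.testing.assert_allclose(pelvis0, 0.0, atol=1e-9)

    def test_bw_normalization_halves_when_mass_doubles(self, quiet_trial):
        seg = segment_cycle(quiet_trial)[0]
        s1 = build_sample(seg, quiet_trial.subject)
        heavier = dataclasses.replace(quiet_trial.subject,
                                      mass=2 * quiet_trial.subject.mass)
        s2 = build_sample(seg, heavier)
        for comp in ("GRFx", "GRFy", "GRFz"):
            np.testing.assert_allclose(s2.targets[comp], 0.5 * s1.targets[comp],
                                       atol=1e-12)
        np.testing.assert_allclose(s2.targets["COPy"], s1.targets["COPy"], atol=1e-12)

    def test_two_right_one_left_per_trial(self, tiny_dataset):
        frame = tiny_dataset.index_frame()
        per_trial = frame.groupby("trial_id")["side"].value_counts().unstack()
        assert (per_trial["right"] == 2).all()
        assert (per_trial["left"] == 1).all()


class TestSplitBySubject:
    def test_split_counts_and_disjointness(self):
        pop = sample_population(8, 8, seed=2)
        samples = []
        for subj in pop:
            trial = simulate_trial(subj, 0, NOISE_FREE)
            samples.extend(build_samples_from_trial(trial))
        ds = split_by_subject(GaitDataset(samples), 2, 2, seed=5)
        test_ids = {sid for sid, part in ds.split.items() if part == "test"}
        train_ids = {sid for sid, part in ds.split.items() if part == "train"}
        assert len(test_ids) == 4
        assert len(train_ids) == 12
        assert not test_ids & train_ids
        train_subjects = {s.subject_id for s in ds.train_samples()}
        assert not train_subjects & test_ids

    def test_deterministic(self, tiny_dataset):
        a = split_by_subject(tiny_dataset, 2, 2, seed=9)
        b = split_by_subject(tiny_dataset, 2, 2, seed=9)
        assert a.split == b.split

    def test_zero_test_counts(self, tiny_dataset):
        ds = split_by_subject(tiny_dataset, 0, 0, seed=1)
        assert all(v == "train" for v in ds.split.values())

    def test_insufficient_subjects_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            split_by_subject(tiny_dataset, 100, 0, seed=1)

    def test_right_stance_policy(self, tiny_dataset):
        first = tiny_dataset.test_samples(side="right", right_stance_policy="first")
        second = tiny_dataset.test_samples(side="right", right_stance_policy="second")
        both = tiny_dataset.test_samples(side="right", right_stance_policy="both")
        assert {s.stance_index for s in first} == {1}
        assert {s.stance_index for s in second} == {3}
        assert len(both) == len(first) + len(second)


class TestDatasetPersistence:
    def test_round_trip(self, tiny_dataset, tmp_path):
        path = tiny_dataset.save(tmp_path / "dataset.npz")
        assert (tmp_path / "samples.csv").exists()
        back = GaitDataset.load(path)
        assert len(back.samples) == len(tiny_dataset.samples)
        assert back.split == tiny_dataset.split
        np.testing.assert_array_equal(back.samples[5].kin, tiny_dataset.samples[5].kin)
        np.testing.assert_array_equal(back.samples[5].targets["COPx"],
                                      tiny_dataset.samples[5].targets["COPx"])
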