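"""From raw trials to model-ready stance samples.

A gait cycle is segmented into its three support phases (right, left,
right), each phase is time-normalized to 100 points with natural cubic
splines (0% = heel strike, 100% = toe-off), forces are expressed in body
weights and COP in millimetres relative to the stance-side heel at heel
strike.  Datasets are split into train/test by whole subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .synthetic import ForcePlateRecord, GaitTrial, SubjectProfile, MARKER_NAMES

__all__ = [
    "StanceSample",
    "GaitDataset",
    "RawStanceSegment",
    "NoContactError",
    "SegmentationError",
    "detect_stance_events",
    "segment_cycle",
    "time_normalize",
    "build_sample",
    "build_samples_from_trial",
    "split_by_subject",
]

COMPONENTS = ("GRFx", "GRFy", "GRFz", "COPx", "COPy")


class NoContactError(RuntimeError):
    """Raised when no sustained loading is found on a force plate."""


class SegmentationError(RuntimeError):
    """Raised when a cycle does not decompose into three R-L-R stances."""


@dataclass
class RawStanceSegment:
    """One support phase before time normalization."""

    side: str
    stance_index: int                 # 1..3 within the cycle (1 and 3 right)
    kin_times_s: np.ndarray
    kin_mm: np.ndarray                # frames x 21 x 3
    kinetic_times_s: np.ndarray
    grf_n: np.ndarray                 # frames x 3
    cop_mm: np.ndarray                # frames x 2, NaN while unloaded
    heel_strike_s: float
    toe_off_s: float


@dataclass
class StanceSample:
    """One model-ready support phase.

    ``kin`` is the 3 x 21 x 100 tensor (coordinate x marker x normalized
    time, mm, pelvis-at-heel-strike referenced); ``targets`` maps each of
    GRFx/GRFy/GRFz (BW) and COPx/COPy (mm, heel-referenced) to a length-100
    curve.
    """

    subject_id: str
    sex: str
    side: str
    stance_index: int
    kin: np.ndarray
    targets: dict[str, np.ndarray]
    trial_id: str = ""

    def __post_init__(self) -> None:
        if self.kin.shape != (3, 21, 100):
            raise ValueError(f"kin must have shape (3, 21, 100), got {self.kin.shape}")
        for comp in COMPONENTS:
            if comp not in self.targets or self.targets[comp].shape != (100,):
                raise ValueError(f"target {comp} must be a length-100 curve")


@dataclass
class GaitDataset:
    """A collection of stance samples with a subject-wise train/test split."""

    samples: list[StanceSample]
    split: dict[str, str] = field(default_factory=dict)   # subject_id -> train|test

    def _of(self, part: str, side: str | None,
            right_stance_policy: str = "both") -> list[StanceSample]:
        if right_stance_policy not in ("first", "second", "both"):
            raise ValueError(f"unknown right_stance_policy {right_stance_policy!r}")
        out = []
        for s in self.samples:
            if self.split.get(s.subject_id, "train") != part:
                continue
            if side is not None and s.side != side:
                continue
            if s.side == "right" and right_stance_policy != "both":
                want = 1 if right_stance_policy == "first" else 3
                if s.stance_index != want:
                    continue
            out.append(s)
        return out

    def train_samples(self, side: str | None = None) -> list[StanceSample]:
        return self._of("train", side)

    def test_samples(self, side: str | None = None,
                     right_stance_policy: str = "first") -> list[StanceSample]:
        """Test partition; for the right side, ``right_stance_policy``
        selects the first, second or both stances of each cycle."""
        return self._of("test", side, right_stance_policy)

    def index_frame(self) -> pd.DataFrame:
        rows = [{
            "subject_id": s.subject_id, "sex": s.sex, "side": s.side,
            "stance_index": s.stance_index, "trial_id": s.trial_id,
            "split": self.split.get(s.subject_id, "train"),
        } for s in self.samples]
        return pd.DataFrame(rows)

    # -- persistence (runtime artifact: npz tensor archive + CSV index) ----
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        kin = np.stack([s.kin for s in self.samples]) if self.samples else np.zeros((0, 3, 21, 100))
        tgt = {c: np.stack([s.targets[c] for s in self.samples]) if self.samples
               else np.zeros((0, 100)) for c in COMPONENTS}
        np.savez_compressed(path, kin=kin, **{f"target_{c}": tgt[c] for c in COMPONENTS})
        self.index_frame().to_csv(path.parent / "samples.csv", index=False)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "GaitDataset":
        path = Path(path)
        arch = np.load(path)
        idx = pd.read_csv(path.parent / "samples.csv", keep_default_na=False)
        samples = []
        for i, row in idx.iterrows():
            samples.append(StanceSample(
                subject_id=str(row["subject_id"]), sex=str(row["sex"]),
                side=str(row["side"]), stance_index=int(row["stance_index"]),
                kin=arch["kin"][i],
                targets={c: arch[f"target_{c}"][i] for c in COMPONENTS},
                trial_id=str(row["trial_id"]),
            ))
        split = {str(r["subject_id"]): str(r["split"]) for _, r in idx.iterrows()}
        return cls(samples=samples, split=split)


def detect_stance_events(plate: ForcePlateRecord, threshold_n: float = 20.0,
                         min_duration_s: float = 0.1) -> tuple[float, float]:
    """Detect (heel_strike_s, toe_off_s) from a plate's vertical force.

    The first interval during which Fz stays above ``threshold_n`` for at
    least ``min_duration_s`` is taken as the stance; times are those of the
    first and last super-threshold frames.
    """
    if plate.grf.shape[0] == 0:
        raise NoContactError("empty force record")
    if threshold_n <= 0:
        raise ValueError("threshold must be positive")
    above = plate.grf[:, 2] > threshold_n
    if not above.any():
        raise NoContactError(
            f"no contact detected on plate {plate.plate_id} (threshold {threshold_n} N)")
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)     # exclusive
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size)
    min_frames = int(np.ceil(min_duration_s * plate.rate_hz))
    t = plate.times_s
    for s, e in zip(starts, ends):
        if e - s >= min_frames:
            return float(t[s]), float(t[e - 1])
    raise NoContactError(
        f"no sustained (>= {min_duration_s*1e3:.0f} ms) contact on plate {plate.plate_id}")


def segment_cycle(trial: GaitTrial,
                  events: list[tuple[str, float, float]] | None = None,
                  threshold_n: float = 20.0,
                  min_duration_s: float = 0.1) -> list[RawStanceSegment]:
    """Split one cycle into its three stance segments (right, left, right).

    Events are detected per plate from the vertical force unless supplied.
    Raises :class:`SegmentationError` when fewer than three stances are
    found or they violate the R-L-R ordering.
    """
    if events is None:
        events = []
        for plate in trial.plates:
            try:
                hs, to = detect_stance_events(plate, threshold_n, min_duration_s)
            except NoContactError as exc:
                raise SegmentationError(
                    f"missing stance phase on plate {plate.plate_id} "
                    f"({plate.side} foot): {exc}") from exc
            events.append((plate.side, hs, to))
    if len(events) != 3:
        raise SegmentationError(f"expected 3 stance phases, got {len(events)}")
    sides = [e[0] for e in events]
    if sides != ["right", "left", "right"]:
        raise SegmentationError(f"stance sides {sides} violate the R-L-R pattern")
    hs_times = [e[1] for e in events]
    if not hs_times[0] < hs_times[1] < hs_times[2]:
        raise SegmentationError("heel strikes out of order for the R-L-R pattern")

    tk = trial.markers.times_s
    segments = []
    for idx, ((side, hs, to), plate) in enumerate(zip(events, trial.plates), start=1):
        kin_mask = (tk >= hs) & (tk <= to)
        tp = plate.times_s
        kinetic_mask = (tp >= hs) & (tp <= to)
        segments.append(RawStanceSegment(
            side=side, stance_index=idx,
            kin_times_s=tk[kin_mask],
            kin_mm=trial.markers.positions[kin_mask],
            kinetic_times_s=tp[kinetic_mask],
            grf_n=plate.grf[kinetic_mask],
            cop_mm=plate.cop[kinetic_mask],
            heel_strike_s=hs, toe_off_s=to,
        ))
    return segments


def time_normalize(curve: np.ndarray, n_out: int = 100,
                   bc_type: str = "not-a-knot") -> np.ndarray:
    """Resample a uniformly sampled curve to ``n_out`` points on [0, 1].

    Fits a cubic interpolating spline through the input samples (assumed
    uniformly spaced over the segment) and evaluates it on a uniform
    ``n_out``-point grid spanning the same interval; endpoints are
    preserved exactly.  Works along axis 0 for multi-dimensional input.

    The default not-a-knot boundary condition reproduces cubic
    polynomials exactly; ``bc_type="natural"`` (zero end curvature) is
    also supported.
    """
    curve = np.asarray(curve, dtype=float)
    n = curve.shape[0]
    if n < 4:
        raise ValueError(f"segment too short for cubic interpolation (n={n} < 4)")
    x = np.linspace(0.0, 1.0, n)
    spline = CubicSpline(x, curve, axis=0, bc_type=bc_type)
    out = spline(np.linspace(0.0, 1.0, n_out))
    out[0] = curve[0]
    out[-1] = curve[-1]
    return out


def _fill_cop_gaps(cop: np.ndarray) -> np.ndarray:
    """Replace NaN COP frames (unloaded plate edges) by nearest valid value."""
    cop = cop.copy()
    for j in range(cop.shape[1]):
        col = cop[:, j]
        valid = np.flatnonzero(~np.isnan(col))
        if valid.size == 0:
            raise ValueError("COP undefined over the whole stance")
        idx = np.arange(col.size)
        cop[:, j] = np.interp(idx, valid, col[valid])
    return cop


def build_sample(segment: RawStanceSegment, subject: SubjectProfile,
                 n_points: int = 100, trial_id: str = "") -> StanceSample:
    """Turn a raw stance segment into a normalized :class:`StanceSample`.

    Kinematics are spline-resampled to ``n_points`` per marker and
    coordinate and re-referenced to the pelvis position at heel strike;
    GRF is divided by body weight; COP is re-referenced to the stance-side
    heel marker position at heel strike (mm).
    """
    if np.isnan(segment.kin_mm).any():
        raise ValueError("marker data contains gaps")
    kin = time_normalize(segment.kin_mm, n_points)          # n x 21 x 3
    pelvis_hs = kin[0, MARKER_NAMES.index("pelvis"), :].copy()
    kin = kin - pelvis_hs[None, None, :]
    kin = np.ascontiguousarray(kin.transpose(2, 1, 0))      # 3 x 21 x n

    bw = subject.body_weight_n
    grf = time_normalize(segment.grf_n, n_points) / bw      # n x 3, BW

    heel = f"{segment.side[0]}_heel"
    heel_hs = segment.kin_mm[0, MARKER_NAMES.index(heel), :2]
    cop = time_normalize(_fill_cop_gaps(segment.cop_mm), n_points) - heel_hs[None, :]

    targets = {
        "GRFx": grf[:, 0], "GRFy": grf[:, 1], "GRFz": grf[:, 2],
        "COPx": cop[:, 0], "COPy": cop[:, 1],
    }
    return StanceSample(subject_id=subject.subject_id, sex=subject.sex,
                        side=segment.side, stance_index=segment.stance_index,
                        kin=kin, targets=targets, trial_id=trial_id)


def build_samples_from_trial(trial: GaitTrial, threshold_n: float = 20.0,
                             use_true_events: bool = False) -> list[StanceSample]:
    """Segment one trial and build its three stance samples."""
    events = trial.true_events if use_true_events else None
    segments = segment_cycle(trial, events=events, threshold_n=threshold_n)
    return [build_sample(seg, trial.subject, trial_id=trial.trial_id)
            for seg in segments]


def split_by_subject(dataset: GaitDataset, n_test_male: int, n_test_female: int,
                     seed: int) -> GaitDataset:
    """Assign whole subjects to the test partition, the rest to train.

    Deterministic given ``seed``; raises when a sex has fewer subjects
    than requested.
    """
    if n_test_male < 0 or n_test_female < 0:
        raise ValueError("test counts must be non-negative")
    by_sex: dict[str, list[str]] = {"male": [], "female": []}
    seen = set()
    for s in dataset.samples:
        if s.subject_id not in seen:
            seen.add(s.subject_id)
            by_sex[s.sex].append(s.subject_id)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    test_ids: set[str] = set()
    for sex, n_test in (("male", n_test_male), ("female", n_test_female)):
        pool = sorted(by_sex[sex])
        if len(pool) < n_test:
            raise ValueError(
                f"cannot hold out {n_test} {sex} subjects from {len(pool)}")
        test_ids.update(rng.choice(pool, size=n_test, replace=False))
    split = {sid: ("test" if sid in test_ids else "train") for sid in seen}
    return GaitDataset(samples=dataset.samples, split=split)
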