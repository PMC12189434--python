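"""Synthetic gait generator: subject populations and physically consistent trials.

The generator emulates an overground walking protocol in which a subject
crosses three in-ground force plates in a right-left-right stepping pattern
while 21 full-body landmarks are tracked at 100 Hz and the plates record
three GRF components plus the planar center of pressure at 1000 Hz.

The kinetics are Newtonian by construction: a smooth center-of-mass (CoM)
trajectory is prescribed and the total ground reaction force is
``F = m (a_CoM + g)``, shared between feet by linear double-support ramps
that partition unity.  The mapping from the (noise-free) marker
trajectories to the force and COP curves is therefore deterministic, which
is what makes the data learnable by a regressor.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MARKER_NAMES",
    "GeneratorConfig",
    "SubjectProfile",
    "MarkerTrajectorySet",
    "ForcePlateRecord",
    "GaitTrial",
    "sample_population",
    "simulate_trial",
    "write_trial",
    "read_trial",
]

G = 9.81  # m/s^2

#: Canonical ordered landmark set: 1 head + 1 C7 + 1 pelvis center + 9
#: bilateral pairs (shoulder, elbow, wrist, hand, hip, knee, ankle, heel,
#: toe).  The order is frozen: model inputs and image rows depend on it.
MARKER_NAMES: tuple[str, ...] = (
    "head", "c7", "pelvis",
    "r_shoulder", "l_shoulder",
    "r_elbow", "l_elbow",
    "r_wrist", "l_wrist",
    "r_hand", "l_hand",
    "r_hip", "l_hip",
    "r_knee", "l_knee",
    "r_ankle", "l_ankle",
    "r_heel", "l_heel",
    "r_toe", "l_toe",
)

_PELVIS = MARKER_NAMES.index("pelvis")

# Per-sex anthropometric population parameters (mean, SD): age [y],
# height [m], mass [kg] for a young-adult college population.
_POPULATION = {
    "male": {"age": (20.3, 1.2), "height": (1.77, 0.06), "mass": (71.8, 9.5)},
    "female": {"age": (19.8, 1.4), "height": (1.64, 0.06), "mass": (56.0, 8.1)},
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Tunable parameters of the trial simulator.

    Noise defaults: 3 mm marker noise (markerless-capture landmark error is
    typically well below 30 mm) and 0.005 BW force noise.
    """

    marker_rate_hz: float = 100.0
    plate_rate_hz: float = 1000.0
    marker_noise_mm: float = 3.0
    force_noise_bw: float = 0.005
    contact_threshold_n: float = 20.0
    #: fraction of the gait cycle spent in stance; 0.5/0.85 makes the 15 %
    #: double-support ramps of consecutive feet sum exactly to one.
    stance_fraction: float = 0.5 / 0.85
    ramp_fraction: float = 0.15       # of stance duration, each end
    cycle_time_mean_s: float = 1.15
    cycle_time_sd_s: float = 0.04
    cycle_time_bounds_s: tuple[float, float] = (1.05, 1.25)
    vertical_osc_height_frac: float = 0.01   # half-amplitude, of height
    lateral_sway_m: float = 0.02
    ap_accel_peak_g: float = 0.18            # braking/propulsion peak, in g
    step_width_m: float = 0.12
    cop_x_amplitude_mm: float = 8.0
    margin_s: float = 0.15                   # record margin around stances


@dataclass(frozen=True)
class SubjectProfile:
    """Anthropometrics and gait parameters of one simulated walker."""

    subject_id: str
    sex: str
    age: float
    height: float          # m
    mass: float            # kg
    walking_speed: float   # m/s
    foot_length: float     # m
    leg_length: float      # m
    rng_seed: int

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.height <= 0:
            raise ValueError("height must be positive")
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if not 0.5 <= self.walking_speed <= 2.5:
            raise ValueError("walking_speed must lie in [0.5, 2.5] m/s")
        if self.foot_length >= self.height:
            raise ValueError("foot_length must be smaller than height")

    @property
    def body_weight_n(self) -> float:
        """Body weight BW = mass * g, in newtons."""
        return self.mass * G


@dataclass
class MarkerTrajectorySet:
    """Landmark trajectories in the lab frame.

    ``positions`` is frames x 21 x 3 in millimetres; axis order is
    (x, y, z) = (medial-lateral, anterior-posterior, vertical).
    """

    marker_names: tuple[str, ...]
    positions: np.ndarray
    rate_hz: float
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.marker_names) != 21:
            raise ValueError("exactly 21 markers are required")
        if self.positions.ndim != 3 or self.positions.shape[1:] != (21, 3):
            raise ValueError("positions must have shape (frames, 21, 3)")

    @property
    def times_s(self) -> np.ndarray:
        n = self.positions.shape[0]
        return self.start_time_s + np.arange(n) / self.rate_hz

    def index_of(self, name: str) -> int:
        return self.marker_names.index(name)


@dataclass
class ForcePlateRecord:
    """One force plate's record: GRF in newtons, COP in lab-frame mm.

    COP is undefined (NaN) wherever the vertical force is below the
    contact threshold.
    """

    plate_id: int
    side: str
    grf: np.ndarray        # frames x 3, N
    cop: np.ndarray        # frames x 2, mm; NaN when unloaded
    rate_hz: float
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.grf = np.asarray(self.grf, dtype=float)
        self.cop = np.asarray(self.cop, dtype=float)
        if self.plate_id not in (1, 2, 3):
            raise ValueError("plate_id must be 1, 2 or 3")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if self.grf.ndim != 2 or self.grf.shape[1] != 3:
            raise ValueError("grf must have shape (frames, 3)")
        if self.cop.shape != (self.grf.shape[0], 2):
            raise ValueError("cop must have shape (frames, 2)")

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.grf.shape[0]) / self.rate_hz


@dataclass
class GaitTrial:
    """One full gait cycle: markers, three plate records, true events."""

    subject: SubjectProfile
    markers: MarkerTrajectorySet
    plates: list[ForcePlateRecord]
    #: (side, heel_strike_s, toe_off_s) per stance, in R-L-R order
    true_events: list[tuple[str, float, float]]
    trial_id: str = "trial"

    def __post_init__(self) -> None:
        sides = [e[0] for e in self.true_events]
        if sides != ["right", "left", "right"]:
            raise ValueError("events must follow the right-left-right pattern")
        hs = [e[1] for e in self.true_events]
        if not (hs[0] < hs[1] < hs[2]):
            raise ValueError("heel strikes must be strictly ordered")
        for side, t_hs, t_to in self.true_events:
            if not 0.4 <= t_to - t_hs <= 1.0:
                raise ValueError("stance duration must lie in [0.4, 1.0] s")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      n: int, n_sigma: float = 3.0) -> np.ndarray:
    """Rejection-sample N(mean, sd) truncated to mean +- n_sigma*sd."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=max(n - filled, 8))
        keep = draw[np.abs(draw - mean) <= n_sigma * sd]
        take = min(keep.size, n - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


def sample_population(n_male: int, n_female: int, seed: int) -> list[SubjectProfile]:
    """Draw a population of subject profiles from per-sex normal distributions.

    Heights and masses are truncated to +-3 SD; walking speed is uniform on
    [1.1, 1.5] m/s (self-selected comfortable speed).  Deterministic given
    ``seed``.
    """
    if n_male < 0 or n_female < 0:
        raise ValueError("subject counts must be non-negative")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    profiles: list[SubjectProfile] = []
    idx = 0
    for sex, n in (("male", n_male), ("female", n_female)):
        pars = _POPULATION[sex]
        ages = rng.normal(*pars["age"], size=n)
        heights = _truncated_normal(rng, *pars["height"], n)
        masses = _truncated_normal(rng, *pars["mass"], n)
        speeds = rng.uniform(1.1, 1.5, size=n)
        for i in range(n):
            child_seed = int(np.random.SeedSequence((seed, idx)).generate_state(1)[0] % 2**31)
            profiles.append(SubjectProfile(
                subject_id=f"S{idx:04d}",
                sex=sex,
                age=float(ages[i]),
                height=float(heights[i]),
                mass=float(masses[i]),
                walking_speed=float(speeds[i]),
                foot_length=float(0.152 * heights[i]),
                leg_length=float(0.530 * heights[i]),
                rng_seed=child_seed,
            ))
            idx += 1
    return profiles


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _load_ramp(t: np.ndarray, t_hs: float, t_to: float, ramp_s: float) -> np.ndarray:
    """Piecewise-linear load share: 0 outside stance, ramps at both ends."""
    r = np.zeros_like(t)
    inside = (t >= t_hs) & (t <= t_to)
    r[inside] = 1.0
    up = inside & (t < t_hs + ramp_s)
    r[up] = (t[up] - t_hs) / ramp_s
    down = inside & (t > t_to - ramp_s)
    r[down] = (t_to - t[down]) / ramp_s
    return r


class _ComTrajectory:
    """Prescribed CoM motion for one trial (SI units, seconds)."""

    def __init__(self, subject: SubjectProfile, cfg: GeneratorConfig,
                 cycle_time: float, t_mid_first: float) -> None:
        self.v = subject.walking_speed
        self.tc = cycle_time
        self.t_mid = t_mid_first
        self.az_amp = cfg.vertical_osc_height_frac * subject.height  # half-amplitude, m
        self.ax_amp = cfg.lateral_sway_m
        self.z0 = 0.57 * subject.height
        self.w2 = 4.0 * np.pi / cycle_time        # two oscillations per cycle
        self.w1 = 2.0 * np.pi / cycle_time
        self.by = cfg.ap_accel_peak_g * G / self.w2**2

    def position(self, t: np.ndarray) -> np.ndarray:
        th2 = self.w2 * (t - self.t_mid)
        th1 = self.w1 * (t - self.t_mid)
        x = self.ax_amp * np.cos(th1)
        y = self.v * t - self.by * np.sin(th2)
        z = self.z0 + self.az_amp * np.cos(th2)
        return np.stack([x, y, z], axis=-1)

    def acceleration(self, t: np.ndarray) -> np.ndarray:
        th2 = self.w2 * (t - self.t_mid)
        th1 = self.w1 * (t - self.t_mid)
        ax = -self.ax_amp * self.w1**2 * np.cos(th1)
        ay = self.by * self.w2**2 * np.sin(th2)
        az = -self.az_amp * self.w2**2 * np.cos(th2)
        return np.stack([ax, ay, az], axis=-1)


def _foot_trajectory(t: np.ndarray, footfalls_y: Sequence[float],
                     stance_windows: Sequence[tuple[float, float]],
                     x_foot: float, lift_m: float = 0.08,
                     heel_z: float = 0.025) -> np.ndarray:
    """Heel-point path through an alternating sequence of stances and swings.

    ``footfalls_y`` gives the heel y of each footfall; ``stance_windows``
    the matching (HS, TO) times.  Between consecutive stances the heel
    travels with a smoothstep in y and a half-sine lift in z.
    """
    y = np.full_like(t, footfalls_y[0])
    z = np.full_like(t, heel_z)
    for k, (t_hs, t_to) in enumerate(stance_windows):
        in_stance = (t >= t_hs) & (t <= t_to)
        y[in_stance] = footfalls_y[k]
        if k + 1 < len(stance_windows):
            t_next = stance_windows[k + 1][0]
            swing = (t > t_to) & (t < t_next)
            u = (t[swing] - t_to) / (t_next - t_to)
            y[swing] = footfalls_y[k] + (footfalls_y[k + 1] - footfalls_y[k]) * _smoothstep(u)
            z[swing] = heel_z + lift_m * np.sin(np.pi * u)
    # before the first and after the last stance: clamp
    y[t < stance_windows[0][0]] = footfalls_y[0]
    y[t > stance_windows[-1][1]] = footfalls_y[-1]
    x = np.full_like(t, x_foot)
    return np.stack([x, y, z], axis=-1)


def simulate_trial(subject: SubjectProfile, trial_seed: int,
                   config: GeneratorConfig | None = None) -> GaitTrial:
    """Simulate one full gait cycle (three stances, right-left-right).

    Deterministic given ``(subject.rng_seed, trial_seed)``.  Set the noise
    fields of ``config`` to zero for noise-free mechanics.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(np.random.SeedSequence((subject.rng_seed, trial_seed)))

    lo, hi = cfg.cycle_time_bounds_s
    tc_subject = float(np.clip(
        np.random.default_rng(np.random.SeedSequence((subject.rng_seed, 977))).normal(
            cfg.cycle_time_mean_s, cfg.cycle_time_sd_s), lo, hi))
    tc = float(np.clip(tc_subject * rng.normal(1.0, 0.01), lo, hi))

    stance = cfg.stance_fraction * tc
    ramp = cfg.ramp_fraction * stance
    t1 = cfg.margin_s                       # right heel strike 1
    events = [
        ("right", t1, t1 + stance),
        ("left", t1 + tc / 2.0, t1 + tc / 2.0 + stance),
        ("right", t1 + tc, t1 + tc + stance),
    ]
    t_end = events[-1][2] + cfg.margin_s
    com = _ComTrajectory(subject, cfg, tc, t1 + stance / 2.0)

    step_len = subject.walking_speed * tc / 2.0
    stride = 2.0 * step_len
    half_w = cfg.step_width_m / 2.0
    foot_l = subject.foot_length
    # heel placed so the CoM passes over mid-foot at mid-stance
    heel_y = {}
    for side, t_hs, t_to in events:
        t_mid = (t_hs + t_to) / 2.0
        y_mid = subject.walking_speed * t_mid
        heel_y[(side, t_hs)] = y_mid - foot_l / 2.0

    m = subject.mass
    bw = subject.body_weight_n

    # ---- plates (1000 Hz) -------------------------------------------------
    n_plate = int(round(t_end * cfg.plate_rate_hz)) + 1
    tp = np.arange(n_plate) / cfg.plate_rate_hz
    acc = com.acceleration(tp)
    f_total = m * (acc + np.array([0.0, 0.0, G]))       # N, frames x 3

    plates: list[ForcePlateRecord] = []
    plate_ids = (1, 2, 3)
    for pid, (side, t_hs, t_to) in zip(plate_ids, events):
        share = _load_ramp(tp, t_hs, t_to, ramp)
        grf = f_total * share[:, None]
        y0 = heel_y[(side, t_hs)]
        x_f = half_w if side == "right" else -half_w
        u = (tp - t_hs) / (t_to - t_hs)
        s = _smoothstep(u)
        copy_mm = (y0 + foot_l * (0.05 + 0.85 * s)) * 1000.0
        sgn = 1.0 if side == "right" else -1.0
        copx_mm = x_f * 1000.0 + sgn * cfg.cop_x_amplitude_mm * (1.0 - 2.0 * s)
        cop = np.stack([copx_mm, copy_mm], axis=-1)
        # COP only defined while the plate is loaded above threshold
        loaded = grf[:, 2] > cfg.contact_threshold_n
        cop[~loaded] = np.nan
        if cfg.force_noise_bw > 0:
            grf = grf + rng.normal(0.0, cfg.force_noise_bw * bw, size=grf.shape)
        plates.append(ForcePlateRecord(plate_id=pid, side=side, grf=grf,
                                       cop=cop, rate_hz=cfg.plate_rate_hz))

    # ---- markers (100 Hz) -------------------------------------------------
    n_kin = int(round(t_end * cfg.marker_rate_hz)) + 1
    tk = np.arange(n_kin) / cfg.marker_rate_hz
    h = subject.height
    pos = np.zeros((n_kin, 21, 3))
    com_p = com.position(tk)

    def put(name: str, xyz: np.ndarray) -> None:
        pos[:, MARKER_NAMES.index(name), :] = xyz

    pelvis = com_p.copy()
    put("pelvis", pelvis)
    damp = np.array([0.7, 1.0, 1.0])
    c7 = com_p * damp + np.array([0.0, 0.0, 0.26 * h])
    put("c7", c7)
    put("head", com_p * np.array([0.6, 1.0, 1.0]) + np.array([0.0, 0.0, 0.36 * h]))
    sh_half = 0.129 * h
    hip_half = 0.0955 * h
    put("r_shoulder", c7 + np.array([sh_half, 0.0, -0.02 * h]))
    put("l_shoulder", c7 + np.array([-sh_half, 0.0, -0.02 * h]))
    put("r_hip", pelvis + np.array([hip_half, 0.0, -0.03 * h]))
    put("l_hip", pelvis + np.array([-hip_half, 0.0, -0.03 * h]))

    # arms swing in anti-phase with the ipsilateral leg
    chi = 2.0 * np.pi * (tk - t1) / tc
    l_ua, l_fa = 0.186 * h, 0.146 * h
    for side_tag, sgn in (("r", -1.0), ("l", 1.0)):
        phi = 0.25 * sgn * np.cos(chi)
        sh = pos[:, MARKER_NAMES.index(f"{side_tag}_shoulder"), :]
        elbow = sh + np.stack(
            [np.zeros_like(phi), l_ua * np.sin(phi), -l_ua * np.cos(phi)], axis=-1)
        put(f"{side_tag}_elbow", elbow)
        wrist = elbow + np.stack(
            [np.zeros_like(phi), l_fa * np.sin(1.3 * phi), -l_fa * np.cos(1.3 * phi)], axis=-1)
        put(f"{side_tag}_wrist", wrist)
        put(f"{side_tag}_hand", wrist + np.stack(
            [np.zeros_like(phi), 0.05 * h * np.sin(1.3 * phi), -0.05 * h * np.cos(1.3 * phi)],
            axis=-1))

    # feet: right has two recorded stances, left one; pad with the
    # neighbouring (unrecorded) footfalls so swings are defined at the edges
    r_y1 = heel_y[("right", events[0][1])]
    r_y2 = heel_y[("right", events[2][1])]
    l_y = heel_y[("left", events[1][1])]
    right_falls = [r_y1 - stride, r_y1, r_y2]
    right_windows = [(t1 - tc, t1 - tc + stance), (t1, t1 + stance),
                     (t1 + tc, t1 + tc + stance)]
    left_falls = [l_y - stride, l_y, l_y + stride]
    lt = t1 + tc / 2.0
    left_windows = [(lt - tc, lt - tc + stance), (lt, lt + stance),
                    (lt + tc, lt + tc + stance)]

    for side_tag, falls, windows, x_f in (
            ("r", right_falls, right_windows, half_w),
            ("l", left_falls, left_windows, -half_w)):
        heel = _foot_trajectory(tk, falls, windows, x_f)
        put(f"{side_tag}_heel", heel)
        put(f"{side_tag}_toe", heel + np.array([0.0, foot_l, -0.005]))
        ankle = heel + np.array([0.0, 0.05, 0.07])
        put(f"{side_tag}_ankle", ankle)
        hip = pos[:, MARKER_NAMES.index(f"{side_tag}_hip"), :]
        bow = 0.04 + 0.5 * (heel[:, 2] - 0.025)
        knee = 0.5 * (hip + ankle)
        knee = knee + np.stack([np.zeros_like(bow), bow, np.zeros_like(bow)], axis=-1)
        put(f"{side_tag}_knee", knee)

    pos_mm = pos * 1000.0
    if cfg.marker_noise_mm > 0:
        pos_mm = pos_mm + rng.normal(0.0, cfg.marker_noise_mm, size=pos_mm.shape)

    markers = MarkerTrajectorySet(marker_names=MARKER_NAMES, positions=pos_mm,
                                  rate_hz=cfg.marker_rate_hz)
    return GaitTrial(subject=subject, markers=markers, plates=plates,
                     true_events=events, trial_id=f"{subject.subject_id}_t{trial_seed}")


# ---------------------------------------------------------------------------
# CSV round trip

def write_trial(trial: GaitTrial, directory: str | Path) -> dict[str, Path]:
    """Write one trial to ``directory`` as CSV (plus a JSON metadata sidecar).

    Layout: ``markers.csv`` (long format) and ``plate1..3.csv``; COP cells
    are left empty where the plate is unloaded.  Returns a manifest of the
    written paths.  Lossless round trip with :func:`read_trial` to six
    decimal places.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    mk = trial.markers
    n, _, _ = mk.positions.shape
    frames = np.repeat(np.arange(n), 21)
    times = np.repeat(mk.times_s, 21)
    names = list(mk.marker_names) * n
    flat = mk.positions.reshape(n * 21, 3)
    mdf = pd.DataFrame({
        "frame": frames, "time_s": times, "marker": names,
        "x_mm": flat[:, 0], "y_mm": flat[:, 1], "z_mm": flat[:, 2],
    })
    mpath = directory / "markers.csv"
    mdf.to_csv(mpath, index=False, float_format="%.6f")
    manifest["markers"] = mpath

    for plate in trial.plates:
        pdf = pd.DataFrame({
            "frame": np.arange(plate.grf.shape[0]),
            "time_s": plate.times_s,
            "fx_n": plate.grf[:, 0], "fy_n": plate.grf[:, 1], "fz_n": plate.grf[:, 2],
            "copx_mm": plate.cop[:, 0], "copy_mm": plate.cop[:, 1],
        })
        ppath = directory / f"plate{plate.plate_id}.csv"
        pdf.to_csv(ppath, index=False, float_format="%.6f", na_rep="")
        manifest[f"plate{plate.plate_id}"] = ppath

    meta = {
        "subject": dataclasses.asdict(trial.subject),
        "trial_id": trial.trial_id,
        "marker_rate_hz": mk.rate_hz,
        "plate_rate_hz": trial.plates[0].rate_hz,
        "plate_sides": {str(p.plate_id): p.side for p in trial.plates},
        "true_events": [[s, hs, to] for s, hs, to in trial.true_events],
    }
    jpath = directory / "trial.json"
    jpath.write_text(json.dumps(meta, indent=1))
    manifest["meta"] = jpath
    return manifest


def read_trial(directory: str | Path) -> GaitTrial:
    """Read a trial previously written by :func:`write_trial`."""
    directory = Path(directory)
    meta = json.loads((directory / "trial.json").read_text())
    subject = SubjectProfile(**meta["subject"])

    mdf = pd.read_csv(directory / "markers.csv")
    n = int(mdf["frame"].max()) + 1
    pos = mdf[["x_mm", "y_mm", "z_mm"]].to_numpy().reshape(n, 21, 3)
    markers = MarkerTrajectorySet(marker_names=MARKER_NAMES, positions=pos,
                                  rate_hz=float(meta["marker_rate_hz"]))

    plates = []
    for pid in (1, 2, 3):
        pdf = pd.read_csv(directory / f"plate{pid}.csv")
        plates.append(ForcePlateRecord(
            plate_id=pid,
            side=meta["plate_sides"][str(pid)],
            grf=pdf[["fx_n", "fy_n", "fz_n"]].to_numpy(),
            cop=pdf[["copx_mm", "copy_mm"]].to_numpy(),
            rate_hz=float(meta["plate_rate_hz"]),
        ))
    events = [(s, float(hs), float(to)) for s, hs, to in meta["true_events"]]
    return GaitTrial(subject=subject, markers=markers, plates=plates,
                     true_events=events, trial_id=meta["trial_id"])
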