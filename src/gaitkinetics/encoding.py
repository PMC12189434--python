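"""Network input/output encodings.

Two input representations are produced from the 3 x 21 x 100 stance
tensor: a flat 6300-vector for the MLP, and an RGB image for the CNN in
which the x, y and z coordinate planes are spline-interpolated from
21 x 100 (marker x time) up to ``side_px`` x ``side_px`` and mapped to the
R, G and B channels.  Target curves are affinely squeezed into the
sigmoid-friendly band [0.05, 0.95] and mapped back after prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import RectBivariateSpline

from .preprocessing import StanceSample

__all__ = [
    "TargetScaler",
    "flatten_for_mlp",
    "encode_image",
    "compute_channel_ranges",
    "fit_target_scaler",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetScaler:
    """Affine map of a target component onto [0.05, 0.95].

    ``lo``/``hi`` are the training-set min/max widened by a 5% symmetric
    margin, so that sigmoid outputs slightly beyond the observed range
    remain invertible.
    """

    component: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.hi > self.lo:
            raise ValueError("scaler requires hi > lo")

    def transform(self, curves: np.ndarray) -> np.ndarray:
        return 0.05 + 0.9 * (np.asarray(curves, dtype=float) - self.lo) / (self.hi - self.lo)

    def inverse(self, scaled: np.ndarray) -> np.ndarray:
        return self.lo + (np.asarray(scaled, dtype=float) - 0.05) * (self.hi - self.lo) / 0.9

    def to_dict(self) -> dict:
        return {"component": self.component, "lo": self.lo, "hi": self.hi}

    @classmethod
    def from_dict(cls, d: dict) -> "TargetScaler":
        return cls(component=d["component"], lo=float(d["lo"]), hi=float(d["hi"]))


def fit_target_scaler(train_targets: Iterable[np.ndarray], component: str,
                      margin: float = 0.05) -> TargetScaler:
    """Fit a :class:`TargetScaler` on training target curves only."""
    stack = np.concatenate([np.ravel(c) for c in train_targets]) if not isinstance(
        train_targets, np.ndarray) else np.ravel(train_targets)
    if stack.size == 0:
        raise ValueError("no target curves supplied")
    lo, hi = float(stack.min()), float(stack.max())
    span = hi - lo
    if span <= 0:
        raise ValueError(f"degenerate (constant) targets for {component}")
    return TargetScaler(component=component, lo=lo - margin * span, hi=hi + margin * span)


def flatten_for_mlp(sample: StanceSample) -> np.ndarray:
    """Row-major flatten of the 3 x 21 x 100 tensor to a 6300-vector.

    Element 0 is the x coordinate of marker 0 at time index 0; the order is
    (coordinate, marker, time).  Exact inverse: ``vec.reshape(3, 21, 100)``.
    """
    if sample.kin.shape != (3, 21, 100):
        raise ValueError(f"expected kin shape (3, 21, 100), got {sample.kin.shape}")
    return sample.kin.reshape(-1).copy()


def compute_channel_ranges(samples: Sequence[StanceSample]) -> list[tuple[float, float]]:
    """Global per-coordinate (lo, hi) over a training set's kin tensors."""
    if not samples:
        raise ValueError("no samples supplied")
    stack = np.stack([s.kin for s in samples])          # n x 3 x 21 x 100
    return [(float(stack[:, c].min()), float(stack[:, c].max())) for c in range(3)]


def encode_image(sample: StanceSample,
                 channel_ranges: Sequence[tuple[float, float]],
                 side_px: int = 227) -> np.ndarray:
    """Encode a stance sample as a ``side_px`` x ``side_px`` x 3 RGB image.

    Each coordinate's 21 x 100 (marker x time) plane is interpolated with
    cubic splines along both axes up to the image size, then affinely
    mapped from its training-set (lo, hi) range to [0, 255], clipped and
    rounded half-up.  Channels follow (x, y, z) -> (R, G, B).  A channel
    with a degenerate range is set to zero with a warning.
    """
    if sample.kin.shape != (3, 21, 100):
        raise ValueError(f"expected kin shape (3, 21, 100), got {sample.kin.shape}")
    if len(channel_ranges) != 3:
        raise ValueError("channel_ranges must give (lo, hi) per coordinate")
    img = np.zeros((side_px, side_px, 3), dtype=np.uint8)
    rows = np.arange(21, dtype=float)
    cols = np.arange(100, dtype=float)
    rows_out = np.linspace(0.0, 20.0, side_px)
    cols_out = np.linspace(0.0, 99.0, side_px)
    for c in range(3):
        lo, hi = channel_ranges[c]
        if not hi > lo:
            logger.warning("degenerate channel range for coordinate %d; channel zeroed", c)
            continue
        spline = RectBivariateSpline(rows, cols, sample.kin[c], kx=3, ky=3)
        plane = spline(rows_out, cols_out)
        scaled = (plane - lo) / (hi - lo) * 255.0
        # half-up rounding, with a nudge so exact .5 values survive the
        # spline's ~1e-15 arithmetic fuzz
        img[:, :, c] = np.floor(np.clip(scaled, 0.0, 255.0) + 0.5 + 1e-9).astype(np.uint8)
    return img
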