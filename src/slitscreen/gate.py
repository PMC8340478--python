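"""Blue-difference chroma (Cb) statistic and the differential-ReLU skip gate.

The expensive pupil detector only needs to run while the slit band's position
relative to the pupil is uncertain.  Once the band is confirmed inside the
pupil, the count of ROI pixels whose Cb value exceeds the ROI mean
(``num_cb``) is a cheap per-frame proxy: the blue-shifted band inside the
dark pupil produces a small, stable above-mean population, while a band that
has left the ROI leaves only sensor noise, roughly half of which sits above
the mean.  A jump of the normalised count (``nor_num_cb``) past the
calibrated reference by more than a margin ``tau``, rectified through a ReLU,
flips the gate to "out of pupil" and sends the stream back to the detector.

Colour conversion is the full-range ITU-R BT.601 (JPEG) transform: pure gray
maps to Cr = Cb = 128 and the whole 8-bit scale is used.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "YCrCbFrame",
    "GateStatistic",
    "GateCalibration",
    "rgb_to_ycrcb",
    "ycrcb_to_rgb",
    "cb_gate_statistic",
    "normalize_window",
    "relu",
    "differential_relu_gate",
    "CbGate",
    "write_gate_trace",
]

Box = tuple[int, int, int, int]

#: Default decision margin on the normalised above-mean pixel share.
DEFAULT_TAU = 0.05


@dataclass(frozen=True)
class YCrCbFrame:
    """Per-pixel luma and chroma maps on the 0-255 integer scale."""

    y: np.ndarray
    cr: np.ndarray
    cb: np.ndarray

    @property
    def shape(self) -> tuple[int, ...]:
        return self.y.shape


@dataclass
class GateStatistic:
    """Cb quantities of one ROI: the per-pixel map, its mean, the above-mean
    count, the normalised count and (once calibrated) the binary gate."""

    value_cb: np.ndarray
    aver_cb: float
    num_cb: int
    nor_num_cb: float | None = None
    gate: int | None = None


@dataclass(frozen=True)
class GateCalibration:
    """Reference measured on the confirmation frame (known band-in-pupil).

    ``reference_num_cb`` is the raw above-mean count on that frame;
    ``reference_nor`` its normalised share inside the two-element
    reference/current window (0.5 when current equals reference); ``tau`` the
    dimensionless decision margin.
    """

    reference_num_cb: int
    reference_nor: float = 0.5
    tau: float = DEFAULT_TAU

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.reference_num_cb < 0:
            raise ValueError("reference_num_cb must be >= 0")


def _require_rgb8(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 frame, got shape {frame.shape}")
    return frame.astype(float)


def rgb_to_ycrcb(frame: np.ndarray) -> YCrCbFrame:
    """Full-range BT.601 RGB -> YCrCb, rounded and clipped to [0, 255]."""
    f = _require_rgb8(frame)
    r, g, b = f[..., 0], f[..., 1], f[..., 2]
    y = 0.299 * r + 0.587 * g + 0.114 * b
    cb = 128.0 - 0.168736 * r - 0.331264 * g + 0.5 * b
    cr = 128.0 + 0.5 * r - 0.418688 * g - 0.081312 * b
    def q(c: np.ndarray) -> np.ndarray:
        return np.clip(np.rint(c), 0, 255).astype(np.uint8)
    return YCrCbFrame(y=q(y), cr=q(cr), cb=q(cb))


def ycrcb_to_rgb(ycrcb: YCrCbFrame) -> np.ndarray:
    """Inverse full-range BT.601 transform (uint8; ±1 round-trip tolerance)."""
    y = ycrcb.y.astype(float)
    cr = ycrcb.cr.astype(float) - 128.0
    cb = ycrcb.cb.astype(float) - 128.0
    r = y + 1.402 * cr
    g = y - 0.344136 * cb - 0.714136 * cr
    b = y + 1.772 * cb
    out = np.stack([r, g, b], axis=-1)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _validate_roi(shape: tuple[int, ...], roi: Box) -> Box:
    x, y, w, h = (int(v) for v in roi)
    height, width = shape[:2]
    if w <= 0 or h <= 0:
        raise ValueError(f"ROI {roi} has non-positive size")
    if x < 0 or y < 0 or x + w > width or y + h > height:
        raise ValueError(f"ROI {roi} not fully inside frame of shape {shape}")
    if w * h < 4:
        raise ValueError(f"ROI {roi} has fewer than 4 pixels")
    return x, y, w, h


def cb_gate_statistic(ycrcb: YCrCbFrame, roi: Box) -> GateStatistic:
    """Cb statistic over ``roi``: mean and the count strictly above the mean.

    Strict inequality: on a uniform ROI no pixel exceeds the mean, so
    ``num_cb`` is always smaller than the ROI pixel count.
    """
    x, y, w, h = _validate_roi(ycrcb.shape, roi)
    value_cb = ycrcb.cb[y : y + h, x : x + w].astype(float)
    aver_cb = float(value_cb.mean())
    num_cb = int(np.count_nonzero(value_cb > aver_cb))
    return GateStatistic(value_cb=value_cb, aver_cb=aver_cb, num_cb=num_cb)


def normalize_window(num_cb_values: Sequence[float]) -> np.ndarray:
    """Normalise a window of counts to unit sum (share of the window total).

    An all-zero window returns all zeros instead of raising: blank or
    saturated ROIs occur in real streams and must not crash the pipeline.
    """
    values = np.asarray(num_cb_values, dtype=float)
    if values.ndim != 1 or values.size < 1:
        raise ValueError("expected a non-empty 1-D sequence of counts")
    if np.any(values < 0):
        raise ValueError("counts must be non-negative")
    total = values.sum()
    if total == 0:
        return np.zeros_like(values)
    return values / total


def relu(x):
    """Rectifier: x for x > 0, else 0 (scalar or elementwise)."""
    return np.maximum(x, 0)


def differential_relu_gate(current_nor: float, calib: GateCalibration) -> int:
    """Binarise the rectified excess of the current normalised count.

    ``d = relu(current_nor - reference_nor - tau)``; a gate of 0 (exactly zero
    excess) means the band is still in the pupil, 1 means it has left and the
    detector must be consulted again.
    """
    d = relu(float(current_nor) - calib.reference_nor - calib.tau)
    return 0 if d == 0 else 1


class CbGate:
    """Stateless helper binding the Cb statistic to calibration and decision.

    ``calibrate`` measures the reference on a confirmed band-in-pupil frame;
    ``decide`` evaluates a later frame against it over the same frozen ROI.
    """

    def __init__(self, tau: float = DEFAULT_TAU):
        if tau <= 0:
            raise ValueError("tau must be > 0")
        self.tau = tau

    def statistic(self, frame: np.ndarray, roi: Box) -> GateStatistic:
        return cb_gate_statistic(rgb_to_ycrcb(frame), roi)

    def calibrate(self, frame: np.ndarray, roi: Box) -> GateCalibration:
        stat = self.statistic(frame, roi)
        return GateCalibration(reference_num_cb=stat.num_cb, tau=self.tau)

    def decide(
        self, frame: np.ndarray, roi: Box, calib: GateCalibration
    ) -> GateStatistic:
        """Gate one frame: normalise (reference, current) counts and rectify."""
        stat = self.statistic(frame, roi)
        window = normalize_window([calib.reference_num_cb, stat.num_cb])
        stat.nor_num_cb = float(window[1])
        stat.gate = differential_relu_gate(stat.nor_num_cb, calib)
        return stat


def write_gate_trace(path, rows: Iterable[dict]) -> None:
    """Export a gate trace as CSV: frame_index, num_cb, nor_num_cb, gate."""
    fields = ["frame_index", "num_cb", "nor_num_cb", "gate"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields, extrasaction="ignore")
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row.get(k) for k in fields})
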