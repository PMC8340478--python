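"""Detector-skip screening state machine over a slit-lamp video stream.

Per-frame control flow: the detector runs every frame while the band's
position is uncertain (SEARCHING); a hit must be confirmed on the next frame
too (CONFIRMING) to remove one-frame interference; on the confirming hit the
pupil ROI is frozen, the Cb gate is calibrated on that frame and the frame is
classified.  Subsequent frames are handled by the cheap gate alone (GATED):
gate 0 means the band is still in the pupil, so the frozen ROI is cropped and
classified without any detector call.  The gated budget is bounded — after
``gate_window`` detector-free frames (default 5) the stream must revalidate
through the detector — and a gate of 1 (band left the pupil) forces immediate
revalidation without classifying.  Processing is strictly causal: each frame
is handled once, with no lookahead.

The per-eye verdict aggregates per-frame classifications by majority vote,
with ties resolved toward cataract (a screening tool prefers sensitivity);
a video in which no frame was ever classified is `indeterminate`.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Sequence

import numpy as np

from .config import RunConfig
from .detector import Detection, PupilDetector
from .gate import CbGate, GateCalibration

__all__ = [
    "Mode",
    "PipelineState",
    "FrameRecord",
    "VideoResult",
    "step",
    "run_video",
    "crop_roi",
    "write_trace_jsonl",
    "write_trace_csv",
]

Box = tuple[int, int, int, int]
Classifier = Callable[[np.ndarray], np.ndarray]


class Mode(str, Enum):
    SEARCHING = "SEARCHING"
    CONFIRMING = "CONFIRMING"
    GATED = "GATED"
    REVALIDATE = "REVALIDATE"


@dataclass(frozen=True)
class PipelineState:
    """Controller state between frames.

    ``frozen_roi`` and ``calibration`` are set exactly while in GATED mode;
    ``gated_frames_used`` counts detector-free frames since the last
    calibration and never exceeds the configured window.
    """

    mode: Mode = Mode.SEARCHING
    frozen_roi: Box | None = None
    gated_frames_used: int = 0
    calibration: GateCalibration | None = None
    consecutive_hits: int = 0

    def __post_init__(self) -> None:
        if (self.mode is Mode.GATED) != (self.frozen_roi is not None):
            raise ValueError("frozen_roi must be set iff mode is GATED")
        if (self.mode is Mode.GATED) != (self.calibration is not None):
            raise ValueError("calibration must be set iff mode is GATED")


@dataclass
class FrameRecord:
    """Audit record of how one frame was handled.

    A frame is handled by exactly one mechanism: either the detector was
    called or the gate was evaluated, never both.
    """

    frame_index: int
    mode: Mode
    detector_called: bool
    gate_value: int | None = None
    classified: bool = False
    class_probabilities: np.ndarray | None = None
    nor_num_cb: float | None = None
    num_cb: int | None = None

    def __post_init__(self) -> None:
        if self.detector_called and self.gate_value is not None:
            raise ValueError("a frame is handled by the detector or the gate, not both")


@dataclass
class VideoResult:
    """Outcome of one screened video."""

    records: list[FrameRecord]
    classified_frames: int
    detector_calls: int
    verdict: str  # normal | cataract | indeterminate


class PipelineError(RuntimeError):
    """A component failure, annotated with the frame index it occurred on."""


def crop_roi(frame: np.ndarray, box: Box) -> np.ndarray:
    """Exact pixel crop of a 0-based half-open (x, y, w, h) box."""
    x, y, w, h = (int(v) for v in box)
    height, width = frame.shape[:2]
    if w <= 0 or h <= 0 or x < 0 or y < 0 or x + w > width or y + h > height:
        raise ValueError(f"box {box} not within frame of shape {frame.shape}")
    return frame[y : y + h, x : x + w]


def _classify(
    classifier: Classifier | None, frame: np.ndarray, roi: Box
) -> np.ndarray | None:
    if classifier is None:
        return None
    return np.asarray(classifier(crop_roi(frame, roi)), dtype=float)


def step(
    state: PipelineState,
    frame: np.ndarray,
    frame_index: int,
    detector: PupilDetector,
    gate: CbGate,
    classifier: Classifier | None,
    config: RunConfig | None = None,
) -> tuple[PipelineState, FrameRecord]:
    """Advance the state machine by one frame.

    Transition table (entry confirmation length 2, window length 5 under the
    default config):

    * SEARCHING + detection -> CONFIRMING; + none -> SEARCHING.
    * CONFIRMING + detection -> GATED: freeze the ROI from this (second)
      detection, calibrate the gate on this frame, classify it.
      CONFIRMING + none -> SEARCHING.
    * GATED + gate 0 -> classify through the frozen ROI, spend one frame of
      the window; an exhausted window -> REVALIDATE.
      GATED + gate 1 -> REVALIDATE without classifying.
    * REVALIDATE: the detector path again; with ``revalidate_hits == 1`` a
      single hit re-freezes, re-calibrates and classifies immediately, else
      it behaves exactly like SEARCHING.
    """
    config = config or RunConfig()
    mode = state.mode
    try:
        if mode is Mode.GATED:
            assert state.frozen_roi is not None and state.calibration is not None
            stat = gate.decide(frame, state.frozen_roi, state.calibration)
            record = FrameRecord(
                frame_index=frame_index,
                mode=mode,
                detector_called=False,
                gate_value=stat.gate,
                nor_num_cb=stat.nor_num_cb,
                num_cb=stat.num_cb,
            )
            if stat.gate == 0:
                record.class_probabilities = _classify(
                    classifier, frame, state.frozen_roi
                )
                record.classified = True
                used = state.gated_frames_used + 1
                if used >= config.gate_window:
                    new_state = PipelineState(mode=Mode.REVALIDATE)
                else:
                    new_state = replace(state, gated_frames_used=used)
            else:
                new_state = PipelineState(mode=Mode.REVALIDATE)
            return new_state, record

        # Detector path: SEARCHING, CONFIRMING, REVALIDATE.
        detection = detector.detect(frame)
        record = FrameRecord(
            frame_index=frame_index, mode=mode, detector_called=True
        )
        if detection is None:
            return PipelineState(mode=Mode.SEARCHING), record

        hits_needed = (
            config.revalidate_hits if mode is Mode.REVALIDATE else config.confirm_hits
        )
        hits = state.consecutive_hits + 1 if mode is Mode.CONFIRMING else 1
        if hits >= hits_needed:
            roi = detection.box
            calibration = gate.calibrate(frame, roi)
            record.class_probabilities = _classify(classifier, frame, roi)
            record.classified = True
            new_state = PipelineState(
                mode=Mode.GATED,
                frozen_roi=roi,
                calibration=calibration,
                gated_frames_used=0,
            )
        else:
            new_state = PipelineState(mode=Mode.CONFIRMING, consecutive_hits=hits)
        return new_state, record
    except (ValueError, RuntimeError) as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"frame {frame_index}: {exc}") from exc


def _verdict(records: Sequence[FrameRecord]) -> str:
    votes = []
    for rec in records:
        if rec.classified and rec.class_probabilities is not None:
            votes.append(int(np.argmax(rec.class_probabilities)))
    if not votes:
        return "indeterminate"
    # Class index 1 = cataract; ties resolve toward cataract (screening
    # prefers sensitivity over specificity).
    n_cat = sum(votes)
    return "cataract" if n_cat >= len(votes) - n_cat else "normal"


def run_video(
    frames: Sequence[np.ndarray],
    detector: PupilDetector,
    gate: CbGate,
    classifier: Classifier | None,
    config: RunConfig | None = None,
) -> VideoResult:
    """Fold :func:`step` over a whole video and aggregate the verdict."""
    if len(frames) == 0:
        raise ValueError("empty video")
    config = config or RunConfig()
    state = PipelineState()
    records: list[FrameRecord] = []
    for index, frame in enumerate(frames):
        state, record = step(
            state, frame, index, detector, gate, classifier, config
        )
        records.append(record)
    classified = sum(1 for r in records if r.classified)
    calls = sum(1 for r in records if r.detector_called)
    return VideoResult(
        records=records,
        classified_frames=classified,
        detector_calls=calls,
        verdict=_verdict(records),
    )


def _record_dict(rec: FrameRecord) -> dict:
    probs = rec.class_probabilities
    return {
        "frame_index": rec.frame_index,
        "mode": rec.mode.value,
        "detector_called": rec.detector_called,
        "gate_value": rec.gate_value,
        "classified": rec.classified,
        "class_probabilities": None if probs is None else [float(p) for p in probs],
        "num_cb": rec.num_cb,
        "nor_num_cb": rec.nor_num_cb,
    }


def write_trace_jsonl(path, result: VideoResult) -> None:
    """One JSON object per frame record."""
    with open(path, "w") as fh:
        for rec in result.records:
            fh.write(json.dumps(_record_dict(rec)) + "\n")


def write_trace_csv(path, result: VideoResult) -> None:
    fields = [
        "frame_index", "mode", "detector_called", "gate_value",
        "classified", "class_probabilities", "num_cb", "nor_num_cb",
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for rec in result.records:
            writer.writerow(_record_dict(rec))


def write_summary_json(path, result: VideoResult) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "verdict": result.verdict,
                "frames": len(result.records),
                "classified_frames": result.classified_frames,
                "detector_calls": result.detector_calls,
            },
            fh,
            indent=2,
        )
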