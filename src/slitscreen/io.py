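"""Frame I/O: lossless numbered image sequences (canonical) and, where an
imageio plugin supports it, MP4/AVI containers.

Image sequences are the bit-exact path: frames are written as zero-padded
PNG files and read back in numeric filename order.  Container decoding is
codec-dependent and therefore excluded from bit-exact guarantees.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

__all__ = ["read_video", "write_frames", "write_ground_truth"]

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}
_VIDEO_SUFFIXES = {".mp4", ".avi"}


def _numeric_key(path: Path) -> tuple:
    digits = re.findall(r"\d+", path.stem)
    return (int(digits[-1]) if digits else -1, path.name)


def read_video(path) -> list[np.ndarray]:
    """Read frames from a numbered-image directory or an MP4/AVI container."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES),
            key=_numeric_key,
        )
        if not files:
            raise ValueError(f"{path}: no image frames found")
        return [np.asarray(iio.imread(p))[..., :3] for p in files]
    if not path.exists():
        raise FileNotFoundError(f"{path}: no such file or directory")
    if path.suffix.lower() in _VIDEO_SUFFIXES:
        try:
            frames = [np.asarray(f)[..., :3] for f in iio.imiter(path)]
        except Exception as exc:  # plugin/codec availability varies
            raise IOError(f"{path}: cannot decode container ({exc})") from exc
        if not frames:
            raise ValueError(f"{path}: container holds no frames")
        return frames
    raise ValueError(f"{path}: expected a frame directory or MP4/AVI file")


def write_frames(directory, frames: Sequence[np.ndarray], prefix: str = "frame") -> list[Path]:
    """Write frames as zero-padded PNGs; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(max(len(frames) - 1, 0))))
    paths = []
    for i, frame in enumerate(frames):
        p = directory / f"{prefix}_{i:0{width}d}.png"
        iio.imwrite(p, np.asarray(frame, dtype=np.uint8))
        paths.append(p)
    return paths


def write_ground_truth(directory, truth, params=None) -> None:
    """JSON-lines per-frame records plus a per-video metadata JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "ground_truth.jsonl", "w") as fh:
        for i, flag in enumerate(truth.slit_in_pupil):
            fh.write(
                json.dumps(
                    {
                        "frame_index": i,
                        "slit_in_pupil": bool(flag),
                        "pupil_box": list(truth.pupil_box),
                    }
                )
                + "\n"
            )
    meta = {
        "class_label": truth.class_label,
        "protocol": truth.protocol,
        "pupil_box": list(truth.pupil_box),
    }
    if params is not None:
        meta["params"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(params).items()
        }
    with open(directory / "video.json", "w") as fh:
        json.dump(meta, fh, indent=2)
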