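"""Run configuration: gate, controller, detector and verdict knobs.

Serialisable to/from YAML or JSON; precedence when merging is CLI flag >
config file > built-in default.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """All tunables of one screening run.

    ``gate_window`` is the number of detector-free frames the Cb gate may
    cover before detector revalidation (staleness bound); ``confirm_hits``
    the consecutive detector hits required to enter the gated mode from
    scratch; ``revalidate_hits`` the hits required to re-enter it at
    revalidation after an exhausted window.
    """

    tau: float = 0.05
    gate_window: int = 5
    confirm_hits: int = 2
    revalidate_hits: int = 1
    detector_dark_threshold: float = 70.0
    detector_circularity_min: float = 0.6
    detector_band_bridge: int = 25
    classifier_checkpoint: str | None = None
    verdict_rule: str = "majority_ties_cataract"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gate_window < 1:
            raise ValueError("gate_window must be >= 1")
        if self.confirm_hits < 1:
            raise ValueError("confirm_hits must be >= 1")
        if self.revalidate_hits < 1:
            raise ValueError("revalidate_hits must be >= 1")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def merged(self, overrides: dict) -> "RunConfig":
        data = self.to_dict()
        data.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig.from_dict(data)


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(data)
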