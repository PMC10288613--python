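"""Pipeline configuration: one serializable object holding every tunable.

The config round-trips through JSON; unknown keys are rejected so typos in
a config file fail loudly instead of silently running with defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .grids import GridSpec
from .segment3d import SegmentationConfig
from .track4d import SpiculeConfig

__all__ = ["PipelineConfig"]


@dataclass
class ClassifierConfig:
    n_estimators: int = 200
    split_fraction: float = 0.33
    rng_seed: int = 0


@dataclass
class TrackingConfig:
    max_disp_um: float = 2.0
    max_gap_frames: int = 1
    reversibility_window_s: float = 1200.0


@dataclass
class PipelineConfig:
    grid: GridSpec = field(default_factory=GridSpec)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    spicules: SpiculeConfig = field(default_factory=SpiculeConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    seed: int = 0

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PipelineConfig":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            blob = json.loads(Path(source).read_text())
        else:
            blob = json.loads(source)
        return cls._from_dict(blob)

    @classmethod
    def _from_dict(cls, blob: dict) -> "PipelineConfig":
        sections = {
            "grid": GridSpec,
            "segmentation": SegmentationConfig,
            "spicules": SpiculeConfig,
            "classifier": ClassifierConfig,
            "tracking": TrackingConfig,
        }
        kwargs = {}
        for key, val in blob.items():
            if key == "seed":
                kwargs["seed"] = int(val)
                continue
            if key not in sections:
                raise ValueError(f"unknown config section {key!r}")
            klass = sections[key]
            names = {f.name for f in dataclasses.fields(klass)}
            bad = set(val) - names
            if bad:
                raise ValueError(f"unknown key(s) {sorted(bad)} in section {key!r}")
            coerced = {
                k: tuple(v) if isinstance(v, list) else v for k, v in val.items()
            }
            kwargs[key] = klass(**coerced)
        return cls(**kwargs)
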