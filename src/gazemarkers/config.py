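"""YAML configuration for screen geometry, AOIs, detection, and timelines.

All defaults equal the study conditions encoded in :mod:`geometry`,
:mod:`gaze_io`, and :mod:`pupil`; a config file only needs to state what
it overrides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .gaze_io import IVTConfig
from .geometry import ScreenConfig


@dataclass(frozen=True)
class PipelineConfig:
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    ivt: IVTConfig = field(default_factory=IVTConfig)
    validity_threshold: float = 0.8
    filter_alpha: float = 0.05


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a pipeline config; a missing path returns all defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    screen_kwargs = dict(raw.get("screen", {}))
    for key in ("resolution_px", "physical_size_cm"):
        if key in screen_kwargs:
            screen_kwargs[key] = tuple(screen_kwargs[key])
    return PipelineConfig(
        screen=ScreenConfig(**screen_kwargs),
        ivt=IVTConfig(**raw.get("ivt", {})),
        validity_threshold=float(raw.get("validity_threshold", 0.8)),
        filter_alpha=float(raw.get("filter_alpha", 0.05)),
    )
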