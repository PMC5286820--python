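"""Run configuration: thresholds, wave parameters, seed.

One RunConfig flows through the whole pipeline; all randomness derives
from its single seed.  Configs round-trip through YAML
(write -> read -> identical).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class RunConfig:
    fc_cut: float = 1.0
    p_cut: float = 0.05
    q_cut: float = 0.05
    inherent_span: float = 1.0
    moderated: bool = True
    wave_smooth_frac: float = 0.05
    wave_min_window: int = 3
    wave_amplitude_threshold_mm: float = 0.1
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fc_cut",
            "p_cut",
            "q_cut",
            "inherent_span",
            "wave_smooth_frac",
            "wave_amplitude_threshold_mm",
            "alpha",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.wave_min_window < 1:
            raise ValueError("wave_min_window must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kwargs) -> "RunConfig":
        data = asdict(self)
        data.update({k: v for k, v in kwargs.items() if v is not None})
        return RunConfig(**data)
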