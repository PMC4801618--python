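"""Pipeline configuration: one file pins every constant the pipeline uses."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .control import ControlConfig, DecelParams
from .synthetic import SynthParams

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """All tunables in one place, overridable per section from YAML."""

    device: str = "HBS"          # HBS (512 Hz) or BP (1000 Hz)
    b: int = 8                   # feature history window (s)
    channels: tuple = ("O1", "O2")
    schedule: list = field(default_factory=lambda: [["alert", 600], ["drowsy", 600]])
    n_atoms: int = 50            # w, atoms per class
    sparsity: int = 5            # q, OMP budget
    n_iter: int = 30             # KSVD iterations
    method: str = "ksvd"         # or "stacked"
    seed: int = 0
    synth: SynthParams = field(default_factory=SynthParams)
    decel: DecelParams = field(default_factory=DecelParams)
    control: ControlConfig = field(default_factory=ControlConfig)
    own_speed_kmh: float = 95.0  # v11 of the instrumented car
    scenario_v21_kmh: float = 100.0
    scenario_gap_m: float = 10.5

    @property
    def fs(self) -> float:
        return 512.0 if self.device == "HBS" else 1000.0

    def validate(self):
        if self.device not in ("HBS", "BP"):
            raise ValueError(f"device must be HBS or BP, got {self.device!r}")
        if self.b < 0:
            raise ValueError("b must be >= 0")
        if self.n_atoms <= 0 or self.sparsity < 0 or self.n_iter < 1:
            raise ValueError("n_atoms > 0, sparsity >= 0, n_iter >= 1 required")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path=None, **overrides) -> PipelineConfig:
    """Read a YAML config (sections: pipeline/synth/decel/control) with overrides."""
    cfg = PipelineConfig()
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, val in (raw.get("pipeline") or {}).items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown pipeline option {key!r}")
            setattr(cfg, key, val)
        if "synth" in raw:
            cfg.synth = SynthParams(**raw["synth"])
        if "decel" in raw:
            cfg.decel = DecelParams(**raw["decel"])
        if "control" in raw:
            cfg.control = ControlConfig(**raw["control"])
    for key, val in overrides.items():
        if val is not None:
            setattr(cfg, key, val)
    cfg.channels = tuple(cfg.channels)
    return cfg.validate()
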