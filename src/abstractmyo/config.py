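"""Device configuration: the single document a remote server could push.

A :class:`DeviceConfig` bundles everything the prosthesis controller can be
reconfigured with over the air — filter settings, MAV window and gains,
task-space geometry, decision boundaries and the grasp map — plus the data
streaming switches.  Remote reconfiguration is modeled as supplying a new
config with a timestamp; only events after that timestamp are affected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .decoder import DecisionBoundaries, GraspMap, TaskSpaceConfig
from .emg import FilterSpec
from .errors import ConfigurationError

__all__ = ["DeviceConfig", "load_config", "save_config"]


@dataclass
class DeviceConfig:
    filter: FilterSpec = field(default_factory=FilterSpec)
    window_ms: float = 150.0
    step_ms: float = 50.0
    gain: tuple[float, float] = (1.0, 1.0)
    m_cap: float = 1.5
    task_space: TaskSpaceConfig = field(default_factory=TaskSpaceConfig)
    boundaries: DecisionBoundaries = field(default_factory=DecisionBoundaries)
    target2_grasp: str = "tripod"
    data_streaming: bool = True
    mav_streaming: bool = True

    def __post_init__(self) -> None:
        if self.target2_grasp not in ("tripod", "pinch"):
            raise ConfigurationError("target2_grasp must be tripod or pinch")
        if not (self.window_ms >= self.step_ms > 0):
            raise ConfigurationError("require window_ms >= step_ms > 0")

    def grasp_map(self) -> GraspMap:
        return GraspMap().with_target2(self.target2_grasp)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gain"] = list(self.gain)
        d["task_space"]["target_angles"] = list(self.task_space.target_angles)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DeviceConfig":
        d = dict(d)
        try:
            if "filter" in d:
                d["filter"] = FilterSpec(**d["filter"])
            if "task_space" in d:
                ts = dict(d["task_space"])
                ts["target_angles"] = tuple(ts.get("target_angles", (11.25, 33.75, 56.25, 78.75)))
                d["task_space"] = TaskSpaceConfig(**ts)
            if "boundaries" in d:
                d["boundaries"] = DecisionBoundaries(**d["boundaries"])
            if "gain" in d:
                d["gain"] = tuple(d["gain"])
            return cls(**d)
        except TypeError as exc:
            raise ConfigurationError(f"bad device config: {exc}") from exc


def load_config(path: str | Path) -> DeviceConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return DeviceConfig.from_dict(data)


def save_config(cfg: DeviceConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    return path
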