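"""Run configuration for the calibrate-then-monitor workflow (YAML)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .diagnostics import RedundancyGroup
from .multiblock import BlockSpec

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything one monitoring run needs, loadable from a YAML file.

    ``blocks`` maps block name -> {"variables": [...], "components": k} (or
    a bare variable list, taking the default component count).  Calibration
    and monitoring windows are closed-open ``[start, end)`` and the
    calibration window must precede the monitoring window.
    """

    input: str | None = None
    timestamp_column: str | int = 0
    calibration_start: str | None = None
    calibration_end: str | None = None
    monitoring_start: str | None = None
    monitoring_end: str | None = None
    blocks: Mapping[str, Any] = field(default_factory=dict)
    individual_variables: list[str] | None = None
    block_components: int = 3
    super_components: int = 4
    alpha: float = 0.05
    warning_fraction: float = 0.8
    corr_threshold: float = 0.7
    missing_threshold: float = 0.10
    redundancy_groups: Mapping[str, list[str]] = field(default_factory=dict)
    output: str = "."
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        cs, ce = self.calibration_start, self.calibration_end
        ms, me = self.monitoring_start, self.monitoring_end
        if cs and ce and pd.Timestamp(cs) >= pd.Timestamp(ce):
            raise ValueError("empty calibration window")
        if ms and me and pd.Timestamp(ms) >= pd.Timestamp(me):
            raise ValueError("empty monitoring window")
        if ce and ms and pd.Timestamp(ms) < pd.Timestamp(ce):
            raise ValueError("calibration window must precede monitoring window")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["blocks"] = {k: dict(v) if isinstance(v, Mapping) else list(v)
                       for k, v in (d["blocks"] or {}).items()}
        d["redundancy_groups"] = {k: list(v)
                                  for k, v in (d["redundancy_groups"] or {}).items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def block_spec(self) -> BlockSpec | None:
        if not self.blocks:
            return None
        blocks = {}
        components: dict[str, int] = {}
        for name, entry in self.blocks.items():
            if isinstance(entry, Mapping):
                blocks[name] = list(entry["variables"])
                components[name] = int(entry.get("components", self.block_components))
            else:
                blocks[name] = list(entry)
                components[name] = self.block_components
        return BlockSpec(blocks=blocks, block_components=components,
                         individual_variables=self.individual_variables)

    def redundancy(self) -> list[RedundancyGroup]:
        return [RedundancyGroup(name, members)
                for name, members in (self.redundancy_groups or {}).items()]
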