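"""Run configuration: thresholds, paths, and reproducibility settings."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from . import outcome, selection

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All knobs of a scoring run in one validated object.

    Thresholds default to the values anchored by the GLDC analysis; paths
    are optional and checked for existence when given.
    """

    registry_path: str | None = None
    ddg_table: str | None = None
    consurf_table: str | None = None
    annotation_table: str | None = None
    structure_path: str | None = None

    leader_length: int = 35
    ddg_destabilizing_max: float = -1.5
    ddg_very_destabilizing_max: float = -5.0
    severe_wmms_threshold: float = selection.SEVERE_WMMS_THRESHOLD
    cos_cutoff: float = outcome.COS_CUTOFF
    wmms_lower: float = outcome.WMMS_LOWER
    wmms_attenuated_upper: float = 1.3
    wmms_upper: float = outcome.WMMS_UPPER
    rounding_decimals: int = 2
    seed: int = 0

    path_fields: tuple[str, ...] = field(
        default=(
            "registry_path",
            "ddg_table",
            "consurf_table",
            "annotation_table",
            "structure_path",
        ),
        repr=False,
    )

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v}")
        if self.leader_length < 0:
            raise ValueError("leader_length must be >= 0")
        if self.rounding_decimals < 0:
            raise ValueError("rounding_decimals must be >= 0")
        for name in self.path_fields:
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)} - {"path_fields"}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if f.name != "path_fields"
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
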