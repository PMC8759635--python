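"""Run configuration: defaults, YAML overrides, round-tripping."""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .flow import FlowParams
from .frames import ValidationError
from .segment import SegmentationParams

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Effective parameter set of one segmentation run.

    Every field has a default; a YAML config file may override any subset
    (keys ``input``, ``outdir``, ``flow``, ``segment``, ``eval``,
    ``log_level``), and CLI flags override the file. The effective set
    round-trips through :meth:`to_dict`/:meth:`from_dict` unchanged.
    """

    input: str | None = None
    outdir: str | None = None
    flow: FlowParams = field(default_factory=FlowParams)
    segment: SegmentationParams = field(default_factory=SegmentationParams)
    truth: str | None = None
    iou_match_threshold: float = 0.5
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "input": self.input,
            "outdir": self.outdir,
            "flow": asdict(self.flow),
            "segment": asdict(self.segment),
            "eval": {
                "truth": self.truth,
                "iou_match_threshold": self.iou_match_threshold,
            },
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {"input", "outdir", "flow", "segment", "eval", "log_level"}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        flow = FlowParams(**data.get("flow", {}))
        segment = SegmentationParams(**data.get("segment", {}))
        ev = data.get("eval") or {}
        return cls(
            input=data.get("input"),
            outdir=data.get("outdir"),
            flow=flow,
            segment=segment,
            truth=ev.get("truth"),
            iou_match_threshold=ev.get("iou_match_threshold", 0.5),
            log_level=data.get("log_level", "INFO"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"config {path} must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def override(self, **kwargs) -> "RunConfig":
        """Return a copy with non-None keyword overrides applied."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates)
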