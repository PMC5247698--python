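"""Pipeline configuration: a single flat, typed, JSON round-trippable record."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .morphometry import HEXAGON_CONVENTIONS
from .segmentation import DEFAULT_N_FIELDS, SegmentationParams
from .stats import BRACKET_EDGES, DEFAULT_CUTOFFS_U_L

__all__ = ["PipelineConfig", "load_config", "save_config", "config_hash"]


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline settings.

    ``bracket_edges`` is config-locked to the (5, 10, 20)% mFPA brackets the
    analysis is defined over; serialisation keeps it so a config file is
    self-describing, but other values are rejected.
    """

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    n_fields: int = DEFAULT_N_FIELDS
    hexagon_convention: str = "circumradius"
    bracket_edges: tuple[float, float, float] = BRACKET_EDGES
    cutoffs_u_l: tuple[float, ...] = DEFAULT_CUTOFFS_U_L
    seed: int = 0
    um_per_px: float = 0.5
    n_patients: int = 20
    field_px: int = 512
    artifact_density: float = 0.0

    def validate(self) -> None:
        self.segmentation.validate()
        if self.n_fields < 1:
            raise ValueError("n_fields must be at least 1")
        if self.hexagon_convention not in HEXAGON_CONVENTIONS:
            raise ValueError(
                f"hexagon_convention must be one of {HEXAGON_CONVENTIONS}"
            )
        if tuple(self.bracket_edges) != BRACKET_EDGES:
            raise ValueError(f"bracket_edges is locked to {BRACKET_EDGES}")
        if not self.cutoffs_u_l or any(c <= 0 for c in self.cutoffs_u_l):
            raise ValueError("cutoffs_u_l must be positive")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if self.n_patients < 10:
            raise ValueError("n_patients must be at least 10 for the cohort report")
        if self.field_px < 64:
            raise ValueError("field_px must be at least 64")
        if self.artifact_density < 0:
            raise ValueError("artifact_density must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bracket_edges"] = list(self.bracket_edges)
        d["cutoffs_u_l"] = list(self.cutoffs_u_l)
        d["segmentation"]["channel_thresholds"] = list(
            self.segmentation.channel_thresholds
        )
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        seg_fields = {f.name for f in dataclasses.fields(SegmentationParams)}
        top_fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - top_fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "segmentation" in data:
            seg = dict(data["segmentation"])
            unknown = set(seg) - seg_fields
            if unknown:
                raise ValueError(f"unknown segmentation keys: {sorted(unknown)}")
            if "channel_thresholds" in seg:
                seg["channel_thresholds"] = tuple(seg["channel_thresholds"])
            data["segmentation"] = SegmentationParams(**seg)
        for key in ("bracket_edges", "cutoffs_u_l"):
            if key in data:
                data[key] = tuple(data[key])
        config = cls(**data)
        config.validate()
        return config


def load_config(path: str | Path) -> PipelineConfig:
    """Load a JSON config file; an empty file means all defaults."""
    path = Path(path)
    text = path.read_text().strip()
    data = json.loads(text) if text else {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must contain a JSON object")
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    config.validate()
    Path(path).write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n")


def config_hash(config: PipelineConfig) -> str:
    """Stable sha256 over the canonical JSON form of a config."""
    canonical = json.dumps(config.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
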