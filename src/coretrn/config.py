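"""Pipeline configuration: defaults for every threshold, loadable from a
YAML file with unknown keys rejected; CLI flags override file values."""

from __future__ import annotations

from dataclasses import dataclass, fields

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    fold_threshold: float = 2.0
    p_threshold: float = 0.05
    signature_p_threshold: float = 0.03
    edge_threshold: float = 0.05
    top_k: int = 20
    prior: float = 1e-5
    regularization: float | None = None
    keywords: tuple[str, ...] = ("differentiation", "development", "transformation")
    cell_term: str = "monocyte"
    detection_alpha: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fold_threshold <= 0 or self.edge_threshold <= 0:
            raise ValueError("fold and edge thresholds must be positive")
        for p in (self.p_threshold, self.signature_p_threshold, self.detection_alpha):
            if not 0 < p <= 1:
                raise ValueError("p-value thresholds must lie in (0, 1]")
        if self.top_k <= 0:
            raise ValueError("top_k must be positive")
        if not 0 <= self.prior < 1:
            raise ValueError("prior must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "keywords" in data and data["keywords"] is not None:
            data["keywords"] = tuple(data["keywords"])
        return cls(**data)

    def override(self, **kwargs) -> "PipelineConfig":
        clean = {k: v for k, v in kwargs.items() if v is not None}
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data.update(clean)
        return PipelineConfig(**data)
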