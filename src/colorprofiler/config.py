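"""Run configuration shared by the command-line workflow.

Defaults follow the study conditions the pipeline was designed around:
a CIEDE2000 merge threshold of 2 (the conventional just-noticeable
difference), a 0.1 % abundance filter, black-background threshold 30,
JPEG export quality 90, average linkage and a 10-group dendrogram cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    delta_e_threshold: float = 2.0
    min_pct: float = 0.1
    black_threshold: int = 30
    min_area: int = 0
    jpeg_quality: int = 90
    linkage: str = "average"
    cluster_k: int = 10
    kmeans_K: int = 20
    rng_seed: int = 0
    reference_white: tuple[int, int, int] = (255, 255, 255)

    def __post_init__(self) -> None:
        if self.delta_e_threshold <= 0 or self.min_pct < 0 or not (0 <= self.black_threshold <= 255):
            raise ValueError("invalid threshold in run configuration")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "reference_white" in data:
            data["reference_white"] = tuple(data["reference_white"])
        return cls(**data)

    def metadata_lines(self) -> list[str]:
        from . import __version__

        lines = [f"# colorprofiler_version: {__version__}"]
        for k, v in asdict(self).items():
            lines.append(f"# {k}: {v}")
        return lines
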