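"""Pipeline configuration with YAML loading.

Keys mirror the analysis stages::

    background:
      k_sd: 2.0          # threshold = neg mean + k_sd * neg SD
    detect:
      min_fraction: 0.5  # fraction of samples that must exceed background
    genorm:
      v_cutoff: 0.15     # pairwise-variation cutoff for n reference genes
      min_genes: 2
    zscore:
      log2: false        # score log2 values instead of normalized counts
    stats:
      alpha: 0.05
      alpha_normality: 0.05
      welch: false       # Welch instead of Student t on the parametric branch
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    background_k_sd: float = 2.0
    detect_min_fraction: float = 0.5
    genorm_v_cutoff: float = 0.15
    genorm_min_genes: int = 2
    zscore_log2: bool = False
    alpha: float = 0.05
    alpha_normality: float = 0.05
    welch: bool = False

    def __post_init__(self) -> None:
        if self.background_k_sd < 0:
            raise ValueError("background.k_sd must be >= 0")
        if not 0 < self.detect_min_fraction <= 1:
            raise ValueError("detect.min_fraction must be in (0, 1]")
        if self.genorm_v_cutoff <= 0:
            raise ValueError("genorm.v_cutoff must be > 0")
        if self.genorm_min_genes < 2:
            raise ValueError("genorm.min_genes must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: dict) -> "PipelineConfig":
        known = {
            ("background", "k_sd"): "background_k_sd",
            ("detect", "min_fraction"): "detect_min_fraction",
            ("genorm", "v_cutoff"): "genorm_v_cutoff",
            ("genorm", "min_genes"): "genorm_min_genes",
            ("zscore", "log2"): "zscore_log2",
            ("stats", "alpha"): "alpha",
            ("stats", "alpha_normality"): "alpha_normality",
            ("stats", "welch"): "welch",
        }
        kwargs = {}
        bad: list[str] = []
        for section, content in raw.items():
            if not isinstance(content, dict):
                bad.append(str(section))
                continue
            for key, value in content.items():
                attr = known.get((section, key))
                if attr is None:
                    bad.append(f"{section}.{key}")
                else:
                    kwargs[attr] = value
        if bad:
            raise ValueError(f"unknown config keys: {bad}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)
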